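"""Synthetic fixtures with known ground truth for every pipeline stage.

Two generators. ``simulate_alignment`` emits an encoded 16-symbol sequence
with planted change-points and per-class compositions — the statistical
structure the segmentation model assumes (piecewise-homogeneous symbol
composition, matches concentrated on {a, f, k, p}). ``simulate_reads`` builds
a toy annotated genome and samples paired-end fragments (default 300 +/- 30 nt
fragments, 72 nt mates, mirroring a 300 bp size selection with ~70-75 nt
paired-end sequencing) from transcripts of the three structural kinds the
intergenic filter must distinguish: intergenic-specific, polycistronic, and
UTR read-through. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Feature, GenomicInterval, build_intergenic_features, write_annotation
from .encode import MATCH_INDICES, EncodedAlignment
from .errors import ContentError
from .model import ClassComposition, Segmentation
from .rnaseq import ReadPairAlignment

MISMATCH_INDICES = np.array([i for i in range(16) if i not in set(int(j) for j in MATCH_INDICES)])


# ---------------------------------------------------------------------------
# encoded-alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class ClassSpec:
    """Emission law of one planted class: match probability plus a mismatch
    distribution over the 12 non-match symbols (uniform by default)."""

    match_p: float
    mismatch_probs: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.match_p <= 1.0:
            raise ContentError("match probability must be in [0, 1]")
        if self.mismatch_probs is None:
            self.mismatch_probs = np.full(12, 1.0 / 12)
        else:
            self.mismatch_probs = np.asarray(self.mismatch_probs, dtype=float)
            if self.mismatch_probs.shape != (12,) or abs(self.mismatch_probs.sum() - 1) > 1e-9:
                raise ContentError("mismatch distribution must be a 12-simplex")

    def theta(self) -> np.ndarray:
        out = np.zeros(16)
        out[MATCH_INDICES] = self.match_p / 4.0
        out[MISMATCH_INDICES] = (1.0 - self.match_p) * self.mismatch_probs
        return out


@dataclass
class AlignmentSimSpec:
    """Planted segmentation: ``segments`` is a list of (length, class_id)."""

    segments: list
    classes: dict                      # class_id -> ClassSpec
    indel_rate: float = 0.0            # probability of a coordinate gap after a symbol
    block_breaks: list = field(default_factory=list)  # '#' after this many symbols
    seed: int = 0

    def __post_init__(self):
        if not self.segments:
            raise ContentError("need at least one planted segment")
        for length, cid in self.segments:
            if length < 1:
                raise ContentError("segment lengths must be >= 1")
            if cid not in self.classes:
                raise ContentError(f"segment references unknown class {cid}")
        total = sum(length for length, _ in self.segments)
        for br in self.block_breaks:
            if not 0 < br < total:
                raise ContentError("block breaks must be strictly inside the sequence")


def simulate_alignment(spec: AlignmentSimSpec):
    """Generate an encoded alignment plus its ground truth.

    Returns ``(encoded, truth_segmentation, truth_compositions)`` where
    compositions are keyed by planted class id (1-based order of ``classes``).
    Indels appear as coordinate gaps (reference positions consumed without an
    emitted symbol), not as symbols — matching how encoding drops gapped
    columns.
    """
    rng = np.random.default_rng(spec.seed)
    class_ids = sorted(spec.classes)
    symbols = []
    for length, cid in spec.segments:
        cls = spec.classes[cid]
        is_match = rng.random(length) < cls.match_p
        out = np.empty(length, dtype=np.int64)
        out[is_match] = rng.choice(MATCH_INDICES, size=int(is_match.sum()))
        n_mm = int((~is_match).sum())
        out[~is_match] = rng.choice(MISMATCH_INDICES, size=n_mm, p=cls.mismatch_probs)
        symbols.append(out)
    x = np.concatenate(symbols)
    n = x.size

    # reference coordinates with occasional gaps (excluded indel columns)
    if spec.indel_rate > 0:
        steps = 1 + rng.geometric(1.0 - spec.indel_rate, size=n) - 1
        steps[0] = 1
        coords = np.cumsum(steps)
    else:
        coords = np.arange(1, n + 1)

    breaks = sorted(set(spec.block_breaks))
    block_index = np.zeros(n, dtype=np.int64)
    for br in breaks:
        block_index[br:] += 1

    seq_chars = []
    prev_block = 0
    for i in range(n):
        if block_index[i] != prev_block:
            seq_chars.append("#")
            prev_block = block_index[i]
        seq_chars.append("abcdefghijklmnop"[x[i]])
    encoded = EncodedAlignment(
        ref_id="synthetic",
        symbols="".join(seq_chars),
        coords=coords.astype(np.int64),
        block_index=block_index,
    )

    seg_ends = np.cumsum([length for length, _ in spec.segments])
    cuts = sorted(set(seg_ends[:-1].tolist()) | set(breaks))
    planted_class = np.empty(n, dtype=np.int64)
    prev = 0
    for (length, cid), end in zip(spec.segments, seg_ends):
        planted_class[prev:end] = class_ids.index(cid) + 1
        prev = end
    labels = [int(planted_class[s]) for s in [0] + cuts]
    truth_seg = Segmentation(change_points=cuts, labels=labels)
    comps = []
    for idx, cid in enumerate(class_ids, start=1):
        comps.append(
            ClassComposition(
                theta=spec.classes[cid].theta(),
                mixture_proportion=float((planted_class == idx).mean()),
            )
        )
    return encoded, truth_seg, comps


# ---------------------------------------------------------------------------
# paired-end read simulation
# ---------------------------------------------------------------------------

TRANSCRIPT_KINDS = ("intergenic_specific", "polycistronic", "utr_readthrough")


@dataclass
class Transcript:
    start: int
    end: int
    kind: str
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in TRANSCRIPT_KINDS:
            raise ContentError(f"unknown transcript kind {self.kind!r}")
        if self.weight <= 0:
            raise ContentError("transcript weight must be positive")
        if self.start > self.end:
            raise ContentError("invalid transcript interval")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptomeSimSpec:
    genome_length: int
    genes: list                    # (start, end) 1-based inclusive CDS intervals
    transcripts: list              # Transcript objects
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    read_length: int = 72
    n_pairs: int = 1000
    min_pairs: int = 10            # threshold used when deriving truth verdicts
    base_quality: int = 40
    seed: int = 0

    def __post_init__(self):
        for t in self.transcripts:
            if t.end > self.genome_length:
                raise ContentError("transcript extends past the genome end")
        for s, e in self.genes:
            if not 1 <= s <= e <= self.genome_length:
                raise ContentError("gene interval outside the genome")


@dataclass
class SimulatedReads:
    spec: TranscriptomeSimSpec
    genome: str
    features: list                 # CDS features + derived intergenic features
    pairs: list                    # (SeqRecord, SeqRecord) mates
    alignments: list               # true ReadPairAlignment per pair
    truth: pd.DataFrame            # per intergenic feature: expected verdict
    resampled_fragments: int       # fragments redrawn because they outsized a transcript

    # -- writers --------------------------------------------------------

    def write_genome_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(">genome\n")
            for i in range(0, len(self.genome), 70):
                fh.write(self.genome[i : i + 70] + "\n")

    def write_gff(self, path) -> None:
        write_annotation(self.features, path,
                         genome_length=self.spec.genome_length, ref_id="genome")

    def write_fastq(self, path1, path2) -> None:
        from Bio import SeqIO

        SeqIO.write((p[0] for p in self.pairs), str(path1), "fastq")
        SeqIO.write((p[1] for p in self.pairs), str(path2), "fastq")

    def write_sam(self, path) -> None:
        """True alignments as a minimal coordinate-correct SAM file."""
        rl = self.spec.read_length
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            fh.write(f"@SQ\tSN:genome\tLN:{self.spec.genome_length}\n")
            qual = chr(self.spec.base_quality + 33) * rl
            for (r1, r2), aln in zip(self.pairs, self.alignments):
                tlen = aln.fragment.length
                fh.write(
                    f"{aln.pair_id}\t99\tgenome\t{aln.mate1.start}\t60\t{rl}M\t=\t"
                    f"{aln.mate2.start}\t{tlen}\t{str(r1.seq)}\t{qual}\n"
                )
                fh.write(
                    f"{aln.pair_id}\t147\tgenome\t{aln.mate2.start}\t60\t{rl}M\t=\t"
                    f"{aln.mate1.start}\t{-tlen}\t{str(Seq(str(r2.seq)).reverse_complement())}\t{qual}\n"
                )

    def write_truth_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_reads(spec: TranscriptomeSimSpec) -> SimulatedReads:
    """Sample paired-end fragments from the planted transcripts.

    Fragments are drawn from transcripts proportionally to weight, positions
    uniform within the transcript; mates are the first and last
    ``read_length`` bases of the fragment (mate 2 on the reverse strand).
    Fragments longer than their transcript are redrawn (counted). Truth
    verdicts per intergenic gap follow the transcript kinds: any sampled
    non-intergenic-specific transcript overlapping a gap means read-through;
    otherwise ``min_pairs`` sampled intergenic-specific pairs mean specific.
    """
    rng = np.random.default_rng(spec.seed)
    genome = "".join(rng.choice(list("ACGT"), size=spec.genome_length))
    cds = [
        Feature(GenomicInterval("genome", s, e, "+"), "CDS", f"gene-{i + 1}")
        for i, (s, e) in enumerate(sorted(spec.genes))
    ]
    features = cds + build_intergenic_features(cds, spec.genome_length)
    features.sort(key=lambda f: f.interval.start)

    pairs, alignments = [], []
    per_transcript_pairs = np.zeros(len(spec.transcripts), dtype=int)
    resampled = 0
    if spec.transcripts and spec.n_pairs > 0:
        weights = np.array([t.weight for t in spec.transcripts], dtype=float)
        weights /= weights.sum()
        rl = spec.read_length
        qual = [spec.base_quality] * rl
        for idx in range(spec.n_pairs):
            for _attempt in range(100):
                ti = int(rng.choice(len(spec.transcripts), p=weights))
                t = spec.transcripts[ti]
                frag = int(round(rng.normal(spec.fragment_mean, spec.fragment_sd)))
                frag = max(frag, rl)
                if frag <= t.length:
                    break
                resampled += 1
            else:
                frag = t.length
            start = int(rng.integers(t.start, t.end - frag + 2))
            end = start + frag - 1
            per_transcript_pairs[ti] += 1
            m1 = GenomicInterval("genome", start, start + rl - 1)
            m2 = GenomicInterval("genome", end - rl + 1, end)
            name = f"pair-{idx + 1}"
            seq1 = genome[m1.start - 1 : m1.end]
            seq2 = str(Seq(genome[m2.start - 1 : m2.end]).reverse_complement())
            r1 = SeqRecord(Seq(seq1), id=name, description="")
            r2 = SeqRecord(Seq(seq2), id=name, description="")
            r1.letter_annotations["phred_quality"] = qual
            r2.letter_annotations["phred_quality"] = qual
            pairs.append((r1, r2))
            alignments.append(ReadPairAlignment(name, m1, m2, mapq=60))

    rows = []
    for feat in features:
        if feat.role != "intergenic":
            continue
        gap = feat.interval
        sampled_kinds = set()
        n_is_pairs = 0
        for ti, t in enumerate(spec.transcripts):
            if per_transcript_pairs[ti] == 0:
                continue
            if gap.overlaps(GenomicInterval("genome", t.start, t.end)):
                sampled_kinds.add(t.kind)
                if t.kind == "intergenic_specific":
                    n_is_pairs += int(per_transcript_pairs[ti])
        if not sampled_kinds:
            verdict = "untranscribed"
        elif sampled_kinds - {"intergenic_specific"}:
            verdict = "readthrough"
        elif n_is_pairs >= spec.min_pairs:
            verdict = "specific"
        else:
            verdict = "untranscribed"
        rows.append(
            {
                "feature_id": feat.id,
                "start": gap.start,
                "end": gap.end,
                "expected_verdict": verdict,
            }
        )
    truth = pd.DataFrame(rows, columns=["feature_id", "start", "end", "expected_verdict"])
    return SimulatedReads(
        spec=spec,
        genome=genome,
        features=features,
        pairs=pairs,
        alignments=alignments,
        truth=truth,
        resampled_fragments=resampled,
    )
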