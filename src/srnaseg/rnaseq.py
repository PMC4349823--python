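"""RNA-Seq arm: quality filtering, feature counting, intergenic specificity.

The discriminating filter is positional: an intergenic region is called
*specifically transcribed* only when enough read pairs map with both mates
fully inside the region and no pair straddles into a flanking gene. A single
straddling pair (one mate in the region, the other touching a flanking CDS) is
evidence of read-through — UTR or polycistronic transcription — and flips the
verdict. Strand is ignored throughout (library preparation is assumed
unstranded); only mate spans matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam
from Bio import SeqIO

from .annotate import Feature, GenomicInterval
from .errors import ContentError

VERDICTS = ("specific", "readthrough", "untranscribed")


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    pairs_in: int = 0
    pairs_out: int = 0
    reads_trimmed: int = 0

    @property
    def pairs_dropped(self) -> int:
        return self.pairs_in - self.pairs_out


def trimmed_length(quals, q_min: int) -> int:
    """Length after removing all trailing bases with quality < q_min."""
    n = len(quals)
    while n > 0 and quals[n - 1] < q_min:
        n -= 1
    return n


def quality_filter(pairs, q_min: int = 30, len_min: int = 40):
    """Trim and filter paired reads.

    ``pairs`` iterates over ``(record1, record2)`` Bio.SeqRecord tuples with
    phred qualities. Each read is trimmed from the 3' end while its terminal
    base quality is below ``q_min``; a read shorter than ``len_min`` after
    trimming discards the whole pair. Returns ``(surviving_pairs, report)``.
    """
    kept = []
    report = FilterReport()
    for r1, r2 in pairs:
        report.pairs_in += 1
        trimmed = []
        ok = True
        for rec in (r1, r2):
            quals = rec.letter_annotations.get("phred_quality")
            if quals is None or len(quals) != len(rec.seq):
                raise ContentError(
                    f"record {rec.id}: sequence and quality lengths differ"
                )
            n = trimmed_length(quals, q_min)
            if n < len_min:
                ok = False
                break
            if n < len(rec.seq):
                report.reads_trimmed += 1
                rec = rec[:n]
            trimmed.append(rec)
        if ok:
            report.pairs_out += 1
            kept.append(tuple(trimmed))
    return kept, report


def quality_filter_fastq(in1, in2, out1=None, out2=None, q_min: int = 30,
                         len_min: int = 40) -> FilterReport:
    """File-level paired FASTQ filter; writes survivors if output paths given."""
    reads1 = SeqIO.parse(str(in1), "fastq")
    reads2 = SeqIO.parse(str(in2), "fastq")
    kept, report = quality_filter(zip(reads1, reads2), q_min=q_min, len_min=len_min)
    if out1 and out2:
        SeqIO.write((p[0] for p in kept), str(out1), "fastq")
        SeqIO.write((p[1] for p in kept), str(out2), "fastq")
    return report


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class ReadPairAlignment:
    """Mapped mate spans of one proper pair (pre-resolved to one location)."""

    pair_id: str
    mate1: GenomicInterval
    mate2: GenomicInterval
    mapq: int = 0
    multimap_count: int = 1

    def __post_init__(self):
        if self.mate1.ref_id != self.mate2.ref_id:
            raise ContentError(f"pair {self.pair_id}: mates on different references")

    @property
    def fragment(self) -> GenomicInterval:
        """Outer span from leftmost mate start to rightmost mate end."""
        return GenomicInterval(
            self.mate1.ref_id,
            min(self.mate1.start, self.mate2.start),
            max(self.mate1.end, self.mate2.end),
        )


def read_sam(path) -> list:
    """Read primary mapped proper pairs from a SAM file.

    Unmapped, secondary and supplementary records are dropped; mates are
    paired by query name; spans come from POS and the reference-consuming
    CIGAR length (1-based inclusive).
    """
    mates: dict = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        ref_names = sam.references
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigarstring is None:
                raise ContentError(f"record {rec.query_name}: missing CIGAR")
            span = GenomicInterval(
                ref_names[rec.reference_id],
                rec.reference_start + 1,
                rec.reference_end,  # pysam end is exclusive 0-based == inclusive 1-based
            )
            try:
                nh = rec.get_tag("NH")
            except KeyError:
                nh = 1
            mates.setdefault(rec.query_name, []).append((rec.mapping_quality, span, nh))
    pairs = []
    for name in sorted(mates):
        recs = mates[name]
        if len(recs) != 2:
            continue  # unpaired after filtering
        (q1, s1, n1), (q2, s2, n2) = recs
        pairs.append(
            ReadPairAlignment(
                pair_id=name,
                mate1=s1,
                mate2=s2,
                mapq=min(q1, q2),
                multimap_count=max(n1, n2),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# counting and the specificity filter
# ---------------------------------------------------------------------------

@dataclass
class FeatureCountTable:
    counts: dict           # feature id -> pair count
    role_totals: dict      # role -> total assigned pairs
    assignment_rule: str = "fragment-span overlap >= 1 nt; one location per pair"

    def to_tsv(self, path, features=None) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\trole\tcount\n")
            roles = {f.id: f.role for f in features} if features else {}
            for fid in sorted(self.counts):
                fh.write(f"{fid}\t{roles.get(fid, '')}\t{self.counts[fid]}\n")


def count_features(alignments, features) -> FeatureCountTable:
    """Assign each pair to every feature its fragment span overlaps (>= 1 nt)."""
    feats = sorted(features, key=lambda f: f.interval.start)
    starts = [f.interval.start for f in feats]
    counts = {f.id: 0 for f in feats}
    role_totals = {}
    import bisect

    max_len = max((f.interval.length for f in feats), default=0)
    for aln in alignments:
        frag = aln.fragment
        # features starting at or before frag.end and ending at or after frag.start
        hi = bisect.bisect_right(starts, frag.end)
        lo = bisect.bisect_left(starts, frag.start - max_len)
        for f in feats[lo:hi]:
            if f.interval.overlaps(frag):
                counts[f.id] += 1
                role_totals[f.role] = role_totals.get(f.role, 0) + 1
    return FeatureCountTable(counts=counts, role_totals=role_totals)


@dataclass
class IntergenicCall:
    feature: Feature
    n_pairs_inside: int
    n_pairs_straddling: int
    verdict: str

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ContentError(f"unknown verdict {self.verdict!r}")


def intergenic_specificity(alignments, intergenic: Feature, flanks,
                           min_pairs: int = 10) -> IntergenicCall:
    """Verdict for one intergenic region.

    *inside*: both mate spans fully contained in the region. *straddling*: one
    mate overlapping the region and the other overlapping a flanking feature.
    Verdict is ``readthrough`` on any straddling pair, else ``specific`` with
    at least ``min_pairs`` inside pairs, else ``untranscribed``.
    """
    region = intergenic.interval
    n_inside = 0
    n_straddle = 0
    for aln in alignments:
        m1, m2 = aln.mate1, aln.mate2
        if region.contains(m1) and region.contains(m2):
            n_inside += 1
            continue
        for a, b in ((m1, m2), (m2, m1)):
            if region.overlaps(a) and any(b.overlaps(f.interval) for f in flanks):
                n_straddle += 1
                break
    if n_straddle >= 1:
        verdict = "readthrough"
    elif n_inside >= min_pairs:
        verdict = "specific"
    else:
        verdict = "untranscribed"
    return IntergenicCall(intergenic, n_inside, n_straddle, verdict)


def nearest_flanks(intergenic: Feature, features) -> list:
    """Nearest non-intergenic features on each side of an intergenic region."""
    up, down = None, None
    for f in features:
        if f.role == "intergenic":
            continue
        if f.interval.end < intergenic.interval.start:
            if up is None or f.interval.end > up.interval.end:
                up = f
        elif f.interval.start > intergenic.interval.end:
            if down is None or f.interval.start < down.interval.start:
                down = f
    return [f for f in (up, down) if f is not None]


def call_all_intergenic(alignments, features, min_pairs: int = 10) -> list:
    """Specificity verdicts for every intergenic feature in the annotation."""
    calls = []
    for feat in features:
        if feat.role != "intergenic":
            continue
        flanks = nearest_flanks(feat, features)
        calls.append(
            intergenic_specificity(alignments, feat, flanks, min_pairs=min_pairs)
        )
    return calls


def calls_to_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tstart\tend\tn_pairs_inside\tn_pairs_straddling\tverdict\n")
        for c in calls:
            iv = c.feature.interval
            fh.write(
                f"{c.feature.id}\t{iv.start}\t{iv.end}\t"
                f"{c.n_pairs_inside}\t{c.n_pairs_straddling}\t{c.verdict}\n"
            )
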