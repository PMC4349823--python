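"""Annotation intersection: conserved non-CDS candidates and intergenic features.

Two jobs live here. First, the conserved arm: thresholded runs of the
posterior conservation profile (> 50 nt at probability >= 0.5 by default) are
intersected with the genome annotation — runs touching a CDS are rejected,
runs inside known non-coding features (rRNA, tRNA, tmRNA, ncRNA, pseudogene)
are binned as already-annotated, and the remainder become novel intergenic
candidates reported with their flanking genes. Second, the shared annotation:
explicit intergenic features are derived as the maximal gaps left by the union
of all annotated features, so the RNA-Seq arm and the conserved arm work from
one modified GFF3.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import ContentError, ParseError
from .profile import ClassProfile

ROLES = ("CDS", "rRNA", "tRNA", "tmRNA", "ncRNA", "pseudogene", "intergenic", "other")
#: known non-coding roles that bin a conserved run as "annotated non-coding"
NONCODING_ROLES = ("rRNA", "tRNA", "tmRNA", "ncRNA", "pseudogene")


@dataclass(frozen=True)
class GenomicInterval:
    ref_id: str
    start: int   # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ContentError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ContentError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class Feature:
    interval: GenomicInterval
    role: str
    id: str
    name: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ContentError(f"unknown feature role {self.role!r}")
        if not self.name:
            self.name = self.id


@dataclass
class ConservedCandidate:
    interval: GenomicInterval
    mean_profile: float
    min_profile: float
    upstream_feature: str
    downstream_feature: str
    class_conservation: float

    @property
    def length(self) -> int:
        return self.interval.length


_ROLE_MAP = {
    "cds": "CDS",
    "rrna": "rRNA",
    "trna": "tRNA",
    "tmrna": "tmRNA",
    "ncrna": "ncRNA",
    "pseudogene": "pseudogene",
    "intergenic": "intergenic",
    "intergenic_region": "intergenic",
}


def read_annotation(path) -> list:
    """Read a GFF3 file into coordinate-sorted :class:`Feature` objects.

    Feature types outside the role vocabulary map to ``other``; ``region`` /
    ``source`` container lines are skipped.
    """
    import gffutils

    # quick structural pass for precise line errors (gffutils reports little)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"GFF3 line has {len(parts)} columns, expected 9", path, lineno
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise ParseError("non-integer GFF3 coordinates", path, lineno)
            if start > end:
                raise ParseError("GFF3 start > end", path, lineno)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted types
        raise ParseError(f"gffutils failed: {exc}", path)

    features = []
    seen = 0
    for f in db.all_features():
        ftype = f.featuretype.lower()
        if ftype in ("region", "source", "chromosome"):
            continue
        role = _ROLE_MAP.get(ftype, "other")
        seen += 1
        fid = f.id or f"feature-{seen}"
        name = f.attributes.get("Name", [fid])[0]
        features.append(
            Feature(
                interval=GenomicInterval(f.seqid, f.start, f.end, f.strand or "."),
                role=role,
                id=fid,
                name=name,
            )
        )
    features.sort(key=lambda f: (f.interval.start, f.interval.end))
    return features


def write_annotation(features, path, genome_length: int | None = None,
                     ref_id: str | None = None) -> None:
    """Write features (including derived intergenic ones) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome_length and ref_id:
            fh.write(f"##sequence-region {ref_id} 1 {genome_length}\n")
        for f in sorted(features, key=lambda f: (f.interval.start, f.interval.end)):
            ftype = "intergenic_region" if f.role == "intergenic" else f.role
            fh.write(
                "\t".join(
                    [
                        f.interval.ref_id,
                        "srnaseg",
                        ftype,
                        str(f.interval.start),
                        str(f.interval.end),
                        ".",
                        f.interval.strand,
                        ".",
                        f"ID={f.id};Name={f.name}",
                    ]
                )
                + "\n"
            )


def _union_intervals(intervals) -> list:
    """Merge overlapping/adjacent-free union of (start, end) pairs, sorted."""
    ivs = sorted((iv.start, iv.end) for iv in intervals)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def build_intergenic_features(features, genome_length: int) -> list:
    """Maximal gaps between annotated features, as ``intergenic`` Features.

    Overlapping or nested annotations are collapsed by interval union
    (strand-ignored); zero-length gaps are omitted; ids run ``IG-1``,
    ``IG-2``, ... in coordinate order.
    """
    annotated = [f.interval for f in features if f.role != "intergenic"]
    if annotated and genome_length < max(iv.end for iv in annotated):
        raise ContentError("genome_length smaller than the last annotated feature")
    ref_id = annotated[0].ref_id if annotated else "genome"
    merged = _union_intervals(annotated)
    gaps = []
    cursor = 1
    for s, e in merged:
        if s > cursor:
            gaps.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= genome_length:
        gaps.append((cursor, genome_length))
    return [
        Feature(
            interval=GenomicInterval(ref_id, s, e),
            role="intergenic",
            id=f"IG-{i + 1}",
        )
        for i, (s, e) in enumerate(gaps)
    ]


def conserved_segments(profile: ClassProfile, p_min: float = 0.5,
                       len_min: int = 50) -> list:
    """Maximal runs of profiled positions with value >= ``p_min``.

    Runs break at coordinate gaps (unprofiled positions). A run survives iff
    strictly longer than ``len_min`` nt.
    """
    if not 0 < p_min <= 1:
        raise ValueError("p_min must be in (0, 1]")
    coords = profile.coords
    good = profile.values >= p_min
    out = []
    run_start = None
    prev = None
    for c, g in zip(coords, good):
        contiguous = prev is not None and c == prev + 1
        if g and run_start is not None and contiguous:
            prev = c
            continue
        if run_start is not None:
            if prev - run_start + 1 > len_min:
                out.append(GenomicInterval(profile.ref_id, int(run_start), int(prev)))
            run_start = None
        if g:
            run_start = c
        prev = c
    if run_start is not None and prev - run_start + 1 > len_min:
        out.append(GenomicInterval(profile.ref_id, int(run_start), int(prev)))
    return out


@dataclass
class ClassifiedCandidates:
    candidates: list          # novel intergenic ConservedCandidate
    annotated_noncoding: list # (GenomicInterval, containing Feature) pairs
    rejected: list            # intervals overlapping a CDS


def classify_candidates(segments, features, profile: ClassProfile | None = None,
                        class_conservation: float = float("nan")) -> ClassifiedCandidates:
    """Partition conserved runs by their relationship to the annotation.

    A run overlapping any CDS by >= 1 nt is rejected (candidates must lie
    entirely within intergenic space); a run fully inside a known non-coding
    feature is reported as annotated non-coding; anything else becomes a novel
    candidate with its nearest flanking features.
    """
    cds = [f for f in features if f.role == "CDS"]
    noncoding = [f for f in features if f.role in NONCODING_ROLES]
    flankable = sorted(
        (f for f in features if f.role != "intergenic"),
        key=lambda f: (f.interval.start, f.interval.end),
    )
    candidates, annotated, rejected = [], [], []
    for seg in segments:
        if any(seg.overlaps(f.interval) for f in cds):
            rejected.append(seg)
            continue
        container = next((f for f in noncoding if f.interval.contains(seg)), None)
        if container is not None:
            annotated.append((seg, container))
            continue
        upstream = None
        downstream = None
        for f in flankable:
            if f.interval.end < seg.start:
                if upstream is None or f.interval.end > upstream.interval.end:
                    upstream = f
            elif f.interval.start > seg.end:
                if downstream is None or f.interval.start < downstream.interval.start:
                    downstream = f
        if profile is not None:
            sel = (profile.coords >= seg.start) & (profile.coords <= seg.end)
            mean_p = float(profile.values[sel].mean()) if sel.any() else float("nan")
            min_p = float(profile.values[sel].min()) if sel.any() else float("nan")
        else:
            mean_p = min_p = float("nan")
        candidates.append(
            ConservedCandidate(
                interval=seg,
                mean_profile=mean_p,
                min_profile=min_p,
                upstream_feature=upstream.name if upstream else "",
                downstream_feature=downstream.name if downstream else "",
                class_conservation=class_conservation,
            )
        )
    return ClassifiedCandidates(candidates, annotated, rejected)


def candidates_to_dataframe(classified: ClassifiedCandidates) -> pd.DataFrame:
    rows = [
        {
            "ref_id": c.interval.ref_id,
            "start": c.interval.start,
            "end": c.interval.end,
            "length_nt": c.length,
            "upstream": c.upstream_feature,
            "downstream": c.downstream_feature,
            "mean_profile": c.mean_profile,
            "min_profile": c.min_profile,
            "class_conservation": c.class_conservation,
        }
        for c in classified.candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ref_id", "start", "end", "length_nt", "upstream", "downstream",
            "mean_profile", "min_profile", "class_conservation",
        ],
    )


def write_candidates_bed(classified: ClassifiedCandidates, path) -> None:
    """BED (0-based half-open) of the novel candidates."""
    with open(path, "w") as fh:
        for i, c in enumerate(classified.candidates, 1):
            fh.write(
                f"{c.interval.ref_id}\t{c.interval.start - 1}\t{c.interval.end}"
                f"\tcandidate-{i}\t{int(round(1000 * c.mean_profile)) if c.mean_profile == c.mean_profile else 0}\t.\n"
            )


def export_candidate_fasta(classified: ClassifiedCandidates, genome_fasta, path) -> None:
    """Write candidate sequences for external screening (e.g. BLAST checks)."""
    from Bio import SeqIO

    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    with open(path, "w") as fh:
        for i, c in enumerate(classified.candidates, 1):
            seq = genome[c.interval.ref_id][c.interval.start - 1 : c.interval.end]
            fh.write(f">candidate-{i} {c.interval.ref_id}:{c.interval.start}-{c.interval.end}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")


def load_wmel_conserved_regions() -> pd.DataFrame:
    """Published coordinates of the 19 highly conserved intergenic regions of
    the Wolbachia wMel genome (NC_002978.6) found in the wMel-wPip comparison,
    with their flanking genes. Lengths are recomputed from coordinates under
    the 1-based inclusive convention."""
    path = resources.files("srnaseg.data") / "wmel_conserved_intergenic.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df["length_nt"] = df["end"] - df["start"] + 1
    return df
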