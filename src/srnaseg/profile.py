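"""Posterior class-membership profiles and wiggle-track output.

The profile of a class rank r assigns each reference position the Monte Carlo
posterior probability (over post-burn-in draws) that its segment belongs to
the class ranking r-th by conservation E(theta) in that draw. Ranking per draw
resolves label switching: class identity is defined by conservation level, not
by label index. Positions excluded from the encoding (indels, masked or
ambiguous columns) are absent from the profile rather than zero, so length
thresholds downstream act only on genuinely profiled spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContentError, ParseError


@dataclass
class ClassProfile:
    """Per-reference-position membership probability for one class rank."""

    ref_id: str
    coords: np.ndarray        # 1-based reference coordinates, strictly increasing
    values: np.ndarray        # probabilities in [0, 1]
    designated_class: int     # conservation rank (1 = most conserved)
    n_samples: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.shape != self.values.shape:
            raise ContentError("coords and values must be parallel")
        if self.coords.size and np.any(np.diff(self.coords) <= 0):
            raise ContentError("profile coordinates must be strictly increasing")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ContentError("profile values must lie in [0, 1]")

    def __len__(self):
        return len(self.coords)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_coord\tprobability\n")
            for c, v in zip(self.coords, self.values):
                fh.write(f"{c}\t{v:.6f}\n")


def rank_membership_matrix(results) -> np.ndarray:
    """(n_symbols, k) matrix: P(position's segment holds conservation rank r+1).

    Monte Carlo average over post-burn-in draws; the k columns partition the
    classes in every draw, so rows sum to 1.
    """
    sl = results.post_burnin()
    labels = results.labels[sl]          # (S, N) 0-based class per position
    ranks = results.class_ranks()[sl]    # (S, k) rank per class, 1-based
    S, N = labels.shape
    k = results.k
    pos_rank = np.take_along_axis(
        ranks, labels.astype(np.int64), axis=1
    )  # (S, N): rank of each position's class
    out = np.zeros((N, k))
    for r in range(1, k + 1):
        out[:, r - 1] = (pos_rank == r).mean(axis=0)
    return out


def compute_profile_from_results(results, class_rank: int = 1) -> ClassProfile:
    if not 1 <= class_rank <= results.k:
        raise ValueError(f"class_rank {class_rank} out of range 1..{results.k}")
    memb = rank_membership_matrix(results)
    enc = results.model.encoded
    return ClassProfile(
        ref_id=enc.ref_id,
        coords=enc.coords.copy(),
        values=memb[:, class_rank - 1],
        designated_class=class_rank,
        n_samples=results.n_post_burnin,
    )


def compute_profile(samples, seq, class_rank: int = 1) -> ClassProfile:
    """Profile from an explicit post-burn-in :class:`PosteriorSample` list.

    Same functional as :func:`compute_profile_from_results`; accepts samples
    directly so externally stored draws can be profiled.
    """
    from .encode import MATCH_INDICES

    if not samples:
        raise ContentError("need at least one post-burn-in sample")
    n = seq.n_symbols
    k = len(samples[0].compositions)
    if not 1 <= class_rank <= k:
        raise ValueError(f"class_rank {class_rank} out of range 1..{k}")
    hits = np.zeros(n)
    for sample in samples:
        cons = np.array(
            [comp.theta[MATCH_INDICES].sum() for comp in sample.compositions]
        )
        order = np.argsort(-cons, kind="stable")
        target_class = int(order[class_rank - 1]) + 1  # 1-based class id
        labels = sample.segmentation.position_labels(n)
        hits += labels == target_class
    return ClassProfile(
        ref_id=seq.ref_id,
        coords=seq.coords.copy(),
        values=hits / len(samples),
        designated_class=class_rank,
        n_samples=len(samples),
    )


def write_wig(profile: ClassProfile, path, track_name: str | None = None) -> None:
    """Write a UCSC fixedStep wiggle track (step=1, span=1, 4 decimals).

    A new ``fixedStep`` declaration starts at every coordinate gap.
    """
    if len(profile) == 0:
        raise ContentError("cannot write an empty profile")
    name = track_name or f"class_rank_{profile.designated_class}"
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        prev = None
        for c, v in zip(profile.coords, profile.values):
            if prev is None or c != prev + 1:
                fh.write(f"fixedStep chrom={profile.ref_id} start={c} step=1 span=1\n")
            fh.write(f"{v:.4f}\n")
            prev = c


def read_wig(path) -> ClassProfile:
    """Read a fixedStep wiggle track written by :func:`write_wig`."""
    coords, values = [], []
    ref_id = None
    pos = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    part.split("=", 1) for part in line.split()[1:] if "=" in part
                )
                try:
                    pos = int(fields["start"])
                    ref_id = fields.get("chrom", ref_id)
                    if int(fields.get("step", 1)) != 1 or int(fields.get("span", 1)) != 1:
                        raise ParseError("only step=1 span=1 supported", path, lineno)
                except KeyError as exc:
                    raise ParseError(f"fixedStep missing {exc}", path, lineno)
                continue
            if pos is None:
                raise ParseError("data line before fixedStep declaration", path, lineno)
            try:
                values.append(float(line))
            except ValueError:
                raise ParseError(f"bad wiggle value {line!r}", path, lineno)
            coords.append(pos)
            pos += 1
    if not coords:
        raise ParseError("no data lines in wiggle file", path)
    return ClassProfile(
        ref_id=ref_id or "unknown",
        coords=np.array(coords),
        values=np.array(values),
        designated_class=0,
        n_samples=0,
    )
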