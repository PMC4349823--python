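"""Bayesian multiple change-point model over the 16-letter encoded alignment.

The model assumes the encoded sequence is piecewise homogeneous: unknown
change-points partition it into segments, each segment carries one of ``k``
latent classes, and symbols within a segment are i.i.d. categorical draws from
the class's 16-dimensional emission simplex theta. Priors are conjugate
throughout: Dirichlet(alpha) on each theta, an independent Bernoulli(cp_prior_p)
on each eligible boundary, and segment labels drawn from a mixture with a
symmetric Dirichlet(class_prior) prior. Block separators (``#``) are fixed
change-points.

Usage follows the model/results convention::

    model = ChangePointModel(encoded, n_classes=7)
    res = model.fit(iterations=1000, burn_in=150, seed=11)
    res.summary()
    res.profile(class_rank=1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from ._sampler import run_chain
from .encode import MATCH_INDICES, EncodedAlignment
from .errors import ContentError

ALPHABET_SIZE = 16


@dataclass
class ModelSpec:
    """Model and sampler configuration.

    ``cp_prior_p`` defaults to 0.005: under a geometric segment-length prior
    this puts the prior mean segment length at 200 nt, the scale of the
    conserved elements the method targets.
    """

    k: int
    alphabet_size: int = ALPHABET_SIZE
    dirichlet_alpha: float = 1.0
    cp_prior_p: float = 0.005
    class_prior: float = 1.0
    iterations: int = 1000
    burn_in: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.cp_prior_p < 1.0:
            raise ValueError("cp_prior_p must be in (0, 1)")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.dirichlet_alpha <= 0 or self.class_prior <= 0:
            raise ValueError("prior pseudo-counts must be positive")


@dataclass
class Segmentation:
    """Cut positions and per-segment class labels.

    ``change_points`` holds 1-based positions p meaning a cut between symbol p
    and p+1 of the separator-free sequence; it includes every mandatory cut at
    a ``#`` separator but not the sequence end. Labels are class ids
    ``1..k``, one per segment (``len(change_points) + 1`` segments).
    """

    change_points: list
    labels: list

    def __post_init__(self):
        cps = list(self.change_points)
        if any(b >= a for a, b in zip(cps[1:], cps)):
            raise ContentError("change-points must be strictly increasing")
        if len(self.labels) != len(cps) + 1:
            raise ContentError("need exactly one label per segment")

    def n_segments(self) -> int:
        return len(self.labels)

    def position_labels(self, n: int) -> np.ndarray:
        """Class id per symbol position (length n)."""
        bounds = [0] + list(self.change_points) + [n]
        out = np.empty(n, dtype=np.int64)
        for lab, (s, e) in zip(self.labels, zip(bounds, bounds[1:])):
            out[s:e] = lab
        return out


@dataclass
class ClassComposition:
    """Emission simplex and occupancy of one segment class."""

    theta: np.ndarray
    mixture_proportion: float

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (ALPHABET_SIZE,):
            raise ContentError("theta must have 16 entries")
        if np.any(self.theta < 0) or abs(self.theta.sum() - 1.0) > 1e-9:
            raise ContentError("theta must be a simplex vector")


@dataclass
class PosteriorSample:
    """One recorded MCMC draw."""

    iteration: int
    segmentation: Segmentation
    compositions: list
    log_likelihood: float


def log_likelihood(seq: EncodedAlignment, seg: Segmentation, comps: list) -> float:
    """Data log-likelihood of the separator-free sequence under (seg, comps).

    Positions whose class assigns zero probability to the observed symbol give
    ``-inf``; ``#`` separators contribute nothing.
    """
    x = seq.symbol_indices()
    labels = seg.position_labels(x.size)
    total = 0.0
    for comp_id, comp in enumerate(comps, start=1):
        sel = x[labels == comp_id]
        if sel.size == 0:
            continue
        with np.errstate(divide="ignore"):
            logtheta = np.log(comp.theta)
        vals = logtheta[sel]
        if np.any(np.isneginf(vals)):
            return float("-inf")
        total += float(vals.sum())
    return total


class ChangePointModel:
    """Multiple change-point segmentation model for an encoded alignment."""

    def __init__(self, encoded: EncodedAlignment, n_classes: int,
                 dirichlet_alpha: float = 1.0, cp_prior_p: float = 0.005,
                 class_prior: float = 1.0):
        if encoded.n_symbols == 0:
            raise ContentError("cannot model an empty encoding")
        self.encoded = encoded
        self.n_classes = int(n_classes)
        self.dirichlet_alpha = float(dirichlet_alpha)
        self.cp_prior_p = float(cp_prior_p)
        self.class_prior = float(class_prior)

    @classmethod
    def from_spec(cls, encoded: EncodedAlignment, spec: ModelSpec) -> "ChangePointModel":
        return cls(encoded, spec.k, spec.dirichlet_alpha, spec.cp_prior_p,
                   spec.class_prior)

    def fit(self, iterations: int = 1000, burn_in: int = 150,
            seed: int = 0) -> "ChangePointResults":
        spec = ModelSpec(
            k=self.n_classes,
            dirichlet_alpha=self.dirichlet_alpha,
            cp_prior_p=self.cp_prior_p,
            class_prior=self.class_prior,
            iterations=iterations,
            burn_in=burn_in,
            seed=seed,
        )
        x = self.encoded.symbol_indices()
        fixed = self.encoded.fixed_boundaries()
        b, z, theta, pi, logl = run_chain(
            x, fixed, spec.k, spec.dirichlet_alpha, spec.class_prior,
            spec.cp_prior_p, spec.iterations, int(seed) & 0x7FFFFFFF,
        )
        return ChangePointResults(self, spec, b, z, theta, pi, logl)


@dataclass
class ChangePointResults:
    """Posterior draws from one fitted change-point model."""

    model: ChangePointModel
    spec: ModelSpec
    boundaries: np.ndarray   # (iterations, N) bool; index N-1 is the end sentinel
    labels: np.ndarray       # (iterations, N) int8, 0-based class per position
    thetas: np.ndarray       # (iterations, k, 16)
    pis: np.ndarray          # (iterations, k) segment-label mixture weights
    log_likelihoods: np.ndarray = field(default=None)

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def n_symbols(self) -> int:
        return self.model.encoded.n_symbols

    @property
    def n_post_burnin(self) -> int:
        return self.spec.iterations - self.spec.burn_in

    def post_burnin(self) -> slice:
        return slice(self.spec.burn_in, None)

    # -- sample views ---------------------------------------------------

    @cached_property
    def samples(self) -> list:
        """All draws as :class:`PosteriorSample` objects (1-based class ids)."""
        out = []
        n = self.n_symbols
        for it in range(self.spec.iterations):
            cuts = np.flatnonzero(self.boundaries[it, : n - 1]) + 1 if n > 1 else np.array([], int)
            seg_labels = []
            prev = 0
            for cp in list(cuts) + [n]:
                seg_labels.append(int(self.labels[it, prev]) + 1)
                prev = cp
            seg = Segmentation(change_points=[int(c) for c in cuts], labels=seg_labels)
            props = self.mixture_proportions[it]
            comps = [
                ClassComposition(self.thetas[it, c], float(props[c]))
                for c in range(self.k)
            ]
            out.append(PosteriorSample(it, seg, comps, float(self.log_likelihoods[it])))
        return out

    def post_burnin_samples(self) -> list:
        return self.samples[self.spec.burn_in:]

    # -- summaries ------------------------------------------------------

    @cached_property
    def mixture_proportions(self) -> np.ndarray:
        """(iterations, k) fraction of positions assigned to each class."""
        n = self.n_symbols
        out = np.zeros((self.spec.iterations, self.k))
        for c in range(self.k):
            out[:, c] = (self.labels == c).sum(axis=1) / n
        return out

    def mean_mixture_proportions(self) -> np.ndarray:
        return self.mixture_proportions[self.post_burnin()].mean(axis=0)

    def conservation_trace(self) -> np.ndarray:
        """(iterations, k) per-class match proportion E(theta) per draw."""
        return self.thetas[:, :, MATCH_INDICES].sum(axis=2)

    def class_ranks(self) -> np.ndarray:
        """(iterations, k): rank (1 = most conserved) of each class per draw."""
        cons = self.conservation_trace()
        order = np.argsort(-cons, axis=1, kind="stable")
        ranks = np.empty_like(order)
        rows = np.arange(order.shape[0])[:, None]
        ranks[rows, order] = np.arange(1, self.k + 1)[None, :]
        return ranks

    def rank_conservation(self, class_rank: int = 1) -> float:
        """Posterior mean E(theta) of the class holding ``class_rank`` per draw."""
        cons = self.conservation_trace()[self.post_burnin()]
        return float(np.sort(cons, axis=1)[:, self.k - class_rank].mean())

    def n_internal_changepoints(self) -> np.ndarray:
        """Per-iteration count of sampled (non-mandatory) internal cuts."""
        n = self.n_symbols
        if n <= 1:
            return np.zeros(self.spec.iterations, dtype=int)
        fixed = self.model.encoded.fixed_boundaries()
        internal = self.boundaries[:, : n - 1] & ~fixed[None, :]
        return internal.sum(axis=1)

    def profile(self, class_rank: int = 1):
        from .profile import compute_profile_from_results

        return compute_profile_from_results(self, class_rank)

    def information_criteria(self):
        from .select import information_criteria_from_results

        return information_criteria_from_results(self)

    def convergence_report(self, out_dir=None):
        from .select import convergence_report

        return convergence_report(self, out_dir=out_dir)

    def summary(self) -> str:
        crit = self.information_criteria()
        props = self.mean_mixture_proportions()
        cons = self.conservation_trace()[self.post_burnin()].mean(axis=0)
        lines = [
            "Change-point segmentation results",
            "=================================",
            f"classes (k):            {self.k}",
            f"sequence length:        {self.n_symbols} symbols",
            f"iterations / burn-in:   {self.spec.iterations} / {self.spec.burn_in}",
            f"seed:                   {self.spec.seed}",
            f"max log-likelihood:     {crit['max_logl']:.2f}",
            f"AIC / BIC / DICV:       {crit['AIC']:.1f} / {crit['BIC']:.1f} / {crit['DICV']:.1f}",
            f"mean internal cuts:     {self.n_internal_changepoints()[self.post_burnin()].mean():.1f}",
            "",
            "class  mean E(theta)  mean mixture prop.",
        ]
        order = np.argsort(-cons)
        for c in order:
            lines.append(f"  {c + 1:>3}  {cons[c]:>12.4f}  {props[c]:>17.4f}")
        return "\n".join(lines)

    # -- serialization --------------------------------------------------

    def write_samples_tsv(self, path) -> None:
        n = self.n_symbols
        with open(path, "w") as fh:
            fh.write("iteration\tlog_likelihood\tchange_points\tlabels\n")
            for it in range(self.spec.iterations):
                cuts = np.flatnonzero(self.boundaries[it, : n - 1]) + 1
                labs = []
                prev = 0
                for cp in list(cuts) + [n]:
                    labs.append(str(int(self.labels[it, prev]) + 1))
                    prev = cp
                fh.write(
                    f"{it}\t{self.log_likelihoods[it]:.6f}\t"
                    f"{','.join(map(str, cuts))}\t{','.join(labs)}\n"
                )

    def write_compositions_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration\tclass\t" + "\t".join(f"theta_{s}" for s in "abcdefghijklmnop") + "\n")
            for it in range(self.spec.iterations):
                for c in range(self.k):
                    vals = "\t".join(f"{v:.6g}" for v in self.thetas[it, c])
                    fh.write(f"{it}\t{c + 1}\t{vals}\n")


def run_sampler(seq: EncodedAlignment, spec: ModelSpec) -> list:
    """Functional wrapper: fit under ``spec`` and return all posterior samples."""
    model = ChangePointModel.from_spec(seq, spec)
    res = model.fit(iterations=spec.iterations, burn_in=spec.burn_in, seed=spec.seed)
    return res.samples
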