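"""Exact posterior for tiny instances, by full enumeration.

Serves as an independent oracle for the Gibbs sampler. All segmentations and
labelings are enumerated with the emission simplices and mixture weights
integrated out analytically (Dirichlet-multinomial predictives), giving exact
change-point marginals.

Per-position *raw* label marginals are uninformative here: the prior is
symmetric in the class labels, so every position belongs to every class with
probability 1/k. The identifiable quantity — the one the profile stage reports
— is membership in the class of a given conservation *rank*. Within one
enumerated configuration the conservation E(theta) of class c, under its
conditional Dirichlet, is Beta(4*alpha + matches_c, 12*alpha + mismatches_c)
(the four match coordinates of a Dirichlet aggregate to a Beta); classes'
conservations are independent, so P(class c attains rank r) is an order
statistic of independent Betas, computed by numerical quadrature. Summing over
configurations gives exact rank-membership marginals, the same functional the
sampler estimates by ranking each draw's sampled theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import beta as beta_dist

from .encode import MATCH_INDICES, EncodedAlignment
from .errors import ContentError
from .model import ModelSpec

MAX_SYMBOLS = 14
MAX_CLASSES = 3

_MATCH_SET = set(int(i) for i in MATCH_INDICES)


def _beta_rank_probs(params: tuple) -> np.ndarray:
    """R[c, r] = P(Beta_c is the (r+1)-th largest) for independent Betas."""
    k = len(params)
    if k == 1:
        return np.ones((1, 1))
    R = np.zeros((k, k))
    dists = [beta_dist(a, b) for a, b in params]
    # P(c is max) = int f_c(x) prod_{o != c} F_o(x) dx
    # P(c is min) = int f_c(x) prod_{o != c} (1 - F_o(x)) dx
    for c in range(k):
        others = [o for o in range(k) if o != c]

        def f_top(x, c=c, others=others):
            v = dists[c].pdf(x)
            for o in others:
                v = v * dists[o].cdf(x)
            return v

        def f_bot(x, c=c, others=others):
            v = dists[c].pdf(x)
            for o in others:
                v = v * dists[o].sf(x)
            return v

        R[c, 0], _ = integrate.quad(f_top, 0.0, 1.0, limit=100)
        R[c, k - 1], _ = integrate.quad(f_bot, 0.0, 1.0, limit=100)
    if k == 2:
        R[:, 1] = 1.0 - R[:, 0]
    else:  # k == 3: middle rank by complement
        R[:, 1] = 1.0 - R[:, 0] - R[:, 2]
    return np.clip(R, 0.0, 1.0)


@dataclass
class ExactPosterior:
    """Exact marginals for a small instance."""

    cp_marginals: np.ndarray      # P(cut between symbol i and i+1), length N-1
    rank_membership: np.ndarray   # (N, k): P(position in rank-(r+1) class)
    log_evidence: float


def exact_posterior_small(seq: EncodedAlignment, spec: ModelSpec) -> ExactPosterior:
    """Enumerate the full posterior of a small instance.

    Refuses instances with more than 14 symbols or more than 3 classes: the
    enumeration is O(k * (1+k)^(n-1)).
    """
    x = seq.symbol_indices()
    n = x.size
    k = spec.k
    if n == 0:
        raise ContentError("empty sequence")
    if n > MAX_SYMBOLS or k > MAX_CLASSES:
        raise ContentError(
            f"instance too large for enumeration (n={n} > {MAX_SYMBOLS} or k={k} > {MAX_CLASSES})"
        )
    from math import exp, log

    fixed = [bool(v) for v in seq.fixed_boundaries()]
    xs = [int(v) for v in x]
    is_match = [s in _MATCH_SET for s in xs]
    alpha = float(spec.dirichlet_alpha)
    class_prior = float(spec.class_prior)
    logp = log(spec.cp_prior_p)
    log1mp = log(1.0 - spec.cp_prior_p)

    counts = [[0] * 16 for _ in range(k)]   # symbol counts per class
    totals = [0] * k
    matches = [0] * k                       # match-symbol counts per class
    segs = [0] * k                          # segment counts per class
    nseg = [0]                              # total segments
    z = [0] * n

    cp_weight = [0.0] * max(n - 1, 0)
    membership = [[0.0] * k for _ in range(n)]
    total_weight = 0.0
    max_logw = [-np.inf]
    rank_cache: dict = {}

    def leaf(logw: float, cuts: list) -> None:
        nonlocal total_weight
        w = exp(logw)
        if logw > max_logw[0]:
            max_logw[0] = logw
        for i in cuts:
            cp_weight[i] += w
        key = tuple((matches[c], totals[c]) for c in range(k))
        R = rank_cache.get(key)
        if R is None:
            params = tuple((4.0 * alpha + m, 12.0 * alpha + (t - m)) for m, t in key)
            R = [list(row) for row in _beta_rank_probs(params)]
            rank_cache[key] = R
        for i in range(n):
            row = R[z[i]]
            mrow = membership[i]
            for r in range(k):
                mrow[r] += w * row[r]
        total_weight += w

    cuts: list = []

    def extend(i: int, c: int, logw: float) -> None:
        """Assign position i to class c (current segment class) and recurse."""
        s = xs[i]
        dlog = log((alpha + counts[c][s]) / (16.0 * alpha + totals[c]))
        counts[c][s] += 1
        totals[c] += 1
        if is_match[i]:
            matches[c] += 1
        z[i] = c
        step(i + 1, c, logw + dlog)
        counts[c][s] -= 1
        totals[c] -= 1
        if is_match[i]:
            matches[c] -= 1

    def open_segment(i: int, logw: float) -> None:
        for c in range(k):
            dlog = log((class_prior + segs[c]) / (k * class_prior + nseg[0]))
            segs[c] += 1
            nseg[0] += 1
            extend(i, c, logw + dlog)
            segs[c] -= 1
            nseg[0] -= 1

    def step(i: int, cur: int, logw: float) -> None:
        if i == n:
            leaf(logw, cuts)
            return
        if fixed[i - 1]:
            cuts.append(i - 1)
            open_segment(i, logw)
            cuts.pop()
            return
        # no cut
        extend(i, cur, logw + log1mp)
        # cut
        cuts.append(i - 1)
        open_segment(i, logw + logp)
        cuts.pop()

    open_segment(0, 0.0)

    cp_marg = np.array(cp_weight) / total_weight
    memb = np.array(membership) / total_weight
    # total_weight is the evidence itself (all leaf weights summed linearly)
    log_evidence = float(log(total_weight))
    return ExactPosterior(cp_marg, memb, log_evidence)
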