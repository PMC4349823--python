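"""Class-count selection: information criteria, conservation traces, sweeps.

Models with k = 1..12 classes are fitted independently and compared with
approximations to AIC, BIC and a deviance-variance DIC (DICV) computed from
the post-burn-in log-likelihood trace. Selection takes the smallest k that is
a local minimum of both AIC and DICV, skipping over-fitted candidates (any
class with very low mixture proportion). BIC is reported for completeness but
never drives selection: with effective sample sizes in the tens of kilobases
its penalty overwhelms the likelihood differences between neighbouring k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encode import MATCH_INDICES
from .errors import ContentError, UndefinedInputError
from .model import ChangePointModel, ModelSpec


def conservation(theta) -> float:
    """Match proportion E(theta) = (theta_a + theta_f + theta_k + theta_p) / sum(theta).

    Accepts unnormalized non-negative frequency vectors; an all-zero vector is
    undefined.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (16,):
        raise ValueError("theta must have 16 entries")
    if np.any(theta < 0):
        raise ValueError("theta entries must be non-negative")
    denom = theta.sum()
    if denom == 0:
        raise UndefinedInputError("conservation undefined for an all-zero vector")
    return float(theta[MATCH_INDICES].sum() / denom)


def n_free_parameters(k: int) -> int:
    """15 free emission entries per class plus k-1 free mixture weights."""
    return 15 * k + (k - 1)


def information_criteria(samples, spec: ModelSpec, n: int) -> dict:
    """Criteria row from a posterior sample list (post-burn-in trace based).

    AIC = -2*Lhat + 2p, BIC = -2*Lhat + p*ln(n) with Lhat the maximum sampled
    log-likelihood and p the free-parameter count; DICV = mean(D) + var(D)
    over the post-burn-in deviance trace D = -2*logL (equivalently
    mean(D) + 2*p_D with the variance-based p_D = var(D)/2).
    """
    logl = np.array([s.log_likelihood for s in samples[spec.burn_in:]])
    return _criteria_from_trace(logl, spec.k, n)


def _criteria_from_trace(post_logl: np.ndarray, k: int, n: int) -> dict:
    if post_logl.size < 1:
        raise ContentError("no post-burn-in samples")
    p = n_free_parameters(k)
    lhat = float(post_logl.max())
    dev = -2.0 * post_logl
    var_d = float(dev.var(ddof=1)) if dev.size > 1 else 0.0
    return {
        "k": k,
        "AIC": -2.0 * lhat + 2.0 * p,
        "BIC": -2.0 * lhat + p * np.log(n),
        "DICV": float(dev.mean()) + var_d,
        "max_logl": lhat,
        "mean_logl": float(post_logl.mean()),
    }


def information_criteria_from_results(results) -> dict:
    row = _criteria_from_trace(
        results.log_likelihoods[results.post_burnin()],
        results.k,
        results.n_symbols,
    )
    row["min_mixture"] = float(results.mean_mixture_proportions().min())
    return row


@dataclass
class SelectionResult:
    k: int
    warning: bool
    disqualified: list
    rationale: str


def _local_minima(values: np.ndarray) -> list:
    """Indices that are local minima; boundary points need only their one
    neighbour to be larger."""
    idx = []
    m = len(values)
    for i in range(m):
        left_ok = i == 0 or values[i] < values[i - 1]
        right_ok = i == m - 1 or values[i] < values[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return idx


def select_model(table: pd.DataFrame, min_mixture: float = 0.01) -> SelectionResult:
    """Pick the working class count from a criteria table.

    ``table`` needs columns ``k``, ``AIC``, ``DICV`` and ``min_mixture`` over a
    contiguous k range. The smallest k that is a local minimum of both AIC and
    DICV wins; candidates whose fitted model contains a class with mixture
    proportion below ``min_mixture`` are over-fitted and skipped. With no
    joint local minimum the AIC argmin is returned, warning-flagged.
    """
    if table is None or len(table) == 0:
        raise ContentError("empty criteria table")
    table = table.sort_values("k").reset_index(drop=True)
    ks = table["k"].to_numpy()
    if len(ks) > 1 and np.any(np.diff(ks) != 1):
        raise ContentError("criteria table must cover a contiguous k range")
    aic = table["AIC"].to_numpy(dtype=float)
    dicv = table["DICV"].to_numpy(dtype=float)
    minmix = table["min_mixture"].to_numpy(dtype=float)

    joint = sorted(set(_local_minima(aic)) & set(_local_minima(dicv)))
    disqualified = []
    for i in joint:
        if minmix[i] < min_mixture:
            disqualified.append(int(ks[i]))
            continue
        return SelectionResult(
            k=int(ks[i]),
            warning=False,
            disqualified=disqualified,
            rationale=(
                f"first joint local minimum of AIC and DICV at k={int(ks[i])}"
                + (f" (skipped over-fitted k={disqualified})" if disqualified else "")
            ),
        )
    # fallback: AIC argmin, still skipping over-fitted models when possible
    admissible = np.flatnonzero(minmix >= min_mixture)
    pool = admissible if admissible.size else np.arange(len(ks))
    i = int(pool[np.argmin(aic[pool])])
    return SelectionResult(
        k=int(ks[i]),
        warning=True,
        disqualified=disqualified,
        rationale="no admissible joint local minimum; falling back to AIC argmin "
                  "over models without under-populated classes",
    )


@dataclass
class ConvergenceReport:
    converged: bool
    split_z: float
    most_conserved_class: int
    mean_conservation: np.ndarray
    logl_trace: np.ndarray
    conservation_trace: np.ndarray


def convergence_report(results, out_dir=None) -> ConvergenceReport:
    """Trace-based convergence diagnostics.

    Compares the means of the two halves of the post-burn-in log-likelihood
    trace; a difference beyond 3 pooled standard errors flags non-convergence.
    Optionally writes trace TSVs and plots under ``out_dir``.
    """
    if results.spec.iterations < 10:
        raise ContentError("need at least 10 samples for diagnostics")
    logl = results.log_likelihoods
    post = logl[results.post_burnin()]
    half = post.size // 2
    a, b = post[:half], post[half:]
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    split_z = float(abs(a.mean() - b.mean()) / se) if se > 0 else 0.0
    cons = results.conservation_trace()
    mean_cons = cons[results.post_burnin()].mean(axis=0)
    report = ConvergenceReport(
        converged=split_z <= 3.0,
        split_z=split_z,
        most_conserved_class=int(np.argmax(mean_cons)) + 1,
        mean_conservation=mean_cons,
        logl_trace=logl,
        conservation_trace=cons,
    )
    if out_dir is not None:
        _write_diagnostics(results, report, out_dir)
    return report


def _write_diagnostics(results, report: ConvergenceReport, out_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = results.k
    df = pd.DataFrame(report.conservation_trace,
                      columns=[f"class_{c + 1}" for c in range(k)])
    df.insert(0, "iteration", np.arange(len(df)))
    df.insert(1, "log_likelihood", report.logl_trace)
    df.to_csv(out / f"traces_k{k}.tsv", sep="\t", index=False)

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    axes[0].plot(report.logl_trace, lw=0.7)
    axes[0].axvline(results.spec.burn_in, color="grey", ls="--", lw=0.7)
    axes[0].set_ylabel("log-likelihood")
    for c in range(k):
        axes[1].plot(report.conservation_trace[:, c], lw=0.7, label=f"class {c + 1}")
    axes[1].set_ylabel("E(theta)")
    axes[1].set_xlabel("iteration")
    axes[1].legend(fontsize=7, ncol=min(k, 4))
    fig.tight_layout()
    fig.savefig(out / f"traces_k{k}.png", dpi=120)
    plt.close(fig)


@dataclass
class SweepResults:
    """Fits and criteria across a contiguous range of class counts."""

    criteria: pd.DataFrame
    results: dict = field(repr=False)

    def select(self, min_mixture: float = 0.01) -> SelectionResult:
        return select_model(self.criteria, min_mixture=min_mixture)

    def best(self, min_mixture: float = 0.01):
        return self.results[self.select(min_mixture).k]

    def write_criteria_tsv(self, path) -> None:
        self.criteria.to_csv(path, sep="\t", index=False, float_format="%.4f")


def sweep_classes(encoded, k_range=range(1, 13), iterations: int = 1000,
                  burn_in: int = 150, seed: int = 0, cp_prior_p: float = 0.005,
                  dirichlet_alpha: float = 1.0, class_prior: float = 1.0,
                  keep_results: bool = True) -> SweepResults:
    """Fit one model per class count; derive per-k seeds from ``seed``."""
    rows, fits = [], {}
    for k in k_range:
        model = ChangePointModel(
            encoded, k, dirichlet_alpha=dirichlet_alpha,
            cp_prior_p=cp_prior_p, class_prior=class_prior,
        )
        res = model.fit(iterations=iterations, burn_in=burn_in,
                        seed=(seed * 1000 + k) & 0x7FFFFFFF)
        rows.append(information_criteria_from_results(res))
        if keep_results:
            fits[k] = res
    return SweepResults(criteria=pd.DataFrame(rows), results=fits)
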