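"""Beta-binomial inference of per-peptide editing effects.

Replicate edited-read counts for peptide i are modelled hierarchically:
p_ij ~ Beta(α_i, β_i) and y_ij ~ Bin(n_j, p_ij), so the marginal count is
beta-binomial and the spread of α_i + β_i captures replicate-to-replicate
overdispersion beyond sampling noise. The MLE of (α_i, β_i) solves the
digamma score equations of the beta-binomial log-likelihood

    0 = Σ_j [ψ(y_ij + α) − ψ(n_j + α + β)] − k·[ψ(α) − ψ(α + β)]
    0 = Σ_j [ψ(n_j − y_ij + β) − ψ(n_j + α + β)] − k·[ψ(β) − ψ(α + β)]

solved numerically in log-parameter space; when the solver fails (or the
data are degenerate) a fast moment-matching approximation is used instead,
equating the observed variance of y_ij/n_j with the overdispersed-binomial
expectation. Peptides are ranked against a pooled control fit by the
probability that a beta-binomial count drawn under the peptide's
parameters exceeds one drawn under the control parameters, and hits are
called from control-normalised fractions with a paired t-test and
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from pepseq.reads import CountMatrix

__all__ = [
    "EffectEstimate",
    "EmptyAnalysisError",
    "filter_low_coverage",
    "fit_moment_match",
    "fit_betabin_mle",
    "beta_moments",
    "betabin_loglik",
    "prob_beat_control",
    "estimate_effect",
    "fit_all",
    "normalize_and_call",
]

MIN_READS = 100
DEFAULT_CAP_FACTOR = 10.0
_CONCENTRATION_FLOOR = 1e-2
EXACT_ENUM_MAX_N = 5000


class EmptyAnalysisError(ValueError):
    """No peptides left after coverage filtering."""


@dataclass(frozen=True)
class EffectEstimate:
    """Fitted Beta law for one peptide's replicate editing rates."""

    peptide_id: str
    alpha: float
    beta: float
    method: str  # score_equations | moment_match

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def filter_low_coverage(counts: CountMatrix, min_reads: int = MIN_READS) -> CountMatrix:
    """Drop peptides with fewer than ``min_reads`` kept reads in any replicate.

    The threshold is strict: a peptide with exactly ``min_reads`` reads
    everywhere is retained. Raises :class:`EmptyAnalysisError` when nothing
    survives.
    """
    n = counts.pivot("n")
    keep = n.index[(n >= min_reads).all(axis=1)]
    if len(keep) == 0:
        raise EmptyAnalysisError(
            f"no peptide has >= {min_reads} reads in every replicate"
        )
    return counts.subset(keep)


def betabin_loglik(alpha: float, beta: float, y: np.ndarray, n: np.ndarray) -> float:
    """Beta-binomial log-likelihood up to the binomial-coefficient constant."""
    if alpha <= 0 or beta <= 0:
        return -np.inf
    return float(
        np.sum(special.betaln(y + alpha, n - y + beta)) - len(y) * special.betaln(alpha, beta)
    )


def _validated(y, n) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if y.shape != n.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("y and n must be equal-length non-empty vectors")
    if (y < 0).any() or (y > n).any() or (n < 1).any():
        raise ValueError("need 0 <= y_j <= n_j and n_j >= 1")
    return y, n


def fit_moment_match(
    y: Sequence[float],
    n: Sequence[float],
    cap_factor: float = DEFAULT_CAP_FACTOR,
) -> tuple[float, float]:
    """Moment-matching estimate of (α, β) from replicate counts.

    Matches the observed variance of the replicate fractions y_j/n_j
    against the binomial expectation mean·(1−mean)/mean(n): with
    r = obsvar/expvar, the concentration is α+β = (mean(n)−1)/(r−1) − 1 and
    α = mean·(α+β). Degenerate regimes are handled explicitly: a mean of
    exactly 0 or 1 gets a half-count pseudocount (y+½, n+1); observed
    variance at or below the binomial expectation (underdispersion, where
    the concentration formula has no positive solution) clamps the
    concentration to ``cap_factor·mean(n)``; overdispersion so extreme the
    formula turns non-positive clamps it to a small floor.
    """
    y, n = _validated(y, n)
    k = len(y)
    cap = cap_factor * float(n.mean())
    f = y / n
    m = float(f.mean())
    if m <= 0.0 or m >= 1.0:
        y = y + 0.5
        n = n + 1.0
        f = y / n
        m = float(f.mean())
    if k < 2:
        s = cap
    else:
        obsvar = float(f.var(ddof=1))
        expvar = m * (1.0 - m) / float(n.mean())
        if obsvar <= expvar:
            s = cap
        else:
            s = (float(n.mean()) - 1.0) / (obsvar / expvar - 1.0) - 1.0
            if s <= 0:
                s = _CONCENTRATION_FLOOR
    return m * s, (1.0 - m) * s


def fit_betabin_mle(
    y: Sequence[float],
    n: Sequence[float],
    cap_factor: float = DEFAULT_CAP_FACTOR,
) -> tuple[float, float, str]:
    """Maximum-likelihood (α, β) via the digamma score equations.

    Roots are found in log-parameter space starting from the
    moment-matching estimate; the result is accepted only if the solver
    converges to positive finite parameters whose likelihood is no worse
    than the starting point. Boundary data (all counts 0 or all saturated)
    and single-replicate data are unidentifiable and fall back to
    :func:`fit_moment_match`, as does any solver failure; the third return
    value reports which path produced the estimate.
    """
    y, n = _validated(y, n)
    k = len(y)
    a0, b0 = fit_moment_match(y, n, cap_factor=cap_factor)
    if k < 2 or np.all(y == 0) or np.all(y == n):
        return a0, b0, "moment_match"

    def score(t: np.ndarray) -> np.ndarray:
        a, b = np.exp(t)
        da = np.sum(special.psi(y + a) - special.psi(n + a + b)) - k * (
            special.psi(a) - special.psi(a + b)
        )
        db = np.sum(special.psi(n - y + b) - special.psi(n + a + b)) - k * (
            special.psi(b) - special.psi(a + b)
        )
        return np.array([da, db])

    with np.errstate(all="ignore"):
        sol = optimize.root(score, np.log([a0, b0]), method="hybr")
    if sol.success:
        a, b = np.exp(sol.x)
        if (
            np.isfinite(a)
            and np.isfinite(b)
            and a > 0
            and b > 0
            and betabin_loglik(a, b, y, n) >= betabin_loglik(a0, b0, y, n) - 1e-9
        ):
            return float(a), float(b), "score_equations"
    return a0, b0, "moment_match"


def beta_moments(alpha: float, beta: float) -> tuple[float, float]:
    """Mean α/(α+β) and variance αβ/((α+β)²(α+β+1)) of a Beta law."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    s = alpha + beta
    return alpha / s, alpha * beta / (s * s * (s + 1.0))


def prob_beat_control(
    pep: tuple[float, float],
    ctrl: tuple[float, float],
    n_ref: int,
    mode: str = "auto",
    draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """P(peptide count > control count) + ½·P(tie) at a reference depth.

    Both counts are beta-binomial(n_ref, ·) under the respective fitted
    parameters. ``exact_enumeration`` sums the pmf product (used
    automatically up to n_ref = 5000); ``monte_carlo`` draws paired samples
    and is deterministic given ``seed``.
    """
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    if mode == "auto":
        mode = "exact_enumeration" if n_ref <= EXACT_ENUM_MAX_N else "monte_carlo"
    a1, b1 = pep
    a2, b2 = ctrl
    if min(a1, b1, a2, b2) <= 0:
        raise ValueError("parameters must be positive")
    if mode == "exact_enumeration":
        ks = np.arange(n_ref + 1)
        pmf_p = stats.betabinom.pmf(ks, n_ref, a1, b1)
        pmf_c = stats.betabinom.pmf(ks, n_ref, a2, b2)
        cdf_c = np.cumsum(pmf_c)
        p_gt = float(np.sum(pmf_p * (cdf_c - pmf_c)))
        p_eq = float(np.sum(pmf_p * pmf_c))
        return p_gt + 0.5 * p_eq
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        yp = rng.binomial(n_ref, rng.beta(a1, b1, draws))
        yc = rng.binomial(n_ref, rng.beta(a2, b2, draws))
        return float(np.mean(yp > yc) + 0.5 * np.mean(yp == yc))
    raise ValueError(f"unknown mode {mode!r}")


def estimate_effect(
    peptide_id: str, y: Sequence[float], n: Sequence[float], cap_factor: float = DEFAULT_CAP_FACTOR
) -> EffectEstimate:
    a, b, method = fit_betabin_mle(y, n, cap_factor=cap_factor)
    return EffectEstimate(peptide_id, a, b, method)


def fit_all(counts: CountMatrix, cap_factor: float = DEFAULT_CAP_FACTOR) -> pd.DataFrame:
    """Fit (α, β) per peptide from its replicate edited/total counts."""
    ymat = counts.pivot("prime_edited")
    nmat = counts.pivot("n")
    rows = []
    for pid in ymat.index:
        yv = ymat.loc[pid].to_numpy(dtype=float)
        nv = nmat.loc[pid].to_numpy(dtype=float)
        mask = nv > 0
        est = estimate_effect(pid, yv[mask], nv[mask], cap_factor=cap_factor)
        rows.append(
            {
                "peptide_id": pid,
                "alpha": est.alpha,
                "beta": est.beta,
                "method": est.method,
                "mean": est.mean,
                "variance": est.variance,
            }
        )
    return pd.DataFrame(rows).set_index("peptide_id")


def normalize_and_call(
    counts: CountMatrix,
    estimates: Optional[pd.DataFrame],
    control_ids: set[str],
    fdr: float = 0.05,
    n_ref: Optional[int] = None,
    mode: str = "auto",
    draws: int = 1_000_000,
    cap_factor: float = DEFAULT_CAP_FACTOR,
    seed: int = 0,
) -> pd.DataFrame:
    """Control-normalised fold changes, significance calls, and ranking.

    Per replicate, each peptide's edited fraction is divided by the mean
    edited fraction of the control peptides in that replicate (replicates
    with zero control editing are excluded with a warning). Significance
    uses a two-sided paired t-test of each peptide's replicate fractions
    against the control means, corrected by Benjamini–Hochberg at ``fdr``.
    Peptides are additionally scored by ``p_beat_control`` against a single
    beta-binomial fit pooling all control counts, and the composite rank
    orders by that probability, breaking ties by higher fitted mean and
    then lower fitted variance.
    """
    if estimates is None:
        estimates = fit_all(counts, cap_factor=cap_factor)
    frac = counts.edited_fraction()
    present_controls = [c for c in control_ids if c in frac.index]
    if not present_controls:
        raise ValueError("no control peptide present in the count matrix")

    ctrl_mean = frac.loc[present_controls].mean(axis=0)
    usable = ctrl_mean.index[(ctrl_mean > 0) & ctrl_mean.notna()]
    dropped_reps = sorted(set(ctrl_mean.index) - set(usable))
    if dropped_reps:
        warnings.warn(
            f"replicates with zero control editing excluded from normalization: {dropped_reps}"
        )
    if len(usable) == 0:
        raise ValueError("no replicate has nonzero control editing")
    normalized = frac[usable] / ctrl_mean[usable]
    fold_change = normalized.mean(axis=1)

    # paired t-test of per-replicate fractions vs the control means
    pvals = {}
    for pid in frac.index:
        x = frac.loc[pid, usable].to_numpy(dtype=float)
        c = ctrl_mean[usable].to_numpy(dtype=float)
        if len(usable) < 2:
            pvals[pid] = 1.0
            continue
        with np.errstate(all="ignore"):
            res = stats.ttest_rel(x, c)
        pvals[pid] = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    pval = pd.Series(pvals)

    reject, qval, _, _ = multipletests(pval.to_numpy(), alpha=fdr if fdr > 0 else 0.05, method="fdr_bh")
    significant = reject if fdr > 0 else np.zeros(len(pval), dtype=bool)

    # pooled control beta-binomial comparison distribution
    ctrl_counts = counts.df[counts.df["peptide_id"].isin(present_controls)]
    ctrl_fit = fit_betabin_mle(
        ctrl_counts["prime_edited"].to_numpy(dtype=float),
        ctrl_counts["n"].to_numpy(dtype=float).clip(min=1),
        cap_factor=cap_factor,
    )
    if n_ref is None:
        n_ref = int(max(1, counts.df["n"].median()))
    p_beat = {
        pid: prob_beat_control(
            (estimates.loc[pid, "alpha"], estimates.loc[pid, "beta"]),
            ctrl_fit[:2],
            n_ref=n_ref,
            mode=mode,
            draws=draws,
            seed=seed,
        )
        for pid in frac.index
    }

    table = pd.DataFrame(
        {
            "peptide_id": frac.index,
            "alpha": estimates.loc[frac.index, "alpha"].to_numpy(),
            "beta": estimates.loc[frac.index, "beta"].to_numpy(),
            "method": estimates.loc[frac.index, "method"].to_numpy(),
            "mean": estimates.loc[frac.index, "mean"].to_numpy(),
            "variance": estimates.loc[frac.index, "variance"].to_numpy(),
            "p_beat_control": [p_beat[pid] for pid in frac.index],
            "fold_change": fold_change.loc[frac.index].to_numpy(),
            "pvalue": pval.loc[frac.index].to_numpy(),
            "qvalue": qval,
            "significant": significant,
            "is_control": [pid in control_ids for pid in frac.index],
        }
    )
    order = np.lexsort(
        (table["variance"].to_numpy(), -table["mean"].to_numpy(), -table["p_beat_control"].to_numpy())
    )
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
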