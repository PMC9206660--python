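"""Beta-binomial fitting, exceedance probabilities, and hit calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from pepseq.inference import (
    EmptyAnalysisError,
    beta_moments,
    betabin_loglik,
    filter_low_coverage,
    fit_all,
    fit_betabin_mle,
    fit_moment_match,
    normalize_and_call,
    prob_beat_control,
)
from pepseq.reads import CountMatrix
from pepseq.simulate import draw_true_effects, simulate_counts


def make_counts(rows):
    df = pd.DataFrame(
        [
            {
                "peptide_id": pid,
                "replicate": rep,
                "n": n,
                "prime_edited": y,
                "unedited": n - y,
                "indel": 0,
                "other": 0,
            }
            for pid, rep, y, n in rows
        ]
    )
    return CountMatrix(df)


# ---------------------------------------------------------------------------
# coverage filter


def test_low_coverage_peptide_excluded_on_any_replicate():
    cm = make_counts(
        [("a", f"r{i}", 10, n) for i, n in enumerate((99, 5000, 5000))]
        + [("b", f"r{i}", 10, 100) for i in range(3)]
    )
    kept = filter_low_coverage(cm, min_reads=100)
    assert kept.peptides == ["b"]  # boundary is strict "less than"


def test_min_reads_zero_is_identity():
    cm = make_counts([("a", "r1", 0, 1), ("b", "r1", 1, 1)])
    assert filter_low_coverage(cm, min_reads=0).peptides == ["a", "b"]


def test_all_filtered_raises():
    cm = make_counts([("a", "r1", 1, 50)])
    with pytest.raises(EmptyAnalysisError):
        filter_low_coverage(cm, min_reads=100)


# ---------------------------------------------------------------------------
# moment matching


def test_moment_match_worked_instance():
    # hand evaluation: fractions (0.2, 0.4); mean 0.3; obsvar 0.02 (k-1
    # denominator); expvar 0.3*0.7/100 = 0.0021; ratio 200/21;
    # concentration = 99/(ratio-1) - 1; alpha = 0.3 * concentration
    a, b = fit_moment_match([20, 40], [100, 100])
    conc_expected = 99.0 / (0.02 / 0.0021 - 1.0) - 1.0
    assert np.isclose(a + b, conc_expected)
    assert np.isclose(a, 0.3 * conc_expected)
    assert np.isclose(a + b, 10.61, atol=0.01)
    assert np.isclose(a, 3.18, atol=0.01)


def test_moment_match_zero_variance_clamps_concentration():
    a, b = fit_moment_match([30, 30], [100, 100])
    assert np.isclose(a / (a + b), 0.3)
    assert np.isclose(a + b, 10.0 * 100)  # default cap


def test_moment_match_depth_dependence():
    # the concentration formula depends on mean(n): scaling all counts by 10
    # with fixed fractions must follow the formula, not stay invariant
    for scale in (1, 10):
        y = np.array([20, 40]) * scale
        n = np.array([100, 100]) * scale
        a, b = fit_moment_match(y, n)
        f = y / n
        obsvar = f.var(ddof=1)
        expvar = f.mean() * (1 - f.mean()) / n.mean()
        expected = (n.mean() - 1.0) / (obsvar / expvar - 1.0) - 1.0
        assert np.isclose(a + b, expected)
    a1, _ = fit_moment_match([20, 40], [100, 100])
    a10, _ = fit_moment_match([200, 400], [1000, 1000])
    assert not np.isclose(a1, a10)


def test_boundary_counts_get_pseudocounts():
    a, b, method = fit_betabin_mle([0, 0], [100, 100])
    assert method == "moment_match"
    assert 0 < a / (a + b) < 0.01


def test_single_replicate_falls_back_with_cap():
    a, b, method = fit_betabin_mle([30], [100])
    assert method == "moment_match"
    assert np.isclose(a + b, 1000.0)
    assert np.isclose(a / (a + b), 0.3)


# ---------------------------------------------------------------------------
# beta moments


@pytest.mark.parametrize(
    "alpha, beta, mean, var",
    [(2, 2, 0.5, 0.05), (1, 1, 0.5, 1 / 12), (10, 40, 0.2, 400 / (2500 * 51))],
)
def test_beta_moments(alpha, beta, mean, var):
    m, v = beta_moments(alpha, beta)
    assert np.isclose(m, mean)
    assert np.isclose(v, var)


def test_beta_moments_rejects_nonpositive():
    with pytest.raises(ValueError):
        beta_moments(0.0, 1.0)


# ---------------------------------------------------------------------------
# maximum likelihood


def grid_mle(y, n, mean_pts=400, conc_pts=140):
    """Two-stage likelihood-grid maximization (independent oracle)."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)

    def ll_grid(means, concs):
        A = means[:, None] * concs[None, :]
        B = (1.0 - means[:, None]) * concs[None, :]
        ll = -len(y) * special.betaln(A, B)
        for yj, nj in zip(y, n):
            ll = ll + special.betaln(yj + A, nj - yj + B)
        return ll

    means = np.linspace(0.001, 0.999, mean_pts)
    concs = np.logspace(-1.0, 4.0, conc_pts)
    ll = ll_grid(means, concs)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    m_lo, m_hi = means[max(i - 1, 0)], means[min(i + 1, mean_pts - 1)]
    c_lo, c_hi = concs[max(j - 1, 0)], concs[min(j + 1, conc_pts - 1)]
    means2 = np.linspace(m_lo, m_hi, 61)
    concs2 = np.logspace(np.log10(c_lo), np.log10(c_hi), 61)
    ll2 = ll_grid(means2, concs2)
    i2, j2 = np.unravel_index(np.argmax(ll2), ll2.shape)
    return means2[i2], concs2[j2]


def overdispersed_instances(n_instances, seed):
    """Random beta-binomial samples whose likelihood peaks at finite concentration.

    Samples that look binomial (the likelihood increases toward infinite
    concentration) have no finite MLE — the clamp rule applies there, and a
    grid comparison is ill-posed — so they are skipped. The screen uses an
    inline likelihood evaluation independent of the fitting code.
    """

    def loglik(mean, conc, y, n):
        a, b = mean * conc, (1.0 - mean) * conc
        return np.sum(special.betaln(y + a, n - y + b)) - len(y) * special.betaln(a, b)

    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_instances:
        k = int(rng.integers(2, 6))
        n = rng.integers(80, 501, k).astype(float)
        m = rng.uniform(0.1, 0.6)
        s = rng.uniform(3.0, 40.0)
        p = rng.beta(m * s, (1 - m) * s, k)
        y = rng.binomial(n.astype(int), p).astype(float)
        f = y / n
        if f.mean() <= 0.0 or f.mean() >= 1.0:
            continue
        obsvar = f.var(ddof=1)
        expvar = f.mean() * (1 - f.mean()) / n.mean()
        if obsvar <= expvar:
            continue
        # interior candidate (the printed moment formulas) must beat the
        # near-binomial boundary for a finite maximizer to exist
        s_mm = (n.mean() - 1.0) / (obsvar / expvar - 1.0) - 1.0
        if s_mm <= 0:
            continue
        ll_interior = loglik(f.mean(), s_mm, y, n)
        ll_boundary = loglik(y.sum() / n.sum(), 1e7, y, n)
        if ll_interior <= ll_boundary:
            continue
        out.append((y, n))
    return out


def test_mle_matches_grid_oracle():
    for y, n in overdispersed_instances(40, seed=2024):
        a, b, method = fit_betabin_mle(y, n)
        m_grid, _ = grid_mle(y, n)
        assert abs(a / (a + b) - m_grid) <= 1e-3, (y, n, method)


def test_mle_never_below_moment_likelihood():
    for y, n in overdispersed_instances(20, seed=77):
        a, b, _ = fit_betabin_mle(y, n)
        a0, b0 = fit_moment_match(y, n)
        assert betabin_loglik(a, b, y, n) >= betabin_loglik(a0, b0, y, n) - 1e-9


def test_mle_consistency_limit():
    # equal large counts: fitted mean converges to the common fraction
    a, b, _ = fit_betabin_mle([300] * 6, [1000] * 6)
    assert np.isclose(a / (a + b), 0.3, atol=1e-6)


def test_moment_match_inverts_beta_moments_at_scale():
    rng = np.random.default_rng(4)
    alpha, beta, n, k = 10.0, 40.0, 2000, 3000
    p = rng.beta(alpha, beta, k)
    y = rng.binomial(n, p)
    a, b = fit_moment_match(y, np.full(k, n))
    m_true, v_true = beta_moments(alpha, beta)
    m_fit, v_fit = beta_moments(a, b)
    assert np.isclose(m_fit, m_true, atol=0.01)
    assert np.isclose(v_fit, v_true, rtol=0.2)


# ---------------------------------------------------------------------------
# exceedance probability


def test_prob_beat_identical_is_half():
    assert np.isclose(prob_beat_control((5, 20), (5, 20), n_ref=100), 0.5)


def test_prob_beat_separated_distributions():
    p = prob_beat_control((900, 100), (100, 900), n_ref=1000)
    assert p > 0.999


def test_prob_beat_monotone_in_peptide_mean():
    ctrl = (20, 80)
    probs = [
        prob_beat_control((m * 100, (1 - m) * 100), ctrl, n_ref=500)
        for m in (0.1, 0.2, 0.3, 0.4, 0.5)
    ]
    assert all(b > a for a, b in zip(probs, probs[1:]))


def test_monte_carlo_agrees_with_exact_enumeration():
    pep, ctrl = (6.0, 14.0), (4.0, 16.0)
    exact = prob_beat_control(pep, ctrl, n_ref=10, mode="exact_enumeration")
    mc = prob_beat_control(pep, ctrl, n_ref=10, mode="monte_carlo", draws=10**6, seed=3)
    assert abs(exact - mc) <= 0.003


def test_prob_beat_validates_inputs():
    with pytest.raises(ValueError):
        prob_beat_control((1, 1), (1, 1), n_ref=0)
    with pytest.raises(ValueError):
        prob_beat_control((0, 1), (1, 1), n_ref=10)
    with pytest.raises(ValueError):
        prob_beat_control((1, 1), (1, 1), n_ref=10, mode="nope")


# ---------------------------------------------------------------------------
# normalization and hit calling


def screen_counts(seed=0, enhancer_fold=1.8, depth=2000):
    ids = [f"pep{i}" for i in range(20)] + ["ctrl1", "ctrl2", "ctrl3"]
    lib = [type("R", (), {"peptide_id": pid})() for pid in ids]
    effects = draw_true_effects(
        lib, control_mean=0.2, enhancer_ids={"pep0"}, enhancer_fold=enhancer_fold,
        concentration=400.0, seed=seed,
    )
    cm, truth = simulate_counts(effects, depth_per_peptide=depth, replicates=4, seed=seed)
    return cm, {"ctrl1", "ctrl2", "ctrl3"}


def test_control_fold_change_averages_one_exactly():
    cm, controls = screen_counts(seed=5)
    table = normalize_and_call(cm, None, controls)
    ctrl_rows = table[table["is_control"]]
    assert np.isclose(ctrl_rows["fold_change"].mean(), 1.0)


def test_planted_enhancer_ranks_first():
    cm, controls = screen_counts(seed=6)
    table = normalize_and_call(cm, None, controls)
    assert table.iloc[0]["peptide_id"] == "pep0"
    assert table.iloc[0]["fold_change"] > 1.3


def test_fdr_zero_yields_no_hits():
    cm, controls = screen_counts(seed=7)
    table = normalize_and_call(cm, None, controls, fdr=0.0)
    assert not table["significant"].any()


def test_zero_control_replicate_excluded_with_warning():
    rows = []
    for pid in ("a", "ctrl"):
        for rep, y in (("r1", 20), ("r2", 30), ("r3", 0)):
            rows.append((pid, rep, y if pid == "a" or rep != "r3" else 0, 100))
    cm = make_counts(rows)
    with pytest.warns(UserWarning, match="zero control editing"):
        table = normalize_and_call(cm, None, {"ctrl"})
    assert len(table) == 2


def test_missing_controls_rejected():
    cm = make_counts([("a", "r1", 5, 100), ("a", "r2", 6, 100)])
    with pytest.raises(ValueError, match="control"):
        normalize_and_call(cm, None, {"ctrl"})


def test_fit_all_reports_methods_and_moments():
    cm, _ = screen_counts(seed=8)
    est = fit_all(cm)
    assert set(est.columns) == {"alpha", "beta", "method", "mean", "variance"}
    s = est["alpha"] + est["beta"]
    assert np.allclose(est["mean"], est["alpha"] / s)
    assert np.allclose(est["variance"], est["alpha"] * est["beta"] / (s**2 * (s + 1)))
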