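"""Nonparametric layer and the random-intercept mixed model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from speechtrf.stats import (
    MODEL_LEVELS,
    StatsError,
    emm_at_pta,
    fit_lmm,
    holm_adjust,
    mann_whitney,
    pta_from_audiogram,
    spearman_fisher,
    u_to_rank_biserial,
)


# ---------------------------------------------------------------------------
# audiometry
# ---------------------------------------------------------------------------


def test_pta_averages_frequencies_then_ears():
    assert pta_from_audiogram([10, 20, 30, 40]) == 25.0
    assert pta_from_audiogram([10, 20, 30, 40], [10, 20, 30, 40]) == 25.0
    assert pta_from_audiogram([20] * 4, [30] * 4) == 25.0
    with pytest.raises(StatsError, match="missing"):
        pta_from_audiogram({500: 10, 1000: 20, 2000: 30})


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def _exact_two_sided_p(x, y):
    """Enumerate all group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    mu = n1 * len(y) / 2
    return np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mann_whitney_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(6)
    y = rng.standard_normal(5) + 0.5
    res = mann_whitney(x, y, method="exact")
    assert res.p_raw == pytest.approx(_exact_two_sided_p(x, y), abs=1e-9)
    assert res.r == pytest.approx(1 - 2 * res.U / 30)


def test_mann_whitney_identical_samples():
    res = mann_whitney([3.0, 3.0, 3.0], [3.0, 3.0])
    assert res.p_raw == 1.0 and res.r == 0.0


def test_symmetric_u_gives_zero_effect():
    assert u_to_rank_biserial(237.5, 25, 19) == 0.0


# ---------------------------------------------------------------------------
# Holm and Spearman
# ---------------------------------------------------------------------------


def test_holm_worked_example():
    adj = holm_adjust([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    assert holm_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=15))
def test_holm_dominates_input_and_preserves_order(p):
    p = np.asarray(p)
    adj = holm_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    # significance ordering preserved
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_spearman_fisher_values(rng):
    x = np.arange(20.0)
    rho, p, z = spearman_fisher(x, 2 * x + 1)
    assert rho == 1.0 and np.isinf(z)
    y = x + rng.normal(0, 8, 20)
    rho, p, z = spearman_fisher(x, y)
    assert z == pytest.approx(np.arctanh(rho))
    rho, p, z = spearman_fisher(x, np.ones(20))
    assert np.isnan(rho)


def test_spearman_null_p_is_uniform(rng):
    ps = []
    for _ in range(400):
        x = rng.standard_normal(44)
        y = rng.standard_normal(44)
        ps.append(spearman_fisher(x, y)[1])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# LMM
# ---------------------------------------------------------------------------


def _accuracy_table(rng, n=44, n_normal=25, re_sd=0.01, noise=0.005,
                    model_effects=None, pta_slopes=None):
    pta_z = rng.standard_normal(n)
    pta_z = (pta_z - pta_z.mean()) / pta_z.std()
    u = rng.normal(0, re_sd, n)
    model_effects = model_effects or {}
    pta_slopes = pta_slopes or {}
    rows = []
    for i in range(n):
        grp = "normal" if i < n_normal else "low"
        for m in MODEL_LEVELS:
            acc = (0.03 + model_effects.get(m, 0.0)
                   + pta_slopes.get(m, 0.0) * pta_z[i]
                   + u[i] + rng.normal(0, noise))
            rows.append(dict(participant_id=f"p{i:02d}", moca_group=grp,
                             moca_score=27 if grp == "normal" else 23,
                             pta_z=pta_z[i], model=m, accuracy=acc))
    return pd.DataFrame(rows)


def test_lmm_matches_statsmodels_mixedlm(rng):
    """Independent cross-check of the REML fit against statsmodels."""
    import statsmodels.formula.api as smf

    tab = _accuracy_table(rng)
    mine = fit_lmm(tab, "encoding_accuracy", n_boot=0)
    md = smf.mixedlm("accuracy ~ C(moca_group)*pta_z*C(model)", tab,
                     groups=tab["participant_id"])
    ref = md.fit(reml=True)
    assert mine.sigma2 == pytest.approx(float(ref.scale), rel=1e-4)
    assert mine.tau2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
    # the intercept under sum coding equals the grand mean of cell means
    cell_means = tab.groupby(["participant_id", "model"]).accuracy.mean()
    grand = cell_means.groupby(level="model").mean().mean()
    assert mine.coef("intercept").beta == pytest.approx(grand, abs=2e-3)


def test_lmm_bootstrap_cis_bracket_estimates(rng):
    tab = _accuracy_table(rng)
    res = fit_lmm(tab, "encoding_accuracy", n_boot=200, seed=0)
    c = res.coefficients
    assert np.all(c.ci_low <= c.beta + 1e-12)
    assert np.all(c.ci_high >= c.beta - 1e-12)


def test_lmm_recovers_known_interaction(rng):
    """A negative PTA slope on the seg_word accuracies yields a positive
    acoustic-minus-seg_word difference slope in most seeds."""
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        tab = _accuracy_table(r, pta_slopes={"seg_word": -0.004})
        res = fit_lmm(tab, "encoding_accuracy", n_boot=0)
        emm = emm_at_pta(res, "seg_word")
        slope = emm.estimate.iloc[-1] - emm.estimate.iloc[0]
        hits += slope > 0
    assert hits >= 9


def test_emm_identity_contrast_is_zero(rng):
    res = fit_lmm(_accuracy_table(rng), "encoding_accuracy", n_boot=0)
    emm = emm_at_pta(res, "acoustic")
    assert np.allclose(emm.estimate, 0.0)
    assert np.allclose(emm.p_adj, 1.0)


def test_emm_differences_linear_in_pta(rng):
    res = fit_lmm(_accuracy_table(rng, pta_slopes={"seg_word": -0.004}),
                  "encoding_accuracy", n_boot=0)
    emm = emm_at_pta(res, "seg_word", pta_levels=(-1.0, 0.0, 1.0))
    d = np.diff(emm.estimate.to_numpy())
    assert d[0] == pytest.approx(d[1], abs=1e-12)  # exact model linearity


def test_continuous_moca_variant(rng):
    res = fit_lmm(_accuracy_table(rng), "encoding_accuracy", moca="continuous",
                  n_boot=0)
    assert "moca_z" in set(res.coefficients.term)


def test_lmm_type_one_error_for_group_effect(rng):
    """Under the null the group main effect rejects at ~5%."""
    n_sims, hits = 400, 0
    for s in range(n_sims):
        r = np.random.default_rng(10_000 + s)
        tab = _accuracy_table(r, n=20, n_normal=11)
        res = fit_lmm(tab, "encoding_accuracy", n_boot=0)
        hits += res.coef("moca_group_low").p < 0.05
    assert 0.02 <= hits / n_sims <= 0.09


def test_lmm_requires_identifiable_design(rng):
    tab = _accuracy_table(rng).iloc[:15]
    with pytest.raises(StatsError):
        fit_lmm(tab, "encoding_accuracy", n_boot=0)
    with pytest.raises(StatsError, match="formula"):
        fit_lmm(tab, "nonsense", n_boot=0)
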