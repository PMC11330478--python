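"""Group-level statistics for the encoding analysis.

Nonparametric layer: two-tailed Mann-Whitney U tests with the signed
rank-biserial effect size r = 1 - 2U/(n1*n2), Holm-Bonferroni familywise
correction, and Spearman correlation with the Fisher z transform.

Model layer: linear mixed models with a participant random intercept,
sum-to-zero contrasts for the categorical predictors, standardized PTA, and
Satterthwaite-approximated denominator degrees of freedom. Three formula
tags cover the analyses:

``encoding_accuracy``   accuracy ~ group * PTA_z * model + (1 | participant)
``rms_two_feature``     rms ~ group * PTA_z + feature + cluster + (1 | participant)
``rms_one_feature``     rms ~ group * PTA_z + cluster + (1 | participant)

The random-intercept REML fit is computed in closed form per participant
block (Woodbury identity), profiled to a one-dimensional search over the
variance ratio; that also makes the parametric bootstrap for confidence
intervals cheap. Satterthwaite df for a contrast c follows
2 f^2 / (g' A g) with f = c' Cov(beta) c, g its gradient in the variance
components, and A the inverse curvature of the REML criterion.
Estimated marginal means of the model-vs-acoustic differences are evaluated
at PTA z in {-1, 0, +1}, with Tukey (studentized-range) adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MODEL_LEVELS = ("acoustic", "seg_word", "seg_phoneme", "ling_word", "ling_phoneme")


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Audiometry
# ---------------------------------------------------------------------------

PTA_FREQS = (500, 1000, 2000, 4000)


def pta_from_audiogram(left, right=None) -> float:
    """Four-frequency pure-tone average: mean of the 500/1000/2000/4000 Hz
    thresholds per ear, then the mean over ears (dB HL)."""

    def ear(t) -> float:
        if isinstance(t, Mapping):
            missing = [f for f in PTA_FREQS if f not in t]
            if missing:
                raise StatsError(f"missing audiogram frequencies: {missing}")
            vals = [t[f] for f in PTA_FREQS]
        else:
            vals = list(t)
            if len(vals) != 4:
                raise StatsError("need exactly four thresholds per ear")
        return float(np.mean(vals))

    if right is None:
        return ear(left)
    return (ear(left) + ear(right)) / 2.0


# ---------------------------------------------------------------------------
# Mann-Whitney / Holm / Spearman
# ---------------------------------------------------------------------------


@dataclass
class StatResult:
    U: float
    n1: int
    n2: int
    p_raw: float
    r: float  # signed rank-biserial, 1 - 2U/(n1*n2)
    p_corrected: float | None = None


def u_to_rank_biserial(U: float, n1: int, n2: int) -> float:
    return 1.0 - 2.0 * U / (n1 * n2)


def u_to_p(U: float, n1: int, n2: int) -> float:
    """Two-sided p from the continuity-corrected normal approximation
    (no tie correction; used to convert printed U statistics)."""
    mu = n1 * n2 / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    diff = U - mu
    z = (diff - 0.5 * np.sign(diff)) / sd
    return float(2.0 * sps.norm.sf(abs(z)))


def mann_whitney(x, y, *, method: str = "asymptotic") -> StatResult:
    """Two-tailed Mann-Whitney U test; U is the statistic of the first group.

    The asymptotic p uses the continuity-corrected normal approximation with
    tie-corrected variance; ``method='exact'`` enumerates (no ties only).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if min(n1, n2) < 2:
        raise StatsError("each group needs >= 2 values")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return StatResult(U=n1 * n2 / 2.0, n1=n1, n2=n2, p_raw=1.0, r=0.0)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    U = float(res.statistic)
    return StatResult(U=U, n1=n1, n2=n2, p_raw=float(res.pvalue),
                      r=u_to_rank_biserial(U, n1, n2))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise StatsError("empty p-value family")
    return multipletests(p, method="holm")[1]


def spearman_fisher(x, y) -> tuple[float, float, float]:
    """Spearman rho, its p value, and Fisher's z = atanh(rho)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise StatsError("need paired samples of length >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    z = float(np.arctanh(rho)) if abs(rho) < 1 else float(np.sign(rho) * np.inf)
    return float(rho), float(p), z


# ---------------------------------------------------------------------------
# Random-intercept LMM (REML, Satterthwaite)
# ---------------------------------------------------------------------------


class _RandomInterceptREML:
    """Closed-form REML machinery for y = X b + u_group + e."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X = np.asarray(X, float)
        y = np.asarray(y, float)
        # normalise the response so variance components are O(1) regardless
        # of units (df and t statistics are scale-invariant)
        self.yscale = float(y.std()) or 1.0
        self.y = y / self.yscale
        codes, _ = pd.factorize(groups)
        self.codes = codes
        self.n, self.p = self.X.shape
        self.ngroups = codes.max() + 1
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        # per-group sums
        self.m = np.bincount(codes)
        self.sx = np.zeros((self.ngroups, self.p))
        np.add.at(self.sx, codes, self.X)
        self.sy = np.bincount(codes, weights=self.y)

    def _parts(self, lam: float):
        a = lam / (1.0 + self.m * lam)  # (ngroups,)
        A = self.XtX - (self.sx * a[:, None]).T @ self.sx
        b = self.Xty - self.sx.T @ (a * self.sy)
        q = self.yty - float(a @ self.sy**2)
        return A, b, q

    def criterion(self, lam: float) -> float:
        """Profiled -2 REML log-likelihood (up to a constant)."""
        A, b, q = self._parts(lam)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, b)
        rss = q - float(b @ beta)
        if rss <= 0:
            return np.inf
        df = self.n - self.p
        return df * np.log(rss / df) + float(np.sum(np.log1p(self.m * lam))) + logdetA

    def fit(self):
        res = minimize_scalar(
            lambda u: self.criterion(np.exp(u)), bounds=(-14.0, 14.0),
            method="bounded", options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        if self.criterion(1e-12) <= res.fun:  # boundary: no group variance
            lam = 0.0
        A, b, q = self._parts(lam)
        beta = np.linalg.solve(A, b)
        rss = q - float(b @ beta)
        sigma2 = rss / (self.n - self.p)
        tau2 = lam * sigma2
        cov_beta = sigma2 * np.linalg.inv(A)
        s2 = self.yscale**2
        return beta * self.yscale, cov_beta * s2, tau2 * s2, sigma2 * s2

    # -- Satterthwaite ----------------------------------------------------

    def _neg2reml(self, tau2: float, sigma2: float) -> float:
        """-2 REML log-likelihood at external-scale variance components."""
        s2 = self.yscale**2
        tau2, sigma2 = tau2 / s2, sigma2 / s2
        lam = tau2 / sigma2
        A, b, q = self._parts(lam)
        beta = np.linalg.solve(A, b)
        rss = q - float(b @ beta)
        sign, logdetA = np.linalg.slogdet(A)
        return (
            float(np.sum((self.m - 1) * np.log(sigma2)
                         + np.log(sigma2 + self.m * tau2)))
            + logdetA
            - self.p * np.log(sigma2)
            + rss / sigma2
        )

    def _contrast_var(self, c: np.ndarray, tau2: float, sigma2: float) -> float:
        lam = tau2 / sigma2
        A, _, _ = self._parts(lam)
        return sigma2 * float(c @ np.linalg.solve(A, c))

    def satterthwaite_df(self, c: np.ndarray, tau2: float, sigma2: float) -> float:
        """df = 2 f^2 / (g' Cov(theta) g) with f = Var(c' beta_hat)."""
        theta = np.array([max(tau2, 0.0), sigma2])
        scale = float(np.max(theta))
        h = np.maximum(1e-7 * np.abs(theta), 1e-9 * scale)
        f0 = self._contrast_var(c, *theta)

        def fvar(t):
            return self._contrast_var(c, max(t[0], 0.0), t[1])

        g = np.zeros(2)
        for i in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            g[i] = (fvar(tp) - fvar(tm)) / (2 * h[i])

        cov_theta = self._cov_theta(theta)
        denom = float(g @ cov_theta @ g) if cov_theta is not None else 0.0
        if denom <= 0:
            return float(self.n - self.p)
        return float(2.0 * f0**2 / denom)

    def _cov_theta(self, theta: np.ndarray):
        """2 * inverse observed Hessian of the REML criterion (cached; the
        Hessian does not depend on the contrast)."""
        key = (float(theta[0]), float(theta[1]))
        cache = getattr(self, "_cov_cache", None)
        if cache is None:
            cache = self._cov_cache = {}
        if key in cache:
            return cache[key]
        scale = float(np.max(theta))

        def crit(t):
            return self._neg2reml(max(t[0], 1e-12 * scale), t[1])

        H = np.zeros((2, 2))
        hh = np.maximum(1e-4 * np.abs(theta), 1e-6 * scale)
        for i in range(2):
            for j in range(2):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += hh[i]
                tpp[j] += hh[j]
                tmm[i] -= hh[i]
                tmm[j] -= hh[j]
                tpm[i] += hh[i]
                tpm[j] -= hh[j]
                tmp[i] -= hh[i]
                tmp[j] += hh[j]
                H[i, j] = (crit(tpp) - crit(tpm) - crit(tmp) + crit(tmm)) / (
                    4 * hh[i] * hh[j]
                )
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
        cache[key] = cov
        return cov


@dataclass
class LMMResult:
    formula: str
    coefficients: pd.DataFrame  # term, beta, ci_low, ci_high, df, t, p
    tau2: float
    sigma2: float
    singular: bool
    n_obs: int
    _reml: _RandomInterceptREML = field(repr=False)
    _beta: np.ndarray = field(repr=False)
    _cov_beta: np.ndarray = field(repr=False)
    _terms: list = field(repr=False)
    _row_builder: object = field(repr=False)
    _levels: dict = field(repr=False)

    def coef(self, term: str) -> pd.Series:
        return self.coefficients.set_index("term").loc[term]

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """(estimate, SE, Satterthwaite df) of the contrast c' beta."""
        est = float(c @ self._beta)
        var = self._reml._contrast_var(c, self.tau2, self.sigma2)
        df = self._reml.satterthwaite_df(c, self.tau2, self.sigma2)
        return est, float(np.sqrt(var)), df


# -- design encoders --------------------------------------------------------


def _sum_code(level: str, levels: Sequence[str], reference: str) -> np.ndarray:
    """Sum-to-zero coding: one column per non-reference level, the reference
    level scoring -1 everywhere."""
    cols = [l for l in levels if l != reference]
    v = np.zeros(len(cols))
    for i, l in enumerate(cols):
        if level == l:
            v[i] = 1.0
    if level == reference:
        v[:] = -1.0
    return v


_FORMULAS = {
    "encoding_accuracy": dict(response="accuracy", factor="model",
                              levels=MODEL_LEVELS, reference="acoustic",
                              interactions=True),
    "rms_two_feature": dict(response="rms", factor="feature", levels=None,
                            reference=None, interactions=False),
    "rms_one_feature": dict(response="rms", factor=None, levels=None,
                            reference=None, interactions=False),
}


def _make_row_builder(formula: str, levels: dict, moca: str):
    """Return (terms, build(group_val, pta_z, factor_level, cluster)) for the
    formula tag. group_val is the sum-coded score (+1 low, -1 normal, 0 for
    the EMM average) or the standardized MoCA score in continuous mode."""

    spec = _FORMULAS[formula]

    def build(group: float, pta: float, level: str | None = None,
              cluster: str | None = None) -> np.ndarray:
        row = [1.0, group, pta, group * pta]
        if formula == "encoding_accuracy":
            mcols = _sum_code(level, levels["model"], "acoustic")
            row.extend(mcols)
            row.extend(group * mcols)
            row.extend(pta * mcols)
            row.extend(group * pta * mcols)
        else:
            if spec["factor"] is not None:
                row.extend(_sum_code(level, levels["feature"],
                                     levels["feature"][0]))
            row.extend(_sum_code(cluster, levels["cluster"],
                                 levels["cluster"][0]))
        return np.asarray(row)

    group_label = "moca_z" if moca == "continuous" else "moca_group_low"
    terms = ["intercept", group_label, "pta_z", f"{group_label}:pta_z"]
    if formula == "encoding_accuracy":
        mlev = [l for l in levels["model"] if l != "acoustic"]
        terms += [f"model_{m}" for m in mlev]
        terms += [f"{group_label}:model_{m}" for m in mlev]
        terms += [f"pta_z:model_{m}" for m in mlev]
        terms += [f"{group_label}:pta_z:model_{m}" for m in mlev]
    else:
        if spec["factor"] is not None:
            terms += [f"feature_{f}" for f in levels["feature"][1:]]
        terms += [f"cluster_{c}" for c in levels["cluster"][1:]]
    return terms, build


def fit_lmm(
    table: pd.DataFrame,
    formula: str,
    *,
    moca: str = "binary",
    n_boot: int = 500,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> LMMResult:
    """Fit one of the three mixed-model specifications (REML).

    ``table`` is long-format with columns ``participant_id``, ``pta_z``,
    ``moca_group`` (or ``moca_score`` in continuous mode), the response, and
    the factors the formula requires (``model``; ``feature``/``cluster``).
    Confidence bounds come from a seed-controlled parametric bootstrap
    (``n_boot`` resamples; Wald intervals when ``n_boot=0``).
    """
    if formula not in _FORMULAS:
        raise StatsError(f"unknown formula tag {formula!r}")
    spec = _FORMULAS[formula]
    df = table.copy()

    if moca == "continuous":
        score = df["moca_score"].astype(float)
        gv = ((score - score.mean()) / score.std()).to_numpy()
    else:
        gv = np.where(df["moca_group"].to_numpy() == "low", 1.0, -1.0)
    pta = df["pta_z"].to_numpy(dtype=float)

    levels: dict = {}
    if formula == "encoding_accuracy":
        obs_levels = set(df["model"])
        levels["model"] = tuple(l for l in MODEL_LEVELS if l in obs_levels)
        if "acoustic" not in obs_levels:
            raise StatsError("the acoustic reference model is required")
    else:
        levels["cluster"] = tuple(pd.unique(df["cluster"]))
        if spec["factor"] is not None:
            levels["feature"] = tuple(pd.unique(df["feature"]))

    terms, build = _make_row_builder(formula, levels, moca)
    rows = []
    for i in range(len(df)):
        level = df["model"].iat[i] if formula == "encoding_accuracy" else (
            df["feature"].iat[i] if spec["factor"] is not None else None
        )
        cluster = df["cluster"].iat[i] if formula != "encoding_accuracy" else None
        rows.append(build(gv[i], pta[i], level, cluster))
    X = np.vstack(rows)
    y = df[spec["response"]].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()

    cells = df.groupby("participant_id").size()
    if cells.nunique() > 1:
        logger.warning("unbalanced cells per participant: %s", dict(cells))

    if len(y) <= X.shape[1]:
        raise StatsError(
            f"{len(y)} observations cannot identify {X.shape[1]} fixed effects"
        )
    reml = _RandomInterceptREML(X, y, groups)
    beta, cov_beta, tau2, sigma2 = reml.fit()
    singular = tau2 <= 1e-10 * sigma2
    if singular:
        logger.warning("random-intercept variance estimated at zero (singular)")

    dfs = np.empty(len(beta))
    ts = beta / np.sqrt(np.diag(cov_beta))
    for j in range(len(beta)):
        e = np.zeros(len(beta))
        e[j] = 1.0
        dfs[j] = reml.satterthwaite_df(e, tau2, sigma2)
    ps = 2.0 * sps.t.sf(np.abs(ts), dfs)

    alpha = 1.0 - ci_level
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(beta)))
        mu = X @ beta
        for bi in range(n_boot):
            u = rng.normal(0.0, np.sqrt(max(tau2, 0.0)), size=reml.ngroups)
            ystar = mu + u[reml.codes] + rng.normal(0.0, np.sqrt(sigma2),
                                                    size=reml.n)
            bstar = _RandomInterceptREML(X, ystar, groups)
            boots[bi] = bstar.fit()[0]
        ci_low = np.quantile(boots, alpha / 2, axis=0)
        ci_high = np.quantile(boots, 1 - alpha / 2, axis=0)
    else:
        crit = sps.t.ppf(1 - alpha / 2, dfs)
        se = np.sqrt(np.diag(cov_beta))
        ci_low = beta - crit * se
        ci_high = beta + crit * se

    coef = pd.DataFrame(
        {"term": terms, "beta": beta, "ci_low": ci_low, "ci_high": ci_high,
         "df": dfs, "t": ts, "p": ps}
    )
    return LMMResult(
        formula=formula, coefficients=coef, tau2=tau2, sigma2=sigma2,
        singular=singular, n_obs=reml.n, _reml=reml, _beta=beta,
        _cov_beta=cov_beta, _terms=terms, _row_builder=build, _levels=levels,
    )


def emm_at_pta(
    result: LMMResult,
    model: str,
    pta_levels: Sequence[float] = (-1.0, 0.0, 1.0),
    *,
    adjust: str = "tukey",
) -> pd.DataFrame:
    """Acoustic-minus-model EMM differences at fixed PTA z levels.

    Marginal means average over the MoCA factor; the difference, its SE,
    Satterthwaite df, t and Tukey-adjusted p (studentized range over the
    model family) are returned per level.
    """
    if result.formula != "encoding_accuracy":
        raise StatsError("EMMs are defined for the encoding-accuracy model")
    levels = result._levels["model"]
    if model not in levels:
        raise StatsError(f"model {model!r} not in the fitted factor {levels}")
    build = result._row_builder
    k = len(levels)
    rows = []
    for z in pta_levels:
        c = build(0.0, z, "acoustic") - build(0.0, z, model)
        est, se, df = result.contrast(c)
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = est / se
            if adjust == "tukey":
                p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            else:
                p = float(2.0 * sps.t.sf(abs(t), df))
        rows.append({"contrast": f"acoustic - {model}", "pta_z": z,
                     "estimate": est, "se": se, "df": df, "t": t, "p_adj": p})
    return pd.DataFrame(rows)
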