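"""Inferential chain: RM-ANOVA, paired tests, JZS Bayes factors, mixed
models with cluster-bootstrap CIs, bootstrap mediation, and a priori power.

Everything returns a :class:`StatResult` bundle so pipeline reports stay
uniform.  Conventions:

* Two-sided p-values throughout.
* "Modified Bonferroni" multiple-comparison control is implemented as the
  Holm step-down procedure.
* Bayes factors are the default JZS (Jeffreys–Zellner–Siow) one-sample
  form with Cauchy prior scale r = √2/2, evaluated by adaptive quadrature.
* Greenhouse–Geisser correction applies when Mauchly's test is significant
  (only meaningful for ≥ 3 within levels; in a 2×2 design ε ≡ 1).
* Bootstrap resampling for clustered data resamples subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "StatResult",
    "PowerSpec",
    "paired_t",
    "holm_adjust",
    "bf10_ttest",
    "rm_anova_2x2",
    "rm_anova_oneway",
    "fit_lmm_random_intercept",
    "mediate",
    "achieved_power_rm_anova",
    "apriori_n_rm_anova",
]


@dataclass(frozen=True)
class StatResult:
    """Named statistic bundle (estimate, df, p, effect size, BF, CI)."""

    name: str
    estimate: float
    df: float | tuple[float, float]
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    bf10: float | None = None
    ci: tuple[float, float] | None = None
    correction: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")
        if self.bf10 is not None and self.bf10 <= 0:
            raise ValueError("BF10 must be positive")


# ---------------------------------------------------------------------------
# t-tests, Holm, Bayes factors


class DegenerateDataError(ValueError):
    pass


def paired_t(x, y, compute_bf: bool = False) -> StatResult:
    """Paired t-test with Cohen's dz (= mean(d)/sd(d)) and optional BF10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n ≥ 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    dz = d.mean() / sd
    bf = bf10_ttest(t, n) if compute_bf else None
    return StatResult(
        name="paired_t", estimate=float(t), df=float(n - 1), p=float(p),
        effect_size=float(dz), effect_size_name="dz", bf10=bf,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, ≤ 1, dominate raw)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bf10_ttest(t: float, n: int, prior_scale: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor BF10 for a one-sample/paired t statistic.

    BF10 = ∫ (1+Ngr²)^(−1/2) (1+t²/((1+Ngr²)ν))^(−(ν+1)/2) π(g) dg
           ÷ (1+t²/ν)^(−(ν+1)/2),

    with ν = n−1 and π(g) the inverse-χ²(1) prior density
    (2π)^(−1/2) g^(−3/2) e^(−1/(2g)) — equivalently a Cauchy(0, r) prior
    on the standardised effect.  Evaluated in log space by adaptive
    quadrature to ~1e-8 relative accuracy.
    """
    if n < 2:
        raise ValueError("n must be ≥ 2")
    if prior_scale <= 0:
        raise ValueError("prior scale must be positive")
    nu = n - 1
    r2 = prior_scale**2
    log_h0 = -(nu + 1) / 2.0 * math.log1p(t * t / nu)

    def integrand(g: float) -> float:
        if g <= 0:
            return 0.0
        c = 1.0 + n * g * r2
        log_f = (
            -0.5 * math.log(c)
            - (nu + 1) / 2.0 * math.log1p(t * t / (c * nu))
            - 0.5 * math.log(2 * math.pi)
            - 1.5 * math.log(g)
            - 1.0 / (2.0 * g)
            - log_h0
        )
        return math.exp(log_f)

    # substitute g = u/(1−u) to map (0, ∞) → (0, 1)
    val, err = integrate.quad(
        lambda u: integrand(u / (1 - u)) / (1 - u) ** 2, 0.0, 1.0,
        limit=200, epsabs=0.0, epsrel=1e-10,
    )
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise FloatingPointError("Bayes factor quadrature did not converge")
    return float(val)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


class IncompleteDesignError(ValueError):
    pass


def _eta_p2(ss_effect: float, ss_error: float) -> float:
    return ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("light", "task"),
    subject: str = "subject",
) -> dict[str, StatResult]:
    """Two-way fully-within 2×2 ANOVA from a long table of cell means.

    Classical sums-of-squares decomposition; each effect is tested against
    its own effect-by-subject interaction.  With two levels per factor the
    sphericity correction is vacuous (ε ≡ 1), so no correction is applied.
    Returns results keyed by factor name and ``"interaction"``.
    """
    a, b = within
    wide = data.pivot_table(index=subject, columns=[a, b], values=dv)
    if wide.isna().any().any():
        raise IncompleteDesignError("every subject needs all four cells")
    if wide.shape[1] != 4:
        raise IncompleteDesignError("design must be 2×2 within-subject")
    n = wide.shape[0]
    if n < 3:
        raise IncompleteDesignError("need at least 3 complete subjects")
    y = wide.to_numpy(dtype=float)  # columns ordered (a1b1, a1b2, a2b1, a2b2)
    subj_mean = y.mean(axis=1)
    grand = y.mean()
    a_means = np.stack([y[:, :2].mean(axis=1), y[:, 2:].mean(axis=1)], axis=1)
    b_means = np.stack([y[:, [0, 2]].mean(axis=1), y[:, [1, 3]].mean(axis=1)], axis=1)

    out: dict[str, StatResult] = {}
    for key, margins in ((a, a_means), (b, b_means)):
        eff = margins.mean(axis=0) - grand
        ss_eff = n * 2 * float(np.sum(eff**2))
        cell_dev = margins - margins.mean(axis=0) - subj_mean[:, None] + grand
        ss_err = 2 * float(np.sum(cell_dev**2))
        f = (ss_eff / 1.0) / (ss_err / (n - 1)) if ss_err > 0 else np.inf
        p = float(stats.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
        out[key] = StatResult(
            name=f"main:{key}", estimate=float(f), df=(1.0, float(n - 1)), p=p,
            effect_size=_eta_p2(ss_eff, ss_err), effect_size_name="eta_p2",
            extra={"ss_effect": ss_eff, "ss_error": ss_err},
        )
    # interaction contrast per subject: (a1b1 − a1b2) − (a2b1 − a2b2)
    inter = (y[:, 0] - y[:, 1]) - (y[:, 2] - y[:, 3])
    ss_ab = n * float(inter.mean() ** 2) / 4.0
    ss_ab_err = float(np.sum((inter - inter.mean()) ** 2)) / 4.0
    f = (ss_ab / 1.0) / (ss_ab_err / (n - 1)) if ss_ab_err > 0 else np.inf
    p = float(stats.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
    out["interaction"] = StatResult(
        name="interaction", estimate=float(f), df=(1.0, float(n - 1)), p=p,
        effect_size=_eta_p2(ss_ab, ss_ab_err), effect_size_name="eta_p2",
        extra={"ss_effect": ss_ab, "ss_error": ss_ab_err},
    )
    return out


def _mauchly_gg(y: np.ndarray) -> tuple[float, float, float]:
    """Mauchly W test p-value and Greenhouse–Geisser ε for k-level data."""
    n, k = y.shape
    # orthonormal contrast basis via QR of the centering matrix
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    s = c.T @ np.cov(y, rowvar=False, ddof=1) @ c
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 1e-300, None)
    k1 = k - 1
    w = float(np.prod(eig) / (eig.mean() ** k1))
    fcorr = (2 * k1**2 + k1 + 2) / (6.0 * k1 * (n - 1))
    chi2 = -(1 - fcorr) * (n - 1) * math.log(w)
    df = k * k1 // 2 - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    eps = float(eig.sum() ** 2 / (k1 * np.sum(eig**2)))
    return w, p, eps


def rm_anova_oneway(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "subject",
    gg_alpha: float = 0.05,
) -> StatResult:
    """One-way repeated-measures ANOVA with Mauchly test and GG correction.

    The Greenhouse–Geisser ε deflates both degrees of freedom whenever
    Mauchly's sphericity test is significant at ``gg_alpha`` (k ≥ 3).
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise IncompleteDesignError("incomplete within-subject design")
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if n < 3 or k < 2:
        raise IncompleteDesignError("need ≥ 3 subjects and ≥ 2 levels")
    grand = y.mean()
    ss_cond = n * float(np.sum((y.mean(axis=0) - grand) ** 2))
    ss_err = float(np.sum((y - y.mean(axis=0) - y.mean(axis=1)[:, None] + grand) ** 2))
    df1, df2 = float(k - 1), float((n - 1) * (k - 1))
    correction = "none"
    eps = 1.0
    if k >= 3:
        _, mauchly_p, eps_hat = _mauchly_gg(y)
        if mauchly_p < gg_alpha:
            eps = eps_hat
            correction = "GG"
    f = (ss_cond / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    p = float(stats.f.sf(f, df1 * eps, df2 * eps)) if np.isfinite(f) else 0.0
    return StatResult(
        name=f"rm_anova:{within}", estimate=float(f), df=(df1 * eps, df2 * eps),
        p=p, effect_size=_eta_p2(ss_cond, ss_err), effect_size_name="eta_p2",
        correction=correction, extra={"epsilon": eps},
    )


# ---------------------------------------------------------------------------
# Mixed model with cluster bootstrap


def _within_estimator(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """Per-group demeaned OLS sufficient statistics for the fixed slopes."""
    uniq, inv = np.unique(groups, return_inverse=True)
    p = x.shape[1]
    a = np.zeros((uniq.size, p, p))
    b = np.zeros((uniq.size, p))
    for gi in range(uniq.size):
        sel = inv == gi
        xg = x[sel] - x[sel].mean(axis=0)
        yg = y[sel] - y[sel].mean()
        a[gi] = xg.T @ xg
        b[gi] = xg.T @ yg
    return a, b


def fit_lmm_random_intercept(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    subject: str = "subject",
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict[str, StatResult]:
    """Random-intercept linear mixed model with cluster-bootstrap CIs.

    The model (e.g. ``rt ~ light + (1 | subject)``) is fitted by REML via
    statsmodels MixedLM.  Percentile confidence intervals resample
    *subjects* with replacement; the bootstrap statistic is the within-
    subject (demeaned) OLS slope, which coincides with the mixed-model
    fixed effect for balanced random-intercept data and keeps 10,000
    resamples cheap.
    """
    import statsmodels.formula.api as smf

    df = data.dropna(subset=[outcome, *predictors]).copy()
    if df[subject].nunique() < 2:
        raise ValueError("need at least two subjects")
    formula = f"{outcome} ~ " + " + ".join(predictors)
    model = smf.mixedlm(formula, df, groups=df[subject])
    fit = model.fit(reml=True)
    singular = bool(fit.cov_re.values.min() < 1e-10)

    x = pd.get_dummies(df[predictors], drop_first=True, dtype=float)
    colnames = list(x.columns)
    xmat = x.to_numpy(dtype=float)
    yvec = df[outcome].to_numpy(dtype=float)
    a, b = _within_estimator(yvec, xmat, df[subject].to_numpy())
    rng = np.random.default_rng(seed)
    n_subj = a.shape[0]
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boots = np.empty((n_boot, xmat.shape[1]))
    for i in range(n_boot):
        asum = a[idx[i]].sum(axis=0)
        bsum = b[idx[i]].sum(axis=0)
        boots[i] = np.linalg.solve(asum, bsum)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2

    out: dict[str, StatResult] = {}
    for j, name in enumerate(colnames):
        # map dummy column back to the statsmodels parameter name
        sm_name = next(
            (p for p in fit.params.index if p.replace("[T.", "_").rstrip("]") == name
             or p == name),
            None,
        )
        est = float(fit.params[sm_name]) if sm_name is not None else float("nan")
        pval = float(fit.pvalues[sm_name]) if sm_name is not None else float("nan")
        ci = (float(np.quantile(boots[:, j], lo_q)), float(np.quantile(boots[:, j], hi_q)))
        out[name] = StatResult(
            name=f"lmm:{name}", estimate=est, df=float(len(df) - len(colnames) - 1),
            p=min(max(pval, 0.0), 1.0), ci=ci,
            extra={"singular": singular, "boot_mean": float(boots[:, j].mean())},
        )
    return out


# ---------------------------------------------------------------------------
# Mediation


def mediate(
    x, m, y, n_boot: int = 10_000, seed: int = 0, ci_level: float = 0.95
) -> dict[str, StatResult]:
    """Simple mediation X → M → Y with percentile bootstrap CIs.

    X is a 0/1 condition code; M and Y are z-scored before fitting, so all
    paths are standardised coefficients: a from M ~ X, b and c′ from
    Y ~ X + M, indirect = a·b.  The bootstrap resamples complete triples.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape):
        raise ValueError("x, m, y must have equal length")
    if m.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("M and Y must have positive variance")
    if np.corrcoef(x, m)[0, 1] ** 2 > 1 - 1e-12:
        raise np.linalg.LinAlgError("M is collinear with X")
    mz = (m - m.mean()) / m.std(ddof=0)
    yz = (y - y.mean()) / y.std(ddof=0)
    n = x.size

    def paths(xi, mi, yi):
        vx = xi.var()
        a = np.cov(xi, mi, bias=True)[0, 1] / vx
        xm = np.stack([np.ones_like(xi), xi, mi], axis=1)
        coef = np.linalg.lstsq(xm, yi, rcond=None)[0]
        cprime, b = coef[1], coef[2]
        return a, b, cprime

    a, b, cprime = paths(x, mz, yz)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.empty((n_boot, 4))  # a, b, c', ab
    for i in range(n_boot):
        ii = idx[i]
        if x[ii].var() == 0:  # degenerate resample: keep previous draw space
            boots[i] = boots[i - 1] if i else (a, b, cprime, a * b)
            continue
        ai, bi, ci_ = paths(x[ii], mz[ii], yz[ii])
        boots[i] = (ai, bi, ci_, ai * bi)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2

    def res(name, est, col):
        ci = (float(np.quantile(boots[:, col], lo_q)), float(np.quantile(boots[:, col], hi_q)))
        se = float(boots[:, col].std(ddof=1))
        # normal-approximation two-sided p from the bootstrap distribution
        pz = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else 1.0
        return StatResult(name=f"mediation:{name}", estimate=float(est),
                          df=float(n - 3), p=min(1.0, float(pz)), ci=ci,
                          extra={"se": se})

    return {
        "a": res("a", a, 0),
        "b": res("b", b, 1),
        "c_prime": res("c_prime", cprime, 2),
        "indirect": res("indirect", a * b, 3),
    }


# ---------------------------------------------------------------------------
# A priori power


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the within-factors repeated-measures power analysis."""

    f: float = 0.3
    alpha: float = 0.05
    power: float = 0.8
    m_levels: int = 2
    corr: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.f <= 0 or not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("invalid power specification")
        if self.m_levels < 2 or not -1 < self.corr < 1 or not 0 < self.epsilon <= 1:
            raise ValueError("invalid power specification")


def achieved_power_rm_anova(n: int, spec: PowerSpec) -> float:
    """Power of the within-factor F test at sample size ``n``.

    G*Power "as in SPSS"-style convention for within factors: noncentrality
    λ = n·f²·(m/(1−ρ))·ε with df1 = (m−1)ε and df2 = (n−1)(m−1)ε.
    """
    m, eps = spec.m_levels, spec.epsilon
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    if df2 <= 0:
        return 0.0
    lam = n * spec.f**2 * (m / (1.0 - spec.corr)) * eps
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def apriori_n_rm_anova(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest N whose achieved power reaches the target."""
    for n in range(2, n_max + 1):
        if achieved_power_rm_anova(n, spec) >= spec.power:
            return n
    raise ValueError(f"target power unreachable within N ≤ {n_max}")
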