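"""Gene-environment association stage.

Relates genetic (PRS, family history) and environmental (MPS, childhood
trauma scale) risk factors to standardised brain structure measures in a
case cohort, adjusting for age, age^2, gender, race and smoking status via
ordinary least squares. Effect sizes are reported as the factor coefficient
with a partial R^2 (1 - SSR_full / SSR_covariates-only) quantifying variance
explained beyond covariates; gene-environment interaction is the product
term in G + E + G:E models; clinical vs molecular factor pairs are compared
by bootstrapping the difference in interaction-model partial R^2; multiple
testing across measures is handled with Storey q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalysisConfig",
    "FitResult",
    "InteractionResult",
    "BootstrapComparison",
    "AnalysisBundle",
    "describe_cohort",
    "standardize_measures",
    "spearman_corr",
    "build_covariate_design",
    "fit_main_model",
    "partial_r2",
    "fit_interaction_model",
    "bootstrap_compare_partial_r2",
    "storey_qvalues",
    "run_full_analysis",
]

DEFAULT_COVARIATES = ["age", "gender", "race", "smoking"]


@dataclass
class AnalysisConfig:
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    include_age_squared: bool = True
    fdr_level: float = 0.1
    n_boot: int = 2000  # 0 skips the bootstrap comparison stage
    bootstrap_two_sided: bool = False
    qvalue_family: str = "per_factor"  # or "pooled"
    restrict_group: str | None = "BDS"
    seed: int = 0


@dataclass
class FitResult:
    measure: str
    factor: str
    beta: float
    se: float
    p: float
    partial_r2: float
    n_used: int
    spearman_r: float = np.nan
    q: float = np.nan


@dataclass
class InteractionResult:
    measure: str
    pair: str  # "clinical" or "molecular"
    g_factor: str
    e_factor: str
    beta: float
    se: float
    p: float
    partial_r2: float  # three-term {G, E, GxE} block vs covariates only
    n_used: int
    g_beta: float = np.nan
    g_se: float = np.nan
    e_beta: float = np.nan
    e_se: float = np.nan
    q: float = np.nan


@dataclass
class BootstrapComparison:
    measure: str
    delta_partial_r2: float  # molecular - clinical, on the original sample
    p_boot: float
    n_boot: int
    two_sided: bool
    ci_low: float
    ci_high: float
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# core OLS machinery (shared by the public fits and the bootstrap loop)
# ---------------------------------------------------------------------------

class RankDeficientError(np.linalg.LinAlgError):
    pass


def _ols(X: np.ndarray, y: np.ndarray, names: list[str] | None = None):
    """OLS fit returning (coef, se, t-p-values, ssr, rank).

    Raises :class:`RankDeficientError` when the design is column-rank
    deficient, naming the offending columns when names are supplied.
    """
    n, k = X.shape
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, k) * np.finfo(float).eps if diag.size else 0.0
    if np.any(diag <= tol):
        bad = np.flatnonzero(diag <= tol)
        label = [names[i] for i in bad] if names else list(bad)
        raise RankDeficientError(f"collinear design columns: {label}")
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    df = n - k
    if df <= 0:
        raise ValueError("not enough observations for the requested model")
    sigma2 = ssr / df
    rinv = np.linalg.solve(r, np.eye(k))
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return coef, se, pvals, ssr, k


def build_covariate_design(
    df: pd.DataFrame,
    covariates: list[str] | None = None,
    include_age_squared: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Covariate design matrix with intercept.

    Continuous covariates enter as-is (age also as age^2 when requested);
    object/categorical columns are dummy-coded dropping the first level, with
    any 'unknown' level retained as its own category.
    """
    cov = covariates if covariates is not None else list(DEFAULT_COVARIATES)
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for c in cov:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
            if c == "age" and include_age_squared:
                cols.append(s.to_numpy(dtype=float) ** 2)
                names.append("age_sq")
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=c, drop_first=True)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy(dtype=float))
                names.append(dcol)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def describe_cohort(
    subjects: pd.DataFrame,
    group_col: str = "group",
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group descriptive comparison (demographics table).

    Categorical variables: per-level count and percent of non-missing, with a
    chi-squared test (no continuity correction; Fisher exact fallback on 2x2
    tables with any expected cell below 5). Continuous variables: median and
    IQR per group with a Wilcoxon rank-sum test (normal approximation with
    tie correction).
    """
    groups = [g for g in subjects[group_col].dropna().unique()]
    if len(groups) != 2:
        raise ValueError(f"expected two groups, found {groups}")
    groups = sorted(groups)
    g0 = subjects[subjects[group_col] == groups[0]]
    g1 = subjects[subjects[group_col] == groups[1]]
    if categorical is None:
        categorical = [
            c for c in subjects.columns
            if c not in (group_col, "subject_id")
            and not pd.api.types.is_numeric_dtype(subjects[c])
        ]
    if continuous is None:
        continuous = [
            c for c in subjects.columns
            if c not in (group_col, "subject_id")
            and pd.api.types.is_numeric_dtype(subjects[c])
            and subjects[c].nunique() > 2
        ]
        categorical = categorical + [
            c for c in subjects.columns
            if c not in (group_col, "subject_id")
            and pd.api.types.is_numeric_dtype(subjects[c])
            and subjects[c].nunique() <= 2
        ]

    rows = []
    for c in categorical:
        a, b = g0[c].dropna(), g1[c].dropna()
        table = pd.crosstab(
            subjects[group_col], subjects[c].astype(str), dropna=True
        )
        pval = _categorical_p(table.to_numpy())
        for level in sorted(set(a.astype(str)) | set(b.astype(str))):
            na = int((a.astype(str) == level).sum())
            nb = int((b.astype(str) == level).sum())
            rows.append(
                {
                    "variable": c, "level": level,
                    f"{groups[0]}_n": na,
                    f"{groups[0]}_stat": 100.0 * na / max(len(a), 1),
                    f"{groups[1]}_n": nb,
                    f"{groups[1]}_stat": 100.0 * nb / max(len(b), 1),
                    "test": "chi2/fisher", "p": pval,
                }
            )
    for c in continuous:
        a, b = g0[c].dropna().to_numpy(), g1[c].dropna().to_numpy()
        if len(a) and len(b):
            pval = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            )
        else:
            pval = np.nan
        rows.append(
            {
                "variable": c, "level": "median[IQR]",
                f"{groups[0]}_n": len(a),
                f"{groups[0]}_stat": float(np.median(a)) if len(a) else np.nan,
                f"{groups[1]}_n": len(b),
                f"{groups[1]}_stat": float(np.median(b)) if len(b) else np.nan,
                "test": "wilcoxon", "p": pval,
            }
        )
    return pd.DataFrame(rows)


def _categorical_p(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or min(table.shape) < 2:
        return np.nan
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and (expected < 5).any():
        return float(stats.fisher_exact(table)[1])
    return float(p)


def standardize_measures(brain: pd.DataFrame, id_col: str = "subject_id") -> pd.DataFrame:
    """Z-score every measure column (mean 0, sd 1 with n-1 denominator)."""
    out = brain.copy()
    for c in out.columns:
        if c == id_col:
            continue
        x = out[c].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"measure {c!r} has zero variance; cannot standardise")
        out[c] = (x - np.nanmean(x)) / sd
    return out


def spearman_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (ties mid-ranked); NaN when undefined."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    x, y = x[ok], y[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

def partial_r2(ssr_full: float, ssr_cov: float) -> float:
    """1 - SSR_full / SSR_covariates-only, clipped into [0, 1]."""
    if ssr_cov <= 0:
        raise ValueError("covariate-only model has zero residual sum of squares")
    value = 1.0 - ssr_full / ssr_cov
    if value < 0 or value > 1:
        warnings.warn(f"partial R^2 {value:.3g} clipped into [0, 1]")
    return float(np.clip(value, 0.0, 1.0))


def _complete_cases(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.dropna(subset=cols)


def fit_main_model(
    data: pd.DataFrame,
    measure: str,
    factor: str,
    covariates: list[str] | None = None,
    include_age_squared: bool = True,
) -> FitResult:
    """Covariate-adjusted main-effect model: measure ~ factor + covariates.

    Complete-case OLS; returns the factor coefficient, its SE and two-sided
    p, and the partial R^2 of the factor against the covariate-only model
    fitted on the same subjects.
    """
    cov = covariates if covariates is not None else list(DEFAULT_COVARIATES)
    d = _complete_cases(data, [measure, factor] + cov)
    y = d[measure].to_numpy(dtype=float)
    Xc, names = build_covariate_design(d, cov, include_age_squared)
    f = d[factor].to_numpy(dtype=float)
    X = np.column_stack([Xc, f])
    coef, se, pv, ssr_full, _ = _ols(X, y, names + [factor])
    _, _, _, ssr_cov, _ = _ols(Xc, y, names)
    r = np.nan
    try:
        r = spearman_corr(f, y)
    except ValueError:
        pass
    return FitResult(
        measure=measure, factor=factor,
        beta=float(coef[-1]), se=float(se[-1]), p=float(pv[-1]),
        partial_r2=partial_r2(ssr_full, ssr_cov),
        n_used=len(d), spearman_r=r,
    )


def fit_interaction_model(
    data: pd.DataFrame,
    measure: str,
    g_factor: str,
    e_factor: str,
    covariates: list[str] | None = None,
    include_age_squared: bool = True,
    pair_label: str | None = None,
) -> InteractionResult:
    """Gene-environment interaction model: measure ~ G + E + G:E + covariates.

    Reports the product-term coefficient and the partial R^2 of the full
    three-term factor block {G, E, GxE} against the covariate-only model.
    """
    cov = covariates if covariates is not None else list(DEFAULT_COVARIATES)
    d = _complete_cases(data, [measure, g_factor, e_factor] + cov)
    y = d[measure].to_numpy(dtype=float)
    Xc, names = build_covariate_design(d, cov, include_age_squared)
    g = d[g_factor].to_numpy(dtype=float)
    e = d[e_factor].to_numpy(dtype=float)
    X = np.column_stack([Xc, g, e, g * e])
    coef, se, pv, ssr_full, _ = _ols(X, y, names + [g_factor, e_factor, "gxe"])
    _, _, _, ssr_cov, _ = _ols(Xc, y, names)
    return InteractionResult(
        measure=measure,
        pair=pair_label or f"{g_factor}x{e_factor}",
        g_factor=g_factor, e_factor=e_factor,
        beta=float(coef[-1]), se=float(se[-1]), p=float(pv[-1]),
        partial_r2=partial_r2(ssr_full, ssr_cov),
        n_used=len(d),
        g_beta=float(coef[-3]), g_se=float(se[-3]),
        e_beta=float(coef[-2]), e_se=float(se[-2]),
    )


def _interaction_partial_r2(
    y: np.ndarray, Xc: np.ndarray, g: np.ndarray, e: np.ndarray
) -> float:
    # a bootstrap resample can lose a rare categorical level entirely; the
    # resulting constant dummy column is absorbed by the intercept and dropped
    keep = np.ptp(Xc, axis=0) > 0
    keep[0] = True  # intercept
    Xc = Xc[:, keep]
    X = np.column_stack([Xc, g, e, g * e])
    _, _, _, ssr_full, _ = _ols(X, y)
    _, _, _, ssr_cov, _ = _ols(Xc, y)
    if ssr_cov <= 0:
        raise ValueError("degenerate covariate fit")
    return float(np.clip(1.0 - ssr_full / ssr_cov, 0.0, 1.0))


def bootstrap_compare_partial_r2(
    data: pd.DataFrame,
    measure: str,
    clinical_pair: tuple[str, str],
    molecular_pair: tuple[str, str],
    covariates: list[str] | None = None,
    include_age_squared: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
    two_sided: bool = False,
    max_redraws: int = 100,
) -> BootstrapComparison:
    """Bootstrap comparison of interaction-model partial R^2: molecular vs clinical.

    Subjects are resampled with replacement ``n_boot`` times; each resample
    refits both interaction models and records
    delta = partialR2(molecular) - partialR2(clinical). The one-sided
    p-value is the proportion of resamples with delta < 0 (molecular not
    higher; exact ties counted half); the two-sided version doubles the
    smaller tail. Rank-deficient resamples are redrawn (counted).
    """
    cov = covariates if covariates is not None else list(DEFAULT_COVARIATES)
    needed = [measure, *clinical_pair, *molecular_pair] + cov
    d = _complete_cases(data, needed).reset_index(drop=True)
    y = d[measure].to_numpy(dtype=float)
    Xc, _ = build_covariate_design(d, cov, include_age_squared)
    gc_, ec_ = (d[c].to_numpy(dtype=float) for c in clinical_pair)
    gm, em = (d[c].to_numpy(dtype=float) for c in molecular_pair)

    delta_obs = _interaction_partial_r2(y, Xc, gm, em) - _interaction_partial_r2(
        y, Xc, gc_, ec_
    )
    rng = np.random.default_rng(seed)
    n = len(d)
    deltas = np.empty(n_boot)
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            dm = _interaction_partial_r2(y[idx], Xc[idx], gm[idx], em[idx])
            dc = _interaction_partial_r2(y[idx], Xc[idx], gc_[idx], ec_[idx])
        except (RankDeficientError, ValueError):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        deltas[b] = dm - dc
        b += 1
    # ties at zero counted half (matters only for degenerate comparisons)
    p_low = float((deltas < 0).mean() + 0.5 * (deltas == 0).mean())
    if two_sided:
        p_high = float((deltas > 0).mean() + 0.5 * (deltas == 0).mean())
        p_boot = min(1.0, 2.0 * min(p_low, p_high))
    else:
        p_boot = p_low
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return BootstrapComparison(
        measure=measure, delta_partial_r2=float(delta_obs), p_boot=p_boot,
        n_boot=n_boot, two_sided=two_sided, ci_low=float(lo), ci_high=float(hi),
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(
    p_values: np.ndarray,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values with smoothed pi0 estimation.

    pi0 (the null proportion) is estimated from #{p > lambda} / (m (1-lambda))
    over lambda = 0.05..0.95 (step 0.05), extrapolated to lambda -> 1 with a
    cubic smoothing spline, then clipped into (0, 1]. With fewer than 10
    p-values pi0 is fixed at 1 (the Benjamini-Hochberg special case, with a
    warning). q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j);
    monotone non-decreasing in p. Forcing ``pi0=1`` reproduces BH exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        if m < 10:
            warnings.warn("fewer than 10 p-values; pi0 fixed at 1 (BH)")
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.951, 0.05)
            pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
            from scipy.interpolate import UnivariateSpline

            spline = UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spline(lambdas[-1]))
            pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * ranked / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisBundle:
    table1: pd.DataFrame
    main_effects: pd.DataFrame
    interactions: pd.DataFrame
    bootstrap: pd.DataFrame
    provenance: dict


def run_full_analysis(
    subjects: pd.DataFrame,
    brain: pd.DataFrame,
    prs: pd.Series,
    mps: pd.Series,
    config: AnalysisConfig | None = None,
    factors: list[str] | None = None,
) -> AnalysisBundle:
    """Complete association stage over every factor x measure combination.

    Workflow: merge scores into the subject table; restrict to the case
    group; standardise measures; per factor and measure, Spearman r plus the
    adjusted main-effect model with q-values per factor family (configurable
    to a single pooled family); per measure, both interaction models
    (clinical = family history x trauma scale, molecular = PRS x MPS) with
    q-values per pair, and the bootstrap partial-R^2 comparison.
    """
    cfg = config or AnalysisConfig()
    subj = subjects.copy()
    subj["prs"] = subj["subject_id"].map(prs)
    subj["mps"] = subj["subject_id"].map(mps)

    orphans = set(brain["subject_id"]) - set(subj["subject_id"])
    if orphans:
        raise ValueError(f"brain-measure subjects missing from subject table: {sorted(orphans)[:5]}")

    table1 = describe_cohort(subj.drop(columns=["subject_id"]))

    if cfg.restrict_group is not None:
        subj = subj[subj["group"] == cfg.restrict_group]
    measures = [c for c in brain.columns if c != "subject_id"]
    data = subj.merge(brain, on="subject_id", how="inner")
    std_brain = standardize_measures(data[["subject_id"] + measures])
    data[measures] = std_brain[measures]

    if factors is None:
        factors = ["prs", "mps", "family_history", "cles"]

    main_rows = []
    for factor in factors:
        base = _complete_cases(data, [factor] + cfg.covariates)
        Xc, names = build_covariate_design(base, cfg.covariates,
                                           cfg.include_age_squared)
        f = base[factor].to_numpy(dtype=float)
        for measure in measures:
            y = base[measure].to_numpy(dtype=float)
            if np.isnan(y).any():  # measure-specific missingness: slow path
                fit = fit_main_model(
                    data, measure, factor, cfg.covariates, cfg.include_age_squared
                )
            else:
                X = np.column_stack([Xc, f])
                coef, se, pv, ssr_full, _ = _ols(X, y, names + [factor])
                _, _, _, ssr_cov, _ = _ols(Xc, y, names)
                try:
                    r = spearman_corr(f, y)
                except ValueError:
                    r = np.nan
                fit = FitResult(
                    measure=measure, factor=factor,
                    beta=float(coef[-1]), se=float(se[-1]), p=float(pv[-1]),
                    partial_r2=partial_r2(ssr_full, ssr_cov),
                    n_used=len(base), spearman_r=r,
                )
            main_rows.append(fit.__dict__)
    main = pd.DataFrame(main_rows)
    if cfg.qvalue_family == "pooled":
        main["q"] = storey_qvalues(main["p"].to_numpy())
    else:
        for factor in factors:
            sel = main["factor"] == factor
            main.loc[sel, "q"] = storey_qvalues(main.loc[sel, "p"].to_numpy())

    pairs = {
        "clinical": ("family_history", "cles"),
        "molecular": ("prs", "mps"),
    }
    inter_rows = []
    for label, (gf, ef) in pairs.items():
        base = _complete_cases(data, [gf, ef] + cfg.covariates)
        Xc, names = build_covariate_design(base, cfg.covariates,
                                           cfg.include_age_squared)
        g = base[gf].to_numpy(dtype=float)
        e = base[ef].to_numpy(dtype=float)
        for measure in measures:
            y = base[measure].to_numpy(dtype=float)
            if np.isnan(y).any():
                res = fit_interaction_model(
                    data, measure, gf, ef, cfg.covariates,
                    cfg.include_age_squared, pair_label=label,
                )
            else:
                X = np.column_stack([Xc, g, e, g * e])
                coef, se, pv, ssr_full, _ = _ols(X, y, names + [gf, ef, "gxe"])
                _, _, _, ssr_cov, _ = _ols(Xc, y, names)
                res = InteractionResult(
                    measure=measure, pair=label, g_factor=gf, e_factor=ef,
                    beta=float(coef[-1]), se=float(se[-1]), p=float(pv[-1]),
                    partial_r2=partial_r2(ssr_full, ssr_cov),
                    n_used=len(base),
                    g_beta=float(coef[-3]), g_se=float(se[-3]),
                    e_beta=float(coef[-2]), e_se=float(se[-2]),
                )
            inter_rows.append(res.__dict__)
    inter = pd.DataFrame(inter_rows)
    if cfg.qvalue_family == "pooled":
        inter["q"] = storey_qvalues(inter["p"].to_numpy())
    else:
        for label in pairs:
            sel = inter["pair"] == label
            inter.loc[sel, "q"] = storey_qvalues(inter.loc[sel, "p"].to_numpy())

    boot_rows = []
    for i, measure in enumerate(measures if cfg.n_boot > 0 else []):
        comp = bootstrap_compare_partial_r2(
            data, measure, pairs["clinical"], pairs["molecular"],
            cfg.covariates, cfg.include_age_squared,
            n_boot=cfg.n_boot, seed=cfg.seed + i, two_sided=cfg.bootstrap_two_sided,
        )
        boot_rows.append(comp.__dict__)
    boot = pd.DataFrame(boot_rows)

    provenance = {
        "n_subjects_analysed": int(data.shape[0]),
        "n_measures": len(measures),
        "factors": factors,
        "fdr_level": cfg.fdr_level,
        "qvalue_family": cfg.qvalue_family,
        "n_boot": cfg.n_boot,
        "seed": cfg.seed,
        "covariates": cfg.covariates,
        "restrict_group": cfg.restrict_group,
    }
    return AnalysisBundle(
        table1=table1, main_effects=main, interactions=inter,
        bootstrap=boot, provenance=provenance,
    )


def plot_partial_r2_comparison(bundle: AnalysisBundle, path: str) -> None:
    """Paired bar plot of interaction-model partial R^2 per measure
    (clinical vs molecular factor pairs)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    inter = bundle.interactions
    piv = inter.pivot(index="measure", columns="pair", values="partial_r2")
    ax = piv.plot.bar(figsize=(max(8, 0.25 * len(piv)), 4))
    ax.set_ylabel("partial $R^2$ (G + E + G:E block)")
    ax.set_xlabel("brain measure")
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
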