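"""Methylation handling: QC, BMIQ normalisation, M-values, and the MPS.

The methylation profile score (MPS) treats the methylome as a molecular
readout of environmental exposure. With no well-powered external
epigenome-wide study to supply probe weights, the weights are estimated
internally: an L1-penalised (LASSO) logistic regression of case status on
M-values selects a sparse probe panel, and the MPS is the weighted sum of
the selected probes' M-values (no intercept).

Beta values from Illumina-style arrays come in two probe chemistries whose
distributions differ systematically (type II compressed toward 0.5); BMIQ
(beta-mixture quantile normalisation) fits a three-state beta mixture per
sample and maps the type II state distributions onto the type I ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethylationMatrix",
    "ProbeQcThresholds",
    "MpsModel",
    "probe_qc",
    "sample_qc_pca",
    "bmiq_normalize",
    "logit_transform",
    "inverse_logit_transform",
    "fit_lasso_mps",
    "compute_mps",
    "meqtl_scan",
]

BETA_EPS = 1e-6

PROBE_COLUMNS = ["probe_id", "chrom", "pos", "design_type", "snp_overlap"]


@dataclass
class MethylationMatrix:
    """Subjects x probes beta-value matrix with probe annotation.

    ``probes`` columns: probe_id, chrom, pos, design_type ('I'/'II'),
    snp_overlap (bool: SNP at the interrogation or extension site).
    Betas are clamped into [1e-6, 1 - 1e-6] on construction.
    ``detection_p`` and ``bead_count`` optionally mirror the beta layout.
    """

    subject_ids: list[str]
    probes: pd.DataFrame
    beta: np.ndarray
    detection_p: np.ndarray | None = None
    bead_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.clip(np.asarray(self.beta, dtype=float), BETA_EPS, 1 - BETA_EPS)
        shape = (len(self.subject_ids), len(self.probes))
        if self.beta.shape != shape:
            raise ValueError(f"beta shape {self.beta.shape} != {shape}")
        for name in ("detection_p", "bead_count"):
            m = getattr(self, name)
            if m is not None and np.asarray(m).shape != shape:
                raise ValueError(f"{name} shape mismatch")
        if not self.probes["design_type"].isin(["I", "II"]).all():
            raise ValueError("design_type must be 'I' or 'II'")
        if self.probes["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def probe_index(self, ids: list[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.probes["probe_id"])}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"probes not present: {missing[:10]}")
        return np.array([lookup[i] for i in ids], dtype=int)

    def subset_subjects(self, keep: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            subject_ids=[self.subject_ids[i] for i in keep],
            probes=self.probes.copy(),
            beta=self.beta[keep],
            detection_p=None if self.detection_p is None else self.detection_p[keep],
            bead_count=None if self.bead_count is None else self.bead_count[keep],
        )

    def subset_probes(self, keep: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            subject_ids=list(self.subject_ids),
            probes=self.probes.iloc[keep].reset_index(drop=True),
            beta=self.beta[:, keep],
            detection_p=None if self.detection_p is None else self.detection_p[:, keep],
            bead_count=None if self.bead_count is None else self.bead_count[:, keep],
        )


@dataclass
class ProbeQcThresholds:
    """Probe filters: detection failure (p >= detection_p_cut) in more than
    ``max_detection_fail_fraction`` of samples; bead count < ``min_bead_count``
    in at least ``bead_fail_fraction`` of samples; SNP overlap."""

    detection_p_cut: float = 0.01
    max_detection_fail_fraction: float = 0.01
    min_bead_count: int = 3
    bead_fail_fraction: float = 0.05


def probe_qc(
    meth: MethylationMatrix, thresholds: ProbeQcThresholds | None = None
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove probes failing detection, bead-count, or SNP-overlap criteria.

    The criteria are applied independently (survivors do not depend on
    application order). Returns the filtered matrix and a per-probe report
    with one boolean column per criterion.
    """
    thr = thresholds or ProbeQcThresholds()
    n = meth.n_subjects
    fail_det = np.zeros(meth.n_probes, dtype=bool)
    if meth.detection_p is not None:
        frac = (meth.detection_p >= thr.detection_p_cut).sum(axis=0) / n
        fail_det = frac > thr.max_detection_fail_fraction
    else:
        warnings.warn("no detection-p matrix; detection criterion skipped")
    fail_bead = np.zeros(meth.n_probes, dtype=bool)
    if meth.bead_count is not None:
        frac = (meth.bead_count < thr.min_bead_count).sum(axis=0) / n
        fail_bead = frac >= thr.bead_fail_fraction
    else:
        warnings.warn("no bead-count matrix; bead criterion skipped")
    fail_snp = meth.probes["snp_overlap"].to_numpy(dtype=bool)
    passed = ~(fail_det | fail_bead | fail_snp)
    report = pd.DataFrame(
        {
            "probe_id": meth.probes["probe_id"].to_numpy(),
            "fail_detection": fail_det,
            "fail_bead_count": fail_bead,
            "fail_snp_overlap": fail_snp,
            "passed": passed,
        }
    )
    if not passed.any():
        raise ValueError("no probes remain after QC")
    return meth.subset_probes(np.flatnonzero(passed)), report


def sample_qc_pca(
    meth: MethylationMatrix, k: int = 2, sd_limit: float = 4.0
) -> list[str]:
    """Flag outlier subjects on the first ``k`` beta-matrix principal components.

    A subject is an outlier if any of its first k PC coordinates lies more
    than ``sd_limit`` standard deviations from that component's mean.
    """
    if meth.n_subjects < 3:
        raise ValueError("need at least 3 subjects for PCA outlier detection")
    x = meth.beta - meth.beta.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(k, (s > 1e-12).sum())
    coords = u[:, :k] * s[:k]
    sd = coords.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.abs((coords - coords.mean(axis=0)) / sd)
    flagged = np.flatnonzero((z > sd_limit).any(axis=1))
    return [meth.subject_ids[i] for i in flagged]


# ---------------------------------------------------------------------------
# BMIQ normalisation
# ---------------------------------------------------------------------------

@dataclass
class _BetaMixture:
    weights: np.ndarray  # (3,)
    a: np.ndarray  # (3,) alpha, states ordered unmethylated < hemi < methylated
    b: np.ndarray
    converged: bool = True


def _moments_to_ab(mean: float, var: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    var = max(min(var, mean * (1 - mean) * 0.99), 1e-6)
    phi = mean * (1 - mean) / var - 1.0
    return max(mean * phi, 1e-2), max((1 - mean) * phi, 1e-2)


def _fit_beta_mixture(
    x: np.ndarray, tol: float = 1e-5, max_iter: int = 200
) -> _BetaMixture:
    """EM fit of a 3-state beta mixture (unmethylated / hemi / methylated).

    Component densities are beta; M-step uses weighted method-of-moments
    updates for (alpha, beta), which keeps the fit fast and stable at the
    boundaries. Initialisation splits at 0.25 and 0.75.
    """
    x = np.clip(x, BETA_EPS, 1 - BETA_EPS)
    edges = [(x < 0.25), (x >= 0.25) & (x <= 0.75), (x > 0.75)]
    w = np.array([max(m.mean(), 0.02) for m in edges])
    w /= w.sum()
    a = np.empty(3)
    b = np.empty(3)
    defaults = [(0.1, 0.02), (0.5, 0.04), (0.9, 0.02)]
    for k, m in enumerate(edges):
        if m.sum() >= 5:
            mu, var = float(x[m].mean()), float(x[m].var()) + 1e-6
        else:
            mu, var = defaults[k]
        a[k], b[k] = _moments_to_ab(mu, var)

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = np.stack([stats.beta.pdf(x, a[k], b[k]) for k in range(3)])
        dens = np.maximum(dens, 1e-300)
        num = w[:, None] * dens
        total = num.sum(axis=0)
        r = num / total
        ll = float(np.log(total).sum())
        w = r.mean(axis=1)
        w = np.maximum(w, 1e-6)
        w /= w.sum()
        for k in range(3):
            rk = r[k]
            s = rk.sum()
            if s < 1e-8:
                continue
            mu = float((rk * x).sum() / s)
            var = float((rk * (x - mu) ** 2).sum() / s) + 1e-8
            a[k], b[k] = _moments_to_ab(mu, var)
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll
    # order states by mean so index 0/1/2 = unmethylated/hemi/methylated
    order = np.argsort(a / (a + b))
    return _BetaMixture(w[order], a[order], b[order], converged)


def _classify(x: np.ndarray, mix: _BetaMixture) -> np.ndarray:
    dens = np.stack(
        [mix.weights[k] * stats.beta.pdf(x, mix.a[k], mix.b[k]) for k in range(3)]
    )
    return dens.argmax(axis=0)


def bmiq_normalize(meth: MethylationMatrix) -> MethylationMatrix:
    """Beta-mixture quantile normalisation of type II probes onto type I.

    Per subject: fit 3-state beta mixtures separately to type I and type II
    betas; type II probes classified unmethylated (or methylated) are mapped
    through the type II state CDF into the matching type I state quantile;
    hemi-methylated probes are linearly dilated into the gap between the two
    mapped outer states. Type I probes are returned unchanged. If either EM
    fails to converge for a subject, that subject's betas are left unadjusted
    (with a warning).
    """
    is_ii = (meth.probes["design_type"] == "II").to_numpy()
    if not is_ii.any() or is_ii.all():
        warnings.warn("need both type I and type II probes; returning input")
        return meth
    out = meth.beta.copy()
    n_fallback = 0
    for i in range(meth.n_subjects):
        b1 = meth.beta[i, ~is_ii]
        b2 = meth.beta[i, is_ii]
        mix1 = _fit_beta_mixture(b1)
        mix2 = _fit_beta_mixture(b2)
        if not (mix1.converged and mix2.converged):
            n_fallback += 1
            continue
        out[i, is_ii] = _bmiq_map(b2, mix2, mix1)
    if n_fallback:
        warnings.warn(f"BMIQ EM non-convergence: {n_fallback} subjects unadjusted")
    return MethylationMatrix(
        subject_ids=list(meth.subject_ids),
        probes=meth.probes.copy(),
        beta=out,
        detection_p=meth.detection_p,
        bead_count=meth.bead_count,
    )


def _bmiq_map(b2: np.ndarray, mix2: _BetaMixture, mix1: _BetaMixture) -> np.ndarray:
    state = _classify(b2, mix2)
    new = b2.copy()
    for k in (0, 2):  # unmethylated / methylated: CDF quantile map
        m = state == k
        if not m.any():
            continue
        p = stats.beta.cdf(b2[m], mix2.a[k], mix2.b[k])
        p = np.clip(p, 1e-12, 1 - 1e-12)
        new[m] = stats.beta.ppf(p, mix1.a[k], mix1.b[k])
    hemi = state == 1
    if hemi.any():
        # dilation: stretch the hemi range linearly so its endpoints land
        # where the outer-state CDF maps would send them
        lo_src = b2[hemi].min()
        hi_src = b2[hemi].max()

        def through(k: int, x: float) -> float:
            pq = float(np.clip(stats.beta.cdf(x, mix2.a[k], mix2.b[k]),
                               1e-12, 1 - 1e-12))
            return float(stats.beta.ppf(pq, mix1.a[k], mix1.b[k]))

        lo_dst = through(0, lo_src)
        hi_dst = through(2, hi_src)
        if hi_dst <= lo_dst or hi_src <= lo_src:
            pass  # degenerate layout: leave hemi probes untouched
        else:
            new[hemi] = lo_dst + (b2[hemi] - lo_src) * (hi_dst - lo_dst) / (
                hi_src - lo_src
            )
    return np.clip(new, BETA_EPS, 1 - BETA_EPS)


# ---------------------------------------------------------------------------
# M-values
# ---------------------------------------------------------------------------

def logit_transform(beta: np.ndarray, base: float = 2.0) -> np.ndarray:
    """M-value transform M = log_base(beta / (1 - beta))."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("beta values must lie strictly in (0, 1)")
    return np.log(beta / (1.0 - beta)) / np.log(base)


def inverse_logit_transform(m: np.ndarray, base: float = 2.0) -> np.ndarray:
    x = np.power(base, np.asarray(m, dtype=float))
    return x / (1.0 + x)


# ---------------------------------------------------------------------------
# LASSO methylation profile score
# ---------------------------------------------------------------------------

@dataclass
class MpsModel:
    """Sparse probe panel and weights defining the methylation profile score.

    Weights are on the M-value scale (the fitting standardisation is undone),
    so score = sum_i w_i * M_i over the selected probes, no intercept.
    """

    probe_ids: list[str]
    weights: np.ndarray
    intercept: float
    lambda_: float
    cv_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return len(self.probe_ids)


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 * mean Bernoulli log-likelihood at linear predictor eta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_lasso_mps(
    m_matrix: np.ndarray,
    probe_ids: list[str],
    group_labels: np.ndarray,
    n_lambda: int = 25,
    lambda_min_ratio: float = 1e-3,
    n_folds: int = 5,
    one_se: bool = True,
    seed: int = 0,
) -> MpsModel:
    """L1-penalised logistic regression selecting a sparse probe panel.

    Probes are standardised internally; a descending lambda path is built from
    the data-derived lambda_max (smallest lambda shrinking everything to zero)
    and the penalty is chosen by stratified k-fold cross-validated binomial
    deviance with the one-standard-error rule (the sparsest model within one
    SE of the minimum). Reported weights are rescaled to the M-value scale.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(m_matrix, dtype=float)
    y = np.asarray(group_labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("subject dimension mismatch")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (y == classes.max()).astype(float)
    n, p = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd

    lambda_max = np.abs(Z.T @ (y - y.mean())).max() / n
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)

    def fit_one(zt: np.ndarray, yt: np.ndarray, lam: float) -> LogisticRegression:
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (len(yt) * lam), solver="liblinear",
            max_iter=2000, tol=1e-6, random_state=seed,
        )
        clf.fit(zt, yt)
        return clf

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, n_lambda))
    for f, (tr, va) in enumerate(skf.split(Z, y)):
        for j, lam in enumerate(lambdas):
            clf = fit_one(Z[tr], y[tr], lam)
            eta = Z[va] @ clf.coef_.ravel() + clf.intercept_[0]
            dev[f, j] = _binomial_deviance(y[va], eta)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    j_min = int(mean_dev.argmin())
    if one_se:
        # largest lambda (sparsest model) within one SE of the minimum
        ok = np.flatnonzero(mean_dev <= mean_dev[j_min] + se_dev[j_min])
        j_sel = int(ok.min())
    else:
        j_sel = j_min
    lam = float(lambdas[j_sel])

    clf = fit_one(Z, y, lam)
    coef_std = clf.coef_.ravel()
    nz = np.flatnonzero(coef_std != 0)
    if nz.size == 0:
        warnings.warn("LASSO selected no probes; MPS will be 0 for all subjects")
    weights = coef_std[nz] / sd[nz]
    intercept = float(clf.intercept_[0] - np.sum(coef_std[nz] * mu[nz] / sd[nz]))
    cv_table = pd.DataFrame(
        {"lambda": lambdas, "mean_deviance": mean_dev, "se_deviance": se_dev,
         "selected": [j == j_sel for j in range(n_lambda)]}
    )
    return MpsModel(
        probe_ids=[probe_ids[i] for i in nz],
        weights=weights,
        intercept=intercept,
        lambda_=lam,
        cv_table=cv_table,
    )


def compute_mps(
    m_matrix: np.ndarray,
    probe_ids: list[str],
    model: MpsModel,
    subject_ids: list[str] | None = None,
) -> pd.Series:
    """Methylation profile score: sum of w_i x M_i over the selected probes."""
    lookup = {v: i for i, v in enumerate(probe_ids)}
    missing = [pid for pid in model.probe_ids if pid not in lookup]
    if missing:
        raise KeyError(f"model probes absent from matrix: {missing}")
    if model.n_selected == 0:
        scores = np.zeros(np.asarray(m_matrix).shape[0])
    else:
        cols = np.array([lookup[pid] for pid in model.probe_ids])
        scores = np.asarray(m_matrix, dtype=float)[:, cols] @ model.weights
    index = pd.Index(subject_ids, name="subject_id") if subject_ids else None
    return pd.Series(scores, index=index, name="mps")


# ---------------------------------------------------------------------------
# cis-meQTL scan
# ---------------------------------------------------------------------------

def meqtl_scan(
    m_matrix: np.ndarray,
    probes: pd.DataFrame,
    probe_ids: list[str],
    genotypes,
    window_kb: float = 500.0,
) -> pd.DataFrame:
    """cis-meQTL scan: regress each probe's M-value on nearby SNP dosages.

    For each requested probe, every variant within ``window_kb`` on the same
    chromosome is tested by simple linear regression (slope, two-sided p).
    q-values are computed across all tested pairs. Subjects are matched by
    position; callers must supply matrices over the same subjects.
    """
    from .association import storey_qvalues

    probe_lookup = {v: i for i, v in enumerate(probes["probe_id"])}
    win = window_kb * 1000.0
    var = genotypes.variants
    rows = []
    for pid in probe_ids:
        j = probe_lookup[pid]
        chrom, pos = probes["chrom"].iat[j], probes["pos"].iat[j]
        near = np.flatnonzero(
            (var["chrom"].to_numpy() == chrom)
            & (np.abs(var["pos"].to_numpy() - pos) <= win)
        )
        mval = np.asarray(m_matrix, dtype=float)[:, j]
        for v in near:
            d = genotypes.dosage[:, v]
            ok = ~np.isnan(d)
            if ok.sum() < 3 or d[ok].std() == 0 or mval[ok].std() == 0:
                continue
            res = stats.linregress(d[ok], mval[ok])
            rows.append(
                {"probe_id": pid, "variant_id": var["id"].iat[v],
                 "beta": res.slope, "se": res.stderr, "p": res.pvalue,
                 "n": int(ok.sum())}
            )
    out = pd.DataFrame(rows, columns=["probe_id", "variant_id", "beta", "se", "p", "n"])
    if len(out):
        out["q"] = storey_qvalues(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out
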