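"""Genotype handling: QC, relatedness, LD clumping, and polygenic risk scores.

A polygenic risk score (PRS) summarises a subject's genetic liability as the
weighted sum of risk-allele dosages, with weights taken from an external GWAS.
This module provides the standard pre-scoring steps (per-variant quality
control with an exact Hardy-Weinberg test, identity-by-descent screening for
cryptic relatedness, greedy LD clumping, allele alignment between the GWAS and
the target cohort) and the scoring itself, including a scan over GWAS p-value
thresholds that picks the threshold most predictive of family history of
disease via logistic regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "RelatednessEstimate",
    "PrsResult",
    "load_genotypes",
    "hwe_exact_test",
    "snp_qc",
    "prune_for_ibd",
    "ibd_estimate",
    "ld_r2",
    "greedy_clump",
    "align_alleles",
    "compute_prs",
    "optimize_threshold",
    "genotype_pca",
]

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]

# strand-ambiguous allele pairs (indistinguishable after strand flip)
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenotypeMatrix:
    """Subjects x variants additive dosage matrix.

    ``dosage`` counts copies of the ALT allele; missing calls are NaN.
    ``variants`` is a DataFrame with columns id, chrom, pos, ref, alt.
    ``quality`` optionally holds per-call quality scores in [0, 1]
    (GenCall-style); same shape as ``dosage``.
    """

    subject_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.variants)} variants"
            )
        ids = self.variants["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        # imputed dosages may be fractional; only range-check those
        if not valid.all():
            frac = self.dosage[~valid]
            if np.any((frac < 0) | (frac > 2)):
                raise ValueError("dosage values must lie in [0, 2] or be NaN")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, ids: list[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"variants not present: {missing[:5]}")
        return np.array([lookup[i] for i in ids], dtype=int)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            variants=self.variants.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep],
            quality=None if self.quality is None else self.quality[:, keep],
        )

    def subset_subjects(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            subject_ids=[self.subject_ids[i] for i in keep],
            variants=self.variants.copy(),
            dosage=self.dosage[keep],
            quality=None if self.quality is None else self.quality[keep],
        )


@dataclass
class QcThresholds:
    """Variant/subject QC cut-offs.

    Defaults follow common array-QC practice: variant call rate >= 0.95,
    MAF >= 0.01, HWE exact p >= 1e-6, subject call rate >= 0.95, and per-call
    quality >= 0.2 when a quality matrix is available.
    """

    min_variant_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_subject_call_rate: float = 0.95
    min_call_quality: float = 0.2


@dataclass
class QcReport:
    variant_table: pd.DataFrame  # id, call_rate, maf, hwe_p, pass flags
    subject_table: pd.DataFrame  # subject_id, call_rate, passed
    n_variants_removed: int = 0
    n_subjects_removed: int = 0
    n_calls_masked_quality: int = 0


@dataclass
class RelatednessEstimate:
    subject_a: str
    subject_b: str
    ibs0: int
    ibs1: int
    ibs2: int
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_variants: int
    low_information: bool = False


@dataclass
class PrsResult:
    p_threshold: float
    variant_ids: list[str]
    scores: pd.Series  # indexed by subject id
    scan: pd.DataFrame | None = None  # p_T, n_snps, beta, p, converged
    n_flipped: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_genotypes(path: str, fmt: str = "vcf") -> GenotypeMatrix:
    """Load a genotype matrix from a VCF (v4.2) or additive-dosage TSV.

    VCF dosages count ALT alleles from the GT field; ``./.`` becomes NaN.
    Non-biallelic and non-SNP sites are skipped (counted in a warning).
    The TSV layout is one row per variant with columns
    id, chrom, pos, ref, alt followed by one dosage column per subject.
    """
    if fmt == "vcf":
        return _load_vcf(path)
    if fmt == "tsv":
        return _load_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _load_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    subject_ids = list(vcf.samples)
    records, rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        records.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        rows.append(g)
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic/non-SNP sites")
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    variants = pd.DataFrame.from_records(records)
    return GenotypeMatrix(subject_ids, variants, np.vstack(rows).T)


def _load_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dosage TSV missing required columns: {missing_cols}")
    subject_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
    variants = df[VARIANT_COLUMNS].copy().reset_index(drop=True)
    dosage = df[subject_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(subject_ids, variants, dosage)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_log_probs(n_het_obs: int, n_a: int, n: int) -> tuple[np.ndarray, int]:
    """Log-probabilities of every possible heterozygote count.

    Conditional on the minor-allele count ``n_a`` out of ``2n`` alleles, the
    heterozygote count under random mating follows
    P(h) = C(n; nAA, h, naa) * 2^h / C(2n, n_a); the support is every h with
    the same parity as n_a, 0 <= h <= min(n_a, 2n - n_a).
    Returns (log-probs over support, index of observed h in the support).
    """
    h_max = min(n_a, 2 * n - n_a)
    support = np.arange(n_a % 2, h_max + 1, 2)
    lg = math.lgamma
    logs = np.empty(len(support))
    for k, h in enumerate(support):
        n_aa = (n_a - h) // 2
        n_AA = n - n_aa - h
        logs[k] = (
            lg(n + 1) - lg(n_AA + 1) - lg(h + 1) - lg(n_aa + 1) + h * math.log(2.0)
        )
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    idx = int(np.searchsorted(support, n_het_obs))
    return probs, idx


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the probabilities no larger than that of the observed table
    (the standard exact formulation conditioned on allele counts).
    Returns the p-value; monomorphic sites give p = 1.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype observation required")
    n_a = 2 * n_aa + n_Aa  # count of the 'a' allele
    n_a = min(n_a, 2 * n - n_a)  # rarer allele; test is label-symmetric
    if n_a == 0:
        return 1.0
    probs, idx = _hwe_log_probs(n_Aa, n_a, n)
    p_obs = probs[idx]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _variant_stats(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant call rate, MAF, and HWE exact p (NaN-aware)."""
    n_sub = dosage.shape[0]
    obs = ~np.isnan(dosage)
    call_rate = obs.sum(axis=0) / n_sub
    maf = np.full(dosage.shape[1], np.nan)
    hwe_p = np.ones(dosage.shape[1])
    for j in range(dosage.shape[1]):
        col = dosage[obs[:, j], j]
        if col.size == 0:
            maf[j] = 0.0
            continue
        # round fractional (imputed) dosages to hard calls for HWE
        hard = np.rint(col).astype(int)
        n_aa = int((hard == 0).sum())
        n_het = int((hard == 1).sum())
        n_AA = int((hard == 2).sum())
        af = col.mean() / 2.0
        maf[j] = min(af, 1.0 - af)
        hwe_p[j] = hwe_exact_test(n_AA, n_het, n_aa)
    return call_rate, maf, hwe_p


def snp_qc(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Variant- and subject-level genotype QC.

    Applies, in order: per-call quality masking (only when a quality matrix is
    present), variant filters (call rate, MAF, exact HWE), then subject
    call-rate filtering on the surviving variants. Every decision is recorded
    in the returned :class:`QcReport`.
    """
    thr = thresholds or QcThresholds()
    dosage = genotypes.dosage.copy()
    n_masked = 0
    if genotypes.quality is not None:
        mask = genotypes.quality < thr.min_call_quality
        n_masked = int((mask & ~np.isnan(dosage)).sum())
        dosage[mask] = np.nan

    call_rate, maf, hwe_p = _variant_stats(dosage)
    pass_cr = call_rate >= thr.min_variant_call_rate
    pass_maf = maf >= thr.min_maf
    pass_hwe = hwe_p >= thr.min_hwe_p
    keep_var = pass_cr & pass_maf & pass_hwe

    variant_table = pd.DataFrame(
        {
            "id": genotypes.variants["id"].to_numpy(),
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass_call_rate": pass_cr,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "passed": keep_var,
        }
    )
    if not keep_var.any():
        raise ValueError("no variants remain after QC")

    kept = GenotypeMatrix(
        subject_ids=list(genotypes.subject_ids),
        variants=genotypes.variants.iloc[np.flatnonzero(keep_var)].reset_index(drop=True),
        dosage=dosage[:, keep_var],
    )
    sub_rate = (~np.isnan(kept.dosage)).sum(axis=1) / kept.n_variants
    keep_sub = sub_rate >= thr.min_subject_call_rate
    subject_table = pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "call_rate": sub_rate,
            "passed": keep_sub,
        }
    )
    if not keep_sub.any():
        raise ValueError("no subjects remain after QC")
    kept = kept.subset_subjects(np.flatnonzero(keep_sub))
    report = QcReport(
        variant_table=variant_table,
        subject_table=subject_table,
        n_variants_removed=int((~keep_var).sum()),
        n_subjects_removed=int((~keep_sub).sum()),
        n_calls_masked_quality=n_masked,
    )
    return kept, report


# ---------------------------------------------------------------------------
# LD, pruning, clumping
# ---------------------------------------------------------------------------

def ld_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete)."""
    ok = ~(np.isnan(dosage_i) | np.isnan(dosage_j))
    if ok.sum() < 2:
        raise ValueError("need at least 2 pairwise-complete calls")
    x, y = dosage_i[ok], dosage_j[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def prune_for_ibd(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy sliding-window LD prune giving approximately independent markers.

    Within each window of ``window`` adjacent variants (advanced by ``step``),
    repeatedly drops the later member of any pair with r-squared at or above
    the threshold. Mirrors the usual pre-IBD pruning procedure.
    """
    order = np.lexsort(
        (genotypes.variants["pos"].to_numpy(), genotypes.variants["chrom"].to_numpy())
    )
    removed: set[int] = set()
    for start in range(0, len(order), step):
        idx = [order[k] for k in range(start, min(start + window, len(order)))
               if order[k] not in removed]
        for a in range(len(idx)):
            if idx[a] in removed:
                continue
            for b in range(a + 1, len(idx)):
                if idx[b] in removed:
                    continue
                if genotypes.variants["chrom"].iat[idx[a]] != genotypes.variants["chrom"].iat[idx[b]]:
                    continue
                if ld_r2(genotypes.dosage[:, idx[a]], genotypes.dosage[:, idx[b]]) >= r2_threshold:
                    removed.add(idx[b])
        if start + window >= len(order):
            break
    keep = [i for i in order if i not in removed]
    return [genotypes.variants["id"].iat[i] for i in sorted(keep)]


def greedy_clump(
    gwas: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping of GWAS variants.

    Iterates shared variants by ascending GWAS p-value (ties broken by
    chromosome then position) and keeps a variant unless it lies within
    ``window_kb`` of an already-kept variant on the same chromosome with
    dosage r-squared >= ``r2_threshold``. Returns kept variant ids in
    selection order.
    """
    geno_idx = {v: i for i, v in enumerate(genotypes.variants["id"])}
    shared = gwas[gwas["id"].isin(geno_idx)].copy()
    chrom = genotypes.variants["chrom"]
    pos = genotypes.variants["pos"]
    shared["geno_chrom"] = [chrom.iat[geno_idx[i]] for i in shared["id"]]
    shared["geno_pos"] = [pos.iat[geno_idx[i]] for i in shared["id"]]
    shared = shared.sort_values(["p_value", "geno_chrom", "geno_pos"], kind="mergesort")

    kept: list[str] = []
    kept_meta: list[tuple[str, int, int]] = []  # chrom, pos, column index
    win = window_kb * 1000.0
    for row in shared.itertuples():
        j = geno_idx[row.id]
        c, p = row.geno_chrom, row.geno_pos
        clumped = False
        for kc, kp, kj in kept_meta:
            if kc == c and abs(kp - p) <= win:
                if ld_r2(genotypes.dosage[:, j], genotypes.dosage[:, kj]) >= r2_threshold:
                    clumped = True
                    break
        if not clumped:
            kept.append(row.id)
            kept_meta.append((c, p, j))
    return kept


# ---------------------------------------------------------------------------
# IBD relatedness (method of moments)
# ---------------------------------------------------------------------------

def ibd_estimate(
    genotypes: GenotypeMatrix,
    pruned_variant_ids: list[str] | None = None,
    min_informative: int = 50,
) -> list[RelatednessEstimate]:
    """Method-of-moments IBD estimation for every subject pair.

    Uses observed identity-by-state (IBS) sharing together with the expected
    IBS distribution under each IBD state given allele frequencies (the
    classic PLINK-style estimator). pi-hat = P(IBD=1)/2 + P(IBD=2), clipped
    to [0, 1]. Pairs with fewer than ``min_informative`` complete calls are
    flagged ``low_information``.
    """
    if pruned_variant_ids is not None:
        cols = genotypes.variant_index(pruned_variant_ids)
    else:
        cols = np.arange(genotypes.n_variants)
    d = genotypes.dosage[:, cols]
    obs = ~np.isnan(d)
    af = np.nanmean(d, axis=0) / 2.0  # ALT allele frequency
    # drop monomorphic variants: they carry no IBD information
    poly = (af > 0) & (af < 1)
    d, obs, af = d[:, poly], obs[:, poly], af[poly]
    p, q = af, 1.0 - af
    # expected per-variant P(IBS=i | IBD=j)
    e_ibs0_z0 = 2 * p**2 * q**2
    e_ibs1_z0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs2_z0 = 1.0 - e_ibs0_z0 - e_ibs1_z0
    e_ibs1_z1 = 2 * p**2 * q + 2 * p * q**2
    e_ibs2_z1 = 1.0 - e_ibs1_z1

    out: list[RelatednessEstimate] = []
    n_sub = genotypes.n_subjects
    for a in range(n_sub):
        for b in range(a + 1, n_sub):
            ok = obs[a] & obs[b]
            n_ok = int(ok.sum())
            diff = np.abs(d[a, ok] - d[b, ok])
            ibs0 = int((diff == 2).sum())
            ibs1 = int((diff == 1).sum())
            ibs2 = n_ok - ibs0 - ibs1
            if n_ok == 0:
                out.append(
                    RelatednessEstimate(
                        genotypes.subject_ids[a], genotypes.subject_ids[b],
                        0, 0, 0, np.nan, np.nan, np.nan, np.nan, 0, True,
                    )
                )
                continue
            s00 = float(e_ibs0_z0[ok].sum())
            s10 = float(e_ibs1_z0[ok].sum())
            s20 = float(e_ibs2_z0[ok].sum())
            s11 = float(e_ibs1_z1[ok].sum())
            s21 = float(e_ibs2_z1[ok].sum())
            z0 = ibs0 / s00 if s00 > 0 else 0.0
            z1 = (ibs1 - z0 * s10) / s11 if s11 > 0 else 0.0
            z2 = (ibs2 - z0 * s20 - z1 * s21) / n_ok
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            total = z.sum()
            if total > 0:
                z = z / total
            pi_hat = float(np.clip(z[1] / 2.0 + z[2], 0.0, 1.0))
            out.append(
                RelatednessEstimate(
                    genotypes.subject_ids[a], genotypes.subject_ids[b],
                    ibs0, ibs1, ibs2, float(z[0]), float(z[1]), float(z[2]),
                    pi_hat, n_ok, n_ok < min_informative,
                )
            )
    return out


# ---------------------------------------------------------------------------
# allele alignment and PRS
# ---------------------------------------------------------------------------

@dataclass
class AllelAlignment:
    """Per-variant aligned weights: score contribution = weight * dosage + offset."""

    weights: dict[str, float] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)
    flipped: set[str] = field(default_factory=set)
    dropped_ambiguous: list[str] = field(default_factory=list)
    dropped_mismatch: list[str] = field(default_factory=list)


def align_alleles(
    gwas: pd.DataFrame,
    variants: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> AllelAlignment:
    """Map GWAS effect-allele weights onto the cohort's counted (ALT) allele.

    If the effect allele equals ALT the weight applies to the dosage directly;
    if it equals REF the contribution is weight * (2 - dosage), folded into a
    negated weight plus constant offset. Strand-ambiguous pairs (A/T, C/G) are
    dropped by default; variants whose allele sets do not match are dropped
    and reported.
    """
    res = AllelAlignment()
    meta = variants.set_index("id")
    for row in gwas.itertuples():
        if row.id not in meta.index:
            continue
        ref, alt = meta.at[row.id, "ref"], meta.at[row.id, "alt"]
        ea, oa = row.effect_allele, row.other_allele
        if drop_ambiguous and frozenset((ea, oa)) in _AMBIGUOUS:
            res.dropped_ambiguous.append(row.id)
            continue
        pair = {ref, alt}
        if {ea, oa} == pair:
            pass
        elif {_COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")} == pair:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]  # strand flip
        else:
            res.dropped_mismatch.append(row.id)
            continue
        if ea == alt:
            res.weights[row.id] = float(row.weight)
            res.offsets[row.id] = 0.0
        else:  # effect allele is REF: w * (2 - d) = -w * d + 2w
            res.weights[row.id] = -float(row.weight)
            res.offsets[row.id] = 2.0 * float(row.weight)
            res.flipped.add(row.id)
    return res


def compute_prs(
    genotypes: GenotypeMatrix,
    gwas: pd.DataFrame,
    clumped_ids: list[str],
    p_threshold: float,
    alignment: AllelAlignment | None = None,
) -> PrsResult:
    """Polygenic risk score at one GWAS p-value threshold.

    score = sum over clumped variants with GWAS p <= threshold of
    weight x risk-allele dosage (alleles aligned to the GWAS effect allele).
    Missing dosages are imputed as 2 x effect-allele frequency.
    """
    align = alignment if alignment is not None else align_alleles(gwas, genotypes.variants)
    pmap = dict(zip(gwas["id"], gwas["p_value"]))
    use = [v for v in clumped_ids if v in align.weights and pmap.get(v, 1.1) <= p_threshold]
    n = genotypes.n_subjects
    if not use:
        warnings.warn(f"no variants selected at p_T={p_threshold}; scores set to 0")
        scores = np.zeros(n)
    else:
        cols = genotypes.variant_index(use)
        d = genotypes.dosage[:, cols].copy()
        af = np.nanmean(d, axis=0) / 2.0
        w = np.array([align.weights[v] for v in use])
        off = np.array([align.offsets[v] for v in use])
        # mean-impute missing with 2 * ALT frequency (= 2 * EAF after folding)
        nan_rows, nan_cols = np.where(np.isnan(d))
        d[nan_rows, nan_cols] = 2.0 * af[nan_cols]
        scores = d @ w + off.sum()
    return PrsResult(
        p_threshold=p_threshold,
        variant_ids=use,
        scores=pd.Series(scores, index=pd.Index(genotypes.subject_ids, name="subject_id")),
        n_flipped=len(align.flipped),
        n_dropped_ambiguous=len(align.dropped_ambiguous),
        n_dropped_mismatch=len(align.dropped_mismatch),
    )


def optimize_threshold(
    genotypes: GenotypeMatrix,
    gwas: pd.DataFrame,
    clumped_ids: list[str],
    family_history: pd.Series,
    grid: np.ndarray | None = None,
) -> PrsResult:
    """Scan GWAS p-value thresholds for the PRS most predictive of family history.

    For each threshold on the grid (default 0.01..0.50 step 0.01) computes the
    PRS and fits logistic regression family_history ~ PRS; the threshold with
    the smallest two-sided Wald p on the PRS coefficient wins, ties broken by
    the smaller threshold. Thresholds with non-convergent or separated fits
    are recorded and excluded from selection.
    """
    import statsmodels.api as sm

    if grid is None:
        grid = np.round(np.arange(0.01, 0.501, 0.01), 10)
    fh = family_history.reindex(genotypes.subject_ids)
    if fh.isna().any():
        raise ValueError("family history missing for some genotyped subjects")
    y = fh.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both family-history classes must be non-empty")

    align = align_alleles(gwas, genotypes.variants)
    rows = []
    results: dict[float, PrsResult] = {}
    for p_t in grid:
        prs = compute_prs(genotypes, gwas, clumped_ids, float(p_t), alignment=align)
        results[float(p_t)] = prs
        x = prs.scores.to_numpy()
        beta = p = np.nan
        converged = False
        if np.std(x) > 0:
            X = sm.add_constant((x - x.mean()) / x.std())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                    if fit.mle_retvals.get("converged", False) and np.all(
                        np.isfinite(fit.bse)
                    ) and fit.bse[1] < 50:
                        beta, p = float(fit.params[1]), float(fit.pvalues[1])
                        converged = True
                except (np.linalg.LinAlgError, ValueError):
                    pass
        rows.append(
            {"p_threshold": float(p_t), "n_snps": len(prs.variant_ids),
             "beta": beta, "p": p, "converged": converged}
        )
    scan = pd.DataFrame(rows)
    ok = scan[scan["converged"] & scan["p"].notna()]
    if ok.empty:
        raise RuntimeError("logistic scan failed to converge at every threshold")
    best_row = ok.sort_values(["p", "p_threshold"], kind="mergesort").iloc[0]
    best = results[float(best_row["p_threshold"])]
    best.scan = scan
    return best


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(genotypes: GenotypeMatrix, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the column-standardised dosage matrix.

    Missing calls are mean-imputed per variant before standardisation.
    Returns (coordinates: subjects x k, variance_explained: k).
    Components are deterministic up to sign.
    """
    d = genotypes.dosage.copy()
    mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    sd = d.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (d - d.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum()) if s.size else 0
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = rank
    coords = u[:, :k] * s[:k]
    var_exp = (s[:k] ** 2) / (s**2).sum()
    return coords, var_exp
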