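"""Synthetic cohort generator with known ground truth.

Generates complete study cohorts — genotypes in Hardy-Weinberg equilibrium
with block LD, an external GWAS weight file with planted risk SNPs,
Illumina-style beta-value methylation with planted group-differential probes
(two probe design types, type II compressed toward 0.5), a subject table
(diagnostic group, family history, childhood trauma scale, demographics),
and brain structure measures generated as linear functions of the true
genetic score, environmental score, their product, and covariates plus
Gaussian noise — so every downstream stage can be tested against planted
effects without any external data.

Genotype LD uses a latent multivariate Gaussian with equicorrelated blocks
thresholded at Hardy-Weinberg quantiles, which controls minor-allele
frequency and LD strength independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix
from .methylation import MethylationMatrix

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "Cohort",
    "simulate_genotypes",
    "simulate_gwas_weights",
    "simulate_methylation",
    "simulate_subjects",
    "simulate_brain_measures",
    "simulate_cohort",
    "offspring_dosage",
    "write_cohort",
    "write_vcf",
    "default_measure_names",
]

_NON_AMBIGUOUS_ALT = {"A": ("C", "G"), "T": ("C", "G"), "C": ("A", "T"), "G": ("A", "T")}

_BASE_MEASURES = [
    "whole_brain_fraction", "gray_matter_fraction", "white_matter_fraction",
    "frontal_cortex_thickness", "parietal_cortex_thickness",
    "temporal_cortex_thickness", "occipital_cortex_thickness",
    "cingulate_cortex_thickness", "insula_cortex_thickness",
    "global_cortex_thickness",
    "left_accumbens", "right_accumbens", "left_amygdala", "right_amygdala",
    "left_caudate", "right_caudate", "left_hippocampus", "right_hippocampus",
    "left_pallidum", "right_pallidum", "left_putamen", "right_putamen",
    "left_thalamus", "right_thalamus",
    "accumbens", "amygdala", "caudate", "hippocampus", "pallidum", "putamen",
    "thalamus", "claustrum",
    "anterior_thalamus", "centromedian_thalamus", "habenula_thalamus",
    "lateral_thalamus", "lateral_geniculate_thalamus", "medial_thalamus",
    "medial_geniculate_thalamus", "mediodorsal_thalamus", "pulvinar_thalamus",
    "mtt_thalamus", "subthalamic_nucleus", "brainstem",
]


def default_measure_names(n: int) -> list[str]:
    if n <= len(_BASE_MEASURES):
        return _BASE_MEASURES[:n]
    return _BASE_MEASURES + [f"measure_{k}" for k in range(len(_BASE_MEASURES), n)]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Cohort composition mirrors the target study design: 119 subjects of whom
    55 form the case-spectrum (BDS) group, 8 of them without brain measures,
    44 structural measures, and a trauma scale missing for a handful of
    subjects. Genetic and epigenetic scales are desk-sized stand-ins for
    array-scale data; effect sizes are standardised coefficients chosen to
    give partial R^2 values in the 0.1-0.35 range at n ~ 47.
    """

    n_subjects: int = 119
    n_bds: int = 55
    n_snps: int = 600
    n_causal_snps: int = 25
    ld_block_size: int = 5
    ld_rho: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_probes: int = 800
    n_signal_probes: int = 20
    probe_effect_delta: float = 0.1
    exposure_within_sd: float = 0.5
    type_ii_fraction: float = 0.84
    type_ii_compression: float = 0.8
    n_measures: int = 44
    beta_G: float = 0.25
    beta_E: float = 0.45
    beta_GxE: float = 0.4
    n_affected_measures: int | None = None  # None = all measures
    noise_sd: float = 1.0
    covariate_effects: tuple[float, ...] = (0.2, 0.1, 0.2, 0.2, 0.2)
    cles_mps_correlation: float = 0.3
    cles_missing_rate: float = 4.0 / 119.0
    mri_missing_bds: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bds > self.n_subjects:
            raise ValueError("n_bds cannot exceed n_subjects")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps cannot exceed n_snps")
        if self.n_signal_probes > self.n_probes:
            raise ValueError("n_signal_probes cannot exceed n_probes")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_subjects", "n_snps", "n_probes", "n_measures",
                     "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class CohortTruth:
    """Planted ground truth for a simulated cohort."""

    causal_snp_ids: list[str]
    true_snp_weights: np.ndarray
    signal_probe_ids: list[str]
    true_probe_directions: np.ndarray
    true_effects: pd.DataFrame  # per measure: beta_G, beta_E, beta_GxE

    def __post_init__(self) -> None:
        if len(self.causal_snp_ids) != len(self.true_snp_weights):
            raise ValueError("causal SNP ids and weights length mismatch")
        if len(self.signal_probe_ids) != len(self.true_probe_directions):
            raise ValueError("signal probe ids and directions length mismatch")


@dataclass
class Cohort:
    config: SimulationConfig
    truth: CohortTruth
    genotypes: GenotypeMatrix
    gwas: pd.DataFrame
    methylation: MethylationMatrix
    subjects: pd.DataFrame
    brain: pd.DataFrame
    prs_true: pd.Series
    mps_true: pd.Series


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Biallelic SNP dosages in HWE with equicorrelated LD blocks.

    Each block of ``ld_block_size`` adjacent variants shares a latent
    Gaussian factor with pairwise correlation ``ld_rho``; per-variant latents
    are thresholded at the HWE genotype-frequency quantiles of a minor-allele
    frequency drawn uniformly from ``maf_range`` (the ALT allele is the minor
    allele). Missing calls are injected completely at random at
    ``missing_rate``. Deterministic given the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)

    z = np.empty((n, m))
    rho = config.ld_rho
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        width = stop - start
        shared = rng.standard_normal((n, 1))
        indep = rng.standard_normal((n, width))
        z[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep

    # HWE thresholds: P(0)=(1-f)^2, P(1)=2f(1-f), P(2)=f^2 for ALT freq f
    t1 = stats.norm.ppf((1.0 - maf) ** 2)
    t2 = stats.norm.ppf((1.0 - maf) ** 2 + 2.0 * maf * (1.0 - maf))
    dosage = (z > t1).astype(float) + (z > t2).astype(float)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan

    ref = rng.choice(list("ACGT"), size=m)
    alt = np.array([rng.choice(_NON_AMBIGUOUS_ALT[r]) for r in ref])
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": 1 + 5000 * np.arange(m),
            "ref": ref,
            "alt": alt,
        }
    )
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(subject_ids, variants, dosage)


def simulate_gwas_weights(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
    causal_weight_sd: float = 0.06,
    causal_weight_mean: float = 0.2,
    null_weight_sd: float = 0.02,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """External GWAS summary statistics with planted risk SNPs.

    Causal SNPs (one per LD block, up to ``n_causal_snps``) receive log-odds
    weights of magnitude ~ causal_weight_mean and p-values in [1e-8, 1e-4];
    the rest receive weights near zero and uniform p-values. The effect
    allele is the cohort's ALT allele. Returns (summary table, causal ids,
    causal weights).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    m = config.n_snps
    # one causal SNP per block so clumping cannot merge two causal signals
    block_starts = np.arange(0, m, config.ld_block_size)
    chosen_blocks = rng.choice(
        len(block_starts), size=min(config.n_causal_snps, len(block_starts)),
        replace=False,
    )
    causal_idx = np.sort(
        np.array(
            [block_starts[b]
             + rng.integers(0, min(config.ld_block_size, m - block_starts[b]))
             for b in chosen_blocks],
            dtype=int,
        )
    )
    weights = rng.normal(0.0, null_weight_sd, size=m)
    p_values = rng.uniform(0.0, 1.0, size=m)
    p_values = np.clip(p_values, 1e-300, 1.0)
    signs = rng.choice([-1.0, 1.0], size=len(causal_idx))
    weights[causal_idx] = signs * np.abs(
        rng.normal(causal_weight_mean, causal_weight_sd, size=len(causal_idx))
    )
    p_values[causal_idx] = 10.0 ** rng.uniform(-8, -4, size=len(causal_idx))

    gwas = pd.DataFrame(
        {
            "id": genotypes.variants["id"].to_numpy(),
            "chrom": genotypes.variants["chrom"].to_numpy(),
            "pos": genotypes.variants["pos"].to_numpy(),
            "effect_allele": genotypes.variants["alt"].to_numpy(),
            "other_allele": genotypes.variants["ref"].to_numpy(),
            "weight": weights,
            "p_value": p_values,
        }
    )
    causal_ids = [genotypes.variants["id"].iat[j] for j in causal_idx]
    return gwas, causal_ids, weights[causal_idx]


def offspring_dosage(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian offspring: one transmitted allele per parent per variant."""
    pa = np.asarray(parent_a, dtype=float)
    pb = np.asarray(parent_b, dtype=float)
    return (rng.random(pa.shape) < pa / 2.0).astype(float) + (
        rng.random(pb.shape) < pb / 2.0
    ).astype(float)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    config: SimulationConfig,
    group_labels: np.ndarray,
    rng: np.random.Generator | None = None,
    precision: float = 80.0,
    emit_qc_matrices: bool = True,
) -> tuple[MethylationMatrix, list[str], np.ndarray, np.ndarray]:
    """Beta-distributed methylation with planted group-differential probes.

    Probe baselines come from a 3-state mixture (unmethylated / hemi /
    methylated); individual betas are Beta-distributed around the baseline.
    A continuous per-subject exposure latent (case-group mean 1, comparison
    mean 0, within-group sd ``exposure_within_sd``) drives the signal probes
    (baselines restricted to the mid-range so the shift fits): each moves by
    ``probe_effect_delta`` x direction x exposure, so the expected
    case-vs-comparison beta difference is exactly the configured delta. A
    random ``type_ii_fraction`` of probes is labelled design type II and
    compressed toward 0.5 by ``type_ii_compression`` to exercise
    normalisation. Detection-p and bead-count matrices are emitted with rare
    planted failures.
    Returns (matrix, signal probe ids, signal directions, exposure latent).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n, p = config.n_subjects, config.n_probes
    is_case = np.asarray(group_labels, dtype=bool)

    state = rng.choice(3, size=p, p=[0.45, 0.1, 0.45])
    lows = rng.uniform(0.03, 0.25, size=p)
    mids = rng.uniform(0.35, 0.65, size=p)
    highs = rng.uniform(0.75, 0.97, size=p)
    baseline = np.where(state == 0, lows, np.where(state == 1, mids, highs))

    # signal probes need mid-range baselines so a +/- delta shift stays in (0,1)
    eligible = np.flatnonzero((baseline > 0.2) & (baseline < 0.8))
    signal_idx = np.sort(rng.choice(eligible, size=config.n_signal_probes, replace=False))
    directions = rng.choice([-1.0, 1.0], size=config.n_signal_probes)

    exposure = is_case.astype(float) + config.exposure_within_sd * rng.standard_normal(n)

    mean = np.tile(baseline, (n, 1))
    shift = np.zeros(p)
    shift[signal_idx] = directions * config.probe_effect_delta
    mean = mean + exposure[:, None] * shift[None, :]
    mean = np.clip(mean, 0.02, 0.98)
    beta = rng.beta(mean * precision, (1.0 - mean) * precision)

    design = np.where(
        rng.random(p) < config.type_ii_fraction, "II", "I"
    )
    compressed = beta.copy()
    ii = design == "II"
    compressed[:, ii] = 0.5 + config.type_ii_compression * (beta[:, ii] - 0.5)

    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{j + 1:08d}" for j in range(p)],
            "chrom": "1",
            "pos": 1 + 3000 * np.arange(p),
            "design_type": design,
            "snp_overlap": rng.random(p) < 0.01,
        }
    )
    detection_p = bead_count = None
    if emit_qc_matrices:
        detection_p = rng.uniform(0.0, 1e-4, size=(n, p))
        bad = rng.random(p) < 0.005  # rare failed probes
        detection_p[:, bad] = rng.uniform(0.01, 0.5, size=(n, int(bad.sum())))
        bead_count = rng.poisson(12, size=(n, p)) + 3
        low = rng.random(p) < 0.005
        bead_count[:, low] = rng.integers(1, 3, size=(n, int(low.sum())))
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    meth = MethylationMatrix(
        subject_ids=subject_ids,
        probes=probes,
        beta=compressed,
        detection_p=detection_p,
        bead_count=bead_count,
    )
    signal_ids = [probes["probe_id"].iat[j] for j in signal_idx]
    return meth, signal_ids, directions, exposure


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


# ---------------------------------------------------------------------------
# subjects and brain measures
# ---------------------------------------------------------------------------

def simulate_subjects(
    config: SimulationConfig,
    prs_true: np.ndarray,
    mps_true: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Subject table: group, family history, trauma scale, demographics.

    Family history is Bernoulli with log-odds increasing in the true genetic
    score (and higher in the case group); the trauma scale (CLES, counts
    0-11) is tied to the true environmental score through a Gaussian copula
    with correlation ``cles_mps_correlation``. The joint distribution of
    these clinical proxies with the molecular scores is a configurable
    modelling assumption, not an estimate from data.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    n = config.n_subjects
    is_bds = np.zeros(n, dtype=bool)
    is_bds[: config.n_bds] = True

    g = _standardize(np.asarray(prs_true, dtype=float))
    e = _standardize(np.asarray(mps_true, dtype=float))

    logit_fh = -2.6 + 1.0 * g + 2.2 * is_bds
    family_history = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit_fh))).astype(int)

    c = config.cles_mps_correlation
    latent = c * e + np.sqrt(max(1.0 - c * c, 0.0)) * rng.standard_normal(n)
    u = stats.norm.cdf(latent)
    cles = stats.binom.ppf(u, 11, 0.35).astype(float)
    if config.cles_missing_rate > 0:
        cles[rng.random(n) < config.cles_missing_rate] = np.nan

    age = np.clip(np.round(rng.normal(24.0, 3.5, size=n)), 15, 30)
    gender = rng.choice(["Female", "Male"], size=n, p=[0.65, 0.35])
    race = rng.choice(
        ["Caucasian", "African American", "Asian"], size=n, p=[0.78, 0.16, 0.06]
    )
    smoking = rng.choice(["No", "Yes", "Unknown"], size=n, p=[0.63, 0.22, 0.15])
    alcohol = (rng.random(n) < 0.03) & is_bds
    drug = (rng.random(n) < 0.05) & is_bds

    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "group": np.where(is_bds, "BDS", "non-BDS"),
            "family_history": family_history,
            "cles": cles,
            "age": age,
            "gender": gender,
            "race": race,
            "smoking": smoking,
            "alcohol_abuse": alcohol.astype(int),
            "drug_abuse": drug.astype(int),
        }
    )


def simulate_brain_measures(
    config: SimulationConfig,
    truth: CohortTruth,
    prs_true: np.ndarray,
    mps_true: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Brain measures as linear functions of true G, E, GxE, and covariates.

    y = beta_G*G + beta_E*E + beta_GxE*G*E + covariate terms (standardised
    age, age^2, gender, race, smoking) + Normal(0, noise_sd), with G and E
    standardised. Effects per measure come from ``truth.true_effects``.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    g = _standardize(np.asarray(prs_true, dtype=float))
    e = _standardize(np.asarray(mps_true, dtype=float))
    age_std = _standardize(covariates["age"].to_numpy(dtype=float))
    cov_design = np.column_stack(
        [
            age_std,
            age_std**2,
            (covariates["gender"] == "Female").to_numpy(dtype=float),
            (covariates["race"] == "Caucasian").to_numpy(dtype=float),
            (covariates["smoking"] == "Yes").to_numpy(dtype=float),
        ]
    )
    cov_effect = cov_design @ np.asarray(config.covariate_effects, dtype=float)

    n = len(g)
    out = {"subject_id": covariates["subject_id"].to_numpy()}
    for row in truth.true_effects.itertuples():
        y = (
            row.beta_G * g
            + row.beta_E * e
            + row.beta_GxE * g * e
            + cov_effect
            + rng.normal(0.0, config.noise_sd, size=n)
        )
        out[row.measure] = y
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate a full cohort: genotypes, GWAS weights, methylation, subject
    table, and brain measures, with the planted truth attached.

    Brain measures are produced only for imaged case-group subjects plus all
    comparison subjects (``mri_missing_bds`` cases are dropped at random,
    mirroring subjects who never underwent scanning).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    genotypes = simulate_genotypes(config, rng)
    gwas, causal_ids, causal_weights = simulate_gwas_weights(
        config, genotypes, np.random.default_rng(config.seed + 1)
    )

    dosage = np.nan_to_num(genotypes.dosage, nan=0.0)
    cols = genotypes.variant_index(causal_ids)
    prs_true = dosage[:, cols] @ causal_weights

    is_bds = np.zeros(config.n_subjects, dtype=bool)
    is_bds[: config.n_bds] = True
    meth, signal_ids, directions, exposure = simulate_methylation(
        config, is_bds, np.random.default_rng(config.seed + 2)
    )
    mps_true_arr = _standardize(exposure)

    measures = default_measure_names(config.n_measures)
    n_affected = (
        config.n_measures if config.n_affected_measures is None
        else config.n_affected_measures
    )
    effects = pd.DataFrame(
        {
            "measure": measures,
            "beta_G": [config.beta_G if k < n_affected else 0.0 for k in range(config.n_measures)],
            "beta_E": [config.beta_E if k < n_affected else 0.0 for k in range(config.n_measures)],
            "beta_GxE": [config.beta_GxE if k < n_affected else 0.0 for k in range(config.n_measures)],
        }
    )
    truth = CohortTruth(
        causal_snp_ids=causal_ids,
        true_snp_weights=np.asarray(causal_weights),
        signal_probe_ids=signal_ids,
        true_probe_directions=np.asarray(directions),
        true_effects=effects,
    )

    subjects = simulate_subjects(
        config, prs_true, mps_true_arr, np.random.default_rng(config.seed + 3)
    )
    brain = simulate_brain_measures(
        config, truth, prs_true, mps_true_arr, subjects,
        np.random.default_rng(config.seed + 4),
    )
    if config.mri_missing_bds > 0:
        rng_mri = np.random.default_rng(config.seed + 5)
        bds_ids = subjects.loc[subjects["group"] == "BDS", "subject_id"].to_numpy()
        drop = rng_mri.choice(bds_ids, size=min(config.mri_missing_bds, len(bds_ids)),
                              replace=False)
        brain = brain[~brain["subject_id"].isin(drop)].reset_index(drop=True)

    idx = pd.Index(subjects["subject_id"], name="subject_id")
    return Cohort(
        config=config,
        truth=truth,
        genotypes=genotypes,
        gwas=gwas,
        methylation=meth,
        subjects=subjects,
        brain=brain,
        prs_true=pd.Series(prs_true, index=idx, name="prs_true"),
        mps_true=pd.Series(mps_true_arr, index=idx, name="mps_true"),
    )


# ---------------------------------------------------------------------------
# file-set writer
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 writer (GT field only, 1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids) + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in enumerate(genotypes.variants.itertuples()):
            calls = [
                "./." if np.isnan(d) else gt_map[float(np.rint(d))]
                for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def write_cohort(
    cohort: Cohort, outdir: str | Path, genotype_format: str = "vcf"
) -> dict[str, str]:
    """Write the full cohort file set in the formats the analysis stages read.

    Emits genotypes (VCF or dosage TSV), GWAS summary TSV
    (SNP/CHR/BP/A1/A2/BETA/P), methylation beta + probe annotation TSVs with
    detection-p and bead-count TSVs when present, subject TSV, brain-measure
    TSV, and the planted truth as JSON. Returns {role: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    if genotype_format == "vcf":
        gpath = outdir / "genotypes.vcf"
        write_vcf(cohort.genotypes, gpath)
    elif genotype_format == "tsv":
        gpath = outdir / "genotypes.tsv"
        g = cohort.genotypes
        df = pd.concat(
            [g.variants,
             pd.DataFrame(g.dosage.T, columns=g.subject_ids)], axis=1
        )
        df.to_csv(gpath, sep="\t", index=False)
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")
    paths["genotypes"] = str(gpath)

    gw = cohort.gwas.rename(
        columns={
            "id": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
            "other_allele": "A2", "weight": "BETA", "p_value": "P",
        }
    )
    gw_path = outdir / "gwas_summary.tsv"
    gw.to_csv(gw_path, sep="\t", index=False)
    paths["gwas"] = str(gw_path)

    meth = cohort.methylation
    beta_df = pd.DataFrame(
        meth.beta.T, index=meth.probes["probe_id"], columns=meth.subject_ids
    )
    beta_path = outdir / "methylation_beta.tsv"
    beta_df.to_csv(beta_path, sep="\t", index_label="probe_id")
    paths["methylation_beta"] = str(beta_path)
    ann_path = outdir / "probe_annotation.tsv"
    meth.probes.to_csv(ann_path, sep="\t", index=False)
    paths["probe_annotation"] = str(ann_path)
    if meth.detection_p is not None:
        dp = pd.DataFrame(
            meth.detection_p.T, index=meth.probes["probe_id"], columns=meth.subject_ids
        )
        dp_path = outdir / "detection_p.tsv"
        dp.to_csv(dp_path, sep="\t", index_label="probe_id")
        paths["detection_p"] = str(dp_path)
    if meth.bead_count is not None:
        bc = pd.DataFrame(
            meth.bead_count.T, index=meth.probes["probe_id"], columns=meth.subject_ids
        )
        bc_path = outdir / "bead_count.tsv"
        bc.to_csv(bc_path, sep="\t", index_label="probe_id")
        paths["bead_count"] = str(bc_path)

    subj_path = outdir / "subjects.tsv"
    cohort.subjects.to_csv(subj_path, sep="\t", index=False)
    paths["subjects"] = str(subj_path)
    brain_path = outdir / "brain_measures.tsv"
    cohort.brain.to_csv(brain_path, sep="\t", index=False)
    paths["brain"] = str(brain_path)

    truth_path = outdir / "truth.json"
    truth = {
        "causal_snp_ids": cohort.truth.causal_snp_ids,
        "true_snp_weights": cohort.truth.true_snp_weights.tolist(),
        "signal_probe_ids": cohort.truth.signal_probe_ids,
        "true_probe_directions": cohort.truth.true_probe_directions.tolist(),
        "true_effects": cohort.truth.true_effects.to_dict(orient="records"),
        "config": asdict(cohort.config),
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    paths["truth"] = str(truth_path)
    return paths
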