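"""Readers/writers for the pipeline's tabular formats and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, load_genotypes  # re-export for convenience
from .methylation import MethylationMatrix, MpsModel

__all__ = [
    "load_genotypes",
    "read_gwas_summary",
    "read_methylation",
    "read_subjects",
    "read_brain_measures",
    "read_scores",
    "write_scores",
    "write_mps_model",
    "read_mps_model",
    "write_manifest",
    "sha256_file",
]

GWAS_COLUMN_MAP = {
    "SNP": "id", "CHR": "chrom", "BP": "pos", "A1": "effect_allele",
    "A2": "other_allele", "BETA": "weight", "P": "p_value", "OR": "odds_ratio",
}

SUBJECT_REQUIRED = ["subject_id", "group", "family_history", "cles", "age",
                    "gender", "race", "smoking"]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def read_gwas_summary(path: str | Path, or_scale: bool = False) -> pd.DataFrame:
    """GWAS summary TSV with columns SNP, CHR, BP, A1, A2, BETA (or OR), P.

    With ``or_scale=True`` the effect column is an odds ratio and is
    log-transformed to the log-odds weight.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    df = df.rename(columns=GWAS_COLUMN_MAP)
    needed = ["id", "effect_allele", "other_allele", "p_value"]
    _require(df, needed, "GWAS summary")
    if or_scale:
        if "odds_ratio" not in df.columns:
            raise ValueError("or_scale=True requires an OR column")
        df["weight"] = np.log(df["odds_ratio"].to_numpy(dtype=float))
    _require(df, ["weight"], "GWAS summary")
    bad = df["p_value"].to_numpy(dtype=float)
    if np.any((bad <= 0) | (bad > 1) | ~np.isfinite(bad)):
        raise ValueError("GWAS p-values must lie in (0, 1]")
    if not np.all(np.isfinite(df["weight"].to_numpy(dtype=float))):
        raise ValueError("GWAS weights must be finite")
    return df


def read_methylation(
    beta_path: str | Path,
    annotation_path: str | Path,
    detection_p_path: str | Path | None = None,
    bead_count_path: str | Path | None = None,
) -> MethylationMatrix:
    """Beta TSV (probes x subjects or subjects x probes, auto-detected from
    the annotation ids in the first column) plus probe annotation TSV."""
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    _require(ann, ["probe_id", "chrom", "pos", "design_type"], "probe annotation")
    if "snp_overlap" not in ann.columns:
        ann["snp_overlap"] = False
    ann["snp_overlap"] = ann["snp_overlap"].astype(bool)

    def load_matrix(path: str | Path) -> tuple[pd.DataFrame, bool]:
        df = pd.read_csv(path, sep="\t", index_col=0)
        probes_in_rows = df.index.isin(ann["probe_id"]).mean() > 0.5
        return (df.T if probes_in_rows else df), probes_in_rows

    beta_df, _ = load_matrix(beta_path)  # now subjects x probes
    beta_df = beta_df[ann["probe_id"].tolist()]
    det = bead = None
    if detection_p_path is not None:
        d, _ = load_matrix(detection_p_path)
        det = d.loc[beta_df.index, ann["probe_id"].tolist()].to_numpy(dtype=float)
    if bead_count_path is not None:
        b, _ = load_matrix(bead_count_path)
        bead = b.loc[beta_df.index, ann["probe_id"].tolist()].to_numpy(dtype=float)
    return MethylationMatrix(
        subject_ids=[str(s) for s in beta_df.index],
        probes=ann.reset_index(drop=True),
        beta=beta_df.to_numpy(dtype=float),
        detection_p=det,
        bead_count=bead,
    )


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, SUBJECT_REQUIRED, "subject table")
    df["subject_id"] = df["subject_id"].astype(str)
    cles = df["cles"].to_numpy(dtype=float)
    ok = np.isnan(cles) | ((cles >= 0) & (cles <= 11))
    if not ok.all():
        raise ValueError("CLES values must lie in [0, 11] or be missing")
    return df


def read_brain_measures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["subject_id"], "brain-measure table")
    df["subject_id"] = df["subject_id"].astype(str)
    values = df.drop(columns="subject_id")
    if not all(pd.api.types.is_numeric_dtype(values[c]) for c in values.columns):
        raise ValueError("brain measures must be numeric")
    if not np.all(np.isfinite(values.to_numpy(dtype=float))):
        raise ValueError("brain measures must be finite")
    return df


def read_scores(path: str | Path, name: str = "score") -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["subject_id", "score"], "score table")
    return pd.Series(
        df["score"].to_numpy(dtype=float),
        index=pd.Index(df["subject_id"].astype(str), name="subject_id"),
        name=name,
    )


def write_scores(scores: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"subject_id": scores.index, "score": scores.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def write_mps_model(model: MpsModel, path: str | Path) -> None:
    payload = {
        "probe_ids": model.probe_ids,
        "weights": np.asarray(model.weights).tolist(),
        "intercept": model.intercept,
        "lambda": model.lambda_,
        "cv_table": None
        if model.cv_table is None
        else model.cv_table.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_mps_model(path: str | Path) -> MpsModel:
    with open(path) as fh:
        payload = json.load(fh)
    return MpsModel(
        probe_ids=payload["probe_ids"],
        weights=np.asarray(payload["weights"], dtype=float),
        intercept=payload["intercept"],
        lambda_=payload["lambda"],
        cv_table=None
        if payload.get("cv_table") is None
        else pd.DataFrame(payload["cv_table"]),
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int,
    inputs: dict[str, str] | None = None,
    warnings_log: list[str] | None = None,
) -> None:
    """Run manifest: config hash, seed, package/interpreter versions, and
    input checksums — enough to reproduce every output byte-for-byte."""
    from . import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "gxebrain": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {
            k: {"path": v, "sha256": sha256_file(v)} for k, v in (inputs or {}).items()
        },
        "warnings": warnings_log or [],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
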