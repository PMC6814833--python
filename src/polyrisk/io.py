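"""Readers and writers for the text formats the pipeline exchanges.

Genotypes travel in a PLINK-.raw-style tab-separated dialect (header
``FID IID PAT MAT SEX PHENOTYPE <variant ids>``, one sample per row, dosages
with up to 3 decimals); phenotypes as ``sample_id,status,sex,age`` CSV;
effect models as a ``variant_id,beta`` CSV plus a JSON sidecar holding the
intercept, lambda, and standardization constants; scores as
``sample_id,pgs,augmented`` CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, PhenotypeTable
from .lasso import EffectModel
from .scoring import ScoreSet

__all__ = [
    "write_raw",
    "read_raw",
    "write_phenotypes",
    "read_phenotypes",
    "write_effects",
    "read_effects",
    "write_scores",
    "read_scores",
]

_RAW_FIXED = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_raw(G: GenotypeMatrix, path, pheno: PhenotypeTable | None = None) -> None:
    """Write dosages in the PLINK-.raw-style tab-separated dialect."""
    df = pd.DataFrame(
        {
            "FID": G.sample_ids,
            "IID": G.sample_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": pheno.sex + 1 if pheno is not None else 0,
            "PHENOTYPE": pheno.status + 1 if pheno is not None else -9,
        }
    )
    dosage = pd.DataFrame(np.round(G.dosages, 3), columns=G.variant_ids)
    pd.concat([df, dosage], axis=1).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RAW_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"not a .raw-style file; missing columns {missing}")
    variant_ids = [c for c in df.columns if c not in _RAW_FIXED]
    dosages = df[variant_ids].to_numpy(dtype=float)
    return GenotypeMatrix(
        sample_ids=df["IID"].astype(str).tolist(),
        variant_ids=variant_ids,
        dosages=dosages,
        allele_freqs=dosages.mean(axis=0) / 2,
        chromosome_labels=["?"] * len(variant_ids),
    )


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pd.DataFrame(
        {
            "sample_id": pheno.sample_ids,
            "status": pheno.status,
            "sex": pheno.sex,
            "age": pheno.age,
        }
    ).to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    return PhenotypeTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        status=df["status"].to_numpy(),
        sex=df["sex"].to_numpy(),
        age=df["age"].to_numpy(),
    )


def write_effects(model: EffectModel, prefix) -> None:
    """``<prefix>.csv`` with variant_id,beta and ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    pd.DataFrame({"variant_id": model.variant_ids, "beta": model.beta}).to_csv(
        prefix.with_suffix(".csv"), index=False, float_format="%.17g"
    )
    sidecar = {
        "intercept": model.intercept,
        "lambda_value": model.lambda_value,
        "col_means": None if model.col_means is None else list(model.col_means),
        "col_scales": None if model.col_scales is None else list(model.col_scales),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_effects(prefix) -> EffectModel:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return EffectModel(
        variant_ids=df["variant_id"].astype(str).tolist(),
        beta=df["beta"].to_numpy(dtype=float),
        intercept=float(sidecar["intercept"]),
        lambda_value=float(sidecar["lambda_value"]),
        col_means=None if sidecar["col_means"] is None else np.asarray(sidecar["col_means"]),
        col_scales=None if sidecar["col_scales"] is None else np.asarray(sidecar["col_scales"]),
    )


def write_scores(scores: ScoreSet, path) -> None:
    pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            "pgs": scores.pgs,
            "augmented": scores.augmented if scores.augmented is not None else np.nan,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_scores(path) -> ScoreSet:
    df = pd.read_csv(path, float_precision="round_trip")
    augmented = df["augmented"].to_numpy(dtype=float)
    return ScoreSet(
        sample_ids=df["sample_id"].astype(str).tolist(),
        pgs=df["pgs"].to_numpy(dtype=float),
        augmented=None if np.isnan(augmented).all() else augmented,
    )
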