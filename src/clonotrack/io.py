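"""Readers and writers for the pipeline's plain-text exchange formats.

AIRR-style clonotype TSV, Matrix Market expression with companion
cells/genes TSVs, spatial cell CSV, survival CSV, and the truth JSON of a
synthetic cohort.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

AIRR_COLUMNS = (
    "cell_id", "sample_id", "patient_id", "timepoint",
    "locus", "v_call", "junction", "junction_aa", "duplicate_count",
)


def write_airr(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in AIRR_COLUMNS if c in records.columns]
    records[cols].to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"junction": str, "junction_aa": str})


def write_expression_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """matrix.mtx (cells x genes) + cells.tsv + genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(outdir / "matrix.mtx", X.astype(np.int64))
    adata.obs.reset_index(names="cell_id").to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": adata.var_names}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )


def read_expression_mtx(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(scio.mmread(indir / "matrix.mtx"))
    cells = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell_id")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    return ad.AnnData(X=X, obs=cells, var=pd.DataFrame(index=genes["gene"]))


def write_spatial_csv(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_spatial_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_survival_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_cohort(cohort, outdir: str | Path) -> None:
    """Serialize every generated arm of a synthetic cohort to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort.clonotypes is not None:
        write_airr(cohort.clonotypes, outdir / "clonotypes.tsv")
    if cohort.expression is not None:
        write_expression_mtx(cohort.expression, outdir / "expression")
    if cohort.survival is not None:
        write_survival_csv(cohort.survival, outdir / "survival.csv")
    for smp in cohort.spatial_samples:
        write_spatial_csv(smp.cells, outdir / f"spatial_{smp.sample_id}.csv")
    write_truth_json(cohort.truth, outdir / "truth.json")
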