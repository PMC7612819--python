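"""Readers and writers for the standard on-disk formats.

Cell tables travel as Matrix Market sparse counts plus barcode/feature
TSVs and an obs CSV; repertoires as AIRR Rearrangement TSV; spatial
abundances as a spot CSV with coordinates and one column per cell type;
ground truth and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

__all__ = [
    "write_cell_table",
    "read_cell_table",
    "write_airr",
    "read_airr",
    "write_spatial",
    "read_spatial",
    "write_json",
]

AIRR_COLUMNS = [
    "cell_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_length",
    "np1_length",
    "np2_length",
    "productive",
]


def write_cell_table(adata: ad.AnnData, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(out / "matrix.mtx", X.T.tocoo())  # genes × cells, convention
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(out / "obs.csv")
    if "X_emb" in adata.obsm:
        pd.DataFrame(adata.obsm["X_emb"], index=adata.obs_names).to_csv(out / "embedding.csv")


def read_cell_table(indir: str | Path) -> ad.AnnData:
    p = Path(indir)
    X = sparse.csr_matrix(scio.mmread(p / "matrix.mtx").T)
    barcodes = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(p / "features.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(p / "obs.csv", index_col=0)
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs.loc[barcodes], var=pd.DataFrame(index=features))
    emb_path = p / "embedding.csv"
    if emb_path.exists():
        adata.obsm["X_emb"] = pd.read_csv(emb_path, index_col=0).to_numpy()
    return adata


def write_airr(chains: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in AIRR_COLUMNS if c in chains.columns]
    extra = [c for c in chains.columns if c not in cols]
    chains[cols + extra].to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("cell_id", "locus", "v_call", "j_call") if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR table missing required columns: {missing}")
    return df


def write_spatial(abundance: pd.DataFrame, coords: pd.DataFrame, path: str | Path) -> None:
    pd.concat([coords, abundance], axis=1).to_csv(path, index_label="spot_id")


def read_spatial(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, index_col="spot_id")
    coord_cols = ["x", "y", "slide_id"]
    coords = df[coord_cols]
    abundance = df.drop(columns=coord_cols)
    return abundance, coords


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))
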