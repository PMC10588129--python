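"""On-disk formats: MTX + TSV single-cell layout, bulk and table TSVs, YAML config.

All tabular writers emit deterministic bytes for fixed inputs: tab-separated
UTF-8 with a header row, '.' decimal, floats at 6 significant digits, rows in
input order. Sparse counts use MatrixMarket coordinate integer format. The
single-cell layout is the 10x-style triplet (matrix.mtx, features.tsv,
barcodes.tsv) plus a cells.tsv carrying the per-cell annotations; gzipped
triplet directories are read transparently.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .errors import AnnotationError, FormatError
from .simulate import AssignmentTable, BulkSample

__all__ = [
    "write_single_cell",
    "read_single_cell",
    "write_bulk",
    "read_bulk",
    "write_assignment_table",
    "read_assignment_table",
    "write_table",
    "load_config",
    "write_provenance",
]

FLOAT_FMT = "%.6g"


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return FLOAT_FMT % x
    return str(x)


def write_table(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    """Deterministic TSV writer (6-significant-digit floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if index:
        out = out.reset_index()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_single_cell(adata: ad.AnnData, outdir: Path) -> None:
    """Write the MTX + features/barcodes/cells TSV layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(np.asarray(adata.X))
    sio.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(X.T), field="integer")
    (outdir / "features.tsv").write_text(
        "".join(f"{g}\n" for g in adata.var_names), encoding="utf-8"
    )
    (outdir / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in adata.obs_names), encoding="utf-8"
    )
    cells = pd.DataFrame({
        "barcode": adata.obs_names,
        "sample_id": adata.obs["sample_id"].astype(str).to_numpy(),
        "cell_type": adata.obs["cell_type"].astype(str).to_numpy(),
    })
    write_table(cells, outdir / "cells.tsv")


def _read_lines(path: Path) -> list[str]:
    if path.suffix == ".gz":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return [ln.rstrip("\n") for ln in fh if ln.strip()]
    return [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]


def _find(outdir: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = outdir / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {outdir}")


def read_single_cell(indir: Path) -> ad.AnnData:
    """Read the MTX + TSV layout (plain or gzipped triplet) back to AnnData.

    Round-trips bit-exactly with :func:`write_single_cell`. Every barcode
    must appear in cells.tsv; first column of features.tsv is the gene id.
    """
    indir = Path(indir)
    mtx = _find(indir, "matrix.mtx")
    if mtx.suffix == ".gz":
        with gzip.open(mtx, "rb") as fh:
            M = sio.mmread(fh)
    else:
        M = sio.mmread(mtx)
    M = sp.csr_matrix(M.T)
    if not np.issubdtype(M.dtype, np.integer):
        if np.any(M.data != np.round(M.data)):
            raise FormatError("matrix.mtx contains non-integer entries")
        M = M.astype(np.int64)

    genes = [ln.split("\t")[0] for ln in _read_lines(_find(indir, "features.tsv"))]
    barcodes = [ln.split("\t")[0] for ln in _read_lines(_find(indir, "barcodes.tsv"))]
    if M.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"matrix shape {M.shape} does not match {len(barcodes)} barcodes x {len(genes)} genes"
        )
    cells_path = _find(indir, "cells.tsv")
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    cells = cells.set_index("barcode")
    missing = pd.Index(barcodes).difference(cells.index)
    if len(missing):
        raise AnnotationError(f"cells.tsv missing barcode {missing[0]!r} "
                              f"({len(missing)} total)")
    cells = cells.loc[barcodes]
    obs = pd.DataFrame({
        "cell_type": pd.Categorical(cells["cell_type"]),
        "sample_id": pd.Categorical(cells["sample_id"]),
    }, index=pd.Index(barcodes, name="barcode"))
    obs["library_size"] = np.asarray(M.sum(axis=1)).ravel().astype(np.int64)
    return ad.AnnData(X=M, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def write_bulk(samples: list[BulkSample], outdir: Path, stem: str = "bulk") -> None:
    """Gene x sample counts TSV plus a sidecar protocol-metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = pd.DataFrame(
        {f"{s.sample_id}:{s.protocol}": s.counts for s in samples}
    )
    counts.index.name = "gene"
    write_table(counts, outdir / f"{stem}_counts.tsv", index=True)
    meta = pd.DataFrame([
        {
            "column": f"{s.sample_id}:{s.protocol}",
            "sample_id": s.sample_id,
            "protocol": s.protocol,
            "dissociated": s.effects.dissociated,
            "enrichment": s.effects.enrichment,
        }
        for s in samples
    ])
    write_table(meta, outdir / f"{stem}_protocols.tsv")
    truth = pd.DataFrame(
        {f"{s.sample_id}:{s.protocol}": s.true_composition for s in samples}
    ).T
    truth.index.name = "column"
    write_table(truth, outdir / f"{stem}_truth.tsv", index=True)


def read_bulk(path: Path) -> pd.DataFrame:
    """Gene x sample counts TSV -> DataFrame indexed by gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError("bulk counts contain negative entries")
    return df


def write_assignment_table(table: AssignmentTable, path: Path) -> None:
    out = table.posteriors.copy()
    out.insert(0, "barcode", out.index)
    out["true_sample"] = table.true_sample.loc[table.posteriors.index].to_numpy()
    write_table(out, path)


def read_assignment_table(path: Path, modality: str) -> AssignmentTable:
    df = pd.read_csv(path, sep="\t").set_index("barcode")
    true = df.pop("true_sample")
    return AssignmentTable(posteriors=df, modality=modality, true_sample=true)


def load_config(path: Path) -> dict:
    """Parse a YAML run configuration into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a YAML mapping")
    return cfg


def write_provenance(path: Path, payload: dict) -> None:
    """Sorted-key JSON provenance record."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")
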