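"""Readers and writers for spot-level expression tables and results.

Accepted expression layouts:

* ``genes_by_spots`` — wide TSV/CSV, genes in rows, first column gene ids,
  header row of spot ids (the common convention for published SVG tables);
* ``spots_by_genes`` — the transposed dialect;
* ``long`` — triplet table with columns gene, spot, value;
* ``mtx`` — MatrixMarket sparse triplet (genes x spots) with gene ids in an
  optional sidecar text file (one id per line).

The coordinates table has a spot-id column plus ``x``, ``y`` and optionally
``z`` (case-insensitive); presence of ``z`` makes the dataset 3D. Spots
present in only one of the two files are dropped with a logged count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io

from .core import SpatialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_results",
    "write_replicate",
    "read_replicate",
    "write_manifest",
]

LAYOUTS = ("genes_by_spots", "spots_by_genes", "long", "mtx")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_coords(coords_path: Path) -> pd.DataFrame:
    df = pd.read_csv(coords_path, sep=_sep_for(coords_path))
    lower = {c.lower(): c for c in df.columns}
    if "x" not in lower or "y" not in lower:
        raise ValueError("coordinates table must have x and y columns")
    axes = [lower["x"], lower["y"]] + ([lower["z"]] if "z" in lower else [])
    id_cols = [c for c in df.columns if c not in axes]
    if id_cols:
        spot_ids = df[id_cols[0]].astype(str).to_numpy()
    else:
        spot_ids = np.array([f"spot_{i}" for i in range(len(df))])
    coords = df[axes].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-numeric or missing coordinate values")
    out = pd.DataFrame(coords, columns=[a.lower() for a in axes])
    out.insert(0, "spot_id", spot_ids)
    return out


def read_dataset(
    expr_path,
    coords_path,
    layout: str = "genes_by_spots",
    genes_path=None,
) -> SpatialDataset:
    """Load and align an expression matrix with a coordinates table."""
    expr_path, coords_path = Path(expr_path), Path(coords_path)
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}")
    coords = _read_coords(coords_path)

    if layout in ("genes_by_spots", "spots_by_genes"):
        wide = pd.read_csv(expr_path, sep=_sep_for(expr_path), index_col=0)
        if layout == "spots_by_genes":
            wide = wide.T
        gene_ids = wide.index.astype(str)
        spot_ids = wide.columns.astype(str)
        matrix = wide.to_numpy(dtype=float).T  # -> spots x genes
    elif layout == "long":
        long = pd.read_csv(expr_path, sep=_sep_for(expr_path))
        gcol, scol, vcol = long.columns[:3]
        wide = long.pivot_table(index=scol, columns=gcol, values=vcol, fill_value=0.0)
        gene_ids = wide.columns.astype(str)
        spot_ids = wide.index.astype(str)
        matrix = wide.to_numpy(dtype=float)
    else:  # mtx: genes x spots triplet
        mat = scipy_io.mmread(str(expr_path)).toarray().astype(float)
        if genes_path is not None:
            gene_ids = pd.Index(Path(genes_path).read_text().split())
        else:
            gene_ids = pd.Index([f"gene_{j}" for j in range(mat.shape[0])])
        if mat.shape[1] != len(coords):
            raise ValueError(
                f"MTX has {mat.shape[1]} spot columns but coords table has {len(coords)} rows"
            )
        spot_ids = pd.Index(coords["spot_id"].astype(str))
        matrix = mat.T

    gene_ids = pd.Index(gene_ids)
    if gene_ids.duplicated().any():
        dup = gene_ids[gene_ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup[:5]}")

    spot_ids = pd.Index(spot_ids)
    coord_ids = pd.Index(coords["spot_id"].astype(str))
    common = spot_ids.intersection(coord_ids)
    if len(common) == 0:
        raise ValueError("no spot ids shared between expression and coordinates")
    dropped = (len(spot_ids) - len(common)) + (len(coord_ids) - len(common))
    if dropped:
        logger.warning("dropping %d spot(s) present in only one file", dropped)
    # preserve the expression file's spot order
    keep = [s for s in spot_ids if s in set(common)]
    expr_df = pd.DataFrame(matrix, index=spot_ids).loc[keep]
    coords_df = coords.set_index(coords["spot_id"].astype(str)).loc[keep]
    axis_cols = [c for c in ("x", "y", "z") if c in coords_df.columns]
    return SpatialDataset(
        coords=coords_df[axis_cols].to_numpy(dtype=float),
        expr=expr_df.to_numpy(dtype=float),
        gene_ids=np.asarray(gene_ids, dtype=object),
        spot_ids=np.asarray(keep, dtype=object),
    )


def write_dataset(dataset: SpatialDataset, expr_path, coords_path) -> None:
    """Write a dataset as a genes-by-spots wide TSV plus a coords TSV."""
    expr_path, coords_path = Path(expr_path), Path(coords_path)
    wide = pd.DataFrame(
        dataset.expr.T, index=dataset.gene_ids, columns=dataset.spot_ids
    )
    wide.index.name = "gene_id"
    wide.to_csv(expr_path, sep=_sep_for(expr_path))
    axes = ["x", "y", "z"][: dataset.ndim]
    coords = pd.DataFrame(dataset.coords, columns=axes)
    coords.insert(0, "spot_id", dataset.spot_ids)
    coords.to_csv(coords_path, sep=_sep_for(coords_path), index=False)


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


def write_replicate(replicate, outdir) -> dict:
    """Write a simulated replicate as the coords/expression/truth TSV trio."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coords": outdir / "coords.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_dataset(replicate.dataset, paths["expression"], paths["coords"])
    replicate.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_replicate(outdir):
    """Read back a replicate trio written by :func:`write_replicate`."""
    from .sim2d import SimulatedReplicate

    outdir = Path(outdir)
    dataset = read_dataset(outdir / "expression.tsv", outdir / "coords.tsv")
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
    return SimulatedReplicate(
        dataset=dataset,
        truth=truth,
        marked_mask=np.zeros(dataset.n_spots, dtype=bool),
    )


def write_manifest(path, **fields) -> None:
    """Write a run manifest (inputs, config echo, stage counts) as JSON text."""
    from . import __version__

    manifest = {"software": "bsp-spatial", "version": __version__, **fields}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
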