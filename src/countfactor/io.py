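"""Readers and writers for counts, fits and score tables.

Counts are exchanged as 10x-style MatrixMarket triplets (``matrix.mtx`` with
companion ``features.tsv``/``barcodes.tsv``, genes on rows) or as a dense
delimited genes x cells table with header row and index column.  Fits are
persisted as a versioned ``.npz`` container of named arrays plus a JSON
metadata entry.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .model_core import CountMatrix, GBMFit

logger = logging.getLogger(__name__)

FIT_SCHEMA_VERSION = 1
_FIT_ARRAYS = ("alpha", "beta", "U", "sigma", "V", "trace")


def read_counts(path, genes=None, barcodes=None) -> CountMatrix:
    """Read a CountMatrix from ``.mtx`` (+ id files) or a delimited table.

    For MatrixMarket input, identifier files default to ``features.tsv`` /
    ``genes.tsv`` and ``barcodes.tsv`` next to the matrix; missing files
    yield generated identifiers.  Orientation is genes x cells unless the
    identifier file lengths disambiguate a transposed matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        return _read_mtx(path, genes, barcodes)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        sp.csr_matrix(_validated(df.to_numpy())),
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
    )


def _validated(arr: np.ndarray) -> np.ndarray:
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative entry at row {i}, column {j}")
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(f"non-integer entry at row {i}, column {j}")
    return np.round(arr).astype(np.int64)


def _read_ids(path: Path) -> list[str] | None:
    if path is None or not Path(path).exists():
        return None
    # first column of a headerless TSV (10x style: id, name, ...)
    return pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()


def _read_mtx(path: Path, genes, barcodes) -> CountMatrix:
    mat = scipy.io.mmread(path)  # mmread maps 1-based file indices to 0-based
    mat = sp.csr_matrix(mat)  # entry validation happens in CountMatrix
    gene_ids = _read_ids(Path(genes) if genes else _sibling(path, "features.tsv", "genes.tsv"))
    cell_ids = _read_ids(Path(barcodes) if barcodes else _sibling(path, "barcodes.tsv"))
    I, J = mat.shape
    if gene_ids and cell_ids and len(gene_ids) == J and len(cell_ids) == I and I != J:
        logger.info("matrix appears transposed (cells x genes); transposing")
        mat = mat.T.tocsr()
        I, J = mat.shape
    if gene_ids is None:
        logger.info("no feature file found; generating gene identifiers")
        gene_ids = [f"gene{i}" for i in range(I)]
    if cell_ids is None:
        logger.info("no barcode file found; generating cell identifiers")
        cell_ids = [f"cell{j}" for j in range(J)]
    return CountMatrix(mat, gene_ids, cell_ids)


def _sibling(path: Path, *names: str) -> Path | None:
    for n in names:
        cand = path.parent / n
        if cand.exists():
            return cand
    return None


def write_counts(Y: CountMatrix, out_dir) -> Path:
    """Write matrix.mtx + features.tsv + barcodes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", Y.values.tocoo(), field="integer")
    (out / "features.tsv").write_text("\n".join(Y.gene_ids) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(Y.cell_ids) + "\n")
    return out / "matrix.mtx"


def write_fit(path, fit: GBMFit) -> Path:
    """Persist a fit losslessly to a versioned .npz container."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = {
        "schema_version": FIT_SCHEMA_VERSION,
        "tau": fit.tau,
        "converged": bool(fit.converged),
        "orthonormal_V": bool(fit.orthonormal_V),
        "meta": fit.meta,
    }
    np.savez(
        path,
        alpha=fit.alpha, beta=fit.beta, U=fit.U, sigma=fit.sigma, V=fit.V,
        trace=np.asarray(fit.trace, dtype=float),
        meta_json=np.array(json.dumps(meta)),
    )
    return path


def read_fit(path) -> GBMFit:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        missing = [k for k in (*_FIT_ARRAYS, "meta_json") if k not in z]
        if missing:
            raise ValueError(f"fit file {path} is missing fields: {missing}")
        meta = json.loads(str(z["meta_json"]))
        if meta.get("schema_version") != FIT_SCHEMA_VERSION:
            raise ValueError(
                f"fit schema version {meta.get('schema_version')} != "
                f"{FIT_SCHEMA_VERSION}"
            )
        fit = GBMFit(
            z["alpha"], z["beta"], z["U"], z["sigma"], z["V"],
            tau=float(meta["tau"]),
            converged=meta["converged"],
            orthonormal_V=meta["orthonormal_V"],
            meta=meta["meta"],
        )
        fit.trace = z["trace"].tolist()
    return fit


def write_scores(path, fit: GBMFit, cell_ids=None) -> Path:
    """Export cell scores V as a delimited table with identifiers."""
    path = Path(path)
    ids = cell_ids or [f"cell{j}" for j in range(fit.V.shape[0])]
    df = pd.DataFrame(fit.V, index=ids,
                      columns=[f"factor{m+1}" for m in range(fit.M)])
    df.to_csv(path, sep="\t")
    return path


def write_loadings(path, fit: GBMFit, gene_ids=None) -> Path:
    path = Path(path)
    ids = gene_ids or [f"gene{i}" for i in range(fit.U.shape[0])]
    df = pd.DataFrame(fit.U, index=ids,
                      columns=[f"factor{m+1}" for m in range(fit.M)])
    df.to_csv(path, sep="\t")
    return path
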