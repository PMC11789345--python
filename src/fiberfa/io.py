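"""Readers and writers for the on-disk formats the pipeline touches.

On disk the count matrix follows the common single-cell convention:
Matrix Market triplet, genes x cells, with ``features.tsv`` and
``barcodes.tsv`` carrying the axis labels and ``meta.tsv`` carrying the
per-cell condition label.  Internally the matrix is cells x genes
(row per observation).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix", "RunReport", "FormatError",
    "read_mtx_triplet", "write_mtx_triplet", "read_gaf", "write_report",
]


class FormatError(ValueError):
    """Malformed input file."""


def default_mito_mask(genes: list[str]) -> np.ndarray:
    """Mouse-convention mitochondrial flag: case-insensitive ``mt-`` prefix."""
    return np.array([g.lower().startswith("mt-") for g in genes], dtype=bool)


@dataclass
class CountMatrix:
    """Integer gene-by-cell counts with identifiers and per-cell condition."""

    cells: list[str]
    genes: list[str]
    counts: np.ndarray  # (n_cells, n_genes) non-negative integers
    condition: list[str] | None = None
    mito_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes")
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts contain negative entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if self.counts.size and not np.all(self.counts == np.floor(self.counts)):
                raise FormatError("counts contain non-integer values")
            self.counts = self.counts.astype(np.int64)
        for name, ids in (("cell", self.cells), ("gene", self.genes)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()][0]
                raise FormatError(f"duplicate {name} id: {dup!r}")
        if self.condition is not None and len(self.condition) != len(self.cells):
            raise FormatError("condition length does not match cell axis")
        if self.mito_mask is None:
            self.mito_mask = default_mito_mask(self.genes)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if self.mito_mask.shape != (len(self.genes),):
            raise FormatError("mito_mask length does not match gene axis")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def mito_fraction(self) -> np.ndarray:
        tot = self.totals().astype(float)
        mito = self.counts[:, self.mito_mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / tot, 0.0)
        return frac

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            cells=[self.cells[i] for i in keep],
            genes=list(self.genes),
            counts=self.counts[keep],
            condition=([self.condition[i] for i in keep]
                       if self.condition is not None else None),
            mito_mask=self.mito_mask.copy(),
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (self.cells == other.cells and self.genes == other.genes
                and np.array_equal(self.counts, other.counts)
                and self.condition == other.condition
                and np.array_equal(self.mito_mask, other.mito_mask))


def _read_id_column(path: Path, what: str) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate ids in {what} file {path}")
    return ids


def read_mtx_triplet(mtx_path, features_path, barcodes_path,
                     meta_path=None) -> CountMatrix:
    """Read a genes x cells MTX bundle into the internal cells x genes model.

    1-based triplet indices become 0-based positions; a ``meta.tsv`` with
    columns ``cell`` and ``condition`` attaches the condition labels.
    """
    mat = scipy.io.mmread(str(mtx_path))
    mat = scipy.sparse.coo_matrix(mat)
    genes = _read_id_column(Path(features_path), "features")
    cells = _read_id_column(Path(barcodes_path), "barcodes")
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX header declares {mat.shape[0]} genes x {mat.shape[1]} cells "
            f"but features/barcodes list {len(genes)}/{len(cells)} entries")
    data = mat.data
    if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
        bad = int(np.flatnonzero((data < 0) | (data != np.floor(data)))[0])
        raise FormatError(
            f"non-count value {data[bad]} at gene {genes[mat.row[bad]]!r}, "
            f"cell {cells[mat.col[bad]]!r}")
    counts = np.asarray(mat.T.todense()).astype(np.int64)

    condition = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if not {"cell", "condition"} <= set(meta.columns):
            raise FormatError("meta.tsv must have 'cell' and 'condition' columns")
        lookup = meta.set_index("cell")["condition"]
        missing = [c for c in cells if c not in lookup.index]
        if missing:
            raise FormatError(f"meta.tsv missing condition for cell {missing[0]!r}")
        condition = [lookup[c] for c in cells]
    return CountMatrix(cells=cells, genes=genes, counts=counts,
                       condition=condition)


def write_mtx_triplet(cm: CountMatrix, out_dir, truth: pd.DataFrame | None = None
                      ) -> dict[str, Path]:
    """Write matrix.mtx (genes x cells), features/barcodes/meta TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "meta": out / "meta.tsv",
    }
    sparse = scipy.sparse.coo_matrix(cm.counts.T)
    scipy.io.mmwrite(str(paths["matrix"]), sparse, field="integer")
    paths["features"].write_text("".join(f"{g}\n" for g in cm.genes))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in cm.cells))
    meta = pd.DataFrame({
        "cell": cm.cells,
        "condition": cm.condition if cm.condition is not None
        else ["NA"] * cm.n_cells,
    })
    meta.to_csv(paths["meta"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_gaf(path) -> dict[str, set[str]]:
    """Parse GO annotations from GAF 2.x or a two-column gene/GO TSV.

    GAF carries the gene symbol in column 3 and the GO id in column 5;
    comment lines starting with ``!`` are skipped and duplicate
    (gene, term) pairs collapse into the set.
    """
    table: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x data row
                gene, term = fields[2], fields[4]
            elif len(fields) == 2:
                gene, term = fields
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 (TSV) or >=15 (GAF) columns, "
                    f"got {len(fields)}")
            if not gene or not term:
                raise FormatError(f"{path}:{lineno}: empty gene or term field")
            table.setdefault(gene, set()).add(term)
            n_rows += 1
    if n_rows == 0:
        logger.warning("GO annotation file %s contains no data rows", path)
    return table


@dataclass
class RunReport:
    """Machine-readable audit trail of one pipeline run."""

    seed: int
    config: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    stage_tallies: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    design_choices: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        from . import __version__
        return {
            "seed": self.seed,
            "config": self.config,
            "thresholds": self.thresholds,
            "stage_tallies": self.stage_tallies,
            "stage_seeds": self.stage_seeds,
            "design_choices": self.design_choices,
            "version": self.version or __version__,
        }


_REPORT_FILES = ("loadings.tsv", "scores.tsv", "classes.tsv", "clusters.tsv",
                 "sigups.tsv", "proportions.tsv", "report.json")


def write_report(results: dict, out_dir) -> dict[str, Path]:
    """Write the pipeline's tabular outputs plus report.json.

    ``results`` maps table names (stem of the files above) to DataFrames,
    and ``"report"`` to a :class:`RunReport`.  Returns the file manifest;
    rerunning with identical inputs yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for fname in _REPORT_FILES:
        stem = fname.split(".")[0]
        path = out / fname
        if fname == "report.json":
            report = results.get("report")
            payload = report.to_dict() if isinstance(report, RunReport) else (report or {})
            path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                       default=str) + "\n")
        else:
            df = results.get(stem)
            if df is None:
                df = pd.DataFrame()
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest[stem] = path
    return manifest


def file_checksums(paths: dict[str, Path]) -> dict[str, str]:
    return {k: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for k, p in paths.items()}
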