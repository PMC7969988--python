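"""Domain types and on-disk formats shared by every pipeline stage.

Expression matrices are stored cell×gene internally; file orientation is
normalized at read time using the lengths of the companion feature and
barcode files.  Gene identifiers are opaque strings matched across
datasets by exact equality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["gene", "subgroup", "log2fc", "p", "p_adj", "pct_in", "pct_out"]


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw cell×gene non-negative integer counts.

    Attributes
    ----------
    values
        Dense ``(n_cells, n_genes)`` array of non-negative integers.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns respectively.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene ids are not unique")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded, atol=1e-9):
                raise ValidationError("count matrix contains non-integer entries")
            self.values = rounded.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class NormMatrix:
    """Cell×gene log-normalized expression: ``ln(1 + count * sf / depth)``.

    Zero counts map to exactly 0 and all entries are non-negative; the
    same id contract as :class:`CountMatrix` applies.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("normalized matrix must be 2-dimensional")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("normalized matrix dimensions do not match id lists")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("normalized matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def expm1(self) -> np.ndarray:
        """Depth-normalized (pre-log) expression, ``exp(norm) - 1``."""
        return np.expm1(self.values)


@dataclass
class ClusterLabeling:
    """Assignment of cells to subgroup labels."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValidationError("empty cluster labeling")
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}

    @property
    def labels(self) -> list[str]:
        """Sorted list of distinct subgroup labels."""
        return sorted(set(self.assignments.values()))

    def cells_of(self, label: str) -> list[str]:
        return [c for c, l in self.assignments.items() if l == label]

    def mask_for(self, label: str, cell_ids: list[str]) -> np.ndarray:
        """Boolean mask over ``cell_ids`` selecting cells of ``label``."""
        return np.array([self.assignments.get(c) == label for c in cell_ids])

    def vector_for(self, cell_ids: list[str]) -> np.ndarray:
        """Label per cell in ``cell_ids`` order; raises if any is unlabeled."""
        missing = [c for c in cell_ids if c not in self.assignments]
        if missing:
            raise ValidationError(
                f"{len(missing)} cells have no label (first: {missing[0]!r})"
            )
        return np.array([self.assignments[c] for c in cell_ids])

    def unmatched_cells(self, cell_ids: list[str]) -> tuple[set[str], set[str]]:
        """Set difference both ways between labeled cells and ``cell_ids``."""
        matrix = set(cell_ids)
        labeled = set(self.assignments)
        return labeled - matrix, matrix - labeled


@dataclass
class MarkerTable:
    """Per-subgroup enriched genes with enrichment and adjusted p-values.

    Wraps a DataFrame with columns (gene, subgroup, log2fc, p, p_adj,
    pct_in, pct_out).  Rows of a threshold-filtered table satisfy
    ``log2fc > 0.25`` and ``p_adj < 0.01`` (the retention defaults).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"marker table missing columns: {missing}")
        self.df = self.df[MARKER_COLUMNS].reset_index(drop=True)
        for col in ("pct_in", "pct_out"):
            vals = self.df[col].to_numpy(dtype=float)
            if len(vals) and (vals.min() < 0 or vals.max() > 1):
                raise ValidationError(f"{col} outside [0, 1]")
        if len(self.df) and not np.all(np.isfinite(self.df["log2fc"].to_numpy(float))):
            raise ValidationError("non-finite log2fc in marker table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subgroups(self) -> list[str]:
        return sorted(self.df["subgroup"].unique())

    def genes_of(self, subgroup: str) -> set[str]:
        return set(self.df.loc[self.df["subgroup"] == subgroup, "gene"])

    def log2fc_of(self, subgroup: str) -> dict[str, float]:
        sub = self.df[self.df["subgroup"] == subgroup]
        return dict(zip(sub["gene"], sub["log2fc"].astype(float)))

    def drop_subgroup(self, subgroup: str) -> "MarkerTable":
        """Remove one subgroup's markers before a comparison."""
        return MarkerTable(self.df[self.df["subgroup"] != subgroup].copy())


@dataclass
class RegulonSet:
    """Transcription-factor name → set of target gene ids."""

    regulons: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, targets in self.regulons.items():
            if not targets:
                raise ValidationError(f"regulon {name!r} has an empty target set")
            self.regulons[name] = set(targets)

    @property
    def names(self) -> list[str]:
        return sorted(self.regulons)

    def __len__(self) -> int:
        return len(self.regulons)

    def __getitem__(self, name: str) -> set[str]:
        return self.regulons[name]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_id_file(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                # 10x-style features files may carry extra tab-separated
                # columns; the first one is the identifier.
                ids.append(line.split("\t")[0])
    return ids


def read_counts(
    path: str | Path,
    features: str | Path | None = None,
    barcodes: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from matrix-market triplet or dense TSV.

    Matrix-market files require companion one-column text files naming
    genes (``features``) and cells (``barcodes``); orientation is
    auto-detected from their lengths and normalized to cell×gene.  A
    dense TSV has a header row of gene names and a first column of cell
    ids.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if features is None or barcodes is None:
            features = features or path.with_name("features.tsv")
            barcodes = barcodes or path.with_name("barcodes.tsv")
        gene_ids = _read_id_file(Path(features))
        cell_ids = _read_id_file(Path(barcodes))
        mat = scipy.io.mmread(path)
        mat = scipy.sparse.coo_matrix(mat).toarray()
        n_rows, n_cols = mat.shape
        if n_rows == len(cell_ids) and n_cols == len(gene_ids):
            values = mat
        elif n_rows == len(gene_ids) and n_cols == len(cell_ids):
            values = mat.T
        else:
            for name, n, fname in (
                ("features", len(gene_ids), features),
                ("barcodes", len(cell_ids), barcodes),
            ):
                if n not in mat.shape:
                    raise FormatError(
                        f"matrix dimensions {mat.shape} do not match the "
                        f"{n} ids in {name} file {fname}"
                    )
            raise FormatError(
                f"matrix dimensions {mat.shape} are ambiguous or inconsistent "
                f"with companion files {features}, {barcodes}"
            )
        try:
            return CountMatrix(values, cell_ids, gene_ids)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    # dense TSV
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.shape[1] == 0:
        raise FormatError(f"{path}: empty or headerless TSV")
    try:
        return CountMatrix(
            df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix; ``.mtx`` writes a gene×cell triplet with
    ``features.tsv``/``barcodes.tsv`` companions, anything else a dense
    TSV (cells as rows)."""
    path = Path(path)
    if path.suffix == ".mtx":
        sparse = scipy.sparse.coo_matrix(cm.values.T)  # gene×cell, 10x convention
        scipy.io.mmwrite(str(path), sparse, field="integer")
        path.with_name("features.tsv").write_text("\n".join(cm.gene_ids) + "\n")
        path.with_name("barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")
    else:
        pd.DataFrame(cm.values, index=cm.cell_ids, columns=cm.gene_ids).to_csv(
            path, sep="\t"
        )


def read_labels(path: str | Path) -> ClusterLabeling:
    """Read a two-column (cell_id, label) TSV into a labeling."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty label file")
    # tolerate a header row
    if df.iloc[0, 0] in ("cell_id", "cell", "barcode"):
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{path}: no label rows")
    dupes = df["cell_id"][df["cell_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate cell id(s): {list(dupes[:5])}")
    return ClusterLabeling(dict(zip(df["cell_id"], df["label"])))


def write_labels(labeling: ClusterLabeling, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cell, label in labeling.assignments.items():
            fh.write(f"{cell}\t{label}\n")


def read_gmt(path: str | Path) -> RegulonSet:
    """Read gene sets in GMT format (name, description, tab-separated genes)."""
    regulons: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            unique = set(genes)
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in regulon {name!r} de-duplicated"
                )
            if name in regulons:
                raise FormatError(f"{path}:{lineno}: duplicate regulon name {name!r}")
            regulons[name] = unique
    return RegulonSet(regulons)


def write_gmt(rs: RegulonSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in rs.names:
            fh.write("\t".join([name, "NA"] + sorted(rs[name])) + "\n")


def write_marker_table(mt: MarkerTable, path: str | Path) -> None:
    """Write markers as TSV with fixed column order and >=6 significant digits."""
    df = mt.df[MARKER_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_marker_table(path: str | Path) -> MarkerTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "subgroup": str})
    return MarkerTable(df)
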