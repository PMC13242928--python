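"""Reading, validation and persistence of the package's domain types.

Conventions
-----------
* Expression tables are cells-as-rows by default; orientation is never
  guessed silently — pass ``cells_as_rows=False`` to transpose.
* BED region intervals are 0-based half-open.  TSS tables carry 1-based
  positions (the usual convention for single-coordinate annotation tables)
  and are converted to 0-based internally.
* Inferred-network tensors are persisted twice: a compressed ``.npz``
  archive (exact round trip) and a long-format TSV edge table (one row per
  cell and unordered gene pair) for downstream tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SpatialCoordinates",
    "AccessibilityInputs",
    "GRNTensor",
    "read_expression",
    "read_spatial_coordinates",
    "read_accessibility",
    "write_grn_tensor",
    "read_grn_tensor",
    "normalize_log1p",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_unique(names: list[str], what: str) -> None:
    seen = set()
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate {what} name: {name!r}")
        seen.add(name)


@dataclass
class ExpressionMatrix:
    """Observed cells × genes expression, the data the copula model is fit to.

    Zeros are meaningful (dropout); entries must be finite and, for real
    expression data, non-negative.  ``check_nonnegative=False`` exists only
    for synthetic latent-Gaussian draws used in calibration tests.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    check_nonnegative: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        self.gene_names = [str(x) for x in self.gene_names]
        self.cell_ids = [str(x) for x in self.cell_ids]
        _check_unique(self.gene_names, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.check_nonnegative and (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_names[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class SpatialCoordinates:
    """Per-cell spatial locations (2-D or 3-D), aligned with an expression matrix."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coordinates must be n_cells × 2 or n_cells × 3")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match coordinate rows")
        self.cell_ids = [str(x) for x in self.cell_ids]
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class AccessibilityInputs:
    """Chromatin-accessibility inputs for prior-network construction.

    ``region_matrix`` is a binary cells × regions matrix (1 = accessible),
    ``region_coords`` a (chrom, start, end) table with 0-based half-open
    intervals, ``tss_table`` one row per gene (chrom, tss, strand) with
    0-based TSS positions, and ``motif_hits`` a set of
    (region_index, tf_gene_name) pairs from an external motif scan.
    """

    region_matrix: np.ndarray
    region_coords: pd.DataFrame
    tss_table: pd.DataFrame
    motif_hits: set[tuple[int, str]]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.region_matrix = np.asarray(self.region_matrix)
        if self.region_matrix.ndim != 2:
            raise ValueError("region matrix must be 2-D (cells × regions)")
        uniq = np.unique(self.region_matrix)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("region matrix must be binary (0/1)")
        self.region_matrix = self.region_matrix.astype(np.uint8)
        if len(self.region_coords) != self.region_matrix.shape[1]:
            raise ValueError(
                f"region count mismatch: matrix has {self.region_matrix.shape[1]} "
                f"columns but BED table has {len(self.region_coords)} rows"
            )
        bad = self.region_coords["start"] >= self.region_coords["end"]
        if bad.any():
            row = self.region_coords[bad].iloc[0]
            raise ValueError(
                f"region with start >= end: {row['chrom']}:{row['start']}-{row['end']}"
            )
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.region_matrix.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.region_matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.region_matrix.shape[1]


_TENSOR_KINDS = ("precision", "partial_correlation")


@dataclass
class GRNTensor:
    """Per-cell networks: precision matrices Θ or partial correlations G."""

    networks: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    kind: str = "precision"

    def __post_init__(self) -> None:
        self.networks = np.asarray(self.networks, dtype=float)
        if self.networks.ndim != 3 or self.networks.shape[1] != self.networks.shape[2]:
            raise ValueError("networks must be an n_cells × g × g array")
        n, g, _ = self.networks.shape
        if len(self.gene_names) != g or len(self.cell_ids) != n:
            raise ValueError("gene_names / cell_ids do not match tensor shape")
        _check_unique(self.gene_names, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.kind not in _TENSOR_KINDS:
            raise ValueError(f"kind must be one of {_TENSOR_KINDS}")
        asym = np.abs(self.networks - self.networks.transpose(0, 2, 1)).max()
        if asym > 1e-8:
            raise ValueError(f"network slices not symmetric (max asymmetry {asym:.2e})")
        if self.kind == "precision":
            for i in range(n):
                w = np.linalg.eigvalsh(self.networks[i])
                if w[0] <= 0:
                    raise ValueError(
                        f"precision slice for cell {self.cell_ids[i]!r} is not "
                        f"positive definite (min eigenvalue {w[0]:.3e})"
                    )
        else:
            off = self.networks.copy()
            idx = np.arange(g)
            off[:, idx, idx] = 0.0
            if np.abs(off).max() > 1 + 1e-9:
                raise ValueError("partial correlations exceed [-1, 1]")

    @property
    def n_cells(self) -> int:
        return self.networks.shape[0]

    @property
    def n_genes(self) -> int:
        return self.networks.shape[1]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:  # keep the line number pandas reports
        raise ValueError(f"parse error in {path}: {exc}") from exc


def read_expression(
    path: str | Path,
    format_hint: str | None = None,
    cells_as_rows: bool = True,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a cells × genes expression matrix from CSV, TSV or MatrixMarket.

    ``format_hint`` is one of ``csv``, ``tsv``, ``mtx-triplet``; when omitted
    it is derived from the file suffix.  For MatrixMarket input, sibling
    ``<stem>_genes.txt`` / ``<stem>_cells.txt`` name files are used unless
    explicit paths are given.  Orientation defaults to cells-as-rows and is
    only changed by the explicit flag, never by guessing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        suffix = path.suffix.lower()
        format_hint = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx-triplet"}.get(suffix)
        if format_hint is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")

    if format_hint in ("csv", "tsv"):
        sep = "," if format_hint == "csv" else "\t"
        header = path.open().readline().rstrip("\n").split(sep)
        df = _read_table(path, sep)
        first = df.columns[0]
        if df[first].dtype == object:
            # first column holds cell ids
            df = df.set_index(first)
            header = header[1:]
        gene_names = [h.strip() for h in header]
        _check_unique(gene_names, "gene")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression entry in {path}: {exc}") from exc
        if isinstance(df.index, pd.RangeIndex):
            cell_ids = [f"cell_{i}" for i in range(len(df))]
        else:
            cell_ids = [str(x) for x in df.index]
    elif format_hint == "mtx-triplet":
        genes_path = Path(genes_path) if genes_path else path.with_name(path.stem + "_genes.txt")
        cells_path = Path(cells_path) if cells_path else path.with_name(path.stem + "_cells.txt")
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"sibling name file missing: {p}")
        try:
            mat = mmread(str(path))
        except Exception as exc:
            raise ValueError(f"parse error in {path}: {exc}") from exc
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        gene_names = genes_path.read_text().split()
        cell_ids = cells_path.read_text().split()
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")

    if not cells_as_rows:
        values = values.T
        gene_names, cell_ids = cell_ids, gene_names
    return ExpressionMatrix(values=values, gene_names=gene_names, cell_ids=cell_ids)


def read_spatial_coordinates(path: str | Path) -> SpatialCoordinates:
    """Read a CSV of per-cell coordinates: first column cell id, then x,y[,z]."""
    path = Path(path)
    df = _read_table(path, ",")
    first = df.columns[0]
    if df[first].dtype == object:
        df = df.set_index(first)
        cell_ids = [str(x) for x in df.index]
    else:
        cell_ids = [f"cell_{i}" for i in range(len(df))]
    return SpatialCoordinates(coords=df.to_numpy(dtype=float), cell_ids=cell_ids)


def read_accessibility(
    region_matrix_path: str | Path,
    bed_path: str | Path,
    tss_path: str | Path,
    motif_path: str | Path,
    gene_names: list[str] | None = None,
) -> AccessibilityInputs:
    """Read the four accessibility inputs used to build prior networks.

    * region matrix: CSV, cells as rows (optional leading cell-id column);
    * BED: chrom / start / end, tab-separated, no header, 0-based half-open;
    * TSS: TSV with header columns gene, chrom, tss, strand (tss 1-based);
    * motif hits: headerless TSV ``region_index <tab> tf_name``.

    If ``gene_names`` is given, motif hits whose TF is absent from it are
    dropped with a logged warning.
    """
    rm_df = pd.read_csv(region_matrix_path)
    first = rm_df.columns[0]
    cell_ids: list[str] = []
    if rm_df[first].dtype == object:
        rm_df = rm_df.set_index(first)
        cell_ids = [str(x) for x in rm_df.index]
    region_matrix = rm_df.to_numpy()

    bed = pd.read_csv(
        bed_path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    tss = pd.read_csv(tss_path, sep="\t")
    required = {"gene", "chrom", "tss", "strand"}
    if not required.issubset(tss.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    tss = tss.copy()
    tss["tss"] = tss["tss"].astype(int) - 1  # 1-based -> 0-based

    motifs = pd.read_csv(
        motif_path, sep="\t", header=None, names=["region_index", "tf_name"]
    )
    hits = {(int(r), str(t)) for r, t in zip(motifs["region_index"], motifs["tf_name"])}
    if gene_names is not None:
        known = set(gene_names)
        kept = {(r, t) for r, t in hits if t in known}
        n_dropped = len(hits) - len(kept)
        if n_dropped:
            dropped = sorted({t for _, t in hits if t not in known})
            logger.warning(
                "dropped %d motif hit(s) naming TFs absent from gene names: %s",
                n_dropped, ", ".join(dropped),
            )
        hits = kept

    return AccessibilityInputs(
        region_matrix=region_matrix,
        region_coords=bed,
        tss_table=tss,
        motif_hits=hits,
        cell_ids=cell_ids,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_grn_tensor(tensor: GRNTensor, out_prefix: str | Path) -> list[Path]:
    """Persist a network tensor as ``<prefix>.npz`` plus ``<prefix>_edges.tsv``.

    The edge table lists each unordered off-diagonal gene pair once per cell
    (gene_a lexicographically before gene_b), so it has exactly
    n_cells · g(g−1)/2 rows.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    npz_path = out_prefix.with_suffix(".npz")
    np.savez_compressed(
        npz_path,
        networks=tensor.networks,
        gene_names=np.array(tensor.gene_names),
        cell_ids=np.array(tensor.cell_ids),
        kind=np.array(tensor.kind),
    )

    g = tensor.n_genes
    iu, ju = np.triu_indices(g, k=1)
    names = np.array(tensor.gene_names)
    a = names[iu].copy()
    b = names[ju].copy()
    flip = a > b
    a[flip], b[flip] = b[flip], a[flip]
    rows = []
    for ci, cid in enumerate(tensor.cell_ids):
        w = tensor.networks[ci][iu, ju]
        rows.append(pd.DataFrame({"cell_id": cid, "gene_a": a, "gene_b": b, "weight": w}))
    edges = pd.concat(rows, ignore_index=True)
    tsv_path = out_prefix.parent / (out_prefix.name + "_edges.tsv")
    edges.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    return [npz_path, tsv_path]


def read_grn_tensor(npz_path: str | Path) -> GRNTensor:
    """Read a tensor archive written by :func:`write_grn_tensor`."""
    with np.load(npz_path, allow_pickle=False) as data:
        return GRNTensor(
            networks=data["networks"],
            gene_names=[str(x) for x in data["gene_names"]],
            cell_ids=[str(x) for x in data["cell_ids"]],
            kind=str(data["kind"]),
        )


def normalize_log1p(expr: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Optional preprocessing: library-size normalization followed by log1p.

    Not applied automatically; callers opt in and the step is logged.
    """
    totals = expr.values.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    values = np.log1p(expr.values / totals * target_sum)
    logger.info("applied library-size normalization (target %g) + log1p", target_sum)
    return ExpressionMatrix(values=values, gene_names=list(expr.gene_names),
                            cell_ids=list(expr.cell_ids))
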