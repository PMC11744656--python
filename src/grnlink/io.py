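"""Data model and readers/writers for the three pipeline inputs.

The pipeline consumes (a) a gene x cell expression matrix whose cells are
ordered along a single-cell trajectory (pseudotime), (b) a table of per-gene
prior-knowledge embedding vectors (e.g. language-model embeddings of gene
descriptions; treated as opaque numbers here), and (c) a labeled list of
directed regulator->target edges (e.g. ChIP-seq supported interactions).
This module defines the containers for the three, file round-trips in plain
text formats (dense TSV and Matrix Market for expression), alignment of the
three inputs onto a shared gene universe, and standard single-cell
preprocessing (delegated to scanpy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, StructuralError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTrajectory",
    "EmbeddingTable",
    "EdgeSet",
    "AlignedDataset",
    "read_expression",
    "write_expression",
    "read_embeddings",
    "write_embeddings",
    "read_edges",
    "write_edges",
    "align",
    "preprocess",
]


def _check_unique(names, kind: str):
    seen = set()
    for n in names:
        if n in seen:
            raise StructuralError(f"duplicate {kind} name {n!r}")
        seen.add(n)


@dataclass
class ExpressionTrajectory:
    """Genes x cells expression matrix with cells ordered along a trajectory.

    ``pseudotime_rank[i]`` is the trajectory position of cell ``i``; the
    default identity rank means cells are already stored in pseudotime order.
    """

    gene_names: list[str]
    cell_names: list[str]
    values: np.ndarray
    pseudotime_rank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = list(self.gene_names)
        self.cell_names = list(self.cell_names)
        if self.pseudotime_rank is None:
            self.pseudotime_rank = np.arange(len(self.cell_names))
        self.pseudotime_rank = np.asarray(self.pseudotime_rank, dtype=np.intp)
        _check_unique(self.gene_names, "gene")
        _check_unique(self.cell_names, "cell")
        if self.values.shape != (len(self.gene_names), len(self.cell_names)):
            raise StructuralError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.gene_names)} genes, {len(self.cell_names)} cells)"
            )
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("expression matrix contains non-finite values")
        if sorted(self.pseudotime_rank.tolist()) != list(range(len(self.cell_names))):
            raise StructuralError("pseudotime_rank is not a permutation of cell indices")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.cell_names)

    def ordered_values(self) -> np.ndarray:
        """Matrix with columns sorted by pseudotime rank."""
        order = np.argsort(self.pseudotime_rank)
        return self.values[:, order]

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, pseudotime_key: str | None = None):
        """Convenience constructor from an AnnData (cells x genes).

        If ``pseudotime_key`` names an ``obs`` column, cells are ranked by it;
        otherwise the stored cell order is taken as the trajectory order.
        """
        X = adata.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        rank = None
        if pseudotime_key is not None:
            pt = np.asarray(adata.obs[pseudotime_key], dtype=float)
            rank = np.argsort(np.argsort(pt, kind="stable"), kind="stable")
        return cls(
            gene_names=list(adata.var_names),
            cell_names=list(adata.obs_names),
            values=np.asarray(X, dtype=np.float64).T,
            pseudotime_rank=rank,
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(X=self.values.T.copy())
        adata.obs_names = list(self.cell_names)
        adata.var_names = list(self.gene_names)
        adata.obs["pseudotime_rank"] = np.asarray(self.pseudotime_rank)
        return adata


@dataclass
class EmbeddingTable:
    """Per-gene prior-knowledge vectors (genes x dim)."""

    gene_names: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        self.gene_names = list(self.gene_names)
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        _check_unique(self.gene_names, "gene")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.gene_names):
            raise StructuralError(
                f"embedding matrix shape {self.vectors.shape} inconsistent with "
                f"{len(self.gene_names)} gene names"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise StructuralError("embedding table contains non-finite values")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class EdgeSet:
    """Labeled directed regulator->target pairs.

    ``regulator_universe`` is the set of genes eligible as edge sources (by
    default, the regulators observed among the edges); negative sampling draws
    sources from it.
    """

    edges: list[tuple[str, str, int]]
    regulator_universe: set[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        cleaned = []
        seen: dict[tuple[str, str], int] = {}
        for reg, tgt, label in self.edges:
            label = int(label)
            if label not in (0, 1):
                raise StructuralError(f"edge label must be 0 or 1, got {label}")
            key = (reg, tgt)
            if key in seen:
                if seen[key] != label:
                    raise StructuralError(
                        f"edge {reg}->{tgt} listed with conflicting labels"
                    )
                continue  # silent dedup of identical rows
            seen[key] = label
            cleaned.append((reg, tgt, label))
        self.edges = cleaned
        if self.regulator_universe is None:
            self.regulator_universe = {r for r, _, _ in self.edges}
        else:
            self.regulator_universe = set(self.regulator_universe)
        for reg, tgt, label in self.edges:
            if label == 1 and reg not in self.regulator_universe:
                raise StructuralError(
                    f"positive-edge regulator {reg!r} missing from regulator_universe"
                )

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(r, t) for r, t, _ in self.edges]

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.edges], dtype=np.intp)

    def positives(self) -> "EdgeSet":
        return EdgeSet(
            [e for e in self.edges if e[2] == 1],
            regulator_universe=self.regulator_universe,
        )

    def genes(self) -> set[str]:
        return {g for r, t, _ in self.edges for g in (r, t)}

    def subset(self, indices) -> "EdgeSet":
        return EdgeSet(
            [self.edges[i] for i in indices], regulator_universe=self.regulator_universe
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["regulator", "target", "label"])


@dataclass
class AlignedDataset:
    """The three inputs restricted to a shared, identically ordered gene universe."""

    trajectory: ExpressionTrajectory
    embeddings: EmbeddingTable
    edges: EdgeSet

    def __post_init__(self):
        if self.embeddings.gene_names != self.trajectory.gene_names:
            raise StructuralError("embedding and trajectory gene lists differ")
        universe = set(self.trajectory.gene_names)
        missing = self.edges.genes() - universe
        if missing:
            raise StructuralError(
                f"edges reference genes outside the aligned universe: {sorted(missing)[:5]}"
            )

    @property
    def gene_names(self) -> list[str]:
        return self.trajectory.gene_names


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "dense-tsv",
                    genes_path=None, cells_path=None) -> ExpressionTrajectory:
    """Read an expression matrix.

    ``dense-tsv``: genes as rows, first column gene name, header row of cell
    names.  ``matrix-market``: ``path`` is the ``.mtx`` file (genes x cells);
    gene and cell name files default to ``genes.tsv`` / ``cells.tsv`` next to
    it.  Cells are taken in file order with an identity pseudotime rank.
    """
    path = Path(path)
    if format == "dense-tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0,
                             float_precision="round_trip")
        except Exception as exc:  # pandas raises many flavours
            raise ParseError(f"cannot parse {path} as dense TSV: {exc}") from exc
        if not df.map(np.isreal).all().all():
            raise ParseError(f"{path}: non-numeric expression value")
        return ExpressionTrajectory(
            gene_names=[str(g) for g in df.index],
            cell_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=np.float64),
        )
    if format == "matrix-market":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "cells.tsv"
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse {path} as Matrix Market: {exc}") from exc
        genes = [line.split("\t")[0] for line in _read_lines(genes_path)]
        cells = [line.split("\t")[0] for line in _read_lines(cells_path)]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                           dtype=np.float64)
        if dense.shape != (len(genes), len(cells)):
            raise StructuralError(
                f"matrix shape {dense.shape} != ({len(genes)} genes, {len(cells)} cells) "
                f"from name files"
            )
        return ExpressionTrajectory(genes, cells, dense)
    raise UsageError(f"unknown expression format {format!r}")


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise ParseError(f"name file {path} not found")
    return [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]


def write_expression(trajectory: ExpressionTrajectory, path, format: str = "dense-tsv"):
    path = Path(path)
    if format == "dense-tsv":
        df = pd.DataFrame(trajectory.values, index=trajectory.gene_names,
                          columns=trajectory.cell_names)
        # 17 significant digits: exact float64 round-trip
        df.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "matrix-market":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(trajectory.values))
        (path.parent / "genes.tsv").write_text("\n".join(trajectory.gene_names) + "\n")
        (path.parent / "cells.tsv").write_text("\n".join(trajectory.cell_names) + "\n")
    else:
        raise UsageError(f"unknown expression format {format!r}")


def read_embeddings(path) -> EmbeddingTable:
    """Read a headerless TSV: gene id in column 1, then a constant number of
    numeric columns (the embedding vector)."""
    path = Path(path)
    genes: list[str] = []
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected gene id plus numeric columns")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise StructuralError(
                    f"{path}:{lineno}: ragged row ({len(fields)} columns, expected {width})"
                )
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
            genes.append(fields[0])
    if not rows:
        raise ParseError(f"{path}: empty embedding file")
    return EmbeddingTable(genes, np.array(rows))


def write_embeddings(table: EmbeddingTable, path):
    with open(path, "w") as fh:
        for gene, vec in zip(table.gene_names, table.vectors):
            fh.write(gene + "\t" + "\t".join("%.17g" % v for v in vec) + "\n")


def read_edges(path) -> EdgeSet:
    """Read a TSV with header ``regulator<TAB>target[<TAB>label]``.

    A missing label column defaults every edge to positive (label 1).
    Identical duplicate rows are collapsed; a pair listed with conflicting
    labels is a structural error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse {path} as edge TSV: {exc}") from exc
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "regulator" not in cols or "target" not in cols:
        raise ParseError(f"{path}: edge file needs 'regulator' and 'target' columns")
    if "label" not in cols:
        df["label"] = 1
    edges = [
        (str(r), str(t), int(l))
        for r, t, l in zip(df["regulator"], df["target"], df["label"])
    ]
    return EdgeSet(edges)


def write_edges(edges: EdgeSet, path):
    edges.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment & preprocessing
# ---------------------------------------------------------------------------

def align(trajectory: ExpressionTrajectory, embeddings: EmbeddingTable,
          edges: EdgeSet) -> AlignedDataset:
    """Restrict all three inputs to the genes common to the trajectory and the
    embedding table, in trajectory order; edges touching dropped genes are
    removed (with a logged count)."""
    emb_index = {g: i for i, g in enumerate(embeddings.gene_names)}
    keep = [i for i, g in enumerate(trajectory.gene_names) if g in emb_index]
    if not keep:
        raise StructuralError("trajectory and embedding gene sets are disjoint")
    genes = [trajectory.gene_names[i] for i in keep]
    traj = ExpressionTrajectory(
        gene_names=genes,
        cell_names=trajectory.cell_names,
        values=trajectory.values[keep, :],
        pseudotime_rank=trajectory.pseudotime_rank.copy(),
    )
    emb = EmbeddingTable(genes, embeddings.vectors[[emb_index[g] for g in genes], :])
    universe = set(genes)
    kept_edges = [(r, t, l) for r, t, l in edges.edges if r in universe and t in universe]
    dropped = len(edges.edges) - len(kept_edges)
    if dropped:
        logger.info("align: dropped %d edges touching genes outside the shared universe",
                    dropped)
    new_edges = EdgeSet(kept_edges,
                        regulator_universe=edges.regulator_universe & universe)
    return AlignedDataset(traj, emb, new_edges)


def preprocess(trajectory: ExpressionTrajectory, min_genes_per_cell: int = 200,
               min_cells_per_gene: int = 3, n_hvg: int = 500,
               target_sum: float = 1e4, log1p: bool = True,
               mito_quantile: float | None = None,
               mito_prefix: tuple[str, ...] = ("MT-", "mt-")) -> ExpressionTrajectory:
    """Standard single-cell preprocessing via scanpy.

    Cells expressing fewer than ``min_genes_per_cell`` genes and genes present
    in fewer than ``min_cells_per_gene`` cells are removed; each surviving
    cell's counts are scaled to ``target_sum``; optionally log1p-transformed;
    the ``n_hvg`` genes of highest (mean-binned, Seurat-style) dispersion are
    retained.  Surviving cells keep their relative pseudotime order.
    ``mito_quantile``, when set, removes cells whose mitochondrial fraction
    (genes matching ``mito_prefix``) exceeds that quantile across cells.
    """
    import scanpy as sc

    if min_genes_per_cell < 0 or min_cells_per_gene < 0 or n_hvg < 1:
        raise UsageError("filter thresholds must be non-negative and n_hvg >= 1")
    adata = trajectory.to_anndata()
    if min_genes_per_cell > 0:
        sc.pp.filter_cells(adata, min_genes=min_genes_per_cell)
    if adata.n_obs == 0:
        raise StructuralError("all cells removed by min_genes_per_cell filter")
    if mito_quantile is not None:
        mito = np.array([g.startswith(mito_prefix) for g in adata.var_names])
        if mito.any():
            frac = np.asarray(adata.X[:, mito]).sum(axis=1) / np.maximum(
                np.asarray(adata.X).sum(axis=1), 1e-12)
            adata = adata[frac <= np.quantile(frac, mito_quantile)].copy()
    if min_cells_per_gene > 0:
        sc.pp.filter_genes(adata, min_cells=min_cells_per_gene)
    if adata.n_vars == 0:
        raise StructuralError("all genes removed by min_cells_per_gene filter")
    if adata.n_obs == 0:
        raise StructuralError("all cells filtered out")
    sc.pp.normalize_total(adata, target_sum=target_sum)
    norm_counts = np.asarray(adata.X, dtype=np.float64)
    if log1p:
        sc.pp.log1p(adata)
    n_keep = min(n_hvg, adata.n_vars)
    # dispersion = variance / mean of the normalized counts; plain (unbinned)
    # so the ranking is deterministic on any input size, top n kept with a
    # stable tie-break on gene order
    mean = norm_counts.mean(axis=0)
    var = norm_counts.var(axis=0, ddof=1) if adata.n_obs > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, -np.inf)
    keep_idx = np.sort(np.argsort(-disp, kind="stable")[:n_keep])
    adata = adata[:, keep_idx].copy()
    return ExpressionTrajectory(
        gene_names=list(adata.var_names),
        cell_names=list(adata.obs_names),
        values=np.asarray(adata.X, dtype=np.float64).T,
        pseudotime_rank=np.argsort(
            np.argsort(adata.obs["pseudotime_rank"].to_numpy(), kind="stable"),
            kind="stable",
        ),
    )
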