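"""Intra-omics layer inference from single-cell count matrices.

Three constructors:

* :func:`infer_gene_layer` — directed transcriptional-regulation layer from
  scRNA counts via tree-ensemble feature importances (GENIE3-style).
* :func:`infer_peak_layer` — undirected peak co-accessibility layer from
  scATAC counts via windowed Pearson correlation.
* :func:`infer_generic_layer` — the same windowed-correlation construction
  for any coordinate-bearing omic (e.g. snmC methylation regions).
* :func:`load_tf_layer` — the TF layer: isolated nodes by default, or a
  weighted TF–TF cooperation graph when an edge list is supplied.

Cells need not match across omics; each layer is inferred from its own
matrix, which is what makes unpaired multi-omics data usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import ExtraTreesRegressor

from .links import GenomicFeatureSet
from .model import Layer, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneLayerConfig",
    "PeakLayerConfig",
    "infer_gene_layer",
    "infer_peak_layer",
    "infer_generic_layer",
    "load_tf_layer",
]


@dataclass
class CountMatrix:
    """Feature x cell count matrix for one omic."""

    features: list[str]
    cells: list[str]
    X: np.ndarray  # dense (features x cells); sparse inputs are densified
    omic: str = "other"

    def __post_init__(self) -> None:
        if sp.issparse(self.X):
            self.X = np.asarray(self.X.todense())
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.features), len(self.cells)):
            raise ValidationError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.features)} features x {len(self.cells)} cells"
            )
        if len(set(self.features)) != len(self.features):
            raise ValidationError("duplicate feature ids")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell ids")
        if not np.isfinite(self.X).all() or (self.X < 0).any():
            raise ValidationError("counts must be finite and >= 0")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def lognorm(self) -> "CountMatrix":
        """Library-size normalization (to median depth) followed by log1p.

        Off by default throughout the pipeline — preprocessing belongs
        upstream — but exposed for convenience.
        """
        depth = self.X.sum(axis=0)
        depth[depth == 0] = 1.0
        target = np.median(depth)
        return CountMatrix(
            self.features,
            self.cells,
            np.log1p(self.X / depth * target),
            self.omic,
        )


@dataclass(frozen=True)
class GeneLayerConfig:
    """Tree-ensemble gene layer parameters.

    n_trees: trees per target-gene regression (default 100).
    keep_fraction: fraction q of all candidate importances retained (default 0.1).
    seed: base seed for the per-gene regressors.
    """

    n_trees: int = 100
    keep_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ValidationError("n_trees must be positive")
        if not (0 < self.keep_fraction <= 1):
            raise ValidationError("keep_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PeakLayerConfig:
    """Windowed-correlation layer parameters.

    window: max distance in bp between interval midpoints (default 500 kb).
    tau: correlation threshold; edges with weight <= tau are dropped.
    pseudocell_size: if set, cells are randomly grouped into pseudo-cells of
        this size (mean profiles) before correlating, under pseudocell_seed.
    """

    window: int = 500_000
    tau: float = 0.0
    pseudocell_size: Optional[int] = None
    pseudocell_seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValidationError("window must be > 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")


def infer_gene_layer(
    x: CountMatrix, cfg: GeneLayerConfig = GeneLayerConfig(), name: str = "rna"
) -> Layer:
    """Directed gene–gene layer from tree-ensemble importances.

    For each target gene, an extremely-randomized-trees regression of its
    profile on all other genes yields per-regulator importance scores; the
    top ``keep_fraction`` of all candidate importances become directed
    (regulator -> target) edges.  Zero-variance genes contribute no edges as
    regulator or target.  Byte-reproducible for a fixed seed.
    """
    if x.n_features < 2:
        raise ValidationError("gene layer needs at least 2 genes")
    if x.X.max() == 0:
        raise ValidationError("all-zero expression matrix")
    if x.n_cells < 10:
        raise ValidationError("gene layer needs at least 10 cells")
    genes = x.features
    mat = x.X
    variable = mat.std(axis=1) > 0
    records: list[tuple[str, str, float]] = []
    var_idx = np.flatnonzero(variable)
    for gi in var_idx:
        candidates = var_idx[var_idx != gi]
        if candidates.size == 0:
            continue
        y = mat[gi]
        y = y / y.std()
        model = ExtraTreesRegressor(
            n_estimators=cfg.n_trees,
            max_features="sqrt",
            random_state=cfg.seed + gi,
            n_jobs=1,
        )
        model.fit(mat[candidates].T, y)
        for ci, imp in zip(candidates, model.feature_importances_):
            if imp > 0:
                records.append((genes[ci], genes[gi], float(imp)))
    if records:
        records.sort(key=lambda t: (-t[2], t[0], t[1]))
        n_keep = int(np.ceil(cfg.keep_fraction * len(records)))
        records = records[:n_keep]
    logger.info("gene layer: %d genes, %d edges retained", len(genes), len(records))
    return Layer(name=name, nodes=list(genes), edges=records, directed=True)


def _candidate_pairs(
    feats: GenomicFeatureSet, ids: Sequence[str], window: int
) -> list[tuple[int, int]]:
    """Same-chromosome index pairs whose interval midpoints are within window."""
    df = feats.frame.set_index("id").loc[list(ids)]
    mid = ((df["start"] + df["end"]) / 2.0).to_numpy()
    chrom = df["chrom"].to_numpy()
    order = np.lexsort((mid, chrom))
    pairs: list[tuple[int, int]] = []
    for k, i in enumerate(order):
        for j in order[k + 1 :]:
            if chrom[j] != chrom[i] or mid[j] - mid[i] > window:
                break
            pairs.append((i, j))
    return pairs


def _windowed_correlation_layer(
    x: CountMatrix, feats: GenomicFeatureSet, cfg: PeakLayerConfig, name: str
) -> Layer:
    missing = set(x.features) - set(feats.frame["id"])
    if missing:
        raise ValidationError(
            f"{len(missing)} feature id(s) lack coordinates, e.g. "
            f"{sorted(missing)[:3]}"
        )
    mat = x.X
    if cfg.pseudocell_size and cfg.pseudocell_size > 1 and x.n_cells > cfg.pseudocell_size:
        rng = np.random.default_rng(cfg.pseudocell_seed)
        perm = rng.permutation(x.n_cells)
        groups = [
            perm[i : i + cfg.pseudocell_size]
            for i in range(0, x.n_cells, cfg.pseudocell_size)
        ]
        mat = np.column_stack([mat[:, g].mean(axis=1) for g in groups])
    # standardize once; Pearson of a pair is then a dot product / n
    std = mat.std(axis=1)
    ok = std > 0
    centered = mat - mat.mean(axis=1, keepdims=True)
    z = centered / np.where(ok, std, 1.0)[:, None]
    n_obs = mat.shape[1]
    edges: list[tuple[str, str, float]] = []
    for i, j in _candidate_pairs(feats, x.features, cfg.window):
        if not (ok[i] and ok[j]):
            continue
        r = float(z[i] @ z[j]) / n_obs
        if r > cfg.tau:
            a, b = sorted((x.features[i], x.features[j]))
            edges.append((a, b, min(r, 1.0)))
    logger.info("%s layer: %d features, %d edges", name, x.n_features, len(edges))
    return Layer(name=name, nodes=list(x.features), edges=edges, directed=False)


def infer_peak_layer(
    x: CountMatrix,
    peaks: GenomicFeatureSet,
    cfg: PeakLayerConfig = PeakLayerConfig(),
    name: str = "atac",
) -> Layer:
    """Undirected peak co-accessibility layer.

    Candidate pairs are same-chromosome peaks with midpoints within
    ``cfg.window``; the edge weight is the Pearson correlation of the
    (optionally pseudo-cell aggregated) accessibility profiles.  Pairs with
    weight <= tau, and all negative correlations, are dropped: RWR needs
    non-negative transition mass, and anti-correlation is not evidence of
    co-regulation.
    """
    return _windowed_correlation_layer(x, peaks, cfg, name)


def infer_generic_layer(
    x: CountMatrix,
    features: GenomicFeatureSet,
    cfg: PeakLayerConfig = PeakLayerConfig(),
    name: str = "generic",
) -> Layer:
    """Windowed-correlation layer for any coordinate-bearing omic (e.g. snmC)."""
    return _windowed_correlation_layer(x, features, cfg, name)


def load_tf_layer(
    tfs: Sequence[str],
    edges: Optional[Sequence[tuple[str, str, float]]] = None,
    name: str = "tf",
) -> Layer:
    """TF layer: isolated nodes, or a TF–TF cooperation graph.

    Without ``edges`` the layer contains unlinked TFs (the default variant,
    which keeps the comparison with motif-database-driven methods fair);
    with an edge list it becomes the +TF variant carrying TF–TF links.
    """
    if not tfs:
        raise ValidationError("tf list must be non-empty")
    tf_set = set(tfs)
    edge_list: list[tuple[str, str, float]] = []
    if edges:
        for a, b, w in edges:
            if a not in tf_set or b not in tf_set:
                raise ValidationError(f"TF edge ({a!r}, {b!r}) references unknown TF")
            edge_list.append((a, b, float(w)))
    return Layer(name=name, nodes=list(tfs), edges=edge_list, directed=False)
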