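"""The five walk-based outputs of the multilayer analysis.

Given an assembled multilayer, seeded random walks produce:

(i)   per-TF rankings of target genes (walk TF -> whole network, rank genes);
(ii)  per-TF rankings of bound peaks (walk restricted to TF + ATAC layers);
(iii) per-gene rankings of regulatory regions (walk restricted to RNA + ATAC);
(iv)  a gene regulatory network, from walks seeded at each *gene* scoring the
      TF layer — this orientation makes TFs compete for each gene, whereas
      (i) makes genes compete for each TF;
(v)   Louvain communities of the (density-filtered) GRN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import Multilayer, TransitionOperator, build_transition, subset_layers
from .rwr import RankedResult, RWRConfig, rank_layer, rwr

logger = logging.getLogger(__name__)

__all__ = [
    "GRN",
    "CommunityConfig",
    "CommunityPartition",
    "tf_targets",
    "tf_binding_regions",
    "gene_regulatory_regions",
    "build_grn",
    "filter_to_density",
    "detect_communities",
]


@dataclass
class GRN:
    """Weighted TF -> gene network.

    ``edges`` has columns (tf, gene, weight); the weight of (t, g) is the
    steady-state probability of TF t in the walk seeded at gene g.  ``tfs``
    and ``genes`` record the universes the network was built over (needed to
    define density).
    """

    edges: pd.DataFrame
    tfs: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        required = ["tf", "gene", "weight"]
        if list(self.edges.columns[:3]) != required:
            self.edges = self.edges.rename(
                columns=dict(zip(self.edges.columns[:3], required))
            )
        if (self.edges["weight"] <= 0).any():
            raise ValueError("GRN weights must be > 0")
        if self.edges.duplicated(["tf", "gene"]).any():
            raise ValueError("duplicate (tf, gene) edge")

    @property
    def density(self) -> float:
        return len(self.edges) / (len(self.tfs) * len(self.genes))

    def regulons(self) -> dict[str, pd.DataFrame]:
        """Per-TF view: genes ranked by association weight (descending)."""
        out = {}
        for tf, sub in self.edges.groupby("tf", sort=True):
            out[tf] = (
                sub.sort_values(["weight", "gene"], ascending=[False, True])
                .reset_index(drop=True)[["gene", "weight"]]
            )
        return out

    @property
    def n_regulons(self) -> int:
        return self.edges["tf"].nunique()


@dataclass(frozen=True)
class CommunityConfig:
    """Community detection parameters.

    density: target GRN density before clustering (networks are filtered to
        equal density so community structure is comparable across methods).
    resolutions: Louvain resolution grid, within [0, 2].
    min_communities: a partition is 'reasonable' when it has at least this
        many communities (default 10).
    seed: Louvain partition seed (fixed -> byte-identical partitions).
    """

    density: float = 0.05
    resolutions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)
    min_communities: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if any(g < 0 or g > 2 for g in self.resolutions):
            raise ValueError("resolution grid must lie within [0, 2]")


@dataclass
class CommunityPartition:
    resolution: float
    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def _per_seed_rankings(
    m: Multilayer,
    cfg: RWRConfig,
    seed_layer: str,
    target_layer: str,
    included: Optional[Sequence[str]],
) -> dict[str, RankedResult]:
    if included is not None:
        walk_m = subset_layers(m, included)
    else:
        walk_m = m
    op = build_transition(walk_m, cfg.with_layers(None))
    seeds = sorted(m.layer(seed_layer).nodes)
    out: dict[str, RankedResult] = {}
    for node in seeds:
        x = rwr(op, {f"{seed_layer}:{node}": 1.0}, cfg)
        out[node] = rank_layer(x, walk_m, target_layer)
    return out


def tf_targets(
    m: Multilayer,
    cfg: RWRConfig = RWRConfig(),
    tf_layer: str = "tf",
    rna_layer: str = "rna",
) -> dict[str, RankedResult]:
    """Output (i): per-TF ranking of putative target genes.

    One walk per TF (seed mass 1) over the full layer set; the ranking is
    restricted to the RNA layer, so genes compete among themselves for each
    TF independently.
    """
    if not m.layer(tf_layer).nodes:
        raise ValueError("TF layer is empty")
    return _per_seed_rankings(m, cfg, tf_layer, rna_layer, included=None)


def tf_binding_regions(
    m: Multilayer,
    cfg: RWRConfig = RWRConfig(),
    tf_layer: str = "tf",
    atac_layer: str = "atac",
) -> dict[str, RankedResult]:
    """Output (ii): per-TF ranking of bound peaks.

    The walk explores only the TF and ATAC layers; downstream the ranking is
    typically filtered at a fraction of the peaks (100/80/60/20%) via
    :meth:`RankedResult.top_fraction`.
    """
    if not m.layer(tf_layer).nodes:
        raise ValueError("TF layer is empty")
    return _per_seed_rankings(
        m, cfg, tf_layer, atac_layer, included=[tf_layer, atac_layer]
    )


def gene_regulatory_regions(
    m: Multilayer,
    cfg: RWRConfig = RWRConfig(),
    rna_layer: str = "rna",
    atac_layer: str = "atac",
) -> dict[str, RankedResult]:
    """Output (iii): per-gene ranking of regulatory regions.

    Walks start at each gene and explore only the RNA and ATAC layers;
    proximal peaks and, via co-accessibility, distal enhancers are ranked.
    """
    if not m.layer(rna_layer).nodes:
        raise ValueError("RNA layer is empty")
    return _per_seed_rankings(
        m, cfg, rna_layer, atac_layer, included=[rna_layer, atac_layer]
    )


def build_grn(
    m: Multilayer,
    cfg: RWRConfig = RWRConfig(),
    tf_layer: str = "tf",
    rna_layer: str = "rna",
) -> GRN:
    """Output (iv): the gene regulatory network.

    For each gene g, a walk seeded at g explores the full network; every
    TF-layer node with positive score contributes an edge (t, g, score).
    Within one walk the TF scores sum to the TF layer's share of probability,
    so TFs compete for the regulation of each gene.  All positive edges are
    retained; sparsify with :func:`filter_to_density` when comparing
    networks.
    """
    tfs = sorted(m.layer(tf_layer).nodes)
    genes = sorted(m.layer(rna_layer).nodes)
    if not tfs or not genes:
        raise ValueError("TF and RNA layers must be non-empty")
    op = build_transition(m, cfg.with_layers(None))
    tf_positions = [(tf, op.position(f"{tf_layer}:{tf}")) for tf in tfs]
    records = []
    for gene in genes:
        x = rwr(op, {f"{rna_layer}:{gene}": 1.0}, cfg)
        for tf, pos in tf_positions:
            score = x.values[pos]
            if score > 0:
                records.append((tf, gene, float(score)))
    edges = pd.DataFrame(records, columns=["tf", "gene", "weight"])
    logger.info("GRN: %d edges over %d TFs x %d genes", len(edges), len(tfs), len(genes))
    return GRN(edges=edges, tfs=tfs, genes=genes)


def filter_to_density(g: GRN, density: float) -> GRN:
    """Keep the top ``ceil(density * |TFs| * |genes|)`` edges by weight.

    Ties at the cutoff break deterministically by (weight desc, tf asc,
    gene asc).  ``density=1`` is the identity.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    n_keep = math.ceil(density * len(g.tfs) * len(g.genes))
    ordered = g.edges.sort_values(
        ["weight", "tf", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    return GRN(edges=ordered.head(n_keep).reset_index(drop=True), tfs=g.tfs, genes=g.genes)


def detect_communities(
    g: GRN, cfg: CommunityConfig = CommunityConfig(), pre_filter: bool = True
) -> dict[float, CommunityPartition]:
    """Output (v): Louvain communities of the GRN at each resolution.

    The GRN is treated as an undirected weighted graph (TF and gene nodes).
    When ``pre_filter`` is set the network is first filtered to the target
    density.  A fixed partition seed makes runs byte-identical.
    """
    if len(g.edges) == 0:
        raise ValueError("GRN is empty")
    if pre_filter:
        g = filter_to_density(g, cfg.density)
    graph = nx.Graph()
    for row in g.edges.itertuples(index=False):
        graph.add_edge(f"tf:{row.tf}", f"gene:{row.gene}", weight=row.weight)
    out: dict[float, CommunityPartition] = {}
    for gamma in cfg.resolutions:
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=gamma, seed=cfg.seed
        )
        comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
        membership = {node: i for i, comm in enumerate(comms) for node in comm}
        mod = nx.community.modularity(
            graph, [set(c) for c in comms], weight="weight", resolution=gamma
        )
        out[gamma] = CommunityPartition(
            resolution=gamma, membership=membership, modularity=mod
        )
        logger.info(
            "louvain gamma=%.2f: %d communities, modularity %.4f",
            gamma, len(comms), mod,
        )
    return out
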