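"""Heterogeneous multilayer network (HMLN) data model.

An HMLN is an ordered collection of *layers* — each an intra-omics graph over
its own node type (TF–TF, peak–peak, gene–gene, ...) — joined by weighted
*bipartite* inter-layer links (TF→peak motif hits, peak→gene proximity, ...).
This module defines the containers (:class:`Layer`, :class:`BipartiteLinks`,
:class:`Multilayer`) and builds the column-stochastic supra-transition
operator that the random walker uses.

Node ids are namespaced internally as ``"layer:node"`` so that a gene that is
also a transcription factor can appear in two layers as two distinct nodes.
External I/O uses bare ids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Layer",
    "BipartiteLinks",
    "Multilayer",
    "TransitionOperator",
    "ValidationError",
    "ConfigurationError",
    "assemble",
    "build_transition",
    "subset_layers",
]


class ValidationError(ValueError):
    """Raised when a layer, bipartite link set or multilayer is inconsistent."""


class ConfigurationError(ValueError):
    """Raised when walk configuration parameters are inconsistent."""


def _check_weights(edges, context: str) -> None:
    for e in edges:
        w = e[2]
        if not np.isfinite(w) or w < 0:
            raise ValidationError(f"{context}: edge {e[:2]} has invalid weight {w!r}")


@dataclass
class Layer:
    """One intra-omics weighted graph.

    Parameters
    ----------
    name
        Layer identifier, unique within a multilayer (e.g. ``"rna"``).
    nodes
        Node ids, unique within the layer.
    edges
        ``(source, target, weight)`` triples; weights finite and >= 0.
        Zero-weight edges are dropped at construction.
    directed
        If False the layer is symmetrized at walk time (each edge used in
        both directions).
    """

    name: str
    nodes: Sequence[str]
    edges: Sequence[tuple[str, str, float]] = field(default_factory=list)
    directed: bool = False

    def __post_init__(self) -> None:
        nodes = list(self.nodes)
        if len(set(nodes)) != len(nodes):
            raise ValidationError(f"layer {self.name!r}: duplicate node ids")
        node_set = set(nodes)
        _check_weights(self.edges, f"layer {self.name!r}")
        kept = []
        for s, t, w in self.edges:
            if s not in node_set or t not in node_set:
                raise ValidationError(
                    f"layer {self.name!r}: edge ({s!r}, {t!r}) references a node "
                    "outside the layer"
                )
            if w > 0:
                kept.append((s, t, float(w)))
        self.nodes = nodes
        self.edges = kept

    @property
    def node_set(self) -> frozenset:
        return frozenset(self.nodes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "directed" if self.directed else "undirected"
        return (
            f"Layer({self.name!r}, {len(self.nodes)} nodes, "
            f"{len(self.edges)} {kind} edges)"
        )


@dataclass
class BipartiteLinks:
    """Weighted inter-layer edges between two named layers."""

    layer_a: str
    layer_b: str
    edges: Sequence[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layer_a == self.layer_b:
            raise ValidationError(
                f"bipartite links must join distinct layers, got {self.layer_a!r} twice"
            )
        _check_weights(self.edges, f"bipartite {self.layer_a}~{self.layer_b}")
        self.edges = [(a, b, float(w)) for a, b, w in self.edges if w > 0]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BipartiteLinks({self.layer_a!r}~{self.layer_b!r}, "
            f"{len(self.edges)} edges)"
        )


@dataclass
class Multilayer:
    """An ordered set of layers plus bipartite link sets: the HMLN."""

    layers: Sequence[Layer]
    bipartites: Sequence[BipartiteLinks] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate layer names: {names}")

    @property
    def M(self) -> int:
        """Number of layers."""
        return len(self.layers)

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def layer(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"unknown layer {name!r}")

    def global_ids(self) -> list[str]:
        """Global node ordering: layers in declared order, lexicographic within."""
        out: list[str] = []
        for l in self.layers:
            out.extend(f"{l.name}:{n}" for n in sorted(l.nodes))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Multilayer({self.M} layers: {self.layer_names}, "
            f"{len(self.bipartites)} bipartite sets)"
        )


@dataclass
class TransitionOperator:
    """Column-stochastic supra-transition matrix over all layers' nodes.

    ``matrix[j, i]`` is the probability of moving from node ``index[i]`` to
    node ``index[j]``.  Dangling columns (nodes with no outgoing mass) are
    all-zero and flagged; the walker redirects their mass to the restart
    distribution.
    """

    index: list[str]
    matrix: sp.csr_matrix
    dangling: np.ndarray
    layer_of: np.ndarray
    layer_names: list[str]

    @property
    def n(self) -> int:
        return len(self.index)

    def position(self, global_id: str) -> int:
        try:
            return self._pos[global_id]
        except AttributeError:
            self._pos = {g: i for i, g in enumerate(self.index)}
            return self._pos[global_id]


def assemble(
    layers: Iterable[Layer], bipartites: Iterable[BipartiteLinks] = ()
) -> Multilayer:
    """Validate layers + bipartite links and return a :class:`Multilayer`.

    Every bipartite endpoint must resolve to a declared node of its named
    layer; a dangling endpoint raises a :class:`ValidationError` naming the
    offending edge.  If the layer graph (layers as vertices, bipartite sets
    as edges) is disconnected a warning is emitted — walks simply assign zero
    probability to unreachable layers.
    """
    layers = list(layers)
    bipartites = list(bipartites)
    if not layers:
        raise ValidationError("at least one layer is required")
    m = Multilayer(layers, bipartites)
    by_name = {l.name: l for l in layers}
    for bp in bipartites:
        for side in (bp.layer_a, bp.layer_b):
            if side not in by_name:
                raise ValidationError(f"bipartite references unknown layer {side!r}")
        a_nodes = by_name[bp.layer_a].node_set
        b_nodes = by_name[bp.layer_b].node_set
        for a, b, w in bp.edges:
            if a not in a_nodes:
                raise ValidationError(
                    f"bipartite {bp.layer_a}~{bp.layer_b}: edge ({a!r}, {b!r}, {w}) "
                    f"names a node absent from layer {bp.layer_a!r}"
                )
            if b not in b_nodes:
                raise ValidationError(
                    f"bipartite {bp.layer_a}~{bp.layer_b}: edge ({a!r}, {b!r}, {w}) "
                    f"names a node absent from layer {bp.layer_b!r}"
                )
    if len(layers) > 1:
        import networkx as nx

        lg = nx.Graph()
        lg.add_nodes_from(by_name)
        lg.add_edges_from((bp.layer_a, bp.layer_b) for bp in bipartites if bp.edges)
        if not nx.is_connected(lg):
            warnings.warn(
                "layer graph is disconnected; layers unreachable from the seeds "
                "will receive zero probability mass",
                stacklevel=2,
            )
    return m


def subset_layers(m: Multilayer, keep: Iterable[str]) -> Multilayer:
    """Restrict to the kept layers and the bipartites internal to them."""
    keep = set(keep)
    if not keep:
        raise ValidationError("keep must be non-empty")
    unknown = keep - set(m.layer_names)
    if unknown:
        raise ValidationError(f"unknown layer(s) in keep: {sorted(unknown)}")
    layers = [l for l in m.layers if l.name in keep]
    bps = [bp for bp in m.bipartites if bp.layer_a in keep and bp.layer_b in keep]
    return Multilayer(layers, bps)


def build_transition(m: Multilayer, cfg) -> TransitionOperator:
    """Build the supra-transition operator for a walk configured by ``cfg``.

    For a node v in layer l with bipartite links into k >= 1 adjacent included
    layers, the outgoing probability splits as: jump probability lambda to
    each adjacent linked layer (mass within a jump distributed proportionally
    to bipartite weight), the remainder ``1 - k*lambda`` over intra-layer
    edges proportionally to weight.  With the default policy lambda is
    renormalized equally (``min(lambda, 1/k)``) so the jump total never
    exceeds 1.  A node with no bipartite links spends all mass intra-layer; a
    node with bipartite links but no intra-layer edges splits all mass
    equally across its adjacent layers; a node with neither is dangling.
    """
    included = cfg.included_layers
    if included is not None:
        m = subset_layers(m, included)
    lam = float(cfg.lambda_jump)
    if not (0 < lam <= 1):
        raise ConfigurationError(f"lambda_jump must be in (0, 1], got {lam}")

    index = m.global_ids()
    pos = {g: i for i, g in enumerate(index)}
    n = len(index)
    layer_names = m.layer_names
    layer_idx = {name: i for i, name in enumerate(layer_names)}
    layer_of = np.empty(n, dtype=np.int32)
    for g, i in pos.items():
        layer_of[i] = layer_idx[g.split(":", 1)[0]]

    # out_intra[i]: list of (target_pos, weight); out_inter[i]: {layer: [(pos, w)]}
    out_intra: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    out_inter: list[dict[str, list[tuple[int, float]]]] = [{} for _ in range(n)]

    for layer in m.layers:
        ln = layer.name
        for s, t, w in layer.edges:
            si, ti = pos[f"{ln}:{s}"], pos[f"{ln}:{t}"]
            out_intra[si].append((ti, w))
            if not layer.directed and si != ti:
                out_intra[ti].append((si, w))

    for bp in m.bipartites:
        for a, b, w in bp.edges:
            ai, bi = pos[f"{bp.layer_a}:{a}"], pos[f"{bp.layer_b}:{b}"]
            out_inter[ai].setdefault(bp.layer_b, []).append((bi, w))
            out_inter[bi].setdefault(bp.layer_a, []).append((ai, w))

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    dangling = np.zeros(n, dtype=bool)

    for i in range(n):
        intra = out_intra[i]
        inter = out_inter[i]
        k = len(inter)
        if k == 0 and not intra:
            dangling[i] = True
            continue
        if k == 0:
            inter_share = 0.0
        elif not intra:
            inter_share = 1.0
        else:
            lam_eff = min(lam, 1.0 / k) if cfg.renormalize_jumps else lam
            if lam_eff * k > 1 + 1e-12:
                raise ConfigurationError(
                    f"jump probabilities sum to {lam_eff * k:.3f} > 1 for node "
                    f"{index[i]!r} (adjacent to {k} layers)"
                )
            inter_share = lam_eff * k
        if k:
            per_layer = inter_share / k
            for targets in inter.values():
                tot = sum(w for _, w in targets)
                for j, w in targets:
                    rows.append(j)
                    cols.append(i)
                    vals.append(per_layer * w / tot)
        if intra:
            intra_share = 1.0 - inter_share
            if intra_share > 0:
                tot = sum(w for _, w in intra)
                for j, w in intra:
                    rows.append(j)
                    cols.append(i)
                    vals.append(intra_share * w / tot)

    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=np.float64
    )
    mat.sum_duplicates()
    colsums = np.asarray(mat.sum(axis=0)).ravel()
    ok = ~dangling
    if ok.any():
        dev = np.abs(colsums[ok] - 1.0).max()
        if dev > 1e-9:  # pragma: no cover - construction guarantees stochasticity
            raise AssertionError(f"non-stochastic column, deviation {dev:.2e}")
    logger.info(
        "transition operator: %d nodes, %d entries, %d dangling columns",
        n,
        mat.nnz,
        int(dangling.sum()),
    )
    return TransitionOperator(
        index=index,
        matrix=mat,
        dangling=dangling,
        layer_of=layer_of,
        layer_names=layer_names,
    )
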