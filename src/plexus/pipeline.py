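"""End-to-end assembly: count matrices + annotations -> multilayer network.

The canonical three-layer build is TF (isolated nodes or TF–TF cooperation
edges), ATAC (peak co-accessibility) and RNA (tree-ensemble transcriptional
regulation), joined by motif-scan TF->peak links and TSS-proximity
peak->gene links.  A methylation layer slots in generically: windowed
correlation intra-layer, proximity links to both genes (TSS) and peaks
(body).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .layers import (
    CountMatrix,
    GeneLayerConfig,
    PeakLayerConfig,
    infer_gene_layer,
    infer_generic_layer,
    infer_peak_layer,
    load_tf_layer,
)
from .links import (
    GenomicFeatureSet,
    MotifModel,
    link_by_proximity,
    link_tf_peaks,
    scan_motifs,
)
from .model import Multilayer, assemble
from .synthetic import SyntheticBundle

logger = logging.getLogger(__name__)

__all__ = ["BuildConfig", "build_multilayer", "build_from_bundle"]


@dataclass(frozen=True)
class BuildConfig:
    """Assembly parameters for the standard multilayer build."""

    gene_layer: GeneLayerConfig = GeneLayerConfig()
    peak_layer: PeakLayerConfig = PeakLayerConfig()
    methyl_layer: PeakLayerConfig = PeakLayerConfig()
    proximity_window: int = 100_000
    motif_rel_threshold: float = 0.8
    score_weighted_tf_links: bool = False
    use_tf_edges: bool = False  # the +TF variant
    include_methyl: bool = False


def build_multilayer(
    tf_names: list[str],
    rna: CountMatrix,
    atac: CountMatrix,
    genes: GenomicFeatureSet,
    peaks: GenomicFeatureSet,
    peak_seqs: dict[str, str],
    motifs: list[MotifModel],
    cfg: BuildConfig = BuildConfig(),
    tf_edges=None,
    methyl: Optional[CountMatrix] = None,
    methyl_regions: Optional[GenomicFeatureSet] = None,
) -> Multilayer:
    """Infer all layers and bipartite links and assemble the multilayer.

    TFs without a motif model stay isolated (and are logged); peak->gene
    links anchor at the TSS within ``cfg.proximity_window``.
    """
    tf_layer = load_tf_layer(tf_names, tf_edges if cfg.use_tf_edges else None)
    atac_layer = infer_peak_layer(atac, peaks, cfg.peak_layer, name="atac")
    rna_layer = infer_gene_layer(rna, cfg.gene_layer, name="rna")

    covered = {tf for m in motifs for tf in m.tf_names}
    missing = sorted(set(tf_names) - covered)
    if missing:
        logger.warning(
            "%d TF(s) have no motif model and stay isolated: %s",
            len(missing), ", ".join(missing[:5]),
        )
    hits = scan_motifs(peak_seqs, motifs, rel_threshold=cfg.motif_rel_threshold)
    motif_map = {m.motif_id: m.tf_names for m in motifs}
    tf_peak = link_tf_peaks(
        hits, tf_layer, atac_layer, motif_to_tfs=motif_map,
        score_weighting=cfg.score_weighted_tf_links,
    )
    peak_gene = link_by_proximity(
        peaks, genes, window=cfg.proximity_window, anchor="tss",
        layer_a="atac", layer_b="rna",
    )
    layers = [tf_layer, atac_layer, rna_layer]
    bipartites = [tf_peak, peak_gene]
    if cfg.include_methyl:
        if methyl is None or methyl_regions is None:
            raise ValueError("include_methyl requires methyl matrix and regions")
        me_layer = infer_generic_layer(methyl, methyl_regions, cfg.methyl_layer, name="methyl")
        me_gene = link_by_proximity(
            methyl_regions, genes, window=cfg.proximity_window, anchor="tss",
            layer_a="methyl", layer_b="rna",
        )
        me_peak = link_by_proximity(
            methyl_regions, peaks, window=cfg.proximity_window, anchor="body",
            layer_a="methyl", layer_b="atac",
        )
        layers.append(me_layer)
        bipartites.extend([me_gene, me_peak])
    return assemble(layers, bipartites)


def build_from_bundle(
    bundle: SyntheticBundle, cfg: BuildConfig = BuildConfig()
) -> Multilayer:
    """Run the standard build on a synthetic bundle."""
    return build_multilayer(
        tf_names=bundle.tf_names,
        rna=bundle.rna,
        atac=bundle.atac,
        genes=bundle.genes,
        peaks=bundle.peaks,
        peak_seqs=bundle.peak_sequences(),
        motifs=bundle.motifs,
        cfg=cfg,
        tf_edges=bundle.tf_tf_edges,
        methyl=bundle.methyl,
        methyl_regions=bundle.methyl_regions,
    )
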