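"""Synthetic unpaired multi-omics data with planted regulatory cascades.

The generator emulates the inputs of a single-cell multi-omics study —
scRNA counts, scATAC accessibility, snmC methylation fractions, a genome
FASTA, peak/gene/region coordinates, TF binding motifs — with a known
ground truth: each TF drives a *cascade*, a genomic locus carrying the TF's
binding motif in a set of co-accessible peaks placed near the TSSs of the
TF's target genes (the TF's own gene included: the motif sits near its own
promoter too, so every planted TF->gene pair is connected by a
TF->peak->gene path).

Cell-group structure drives the correlations: each cascade has a latent
activity per cell group plus per-cell noise, shared by the cascade's genes
(negative-binomial expression), peaks (Bernoulli accessibility) and
methylation region (beta-distributed fraction, anti-correlated with
activity).  The per-omic cell sets are drawn independently from shared
group proportions, so the data are unpaired by construction.

Everything is deterministic for a fixed seed, down to the emitted bytes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .layers import CountMatrix
from .links import GenomicFeatureSet, MotifModel, _interval_point_distance
from .model import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate_multiome", "perturb_cell_groups"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic multi-omics bundle.

    Defaults define the standard desk-scale benchmark: 20 TFs each driving a
    disjoint cascade of 5 peaks and 10 genes (its own gene plus 9 targets),
    500 peaks and 200 genes total, 3 cell groups, unpaired cell sets of
    300/250/200 cells for scRNA/scATAC/snmC.
    """

    n_tfs: int = 20
    n_peaks: int = 500
    n_genes: int = 200
    n_regions_methyl: int = 50
    n_cells_rna: int = 300
    n_cells_atac: int = 250
    n_cells_methyl: int = 200
    n_cell_groups: int = 3
    genes_per_tf: int = 10  # includes the TF's own gene
    peaks_per_tf: int = 5
    motif_width: int = 10
    motif_mutation_rate: float = 0.0
    # latent activity: per-group program value (sd group_effect) + per-cell noise
    group_effect: float = 0.7
    noise_sd: float = 1.0
    # scRNA: NB2 counts, mean = base * max(1 + expr_effect * f, floor)
    nb_dispersion: float = 0.3
    expr_effect: float = 0.8
    # scATAC: Bernoulli with rate sigmoid(base_logit + atac_effect * f)
    atac_base_logit: float = -2.0
    atac_effect: float = 2.0
    # snmC: Beta(kappa*p, kappa*(1-p)) fraction, p = sigmoid(0.5 - methyl_effect*f)
    methyl_effect: float = 1.5
    methyl_concentration: float = 20.0
    # genome layout: cascade loci of locus_span bp spaced locus_spacing apart
    chrom_count: int = 4
    locus_span: int = 80_000
    locus_spacing: int = 600_000
    peak_width: int = 400
    proximity_window: int = 100_000
    disjoint_cascades: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_tfs", "n_peaks", "n_genes", "n_regions_methyl", "n_cells_rna",
            "n_cells_atac", "n_cells_methyl", "n_cell_groups", "genes_per_tf",
            "peaks_per_tf", "motif_width",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.disjoint_cascades:
            if self.n_tfs * self.genes_per_tf > self.n_genes:
                raise ValidationError("disjoint cascades need n_tfs*genes_per_tf <= n_genes")
            if self.n_tfs * self.peaks_per_tf > self.n_peaks:
                raise ValidationError("disjoint cascades need n_tfs*peaks_per_tf <= n_peaks")


@dataclass
class SyntheticBundle:
    """Everything a full pipeline run needs, plus the planted truth."""

    config: SyntheticConfig
    tf_names: list[str]
    rna: CountMatrix
    atac: CountMatrix
    methyl: CountMatrix
    genes: GenomicFeatureSet
    peaks: GenomicFeatureSet
    methyl_regions: GenomicFeatureSet
    genome: dict[str, str]
    motifs: list[MotifModel]
    tf_tf_edges: list[tuple[str, str, float]]
    cell_groups: dict[str, np.ndarray]  # omic -> group index per cell
    truth_tf_genes: pd.DataFrame  # columns tf, gene
    truth_tf_peaks: pd.DataFrame  # columns tf, peak
    truth_gene_peaks: pd.DataFrame  # columns gene, peak
    gene_sets: dict[str, list[str]]  # planted "pathways" = cascade gene sets

    def peak_sequences(self) -> dict[str, str]:
        out = {}
        for row in self.peaks.frame.itertuples(index=False):
            out[row.id] = self.genome[row.chrom][row.start : row.end]
        return out

    def truth_maps(self) -> dict[str, dict[str, set[str]]]:
        return {
            "tf_genes": {
                tf: set(sub["gene"]) for tf, sub in self.truth_tf_genes.groupby("tf")
            },
            "tf_peaks": {
                tf: set(sub["peak"]) for tf, sub in self.truth_tf_peaks.groupby("tf")
            },
            "gene_peaks": {
                g: set(sub["peak"]) for g, sub in self.truth_gene_peaks.groupby("gene")
            },
        }

    def write(self, outdir: str | Path) -> None:
        from . import io as pio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_count_matrix(self.rna, outdir / "rna", fmt="mtx")
        pio.write_count_matrix(self.atac, outdir / "atac", fmt="mtx")
        pio.write_count_matrix(self.methyl, outdir / "methyl", fmt="tsv")
        pio.write_bed(self.peaks, outdir / "peaks.bed")
        pio.write_bed(self.methyl_regions, outdir / "methyl_regions.bed")
        pio.write_gene_table(self.genes, outdir / "genes.tsv")
        pio.write_fasta(self.genome, outdir / "genome.fa")
        pio.write_motifs_jaspar(self.motifs, outdir / "motifs.jaspar")
        pd.DataFrame(self.tf_tf_edges, columns=["tf_a", "tf_b", "weight"]).to_csv(
            outdir / "tf_tf.tsv", sep="\t", index=False
        )
        (outdir / "tfs.txt").write_text("".join(f"{t}\n" for t in self.tf_names))
        gt = outdir / "ground_truth"
        gt.mkdir(exist_ok=True)
        self.truth_tf_genes.to_csv(gt / "tf_genes.tsv", sep="\t", index=False)
        self.truth_tf_peaks.to_csv(gt / "tf_peaks.tsv", sep="\t", index=False)
        self.truth_gene_peaks.to_csv(gt / "gene_peaks.tsv", sep="\t", index=False)
        pio.write_gmt(self.gene_sets, gt / "cascades.gmt")
        for omic in sorted(self.cell_groups):
            cells = getattr(self, omic).cells
            pd.DataFrame(
                {"cell": cells, "group": self.cell_groups[omic]}
            ).to_csv(outdir / f"cell_groups_{omic}.tsv", sep="\t", index=False)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _assign_groups(rng: np.random.Generator, n_cells: int, n_groups: int) -> np.ndarray:
    base = np.arange(n_cells) % n_groups
    return rng.permutation(base)


def _factors(
    rng: np.random.Generator,
    programs: np.ndarray,  # (n_cascades, n_groups)
    groups: np.ndarray,  # (n_cells,)
    cfg: SyntheticConfig,
) -> np.ndarray:
    """(n_cascades, n_cells) latent activity per cascade per cell."""
    f = programs[:, groups] * cfg.group_effect
    f = f + rng.normal(0.0, cfg.noise_sd, size=f.shape)
    return f


def generate_multiome(cfg: SyntheticConfig = SyntheticConfig()) -> SyntheticBundle:
    """Draw one synthetic multi-omics bundle under ``cfg``.

    Returns matrices over independent cell sets (unpaired), coordinates,
    genome, motifs and the planted ground truth.  Byte-identical across runs
    for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_casc = cfg.n_tfs
    per_chrom = -(-n_casc // cfg.chrom_count)  # ceil
    chrom_len = per_chrom * cfg.locus_spacing + cfg.locus_span + 20_000
    chroms = [f"chr{i + 1}" for i in range(cfg.chrom_count)]

    tf_names = [f"Tf{i + 1:02d}" for i in range(n_casc)]
    n_targets = cfg.genes_per_tf - 1
    target_names = [f"G{i + 1:03d}" for i in range(cfg.n_genes - n_casc)]

    # ---- cascade membership -------------------------------------------------
    if cfg.disjoint_cascades:
        casc_targets = [
            target_names[c * n_targets : (c + 1) * n_targets] for c in range(n_casc)
        ]
    else:
        casc_targets = [
            sorted(rng.choice(target_names, size=n_targets, replace=False))
            for _ in range(n_casc)
        ]
    casc_genes = [[tf_names[c]] + list(casc_targets[c]) for c in range(n_casc)]
    extra_genes = sorted(set(target_names) - {g for cg in casc_targets for g in cg})

    # ---- genome layout ------------------------------------------------------
    genome_arr = {
        ch: rng.integers(0, 4, size=chrom_len, dtype=np.int8) for ch in chroms
    }
    locus_chrom = [chroms[c // per_chrom] for c in range(n_casc)]
    locus_start = [10_000 + (c % per_chrom) * cfg.locus_spacing for c in range(n_casc)]

    gene_records: list[tuple[str, str, int, int, str]] = []
    for c in range(n_casc):
        ch, s0 = locus_chrom[c], locus_start[c]
        positions = np.sort(rng.integers(s0, s0 + cfg.locus_span, size=cfg.genes_per_tf))
        strands = rng.choice(["+", "-"], size=cfg.genes_per_tf)
        for g, tss, strand in zip(casc_genes[c], positions, strands):
            if strand == "+":
                gene_records.append((g, ch, int(tss), int(tss) + 2000, "+"))
            else:
                gene_records.append((g, ch, int(tss) - 1999, int(tss) + 1, "-"))
    # background genes (if any) live mid-gap, out of reach of the proximity window
    for i, g in enumerate(extra_genes):
        c = i % n_casc
        ch, s0 = locus_chrom[c], locus_start[c]
        tss = s0 + cfg.locus_span + 150_000 + (i // n_casc) * 997
        gene_records.append((g, ch, int(tss), int(tss) + 2000, "+"))
    genes = GenomicFeatureSet.from_records(gene_records)

    # cascade peaks inside the locus, background peaks in the inter-locus gaps
    peak_records: list[tuple[str, str, int, int, str]] = []
    casc_peak_ids: list[list[str]] = []
    used: set[tuple[str, int]] = set()

    def place_peak(ch: str, lo: int, hi: int) -> tuple[str, int, int]:
        while True:
            start = int(rng.integers(lo, hi))
            start -= start % 10  # grid to keep ids tidy and collisions checkable
            if (ch, start) not in used:
                used.add((ch, start))
                return f"{ch}:{start}-{start + cfg.peak_width}", start, start + cfg.peak_width

    for c in range(n_casc):
        ch, s0 = locus_chrom[c], locus_start[c]
        ids = []
        for _ in range(cfg.peaks_per_tf):
            pid, s, e = place_peak(ch, s0, s0 + cfg.locus_span - cfg.peak_width)
            peak_records.append((pid, ch, s, e, "."))
            ids.append(pid)
        casc_peak_ids.append(ids)
    n_bg_peaks = cfg.n_peaks - n_casc * cfg.peaks_per_tf
    for i in range(n_bg_peaks):
        c = i % n_casc
        ch, s0 = locus_chrom[c], locus_start[c]
        gap_lo = s0 + cfg.locus_span + 120_000
        gap_hi = s0 + cfg.locus_spacing - 120_000
        pid, s, e = place_peak(ch, gap_lo, gap_hi)
        peak_records.append((pid, ch, s, e, "."))
    peaks = GenomicFeatureSet.from_records(peak_records)
    peak_ids = peaks.ids

    # methylation regions: one per cascade (up to n_regions), rest in gaps
    region_records = []
    for i in range(cfg.n_regions_methyl):
        if i < n_casc:
            ch, s0 = locus_chrom[i], locus_start[i]
            start = int(rng.integers(s0, s0 + cfg.locus_span - 1000))
        else:
            c = i % n_casc
            ch, s0 = locus_chrom[c], locus_start[c]
            start = int(rng.integers(s0 + cfg.locus_span + 120_000,
                                     s0 + cfg.locus_spacing - 120_000))
        region_records.append((f"mr{i + 1:03d}", ch, start, start + 1000, "."))
    methyl_regions = GenomicFeatureSet.from_records(region_records)

    # ---- motifs planted in cascade peak sequences ---------------------------
    motifs: list[MotifModel] = []
    for c, tf in enumerate(tf_names):
        consensus = rng.integers(0, 4, size=cfg.motif_width)
        counts = np.zeros((4, cfg.motif_width))
        counts[consensus, np.arange(cfg.motif_width)] = 10.0
        motifs.append(
            MotifModel(motif_id=f"M{c + 1:04d}", tf_names=(tf,), counts=counts)
        )
        for pid in casc_peak_ids[c]:
            row = peaks.frame.loc[peaks.frame["id"] == pid].iloc[0]
            offset = int(rng.integers(0, cfg.peak_width - cfg.motif_width))
            site = consensus.copy()
            if cfg.motif_mutation_rate > 0:
                mut = rng.random(cfg.motif_width) < cfg.motif_mutation_rate
                site[mut] = rng.integers(0, 4, size=int(mut.sum()))
            genome_arr[row.chrom][row.start + offset : row.start + offset + cfg.motif_width] = site
    genome = {
        ch: _BASES[arr].tobytes().decode("ascii") for ch, arr in genome_arr.items()
    }

    # ---- latent structure and count matrices --------------------------------
    programs = rng.normal(0.0, 1.0, size=(n_casc, cfg.n_cell_groups))
    cell_groups: dict[str, np.ndarray] = {}

    # scRNA: negative binomial, mean linear in the cascade activity
    groups_rna = _assign_groups(rng, cfg.n_cells_rna, cfg.n_cell_groups)
    cell_groups["rna"] = groups_rna
    f_rna = _factors(rng, programs, groups_rna, cfg)
    gene_ids = [r[0] for r in gene_records]
    base_expr = {g: float(b) for g, b in zip(gene_ids, rng.uniform(2.0, 8.0, len(gene_ids)))}
    gene_of_casc = {g: c for c in range(n_casc) for g in casc_genes[c]}
    rna_X = np.zeros((len(gene_ids), cfg.n_cells_rna))
    inv_disp = 1.0 / cfg.nb_dispersion
    for gi, g in enumerate(gene_ids):
        if g in gene_of_casc:
            f = f_rna[gene_of_casc[g]]
            mu = base_expr[g] * np.maximum(1.0 + cfg.expr_effect * f, 0.02)
        else:
            mu = np.full(cfg.n_cells_rna, base_expr[g])
        p = inv_disp / (inv_disp + mu)
        rna_X[gi] = rng.negative_binomial(inv_disp, p)
    rna = CountMatrix(
        features=list(gene_ids),
        cells=[f"rna_cell_{i + 1:04d}" for i in range(cfg.n_cells_rna)],
        X=rna_X,
        omic="rna",
    )

    # scATAC: binarized Bernoulli with group-dependent rates for cascade peaks
    groups_atac = _assign_groups(rng, cfg.n_cells_atac, cfg.n_cell_groups)
    cell_groups["atac"] = groups_atac
    f_atac = _factors(rng, programs, groups_atac, cfg)
    peak_of_casc = {pid: c for c in range(n_casc) for pid in casc_peak_ids[c]}
    atac_X = np.zeros((len(peak_ids), cfg.n_cells_atac))
    for pi, pid in enumerate(peak_ids):
        if pid in peak_of_casc:
            rate = _sigmoid(cfg.atac_base_logit + cfg.atac_effect * f_atac[peak_of_casc[pid]])
        else:
            rate = np.full(cfg.n_cells_atac, rng.uniform(0.05, 0.3))
        atac_X[pi] = (rng.random(cfg.n_cells_atac) < rate).astype(float)
    atac = CountMatrix(
        features=list(peak_ids),
        cells=[f"atac_cell_{i + 1:04d}" for i in range(cfg.n_cells_atac)],
        X=atac_X,
        omic="atac",
    )

    # snmC: beta-distributed methylation fraction, anti-correlated with activity
    groups_me = _assign_groups(rng, cfg.n_cells_methyl, cfg.n_cell_groups)
    cell_groups["methyl"] = groups_me
    f_me = _factors(rng, programs, groups_me, cfg)
    me_ids = methyl_regions.ids
    me_X = np.zeros((len(me_ids), cfg.n_cells_methyl))
    kappa = cfg.methyl_concentration
    for ri, rid in enumerate(me_ids):
        if ri < n_casc:
            p = _sigmoid(0.5 - cfg.methyl_effect * f_me[ri])
        else:
            p = np.full(cfg.n_cells_methyl, rng.uniform(0.3, 0.9))
        p = np.clip(p, 1e-3, 1 - 1e-3)
        me_X[ri] = rng.beta(kappa * p, kappa * (1 - p))
    methyl = CountMatrix(
        features=list(me_ids),
        cells=[f"me_cell_{i + 1:04d}" for i in range(cfg.n_cells_methyl)],
        X=me_X,
        omic="methylation",
    )

    # ---- ground truth -------------------------------------------------------
    tf_gene_rows = [
        (tf_names[c], g) for c in range(n_casc) for g in sorted(casc_genes[c])
    ]
    tf_peak_rows = [
        (tf_names[c], p) for c in range(n_casc) for p in sorted(casc_peak_ids[c])
    ]
    # gene -> peak: cascade peaks actually within the proximity window of the TSS
    tss = genes.tss()
    peak_coord = {
        r.id: (r.start, r.end) for r in peaks.frame.itertuples(index=False)
    }
    gene_peak_rows = []
    for c in range(n_casc):
        for g in sorted(casc_genes[c]):
            t = int(tss[g])
            for pid in sorted(casc_peak_ids[c]):
                s, e = peak_coord[pid]
                if _interval_point_distance(s, e, t) <= cfg.proximity_window:
                    gene_peak_rows.append((g, pid))
    gene_sets = {
        f"cascade_{tf_names[c]}": sorted(casc_genes[c]) for c in range(n_casc)
    }
    tf_tf_edges = [
        (tf_names[i], tf_names[i + 1], 1.0) for i in range(0, n_casc - 1, 2)
    ]

    logger.info(
        "synthetic bundle: %d TFs, %d genes, %d peaks, %d methyl regions",
        n_casc, len(gene_ids), len(peak_ids), len(me_ids),
    )
    return SyntheticBundle(
        config=cfg,
        tf_names=tf_names,
        rna=rna,
        atac=atac,
        methyl=methyl,
        genes=genes,
        peaks=peaks,
        methyl_regions=methyl_regions,
        genome=genome,
        motifs=motifs,
        tf_tf_edges=tf_tf_edges,
        cell_groups=cell_groups,
        truth_tf_genes=pd.DataFrame(tf_gene_rows, columns=["tf", "gene"]),
        truth_tf_peaks=pd.DataFrame(tf_peak_rows, columns=["tf", "peak"]),
        truth_gene_peaks=pd.DataFrame(gene_peak_rows, columns=["gene", "peak"]),
        gene_sets=gene_sets,
    )


def perturb_cell_groups(
    bundle: SyntheticBundle,
    omic: str,
    group: int,
    fraction: float,
    seed: Optional[int] = None,
) -> SyntheticBundle:
    """Subsample one cell group of one omic to ``fraction``, all else untouched.

    Mirrors the unbalanced-cell-type robustness scenarios: e.g. halving one
    population's scRNA cells while the scATAC side is unaltered.  The kept
    cells are chosen deterministically from ``seed`` (default derived from
    the bundle's own seed).
    """
    if omic not in bundle.cell_groups:
        raise ValidationError(f"unknown omic {omic!r}")
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    groups = bundle.cell_groups[omic]
    if group not in set(groups.tolist()):
        raise ValidationError(f"unknown group {group} in omic {omic!r}")
    if fraction == 1.0:
        return bundle
    rng = np.random.default_rng(
        bundle.config.seed + 7919 * (group + 1) if seed is None else seed
    )
    members = np.flatnonzero(groups == group)
    n_keep = int(round(fraction * members.size))
    kept_members = np.sort(rng.choice(members, size=n_keep, replace=False))
    keep = np.sort(
        np.concatenate([np.flatnonzero(groups != group), kept_members])
    )
    mat = getattr(bundle, omic)
    new_mat = CountMatrix(
        features=list(mat.features),
        cells=[mat.cells[i] for i in keep],
        X=mat.X[:, keep],
        omic=mat.omic,
    )
    new_groups = dict(bundle.cell_groups)
    new_groups[omic] = groups[keep]
    return dataclasses.replace(
        bundle, **{omic: new_mat, "cell_groups": new_groups}
    )
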