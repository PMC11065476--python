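"""Benchmarking procedures against ground-truth files.

The evaluation consumes ground truths (TF->gene maps, per-TF region sets,
gene->region maps, GMT gene-set collections) as files or in-memory maps; it
does not build them.  Procedures:

* per-TF target rankings cut at increasing levels, overlapped with the truth;
* one-sided Fisher exact enrichment of the top-k per TF;
* F1 of predicted vs true sets (exact ids or >= 1 bp interval overlap);
* hypergeometric gene-set enrichment of GRN communities with BH correction;
* Spearman comparison of two GRNs over the union of their edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .links import GenomicFeatureSet
from .outputs import GRN, CommunityPartition
from .rwr import RankedResult

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationConfig",
    "FisherResult",
    "overlap_at_cutoffs",
    "fisher_significant_tfs",
    "f1_sets",
    "enrich_communities",
    "compare_grns",
    "spearman_edge_weights",
]

DEFAULT_CUTOFFS = (3, 5, 10, 15, 20, 30, 40, 50, 75, 100)
DEFAULT_FRACTIONS = (1.0, 0.8, 0.6, 0.2)


@dataclass(frozen=True)
class EvaluationConfig:
    """Ranking cutoffs, significance level and fraction thresholds."""

    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    alpha: float = 0.05
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cutoffs) or list(self.cutoffs) != sorted(
            set(self.cutoffs)
        ):
            raise ValueError("cutoffs must be positive and strictly increasing")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _ranked_ids(ranking) -> list[str]:
    if isinstance(ranking, RankedResult):
        return ranking.nodes
    return list(ranking)


def overlap_at_cutoffs(
    rankings: Mapping[str, RankedResult | Sequence[str]],
    gt: Mapping[str, Iterable[str]],
    cfg: EvaluationConfig = EvaluationConfig(),
) -> pd.Series:
    """Mean (over TFs) number of correctly predicted targets at each cutoff.

    For each cutoff k, the mean over TFs with a non-empty ground truth of
    ``|top-k of the TF's ranking  ∩  gt(TF)|``.  TFs missing from either side
    or with empty truth are excluded.
    """
    shared = sorted(
        tf for tf in rankings if tf in gt and len(set(gt[tf])) > 0
    )
    if not shared:
        raise ValueError("no TF present in both rankings and ground truth")
    result = {}
    for k in cfg.cutoffs:
        vals = [
            len(set(_ranked_ids(rankings[tf])[:k]) & set(gt[tf])) for tf in shared
        ]
        result[k] = float(np.mean(vals))
    return pd.Series(result, name="mean_overlap")


@dataclass
class FisherResult:
    n_significant: int
    pvalues: pd.Series  # per TF

    def __int__(self) -> int:
        return self.n_significant


def fisher_significant_tfs(
    rankings: Mapping[str, RankedResult | Sequence[str]],
    gt: Mapping[str, Iterable[str]],
    k: int,
    cfg: EvaluationConfig = EvaluationConfig(),
    universe: Optional[set[str]] = None,
) -> FisherResult:
    """Count TFs whose top-k targets are enriched for the truth (p < alpha).

    Per TF the 2x2 table is ``[[|top-k ∩ gt|, |top-k \\ gt|],
    [|gt \\ top-k|, |universe \\ (top-k ∪ gt)|]]`` over the universe of
    ranked genes (overridable), tested one-sided for enrichment — "a
    significant amount of correct targets" is a one-directional claim.  TFs
    with an empty (restricted) truth are excluded.
    """
    pvals = {}
    for tf in sorted(rankings):
        if tf not in gt:
            continue
        ranked = _ranked_ids(rankings[tf])
        uni = set(ranked) if universe is None else set(universe)
        truth = set(gt[tf]) & uni
        if not truth:
            continue
        top = set(ranked[:k]) & uni
        a = len(top & truth)
        b = len(top - truth)
        c = len(truth - top)
        d = len(uni) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        pvals[tf] = p
    if not pvals:
        raise ValueError("no TF present in both rankings and ground truth")
    pseries = pd.Series(pvals)
    return FisherResult(int((pseries < cfg.alpha).sum()), pseries)


def _interval_overlap_counts(
    predicted: GenomicFeatureSet, truth: GenomicFeatureSet
) -> tuple[int, int, int]:
    """TP/FP/FN with >= 1 bp overlap matching on half-open intervals."""
    pdf = predicted.frame
    tdf = truth.frame
    def matched(df_a, df_b):
        hit = np.zeros(len(df_a), dtype=bool)
        for chrom, sub_b in df_b.groupby("chrom"):
            mask = (df_a["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            a_start = df_a["start"].to_numpy()[mask]
            a_end = df_a["end"].to_numpy()[mask]
            b_start = sub_b["start"].to_numpy()
            b_end = sub_b["end"].to_numpy()
            # overlap iff a.start < b.end and b.start < a.end
            ov = (a_start[:, None] < b_end[None, :]) & (
                b_start[None, :] < a_end[:, None]
            )
            hit[np.flatnonzero(mask)] |= ov.any(axis=1)
        return hit
    tp = int(matched(pdf, tdf).sum())
    fp = len(pdf) - tp
    fn = int((~matched(tdf, pdf)).sum())
    return tp, fp, fn


def f1_sets(predicted, truth) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 when precision and recall are both 0.

    Plain sets are matched exactly; :class:`GenomicFeatureSet` inputs are
    matched by >= 1 bp interval overlap (a predicted region counts as a true
    positive if it overlaps any truth region).
    """
    if isinstance(predicted, GenomicFeatureSet) or isinstance(truth, GenomicFeatureSet):
        tp, fp, fn = _interval_overlap_counts(predicted, truth)
    else:
        p, t = set(predicted), set(truth)
        tp = len(p & t)
        fp = len(p - t)
        fn = len(t - p)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def enrich_communities(
    partition: CommunityPartition | Sequence[set[str]],
    collections: Mapping[str, Mapping[str, Iterable[str]]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-collection percentage (and count) of enriched communities.

    For every (community, gene set) pair, a hypergeometric over-representation
    test over the stated universe; Benjamini–Hochberg correction is applied
    per collection across all pairs, and a community counts as enriched when
    at least one adjusted p-value is below alpha.  Community members outside
    the universe are ignored; an internal ``gene:``/``tf:`` namespace prefix
    is stripped before matching.
    """
    if isinstance(partition, CommunityPartition):
        comms = partition.communities()
    else:
        comms = [set(c) for c in partition]
    if not comms:
        raise ValueError("partition has no communities")
    uni = set(universe)

    def members(comm: set[str]) -> set[str]:
        stripped = {n.split(":", 1)[1] if ":" in n else n for n in comm}
        return stripped & uni

    rows = []
    N = len(uni)
    for cname, sets in collections.items():
        if not sets:
            raise ValueError(f"collection {cname!r} is empty")
        tests = []  # (community index, pvalue)
        for ci, comm in enumerate(comms):
            genes = members(comm)
            n = len(genes)
            for sname, sgenes in sets.items():
                K = len(set(sgenes) & uni)
                if K == 0 or n == 0:
                    continue
                x = len(genes & set(sgenes))
                p = stats.hypergeom.sf(x - 1, N, K, n)
                tests.append((ci, p))
        enriched: set[int] = set()
        if tests:
            reject, _, _, _ = multipletests(
                [p for _, p in tests], alpha=alpha, method="fdr_bh"
            )
            enriched = {ci for (ci, _), rej in zip(tests, reject) if rej}
        rows.append(
            {
                "collection": cname,
                "n_communities": len(comms),
                "n_enriched": len(enriched),
                "pct_enriched": 100.0 * len(enriched) / len(comms),
            }
        )
    return pd.DataFrame(rows).set_index("collection")


def spearman_edge_weights(
    e1: pd.DataFrame, e2: pd.DataFrame, key: Sequence[str] = ("tf", "gene")
) -> float:
    """Spearman correlation of two weighted edge lists over their edge union.

    An edge absent from one list gets weight 0 there; ties are handled by
    average ranks (the scipy default).
    """
    key = list(key)
    merged = e1.merge(e2, on=key, how="outer", suffixes=("_1", "_2")).fillna(0.0)
    if merged.empty:
        raise ValueError("edge union is empty")
    rho, _ = stats.spearmanr(merged["weight_1"], merged["weight_2"])
    return float(rho)


def compare_grns(g1: GRN, g2: GRN) -> float:
    """Spearman correlation between two GRNs over the union of their edges."""
    return spearman_edge_weights(g1.edges, g2.edges)
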