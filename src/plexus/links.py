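"""Bipartite inter-layer links.

Two mechanisms join the omics layers:

* **Motif scanning** (TF layer -> peak layer): position-count-matrix
  log-odds scoring of peak sequences on both strands, thresholded relative
  to each motif's maximum attainable score.
* **Genomic proximity** (peak -> gene, methylation region -> gene/peak):
  interval distance to a feature's body or TSS within a window.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .model import BipartiteLinks, Layer, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicFeatureSet",
    "MotifModel",
    "MotifHit",
    "scan_motifs",
    "link_tf_peaks",
    "link_by_proximity",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenomicFeatureSet:
    """Named genomic intervals: (id, chrom, start, end, strand).

    0-based half-open [start, end); strand one of ``+ - .``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"feature frame missing columns {missing}")
        df = self.frame[required].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"feature {bad['id']!r}: start {bad['start']} >= end {bad['end']}"
            )
        if df["id"].duplicated().any():
            raise ValidationError("duplicate feature ids")
        if not df["strand"].isin(["+", "-", "."]).all():
            raise ValidationError("strand must be one of + - .")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, int, str]]
    ) -> "GenomicFeatureSet":
        return cls(
            pd.DataFrame(records, columns=["id", "chrom", "start", "end", "strand"])
        )

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    def tss(self) -> pd.Series:
        """Anchor point per feature: start for + / . strand, end-1 for -."""
        df = self.frame
        return pd.Series(
            np.where(df["strand"] == "-", df["end"] - 1, df["start"]),
            index=df["id"],
            name="tss",
        )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class MotifModel:
    """A TF binding motif as a position count matrix (4 x width, rows ACGT)."""

    motif_id: str
    tf_names: tuple[str, ...]
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValidationError(
                f"motif {self.motif_id!r}: counts must be 4 x width"
            )
        if self.counts.shape[1] == 0:
            raise ValidationError(f"motif {self.motif_id!r} is empty")
        if (self.counts < 0).any():
            raise ValidationError(f"motif {self.motif_id!r}: negative counts")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x width log2-odds matrix: log2((c+p) / (total+4p) / background)."""
        p = self.pseudocount
        totals = self.counts.sum(axis=0, keepdims=True)
        probs = (self.counts + p) / (totals + 4 * p)
        return np.log2(probs / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


class MotifHit(NamedTuple):
    motif_id: str
    seq_id: str
    position: int  # 0-based start of the hit window on the forward strand
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _CODE.items():
        code[arr == ord(base)] = i
    unknown = (code == -1) & ~np.isin(arr, np.frombuffer(b"N", dtype=np.uint8))
    if unknown.any():
        raise ValidationError("sequence contains characters outside {A,C,G,T,N}")
    return code


def _window_scores(code: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score of every window of width lo.shape[1]; windows with N -> -inf."""
    w = lo.shape[1]
    n_win = code.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    has_n = np.zeros(n_win, dtype=bool)
    for j in range(w):
        col = code[j : j + n_win]
        valid = col >= 0
        has_n |= ~valid
        scores += np.where(valid, lo[np.clip(col, 0, 3), j], 0.0)
    scores[has_n] = -np.inf
    return scores


def scan_motifs(
    seqs: Mapping[str, str],
    motifs: Sequence[MotifModel],
    rel_threshold: float = 0.8,
) -> list[MotifHit]:
    """Scan sequences with each motif on both strands.

    A window scores the sum over positions of
    ``log2((count + p) / (column_total + 4p) / background)``; hits with
    score >= ``rel_threshold * max attainable score`` are reported.  A hit on
    the reverse complement is reported with strand ``-`` at its forward-strand
    start position.  Sequences shorter than the motif yield no hits.
    """
    if not (0 < rel_threshold <= 1):
        raise ValidationError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    hits: list[MotifHit] = []
    encoded = {sid: _encode(s) for sid, s in seqs.items()}
    for motif in motifs:
        lo = motif.log_odds()
        w = motif.width
        threshold = rel_threshold * motif.max_score()
        lo_rc = lo[::-1, ::-1]  # scoring the reverse complement in forward coords
        for sid, code in encoded.items():
            for strand, mat in (("+", lo), ("-", lo_rc)):
                scores = _window_scores(code, mat)
                for pos in np.flatnonzero(scores >= threshold):
                    hits.append(
                        MotifHit(motif.motif_id, sid, int(pos), strand, float(scores[pos]))
                    )
    hits.sort()
    return hits


def link_tf_peaks(
    hits: Iterable[MotifHit] | pd.DataFrame,
    tf_layer: Layer,
    peak_layer: Layer,
    motif_to_tfs: Optional[Mapping[str, Sequence[str]]] = None,
    score_weighting: bool = False,
) -> BipartiteLinks:
    """TF -> peak bipartite links from motif hits (or a precomputed table).

    One edge per (TF, peak) pair: weight 1 in the default binary-occurrence
    mode (motif log-odds scales are width-dependent and would distort
    cross-TF competition in the walk), or the maximum hit score when
    ``score_weighting`` is on.  Hits naming unknown TFs or peaks are counted
    and logged, not fatal.
    """
    if isinstance(hits, pd.DataFrame):
        records = [
            MotifHit(r.motif_id, r.seq_id, int(getattr(r, "position", 0)),
                     getattr(r, "strand", "+"), float(getattr(r, "score", 1.0)))
            for r in hits.itertuples(index=False)
        ]
    else:
        records = list(hits)
    tf_nodes = tf_layer.node_set
    peak_nodes = peak_layer.node_set
    best: dict[tuple[str, str], float] = {}
    unmapped = 0
    for hit in records:
        tfs = (
            motif_to_tfs.get(hit.motif_id, ())
            if motif_to_tfs is not None
            else (hit.motif_id,)
        )
        tfs = [tf for tf in tfs if tf in tf_nodes]
        if not tfs or hit.seq_id not in peak_nodes:
            unmapped += 1
            continue
        for tf in tfs:
            key = (tf, hit.seq_id)
            best[key] = max(best.get(key, -np.inf), hit.score)
    if unmapped:
        logger.warning("link_tf_peaks: %d hit(s) could not be mapped", unmapped)
    edges = [
        (tf, peak, score if score_weighting else 1.0)
        for (tf, peak), score in sorted(best.items())
    ]
    return BipartiteLinks(tf_layer.name, peak_layer.name, edges)


def _interval_point_distance(start: int, end: int, t: int) -> int:
    """Distance between half-open [start, end) and point t."""
    if start <= t < end:
        return 0
    return min(abs(t - start), abs(t - (end - 1)))


def _interval_interval_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    if s1 < e2 and s2 < e1:
        return 0
    return max(s1 - (e2 - 1), s2 - (e1 - 1))


def link_by_proximity(
    a: GenomicFeatureSet,
    b: GenomicFeatureSet,
    window: int,
    anchor: str = "tss",
    layer_a: str = "atac",
    layer_b: str = "rna",
) -> BipartiteLinks:
    """Link a-features to b-features within ``window`` bp on the same chromosome.

    With ``anchor="tss"`` the b-feature is reduced to its TSS (start for
    ``+``/``.`` strand, end-1 for ``-``) and the distance is from the
    a-interval to that point; with ``anchor="body"`` it is the minimum
    distance between the two intervals.  Weight is 1 for every link.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    if anchor not in ("tss", "body"):
        raise ValidationError(f"anchor must be 'tss' or 'body', got {anchor!r}")
    edges: list[tuple[str, str, float]] = []
    adf = a.frame
    bdf = b.frame
    if anchor == "tss":
        anchors = np.where(bdf["strand"] == "-", bdf["end"] - 1, bdf["start"])
    for chrom, a_chr in adf.groupby("chrom", sort=True):
        b_mask = bdf["chrom"] == chrom
        if not b_mask.any():
            continue
        b_chr = bdf[b_mask]
        b_anchor = anchors[b_mask.to_numpy()] if anchor == "tss" else None
        for arow in a_chr.itertuples(index=False):
            for k, brow in enumerate(b_chr.itertuples(index=False)):
                if anchor == "tss":
                    d = _interval_point_distance(arow.start, arow.end, int(b_anchor[k]))
                else:
                    d = _interval_interval_distance(
                        arow.start, arow.end, brow.start, brow.end
                    )
                if d <= window:
                    edges.append((arow.id, brow.id, 1.0))
    edges.sort()
    logger.info(
        "proximity links %s->%s: %d links (window %d, anchor %s)",
        layer_a, layer_b, len(edges), window, anchor,
    )
    return BipartiteLinks(layer_a, layer_b, edges)
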