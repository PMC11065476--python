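"""Readers and writers for the standard formats the pipeline touches.

Count matrices: MatrixMarket (with ``*_features.tsv`` / ``*_barcodes.tsv``
sidecars) or dense TSV (features x cells).  Coordinates: BED (0-based
half-open); gene tables as TSV (``gene  chrom  tss  strand`` or full
intervals) or GTF (1-based closed, converted at this boundary).  Motifs:
JASPAR PFM and MEME minimal via Bio.motifs.  Gene sets: GMT.  Layers,
bipartites, rankings and GRNs: 3-column TSV edge lists.

All writers use stable orderings and fixed float formatting, so pipeline
runs under a fixed seed are byte-reproducible end to end.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from Bio import motifs as bio_motifs

from .layers import CountMatrix
from .links import GenomicFeatureSet, MotifModel
from .model import BipartiteLinks, Layer, ValidationError
from .outputs import GRN
from .rwr import RankedResult

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------- matrices
def read_count_matrix(path: str | Path, fmt: str = "mtx", omic: str = "other") -> CountMatrix:
    """Read a feature x cell matrix.

    ``fmt="mtx"``: ``path`` is a prefix; ``<path>.mtx`` plus sidecars
    ``<path>_features.tsv`` and ``<path>_barcodes.tsv`` (one id per line)
    are required, with lengths matching the matrix dimensions.
    ``fmt="tsv"``: dense TSV with feature ids as the index column and cell
    ids as the header.
    """
    path = Path(path)
    if fmt == "mtx":
        X = sio.mmread(str(path) + ".mtx")
        features = Path(str(path) + "_features.tsv").read_text().split()
        cells = Path(str(path) + "_barcodes.tsv").read_text().split()
        if sp.issparse(X):
            X = np.asarray(X.todense())
        if X.shape != (len(features), len(cells)):
            raise ValidationError(
                f"matrix {X.shape} does not match sidecars "
                f"({len(features)} features, {len(cells)} barcodes)"
            )
        return CountMatrix(features, cells, X, omic)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            [str(i) for i in df.index], [str(c) for c in df.columns],
            df.to_numpy(dtype=float), omic,
        )
    raise ValidationError(f"unknown matrix format {fmt!r}")


def write_count_matrix(m: CountMatrix, path: str | Path, fmt: str = "mtx") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        sio.mmwrite(str(path) + ".mtx", sp.coo_matrix(m.X))
        Path(str(path) + "_features.tsv").write_text(
            "".join(f"{f}\n" for f in m.features)
        )
        Path(str(path) + "_barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in m.cells)
        )
    elif fmt == "tsv":
        pd.DataFrame(m.X, index=m.features, columns=m.cells).to_csv(
            path.with_suffix(".tsv") if path.suffix != ".tsv" else path,
            sep="\t", float_format=_FLOAT_FMT,
        )
    else:
        raise ValidationError(f"unknown matrix format {fmt!r}")


# ------------------------------------------------------------- coordinates
def read_bed(path: str | Path) -> GenomicFeatureSet:
    """BED: chrom, start, end[, name[, score[, strand]]]; strand defaults '.'.

    Features without a name column are named ``chrom:start-end``.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{ln}: BED needs >= 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else f"{chrom}:{start}-{end}"
        strand = parts[5] if len(parts) > 5 else "."
        rows.append((name, chrom, start, end, strand))
    return GenomicFeatureSet.from_records(rows)


def write_bed(feats: GenomicFeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in feats.frame.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand}\n")


def parse_interval_ids(ids: Iterable[str]) -> GenomicFeatureSet:
    """Parse ``chrom:start-end`` (or ``chrom-start-end``) peak ids into features."""
    rows = []
    for pid in ids:
        s = pid
        if ":" in s:
            chrom, rest = s.split(":", 1)
        else:
            chrom, rest = s.split("-", 1)
        start, end = rest.replace("-", "\t").split("\t")[:2]
        rows.append((pid, chrom, int(start), int(end), "."))
    return GenomicFeatureSet.from_records(rows)


def read_gene_table(path: str | Path) -> GenomicFeatureSet:
    """Gene annotation from TSV (columns gene/id, chrom, tss or start/end,
    strand) or GTF (gene features; 1-based closed, converted here)."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        rows = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].strip().strip(";").split(";")
                if kv.strip()
            )
            gid = attrs.get("gene_id", attrs.get("gene_name", "")).strip('"')
            rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
        return GenomicFeatureSet.from_records(rows)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    idc = cols.get("gene", cols.get("id"))
    if idc is None:
        raise ValidationError("gene table needs a 'gene' or 'id' column")
    if "start" in cols and "end" in cols:
        sub = df[[idc, cols["chrom"], cols["start"], cols["end"]]].copy()
        sub["strand"] = df[cols["strand"]] if "strand" in cols else "."
        sub.columns = ["id", "chrom", "start", "end", "strand"]
    else:
        tssc = cols.get("tss")
        if tssc is None:
            raise ValidationError("gene table needs tss or start/end columns")
        strand = df[cols["strand"]] if "strand" in cols else "."
        sub = pd.DataFrame(
            {
                "id": df[idc],
                "chrom": df[cols["chrom"]],
                "start": np.where(strand == "-", df[tssc] - 1, df[tssc]),
                "end": np.where(strand == "-", df[tssc] + 1, df[tssc] + 1),
                "strand": strand,
            }
        )
        # a TSS row becomes the 1-bp interval whose anchor reproduces the TSS
        sub.loc[sub["strand"] != "-", "end"] = sub.loc[sub["strand"] != "-", "start"] + 1
        sub.loc[sub["strand"] == "-", "start"] = sub.loc[sub["strand"] == "-", "end"] - 1
    return GenomicFeatureSet(sub)


def write_gene_table(genes: GenomicFeatureSet, path: str | Path) -> None:
    df = genes.frame.rename(columns={"id": "gene"})
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ fasta
def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ------------------------------------------------------------------ motifs
def _from_bio_motif(m, pseudocount: float) -> MotifModel:
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
    name = getattr(m, "name", None) or m.matrix_id
    mid = getattr(m, "matrix_id", None) or name
    return MotifModel(
        motif_id=str(mid),
        tf_names=tuple(str(name).split("::")),
        counts=counts,
        pseudocount=pseudocount,
    )


def read_motifs(path: str | Path, fmt: str = "jaspar", pseudocount: float = 0.8) -> list[MotifModel]:
    """Read motifs from JASPAR PFM (``fmt="jaspar"``) or MEME minimal
    (``fmt="meme"``) files."""
    fmt_map = {"jaspar": "jaspar", "meme": "minimal"}
    if fmt not in fmt_map:
        raise ValidationError(f"unknown motif format {fmt!r}")
    with open(path) as fh:
        records = bio_motifs.parse(fh, fmt_map[fmt])
        return [_from_bio_motif(m, pseudocount) for m in records]


def write_motifs_jaspar(motif_list: Sequence[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motif_list:
            fh.write(f">{m.motif_id}\t{'::'.join(m.tf_names)}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(_FLOAT_FMT % v for v in m.counts[bi])
                fh.write(f"{base} [ {vals} ]\n")


def motif_tf_map(motif_list: Sequence[MotifModel]) -> dict[str, tuple[str, ...]]:
    return {m.motif_id: m.tf_names for m in motif_list}


# --------------------------------------------------------------------- gmt
def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError("GMT lines need name, description, >=1 gene")
        out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sets[name])
            fh.write(f"{name}\tna\t{genes}\n")


# ------------------------------------------------------- layers and links
def write_edge_list(
    edges: Iterable[tuple[str, str, float]], path: str | Path,
    header: tuple[str, str, str] = ("source", "target", "weight"),
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for s, t, w in sorted(edges):
            fh.write(f"{s}\t{t}\t{_FLOAT_FMT % w}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r[0]), str(r[1]), float(r[2])) for r in df.itertuples(index=False)
    ]


def write_layer(layer: Layer, prefix: str | Path) -> None:
    """Edge list TSV plus node list TSV under a common prefix."""
    prefix = Path(prefix)
    write_edge_list(layer.edges, str(prefix) + "_edges.tsv")
    with open(str(prefix) + "_nodes.tsv", "w") as fh:
        fh.write("node\n")
        for n in sorted(layer.nodes):
            fh.write(f"{n}\n")


def read_layer(prefix: str | Path, name: str, directed: bool = False) -> Layer:
    nodes = pd.read_csv(str(prefix) + "_nodes.tsv", sep="\t")["node"].astype(str).tolist()
    edges = read_edge_list(str(prefix) + "_edges.tsv")
    return Layer(name=name, nodes=nodes, edges=edges, directed=directed)


def write_bipartite(bp: BipartiteLinks, path: str | Path) -> None:
    write_edge_list(bp.edges, path, header=(bp.layer_a, bp.layer_b, "weight"))


# --------------------------------------------------------------- rankings
def write_ranking(r: RankedResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tscore\trank\n")
        for i, (n, s) in enumerate(zip(r.nodes, r.scores), 1):
            fh.write(f"{n}\t{_FLOAT_FMT % s}\t{i}\n")


def write_rankings(rankings: Mapping[str, RankedResult], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for seed_node in sorted(rankings):
        write_ranking(rankings[seed_node], outdir / f"{seed_node}.tsv")


def write_grn(g: GRN, path: str | Path) -> None:
    g.edges.sort_values(["tf", "gene"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_grn(path: str | Path, tfs=None, genes=None) -> GRN:
    edges = pd.read_csv(path, sep="\t")
    return GRN(
        edges=edges,
        tfs=sorted(edges["tf"].unique()) if tfs is None else list(tfs),
        genes=sorted(edges["gene"].unique()) if genes is None else list(genes),
    )


def read_seeds(path: str | Path) -> dict[str, float]:
    """Seed file: one node per line, optional second column with mass."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        out[parts[0]] = float(parts[1]) if len(parts) > 1 else 1.0
    return out


def read_ground_truth_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (e.g. tf<TAB>gene) into a source -> targets map."""
    df = pd.read_csv(path, sep="\t")
    a, b = df.columns[:2]
    return {k: set(sub[b]) for k, sub in df.groupby(a)}
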