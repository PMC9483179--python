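"""Window significant SNPs and intersect with gene and QTL interval tables.

Significant variants are extended by a flank (150 kb by default) on both
sides; genes whose intervals intersect a window are candidate genes, and
overlaps with classified QTL intervals (< 1 Mb) are counted per trait-DIM
cell and QTL class.  Coordinates are 1-based inclusive internally (VCF/GFF
convention); BED input (0-based half-open) is shifted on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

DEFAULT_FLANK_BP = 150_000
QTL_CLASSES = ("Exterior", "Health", "Milk", "Production", "Reproduction")
MAX_QTL_SPAN_BP = 1_000_000


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    source_snp: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("window must satisfy 1 <= start <= end")


def make_windows(variants: pd.DataFrame, flank: int = DEFAULT_FLANK_BP):
    """±flank windows around variants (DataFrame with chrom/pos/id columns);
    starts are clipped at 1."""
    return [
        GenomicWindow(str(v.chrom), max(1, int(v.pos) - flank), int(v.pos) + flank,
                      str(v.id))
        for v in variants.itertuples(index=False)
    ]


def read_gene_table(path, fmt: str = "auto") -> pd.DataFrame:
    """Gene intervals as chrom/start/end/name, 1-based inclusive.

    ``fmt``: "bed" (0-based half-open, converted), "tsv" (already 1-based) or
    "auto" (by file extension)."""
    if fmt == "auto":
        fmt = "bed" if str(path).endswith(".bed") else "tsv"
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "name"]
    df["chrom"] = df["chrom"].astype(str)
    if fmt == "bed":
        df["start"] = df["start"] + 1  # 0-based half-open -> 1-based inclusive
    return df


def read_qtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "qtl_class", "name"}
    if not need.issubset(df.columns):
        raise ValueError(f"QTL table must have columns {sorted(need)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def _valid_intervals(table: pd.DataFrame):
    import warnings

    bad = table["start"] > table["end"]
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} malformed interval(s) (start > end)")
    return table[~bad]


def overlap_genes(windows, gene_table: pd.DataFrame):
    """Genes intersecting each window (closed intervals).

    Returns a DataFrame with one row per window: the overlapping gene names,
    and for empty windows the nearest gene and its distance (bp).
    """
    genes = _valid_intervals(gene_table)
    trees: dict = {}
    for g in genes.itertuples(index=False):
        # +1 on end: IntervalTree is half-open, our intervals are inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.name)
    rows = []
    for w in windows:
        tree = trees.get(w.chrom)
        hits = sorted(iv.data for iv in tree.overlap(w.start, w.end + 1)) if tree else []
        nearest, dist = None, None
        if not hits:
            sub = genes[genes["chrom"] == w.chrom]
            if len(sub):
                d = np.maximum(sub["start"] - w.end, w.start - sub["end"]).clip(lower=0)
                i = d.idxmin()
                nearest, dist = genes.loc[i, "name"], int(d.loc[i])
        rows.append(
            {
                "snp_id": w.source_snp,
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "genes": ",".join(hits),
                "n_genes": len(hits),
                "nearest_gene": nearest,
                "nearest_distance": dist,
            }
        )
    out = pd.DataFrame(rows)
    all_genes = set()
    for g in out["genes"]:
        if g:
            all_genes.update(g.split(","))
    return out, len(all_genes)


def overlap_qtls(windows_by_cell: dict, qtl_table: pd.DataFrame) -> pd.DataFrame:
    """Count matrix (trait-DIM cell) x (QTL class).

    ``windows_by_cell`` maps a cell label (e.g. "MY-D7") to its windows.  A
    SNP whose window overlaps at least one QTL of a class counts once for
    that class; one SNP may count in several classes.  QTLs spanning >= 1 Mb
    are excluded first.
    """
    qtls = _valid_intervals(qtl_table)
    unknown = set(qtls["qtl_class"]) - set(QTL_CLASSES)
    if unknown:
        raise ValueError(f"unknown QTL class label(s): {sorted(unknown)}")
    span_ok = (qtls["end"] - qtls["start"] + 1) <= MAX_QTL_SPAN_BP
    qtls = qtls[span_ok]
    trees: dict = {}
    for q in qtls.itertuples(index=False):
        trees.setdefault((q.chrom, q.qtl_class), IntervalTree()).addi(
            q.start, q.end + 1, q.name
        )
    out = pd.DataFrame(0, index=list(windows_by_cell), columns=list(QTL_CLASSES))
    for cell, windows in windows_by_cell.items():
        for w in windows:
            for cls in QTL_CLASSES:
                tree = trees.get((w.chrom, cls))
                if tree and tree.overlap(w.start, w.end + 1):
                    out.loc[cell, cls] += 1
    return out
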