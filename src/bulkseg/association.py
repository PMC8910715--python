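"""Candidate-interval x differential-expression association.

Intersects candidate intervals from the bulked-segregant scan with gene
models, tallies DEG direction inside the intervals, reports the summary
percentages, and runs generic hypergeometric over-representation over
user-supplied gene sets.  All coordinates are 1-based inclusive bp.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .rnaseq import bh_adjust
from .util import round_half_up

__all__ = [
    "intersect_genes_intervals",
    "percent",
    "tally_direction",
    "hypergeometric_enrichment",
]


def intersect_genes_intervals(
    genes: pd.DataFrame,
    intervals,
    rule: str = "overlap",
) -> list[list[str]]:
    """Per-interval gene lists under the any-overlap rule.

    A gene belongs to an interval iff they share >= 1 bp (1-based inclusive:
    ``gene.start <= iv.end and gene.end >= iv.start``).  With
    ``rule='start'`` membership instead requires the gene start to lie inside
    the interval.  A gene may appear in several intervals; callers
    de-duplicate for totals.
    """
    if rule not in ("overlap", "start"):
        raise ValueError("rule must be 'overlap' or 'start'")
    ivs = [
        (iv.chrom, iv.start, iv.end) if hasattr(iv, "chrom") else (iv[0], int(iv[1]), int(iv[2]))
        for iv in intervals
    ]
    gene_chrom = genes["chrom"].to_numpy()
    gs = genes["start"].to_numpy(np.int64)
    ge = genes["end"].to_numpy(np.int64)
    gid = genes["gene_id"].to_numpy()
    if ivs and not (set(c for c, _, _ in ivs) & set(gene_chrom)):
        warnings.warn("no chromosome names shared between genes and intervals", stacklevel=2)
    out = []
    for chrom, start, end in ivs:
        same = gene_chrom == chrom
        if rule == "overlap":
            hit = same & (gs <= end) & (ge >= start)
        else:
            hit = same & (gs >= start) & (gs <= end)
        out.append(list(gid[hit]))
    return out


def percent(numerator: int, denominator: int) -> float:
    """100 x num/den rounded half-up to two decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, 2)


def tally_direction(
    statuses: pd.Series,
    interval_genes: list[list[str]],
) -> pd.DataFrame:
    """Up/down/ns/filtered DEG counts per interval plus a de-duplicated union.

    ``statuses`` maps gene id -> status from the DE stage.  The last row
    ("union") counts each gene once even if it overlaps several intervals.
    ``pct_up`` is the share of up-regulated among (up + down) DEGs, NA where
    an interval holds no DEG.
    """
    rows = []
    union: set = set()
    for i, members in enumerate(interval_genes):
        union.update(members)
        rows.append(_one_tally(f"interval_{i + 1}", members, statuses))
    rows.append(_one_tally("union", sorted(union), statuses))
    return pd.DataFrame(rows)


def _one_tally(name: str, members, statuses: pd.Series) -> dict:
    st = statuses.reindex(members)
    up = int((st == "up").sum())
    down = int((st == "down").sum())
    ns = int((st == "ns").sum())
    filt = int((st == "filtered").sum())
    degs = up + down
    return {
        "interval": name,
        "genes": len(members),
        "degs": degs,
        "up": up,
        "down": down,
        "ns": ns,
        "filtered": filt,
        "pct_up": percent(up, degs) if degs else np.nan,
    }


def hypergeometric_enrichment(
    deg_set,
    gene_sets: dict,
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    For a universe of N genes, a draw of n DEGs and a set of K genes with k
    in the overlap, p = P(X >= k) for X ~ Hypergeom(N, K, n); BH-adjusted
    across sets.  Every set (and the DEG list) must be contained in the
    universe.
    """
    uni = set(universe)
    degs = set(deg_set)
    if not degs <= uni:
        raise ValueError("DEG set not contained in the universe")
    big_n, n_draw = len(uni), len(degs)
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        if not members <= uni:
            raise ValueError(f"gene set {name!r} not contained in the universe")
        k = len(members & degs)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(members), n_draw)) if members else 1.0
        rows.append({"set": name, "set_size": len(members), "overlap": k, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
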