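"""Bulked-segregant QTL-seq scan: SNP-index, Δ(SNP-index), loess, thresholds.

The scan statistic at each SNP is the SNP-index of each pool,
``M / (M + P)`` with M and P the read counts of the maternal (recurrent,
dwarf) and paternal (donor) alleles, and their difference
``Δ = index(dwarf) − index(tall)``.  At loci unlinked to the trait both
pools are drawn from the same BC_n genotype distribution and Δ ≈ 0; at a
recessive causal locus the dwarf pool is fixed for the maternal allele
(index 1) while the tall pool is uniformly heterozygous (index 0.5), so
Δ → 0.5.  Δ is smoothed along physical position by a tricube-weighted local
linear fit and compared against per-depth null quantiles obtained by
simulating pool composition and read sampling under the no-QTL model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import round_half_up

__all__ = [
    "CandidateInterval",
    "filter_informative_snps",
    "compute_snp_index",
    "compute_delta_index",
    "compute_index_track",
    "loess_fit",
    "smooth_delta",
    "simulate_null_thresholds",
    "threshold_at_depth",
    "call_candidate_intervals",
    "total_interval_span",
]


@dataclass(frozen=True)
class CandidateInterval:
    """A genomic segment whose smoothed Δ(SNP-index) exceeds the null threshold.

    Coordinates are 1-based inclusive bp; endpoints are the first and last
    SNP positions of the supporting run.
    """

    chrom: str
    start: int
    end: int
    n_snps: int
    peak_delta: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    @property
    def span_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------


def filter_informative_snps(
    records: pd.DataFrame, min_depth: int = 10, max_depth: int = 200
) -> pd.DataFrame:
    """Keep biallelic parent-polymorphic sites with both pool depths in range.

    Sites flagged missing, monomorphic between the parents (REF == ALT), or
    with either pool's total depth outside ``[min_depth, max_depth]`` are
    dropped.  These criteria follow common QTL-seq practice.
    """
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    d_tall = records["M_tall"] + records["P_tall"]
    d_dwarf = records["M_dwarf"] + records["P_dwarf"]
    keep = (
        ~records["missing"].astype(bool)
        & (records["ref"] != records["alt"])
        & d_tall.between(min_depth, max_depth)
        & d_dwarf.between(min_depth, max_depth)
    )
    return records.loc[keep].reset_index(drop=True)


def compute_snp_index(m, p):
    """SNP-index = M / (M + P); missing (NaN) where the site has no reads."""
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(m < 0) or np.any(p < 0):
        raise ValueError("allele depths must be non-negative")
    tot = m + p
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(tot > 0, m / np.where(tot > 0, tot, 1), np.nan)
    return idx if idx.ndim else float(idx)


def compute_delta_index(index_dwarf, index_tall):
    """Δ(SNP-index) = index(dwarf) − index(tall); missing propagates."""
    return np.asarray(index_dwarf, dtype=float) - np.asarray(index_tall, dtype=float)


def compute_index_track(records: pd.DataFrame) -> pd.DataFrame:
    """Augment a SnpRecord table with both SNP-indices and Δ."""
    out = records.copy()
    out["snp_index_tall"] = compute_snp_index(out["M_tall"], out["P_tall"])
    out["snp_index_dwarf"] = compute_snp_index(out["M_dwarf"], out["P_dwarf"])
    out["delta"] = compute_delta_index(out["snp_index_dwarf"], out["snp_index_tall"])
    return out


# ---------------------------------------------------------------------------
# loess smoothing
# ---------------------------------------------------------------------------


def _loess_windows(x: np.ndarray, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour index matrix (n, k) and tricube weights for sorted x."""
    n = len(x)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted")
    k = min(max(int(np.ceil(span * n)), 3), n)
    # contiguous nearest-neighbour windows via two pointers
    left = np.empty(n, dtype=np.intp)
    l = 0
    for i in range(n):
        while l + k < n and x[i] - x[l] > x[l + k] - x[i]:
            l += 1
        left[i] = l
    cols = left[:, None] + np.arange(k)[None, :]
    d = np.abs(x[cols] - x[:, None])
    h = d.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(h > 0, d / np.where(h > 0, h, 1), 0.0)
    w = np.clip(1.0 - u**3, 0.0, None) ** 3
    return cols, w


def loess_operator(x: np.ndarray, span: float = 0.1):
    """Sparse linear operator S with (S @ y) the loess fit of complete y.

    The degree-1 fit is linear in the responses, so for fixed positions the
    whole smooth is one sparse matrix-vector product; used to smooth many
    simulated null tracks at once.
    """
    from scipy import sparse

    x = np.asarray(x, dtype=float)
    n = len(x)
    cols, w = _loess_windows(x, span)
    xw = x[cols]
    sw = w.sum(axis=1)
    xbar = (w * xw).sum(axis=1) / sw
    dx = xw - xbar[:, None]
    sxx = (w * dx * dx).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = w / sw[:, None] + np.where(sxx > 0, (x - xbar) / np.where(sxx > 0, sxx, 1), 0.0)[
            :, None
        ] * w * dx
    rows = np.repeat(np.arange(n), cols.shape[1])
    return sparse.csr_matrix((coef.ravel(), (rows, cols.ravel())), shape=(n, n))


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.1) -> np.ndarray:
    """Tricube-weighted local linear (degree-1 loess) fit evaluated at every x.

    For each point, the ``k = ceil(span * n)`` nearest neighbours (a
    contiguous window, since x is sorted) receive tricube weights
    ``(1 − (d/h)³)³`` with h the window half-width, and a weighted straight
    line is solved in closed form.  Local linear fits reproduce any globally
    linear signal exactly.  NaN responses are dropped from the local fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    cols, w = _loess_windows(x, span)
    xw = x[cols]  # (n, k) neighbour positions
    yw = y[cols]

    good = np.isfinite(yw)
    w = np.where(good, w, 0.0)
    yw = np.where(good, yw, 0.0)

    sw = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = (w * xw).sum(axis=1) / sw
        ybar = (w * yw).sum(axis=1) / sw
    dx = xw - xbar[:, None]
    sxx = (w * dx * dx).sum(axis=1)
    sxy = (w * dx * (yw - ybar[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1), 0.0)
    fit = ybar + slope * (x - xbar)
    fit[sw == 0] = np.nan
    return fit


def smooth_delta(track: pd.DataFrame, span: float = 0.1) -> pd.DataFrame:
    """Per-chromosome loess of Δ over physical position.

    Chromosomes with fewer than five usable SNPs are skipped with a warning
    (smoothed values NaN); smoothing never crosses a chromosome boundary.
    """
    out = track.copy()
    out["smoothed_delta"] = np.nan
    for chrom, sub in out.groupby("chrom", sort=False):
        usable = sub["delta"].notna()
        if usable.sum() < max(5, int(np.ceil(span * len(sub)))):
            warnings.warn(f"{chrom}: too few SNPs to smooth, skipped", stacklevel=2)
            continue
        sub = sub.sort_values("pos")
        fit = loess_fit(sub["pos"].to_numpy(float), sub["delta"].to_numpy(float), span)
        out.loc[sub.index, "smoothed_delta"] = fit
    return out


# ---------------------------------------------------------------------------
# null thresholds (two-level simulation)
# ---------------------------------------------------------------------------


def _null_bulk_haplotypes(
    n_lineages: int,
    positions: np.ndarray,
    rate_cm_per_mb: float,
    generation: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Donor-carrier indicators for independent no-QTL BC_n lineages.

    Each lineage starts from a fully donor haplotype (the F1's) and loses
    donor material through ``generation`` meioses against the recurrent
    parent (Haldane crossovers, no selection).  Returns an
    (n_lineages, n_markers) boolean array: True where the BC_n individual is
    heterozygous.  Marginal het probability is (1/2)^generation with the
    segmental correlation real backcross genomes carry.
    """
    m = len(positions)
    # cumulative genetic position (Morgans); Haldane = Poisson crossovers
    g = np.concatenate(([0.0], np.cumsum(np.diff(positions) / 1e6 * rate_cm_per_mb / 100.0)))
    total = g[-1]
    hap = np.ones((n_lineages, m), dtype=bool)
    for _ in range(generation):
        start = rng.random(n_lineages) < 0.5
        n_xo = rng.poisson(total, size=n_lineages)
        alive = hap.any(axis=1)
        has_xo = (n_xo > 0) & alive
        # without crossovers the gamete is one whole parental haplotype
        hap[~has_xo & ~start] = False
        rows = np.flatnonzero(has_xo)
        if len(rows):
            flips = np.zeros((len(rows), m), dtype=np.int8)
            counts = n_xo[rows]
            ev_row = np.repeat(np.arange(len(rows)), counts)
            ev_pos = rng.random(counts.sum()) * total
            ev_idx = np.searchsorted(g, ev_pos, side="left")
            inside = ev_idx < m
            np.add.at(flips, (ev_row[inside], ev_idx[inside]), 1)
            parity = np.cumsum(flips, axis=1) % 2 == 1
            orig = parity != start[rows, None]
            hap[rows] &= orig
    return hap


def null_delta_tracks(
    n_tall: int,
    n_dwarf: int,
    depth: int,
    generation: int,
    reps: int,
    rng: np.random.Generator,
    positions: np.ndarray,
    rate_cm_per_mb: float = 2.0,
    het_tall: np.ndarray | None = None,
    het_dwarf: np.ndarray | None = None,
) -> np.ndarray:
    """Δ(SNP-index) tracks under the no-QTL null: (reps, n_markers).

    Two-level sampling: bulk members drawn from the BC_n genotype
    distribution (independent lineages, so marker-to-marker correlation
    follows real donor segments), then maternal read counts
    Binomial(depth, pool 'M' frequency) in each pool.  Precomputed het
    indicator arrays may be passed to reuse one cohort across read depths.
    """
    if het_tall is None:
        het_tall = _null_bulk_haplotypes(reps * n_tall, positions, rate_cm_per_mb, generation, rng)
    if het_dwarf is None:
        het_dwarf = _null_bulk_haplotypes(
            reps * n_dwarf, positions, rate_cm_per_mb, generation, rng
        )
    m = len(positions)
    h_t = het_tall.reshape(reps, n_tall, m).sum(axis=1)
    h_d = het_dwarf.reshape(reps, n_dwarf, m).sum(axis=1)
    f_t = 1.0 - h_t / (2 * n_tall)  # pool 'M' frequency
    f_d = 1.0 - h_d / (2 * n_dwarf)
    # draw reads only where a pool actually segregates (f < 1 -> index < 1)
    idx_t = np.ones_like(f_t)
    seg = f_t < 1.0
    idx_t[seg] = rng.binomial(depth, f_t[seg]) / depth
    idx_d = np.ones_like(f_d)
    seg = f_d < 1.0
    idx_d[seg] = rng.binomial(depth, f_d[seg]) / depth
    return idx_d - idx_t


def simulate_null_thresholds(
    n_tall: int,
    n_dwarf: int,
    depths: np.ndarray,
    generation: int = 8,
    confidence_levels: tuple[float, ...] = (0.95, 0.99),
    reps: int = 1_000,
    rng: np.random.Generator | None = None,
    positions: dict[str, np.ndarray] | np.ndarray | None = None,
    rate_cm_per_mb: float = 2.0,
    span: float = 0.1,
) -> pd.DataFrame:
    """Per-depth thresholds for the smoothed Δ scan under the no-QTL null.

    For each replicate a whole no-QTL cohort is simulated (both pools drawn
    from the BC_n genotype distribution as independent lineages over the
    marker map, then binomial reads at each depth), its Δ track is smoothed
    with the same loess used for the data, and the genome-wide maximum is
    recorded.  The threshold at each confidence level is the corresponding
    quantile of that maximum, so exceeding it anywhere in a null genome has
    probability ~(1 − level) per scan.  In a BC_n the per-marker Δ null is
    nearly degenerate (both pools fixed for the recurrent allele at most
    markers), so raw per-marker quantiles would be useless; the max of the
    smoothed statistic is what interval calling actually thresholds.
    Thresholds are made monotone non-increasing in depth (read noise only
    shrinks with coverage), which also irons out Monte-Carlo jitter.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for stable quantiles")
    if rng is None:
        rng = np.random.default_rng()
    if positions is None:
        positions = {"null": np.arange(15_000, 24_000_001, 15_000, dtype=np.int64)}
    if isinstance(positions, np.ndarray):
        positions = {"null": positions}
    depths = np.sort(np.asarray(depths, dtype=int))

    maxima = np.full((len(depths), reps), -np.inf)
    for pos in positions.values():
        pos = np.asarray(pos, dtype=np.int64)
        het_t = _null_bulk_haplotypes(reps * n_tall, pos, rate_cm_per_mb, generation, rng)
        het_d = _null_bulk_haplotypes(reps * n_dwarf, pos, rate_cm_per_mb, generation, rng)
        smoother = loess_operator(pos.astype(float), span)
        for i, d in enumerate(depths):
            delta = null_delta_tracks(
                n_tall, n_dwarf, int(d), generation, reps, rng, pos,
                rate_cm_per_mb, het_tall=het_t, het_dwarf=het_d,
            )
            smoothed = (smoother @ delta.T).T
            np.maximum(maxima[i], smoothed.max(axis=1), out=maxima[i])

    rows = []
    for i, d in enumerate(depths):
        rows.append([int(d)] + [float(np.quantile(maxima[i], q)) for q in confidence_levels])
    table = pd.DataFrame(rows, columns=["depth"] + [f"q{q:g}" for q in confidence_levels])
    for q in confidence_levels:
        col = f"q{q:g}"
        table[col] = np.minimum.accumulate(table[col].to_numpy())
    return table


def threshold_at_depth(table: pd.DataFrame, depth, level: float = 0.95) -> np.ndarray:
    """Linear interpolation of the threshold table at arbitrary depths."""
    col = f"q{level:g}"
    if col not in table.columns:
        raise KeyError(f"no thresholds at confidence level {level}")
    return np.interp(np.asarray(depth, dtype=float), table["depth"], table[col])


# ---------------------------------------------------------------------------
# interval calling
# ---------------------------------------------------------------------------


def call_candidate_intervals(
    track: pd.DataFrame,
    thresholds: pd.DataFrame,
    min_snps: int = 10,
    merge_gap: int = 100_000,
    level: float = 0.95,
) -> list[CandidateInterval]:
    """Maximal runs of SNPs whose smoothed Δ clears the per-depth threshold.

    Each SNP is compared against the threshold interpolated at the smaller of
    its two pool depths (conservative).  Runs on the same chromosome closer
    than ``merge_gap`` bp are merged, then runs supported by fewer than
    ``min_snps`` above-threshold SNPs are dropped.  Interval endpoints are
    the first and last supporting SNP positions.
    """
    intervals: list[CandidateInterval] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        sm = sub["smoothed_delta"].to_numpy(float)
        d_min = np.minimum(
            sub["M_tall"].to_numpy() + sub["P_tall"].to_numpy(),
            sub["M_dwarf"].to_numpy() + sub["P_dwarf"].to_numpy(),
        )
        thr = threshold_at_depth(thresholds, d_min, level)
        above = np.where(np.isfinite(sm), sm >= thr, False)
        if not above.any():
            continue
        # maximal runs of consecutive above-threshold SNPs
        edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
        runs = [(s, e - 1) for s, e in zip(edges[::2], edges[1::2])]
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if pos[s] - pos[merged[-1][1]] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            support = int(above[s : e + 1].sum())
            if support < min_snps:
                continue
            intervals.append(
                CandidateInterval(
                    chrom=str(chrom),
                    start=int(pos[s]),
                    end=int(pos[e]),
                    n_snps=support,
                    peak_delta=float(np.nanmax(sm[s : e + 1])),
                )
            )
    return intervals


def total_interval_span(intervals) -> float:
    """Total genomic span of the interval union, in Mb (two decimals, half-up).

    Overlapping intervals are unioned per chromosome before summing
    ``end − start``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if isinstance(iv, CandidateInterval):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        else:
            chrom, start, end = iv
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return round_half_up(total / 1e6, 2)
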