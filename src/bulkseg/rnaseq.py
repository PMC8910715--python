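"""Differential expression and expression profiling.

Implements a fully specified, self-contained negative-binomial Wald test
(median-of-ratios size factors, pooled method-of-moments dispersion,
0.5 pseudo-count) so DE calls are reproducible from the count matrix alone,
plus FPKM quantification, the DEG filters, K-means profile clustering and
qPCR 2^-ddCt concordance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_fpkm",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "classify_degs",
    "zscore_profiles",
    "kmeans_cluster",
    "delta_delta_ct",
    "qpcr_fold_changes",
    "qpcr_concordance",
]


def compute_fpkm(counts, gene_lengths, total_fragments):
    """FPKM = count / ((length/1e3) x (library/1e6)).

    ``counts`` may be a vector (one sample) or a genes x samples DataFrame
    with ``total_fragments`` per sample (defaults to the column sums when a
    DataFrame is given and totals are omitted).
    """
    if isinstance(counts, pd.DataFrame):
        totals = (
            counts.sum(axis=0) if total_fragments is None else pd.Series(total_fragments)
        )
        if (totals <= 0).any():
            raise ValueError("library size must be positive")
        lengths = np.asarray(gene_lengths, dtype=float)
        if np.any(lengths <= 0):
            raise ValueError("gene lengths must be positive")
        return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(np.asarray(total_fragments, dtype=float) <= 0):
        raise ValueError("library size must be positive")
    return np.asarray(counts, dtype=float) / ((lengths / 1e3) * (total_fragments / 1e6))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    For genes with nonzero counts in every sample, factor_j is the median of
    count_gj / geometric-mean_g.  Factors are used as computed (no
    re-centring).
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene with nonzero counts in all samples")
    sub = mat[all_nonzero]
    log_gm = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_gm)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test of dwarf vs tall means.

    Counts are divided by the size factors; per gene the two group means
    mu_t, mu_d and a pooled method-of-moments dispersion
    ``alpha = max(0, (s^2 − mu_bar) / mu_bar^2)`` are computed (s^2 the pooled
    within-group variance, mu_bar the mean of the group means).  The
    log2 fold-change is ``log2((mu_d + 0.5) / (mu_t + 0.5))`` and the Wald
    statistic is the natural-log fold-change over its delta-method standard
    error ``SE^2 = (1/n_t)(1/mu_t' + alpha) + (1/n_d)(1/mu_d' + alpha)``,
    where the primed means carry the same 0.5 pseudo-count so all-zero groups
    never divide by zero.  Two-sided p from the standard normal.
    """
    groups = pd.Series(groups)
    if set(groups.unique()) != {"tall", "dwarf"}:
        raise ValueError("groups must label each sample 'tall' or 'dwarf'")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    t_cols = (groups.reindex(counts.columns) == "tall").to_numpy()
    d_cols = ~t_cols
    n_t, n_d = int(t_cols.sum()), int(d_cols.sum())
    if n_t < 2 or n_d < 2:
        raise ValueError("each group needs >= 2 replicates")

    mu_t = norm[:, t_cols].mean(axis=1)
    mu_d = norm[:, d_cols].mean(axis=1)
    ss = (
        ((norm[:, t_cols] - mu_t[:, None]) ** 2).sum(axis=1)
        + ((norm[:, d_cols] - mu_d[:, None]) ** 2).sum(axis=1)
    )
    s2 = ss / (n_t + n_d - 2)
    mu_bar = 0.5 * (mu_t + mu_d)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(mu_bar > 0, (s2 - mu_bar) / np.where(mu_bar > 0, mu_bar, 1) ** 2, 0.0)
    alpha = np.clip(alpha, 0.0, None)

    mu_t5, mu_d5 = mu_t + 0.5, mu_d + 0.5
    ln_fc = np.log(mu_d5 / mu_t5)
    se = np.sqrt((1.0 / n_t) * (1.0 / mu_t5 + alpha) + (1.0 / n_d) * (1.0 / mu_d5 + alpha))
    z = ln_fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "mu_tall": mu_t,
            "mu_dwarf": mu_d,
            "dispersion": alpha,
            "log2fc": ln_fc / np.log(2.0),
            "wald_z": z,
            "pvalue": p,
        },
        index=counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_degs(
    de: pd.DataFrame,
    fpkm: pd.DataFrame,
    lfc_cutoff: float = 1.0,
    padj_cutoff: float = 0.05,
    fpkm_min: float = 1.0,
    filter_rule: str = "any",
) -> pd.DataFrame:
    """Apply the DEG designation rules.

    Genes with FPKM below ``fpkm_min`` in any sample (or, with
    ``filter_rule='all'``, in every sample) are excluded from testing
    (status ``filtered``); the rest are ``up`` / ``down`` when
    |log2FC| >= cutoff and padj <= cutoff, else ``ns``.  Adds ``padj`` and
    ``status`` columns.
    """
    if filter_rule not in ("any", "all"):
        raise ValueError("filter_rule must be 'any' or 'all'")
    out = de.copy()
    low = fpkm.reindex(out.index) < fpkm_min
    excluded = low.any(axis=1) if filter_rule == "any" else low.all(axis=1)
    out["padj"] = np.nan
    tested = ~excluded
    out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    status = np.full(len(out), "ns", dtype=object)
    status[excluded.to_numpy()] = "filtered"
    up = tested & (out["log2fc"] >= lfc_cutoff) & (out["padj"] <= padj_cutoff)
    down = tested & (out["log2fc"] <= -lfc_cutoff) & (out["padj"] <= padj_cutoff)
    status[up.to_numpy()] = "up"
    status[down.to_numpy()] = "down"
    out["status"] = status
    return out


def zscore_profiles(fpkm: pd.DataFrame, genes) -> pd.DataFrame:
    """Per-gene z-scores of log2(FPKM + 1) across the six samples."""
    x = np.log2(fpkm.loc[genes] + 1.0)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0).replace(0.0, 1.0)
    return x.sub(mu, axis=0).div(sd, axis=0)


def kmeans_cluster(
    profiles: pd.DataFrame,
    groups: pd.Series | dict,
    k: int = 6,
    seed: int = 0,
    restarts: int = 10,
) -> pd.DataFrame:
    """Euclidean K-means of DEG expression profiles, deterministic labels.

    Best of ``restarts`` k-means++ runs by within-cluster sum of squares.
    Clusters are relabelled 1..k by decreasing centroid (dwarf − tall) mean
    difference, so low-numbered clusters are up-regulated in dwarf plants.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least {k} genes to form {k} clusters")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(profiles.to_numpy(dtype=float))
    groups = pd.Series(groups).reindex(profiles.columns)
    d_cols = (groups == "dwarf").to_numpy()
    centers = km.cluster_centers_
    diff = centers[:, d_cols].mean(axis=1) - centers[:, ~d_cols].mean(axis=1)
    order = np.argsort(-diff, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return pd.DataFrame({"cluster": relabel[raw]}, index=profiles.index)


def delta_delta_ct(ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
    """Relative expression 2^-ddCt of case vs control."""
    ddct = (np.asarray(ct_target_case, dtype=float) - np.asarray(ct_ref_case, dtype=float)) - (
        np.asarray(ct_target_ctrl, dtype=float) - np.asarray(ct_ref_ctrl, dtype=float)
    )
    return 2.0 ** (-ddct)


def qpcr_fold_changes(ct_table: pd.DataFrame) -> pd.Series:
    """Per-gene log2 fold-change (dwarf vs tall) from replicate-mean Cts."""
    means = ct_table.groupby(["gene_id", "group"])[["ct_target", "ct_reference"]].mean()
    genes = means.index.get_level_values("gene_id").unique()
    out = {}
    for g in genes:
        d = means.loc[(g, "dwarf")]
        t = means.loc[(g, "tall")]
        rel = delta_delta_ct(d["ct_target"], d["ct_reference"], t["ct_target"], t["ct_reference"])
        out[g] = float(np.log2(rel))
    return pd.Series(out, name="qpcr_log2fc")


def qpcr_concordance(qpcr_log2fc, rnaseq_log2fc) -> float:
    """Squared Pearson correlation between paired qPCR and RNA-seq log2FCs."""
    a = np.asarray(qpcr_log2fc, dtype=float)
    b = np.asarray(rnaseq_log2fc, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired fold-changes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a fold-change vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
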