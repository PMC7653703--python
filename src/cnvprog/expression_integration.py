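"""Differential expression, signal-to-noise ranking and preranked GSEA.

Expression input is a genes x samples matrix of non-negative linear-scale
intensities with a binary phenotype (recurrent vs non-recurrent). Fold
changes are ratios of group means on the linear scale, sign-encoded so
that -x denotes a 1/x ratio (down in recurrent); t-tests run on log2
values. Gene ranking uses the signal-to-noise metric
(mu_rec - mu_non) / (sigma_rec + sigma_non) with the canonical GSEA
variance floor. Enrichment is a weighted Kolmogorov-Smirnov running sum
with a seeded gene-set permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "differential_expression",
    "signal_to_noise_ranking",
    "enrichment_score",
    "gsea_preranked",
    "integrate_cnv_expression",
    "read_gmt",
]


def _split_groups(expr: pd.DataFrame, groups: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    g = groups.reindex(expr.columns)
    rec = expr.loc[:, (g == 1).to_numpy()]
    non = expr.loc[:, (g == 0).to_numpy()]
    if rec.shape[1] < 2 or non.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    return rec, non


def differential_expression(
    expr: pd.DataFrame,
    groups: pd.Series,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Fold change + Student t-test per gene.

    ``groups`` maps sample -> 1 (recurrent) / 0 (non-recurrent). The DE
    flag requires |signed fold change| >= ``fc_threshold`` (inclusive)
    and t-test p <= ``p_threshold`` (inclusive). Genes whose reference
    group mean is zero get an infinite-fold-change flag and are excluded
    from the DE set.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    rec, non = _split_groups(expr, groups)
    m_rec = rec.mean(axis=1).to_numpy()
    m_non = non.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m_rec / m_non
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    t_stat, p = stats.ttest_ind(
        np.log2(rec.to_numpy() + 1e-9), np.log2(non.to_numpy() + 1e-9),
        axis=1, equal_var=equal_var,
    )
    infinite = ~np.isfinite(ratio) | (m_non == 0) | (m_rec == 0)
    de = (~infinite) & (np.abs(signed) >= fc_threshold) & (p <= p_threshold)
    return pd.DataFrame({
        "fold_change": signed,
        "t_stat": t_stat,
        "p_value": p,
        "de_flag": de,
        "flag": np.where(infinite, "infinite_fc", ""),
    }, index=expr.index)


def signal_to_noise_ranking(
    expr: pd.DataFrame,
    groups: pd.Series,
    variance_floor: bool = True,
) -> pd.Series:
    """Genes ranked (descending) by the signal-to-noise metric.

    Each group's sd is floored at 0.2 * |mean| (0.2 absolute when the mean
    is zero), the convention of the canonical GSEA implementation, keeping
    the metric finite for near-constant genes. Ties are broken by gene id
    so the order is total and reproducible.
    """
    rec, non = _split_groups(expr, groups)
    mu_r, mu_n = rec.mean(axis=1).to_numpy(), non.mean(axis=1).to_numpy()
    sd_r = rec.std(axis=1, ddof=1).to_numpy()
    sd_n = non.std(axis=1, ddof=1).to_numpy()
    if variance_floor:
        sd_r = np.maximum(sd_r, np.where(mu_r != 0, 0.2 * np.abs(mu_r), 0.2))
        sd_n = np.maximum(sd_n, np.where(mu_n != 0, 0.2 * np.abs(mu_n), 0.2))
    elif np.any(sd_r + sd_n == 0):
        raise ValueError("zero denominator; enable the variance floor")
    s2n = (mu_r - mu_n) / (sd_r + sd_n)
    out = pd.Series(s2n, index=expr.index, name="s2n")
    key = pd.DataFrame({"s2n": out.to_numpy(), "gene": out.index.astype(str)})
    key = key.sort_values(["s2n", "gene"], ascending=[False, True], kind="mergesort")
    return out.iloc[key.index.to_numpy()]


def enrichment_score(ranked: pd.Series, gene_set: set[str], weight: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score of one gene set.

    Walking down the ranked list, hits add |metric|^weight (normalized to
    unit total hit mass) and misses subtract 1/(N - k); the score is the
    running-sum deviation of maximal absolute value, in [-1, 1].
    """
    genes = ranked.index.to_numpy()
    metric = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    k = int(hit.sum())
    n = len(genes)
    if k == 0:
        return 0.0
    w = np.abs(metric[hit]) ** weight
    if w.sum() == 0:
        w = np.ones(k)
    hit_idx = np.flatnonzero(hit)
    cum_hit = np.cumsum(w) / w.sum()
    miss_step = 1.0 / (n - k)
    # running sum just after each hit, and just before each hit
    misses_before = hit_idx - np.arange(k)
    after = cum_hit - misses_before * miss_step
    before = np.concatenate([[0.0], cum_hit[:-1]]) - misses_before * miss_step
    candidates = np.concatenate([after, before, [0.0]])
    peak = float(np.max(np.abs(candidates)))
    # a sign tie in the maximal deviation resolves to the positive peak
    return peak if np.any(candidates >= peak) else -peak


@dataclass
class GSEAResult:
    gene_set: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr_q: float
    significant: bool
    flag: str = ""


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.25,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-set permutation null.

    For each set, the null is the ES of ``n_perm`` random gene sets of the
    same size drawn from the ranked universe (seeded). NES divides ES by
    the mean |null ES| of the same sign; the nominal p is one-sided within
    sign; FDR q uses the ratio-of-tails estimator over the pooled
    normalized null. Sets with fewer than 2 genes in the list are skipped.
    """
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = len(genes)
    metric = ranked.to_numpy(dtype=float)
    absw = np.abs(metric) ** weight
    miss_denominator = {}

    def es_from_hit_idx(hit_idx: np.ndarray) -> float:
        k = len(hit_idx)
        w = absw[hit_idx]
        if w.sum() == 0:
            w = np.ones(k)
        cum_hit = np.cumsum(w) / w.sum()
        miss_step = miss_denominator.setdefault(k, 1.0 / (n - k))
        misses_before = hit_idx - np.arange(k)
        after = cum_hit - misses_before * miss_step
        before = np.concatenate([[0.0], cum_hit[:-1]]) - misses_before * miss_step
        cands = np.concatenate([after, before, [0.0]])
        peak = float(np.max(np.abs(cands)))
        return peak if np.any(cands >= peak) else -peak

    rows = []
    observed: list[tuple[str, int, float]] = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in gene_sets.items():
        hit_idx = np.flatnonzero(np.isin(genes, list(members)))
        if len(hit_idx) < 2:
            rows.append(GSEAResult(name, len(hit_idx), np.nan, np.nan, np.nan,
                                   np.nan, False, flag="too_few_genes"))
            continue
        k = len(hit_idx)
        if k not in null_by_size:
            null = np.empty(n_perm)
            for b in range(n_perm):
                null[b] = es_from_hit_idx(np.sort(rng.choice(n, size=k, replace=False)))
            null_by_size[k] = null
        observed.append((name, k, es_from_hit_idx(hit_idx)))

    # normalize observed and null by signed null means, then pool for FDR
    nes_obs: dict[str, float] = {}
    p_obs: dict[str, float] = {}
    pooled_null_nes: list[np.ndarray] = []
    for name, k, es in observed:
        null = null_by_size[k]
        pos, neg = null[null >= 0], null[null < 0]
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = -neg.mean() if len(neg) else np.nan
        if es >= 0:
            same = pos
            nes = es / mean_pos if mean_pos and np.isfinite(mean_pos) else np.nan
            p = (1 + (same >= es).sum()) / (1 + len(same)) if len(same) else np.nan
        else:
            same = neg
            nes = es / mean_neg if mean_neg and np.isfinite(mean_neg) else np.nan
            p = (1 + (same <= es).sum()) / (1 + len(same)) if len(same) else np.nan
        nes_obs[name] = float(nes)
        p_obs[name] = float(p)
    for k, null in null_by_size.items():
        pos, neg = null[null >= 0], null[null < 0]
        nn = np.concatenate([
            pos / pos.mean() if len(pos) else pos,
            -neg / neg.mean() if len(neg) else neg,
        ])
        pooled_null_nes.append(nn)
    pooled = np.concatenate(pooled_null_nes) if pooled_null_nes else np.array([])
    all_nes = np.array([nes_obs[name] for name, _, _ in observed])

    for name, k, es in observed:
        nes = nes_obs[name]
        if np.isfinite(nes) and len(pooled):
            if nes >= 0:
                null_tail = (pooled >= nes).mean() / max((pooled >= 0).mean(), 1e-12)
                obs_tail = (all_nes >= nes).mean() / max((all_nes >= 0).mean(), 1e-12)
            else:
                null_tail = (pooled <= nes).mean() / max((pooled < 0).mean(), 1e-12)
                obs_tail = (all_nes <= nes).mean() / max((all_nes < 0).mean(), 1e-12)
            q = float(min(1.0, null_tail / max(obs_tail, 1e-12)))
        else:
            q = np.nan
        p = p_obs[name]
        sig = bool(np.isfinite(p) and np.isfinite(q) and p < 0.05 and q < 0.25)
        rows.append(GSEAResult(name, k, es, nes, p, q, sig))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("gene_set")
    return out.loc[[*gene_sets]]


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def integrate_cnv_expression(
    gene_scan_uni: pd.DataFrame,
    gene_scan_multi: pd.DataFrame,
    de: pd.DataFrame,
    gene_annotation: pd.DataFrame | None = None,
    alpha: float = 0.05,
    max_id_mismatch: float = 0.95,
) -> pd.DataFrame:
    """Genes both CNV-prognostic and differentially expressed.

    Rows are genes significant (adjusted p < ``alpha``) in the univariate
    or multivariate CNV scan AND flagged differentially expressed;
    membership in each scan-derived list is flagged separately. Columns
    mirror the standard report: chromosome, raw/adjusted p per scan, fold
    change and t-test p.
    """
    shared = de.index.intersection(gene_scan_uni.index)
    if len(de) and len(shared) < (1.0 - max_id_mismatch) * len(de):
        raise ValueError(
            f"only {len(shared)}/{len(de)} gene identifiers shared between scans"
        )
    sig_uni = gene_scan_uni["adjusted_p"] < alpha
    sig_multi = gene_scan_multi["adjusted_p"] < alpha
    chrom_of = {}
    if gene_annotation is not None:
        chrom_of = dict(zip(gene_annotation["gene"], gene_annotation["chrom"]))
    rows = []
    for gene in shared:
        if not de.loc[gene, "de_flag"]:
            continue
        in_uni = bool(sig_uni.get(gene, False))
        in_multi = bool(sig_multi.get(gene, False))
        if not (in_uni or in_multi):
            continue
        rows.append({
            "gene": gene,
            "chrom": chrom_of.get(gene, np.nan),
            "univariate_p": gene_scan_uni.loc[gene, "p_value"],
            "univariate_adjusted_p": gene_scan_uni.loc[gene, "adjusted_p"],
            "multivariate_p": gene_scan_multi.loc[gene, "p_value"],
            "multivariate_adjusted_p": gene_scan_multi.loc[gene, "adjusted_p"],
            "fold_change": de.loc[gene, "fold_change"],
            "t_test_p": de.loc[gene, "p_value"],
            "in_univariate_list": in_uni,
            "in_multivariate_list": in_multi,
        })
    cols = ["gene", "chrom", "univariate_p", "univariate_adjusted_p",
            "multivariate_p", "multivariate_adjusted_p", "fold_change",
            "t_test_p", "in_univariate_list", "in_multivariate_list"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")
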