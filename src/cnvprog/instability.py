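"""Per-tumor genomic instability: burden fractions, large events, rank tests.

Instability is the fraction of probes called altered (deleted + gained);
copy-neutral LOH is tracked as a separate fraction and only pooled into
"altered" on request, mirroring the two burden definitions the analysis
uses (CNV only, and CNV + cnLOH).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec, ProbeMap

__all__ = [
    "alteration_fractions",
    "LargeEvent",
    "summarize_large_events",
    "group_compare",
]


def alteration_fractions(
    matrix: pd.DataFrame,
    loh_matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample burden summary from a samples x probes state matrix.

    Returns a frame indexed by sample with columns altered_frac,
    gained_frac, deleted_frac, loh_frac, altered_with_loh_frac and
    altered_flag (at least one altered probe).
    """
    if matrix.shape[1] == 0:
        raise ValueError("alteration matrix has zero probes")
    vals = matrix.to_numpy()
    n = matrix.shape[1]
    gained = (vals == 1).sum(axis=1) / n
    deleted = (vals == -1).sum(axis=1) / n
    altered = gained + deleted
    if loh_matrix is not None:
        loh_vals = loh_matrix.reindex(index=matrix.index, columns=matrix.columns).to_numpy()
        loh = np.nan_to_num(loh_vals.astype(float)).astype(bool)
    else:
        loh = np.zeros_like(vals, dtype=bool)
    loh_frac = loh.sum(axis=1) / n
    with_loh = ((vals != 0) | loh).sum(axis=1) / n
    return pd.DataFrame({
        "altered_frac": altered,
        "gained_frac": gained,
        "deleted_frac": deleted,
        "loh_frac": loh_frac,
        "altered_with_loh_frac": with_loh,
        "altered_flag": altered > 0,
    }, index=matrix.index)


@dataclass(frozen=True)
class LargeEvent:
    sample_id: str
    chrom: int
    scope: str       # "chromosome" | "p" | "q"
    direction: str   # "gain" | "loss"
    covered_fraction: float


def summarize_large_events(
    matrix: pd.DataFrame,
    probe_map: ProbeMap,
    genome: GenomeSpec,
    coverage_threshold: float = 0.9,
) -> pd.DataFrame:
    """Whole-chromosome and whole-arm events from the probe-state matrix.

    A unit (chromosome or arm) is declared gained/lost for a sample when at
    least ``coverage_threshold`` of its probes share that direction. A
    whole-chromosome declaration suppresses the two arm declarations of
    the same direction for that chromosome.
    """
    slices = probe_map.chrom_slices()
    for c in slices:
        if c not in genome.lengths:
            raise ValueError(f"chromosome {c} absent from genome spec")
    pos = probe_map.pos
    rows = []
    vals = matrix.to_numpy()
    for ci, (chrom, sl) in enumerate(slices.items()):
        cen = genome.centromeres[chrom]
        idx = np.arange(sl.start, sl.stop)
        on_p = pos[idx] <= cen
        units = [("chromosome", idx)]
        if on_p.any():
            units.append(("p", idx[on_p]))
        if (~on_p).any():
            units.append(("q", idx[~on_p]))
        for si, sample in enumerate(matrix.index):
            declared_chrom: dict[str, float] = {}
            arm_hits = []
            for scope, uidx in units:
                states = vals[si, uidx]
                for direction, code in (("gain", 1), ("loss", -1)):
                    frac = float((states == code).mean())
                    if frac >= coverage_threshold:
                        if scope == "chromosome":
                            declared_chrom[direction] = frac
                        else:
                            arm_hits.append((scope, direction, frac))
            for direction, frac in declared_chrom.items():
                rows.append(LargeEvent(str(sample), chrom, "chromosome", direction, frac))
            for scope, direction, frac in arm_hits:
                if direction not in declared_chrom:
                    rows.append(LargeEvent(str(sample), chrom, scope, direction, frac))
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["sample_id", "chrom", "scope", "direction", "covered_fraction"],
    )


def _exact_ranksum_p(groups: list[np.ndarray]) -> float:
    """Exact two-group rank-sum p by enumeration of group assignments."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n1 = len(groups[0])
    n = len(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(obs - mu) - 1e-9
    count = total = 0
    for comb in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev:
            count += 1
    return count / total


def _exact_kruskal_p(groups: list[np.ndarray]) -> float:
    """Exact Kruskal-Wallis p by enumeration of distinct group assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    ties = np.unique(pooled, return_counts=True)[1]
    corr = 1.0 - (ties**3 - ties).sum() / (n**3 - n)

    def h_of(assignment: list[tuple[int, ...]]) -> float:
        h = sum(len(ix) * (ranks[list(ix)].mean() - (n + 1) / 2.0) ** 2
                for ix in assignment)
        h *= 12.0 / (n * (n + 1))
        return h / corr if corr > 0 else 0.0

    start = 0
    obs_assignment = []
    for k in sizes:
        obs_assignment.append(tuple(range(start, start + k)))
        start += k
    obs = h_of(obs_assignment) - 1e-9

    count = total = 0

    def recurse(remaining: tuple[int, ...], gi: int, chosen: list[tuple[int, ...]]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            total += 1
            if h_of(chosen + [remaining]) >= obs:
                count += 1
            return
        for comb in combinations(remaining, sizes[gi]):
            rest = tuple(i for i in remaining if i not in comb)
            recurse(rest, gi + 1, chosen + [comb])

    recurse(tuple(range(n)), 0, [])
    return count / total


def group_compare(
    values: pd.Series | np.ndarray,
    grouping: pd.Series | np.ndarray,
    test: str = "auto",
    exact_max_n: int = 10,
) -> tuple[float, float, str]:
    """Rank test of a burden measure across groups.

    Two groups use the Wilcoxon rank-sum test (normal approximation with
    tie correction), more than two the Kruskal-Wallis test; when the
    combined sample size is at most ``exact_max_n`` the p-value is
    computed by exhaustive enumeration instead. Returns
    (statistic, p-value, method string).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(grouping)
    levels = pd.unique(g)
    groups = [v[g == lev] for lev in levels]
    if len(groups) < 2 or any(len(x) == 0 for x in groups):
        raise ValueError("need >= 2 non-empty groups")
    if test == "auto":
        test = "wilcoxon" if len(groups) == 2 else "kruskal"
    if test == "wilcoxon" and len(groups) != 2:
        raise ValueError("wilcoxon requires exactly 2 groups")

    n = len(v)
    if test == "wilcoxon":
        stat = float(stats.ranksums(groups[0], groups[1]).statistic)
        if n <= exact_max_n:
            return stat, _exact_ranksum_p(groups), "wilcoxon-exact"
        p = float(stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided", method="asymptotic").pvalue)
        return stat, p, "wilcoxon-normal"
    if test == "kruskal":
        res = stats.kruskal(*groups)
        stat = float(res.statistic)
        if n <= exact_max_n:
            return stat, _exact_kruskal_p(groups), "kruskal-exact"
        return stat, float(res.pvalue), "kruskal-chi2"
    raise ValueError(f"unknown test {test!r}")
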