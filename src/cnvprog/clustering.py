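"""Unsupervised clustering of binary alteration profiles.

Samples are compared by the Jaccard distance between their sets of altered
probes and grouped by Ward-criterion agglomeration. Ward's method is
formally defined for Euclidean data; following common practice with
distance-matrix input, the update is applied to squared distances (the
"ward.D2" convention), which is recorded in the assignment metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd
from scipy import stats

from .genome import InvalidConfigError

__all__ = [
    "jaccard_distances",
    "ward_linkage",
    "ward_cut",
    "ClusterAssignment",
    "fisher_exact_rxc",
    "cluster_clinical_association",
]


def jaccard_distances(matrix: pd.DataFrame, encoding: str = "binary") -> pd.DataFrame:
    """Pairwise Jaccard distances between samples of a state matrix.

    With ``encoding="binary"`` (default) a probe belongs to a sample's set
    when it is altered in either direction; ``encoding="three-state"``
    counts a probe as shared only when both samples agree on the
    direction. Two samples with no alterations at all are at distance 0
    (fully quiet tumors co-cluster).
    """
    vals = matrix.to_numpy()
    if encoding == "binary":
        b = (vals != 0).astype(np.int64)
        inter = b @ b.T
        sizes = b.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
    elif encoding == "three-state":
        # sets of (probe, direction) pairs: discordant directions do not intersect
        gain = (vals == 1).astype(np.int64)
        loss = (vals == -1).astype(np.int64)
        inter = gain @ gain.T + loss @ loss.T
        sizes = (vals != 0).sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class ClusterAssignment:
    labels: pd.Series               # sample id -> cluster label 1..k
    k: int
    merges: list[tuple[int, int, float]]  # (cluster_a, cluster_b, height) in merge order
    metadata: dict = field(default_factory=dict)


def ward_linkage(distances: pd.DataFrame) -> list[tuple[int, int, float]]:
    """Agglomerative Ward merges via Lance-Williams on squared distances.

    Clusters are numbered 0..n-1 for singletons and n, n+1, ... for
    merged clusters, scipy-style. Each merge records the pair and the
    merge height (the root of the Ward squared-distance criterion). Ties
    are broken toward the lexicographically lowest cluster-index pair.
    """
    d2 = np.asarray(distances, dtype=float) ** 2
    n = d2.shape[0]
    active = list(range(n))
    ids = {i: i for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    merges: list[tuple[int, int, float]] = []
    work = d2.copy()
    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                v = work[a, b]
                key = (v, min(ids[a], ids[b]), max(ids[a], ids[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        a, b = best[1], best[2]
        v = work[a, b]
        ia, ib = ids[a], ids[b]
        merges.append((min(ia, ib), max(ia, ib), math.sqrt(max(v, 0.0))))
        na, nb = sizes[a], sizes[b]
        # Lance-Williams Ward update of squared distances to the new cluster
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            new = ((na + nc) * work[a, c] + (nb + nc) * work[b, c] - nc * v) / (na + nb + nc)
            work[a, c] = work[c, a] = new
        sizes[a] = na + nb
        ids[a] = next_id
        next_id += 1
        active.remove(b)
    return merges


def ward_cut(distances: pd.DataFrame, k: int = 3) -> ClusterAssignment:
    """Cut the Ward hierarchy into ``k`` clusters.

    Cluster labels are 1..k in order of first appearance along the sample
    index, so they are stable under row order for a fixed hierarchy.
    """
    n = len(distances)
    if k > n:
        raise InvalidConfigError(f"k={k} exceeds {n} samples")
    merges = ward_linkage(distances)
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b, _) in enumerate(merges[: n - k]):
        new = n + m
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    raw = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        raw.append(roots[r])
    labels = pd.Series(raw, index=distances.index, name="cluster")
    return ClusterAssignment(
        labels=labels, k=k, merges=merges,
        metadata={"linkage": "ward.D2 (Lance-Williams on squared Jaccard distances)"},
    )


def _table_logprob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of an r x c table (margins fixed)."""
    from scipy.special import gammaln

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(row + 1).sum() + gammaln(col + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def fisher_exact_rxc(
    table: np.ndarray,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
    exact_cells_cap: int = 4,
) -> tuple[float, str]:
    """Fisher exact test for an r x c contingency table.

    2 x 2 tables use the exact hypergeometric test; larger tables estimate
    the probability-ordering p-value by Monte-Carlo sampling of tables
    with the observed margins (Patefield sampler, fixed seed).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t, alternative="two-sided")[1]), "fisher-exact"
    rng = np.random.default_rng(seed)
    dist = stats.random_table(t.sum(axis=1), t.sum(axis=0))
    obs = _table_logprob(t) + 1e-9
    draws = dist.rvs(size=n_monte_carlo, random_state=rng)
    lp = np.array([_table_logprob(d) for d in draws])
    p = (1 + int((lp <= obs).sum())) / (n_monte_carlo + 1)
    return float(p), "fisher-monte-carlo"


def cluster_clinical_association(
    assignment: ClusterAssignment,
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
    continuous: tuple[str, ...] = ("age",),
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Test each clinical variable against cluster membership.

    Categorical variables use the Fisher exact test (Monte-Carlo beyond
    2 x 2), continuous ones the Kruskal-Wallis test. Missing levels coded
    "NA" are dropped per variable; a variable constant across samples is
    flagged not-testable.
    """
    clin = clinical.loc[assignment.labels.index]
    if variables is None:
        variables = [c for c in clin.columns if c != "sample_id"]
    rows = []
    for var in variables:
        col = clin[var]
        mask = col.notna() & (col.astype(str) != "NA")
        col = col[mask]
        labs = assignment.labels[mask]
        if col.nunique() <= 1:
            rows.append({"variable": var, "test": "none", "statistic": np.nan,
                         "p_value": np.nan, "flag": "not_testable"})
            continue
        if var in continuous:
            groups = [col[labs == g].to_numpy(dtype=float) for g in sorted(labs.unique())]
            res = stats.kruskal(*groups)
            rows.append({"variable": var, "test": "kruskal", "statistic": float(res.statistic),
                         "p_value": float(res.pvalue), "flag": ""})
        else:
            tab = pd.crosstab(col, labs).to_numpy()
            p, method = fisher_exact_rxc(tab, n_monte_carlo=n_monte_carlo, seed=seed)
            rows.append({"variable": var, "test": method, "statistic": np.nan,
                         "p_value": p, "flag": ""})
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value", "flag"])
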