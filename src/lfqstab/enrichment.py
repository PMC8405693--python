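"""Mean-statistic set enrichment and redundancy clustering of categories.

Categories (GO-style sets of proteins) are scored by the mean of their
members' moderated t-statistics.  The null is protein-label sampling:
random subsets of the universe of the same size, giving directional
permutation p-values (each tail includes the observed draw, so p > 0).
Benjamini-Hochberg FDR is applied within each direction.

Significant categories are then clustered on membership-overlap distance
(1 - overlap coefficient, so nested parent/child terms read as redundant)
with average linkage and an adaptive cut: a static cut at ``cut_height``
followed by merging of undersized clusters into their nearest neighbour
while the merge height stays within ``cut_height + 0.1``.  Clusters with at
least ``min_nodes`` members are flagged for inclusion and each cluster
reports its lowest-p member as representative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .sets import GeneSetCollection

__all__ = [
    "MeanStatEnrichment",
    "OverlapClusterer",
    "mean_stat_enrichment",
    "overlap_distance",
    "cluster_categories",
]


def _null_prefix_means(t: np.ndarray, kmax: int, n_perm: int,
                       rng: np.random.Generator, chunk: int = 512) -> np.ndarray:
    """n_perm x kmax matrix of running means over random orderings of t.

    Row b, column k-1 holds the mean of a uniform random k-subset of t;
    subsets are nested within a row (prefixes of one random permutation),
    which is irrelevant for the per-size marginals used here and lets all
    category sizes share the same draws.
    """
    n = t.size
    out = np.empty((n_perm, kmax))
    denom = np.arange(1, kmax + 1, dtype=float)
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        keys = rng.random((m, n))
        order = np.argsort(keys, axis=1, kind="stable")[:, :kmax]
        out[start:start + m] = np.cumsum(t[order], axis=1) / denom
    return out


def mean_stat_enrichment(t_by_protein, sets: GeneSetCollection,
                         n_perm: int = 10_000, fdr: float = 0.10,
                         seed=None) -> pd.DataFrame:
    """Score every category by its mean member t against a sampling null.

    ``t_by_protein`` maps protein id -> t statistic (dict or Series); the
    universe of the null is the set of scored proteins.  Directional
    p-values use the add-one convention p_up = (1 + #{null >= obs}) /
    (n_perm + 1).  Returns one row per category with p, BH q per direction,
    a ``significant`` flag at min(q_up, q_down) < ``fdr`` and the favoured
    direction.
    """
    t = pd.Series(t_by_protein, dtype=float)
    if t.index.has_duplicates:
        raise ValidationError("duplicate protein ids in t statistics")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    restricted = sets.restrict_to(list(t.index))
    if len(restricted) == 0:
        raise ValidationError("no category retains >= 2 members within the universe")
    sizes = [len(c.members) for c in restricted]
    if max(sizes) > t.size:
        raise ValidationError("universe smaller than the largest category")

    tv = t.to_numpy()
    pos = {p: i for i, p in enumerate(t.index)}
    rng = np.random.default_rng(seed)
    null = _null_prefix_means(tv, max(sizes), n_perm, rng)

    rows = []
    for c in restricted:
        k = len(c.members)
        obs = float(np.mean([tv[pos[m]] for m in c.members]))
        nk = null[:, k - 1]
        p_up = (1.0 + int(np.sum(nk >= obs))) / (n_perm + 1.0)
        p_down = (1.0 + int(np.sum(nk <= obs))) / (n_perm + 1.0)
        rows.append((c.category_id, k, obs, p_up, p_down))
    out = pd.DataFrame(rows, columns=["category_id", "n_members", "mean_t",
                                      "p_up", "p_down"])
    out["q_up"] = multipletests(out["p_up"], method="fdr_bh")[1]
    out["q_down"] = multipletests(out["p_down"], method="fdr_bh")[1]
    out["significant"] = np.minimum(out["q_up"], out["q_down"]) < fdr
    up = np.where(out["p_up"] < out["p_down"], True,
                  np.where(out["p_up"] > out["p_down"], False, out["mean_t"] >= 0))
    out["direction"] = np.where(up, "up", "down")
    return out.set_index("category_id")


def overlap_distance(members_a, members_b) -> float:
    """1 - |A intersect B| / min(|A|, |B|) (overlap-coefficient distance).

    Zero whenever the smaller set is contained in the larger, which is what
    collapses nested GO parent/child terms during redundancy clustering.
    """
    a, b = set(members_a), set(members_b)
    if not a or not b:
        raise ValidationError("overlap_distance requires non-empty sets")
    return 1.0 - len(a & b) / min(len(a), len(b))


def _avg_between(dist: np.ndarray, ia, ib) -> float:
    return float(np.mean([dist[i, j] for i in ia for j in ib]))


def cluster_categories(results: pd.DataFrame, sets: GeneSetCollection,
                       min_nodes: int = 3, cut_height: float = 0.7) -> pd.DataFrame:
    """Collapse redundant significant categories into clusters.

    ``results`` is the (significant-only) enrichment table indexed by
    category id.  Average-linkage hierarchical clustering on pairwise
    overlap distance, cut statically at ``cut_height``; clusters smaller
    than ``min_nodes`` are then iteratively merged into their nearest
    cluster while the average between-cluster distance stays at or below
    ``cut_height + 0.1`` (a deterministic, adaptive-cut approximation).

    Returns one row per cluster: sorted member ids, the lowest-p
    representative (ties: larger |mean_t|, then lexical id) and an
    ``included`` flag for clusters of at least ``min_nodes`` members.
    """
    if len(results) == 0:
        raise ValidationError("need at least one significant category to cluster")
    ids = sorted(results.index)
    members = {i: set(sets.get(i).members) for i in ids}
    m = len(ids)

    if m == 1:
        assignments = {ids[0]: 0}
    else:
        dist = np.zeros((m, m))
        for i, j in itertools.combinations(range(m), 2):
            dist[i, j] = dist[j, i] = overlap_distance(members[ids[i]], members[ids[j]])
        labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                          t=cut_height, criterion="distance")
        clusters = {lab: sorted(np.flatnonzero(labels == lab))
                    for lab in np.unique(labels)}
        # adaptive step: absorb undersized clusters into their nearest
        # neighbour while the merge stays just above the static cut
        limit = cut_height + 0.1
        while True:
            small = sorted((lab for lab, idx in clusters.items()
                            if len(idx) < min_nodes and len(clusters) > 1),
                           key=lambda lab: (len(clusters[lab]), ids[clusters[lab][0]]))
            merged = False
            for lab in small:
                others = [(lb, _avg_between(dist, clusters[lab], clusters[lb]))
                          for lb in clusters if lb != lab]
                others.sort(key=lambda x: (x[1], ids[clusters[x[0]][0]]))
                target, d = others[0]
                if d <= limit:
                    clusters[target] = sorted(clusters[target] + clusters[lab])
                    del clusters[lab]
                    merged = True
                    break
            if not merged:
                break
        assignments = {}
        for lab, idx in clusters.items():
            for i in idx:
                assignments[ids[i]] = lab

    # stable cluster ids, ordered by lexically smallest member
    by_cluster: dict = {}
    for cid, lab in assignments.items():
        by_cluster.setdefault(lab, []).append(cid)
    ordered = sorted(by_cluster.values(), key=lambda ms: min(ms))
    rows = []
    for k, ms in enumerate(ordered, start=1):
        ms = sorted(ms)
        sub = results.loc[ms]
        pmin = np.minimum(sub["p_up"], sub["p_down"])
        key = sorted(ms, key=lambda c: (pmin[c], -abs(sub.loc[c, "mean_t"]), c))
        rows.append({
            "cluster_id": f"K{k}",
            "members": ";".join(ms),
            "n_members": len(ms),
            "representative_id": key[0],
            "included": len(ms) >= min_nodes,
        })
    return pd.DataFrame(rows).set_index("cluster_id")


class MeanStatEnrichment(BaseEstimator):
    """Permutation set enrichment by mean member statistic.

    Parameters: ``n_perm`` null draws (add-one corrected p-values), ``fdr``
    directional significance threshold, ``random_state`` for the sampling
    null.  After ``fit(t_by_protein, sets)`` the table is in ``results_``.
    """

    def __init__(self, n_perm: int = 10_000, fdr: float = 0.10,
                 random_state=None):
        self.n_perm = n_perm
        self.fdr = fdr
        self.random_state = random_state

    def fit(self, t_by_protein, sets: GeneSetCollection):
        self.results_ = mean_stat_enrichment(
            t_by_protein, sets, n_perm=self.n_perm, fdr=self.fdr,
            seed=self.random_state)
        return self


class OverlapClusterer(BaseEstimator):
    """Redundancy clustering of significant categories.

    After ``fit(results, sets)`` (results restricted to significant
    categories) the cluster report is in ``clusters_``.
    """

    def __init__(self, min_nodes: int = 3, cut_height: float = 0.7):
        self.min_nodes = min_nodes
        self.cut_height = cut_height

    def fit(self, results: pd.DataFrame, sets: GeneSetCollection):
        self.clusters_ = cluster_categories(results, sets,
                                            min_nodes=self.min_nodes,
                                            cut_height=self.cut_height)
        return self
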