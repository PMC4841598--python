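"""Set intersections, expression-pattern clustering and term enrichment.

Three post-DE summaries: Venn-region counting over 2-3 named DEG/TF sets,
Eisen-style hierarchical clustering of per-stage log2 fold-change profiles
(uncentered correlation similarity, average linkage, tree cut to k groups
labelled with roman numerals in dendrogram order), and one-sided
hypergeometric over-representation of annotation terms with BH correction
and a corrected-p < 0.01 call.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, ClusterMixin

from .de import bh_fdr

__all__ = [
    "venn_partition",
    "ProfileClusterer",
    "cluster_fc_profiles",
    "hypergeometric_enrichment",
    "DEFAULT_ENRICH_CUT",
]

DEFAULT_ENRICH_CUT = 0.01

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


class SetError(ValueError):
    """Raised on invalid gene-set inputs."""


def venn_partition(collection: dict[str, set]) -> pd.Series:
    """Disjoint-region counts plus the union for 2 or 3 named sets.

    Region keys join set names with ``&`` for membership and prefix
    excluded sets with ``~``; an extra ``union`` entry closes the
    inclusion-exclusion identity.
    """
    names = list(collection)
    if len(names) not in (2, 3):
        raise SetError(
            f"venn partition defined for 2 or 3 sets, got {len(names)}; "
            "report a membership table instead"
        )
    sets = {k: set(v) for k, v in collection.items()}
    universe = set().union(*sets.values())
    counts = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(sets[n] for n in inside)) - set().union(
                set(), *(sets[n] for n in outside)
            )
            key = "&".join(inside) + "".join(f"~{n}" for n in outside)
            counts[key] = len(region)
    counts["union"] = len(universe)
    out = pd.Series(counts, name="count")
    out.index.name = "region"
    return out


def _uncentered_corr_dist(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - uncentered-correlation distances between rows."""
    norms = np.sqrt((x**2).sum(axis=1))
    norms[norms == 0] = 1.0  # all-zero profile: similarity 0 to everything
    xn = x / norms[:, None]
    sim = np.clip(xn @ xn.T, -1.0, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    iu = np.triu_indices_from(d, k=1)
    return np.maximum(d[iu], 0.0)


class ProfileClusterer(ClusterMixin, BaseEstimator):
    """Eisen-style hierarchical clustering of fold-change profiles.

    Similarity is the uncentered Pearson correlation, linkage is average,
    and the tree is cut into `n_clusters` flat groups.  Fitting on a
    genes x stages matrix sets ``labels_`` (integer, 0-based, numbered in
    dendrogram leaf order) and ``cluster_names_`` (roman numerals).
    """

    def __init__(self, n_clusters: int = 6):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        x = np.asarray(X, dtype=float)
        if self.n_clusters < 1:
            raise SetError("n_clusters must be >= 1")
        if self.n_clusters > len(x):
            raise SetError(
                f"cannot form {self.n_clusters} clusters from {len(x)} profiles"
            )
        if np.isnan(x).any():
            raise SetError("profiles contain missing values; impute first")
        z = linkage(_uncentered_corr_dist(x), method="average")
        flat = fcluster(z, t=self.n_clusters, criterion="maxclust")
        order = leaves_list(z)
        seen: dict[int, int] = {}
        for leaf in order:
            seen.setdefault(flat[leaf], len(seen))
        self.linkage_ = z
        self.labels_ = np.array([seen[c] for c in flat])
        self.n_clusters_ = len(seen)
        self.cluster_names_ = [_ROMAN[i] if i < len(_ROMAN) else str(i + 1)
                               for i in range(self.n_clusters_)]
        self.index_ = idx
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def named_labels_(self) -> pd.Series:
        return pd.Series([self.cluster_names_[i] for i in self.labels_],
                         index=self.index_, name="cluster")


def cluster_fc_profiles(profiles: pd.DataFrame, k: int = 6) -> pd.Series:
    """Cluster genes by their per-stage log2-ratio profiles into k groups.

    Returns roman-numeral labels (I..k in dendrogram order) indexed by
    gene.  Note fewer than k groups can result when profiles are tied.
    """
    return ProfileClusterer(n_clusters=k).fit(profiles).named_labels_


@dataclass
class EnrichmentResult:
    term: str
    k: int  # term members in the study set
    K: int  # term members in the background
    n: int  # study set size
    N: int  # background size
    p: float
    corrected_p: float
    enriched: bool


def hypergeometric_enrichment(
    gene_set: set,
    background: set,
    term_table: dict[str, set],
    cutoff: float = DEFAULT_ENRICH_CUT,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    For each term with K background members, p = P(X >= k) where k counts
    term members inside the study set of size n drawn from the N-gene
    background.  Terms are enriched when the BH-corrected p falls below
    `cutoff`.  Output rows keep the input term order.
    """
    gene_set, background = set(gene_set), set(background)
    if not gene_set <= background:
        missing = sorted(gene_set - background)[:3]
        raise SetError(f"study set is not contained in background (e.g. {missing})")
    n, N = len(gene_set), len(background)
    rows = []
    for term, members in term_table.items():
        members = set(members) & background
        k, K = len(members & gene_set), len(members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if not out.empty:
        out["corrected_p"] = bh_fdr(out["p"].to_numpy())
        out["enriched"] = out["corrected_p"] < cutoff
    else:
        out["corrected_p"] = []
        out["enriched"] = []
    return out.set_index("term")
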