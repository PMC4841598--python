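"""Unsigned weighted gene coexpression network analysis.

Pipeline: expressed-gene filtering (RPKM floor), soft-thresholded unsigned
adjacency ``a_ij = |cor(g_i, g_j)|^beta``, topological overlap similarity,
average-linkage clustering of ``1 - TOM`` with a scanned fixed-height tree
cut (a simplified stand-in for the dynamic hybrid cut: candidate cut
heights are scanned and a branch becomes a module iff it reaches the
minimum size), eigengene-based module merging, and the standard kME / GS /
module-trait correlation layer with Student-t p-values.  Module validity is
assessed by permutation: a real module's mean intramodular topological
overlap should beat that of random gene sets of the same size.

The central object is :class:`WGCNA`, a scikit-learn style clustering
estimator (``fit`` on a samples x genes matrix, fitted attributes with
trailing underscores); the module-level functions mirror the individual
pipeline steps and are what the command-line tool calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "NetworkConfig",
    "WGCNA",
    "ModulePartition",
    "PermutationReport",
    "filter_expressed",
    "pick_soft_threshold",
    "adjacency_unsigned",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "compute_kme_gs",
    "module_trait_correlation",
    "hub_screen",
    "permute_module_to",
    "MODULE_COLORS",
    "UNASSIGNED",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "grey"

# Conventional module color sequence, assigned in decreasing module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
]


class NetworkError(ValueError):
    """Raised on degenerate network inputs (zero variance, empty filter...)."""


@dataclass
class NetworkConfig:
    """Network construction parameters.

    soft_power: exponent beta of the unsigned adjacency (>= 1).
    min_module_size: smallest branch accepted as a module.
    merge_cut_height: eigengene dissimilarity (1 - cor) below which two
        modules are merged.
    max_block_size: single-block gene limit; exceeding it is an error.
    rpkm_floor: expressed-gene filter threshold.
    """

    soft_power: int = 6
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    max_block_size: int = 19000
    rpkm_floor: float = 0.3
    network_type: str = "unsigned"

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise NetworkError("soft_power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise NetworkError("merge_cut_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise NetworkError("min_module_size must be >= 2")
        if self.network_type != "unsigned":
            raise NetworkError("only unsigned networks are supported")


def filter_expressed(
    expr: pd.DataFrame, floor: float = 0.3, how: str = "max"
) -> pd.DataFrame:
    """Keep genes expressed above `floor` RPKM (genes x samples input).

    `how="max"` retains a gene when its maximum across samples exceeds the
    floor (keeps stage-specific genes silent elsewhere); `how="mean"` uses
    the per-gene mean instead.
    """
    if how not in ("max", "mean"):
        raise ValueError(f"how must be 'max' or 'mean', got {how!r}")
    stat = expr.max(axis=1) if how == "max" else expr.mean(axis=1)
    kept = expr.loc[stat > floor]
    if kept.empty:
        raise NetworkError(f"no genes pass the RPKM > {floor} filter")
    logger.info("expression filter: kept %d of %d genes", len(kept), len(expr))
    return kept


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns of a and columns of b."""
    az = (a - a.mean(0)) / a.std(0, ddof=1)
    bz = (b - b.mean(0)) / b.std(0, ddof=1)
    return az.T @ bz / (a.shape[0] - 1)


def corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation, Student t with n-2 df.

    Uses the exact beta-distribution form of the t tail, stable at |r|=1.
    """
    if n < 3:
        raise NetworkError("correlation p-values need at least 3 samples")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    # 2*StudentT_df.sf(|r|*sqrt(df/(1-r^2))) == I_{1-r^2}(df/2, 1/2)
    return beta_dist.cdf(1.0 - r**2, df / 2, 0.5)


def adjacency_unsigned(expr: pd.DataFrame, beta: int = 6) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency a_ij = |cor|^beta, zero diagonal.

    `expr` is genes x samples.  Raises :class:`NetworkError` naming the
    first zero-variance gene, since its correlations are undefined.
    """
    x = expr.to_numpy(dtype=float).T  # samples x genes
    sd = x.std(0, ddof=1)
    if (sd == 0).any():
        bad = expr.index[np.asarray(sd == 0)][0]
        raise NetworkError(f"gene {bad!r} has zero variance across samples")
    a = np.abs(_corr_columns(x, x)) ** beta
    np.fill_diagonal(a, 0.0)
    a = np.clip((a + a.T) / 2, 0.0, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, tom_ii = 1.  Entries lie in [0, 1]; two genes that share all
    their neighbours at full weight overlap completely.
    """
    a = adjacency.to_numpy(dtype=float)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log-log degree-distribution fit."""
    k = k[k > 0]
    if k.size == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    centers = np.array([k[which == b].mean() if (which == b).any() else np.nan
                        for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(centers) & (centers > 0)
    if ok.sum() < 3:
        # <= 2 occupied degree bins (e.g. all nodes share one connectivity):
        # the regression through <= 2 points is exact, so the fit is perfect
        return 1.0, 0.0
    lx, ly = np.log10(centers[ok]), np.log10(freq[ok] / freq.sum())
    slope, intercept = np.polyfit(lx, ly, 1)
    r = np.corrcoef(lx, ly)[0, 1]
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by approximate scale-free topology fit.

    Returns the smallest candidate whose signed fit R^2 reaches `r2_target`;
    when none does (e.g. pure noise), falls back to the argmax-R^2 power
    with a warning.  The report frame carries fit R^2, slope and mean/median
    connectivity per candidate power.
    """
    if len(expr) < 3:
        raise NetworkError("need at least 3 genes to pick a soft threshold")
    if expr.shape[1] < 4:
        raise NetworkError("need at least 4 samples to pick a soft threshold")
    rows = []
    for p in candidate_powers:
        a = adjacency_unsigned(expr, beta=p).to_numpy()
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append({"power": p, "fit_r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k))})
    report = pd.DataFrame(rows).set_index("power")
    passing = report.index[report["fit_r2"] >= r2_target]
    if len(passing):
        return int(passing[0]), report
    best = int(report["fit_r2"].idxmax())
    warnings.warn(
        f"no candidate power reached scale-free fit R^2 >= {r2_target}; "
        f"falling back to argmax power {best}",
        stacklevel=2,
    )
    return best, report


def module_eigengene(expr: pd.DataFrame, member_ids) -> pd.Series:
    """First principal component of a module's standardized expression.

    `expr` is genes x samples.  The eigengene is scaled to unit variance
    across samples (ddof=1) and sign-aligned so its mean correlation with
    member profiles is non-negative.
    """
    member_ids = list(member_ids)
    if len(member_ids) < 2:
        raise NetworkError("a module eigengene needs at least 2 member genes")
    m = expr.loc[member_ids].to_numpy(dtype=float)
    if m.shape[1] < 3:
        raise NetworkError("a module eigengene needs at least 3 samples")
    sd = m.std(1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise NetworkError("zero-variance member gene in module")
    z = (m - m.mean(1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    e = e / e.std(ddof=1)
    if _corr_columns(z.T, e[:, None]).mean() < 0:
        e = -e
    return pd.Series(e, index=expr.columns, name="eigengene")


@dataclass
class ModulePartition:
    """Result of module detection: labels, eigengenes and sizes."""

    labels: pd.Series  # gene -> module name; UNASSIGNED for grey genes
    eigengenes: pd.DataFrame  # samples x modules
    config: NetworkConfig
    cut_height: float
    n_merged: int = 0
    kme: pd.DataFrame | None = None
    kme_p: pd.DataFrame | None = None
    gs: pd.DataFrame | None = None
    gs_p: pd.DataFrame | None = None

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, mod in self.labels.items():
            if mod != UNASSIGNED:
                out.setdefault(mod, []).append(gene)
        return out

    @property
    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


def _cut_candidates(heights: np.ndarray, n: int = 60) -> np.ndarray:
    lo, hi = float(heights.min()), float(heights.max())
    return np.unique(np.quantile(heights, np.linspace(0.02, 0.98, n)))


def _static_cut(z: np.ndarray, min_size: int) -> np.ndarray:
    """Scan fixed cut heights; return flat labels (0 = unassigned).

    The chosen height maximizes the number of branches of at least
    `min_size`, breaking ties toward the lowest such height so modules stay
    tight around branch cores rather than absorbing loose outliers.
    """
    heights = z[:, 2]
    best = None
    for h in _cut_candidates(heights):
        flat = fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(flat)
        valid = np.flatnonzero(sizes >= min_size)
        valid = valid[valid > 0]
        score = (len(valid), -h)
        if best is None or score > best[0]:
            best = (score, flat, set(valid.tolist()))
    _, flat, valid = best
    out = np.where(np.isin(flat, list(valid)), flat, 0)
    return out


def _adopt_leftovers(
    tom: np.ndarray, flat: np.ndarray, rel_threshold: float = 0.5
) -> np.ndarray:
    """Assign unlabelled genes to the module they overlap most with.

    Second stage of the hybrid cut: a grey gene joins its nearest module
    (largest mean TOM to the module's members) when that overlap reaches
    `rel_threshold` times the module's own mean intramodular overlap, so
    branch outliers rejoin their module while background genes stay grey.
    """
    labels = np.unique(flat[flat > 0])
    if labels.size == 0:
        return flat
    out = flat.copy()
    mean_to = np.empty((len(flat), labels.size))
    own_level = np.empty(labels.size)
    for j, lab in enumerate(labels):
        members = np.flatnonzero(flat == lab)
        cols = tom[:, members]
        mean_to[:, j] = cols.mean(axis=1)
        # member-to-module overlap excluding self (diagonal is 1)
        own = (cols[members].sum(axis=1) - 1.0) / (len(members) - 1)
        own_level[j] = own.mean()
    for i in np.flatnonzero(flat == 0):
        j = int(np.argmax(mean_to[i]))
        if mean_to[i, j] >= rel_threshold * own_level[j]:
            out[i] = labels[j]
    return out


def _merge_modules(
    expr: pd.DataFrame,
    groups: dict[int, list[str]],
    merge_cut_height: float,
) -> tuple[dict[int, list[str]], int]:
    """Iteratively merge module pairs with eigengene dissimilarity < cut."""
    groups = {k: list(v) for k, v in groups.items()}
    n_merged = 0
    while len(groups) > 1:
        keys = sorted(groups)
        eigs = np.column_stack([module_eigengene(expr, groups[k]).to_numpy() for k in keys])
        diss = 1.0 - _corr_columns(eigs, eigs)
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            break
        a, b = keys[i], keys[j]
        groups[a] = groups[a] + groups[b]
        del groups[b]
        n_merged += 1
    return groups, n_merged


def detect_modules(
    tom: pd.DataFrame,
    config: NetworkConfig,
    expr: pd.DataFrame | None = None,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with size-filtered static cut.

    Branches smaller than ``config.min_module_size`` fall into the grey
    (unassigned) bin.  When `expr` (genes x samples) is given, modules whose
    eigengenes are closer than ``config.merge_cut_height`` in correlation
    dissimilarity are merged until no such pair remains, and eigengenes are
    returned; module names are conventional colors in decreasing size order.
    """
    n = len(tom)
    if n > config.max_block_size:
        raise NetworkError(
            f"{n} genes exceed max_block_size={config.max_block_size}; "
            "raise the limit to analyse them in a single block"
        )
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    flat = _static_cut(z, config.min_module_size)
    flat = _adopt_leftovers(tom.to_numpy(dtype=float), flat)
    cut_height = float(z[:, 2].max())
    genes = tom.index
    groups: dict[int, list[str]] = {}
    for g, lab in zip(genes, flat):
        if lab > 0:
            groups.setdefault(int(lab), []).append(g)

    n_merged = 0
    if expr is not None and len(groups) > 1:
        groups, n_merged = _merge_modules(expr, groups, config.merge_cut_height)

    ordered = sorted(groups.values(), key=lambda m: (-len(m), m[0]))
    names = [MODULE_COLORS[i % len(MODULE_COLORS)] if i < len(MODULE_COLORS)
             else f"module{i + 1}" for i in range(len(ordered))]
    labels = pd.Series(UNASSIGNED, index=genes, name="module")
    for name, members in zip(names, ordered):
        labels.loc[members] = name
    eig = pd.DataFrame(index=expr.columns if expr is not None else [])
    if expr is not None:
        for name, members in zip(names, ordered):
            eig[name] = module_eigengene(expr, members)
    return ModulePartition(
        labels=labels, eigengenes=eig, config=config,
        cut_height=cut_height, n_merged=n_merged,
    )


def compute_kme_gs(
    expr: pd.DataFrame,
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    """Module membership (kME) and gene significance (GS) tables.

    kME is the Pearson correlation of each gene (rows of `expr`,
    genes x samples) with each module eigengene; GS the correlation with
    each trait column.  P-values use the Student t with n-2 df.  Returns
    (kme, kme_p, gs, gs_p); the GS pair is None without traits.
    """
    if not expr.columns.equals(eigengenes.index):
        raise NetworkError("expression samples and eigengene samples differ")
    n = expr.shape[1]
    if n < 3:
        raise NetworkError("kME/GS need at least 3 samples")
    x = expr.to_numpy(dtype=float).T
    kme_r = _corr_columns(x, eigengenes.to_numpy(dtype=float))
    kme = pd.DataFrame(kme_r, index=expr.index, columns=eigengenes.columns)
    kme_p = pd.DataFrame(corr_pvalues(kme_r, n), index=expr.index,
                         columns=eigengenes.columns)
    gs = gs_p = None
    if traits is not None:
        if not expr.columns.equals(traits.index):
            raise NetworkError("expression samples and trait samples differ")
        gs_r = _corr_columns(x, traits.to_numpy(dtype=float))
        gs = pd.DataFrame(gs_r, index=expr.index, columns=traits.columns)
        gs_p = pd.DataFrame(corr_pvalues(gs_r, n), index=expr.index,
                            columns=traits.columns)
    return kme, kme_p, gs, gs_p


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    r_cut: float = 0.8,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Module x trait Pearson r with p-values and significance calls.

    A pair is significant when |r| > `r_cut` and p < `p_cut`.  TF expression
    vectors may be passed in place of physiological traits.
    """
    if not eigengenes.index.equals(traits.index):
        raise NetworkError("eigengene samples and trait samples are misaligned")
    n = len(eigengenes)
    if n < 3:
        raise NetworkError("module-trait correlation needs at least 3 samples")
    r = _corr_columns(eigengenes.to_numpy(dtype=float), traits.to_numpy(dtype=float))
    p = corr_pvalues(r, n)
    rows = []
    for i, mod in enumerate(eigengenes.columns):
        for j, trait in enumerate(traits.columns):
            rows.append({
                "module": mod, "trait": trait,
                "r": float(r[i, j]), "p": float(p[i, j]),
                "significant": bool(abs(r[i, j]) > r_cut and p[i, j] < p_cut),
            })
    return pd.DataFrame(rows)


def hub_screen(
    labels: pd.Series,
    kme: pd.DataFrame,
    kme_p: pd.DataFrame,
    gs: pd.DataFrame,
    gs_p: pd.DataFrame,
    gs_cut: float = 0.8,
    mm_cut: float = 0.8,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Genes with high, significant GS and module membership, per trait.

    A gene qualifies for trait t when |GS| >= gs_cut with p < p_cut and its
    kME to its own module satisfies |kME| >= mm_cut with p < p_cut.
    """
    rows = []
    for gene, mod in labels.items():
        if mod == UNASSIGNED or mod not in kme.columns:
            continue
        mm, mm_p = kme.at[gene, mod], kme_p.at[gene, mod]
        if abs(mm) < mm_cut or mm_p >= p_cut:
            continue
        for trait in gs.columns:
            g, gp = gs.at[gene, trait], gs_p.at[gene, trait]
            if abs(g) >= gs_cut and gp < p_cut:
                rows.append({"gene_id": gene, "module": mod, "trait": trait,
                             "gs": float(g), "gs_p": float(gp),
                             "kme": float(mm), "kme_p": float(mm_p)})
    return pd.DataFrame(rows, columns=["gene_id", "module", "trait",
                                       "gs", "gs_p", "kme", "kme_p"])


@dataclass
class PermutationReport:
    """Permutation validity check of one module's topological overlap."""

    module: str
    observed_mean_to: float
    b: int
    null_mean_to: np.ndarray = field(repr=False)
    p_value: float = 0.0

    def __post_init__(self) -> None:
        self.p_value = float(
            (1 + np.sum(self.null_mean_to >= self.observed_mean_to)) / (self.b + 1)
        )


def _mean_offdiag(tom: np.ndarray, idx: np.ndarray) -> float:
    sub = tom[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def permute_module_to(
    tom: pd.DataFrame,
    member_ids,
    b: int = 999,
    seed: int | np.random.Generator = 0,
    module_name: str = "",
) -> PermutationReport:
    """Empirical p-value for a module's mean intramodular overlap.

    Compares the observed mean off-diagonal TOM among `member_ids` with the
    same statistic on `b` random gene sets of identical size drawn without
    replacement from all genes; p = (1 + #{null >= observed}) / (b + 1).
    """
    if b < 1:
        raise NetworkError("permutation count B must be >= 1")
    member_ids = list(member_ids)
    if len(member_ids) < 2:
        raise NetworkError("module must have at least 2 members to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = tom.to_numpy(dtype=float)
    pos = tom.index.get_indexer(member_ids)
    if (pos < 0).any():
        raise NetworkError("module members missing from the TOM")
    observed = _mean_offdiag(t, pos)
    m, n = len(pos), len(tom)
    null = np.array([_mean_offdiag(t, rng.choice(n, m, replace=False))
                     for _ in range(b)])
    return PermutationReport(module=module_name, observed_mean_to=observed,
                             b=b, null_mean_to=null)


class WGCNA(ClusterMixin, BaseEstimator):
    """Weighted coexpression network module detection, sklearn style.

    Fits on a samples x genes matrix (DataFrame preferred; gene names are
    taken from columns).  After ``fit``: ``labels_`` (module name per gene,
    ``"grey"`` for unassigned), ``eigengenes_`` (samples x modules),
    ``adjacency_``, ``tom_``, ``connectivity_``, ``partition_``.

    Parameters mirror the standard network construction knobs: `power` is
    the unsigned soft threshold, `min_module_size` and `merge_cut_height`
    control branch acceptance and eigengene merging, `max_block_size` caps
    the single-block gene count.
    """

    def __init__(
        self,
        power: int = 6,
        min_module_size: int = 30,
        merge_cut_height: float = 0.25,
        max_block_size: int = 19000,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.max_block_size = max_block_size

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            soft_power=self.power,
            min_module_size=self.min_module_size,
            merge_cut_height=self.merge_cut_height,
            max_block_size=self.max_block_size,
        )

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"g{j}" for j in range(X.shape[1])]
        if X.shape[0] < 3:
            raise NetworkError("network construction needs at least 3 samples")
        expr = X.T  # genes x samples
        cfg = self._config()
        self.adjacency_ = adjacency_unsigned(expr, beta=cfg.soft_power)
        self.tom_ = tom_similarity(self.adjacency_)
        self.connectivity_ = self.adjacency_.sum(axis=1)
        self.partition_ = detect_modules(self.tom_, cfg, expr=expr)
        self.eigengenes_ = self.partition_.eigengenes
        self.labels_ = self.partition_.labels.to_numpy()
        self.module_labels_ = self.partition_.labels
        self.n_modules_ = self.eigengenes_.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def permutation_reports(
        self, b: int = 999, seed: int = 0
    ) -> list[PermutationReport]:
        """Permutation validity check for every fitted module."""
        rng = np.random.default_rng(seed)
        return [
            permute_module_to(self.tom_, members, b=b, seed=rng, module_name=name)
            for name, members in sorted(self.partition_.modules.items())
        ]
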