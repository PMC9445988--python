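"""Weighted co-expression network machinery.

Unsigned adjacency a_ij = |Pearson r|^beta, topological overlap

    T_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

hierarchical module detection on the dissimilarity D = 1 - T, module
eigengenes (first principal component over samples), kME (gene-eigengene
correlation), GS (gene-tissue correlation) and module/tissue correlation
with the |r| > 0.6, p < 0.05 tissue-specificity rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .dataset import ConfigError, DataError


def _corrcoef(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataError(f"zero-variance gene row(s) at positions {zero[:10].tolist()}")
    r = np.corrcoef(X)
    if not np.isfinite(r).all():
        raise DataError("non-finite correlations")
    return np.clip(r, -1.0, 1.0)


@dataclass
class CoexpressionNetwork:
    """Adjacency and TOM for one expression matrix at soft power ``beta``."""

    genes: pd.Index
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


def build_adjacency(X: pd.DataFrame, beta: float, signed: bool = False) -> np.ndarray:
    """|cor|^beta (unsigned, the default) or ((1+cor)/2)^beta (signed)."""
    if beta < 1:
        raise ConfigError("soft power beta must be >= 1")
    r = _corrcoef(X.to_numpy(float))
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Matrix-product TOM; agrees with the direct triple loop to 1e-12."""
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    ell = a0 @ a0  # l_ij: diagonal of a0 is 0, so u = i and u = j drop out
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    t = (ell + a0) / denom
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def build_network(X: pd.DataFrame, beta: float, signed: bool = False) -> CoexpressionNetwork:
    a = build_adjacency(X, beta, signed=signed)
    return CoexpressionNetwork(genes=X.index, beta=beta, adjacency=a,
                               tom=tom_from_adjacency(a))


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Signed scale-free topology fit index.

    Bin connectivity into ``n_bins`` equal-width bins, regress
    log10(p(k_bin)) on log10(mean k_bin) and return
    (-sign(slope) * R^2, slope).  Empty bins are dropped.
    """
    k = np.asarray(k, float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, dens = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_k.append(k[sel].mean())
            dens.append(sel.mean())
    mean_k, dens = np.asarray(mean_k), np.asarray(dens)
    ok = (mean_k > 0) & (dens > 0)
    if ok.sum() < 3:
        return 0.0, 0.0
    lx, ly = np.log10(mean_k[ok]), np.log10(dens[ok])
    slope, _, r_value, _, _ = stats.linregress(lx, ly)
    return float(-np.sign(slope) * r_value**2), float(slope)


def scan_soft_thresholds(
    X: pd.DataFrame,
    powers=range(1, 21),
    fit_target: float = 0.8,
    signed: bool = False,
) -> pd.DataFrame:
    """Evaluate candidate soft powers; returns one row per power with the
    signed fit index, slope and mean connectivity, plus a ``recommended``
    flag on the smallest power reaching ``fit_target`` (else the argmax)."""
    if X.shape[0] < 20 or X.shape[1] < 4:
        raise DataError("soft-threshold scan needs >=20 genes and >=4 samples")
    r = _corrcoef(X.to_numpy(float))
    s = ((1.0 + r) / 2.0) if signed else np.abs(r)
    rows = []
    for beta in powers:
        a = s**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append({"power": beta, "fit": fit, "slope": slope,
                     "mean_connectivity": float(k.mean())})
    scan = pd.DataFrame(rows)
    good = scan.index[scan["fit"] >= fit_target]
    rec = int(good[0]) if len(good) else int(scan["fit"].idxmax())
    scan["recommended"] = False
    scan.loc[rec, "recommended"] = True
    return scan


def recommended_power(scan: pd.DataFrame) -> int:
    return int(scan.loc[scan["recommended"], "power"].iloc[0])


@dataclass
class ModuleSet:
    """Module labels plus the derived eigengene-level quantities.

    ``labels``: gene -> int module id, 0 = unassigned; ``me``: samples x
    modules eigengene matrix; ``kme``: genes x modules; ``gs``: genes x
    tissues; ``module_tissue_r``/``_p``: modules x tissues;
    ``tissue_specific``: boolean modules x tissues flag table.
    """

    labels: pd.Series
    me: pd.DataFrame | None = None
    kme: pd.DataFrame | None = None
    gs: pd.DataFrame | None = None
    module_tissue_r: pd.DataFrame | None = None
    module_tissue_p: pd.DataFrame | None = None
    tissue_specific: pd.DataFrame | None = None
    thresholds: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list:
        return sorted(set(self.labels) - {0})

    def module_genes(self, module_id: int) -> pd.Index:
        return self.labels.index[self.labels == module_id]

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()


def detect_modules(
    net: CoexpressionNetwork, cut_height: float = 0.995, min_module_size: int = 30
) -> ModuleSet:
    """Average-linkage clustering on D = 1 - TOM, cut at ``cut_height``;
    branches of size >= ``min_module_size`` become modules numbered by
    decreasing size (ties by smallest gene position); the rest is module 0."""
    if not (0.0 < cut_height <= 1.0):
        raise ConfigError("cut_height must lie in (0, 1]")
    n = len(net.genes)
    if n < min_module_size:
        raise DataError("fewer genes than min_module_size")
    d = net.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    z = average(squareform(d, checks=False))
    flat = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    clusters = pd.Series(flat).groupby(flat).groups
    keep = [
        (len(members), int(np.min(members)), cid)
        for cid, members in clusters.items()
        if len(members) >= min_module_size
    ]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, cid) in enumerate(keep, start=1):
        labels[flat == cid] = rank
    return ModuleSet(labels=pd.Series(labels, index=net.genes, name="module"))


def compute_eigengenes(X: pd.DataFrame, moduleset: ModuleSet) -> ModuleSet:
    """Fill ME and kME.

    Each eigengene is the first right-singular vector of the
    gene-standardised module submatrix (one value per sample, unit norm,
    zero mean), sign-oriented to correlate non-negatively with the module's
    mean expression profile.  kME is computed for every gene against every
    module eigengene.
    """
    labels = moduleset.labels
    me = {}
    for mid in moduleset.module_ids:
        sub = X.loc[moduleset.module_genes(mid)].to_numpy(float)
        if sub.shape[0] == 1:
            warnings.warn(f"module {mid} has a single gene; eigengene equals "
                          "its standardised profile", stacklevel=2)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        vec = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.std(mean_profile) > 0 and np.corrcoef(vec, mean_profile)[0, 1] < 0:
            vec = -vec
        me[f"ME{mid}"] = vec
    me_df = pd.DataFrame(me, index=X.columns)

    kme = pd.DataFrame(index=X.index, columns=me_df.columns, dtype=float)
    if len(me_df.columns):
        Y = X.to_numpy(float)
        yc = Y - Y.mean(axis=1, keepdims=True)
        ysd = Y.std(axis=1)
        ysd[ysd == 0] = np.inf  # constant gene: kME 0
        for col in me_df.columns:
            v = me_df[col].to_numpy()
            vc = v - v.mean()
            denom = ysd * np.sqrt((vc**2).mean())
            kme[col] = (yc @ vc) / (len(v) * denom)
    return ModuleSet(labels=labels, me=me_df, kme=kme, gs=moduleset.gs,
                     thresholds=moduleset.thresholds)


def merge_similar_modules(
    X: pd.DataFrame, moduleset: ModuleSet, merge_cut: float = 0.25
) -> ModuleSet:
    """Merge modules whose eigengenes cluster below ``merge_cut`` on
    1 - cor(ME) (average linkage); labels are renumbered by size and
    ME/kME recomputed.  ``merge_cut <= 0`` never merges."""
    if moduleset.me is None:
        moduleset = compute_eigengenes(X, moduleset)
    ids = moduleset.module_ids
    if merge_cut <= 0 or len(ids) < 2:
        return moduleset
    me = moduleset.me[[f"ME{m}" for m in ids]].to_numpy(float)
    d = 1.0 - np.corrcoef(me.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = average(squareform(d, checks=False))
    groups = fcluster(z, t=merge_cut, criterion="distance")
    labels = moduleset.labels.copy()
    for gid in np.unique(groups):
        members = [ids[i] for i in np.flatnonzero(groups == gid)]
        if len(members) > 1:
            target = min(members)
            labels[labels.isin(members)] = target
    # renumber by decreasing size, ties by first gene position
    sizes = labels[labels != 0].value_counts()
    first_pos = {mid: int(np.flatnonzero(labels.to_numpy() == mid)[0]) for mid in sizes.index}
    order = sorted(sizes.index, key=lambda m: (-sizes[m], first_pos[m]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = labels.map(lambda m: remap.get(m, 0))
    return compute_eigengenes(X, ModuleSet(labels=labels, thresholds=moduleset.thresholds))


def _indicator_correlation(values: np.ndarray, indicator: np.ndarray):
    """Pearson r of each column-vector in ``values`` (2-D, obs x vars)
    against a 0/1 indicator, with the t-distributed two-sided p (n-2 df)."""
    n = indicator.size
    ind = indicator - indicator.mean()
    isd = ind.std()
    vc = values - values.mean(axis=0, keepdims=True)
    vsd = values.std(axis=0)
    vsd_safe = np.where(vsd == 0, np.inf, vsd)
    r = (vc.T @ ind) / (n * vsd_safe * isd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def module_tissue_correlation(
    X: pd.DataFrame,
    moduleset: ModuleSet,
    tissue_labels: pd.Series,
    r_min: float = 0.6,
    alpha: float = 0.05,
) -> ModuleSet:
    """Correlate eigengenes (and every gene: GS) with each tissue's 0/1
    indicator; a module is tissue-specific iff |r| > r_min and p < alpha."""
    if moduleset.me is None:
        moduleset = compute_eigengenes(X, moduleset)
    tissue_labels = tissue_labels.loc[X.columns]
    tissues = sorted(tissue_labels.unique())
    n = len(tissue_labels)
    if n < 3:
        raise DataError("need >=3 samples for module-tissue correlation")
    me = moduleset.me.to_numpy(float)
    genes_mat = X.to_numpy(float).T
    r_rows, p_rows, gs_cols = [], [], {}
    for t in tissues:
        ind = (tissue_labels == t).to_numpy(float)
        if ind.all() or not ind.any():
            raise DataError(f"tissue {t!r}: indicator is constant across samples")
        r, p = _indicator_correlation(me, ind)
        r_rows.append(r)
        p_rows.append(p)
        gs, _ = _indicator_correlation(genes_mat, ind)
        gs_cols[t] = gs
    idx = moduleset.me.columns
    r_df = pd.DataFrame(np.column_stack(r_rows), index=idx, columns=tissues)
    p_df = pd.DataFrame(np.column_stack(p_rows), index=idx, columns=tissues)
    flags = (r_df.abs() > r_min) & (p_df < alpha)
    gs_df = pd.DataFrame(gs_cols, index=X.index)
    return ModuleSet(
        labels=moduleset.labels, me=moduleset.me, kme=moduleset.kme, gs=gs_df,
        module_tissue_r=r_df, module_tissue_p=p_df, tissue_specific=flags,
        thresholds={"r_min": r_min, "alpha": alpha},
    )


def screen_module_genes(
    moduleset: ModuleSet, gs_min: float = 0.6, kme_min: float = 0.8
) -> pd.DataFrame:
    """Hub-gene screen: for every flagged (module, tissue), the module's
    genes with |GS| > gs_min and |kME| > kme_min (strict inequalities).

    Returns columns gene, module, tissue, GS, kME, module_r, module_p.
    """
    required = (moduleset.gs, moduleset.kme, moduleset.tissue_specific)
    if any(x is None for x in required):
        raise DataError("run module_tissue_correlation before screening genes")
    rows = []
    for me_name in moduleset.tissue_specific.index:
        mid = int(me_name.removeprefix("ME"))
        for tissue in moduleset.tissue_specific.columns:
            if not moduleset.tissue_specific.loc[me_name, tissue]:
                continue
            genes = moduleset.module_genes(mid)
            gs = moduleset.gs.loc[genes, tissue]
            kme = moduleset.kme.loc[genes, me_name]
            keep = (gs.abs() > gs_min) & (kme.abs() > kme_min)
            for g in genes[keep]:
                rows.append(
                    {
                        "gene": g,
                        "module": mid,
                        "tissue": tissue,
                        "GS": gs[g],
                        "kME": kme[g],
                        "module_r": moduleset.module_tissue_r.loc[me_name, tissue],
                        "module_p": moduleset.module_tissue_p.loc[me_name, tissue],
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "module", "tissue", "GS", "kME",
                                       "module_r", "module_p"])


def tissue_dendrogram(X: pd.DataFrame, tissue_labels: pd.Series) -> str:
    """Average-linkage tree over mean per-tissue profiles on 1 - Pearson r;
    returns a Newick string with branch lengths."""
    tissue_labels = tissue_labels.loc[X.columns]
    tissues = sorted(tissue_labels.unique())
    if len(tissues) < 2:
        raise DataError("need >=2 tissues for a dendrogram")
    profiles = np.column_stack(
        [X.loc[:, (tissue_labels == t).to_numpy()].mean(axis=1) for t in tissues]
    )
    d = 1.0 - np.corrcoef(profiles.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = average(squareform(d, checks=False))
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, tissues)
    newick = str(tree).strip()
    return newick if newick.endswith(";") else newick + ";"
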