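"""Signed weighted co-expression network construction.

The pipeline is the classic weighted correlation network recipe:
biweight midcorrelation between protein profiles, signed soft-threshold
adjacency ``((1+r)/2)^beta``, topological overlap with a mean-connectivity
denominator, average-linkage hierarchical clustering with a dynamic
tree cut, eigenprotein-based module merging, and iterative kME
reassignment until each protein's module membership is consistent with
its strongest eigenprotein correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .model import NetworkParams

__all__ = ["NetworkModel", "bicor_matrix", "pearson_matrix", "adjacency",
           "tom_similarity", "cluster_modules", "compute_eigenproteins",
           "enforce_kme_consistency", "merge_close_modules",
           "detect_sample_outliers", "correlate_with_traits", "build_network"]

GREY = 0  # module id of unassigned proteins


def pearson_matrix(X: pd.DataFrame) -> pd.DataFrame:
    C = np.corrcoef(X.to_numpy(), rowvar=False)
    return pd.DataFrame(C, index=X.columns, columns=X.columns)


def bicor_matrix(X: pd.DataFrame, max_p_outliers: float = 1.0) -> pd.DataFrame:
    """Biweight midcorrelation between the columns of X.

    Tukey biweights ``w_i = (1 - u_i^2)^2`` with ``u_i = (x_i - med) /
    (9 MAD)`` and ``w_i = 0`` for ``|u_i| >= 1``; columns with zero MAD
    fall back to the Pearson standardization. Constant columns are an
    error.
    """
    A = X.to_numpy(dtype=float)
    if A.shape[0] < 4:
        raise ValueError("bicor needs at least 4 samples")
    n, p = A.shape
    med = np.median(A, axis=0)
    mad = np.median(np.abs(A - med), axis=0)
    const = (A.std(axis=0) == 0)
    if const.any():
        names = X.columns[const].tolist()[:5]
        raise ValueError(f"constant feature(s), correlation undefined: {names}")

    Z = np.empty_like(A)
    zero_mad = mad == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (A - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    dev = (A - med) * w
    denom = np.sqrt((dev ** 2).sum(axis=0))
    Z[:, ~zero_mad] = (dev / denom)[:, ~zero_mad]
    if zero_mad.any():  # Pearson fallback for zero-MAD columns
        Ac = A[:, zero_mad] - A[:, zero_mad].mean(axis=0)
        Z[:, zero_mad] = Ac / np.sqrt((Ac ** 2).sum(axis=0))
    C = np.clip(Z.T @ Z, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=X.columns, columns=X.columns)


def adjacency(corr: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Signed soft-threshold adjacency ``a_ij = ((1 + r_ij)/2)^beta``."""
    C = np.asarray(corr, dtype=float)
    if (C < -1 - 1e-9).any() or (C > 1 + 1e-9).any():
        raise ValueError("correlations outside [-1, 1]")
    A = ((1.0 + np.clip(C, -1, 1)) / 2.0) ** params.beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=corr.index, columns=corr.columns)


def tom_similarity(adj: pd.DataFrame, denom: str = "mean") -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (m_ij + 1 - a_ij).

    ``l_ij = sum_{k != i,j} a_ik a_kj`` and ``m_ij`` is the mean (or min)
    of the connectivities ``k_i = sum_{j != i} a_ij``.
    """
    A = np.asarray(adj, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    # with a zero diagonal, sum_k a_ik a_kj already excludes k=i and k=j
    L = A @ A
    if denom == "mean":
        M = (k[:, None] + k[None, :]) / 2.0
    elif denom == "min":
        M = np.minimum(k[:, None], k[None, :])
    else:
        raise ValueError("denom must be 'mean' or 'min'")
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / (M + 1.0 - A)
    T = np.where(np.isfinite(T), T, 0.0)
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _recursive_cut(node, cut_height: float, min_size: int, gap: float,
                   clusters: list, grey: list) -> None:
    """Recursively split the average-linkage tree.

    Merges above ``cut_height`` (background chaff and between-module
    joins) are always descended. Below the cut, a node splits when both
    children hold at least ``min_size`` leaves and the merge-height gap
    between the node and its taller child exceeds ``gap`` — this
    separates distinct modules that joined below the static cut without
    shattering the homogeneous interior of a single module. A
    sub-minimum sibling is pruned to the grey pool while recursion
    continues into the larger child.
    """
    if node.is_leaf():
        grey.append(node.id)
        return
    left, right = node.get_left(), node.get_right()
    nl, nr = left.get_count(), right.get_count()
    child_h = max(left.dist, right.dist)
    splittable = node.dist > cut_height or (node.dist - child_h > gap and node.dist > 0)
    if splittable and (node.dist > cut_height or (nl >= min_size and nr >= min_size)):
        _recursive_cut(left, cut_height, min_size, gap, clusters, grey)
        _recursive_cut(right, cut_height, min_size, gap, clusters, grey)
        return
    if splittable and (nl >= min_size) != (nr >= min_size):
        big, small = (left, right) if nl >= nr else (right, left)
        grey.extend(small.pre_order(lambda x: x.id))
        _recursive_cut(big, cut_height, min_size, gap, clusters, grey)
        return
    leaves = node.pre_order(lambda x: x.id)
    if len(leaves) >= min_size:
        clusters.append(leaves)
    else:
        grey.extend(leaves)


def _adaptive_cut_height(heights: np.ndarray) -> float:
    """Static cut height separating tight-module merges from background joins.

    Merge heights of a modular TOM dendrogram are bimodal: dense
    within-module merges low, background/chaff and between-module joins
    high. The cut is placed at the midpoint of the largest gap between
    consecutive sorted heights in the upper part of the distribution
    (above the 25th percentile); if the heights carry no usable gap the
    cut falls back to 99% of the maximum height.
    """
    h = np.sort(np.asarray(heights, dtype=float))
    fallback = 0.99 * h[-1] if len(h) else 0.0
    if len(h) < 4:
        return fallback
    lo = np.quantile(h, 0.25)
    cand = h[h >= lo]
    if len(cand) < 2:
        return fallback
    gaps = np.diff(cand)
    i = int(np.argmax(gaps))
    if gaps[i] <= 1e-12:
        return fallback
    return float((cand[i] + cand[i + 1]) / 2.0)


def cluster_modules(diss: pd.DataFrame, params: NetworkParams,
                    ) -> tuple[pd.Series, np.ndarray]:
    """Initial module detection on a TOM dissimilarity matrix.

    Average-linkage hierarchical clustering followed by a dynamic
    recursive cut whose sensitivity ladder follows ``deep_split`` (4 =
    most aggressive splitting), then a PAM-like stage that assigns
    unlabeled proteins to the nearest module by average dissimilarity
    when that is tighter than the overall mean dissimilarity.

    Returns ``(assignments, linkage)`` with module ids 1..K and 0 for
    grey/unassigned.
    """
    labels = diss.index
    n = len(labels)
    assignments = pd.Series(GREY, index=labels, dtype=int)
    if n < params.min_module_size:
        return assignments, np.empty((0, 4))
    D = np.asarray(diss, dtype=float)
    condensed = squareform((D + D.T) / 2.0, checks=False)
    Z = average(condensed)
    tree = to_tree(Z)
    height_range = float(Z[:, 2].max() - Z[:, 2].min()) if len(Z) else 0.0
    cut_height = _adaptive_cut_height(Z[:, 2])
    # deep_split 0..4 sets how large a merge-height gap a below-cut split
    # must clear (4 = most aggressive splitting)
    gap = (0.02 + 0.06 * (4 - params.deep_split)) * max(height_range, 1e-12)
    clusters: list[list[int]] = []
    grey: list[int] = []
    _recursive_cut(tree, cut_height, params.min_module_size, gap, clusters, grey)
    # stable module numbering: decreasing size, ties by smallest leaf index
    clusters.sort(key=lambda c: (-len(c), min(c)))
    for mid, leaves in enumerate(clusters, start=1):
        assignments.iloc[leaves] = mid

    if params.pam_stage and clusters and grey:
        overall_mean = float(condensed.mean())
        for leaf in grey:
            dists = {mid: D[leaf, c].mean() for mid, c in
                     enumerate(clusters, start=1)}
            best = min(dists, key=lambda m: (dists[m], m))
            if dists[best] < overall_mean:
                assignments.iloc[leaf] = best
    return assignments, Z


def compute_eigenproteins(X: pd.DataFrame, assignments: pd.Series,
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized members.

    Eigenproteins have unit variance across samples and are oriented so
    the mean correlation with their members is positive. Returns
    ``(eigenproteins, variance_explained)`` with modules as columns.
    """
    eig = {}
    varex = {}
    for mid in sorted(m for m in assignments.unique() if m != GREY):
        members = assignments.index[assignments == mid]
        if len(members) < 2:
            raise ValueError(f"module {mid} has fewer than 2 members")
        sub = X[members].to_numpy(dtype=float)
        sub = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        U, S, Vt = np.linalg.svd(sub, full_matrices=False)
        pc = U[:, 0]
        varex[mid] = float(S[0] ** 2 / (S ** 2).sum())
        cors = np.array([np.corrcoef(pc, sub[:, j])[0, 1]
                         for j in range(sub.shape[1])])
        if cors.mean() < 0:
            pc = -pc
        pc = pc / pc.std(ddof=1)
        eig[mid] = pc
    eigdf = pd.DataFrame(eig, index=X.index)
    return eigdf, pd.Series(varex, name="variance_explained")


def _kme_table(X: pd.DataFrame, eigenproteins: pd.DataFrame,
               corr: str = "pearson") -> pd.DataFrame:
    Xs = (X - X.mean()) / X.std(ddof=1)
    Es = (eigenproteins - eigenproteins.mean()) / eigenproteins.std(ddof=1)
    n = len(X)
    K = (Xs.to_numpy().T @ Es.to_numpy()) / (n - 1)
    return pd.DataFrame(np.clip(K, -1, 1), index=X.columns,
                        columns=eigenproteins.columns)


def enforce_kme_consistency(assignments: pd.Series, X: pd.DataFrame,
                            max_rounds: int = 30, kme_min: float = 0.30,
                            ) -> tuple[pd.Series, pd.DataFrame, bool]:
    """Iteratively reassign proteins until the kME table is self-consistent.

    Each round recomputes eigenproteins and kME (correlation of every
    protein with every eigenprotein); a protein moves to its argmax-kME
    module when that beats its current module's kME, and proteins whose
    best kME falls below ``kme_min`` go grey. Converges when a round
    changes nothing.
    """
    assignments = assignments.copy()
    converged = False
    kme = pd.DataFrame(index=X.columns)
    for _ in range(max_rounds):
        mods = [m for m in sorted(assignments.unique()) if m != GREY]
        if not mods:
            return assignments, kme, True
        eig, _ = compute_eigenproteins(X, assignments)
        kme = _kme_table(X, eig)
        new = assignments.copy()
        best_mod = kme.idxmax(axis=1)
        best_val = kme.max(axis=1)
        for label in X.columns:
            cur = assignments[label]
            if best_val[label] < kme_min:
                new[label] = GREY
            elif cur == GREY or kme.loc[label, best_mod[label]] > kme.loc[label, cur] + 1e-12:
                new[label] = best_mod[label]
        # dissolve modules that fell below 2 members
        sizes = new.value_counts()
        for mid in [m for m in sizes.index if m != GREY and sizes[m] < 2]:
            new[new == mid] = GREY
        if new.equals(assignments):
            converged = True
            break
        assignments = new
    return assignments, kme, converged


def merge_close_modules(assignments: pd.Series, X: pd.DataFrame,
                        merge_cut_height: float = 0.07) -> pd.Series:
    """Merge module pairs whose eigenproteins are closer than the cut height.

    Dissimilarity is 1 minus the eigenprotein correlation; after each
    merge the eigenproteins are recomputed, until no pair remains below
    ``merge_cut_height``.
    """
    assignments = assignments.copy()
    while True:
        mods = [m for m in sorted(assignments.unique()) if m != GREY]
        if len(mods) < 2:
            return assignments
        eig, _ = compute_eigenproteins(X, assignments)
        C = np.corrcoef(eig.to_numpy(), rowvar=False)
        diss = 1.0 - C
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            return assignments
        keep, drop = sorted((eig.columns[i], eig.columns[j]))
        assignments[assignments == drop] = keep


def detect_sample_outliers(X: pd.DataFrame, z_cut: float = -2.5) -> list[str]:
    """Sample network connectivity outlier check.

    Each sample's connectivity is the sum of its signed similarities
    ``(1 + cor(s_i, s_j)) / 2`` to the other samples; samples whose
    standardized connectivity falls below ``z_cut`` are flagged.
    """
    if len(X) < 4:
        raise ValueError("need at least 4 samples")
    C = np.corrcoef(X.to_numpy(dtype=float))
    A = (1.0 + C) / 2.0
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    sd = k.std(ddof=1)
    if sd == 0:
        return []
    z = (k - k.mean()) / sd
    return [s for s, zi in zip(X.index, z) if zi < z_cut]


def correlate_with_traits(eigenproteins: pd.DataFrame, traits: pd.DataFrame,
                          method: str = "pearson",
                          ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Module x trait correlation and p-value tables.

    Missing trait values are pairwise-deleted. Also returns the critical
    |r| for significance at alpha = 0.05 at the number of samples
    available (two-sided).
    """
    rtab = pd.DataFrame(index=eigenproteins.columns, columns=traits.columns,
                        dtype=float)
    ptab = rtab.copy()
    for mod in eigenproteins.columns:
        for trait in traits.columns:
            x = eigenproteins[mod]
            y = pd.to_numeric(traits[trait], errors="coerce").reindex(x.index)
            ok = x.notna() & y.notna()
            if ok.sum() < 4 or y[ok].std() == 0:
                continue
            if method == "bicor":
                sub = pd.DataFrame({"x": x[ok], "y": y[ok]})
                r = float(bicor_matrix(sub).iloc[0, 1])
                # p from the t transform of r
                n = int(ok.sum())
                t = r * np.sqrt((n - 2) / max(1 - r ** 2, 1e-300))
                p = 2 * stats.t.sf(abs(t), n - 2)
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rtab.loc[mod, trait] = float(r)
            ptab.loc[mod, trait] = float(p)
    n = len(eigenproteins)
    tcrit = stats.t.ppf(0.975, n - 2)
    r_crit = float(np.sqrt(tcrit ** 2 / (tcrit ** 2 + n - 2)))
    return rtab, ptab, r_crit


@dataclass
class NetworkModel:
    """A constructed co-expression network: assignments, eigenproteins, kME."""

    assignments: pd.Series          # label -> module id (0 = grey)
    eigenproteins: pd.DataFrame     # samples x modules, unit variance
    kme: pd.DataFrame               # labels x modules
    variance_explained: pd.Series
    linkage: np.ndarray
    params: NetworkParams
    converged: bool = True

    @property
    def modules(self) -> list[int]:
        return [m for m in sorted(self.assignments.unique()) if m != GREY]

    def members(self, module: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module])


def build_network(X: pd.DataFrame, params: NetworkParams) -> NetworkModel:
    """Full construction: correlation -> adjacency -> TOM -> dynamic cut ->
    merge -> kME consistency -> eigenproteins."""
    corr = bicor_matrix(X) if params.corr == "bicor" else pearson_matrix(X)
    adj = adjacency(corr, params)
    tom = tom_similarity(adj, denom=params.tom_denom)
    diss = 1.0 - tom
    np.fill_diagonal(diss.values, 0.0)
    assignments, Z = cluster_modules(diss, params)
    if (assignments != GREY).sum() >= 2 and len(set(assignments) - {GREY}) >= 2:
        assignments = merge_close_modules(assignments, X, params.merge_cut_height)
    assignments, kme, converged = enforce_kme_consistency(
        assignments, X, kme_min=params.kme_min)
    mods = [m for m in sorted(assignments.unique()) if m != GREY]
    if mods:
        # renumber 1..K by decreasing size for stable reporting
        sizes = assignments.value_counts()
        order = sorted(mods, key=lambda m: (-sizes[m], m))
        remap = {old: new for new, old in enumerate(order, start=1)}
        remap[GREY] = GREY
        assignments = assignments.map(remap)
        eig, varex = compute_eigenproteins(X, assignments)
        kme = _kme_table(X, eig)
    else:
        eig = pd.DataFrame(index=X.index)
        varex = pd.Series(dtype=float)
        kme = pd.DataFrame(index=X.columns)
    return NetworkModel(assignments=assignments, eigenproteins=eig, kme=kme,
                        variance_explained=varex, linkage=Z, params=params,
                        converged=converged)
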