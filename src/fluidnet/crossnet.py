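"""Cross-network and cross-fluid module statistics.

Covers the ordered label-mapping rubric between networks measured on
different platforms/tissues, synthetic eigenproteins (a module defined
in one network summarized in another dataset), module over-representation
(Fisher exact), permutation-based module preservation (Z_summary), cell
type marker enrichment, and the within-subject cross-fluid slope
statistic Z_slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .harmonize import HarmonizedMatrix
from .model import Platform, parse_label
from .network import NetworkParams, adjacency, compute_eigenproteins, pearson_matrix

__all__ = ["map_labels", "synthetic_eigenprotein", "module_ora",
           "module_preservation", "celltype_enrichment", "zslope",
           "PreservationResult", "ZSlopeResult"]

# rubric precedence: (platform, match-on-uniprot?) in strict order
_RUBRIC = (
    (Platform.TMTMS, True), (Platform.TMTMS, False),
    (Platform.OLINK, True), (Platform.SOMASCAN, True),
    (Platform.OLINK, False), (Platform.SOMASCAN, False),
)


def map_labels(source: pd.DataFrame, target_labels: list[str]) -> pd.DataFrame:
    """Map source proteins onto a target network's canonical labels.

    ``source`` needs columns ``uniprot`` and ``gene_symbol`` (index =
    source protein identifier). Matching follows the strict 6-step
    precedence: exact UniProt to an MS label, symbol to MS, UniProt to
    Olink, UniProt to SomaScan, symbol to Olink, symbol to SomaScan.
    Each source protein maps to at most one target label; the step used
    is recorded. Unmatched proteins come back with step 0 and a null
    label.
    """
    parsed = [(lbl, parse_label(lbl)) for lbl in target_labels]
    index: dict[tuple[Platform, bool], dict[str, str]] = {}
    for (platform, by_uni) in _RUBRIC:
        lut: dict[str, str] = {}
        for lbl, cl in parsed:
            if cl.platform is not platform:
                continue
            key = cl.uniprot if by_uni else cl.symbol
            if key and key not in lut:  # first label in stable order wins
                lut[key] = lbl
        index[(platform, by_uni)] = lut

    rows = []
    for prot, row in source.iterrows():
        chosen, step = None, 0
        for k, (platform, by_uni) in enumerate(_RUBRIC, start=1):
            key = row["uniprot"] if by_uni else row["gene_symbol"]
            if key and key in index[(platform, by_uni)]:
                chosen, step = index[(platform, by_uni)][key], k
                break
        rows.append((prot, chosen, step))
    return pd.DataFrame(rows, columns=["source", "target_label", "step"]
                        ).set_index("source")


def synthetic_eigenprotein(target: pd.DataFrame, member_labels: list[str],
                           groups: pd.Series | None = None,
                           group_a: str = "AD", group_b: str = "CT"):
    """Summarize a module defined elsewhere inside the target dataset.

    First principal component over the mapped member columns of
    ``target`` (samples x labels), oriented positive to the mean member
    correlation and scaled to unit variance. When ``groups`` is given, a
    two-sided Welch t test of the scores between the two groups is
    returned as ``(scores, t, p)``; otherwise just the scores.
    """
    members = [m for m in member_labels if m in target.columns]
    if len(members) < 2:
        raise ValueError(f"fewer than 2 mapped members present "
                         f"({len(members)} of {len(member_labels)})")
    assign = pd.Series(0, index=target.columns, dtype=int)
    assign[members] = 1
    eig, _ = compute_eigenproteins(target[members], assign[members])
    scores = eig[1]
    if groups is None:
        return scores
    grp = groups.reindex(scores.index)
    a = scores[grp == group_a]
    b = scores[grp == group_b]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return scores, float(t), float(p)


def module_ora(assign_a: dict[int, set], assign_b: dict[int, set],
               background: set) -> pd.DataFrame:
    """Pairwise module over-representation between two networks.

    Modules are gene-symbol sets; the 2x2 table per (moduleA, moduleB)
    is built on the shared symbol background and tested with a
    two-tailed Fisher exact test, Benjamini-Hochberg corrected over all
    pairs.
    """
    if not background:
        raise ValueError("empty background universe")
    bg = set(background)
    rows = []
    for ma, sa in assign_a.items():
        sa = sa & bg
        for mb, sb in assign_b.items():
            sb = sb & bg
            k = len(sa & sb)
            table = [[k, len(sa) - k],
                     [len(sb) - k, len(bg) - len(sa) - len(sb) + k]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append((ma, mb, k, len(sa), len(sb), odds, p))
    out = pd.DataFrame(rows, columns=["module_a", "module_b", "overlap",
                                      "size_a", "size_b", "odds", "p"])
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


@dataclass
class PreservationResult:
    """Per-module permutation preservation statistics."""

    table: pd.DataFrame  # index module; Z_density, Z_connectivity, Z_summary, p, p_bh, significance
    n_permutations: int


def _preservation_stats(ref: np.ndarray, test: np.ndarray,
                        cols_ref: np.ndarray, cols_test: np.ndarray,
                        beta: float) -> np.ndarray:
    """Density and connectivity statistics of one candidate module.

    ``ref``/``test`` are samples x features arrays. The observed
    statistics use the same member columns on both sides
    (``cols_ref == cols_test``); the permutation null keeps the
    reference module fixed and draws the test-side columns at random,
    mirroring label permutation in the test network. Returns 5
    statistics: mean within-module test correlation, mean within-module
    test adjacency, cor(kIM), cor(kME proxy), cor(correlation vectors).
    """
    sub_r = np.corrcoef(ref[:, cols_ref], rowvar=False)
    sub_t = np.corrcoef(test[:, cols_test], rowvar=False)
    iu = np.triu_indices_from(sub_t, k=1)
    mean_cor = sub_t[iu].mean()
    adj_t = ((1.0 + sub_t) / 2.0) ** beta
    np.fill_diagonal(adj_t, 0.0)
    mean_adj = adj_t[iu[0], iu[1]].mean() if len(iu[0]) else 0.0
    adj_r = ((1.0 + sub_r) / 2.0) ** beta
    np.fill_diagonal(adj_r, 0.0)
    kim_r, kim_t = adj_r.sum(axis=1), adj_t.sum(axis=1)

    def _safe_cor(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    cor_kim = _safe_cor(kim_r, kim_t)
    # kME proxy: correlation of each member with the module mean profile
    me_r = ref[:, cols_ref].mean(axis=1)
    me_t = test[:, cols_test].mean(axis=1)
    kme_r = np.array([_safe_cor(ref[:, c], me_r) for c in cols_ref])
    kme_t = np.array([_safe_cor(test[:, c], me_t) for c in cols_test])
    cor_kme = _safe_cor(kme_r, kme_t)
    cor_cor = _safe_cor(sub_r[iu], sub_t[iu])
    return np.array([mean_cor, mean_adj, cor_kim, cor_kme, cor_cor])


def module_preservation(ref: pd.DataFrame, assignments: pd.Series,
                        test: pd.DataFrame, n_perm: int = 500,
                        seed: int = 0, beta: float = 6.5,
                        min_size: int = 3) -> PreservationResult:
    """Permutation Z_summary preservation of reference modules in test data.

    ``ref`` and ``test`` are samples x features matrices over a shared
    (already label-mapped) feature universe. For each module the
    observed density statistics (mean within-module correlation and
    adjacency in the test data) and connectivity statistics
    (reference-vs-test correlation of intramodular connectivity, of
    module-membership kME, and of the correlation vectors) are compared
    with ``n_perm`` random same-size modules; Z per statistic =
    (obs - null mean) / null SD. Z_density and Z_connectivity are the
    medians of their statistic sets and Z_summary their mean. One-sided
    normal-tail p values are BH-corrected across modules and reported as
    significance = -log10(adjusted p).
    """
    if n_perm < 1:
        raise ValueError("need at least 1 permutation")
    shared = [c for c in ref.columns if c in set(test.columns)]
    refA = ref[shared].to_numpy(dtype=float)
    testA = test[shared].to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(shared)}
    rng = np.random.default_rng(seed)

    mods, rows, skipped = [], [], []
    for mid in sorted(m for m in assignments.unique() if m != 0):
        cols = np.array([pos[l] for l in
                         assignments.index[assignments == mid] if l in pos])
        if len(cols) < min_size:
            skipped.append(mid)
            continue
        obs = _preservation_stats(refA, testA, cols, cols, beta)
        null = np.empty((n_perm, 5))
        for b in range(n_perm):
            rand = rng.choice(len(shared), size=len(cols), replace=False)
            null[b] = _preservation_stats(refA, testA, cols, rand, beta)
        sd = null.std(axis=0, ddof=1)
        sd[sd == 0] = np.nan
        z = (obs - null.mean(axis=0)) / sd
        z_density = float(np.nanmedian(z[:2]))
        z_connectivity = float(np.nanmedian(z[2:]))
        z_summary = (z_density + z_connectivity) / 2.0
        mods.append(mid)
        rows.append((len(cols), z_density, z_connectivity, z_summary,
                     float(stats.norm.sf(z_summary))))
    table = pd.DataFrame(rows, index=pd.Index(mods, name="module"),
                         columns=["size", "Z_density", "Z_connectivity",
                                  "Z_summary", "p"])
    if len(table):
        table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significance"] = -np.log10(np.clip(table["p_bh"], 1e-300, None))
    for mid in skipped:
        table.loc[mid] = np.nan
    return PreservationResult(table=table, n_permutations=n_perm)


def celltype_enrichment(assignments: dict[int, set], markers: dict[str, set],
                        background: set) -> pd.DataFrame:
    """One-tailed Fisher enrichment of cell-type marker sets in modules."""
    if not background:
        raise ValueError("empty background universe")
    bg = set(background)
    rows = []
    for mid, members in assignments.items():
        members = members & bg
        for ct, mk in markers.items():
            mk = mk & bg
            if not mk:
                continue
            k = len(members & mk)
            table = [[k, len(members) - k],
                     [len(mk) - k, len(bg) - len(members) - len(mk) + k]]
            odds, p = stats.fisher_exact(table, alternative="greater")
            rows.append((mid, ct, k, odds, p))
    out = pd.DataFrame(rows, columns=["module", "cell_type", "overlap",
                                      "odds", "p"])
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


@dataclass
class ZSlopeResult:
    table: pd.DataFrame  # per module: mean slopes, raw difference, Z_slope


def zslope(eigen_fluid1: pd.DataFrame, eigen_fluid2: pd.DataFrame,
           groups: pd.Series, group_a: str = "AD", group_b: str = "CT",
           standardize: bool = True) -> ZSlopeResult:
    """Within-subject cross-fluid slope difference between AD and control.

    Eigenproteins are z-scored within fluid; per subject the slope is
    the fluid-2 minus fluid-1 z score, and
    ``Z_slope = (mean slope_AD - mean slope_CT) / sqrt(SE_AD^2 + SE_CT^2)``.
    The unstandardized mean-slope difference is emitted alongside.
    """
    common = eigen_fluid1.index.intersection(eigen_fluid2.index)
    if len(common) == 0:
        raise ValueError("no shared subjects across fluids")
    grp = groups.reindex(common)
    rows = []
    for mod in eigen_fluid1.columns:
        if mod not in eigen_fluid2.columns:
            continue
        z1 = eigen_fluid1.loc[common, mod].astype(float)
        z2 = eigen_fluid2.loc[common, mod].astype(float)
        if standardize:
            z1 = (z1 - z1.mean()) / z1.std(ddof=1)
            z2 = (z2 - z2.mean()) / z2.std(ddof=1)
        slope = z2 - z1
        a = slope[grp == group_a]
        b = slope[grp == group_b]
        diff = float(a.mean() - b.mean())
        va = a.var(ddof=1) / len(a) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) / len(b) if len(b) > 1 else 0.0
        if va + vb == 0:
            z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            z = diff / np.sqrt(va + vb)
        rows.append((mod, float(a.mean()), float(b.mean()), diff, float(z),
                     len(a), len(b)))
    table = pd.DataFrame(rows, columns=["module", f"mean_slope_{group_a}",
                                        f"mean_slope_{group_b}", "slope_diff",
                                        "Z_slope", f"n_{group_a}", f"n_{group_b}"]
                         ).set_index("module")
    return ZSlopeResult(table=table)
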