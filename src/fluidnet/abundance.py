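"""Differential abundance, absolute-concentration calibration, ranked
cumulative abundance curves, and the correlation power calculation.

Differential abundance deliberately applies no median normalization
between the diagnostic groups: a genuine global shift in measured
protein levels (as seen for low-abundance plasma proteins in AD) is a
signal of interest, not a nuisance to be removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MeasurementMatrix, Scale

__all__ = ["differential_abundance", "calibrate_to_reference",
           "cumulative_abundance_curves", "top_fraction_comparison",
           "min_detectable_rho", "CalibratedAbundance"]


def differential_abundance(matrix: MeasurementMatrix, groups: pd.Series,
                           group_a: str = "AD", group_b: str = "CT",
                           include_below_lod: bool = True,
                           welch: bool = True, min_per_group: int = 3,
                           ) -> pd.DataFrame:
    """Two-sided two-sample t test per assay on log2 values, AD minus control.

    No row or column normalization is applied. Assays with fewer than
    ``min_per_group`` usable values in either group are skipped and
    reported with NaN statistics. Benjamini-Hochberg adjusted p values
    are emitted alongside the raw ones.
    """
    grp = groups.reindex(matrix.samples)
    ga = grp.index[grp == group_a]
    gb = grp.index[grp == group_b]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError(f"need samples in both groups {group_a!r} and {group_b!r}")
    log2v = matrix.to_log2().numeric_values(include_below_lod=include_below_lod)
    rows = []
    for assay in matrix.assays:
        a = log2v.loc[ga, assay].dropna()
        b = log2v.loc[gb, assay].dropna()
        if len(a) < min_per_group or len(b) < min_per_group:
            rows.append((assay, np.nan, np.nan, np.nan, len(a), len(b), True))
            continue
        diff = float(a.mean() - b.mean())
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append((assay, diff, float(t), float(p), len(a), len(b), False))
    out = pd.DataFrame(rows, columns=["assay_id", "log2_diff", "t", "p",
                                      f"n_{group_a}", f"n_{group_b}", "skipped"]
                       ).set_index("assay_id")
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        from statsmodels.stats.multitest import multipletests
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


@dataclass
class CalibratedAbundance:
    """Per-gene absolute concentrations (pg/L) anchored to a reference table."""

    table: pd.DataFrame       # samples x genes, pg/L
    selected_assay: pd.Series  # gene -> assay_id used
    reference: pd.Series       # gene -> reference pg/L


def calibrate_to_reference(matrix: MeasurementMatrix, metas,
                           reference: pd.Series, groups: pd.Series,
                           buffer_medians: pd.Series | None = None,
                           control_group: str = "CT") -> CalibratedAbundance:
    """Scale background-subtracted linear signals to absolute concentrations.

    Per reference gene, the assay with the maximum mean signal is
    selected; its buffer median is subtracted; missing or non-positive
    cells are imputed as one-half the minimum assayed nonzero signal for
    the geometric-mean step; and the gene is scaled so that the
    geometric mean of the control group equals the reference
    concentration (pg/L) exactly.
    """
    if (reference <= 0).any():
        bad = reference.index[reference <= 0].tolist()
        raise ValueError(f"non-positive reference concentrations: {bad}")
    lin = matrix.to_linear().numeric_values()
    by_gene: dict[str, list[str]] = {}
    for m in metas:
        if m.gene_symbol and m.assay_id in lin.columns:
            by_gene.setdefault(m.gene_symbol, []).append(m.assay_id)
    controls = groups.reindex(matrix.samples)
    ctrl_ids = controls.index[controls == control_group]

    cols, chosen = {}, {}
    for gene, conc in reference.items():
        ids = by_gene.get(gene)
        if not ids:
            continue
        means = {a: lin[a].mean() for a in ids}
        assay = min(means, key=lambda a: (-means[a], a))  # max mean signal
        sig = lin[assay].copy()
        if buffer_medians is not None and assay in buffer_medians.index \
                and np.isfinite(buffer_medians[assay]):
            sig = sig - buffer_medians[assay]
        sig[sig <= 0] = np.nan
        nonzero_min = sig.min()
        # half-minimum imputation enters the geometric mean only; missing
        # cells stay missing in the calibrated output
        filled = sig.fillna(nonzero_min / 2.0)
        geo_ctrl = np.exp(np.log(filled.loc[ctrl_ids]).mean())
        scale = conc / geo_ctrl
        cols[gene] = sig * scale
        chosen[gene] = assay
    table = pd.DataFrame(cols, index=matrix.samples)
    return CalibratedAbundance(table=table,
                               selected_assay=pd.Series(chosen),
                               reference=reference.loc[list(cols)])


def cumulative_abundance_curves(data, groups: pd.Series, mode: str = "uncalibrated",
                                buffer_medians: pd.Series | None = None,
                                ) -> pd.DataFrame:
    """Ranked cumulative abundance curves per diagnostic group.

    ``mode='uncalibrated'``: ``data`` is a linear-scale
    :class:`MeasurementMatrix`; assays are ranked by mean
    background-subtracted signal (descending) and the curve is the
    cumulative sum of per-rank group medians.

    ``mode='calibrated'``: ``data`` is a :class:`CalibratedAbundance`;
    genes are ranked by reference concentration and the value at rank r
    is the per-group median of the summed log10 concentrations of all
    lesser-abundant genes below r (left-truncated cumulative sum), which
    is monotone nondecreasing in rank.
    """
    if mode == "uncalibrated":
        lin = data.to_linear().numeric_values()
        if buffer_medians is not None:
            lin = lin.sub(buffer_medians.reindex(lin.columns), axis=1)
        order = lin.mean().sort_values(ascending=False).index
        rows = []
        for gname, gidx in groups.groupby(groups).groups.items():
            gidx = [s for s in gidx if s in lin.index]
            if not gidx:
                raise ValueError(f"group {gname!r} has no samples")
            med = lin.loc[gidx, order].median()
            cum = med.cumsum()
            for r, (assay, v) in enumerate(cum.items(), start=1):
                rows.append((gname, r, assay, float(v)))
        return pd.DataFrame(rows, columns=["group", "rank", "assay_id",
                                           "cumulative_signal"])
    if mode == "calibrated":
        table = data.table
        order = data.reference.sort_values(ascending=True).index  # low to high
        log10 = np.log10(table[order])
        # missing calibrated cells: half the gene's minimum observed concentration
        log10 = log10.fillna(log10.min() - np.log10(2.0))
        rows = []
        for gname, gidx in groups.groupby(groups).groups.items():
            gidx = [s for s in gidx if s in table.index]
            if not gidx:
                raise ValueError(f"group {gname!r} has no samples")
            # value at rank r = group median of the summed log10 concentration
            # over all genes of lower reference abundance
            persample = log10.loc[gidx].cumsum(axis=1).shift(1, axis=1).fillna(0.0)
            med = persample.median()
            for r, gene in enumerate(order, start=1):
                rows.append((gname, r, gene, float(med[gene])))
        return pd.DataFrame(rows, columns=["group", "rank", "gene_symbol",
                                           "cumulative_log10_pg_per_L"])
    raise ValueError("mode must be 'uncalibrated' or 'calibrated'")


def top_fraction_comparison(matrix: MeasurementMatrix, groups: pd.Series,
                            frac: float = 0.05, group_a: str = "AD",
                            group_b: str = "CT") -> pd.DataFrame:
    """Compare per-sample summed signal of the strongest assays vs all assays.

    The top set is the ceiling(frac * n_assays) assays by mean signal.
    A two-sided Welch t test (AD vs control) is run on the per-sample
    sums over the top set and over all assays.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0,1]")
    lin = matrix.to_linear().numeric_values()
    order = lin.mean().sort_values(ascending=False).index
    k = int(np.ceil(frac * len(order)))
    grp = groups.reindex(matrix.samples)
    rows = []
    for name, cols in (("top_fraction", order[:k]), ("all", order)):
        sums = lin[list(cols)].sum(axis=1, min_count=1)
        a = sums[grp == group_a].dropna()
        b = sums[grp == group_b].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((name, len(cols), float(a.mean()), float(b.mean()),
                     float(t), float(p)))
    return pd.DataFrame(rows, columns=["set", "n_assays", f"mean_{group_a}",
                                       f"mean_{group_b}", "t", "p"])


def min_detectable_rho(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest |rho| detectable by a two-sided Pearson test at the given n.

    Fisher z approximation: tanh((z_{1-alpha/2} + z_{power}) / sqrt(n-3)).
    At n=36, alpha=0.05, power=0.80 this is 0.45 to two decimals.
    """
    if n < 4:
        raise ValueError("need at least 4 samples")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return float(np.tanh(z / np.sqrt(n - 3)))
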