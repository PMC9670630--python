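"""Two-way median-polish batch correction (TAMPOR) and its transposed
adaptation for cross-platform harmonization.

Standard TAMPOR removes TMT batch effects by expressing every reporter
intensity as a ratio to the pooled global internal standard (GIS) of its
batch and then median-polishing the log2 ratios, driving both protein
and sample medians to zero. The transposed variant treats samples as
though they were proteins: within each platform the central tendency of
the proteins measured on all platforms (the "anchors") plays the role
of the GIS, which harmonizes platforms into one complete
log2(abundance/central tendency) matrix per fluid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    BatchDesign, CanonicalLabel, Fluid, MeasurementMatrix, Platform, Scale,
    Status, make_label,
)

__all__ = ["PolishResult", "HarmonizedMatrix", "median_polish",
           "tampor_batch_correct", "transposed_tampor"]


@dataclass
class PolishResult:
    """Decomposition ``input = overall + row_effects + col_effects + residual``."""

    residual: pd.DataFrame
    row_effects: pd.Series
    col_effects: pd.Series
    overall: float
    iterations: int
    converged: bool

    def reconstruct(self) -> pd.DataFrame:
        return (self.residual
                .add(self.row_effects, axis=0)
                .add(self.col_effects, axis=1) + self.overall)


def median_polish(matrix: pd.DataFrame, tol: float = 1e-8,
                  max_iter: int = 100, nan_policy: str = "raise") -> PolishResult:
    """Tukey's two-way median polish.

    Alternates row-then-column median sweeps until the largest absolute
    median removed in a full sweep falls below ``tol`` or ``max_iter``
    sweeps have run. With ``nan_policy='omit'``, medians ignore NaN
    cells (used for batch-level TMT missingness); the reconstruction
    identity then holds on the non-missing cells.
    """
    X = matrix.to_numpy(dtype=float).copy()
    if nan_policy == "raise":
        if not np.isfinite(X).all():
            raise ValueError("median_polish: non-finite input "
                             "(use nan_policy='omit' for missing cells)")
        med = np.median
    elif nan_policy == "omit":
        if np.isinf(X).any():
            raise ValueError("median_polish: infinite input")
        med = np.nanmedian
    else:
        raise ValueError("nan_policy must be 'raise' or 'omit'")

    n_rows, n_cols = X.shape
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    overall = 0.0
    converged = False
    it = 0
    with np.errstate(invalid="ignore"):
        for it in range(1, max_iter + 1):
            rmed = med(X, axis=1)
            rmed = np.where(np.isfinite(rmed), rmed, 0.0)
            X -= rmed[:, None]
            row_eff += rmed
            ce_med = med(col_eff) if n_cols else 0.0
            col_eff -= ce_med
            overall += ce_med

            cmed = med(X, axis=0)
            cmed = np.where(np.isfinite(cmed), cmed, 0.0)
            X -= cmed[None, :]
            col_eff += cmed
            re_med = med(row_eff) if n_rows else 0.0
            row_eff -= re_med
            overall += re_med

            if max(np.abs(rmed).max(initial=0.0), np.abs(cmed).max(initial=0.0)) < tol:
                converged = True
                break
    return PolishResult(
        residual=pd.DataFrame(X, index=matrix.index, columns=matrix.columns),
        row_effects=pd.Series(row_eff, index=matrix.index),
        col_effects=pd.Series(col_eff, index=matrix.columns),
        overall=float(overall), iterations=it, converged=converged)


def tampor_batch_correct(tmt: MeasurementMatrix, design: BatchDesign,
                         gis_ids: list[str] | None = None,
                         tol: float = 1e-8, max_iter: int = 100,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """TAMPOR batch correction of a TMT reporter-intensity matrix.

    ``tmt`` must be linear-scale and contain the GIS channels as
    pseudo-samples named ``GIS:<batch>:<channel>`` (or pass their IDs in
    ``gis_ids``). Per protein and batch, each sample's intensity is
    divided by the batch GIS value (geometric mean when a batch carries
    several GIS channels), log2-transformed, and the resulting subject x
    protein matrix is median-polished.

    Returns ``(corrected, clean_relative, dropped)`` where ``corrected``
    is the polished log2 ratio matrix (subjects only), ``clean_relative``
    is ``2^(residual + stored protein-wise medians)`` — all-positive, in
    the same form as reporter abundance — and ``dropped`` lists proteins
    with no usable GIS value in any measured batch.
    """
    lin = tmt.to_linear()
    if gis_ids is None:
        gis_ids = [s for s in lin.samples if s.startswith("GIS:")]
    subjects = [s for s in lin.samples if s not in set(gis_ids)]
    vals = lin.numeric_values()

    gis_by_batch: dict[str, list[str]] = {}
    for g in gis_ids:
        batch = g.split(":")[1] if g.startswith("GIS:") else design.batch_of(g)
        gis_by_batch.setdefault(batch, []).append(g)

    ratio = pd.DataFrame(np.nan, index=subjects, columns=lin.assays)
    dropped: list[str] = []
    for batch in design.batches:
        members = [s for s in subjects if design.batch_of(s) == batch]
        gchans = gis_by_batch.get(batch, [])
        if not members or not gchans:
            continue
        g = vals.loc[gchans]
        if (g.to_numpy()[np.isfinite(g.to_numpy())] <= 0).any():
            bad = g.columns[(g <= 0).any()].tolist()
            raise ValueError(f"batch {batch}: non-positive GIS value for {bad}")
        gis_geo = np.exp2(np.log2(g).mean(axis=0))  # geometric mean across GIS channels
        ratio.loc[members] = np.log2(vals.loc[members].divide(gis_geo, axis=1))

    no_gis = ratio.columns[ratio.isna().all(axis=0)]
    dropped = list(no_gis)
    ratio = ratio.drop(columns=no_gis)

    polish = median_polish(ratio, tol=tol, max_iter=max_iter, nan_policy="omit")
    corrected = polish.residual
    # relative protein abundances = row-wise (per-protein) medians of the log2
    # ratios, reinserted to restore an all-positive reporter-abundance form
    protein_medians = ratio.median(axis=0, skipna=True)
    clean_relative = np.exp2(corrected.add(protein_medians, axis=1))
    return corrected, clean_relative, dropped


@dataclass
class HarmonizedMatrix:
    """Complete samples x labeled-assays log2(abundance/central tendency) matrix."""

    values: pd.DataFrame                # samples x rendered CanonicalLabel strings
    anchor_labels: list[str]            # labels used as cross-platform denominators
    platform_of_label: pd.Series        # rendered label -> Platform

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()[:5]
            raise ValueError(f"harmonized matrix contains missing values, e.g. {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)


def transposed_tampor(blocks: dict[Platform, tuple[MeasurementMatrix, list]],
                      anchor_uniprots: set[str] | None = None,
                      tol: float = 1e-8, max_iter: int = 5000,
                      ) -> HarmonizedMatrix:
    """Harmonize per-platform blocks of one fluid into a single complete matrix.

    ``blocks`` maps each platform to ``(matrix, metas)``; matrices must
    share the same sample set and contain no truly-missing cells
    (below-LOD values are retained as numbers). Anchors are the proteins
    (UniProt accessions) measured in every block; if ``anchor_uniprots``
    is given it is intersected with that set.

    The algorithm alternates (a) subtracting each sample's median over
    its platform's anchor proteins — the cross-platform central
    tendency, playing the role of the GIS — and (b) subtracting each
    protein's median over samples, until convergence. The output is
    log2(abundance/central tendency) with anchors' per-sample medians at
    zero and every label's median at zero.
    """
    if not blocks:
        raise ValueError("no platform blocks supplied")
    sample_sets = {tuple(m.samples) for m, _ in blocks.values()}
    base_samples = None
    for m, _ in blocks.values():
        ss = set(m.samples)
        if base_samples is None:
            base_samples = ss
        elif ss != base_samples:
            raise ValueError("platform blocks do not share the same sample set")
    samples = next(iter(blocks.values()))[0].samples

    # anchors: proteins present in every block
    per_block_uni = []
    for platform, (m, metas) in blocks.items():
        avail = set(m.assays)
        per_block_uni.append({meta.uniprot for meta in metas
                              if meta.uniprot and meta.assay_id in avail})
    anchors = set.intersection(*per_block_uni)
    if anchor_uniprots is not None:
        anchors &= set(anchor_uniprots)
    if not anchors:
        raise ValueError("no anchor proteins shared by all platform blocks")

    col_frames = []
    anchor_labels: list[str] = []
    platform_of: dict[str, Platform] = {}
    block_cols: dict[Platform, list[str]] = {}
    block_anchor_cols: dict[Platform, list[str]] = {}
    for platform, (m, metas) in blocks.items():
        lm = m.to_log2()
        vals = lm.numeric_values()
        if vals.isna().any().any():
            bad = vals.columns[vals.isna().any()].tolist()
            raise ValueError(f"{platform.value}: truly-missing cells remain in "
                             f"{len(bad)} assays (restrict to complete cases first)")
        rename = {}
        acolumns, cols = [], []
        for meta in metas:
            if meta.assay_id not in vals.columns:
                continue
            label = make_label(meta).rendered
            rename[meta.assay_id] = label
            cols.append(label)
            platform_of[label] = platform
            if meta.uniprot in anchors:
                acolumns.append(label)
        sub = vals[list(rename)].rename(columns=rename).loc[samples]
        col_frames.append(sub)
        block_cols[platform] = cols
        block_anchor_cols[platform] = acolumns
        anchor_labels.extend(acolumns)
        if not acolumns:
            raise ValueError(f"platform {platform.value} lacks anchor assays")

    X = pd.concat(col_frames, axis=1)
    arr = X.to_numpy()
    anchor_idx = {p: [X.columns.get_loc(c) for c in block_anchor_cols[p]]
                  for p in blocks}
    col_idx = {p: [X.columns.get_loc(c) for c in block_cols[p]] for p in blocks}

    converged = False
    for _ in range(max_iter):
        delta = 0.0
        for p in blocks:  # per-sample anchor-median centering within platform
            a = arr[:, anchor_idx[p]]
            med = np.median(a, axis=1)
            arr[:, col_idx[p]] -= med[:, None]
            delta = max(delta, np.abs(med).max(initial=0.0))
        cmed = np.median(arr, axis=0)  # per-label centering
        arr -= cmed[None, :]
        delta = max(delta, np.abs(cmed).max(initial=0.0))
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError("transposed TAMPOR did not converge")

    values = pd.DataFrame(arr, index=X.index, columns=X.columns)
    return HarmonizedMatrix(values=values, anchor_labels=anchor_labels,
                            platform_of_label=pd.Series(platform_of))
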