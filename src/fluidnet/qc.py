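"""Signal-to-noise and LOD modeling, filtering, duplicate reduction,
cross-platform pairing, and depletion censoring.

S:N for an assay is ``(median sample signal - median buffer signal) /
median buffer signal`` on the linear scale; it may legitimately be
negative. The limit of detection is the median log2 buffer signal plus
three standard deviations of the assay's log2 buffer measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MeasurementMatrix, Scale, Status

__all__ = [
    "NoiseProfile", "FilterReport", "compute_snr", "compute_lod", "apply_lod",
    "filter_missingness", "select_snr_threshold", "reduce_duplicate_assays",
    "match_assays_across_platforms", "censor_depletion_affected",
]


@dataclass
class NoiseProfile:
    """Per-assay buffer statistics, LOD and S:N (one DataFrame row per assay)."""

    table: pd.DataFrame  # columns: buffer_median_linear, buffer_sd_log2, n_buffer, lod_log2, snr

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class FilterReport:
    """Before/after accounting of one filtering stage."""

    stage: str
    assays_before: int
    assays_after: int
    removed: dict[str, str] = field(default_factory=dict)  # assay_id -> reason

    def __post_init__(self) -> None:
        assert self.assays_before - self.assays_after == len(self.removed), \
            f"{self.stage}: count mismatch"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"assay_id": list(self.removed),
                             "reason": list(self.removed.values()),
                             "stage": self.stage})


def _linear_buffer(buffer: pd.DataFrame, scale: Scale) -> pd.DataFrame:
    return np.exp2(buffer) if scale is Scale.LOG2 else buffer


def compute_snr(matrix: MeasurementMatrix, buffer: pd.DataFrame) -> NoiseProfile:
    """Buffer statistics and S:N per assay.

    ``buffer`` holds buffer-well replicate rows in the matrix's native
    scale. S:N is evaluated at the assay's median sample signal over
    numeric (observed or below-LOD) cells. Assays absent from the buffer
    table get NaN statistics and are flagged, not dropped.
    """
    lin = matrix.to_linear()
    sig = lin.numeric_values()
    rows = []
    for assay in matrix.assays:
        if assay not in buffer.columns or buffer[assay].dropna().empty:
            rows.append((assay, np.nan, np.nan, 0, np.nan, np.nan))
            continue
        buf_lin = _linear_buffer(buffer[[assay]], matrix.scale)[assay].dropna()
        bmed = float(buf_lin.median())
        if bmed <= 0:
            raise ValueError(f"assay {assay!r}: buffer median {bmed} <= 0")
        blog2 = np.log2(buf_lin)
        bsd = float(blog2.std(ddof=1)) if len(buf_lin) >= 2 else np.nan
        lod = float(blog2.median() + 3.0 * bsd) if len(buf_lin) >= 2 else np.nan
        med_sig = float(sig[assay].median())
        snr = (med_sig - bmed) / bmed
        rows.append((assay, bmed, bsd, len(buf_lin), lod, snr))
    table = pd.DataFrame(rows, columns=["assay_id", "buffer_median_linear",
                                        "buffer_sd_log2", "n_buffer",
                                        "lod_log2", "snr"]).set_index("assay_id")
    return NoiseProfile(table)


def compute_lod(buffer: pd.DataFrame, scale: Scale = Scale.LINEAR,
                supplied: pd.Series | None = None) -> pd.Series:
    """LOD per assay: median log2 buffer + 3 SD of log2 buffer.

    Externally supplied LODs (e.g. Olink's predetermined values) take
    precedence. Assays with fewer than 2 buffer replicates and no
    supplied LOD come back NaN — flagged, never silently passed.
    """
    lods = {}
    for assay in buffer.columns:
        if supplied is not None and assay in supplied.index and np.isfinite(supplied[assay]):
            lods[assay] = float(supplied[assay])
            continue
        vals = _linear_buffer(buffer[[assay]], scale)[assay].dropna()
        if len(vals) < 2:
            lods[assay] = np.nan
            continue
        blog2 = np.log2(vals)
        lods[assay] = float(blog2.median() + 3.0 * blog2.std(ddof=1))
    return pd.Series(lods, name="lod_log2")


def apply_lod(matrix: MeasurementMatrix, lods: pd.Series) -> MeasurementMatrix:
    """Mark observed cells below their assay's LOD as BELOW_LOD (value kept)."""
    vals = matrix.values.to_numpy()
    stat = matrix.status.to_numpy().copy()
    if matrix.scale is Scale.LOG2:
        log2v = vals
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            log2v = np.log2(np.where(vals > 0, vals, np.nan))
    arr = lods.reindex(matrix.assays).to_numpy()
    with np.errstate(invalid="ignore"):
        below = (log2v < arr) & (stat == int(Status.OBSERVED))
    stat[below] = int(Status.BELOW_LOD)
    return MeasurementMatrix(matrix.values.copy(),
                             pd.DataFrame(stat, index=matrix.values.index,
                                          columns=matrix.values.columns),
                             matrix.scale)


MISSING_STATUSES_DEFAULT = (Status.BELOW_LOD, Status.QC_FLAGGED, Status.NOT_MEASURED)


def filter_missingness(matrix: MeasurementMatrix, max_frac: float = 0.75,
                       missing_statuses=MISSING_STATUSES_DEFAULT,
                       ) -> tuple[MeasurementMatrix, FilterReport]:
    """First-pass filter: keep assays missing in at most floor(max_frac * n) samples.

    At n=36 and max_frac=0.75 an assay survives with up to 27 missing
    values, i.e. measured in at least 9 subjects.
    """
    if not 0 <= max_frac < 1:
        raise ValueError("max_frac must be in [0,1)")
    n = len(matrix.samples)
    budget = int(np.floor(max_frac * n))
    miss = matrix.status.isin([int(s) for s in missing_statuses]).sum(axis=0)
    keep = [a for a in matrix.assays if miss[a] <= budget]
    keep_set = set(keep)
    removed = {a: f"missing_{int(miss[a])}_of_{n}" for a in matrix.assays
               if a not in keep_set}
    report = FilterReport("missingness", len(matrix.assays), len(keep), removed)
    return matrix.subset_assays(keep), report


def _paired_correlations(matrixA: MeasurementMatrix, matrixB: MeasurementMatrix,
                         pairs: list[tuple[str, str]]) -> pd.Series:
    """Within-subject Pearson r per paired assay, on log2 values."""
    la = matrixA.to_log2().numeric_values()
    lb = matrixB.to_log2().numeric_values()
    common = la.index.intersection(lb.index)
    out = {}
    for a, b in pairs:
        x, y = la.loc[common, a], lb.loc[common, b]
        ok = x.notna() & y.notna()
        if ok.sum() >= 3 and x[ok].std() > 0 and y[ok].std() > 0:
            out[(a, b)] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out, dtype=float)


def select_snr_threshold(filtered: MeasurementMatrix, filtered_meta,
                         profile: NoiseProfile,
                         others: list[tuple[MeasurementMatrix, list]],
                         grid=None) -> tuple[float, pd.DataFrame]:
    """Empirical S:N threshold search.

    For each candidate cutoff, restrict the S:N-filtered platform to
    assays at or above the cutoff, pair with each other platform
    (UniProt first, then symbol, best-correlated candidate), compute the
    within-subject Pearson correlation per paired protein, take the
    median over proteins and then the mean over platform pairs, and
    return the grid value maximizing that summary (ties -> smallest).
    """
    from .model import DEFAULT_SNR_GRID
    grid = list(grid) if grid is not None else list(DEFAULT_SNR_GRID)
    snr = profile["snr"]
    rows = []
    for cutoff in grid:
        keep = [a for a in filtered.assays if np.isfinite(snr.get(a, np.nan))
                and snr[a] >= cutoff]
        sub = filtered.subset_assays(keep)
        sub_meta = [m for m in filtered_meta if m.assay_id in set(keep)]
        medians = []
        n_pairs_total = 0
        for other_matrix, other_meta in others:
            pairs = match_assays_across_platforms(sub_meta, other_meta,
                                                  sub, other_matrix)
            cors = _paired_correlations(sub, other_matrix, pairs)
            n_pairs_total += len(cors)
            if len(cors) >= 5:
                medians.append(float(cors.median()))
        rows.append((cutoff, len(keep), n_pairs_total,
                     float(np.mean(medians)) if medians else np.nan))
    curve = pd.DataFrame(rows, columns=["snr_cutoff", "n_assays", "n_paired",
                                        "median_correlation"])
    valid = curve.dropna(subset=["median_correlation"])
    if valid.empty:
        raise ValueError("no grid point leaves at least 5 paired proteins")
    best = valid.loc[valid["median_correlation"].idxmax(), "median_correlation"]
    threshold = float(valid.loc[valid["median_correlation"] >= best - 1e-12,
                                "snr_cutoff"].min())
    return threshold, curve


def reduce_duplicate_assays(matrix: MeasurementMatrix, metas,
                            ) -> tuple[MeasurementMatrix, FilterReport, list]:
    """Collapse duplicate assays of one target to a single best replicate.

    Duplicates share a UniProt accession (or gene symbol when UniProt is
    empty). The representative is chosen lexicographically: highest mean
    pairwise correlation with the other replicates, then highest median
    signal, then largest log2 dynamic range (p95 - p5), then stable ID
    order.
    """
    groups: dict[str, list[str]] = {}
    by_id = {m.assay_id: m for m in metas}
    for m in metas:
        if m.assay_id not in matrix.values.columns or m.is_control_probe:
            continue
        key = m.uniprot or f"sym:{m.gene_symbol}"
        groups.setdefault(key, []).append(m.assay_id)

    log2v = matrix.to_log2().numeric_values()
    keep: list[str] = []
    removed: dict[str, str] = {}
    for key, ids in groups.items():
        if len(ids) == 1:
            keep.append(ids[0])
            continue
        scores = []
        for a in ids:
            cors = []
            for b in ids:
                if b == a:
                    continue
                x, y = log2v[a], log2v[b]
                ok = x.notna() & y.notna()
                if ok.sum() >= 3 and x[ok].std() > 0 and y[ok].std() > 0:
                    cors.append(float(np.corrcoef(x[ok], y[ok])[0, 1]))
            mean_cor = float(np.mean(cors)) if cors else -np.inf
            med_sig = float(log2v[a].median())
            rng95 = float(log2v[a].quantile(0.95) - log2v[a].quantile(0.05))
            scores.append((mean_cor, med_sig, rng95, a))
        # stable ID order as the final tie-break: descending on the numeric
        # criteria, ascending on the ID
        best = min(scores, key=lambda t: (-t[0], -t[1], -t[2], t[3]))
        keep.append(best[3])
        for a in ids:
            if a != best[3]:
                removed[a] = f"duplicate_of_{best[3]}"
    keep_ordered = [a for a in matrix.assays if a in set(keep)]
    report = FilterReport("duplicate_reduction", len(matrix.assays),
                          len(keep_ordered), removed)
    kept_meta = [by_id[a] for a in keep_ordered if a in by_id]
    return matrix.subset_assays(keep_ordered), report, kept_meta


def match_assays_across_platforms(metaA, metaB,
                                  matrixA: MeasurementMatrix | None = None,
                                  matrixB: MeasurementMatrix | None = None,
                                  ) -> list[tuple[str, str]]:
    """Pair assays across two platforms.

    Exact UniProt accession matches take precedence; remaining assays
    pair by gene symbol. When several candidates compete for one target
    (e.g. multiple SOMAmers for one protein), the candidate with the
    highest within-subject Pearson correlation is kept, provided
    matrices are supplied; otherwise the first in stable ID order.
    """
    availA = set(matrixA.assays) if matrixA is not None else None
    availB = set(matrixB.assays) if matrixB is not None else None
    mA = [m for m in metaA if not m.is_control_probe
          and (availA is None or m.assay_id in availA)]
    mB = [m for m in metaB if not m.is_control_probe
          and (availB is None or m.assay_id in availB)]

    def index_by(metas, attr):
        out: dict[str, list[str]] = {}
        for m in metas:
            key = getattr(m, attr)
            if key:
                out.setdefault(key, []).append(m.assay_id)
        return out

    pairs: list[tuple[str, str]] = []
    usedA: set[str] = set()
    usedB: set[str] = set()

    def best_candidate(cands_a: list[str], cands_b: list[str]) -> tuple[str, str]:
        combos = [(a, b) for a in cands_a for b in cands_b]
        if len(combos) == 1 or matrixA is None or matrixB is None:
            return combos[0]
        cors = _paired_correlations(matrixA, matrixB, combos)
        if cors.empty:
            return combos[0]
        return cors.idxmax()

    for attr in ("uniprot", "gene_symbol"):
        idxA = index_by([m for m in mA if m.assay_id not in usedA], attr)
        idxB = index_by([m for m in mB if m.assay_id not in usedB], attr)
        for key in idxA:
            if key in idxB:
                a, b = best_candidate(sorted(idxA[key]), sorted(idxB[key]))
                pairs.append((a, b))
                usedA.add(a)
                usedB.add(b)
    return pairs


def censor_depletion_affected(depleted: MeasurementMatrix, depleted_meta,
                              undepleted: MeasurementMatrix, undepleted_meta,
                              groups: pd.Series, min_pairs: int = 9,
                              min_per_group: int = 3,
                              ) -> tuple[list[str], FilterReport, pd.DataFrame]:
    """Censor proteins whose abundance is distorted by high-abundance depletion.

    Proteins matched by identical UniProt accession across the depleted
    and undepleted matrices are eligible when they share at least
    ``min_pairs`` paired measurements and at least ``min_per_group``
    per case-status group. A protein is censored when the Pearson
    correlation of its paired log2 values is <= 0 or when its AD-CT
    direction of change differs between the two matrices.

    Returns (censored UniProt accessions, report over eligible proteins,
    detail table).
    """
    uniA = {m.uniprot: m.assay_id for m in depleted_meta
            if m.uniprot and m.assay_id in set(depleted.assays)}
    uniB = {m.uniprot: m.assay_id for m in undepleted_meta
            if m.uniprot and m.assay_id in set(undepleted.assays)}
    shared = sorted(set(uniA) & set(uniB))
    la = depleted.to_log2().numeric_values()
    lb = undepleted.to_log2().numeric_values()
    common = la.index.intersection(lb.index)
    grp = groups.reindex(common)
    is_ad = (grp == "AD").to_numpy()
    is_ct = (grp == "CT").to_numpy()

    rows, censored, skipped = [], [], []
    for uni in shared:
        x = la.loc[common, uniA[uni]]
        y = lb.loc[common, uniB[uni]]
        ok = (x.notna() & y.notna()).to_numpy()
        n_ad, n_ct = int((ok & is_ad).sum()), int((ok & is_ct).sum())
        if ok.sum() < min_pairs or n_ad < min_per_group or n_ct < min_per_group:
            skipped.append(uni)
            continue
        rho = float(np.corrcoef(x[ok], y[ok])[0, 1])
        dA = float(x[ok & is_ad].mean() - x[ok & is_ct].mean())
        dB = float(y[ok & is_ad].mean() - y[ok & is_ct].mean())
        discordant = np.sign(dA) != np.sign(dB)
        censor = rho <= 0 or discordant
        rows.append((uni, rho, dA, dB, bool(discordant), bool(censor)))
        if censor:
            censored.append(uni)
    detail = pd.DataFrame(rows, columns=["uniprot", "rho", "diff_depleted",
                                         "diff_undepleted", "discordant",
                                         "censored"])
    eligible = len(rows)
    report = FilterReport("depletion_censoring", eligible,
                          eligible - len(censored),
                          {u: "depletion_affected" for u in censored})
    report.skipped = skipped  # ineligible proteins, reported but not censored
    return censored, report, detail
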