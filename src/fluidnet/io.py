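"""Readers and writers for the documented flat-file dialects.

Vendor formats are proprietary; this package defines plain-TSV dialects
that carry the same information:

Affinity dialect (SomaScan / Olink), one file per platform+fluid
----------------------------------------------------------------
Tab-separated. A metadata header block of rows whose first field is
``!meta`` followed by the metadata field name (``uniprot``,
``gene_symbol``, ``panel``, ``is_control``, ``is_human``, optionally
``lod_log2``), one value per assay column. Then one row per sample,
first field the sample ID. Buffer (blank well) replicates use reserved
sample IDs starting with ``BUFFER``. Cell grammar: empty = not
measured, ``QC`` = removed by a QC warning, ``<x`` = numeric value x
recorded below LOD, otherwise a plain number.

TMT dialect
-----------
Tab-separated, one row per protein assay, columns named
``<batch>.<channel>``. An empty cell means the protein was not
quantified in that cell's batch (TMT missingness is batch-level).
Assay annotation travels in the same ``!meta`` header block.

Auxiliary tables are ordinary headered TSV/CSV: subject traits,
HPA-style reference concentrations (``gene_symbol``,
``concentration_pg_per_L``), module memberships (``label``, ``module``)
and cell-type markers (``cell_type``, ``gene_symbol``).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AssayMeta, BatchDesign, Fluid, MeasurementMatrix, Platform, Scale, Status,
    SubjectTraits, TRAIT_COLUMNS,
)

__all__ = [
    "read_affinity_table", "write_affinity_table",
    "read_tmt_table", "write_tmt_table",
    "read_traits", "write_traits",
    "read_reference_concentrations", "read_module_membership",
    "read_marker_lists", "write_matrix_tsv", "read_matrix_tsv",
]

BUFFER_PREFIX = "BUFFER"
_META_FIELDS = ("uniprot", "gene_symbol", "panel", "is_control", "is_human")


def _fmt(x: float) -> str:
    # repr round-trips float64 exactly through the text form
    return repr(float(x))


def _parse_cell(text: str) -> tuple[float, int]:
    text = text.strip()
    if text == "":
        return np.nan, int(Status.NOT_MEASURED)
    if text == "QC":
        return np.nan, int(Status.QC_FLAGGED)
    if text.startswith("<"):
        return float(text[1:]), int(Status.BELOW_LOD)
    return float(text), int(Status.OBSERVED)


def _render_cell(value: float, status: int) -> str:
    if status == Status.NOT_MEASURED:
        return ""
    if status == Status.QC_FLAGGED:
        return "QC"
    if status == Status.BELOW_LOD:
        return "<" + _fmt(value)
    return _fmt(value)


def read_affinity_table(path, platform: Platform, fluid: Fluid):
    """Read an affinity-platform TSV.

    Returns ``(matrix, metas, buffer_table)`` where ``matrix`` is the
    sample x assay :class:`MeasurementMatrix` in the platform's native
    scale (linear RFU for SomaScan, log2 NPX for Olink), ``metas`` a list
    of :class:`AssayMeta`, and ``buffer_table`` a DataFrame of buffer
    replicate rows (same columns, native scale). QC-warned cells come
    back with status ``QC_FLAGGED`` and no numeric value.
    """
    platform = Platform(platform)
    if platform is Platform.TMTMS:
        raise ValueError("TMT tables use read_tmt_table")
    fluid = Fluid(fluid)
    rows = list(csv.reader(open(path, newline=""), delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if header[0] != "sample_id":
        raise ValueError(f"{path}: first header field must be 'sample_id'")
    assay_ids = header[1:]
    meta_rows: dict[str, list[str]] = {}
    data_rows: list[tuple[str, list[str]]] = []
    for row in rows[1:]:
        if not row:
            continue
        if row[0] == "!meta":
            meta_rows[row[1]] = row[2:]
        else:
            data_rows.append((row[0], row[1:]))

    missing_meta = [f for f in ("uniprot", "gene_symbol") if f not in meta_rows]
    if missing_meta:
        raise ValueError(f"{path}: missing !meta rows: {missing_meta}")
    for fname, vals in meta_rows.items():
        if len(vals) != len(assay_ids):
            raise ValueError(f"{path}: !meta {fname} has {len(vals)} values "
                             f"for {len(assay_ids)} assay columns")
    metas = []
    for j, aid in enumerate(assay_ids):
        metas.append(AssayMeta(
            assay_id=aid, platform=platform,
            uniprot=meta_rows["uniprot"][j], gene_symbol=meta_rows["gene_symbol"][j],
            fluid=fluid, panel_or_batch=meta_rows.get("panel", [""] * len(assay_ids))[j],
            is_control_probe=meta_rows.get("is_control", ["0"] * len(assay_ids))[j] in ("1", "true", "True"),
            is_human=meta_rows.get("is_human", ["1"] * len(assay_ids))[j] in ("1", "true", "True"),
        ))

    sample_ids = [sid for sid, _ in data_rows]
    dupes = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample IDs {dupes}")

    values = np.full((len(data_rows), len(assay_ids)), np.nan)
    status = np.full(values.shape, int(Status.NOT_MEASURED), dtype=np.int8)
    for i, (_, cells) in enumerate(data_rows):
        if len(cells) != len(assay_ids):
            raise ValueError(f"{path}: row {i} has {len(cells)} cells for "
                             f"{len(assay_ids)} assays")
        for j, cell in enumerate(cells):
            values[i, j], status[i, j] = _parse_cell(cell)

    is_buffer = np.array([sid.startswith(BUFFER_PREFIX) for sid in sample_ids])
    vdf = pd.DataFrame(values, index=sample_ids, columns=assay_ids)
    sdf = pd.DataFrame(status, index=sample_ids, columns=assay_ids)
    scale = Scale.LOG2 if platform is Platform.OLINK else Scale.LINEAR
    matrix = MeasurementMatrix(vdf.loc[~is_buffer], sdf.loc[~is_buffer], scale)
    buffer_table = vdf.loc[is_buffer]
    lods = None
    if "lod_log2" in meta_rows:
        lods = pd.Series([float(x) if x != "" else np.nan for x in meta_rows["lod_log2"]],
                         index=assay_ids)
    return matrix, metas, buffer_table, lods


def write_affinity_table(path, matrix: MeasurementMatrix, metas, buffer_table=None,
                         lods=None) -> None:
    """Write an affinity TSV; exact round-trip partner of :func:`read_affinity_table`."""
    metas = {m.assay_id: m for m in metas}
    assays = matrix.assays
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id"] + assays)
        w.writerow(["!meta", "uniprot"] + [metas[a].uniprot for a in assays])
        w.writerow(["!meta", "gene_symbol"] + [metas[a].gene_symbol for a in assays])
        w.writerow(["!meta", "panel"] + [metas[a].panel_or_batch for a in assays])
        w.writerow(["!meta", "is_control"] + ["1" if metas[a].is_control_probe else "0" for a in assays])
        w.writerow(["!meta", "is_human"] + ["1" if metas[a].is_human else "0" for a in assays])
        if lods is not None:
            w.writerow(["!meta", "lod_log2"] +
                       ["" if not np.isfinite(lods.get(a, np.nan)) else _fmt(lods[a])
                        for a in assays])
        vals, stat = matrix.values.to_numpy(), matrix.status.to_numpy()
        for i, sid in enumerate(matrix.samples):
            w.writerow([sid] + [_render_cell(vals[i, j], stat[i, j])
                                for j in range(len(assays))])
        if buffer_table is not None:
            buf = buffer_table[assays].to_numpy()
            for i, sid in enumerate(buffer_table.index):
                w.writerow([sid] + ["" if not np.isfinite(buf[i, j]) else _fmt(buf[i, j])
                                    for j in range(len(assays))])


def read_tmt_table(path, design: BatchDesign, fluid: Fluid = Fluid.CSF):
    """Read a TMT reporter-intensity TSV against a batch design.

    Returns ``(matrix, metas, gis_sample_ids)``.  The matrix rows are
    subject samples plus pseudo-samples named ``GIS:<batch>:<channel>``
    for the pooled internal-standard channels (listed separately in
    ``gis_sample_ids``); cells of batches in which a protein was not
    quantified are ``NOT_MEASURED``.
    """
    rows = list(csv.reader(open(path, newline=""), delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if header[0] != "assay_id":
        raise ValueError(f"{path}: first header field must be 'assay_id'")
    channel_cols = header[1:]
    chan_to_sample: dict[str, str] = {}
    for sample, (batch, channel) in design.sample_channel.items():
        chan_to_sample[f"{batch}.{channel}"] = sample
    gis_ids = []
    for batch, chans in design.gis_channels.items():
        for ch in chans:
            sid = f"GIS:{batch}:{ch}"
            chan_to_sample[f"{batch}.{ch}"] = sid
            gis_ids.append(sid)
    unknown = [c for c in channel_cols if c not in chan_to_sample]
    if unknown:
        raise ValueError(f"{path}: channels absent from design: {unknown}")

    meta_rows: dict[str, list[str]] = {}
    data: list[tuple[str, list[str]]] = []
    for row in rows[1:]:
        if not row:
            continue
        if row[0] == "!meta":
            meta_rows[row[1]] = row[2:]
        else:
            data.append((row[0], row[1:]))
    if not data:
        raise ValueError(f"{path}: no protein rows")

    assay_ids = [aid for aid, _ in data]
    values = np.full((len(channel_cols), len(assay_ids)), np.nan)
    for j, (_, cells) in enumerate(data):
        for i, cell in enumerate(cells):
            if cell.strip() != "":
                values[i, j] = float(cell)

    sample_ids = [chan_to_sample[c] for c in channel_cols]
    vdf = pd.DataFrame(values, index=sample_ids, columns=assay_ids)
    sdf = pd.DataFrame(np.where(np.isfinite(values), int(Status.OBSERVED),
                                int(Status.NOT_MEASURED)),
                       index=sample_ids, columns=assay_ids, dtype=np.int8)
    # enforce batch-level missingness: a protein absent anywhere in a batch
    # is absent for the whole batch
    for batch in design.batches:
        members = [s for s in sample_ids
                   if s in design.sample_channel and design.batch_of(s) == batch]
        members += [g for g in gis_ids if g.split(":")[1] == batch]
        any_missing = ~np.isfinite(vdf.loc[members].to_numpy()).all(axis=0)
        for aid, miss in zip(assay_ids, any_missing):
            if miss:
                vdf.loc[members, aid] = np.nan
                sdf.loc[members, aid] = int(Status.NOT_MEASURED)

    matrix = MeasurementMatrix(vdf, sdf, Scale.LINEAR)
    uni = meta_rows.get("uniprot", [""] * len(assay_ids))
    sym = meta_rows.get("gene_symbol", assay_ids)
    metas = [AssayMeta(assay_id=a, platform=Platform.TMTMS, uniprot=uni[j],
                       gene_symbol=sym[j], fluid=Fluid(fluid))
             for j, a in enumerate(assay_ids)]
    return matrix, metas, gis_ids


def write_tmt_table(path, matrix: MeasurementMatrix, metas, design: BatchDesign) -> None:
    sample_to_chan = {s: f"{b}.{c}" for s, (b, c) in design.sample_channel.items()}
    for batch, chans in design.gis_channels.items():
        for ch in chans:
            sample_to_chan[f"GIS:{batch}:{ch}"] = f"{batch}.{ch}"
    chans = [sample_to_chan[s] for s in matrix.samples]
    metas = {m.assay_id: m for m in metas}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["assay_id"] + chans)
        vals = matrix.values.to_numpy()
        ok = matrix.numeric_mask().to_numpy()
        for j, aid in enumerate(matrix.assays):
            w.writerow([aid] + [_fmt(vals[i, j]) if ok[i, j] else ""
                                for i in range(len(chans))])
        w.writerow(["!meta", "uniprot"] + [metas[a].uniprot for a in matrix.assays])
        w.writerow(["!meta", "gene_symbol"] + [metas[a].gene_symbol for a in matrix.assays])


def read_traits(path) -> SubjectTraits:
    df = pd.read_csv(path, index_col="subject_id")
    return SubjectTraits(df)


def write_traits(path, traits: SubjectTraits) -> None:
    traits.df.to_csv(path, index_label="subject_id")


def read_reference_concentrations(path) -> pd.Series:
    """HPA-style absolute plasma concentrations, gene symbol -> pg/L."""
    df = pd.read_csv(path, sep="\t")
    ser = df.set_index("gene_symbol")["concentration_pg_per_L"].astype(float)
    if (ser <= 0).any():
        bad = ser.index[ser <= 0].tolist()
        raise ValueError(f"non-positive reference concentrations: {bad}")
    return ser


def read_module_membership(path) -> pd.Series:
    """External module-membership table: label -> module name."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("label")["module"]


def read_marker_lists(path) -> dict[str, set]:
    """Cell-type marker table (cell_type, gene_symbol) -> dict of symbol sets."""
    df = pd.read_csv(path, sep="\t")
    return {ct: set(g["gene_symbol"]) for ct, g in df.groupby("cell_type")}


def write_matrix_tsv(path, df: pd.DataFrame, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_matrix_tsv(path, index_col: str = "sample_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
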