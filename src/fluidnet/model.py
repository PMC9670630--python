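"""Core domain types for multi-platform biofluid proteomics.

The package operates on sample x assay abundance matrices from three
measurement platforms (aptamer-based SomaScan, antibody/PEA-based Olink,
and TMT mass spectrometry) in two biofluids (CSF and plasma).  Every
matrix carries a per-cell status mask distinguishing observed values,
values below the limit of detection (retained numerically but treated as
missing by most filters), QC-flagged cells, and cells that were never
measured.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "Fluid",
    "Scale",
    "Status",
    "AssayMeta",
    "CanonicalLabel",
    "make_label",
    "parse_label",
    "MeasurementMatrix",
    "SubjectTraits",
    "BatchDesign",
    "NetworkParams",
    "PipelineConfig",
]


class Platform(str, enum.Enum):
    SOMASCAN = "SomaScan"
    OLINK = "Olink"
    TMTMS = "MS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Fluid(str, enum.Enum):
    CSF = "CSF"
    PLASMA = "plasma"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Scale(str, enum.Enum):
    LINEAR = "linear"
    LOG2 = "log2"


class Status(enum.IntEnum):
    """Per-cell measurement status.

    BELOW_LOD cells keep their numeric value; downstream consumers must
    choose explicitly whether to treat them as observed or missing.
    """

    OBSERVED = 0
    BELOW_LOD = 1
    QC_FLAGGED = 2
    NOT_MEASURED = 3


#: statuses whose cells carry a finite numeric value
NUMERIC_STATUSES = (Status.OBSERVED, Status.BELOW_LOD)


@dataclass(frozen=True)
class AssayMeta:
    """Identity and annotation of one assay (SOMAmer, Olink assay, or MS protein)."""

    assay_id: str
    platform: Platform
    uniprot: str = ""
    gene_symbol: str = ""
    fluid: Fluid = Fluid.CSF
    panel_or_batch: str = ""
    is_control_probe: bool = False
    is_human: bool = True

    def __post_init__(self) -> None:
        if not self.is_control_probe and not (self.uniprot or self.gene_symbol):
            raise ValueError(
                f"assay {self.assay_id!r}: non-control assays need a UniProt "
                "accession or a gene symbol"
            )


_PLATFORM_ALIASES = {p.value.lower(): p for p in Platform}
_PLATFORM_ALIASES.update({"somascan": Platform.SOMASCAN, "olink": Platform.OLINK,
                          "ms": Platform.TMTMS, "tmtms": Platform.TMTMS,
                          "tmt-ms": Platform.TMTMS})
_FLUID_ALIASES = {f.value.lower(): f for f in Fluid}


@dataclass(frozen=True)
class CanonicalLabel:
    """Canonical assay label rendered as ``Symbol|UniprotID|platform|biofluid``."""

    symbol: str
    uniprot: str
    platform: Platform
    fluid: Fluid

    @property
    def rendered(self) -> str:
        return f"{self.symbol}|{self.uniprot}|{self.platform.value}|{self.fluid.value}"

    def __str__(self) -> str:
        return self.rendered


def make_label(meta: AssayMeta) -> CanonicalLabel:
    """Build the canonical ``Symbol|UniprotID|platform|biofluid`` label for an assay."""
    if meta.is_control_probe:
        raise ValueError(f"control probe {meta.assay_id!r} has no canonical label")
    if not (meta.gene_symbol or meta.uniprot):
        raise ValueError(f"assay {meta.assay_id!r} has neither symbol nor UniProt")
    for name, value in (("gene_symbol", meta.gene_symbol), ("uniprot", meta.uniprot)):
        if "|" in value:
            raise ValueError(f"{name} {value!r} contains the reserved '|' separator")
    return CanonicalLabel(meta.gene_symbol, meta.uniprot, meta.platform, meta.fluid)


def parse_label(rendered: str) -> CanonicalLabel:
    """Parse a rendered canonical label; exact inverse of :func:`make_label`."""
    parts = rendered.split("|")
    if len(parts) != 4:
        raise ValueError(f"label {rendered!r} does not have 4 '|'-separated fields")
    symbol, uniprot, platform_s, fluid_s = parts
    try:
        platform = _PLATFORM_ALIASES[platform_s.lower()]
        fluid = _FLUID_ALIASES[fluid_s.lower()]
    except KeyError as exc:
        raise ValueError(f"label {rendered!r}: unknown platform or fluid") from exc
    if not (symbol or uniprot):
        raise ValueError(f"label {rendered!r} has empty symbol and UniProt")
    return CanonicalLabel(symbol, uniprot, platform, fluid)


class MeasurementMatrix:
    """A samples x assays abundance matrix with status mask and declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by sample ID with assay IDs as columns. Units are
        linear RFU, linear 2^NPX, or TMT reporter intensity when
        ``scale=LINEAR``, or their log2 when ``scale=LOG2``.
    status
        Same-shaped integer DataFrame of :class:`Status` codes. If omitted,
        finite cells are OBSERVED and non-finite cells NOT_MEASURED.
    """

    def __init__(self, values: pd.DataFrame, status: pd.DataFrame | None = None,
                 scale: Scale = Scale.LINEAR):
        values = values.astype(float)
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate assay IDs: {dupes}")
        if status is None:
            status = pd.DataFrame(
                np.where(np.isfinite(values.to_numpy()), Status.OBSERVED, Status.NOT_MEASURED),
                index=values.index, columns=values.columns, dtype=np.int8)
        else:
            status = status.reindex(index=values.index, columns=values.columns).astype(np.int8)
        numeric = np.isin(status.to_numpy(), NUMERIC_STATUSES)
        if not np.isfinite(values.to_numpy()[numeric]).all():
            raise ValueError("non-finite value in an OBSERVED/BELOW_LOD cell")
        self.values = values
        self.status = status
        self.scale = Scale(scale)

    # -- basic introspection -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def assays(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "MeasurementMatrix":
        return MeasurementMatrix(self.values.copy(), self.status.copy(), self.scale)

    # -- masks ---------------------------------------------------------------
    def numeric_mask(self, include_below_lod: bool = True) -> pd.DataFrame:
        """Boolean mask of cells usable as numbers under the stated policy."""
        codes = (Status.OBSERVED, Status.BELOW_LOD) if include_below_lod else (Status.OBSERVED,)
        return self.status.isin([int(c) for c in codes])

    def numeric_values(self, include_below_lod: bool = True) -> pd.DataFrame:
        """Values with non-usable cells set to NaN."""
        return self.values.where(self.numeric_mask(include_below_lod))

    # -- scale conversion (exact inverses on numeric cells) -------------------
    def to_log2(self) -> "MeasurementMatrix":
        if self.scale is Scale.LOG2:
            return self.copy()
        vals = self.values.copy()
        mask = self.numeric_mask().to_numpy()
        arr = vals.to_numpy()
        if (arr[mask] <= 0).any():
            raise ValueError("non-positive linear value; cannot take log2")
        arr[mask] = np.log2(arr[mask])
        return MeasurementMatrix(vals, self.status.copy(), Scale.LOG2)

    def to_linear(self) -> "MeasurementMatrix":
        if self.scale is Scale.LINEAR:
            return self.copy()
        vals = self.values.copy()
        mask = self.numeric_mask().to_numpy()
        arr = vals.to_numpy()
        arr[mask] = np.exp2(arr[mask])
        return MeasurementMatrix(vals, self.status.copy(), Scale.LINEAR)

    # -- subsetting (always by ID, never by position) --------------------------
    def subset_assays(self, assay_ids) -> "MeasurementMatrix":
        assay_ids = [a for a in assay_ids]
        missing = set(assay_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown assay IDs: {sorted(missing)}")
        return MeasurementMatrix(self.values[assay_ids], self.status[assay_ids], self.scale)

    def subset_samples(self, sample_ids) -> "MeasurementMatrix":
        sample_ids = [s for s in sample_ids]
        missing = set(sample_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown sample IDs: {sorted(missing)}")
        return MeasurementMatrix(self.values.loc[sample_ids],
                                 self.status.loc[sample_ids], self.scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"<MeasurementMatrix {n} samples x {m} assays, scale={self.scale.value}>"


TRAIT_COLUMNS = ["diagnosis", "age", "sex", "MoCA", "CSF_Abeta42", "CSF_Ttau",
                 "CSF_pTau181", "Abeta42_Ttau_ratio", "APOE4_dose", "AfrAm"]


@dataclass
class SubjectTraits:
    """Subject-level clinical traits, one row per subject.

    ``diagnosis`` is "CT" / "AD" / other; CSF core biomarkers are in pg/mL.
    The Abeta42/T-tau ratio is recomputed on construction where both
    components are present.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        both = self.df["CSF_Abeta42"].notna() & self.df["CSF_Ttau"].notna()
        ratio = self.df["CSF_Abeta42"] / self.df["CSF_Ttau"]
        self.df.loc[both, "Abeta42_Ttau_ratio"] = ratio[both]

    @property
    def subjects(self) -> list[str]:
        return list(self.df.index)

    def group_labels(self) -> pd.Series:
        return self.df["diagnosis"]

    def groups(self) -> dict[str, list[str]]:
        return {g: list(idx) for g, idx in self.df.groupby("diagnosis").groups.items()}


@dataclass
class BatchDesign:
    """TMT batch layout: which (batch, channel) each sample occupies, and which
    channels in each batch hold the pooled global internal standard (GIS)."""

    sample_channel: dict[str, tuple[str, str]]
    gis_channels: dict[str, list[str]]

    def __post_init__(self) -> None:
        for batch, chans in self.gis_channels.items():
            if not chans:
                raise ValueError(f"batch {batch!r} has no GIS channel")
        seen: dict[tuple[str, str], str] = {}
        for sample, (batch, channel) in self.sample_channel.items():
            key = (batch, channel)
            if key in seen:
                raise ValueError(f"channel {key} assigned to both "
                                 f"{seen[key]!r} and {sample!r}")
            if channel in self.gis_channels.get(batch, []):
                raise ValueError(f"sample {sample!r} occupies GIS channel {key}")
            seen[key] = sample

    @property
    def batches(self) -> list[str]:
        return sorted(self.gis_channels)

    def samples_in_batch(self, batch: str) -> list[str]:
        return [s for s, (b, _) in self.sample_channel.items() if b == batch]

    def batch_of(self, sample: str) -> str:
        return self.sample_channel[sample][0]


DEFAULT_SNR_GRID = (0.0, 0.15, 0.25, 0.3, 0.35, 0.4, 0.45, 0.50,
                    0.625, 0.75, 1.0, 2.0, 4.0, 8.0)


@dataclass
class NetworkParams:
    """Signed weighted co-expression network construction parameters."""

    beta: float = 6.5          # soft-threshold power; 6.5 for CSF, 11 for plasma
    deep_split: int = 4
    min_module_size: int = 10
    merge_cut_height: float = 0.07   # eigenprotein dissimilarity below which modules merge
    tom_denom: str = "mean"          # "mean" or "min"
    corr: str = "bicor"              # "bicor" or "pearson"
    network_type: str = "signed"
    pam_stage: bool = True
    pam_respects_dendro: bool = True
    single_block: bool = True
    kme_min: float = 0.30            # floor below which a protein is sent to grey

    def __post_init__(self) -> None:
        if self.beta <= 1:
            raise ValueError("soft power beta must exceed 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0,1)")
        if self.tom_denom not in ("mean", "min"):
            raise ValueError("tom_denom must be 'mean' or 'min'")
        if self.network_type != "signed":
            raise ValueError("only signed networks are supported")


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults."""

    missingness_max_frac: float = 0.75
    snr_grid: tuple[float, ...] = DEFAULT_SNR_GRID
    network_csf: NetworkParams = field(default_factory=lambda: NetworkParams(beta=6.5))
    network_plasma: NetworkParams = field(default_factory=lambda: NetworkParams(beta=11.0))
    preservation_permutations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.missingness_max_frac < 1:
            raise ValueError("missingness_max_frac must be in (0,1)")
        grid = tuple(self.snr_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("snr_grid must be strictly increasing")
        self.snr_grid = grid

    def network_params(self, fluid: Fluid) -> NetworkParams:
        return self.network_csf if fluid is Fluid.CSF else self.network_plasma
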