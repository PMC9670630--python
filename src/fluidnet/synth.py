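"""Synthetic paired CSF + plasma three-platform cohort generator.

Emulates the statistical structure the downstream analyses assume: a
log-normal latent proteome spanning many orders of magnitude, planted
co-expression modules with AD effects, per-platform sample offsets,
TMT batches with pooled internal-standard (GIS) channels, buffer
replicate noise floors, a subpopulation of aptamer assays that measure
nothing but background (as seen for SomaScan in CSF), below-LOD
missing-not-at-random censoring, QC flags, and duplicated assays.

Every planted quantity is recorded in :class:`GroundTruth` so recovery
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    AssayMeta, BatchDesign, Fluid, MeasurementMatrix, Platform, Scale, Status,
    SubjectTraits,
)

__all__ = ["SimulationDesign", "GroundTruth", "SimulatedCohort",
           "simulate_cohort", "inject_missingness"]

DEFAULT_MODULE_EFFECTS = (1.5, -1.5, 1.0, -1.0, 0.75, -0.75, 0.5, 0.0)


@dataclass
class SimulationDesign:
    """Tunable knobs of the simulated cohort.

    Defaults are scaled-down relative to the real platforms (~1050 assays
    per fluid instead of ~8000) but keep every structural feature.
    """

    n_control: int = 18
    n_AD: int = 18
    n_soma: int = 600          # SomaScan assays per fluid (before duplicates)
    n_olink: int = 150
    n_tmt: int = 300
    n_anchor: int = 150        # proteins measured on all three platforms; sized
                               # so that >=60 survive every platform's filters
    n_modules: int = 8
    module_size: int = 25
    module_effects: tuple[float, ...] = DEFAULT_MODULE_EFFECTS  # AD shift, eigenprotein SD units
    module_loading_range: tuple[float, float] = (0.8, 1.2)      # log2 per factor SD
    member_noise_sd: float = 0.4       # residual log2 sd of module members
    background_noise_sd: float = 0.6   # log2 sd of non-module proteins
    plasma_attenuation_max: float = 0.5  # log2 AD decrease at the lowest plasma abundance
    plasma_attenuation_top_quantile: float = 0.95  # abundance quantile where attenuation hits 0
    platform_offset_sd: float = 0.5    # per-platform per-sample log2 offset SD
    assay_bias_sd: float = 1.0         # per-assay platform scale bias (log2 SD)
    measurement_noise_sd: float = 0.25  # per-cell technical log2 noise
    batch_effect_sd: float = 1.0       # per (protein, batch) TMT effect SD
    batch_size: int = 9                # subjects per TMT batch (+1 GIS channel)
    tmt_batch_missing_rate: float = 0.08  # P(protein unquantified in a batch)
    n_buffer: int = 6
    buffer_sd: float = 0.1             # log2 SD of buffer replicates
    soma_csf_noise_frac: float = 0.5   # fraction of SomaScan CSF assays that are pure noise
    noise_snr_range: tuple[float, float] = (0.05, 0.4)  # planted S:N of pure-noise assays
    clean_gap_range: tuple[float, float] = (3.5, 7.0)   # log2 signal-over-buffer of clean SomaScan CSF assays
    other_gap_range: tuple[float, float] = (1.5, 7.0)   # same for the other affinity data sets
    qc_flag_rate: float = 0.005
    n_soma_duplicates: int = 10        # proteins given a second SOMAmer
    n_olink_duplicates: int = 5        # proteins duplicated across Olink panels

    def __post_init__(self) -> None:
        if self.module_size < 3:
            raise ValueError("module size must be at least 3")
        if self.n_buffer < 2:
            raise ValueError("need at least 2 buffer replicates")
        if self.n_modules * self.module_size > min(self.n_soma, self.n_tmt + self.n_soma):
            raise ValueError("planted modules exceed assay count")
        if self.n_anchor < 1:
            raise ValueError("anchor set must be nonempty")
        if len(self.module_effects) < self.n_modules:
            raise ValueError("need one AD effect per planted module")
        if self.n_anchor > self.n_olink:
            raise ValueError("anchors must all fit on the smallest platform")

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_AD

    @property
    def n_proteins(self) -> int:
        return self.n_soma  # SomaScan covers the whole simulated universe


@dataclass
class GroundTruth:
    """Everything the simulator planted, for recovery scoring."""

    module_of_protein: pd.Series            # protein -> module id (0 = none)
    ad_effect_log2: dict[Fluid, pd.Series]  # protein -> per-fluid AD-CT latent log2 shift
    platform_offsets: dict[tuple[Platform, Fluid], pd.Series]  # sample -> log2 offset
    batch_effects: dict[Fluid, pd.DataFrame]  # batch x protein log2 effects
    noise_assays: dict[tuple[Platform, Fluid], pd.Index]  # pure-noise assay ids
    lod_log2: dict[tuple[Platform, Fluid], pd.Series]     # assay -> true LOD
    protein_of_assay: dict[tuple[Platform, Fluid], pd.Series]  # assay id -> protein
    latent_log2: dict[Fluid, pd.DataFrame]  # sample x protein offset-free abundance
    module_scores: pd.DataFrame             # sample x module factor scores

    def module_of_assay(self, platform: Platform, fluid: Fluid) -> pd.Series:
        prot = self.protein_of_assay[(platform, fluid)]
        return prot.map(self.module_of_protein)


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulated study produces."""

    matrices: dict[tuple[Platform, Fluid], MeasurementMatrix]
    metas: dict[tuple[Platform, Fluid], list[AssayMeta]]
    buffers: dict[tuple[Platform, Fluid], pd.DataFrame]
    olink_lods: dict[Fluid, pd.Series]
    traits: SubjectTraits
    batch_designs: dict[Fluid, BatchDesign]
    truth: GroundTruth
    design: SimulationDesign


def _protein_names(n: int) -> tuple[list[str], list[str]]:
    symbols = [f"GN{i:04d}" for i in range(n)]
    uniprots = [f"Q{i:05d}" for i in range(n)]
    return symbols, uniprots


def simulate_cohort(design: SimulationDesign | None = None, seed: int = 0) -> SimulatedCohort:
    """Simulate one paired-fluid, three-platform cohort.

    The latent subject x protein log2 abundance is a baseline ladder
    spanning >6 orders of magnitude (linear) plus module factor loadings
    times subject factor scores, AD shifts, and a fluid-specific term.
    Observed values add platform/batch factors and technical noise;
    affinity platforms emit buffer replicates and TMT emits GIS channels
    carrying the all-sample average.
    """
    d = design or SimulationDesign()
    rng = np.random.default_rng(seed)

    subjects = [f"CT{i:02d}" for i in range(d.n_control)] + \
               [f"AD{i:02d}" for i in range(d.n_AD)]
    is_ad = np.array([s.startswith("AD") for s in subjects])
    n_sub = d.n_subjects
    n_prot = d.n_proteins
    symbols, uniprots = _protein_names(n_prot)
    proteins = pd.Index(symbols, name="protein")

    # ---- protein-level structure (shared across fluids) ----------------------
    baseline = rng.uniform(4.0, 26.0, n_prot)  # log2; >6 orders of magnitude linear
    module_of = np.zeros(n_prot, dtype=int)
    # plant modules outside the anchor set so harmonization denominators stay calm
    first_member = d.n_anchor
    members_needed = d.n_modules * d.module_size
    if first_member + members_needed > n_prot:
        raise ValueError("planted modules do not fit in the protein universe")
    for m in range(d.n_modules):
        lo = first_member + m * d.module_size
        module_of[lo:lo + d.module_size] = m + 1
    loadings = np.where(module_of > 0,
                        rng.uniform(*d.module_loading_range, n_prot), 0.0)

    # subject factor scores, one per module, shared across fluids
    scores = rng.standard_normal((n_sub, d.n_modules))
    effects = np.asarray(d.module_effects[: d.n_modules])
    shifted_scores = scores + np.outer(is_ad, effects)

    fluids = (Fluid.CSF, Fluid.PLASMA)
    latent: dict[Fluid, pd.DataFrame] = {}
    ad_effect: dict[Fluid, pd.Series] = {}
    for fluid in fluids:
        fluid_term = rng.normal(0.0, 1.0, n_prot)
        noise_sd = np.where(module_of > 0, d.member_noise_sd, d.background_noise_sd)
        eps = rng.standard_normal((n_sub, n_prot)) * noise_sd
        factor_part = np.zeros((n_sub, n_prot))
        sel = module_of > 0
        factor_part[:, sel] = shifted_scores[:, module_of[sel] - 1] * loadings[sel]
        X = baseline + fluid_term + factor_part + eps
        eff = np.where(sel, loadings * effects[np.maximum(module_of - 1, 0)], 0.0)
        if fluid is Fluid.PLASMA and d.plasma_attenuation_max > 0:
            # global AD decrease of low-abundance plasma proteins, ramping to
            # zero at the top of the abundance ladder
            q_hi = np.quantile(baseline, d.plasma_attenuation_top_quantile)
            q_lo = baseline.min()
            w = np.clip((q_hi - baseline) / (q_hi - q_lo), 0.0, 1.0)
            atten = d.plasma_attenuation_max * w
            X[is_ad] -= atten
            eff = eff - atten
        latent[fluid] = pd.DataFrame(X, index=subjects, columns=proteins)
        ad_effect[fluid] = pd.Series(eff, index=proteins)

    # ---- traits from designated module scores --------------------------------
    z0 = shifted_scores[:, 0]
    traits_df = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
    traits_df["diagnosis"] = np.where(is_ad, "AD", "CT")
    traits_df["age"] = np.round(rng.normal(70, 8, n_sub), 1)
    traits_df["sex"] = rng.choice(["F", "M"], n_sub)
    traits_df["MoCA"] = np.clip(np.round(24 - 2.5 * z0 + rng.normal(0, 2, n_sub)), 0, 30)
    traits_df["CSF_Ttau"] = np.clip(300 + 120 * z0 + rng.normal(0, 40, n_sub), 50, None)
    traits_df["CSF_pTau181"] = np.clip(30 + 12 * z0 + rng.normal(0, 5, n_sub), 5, None)
    traits_df["CSF_Abeta42"] = np.clip(700 - 150 * z0 + rng.normal(0, 80, n_sub), 100, None)
    traits_df["Abeta42_Ttau_ratio"] = traits_df["CSF_Abeta42"] / traits_df["CSF_Ttau"]
    traits_df["APOE4_dose"] = rng.binomial(2, np.where(is_ad, 0.45, 0.2))
    traits_df["AfrAm"] = rng.random(n_sub) < 0.25
    traits = SubjectTraits(traits_df)

    # ---- platform membership --------------------------------------------------
    anchor_idx = np.arange(d.n_anchor)
    tmt_idx = np.arange(d.n_tmt)
    olink_extra = np.arange(d.n_tmt, d.n_tmt + (d.n_olink - d.n_anchor))
    olink_idx = np.concatenate([anchor_idx, olink_extra])
    soma_idx = np.arange(d.n_soma)

    matrices: dict[tuple[Platform, Fluid], MeasurementMatrix] = {}
    metas: dict[tuple[Platform, Fluid], list[AssayMeta]] = {}
    buffers: dict[tuple[Platform, Fluid], pd.DataFrame] = {}
    olink_lods: dict[Fluid, pd.Series] = {}
    batch_designs: dict[Fluid, BatchDesign] = {}
    platform_offsets: dict[tuple[Platform, Fluid], pd.Series] = {}
    batch_effects: dict[Fluid, pd.DataFrame] = {}
    noise_assays: dict[tuple[Platform, Fluid], pd.Index] = {}
    lods_truth: dict[tuple[Platform, Fluid], pd.Series] = {}
    protein_of_assay: dict[tuple[Platform, Fluid], pd.Series] = {}

    def affinity_dataset(platform: Platform, fluid: Fluid, prot_rows: np.ndarray,
                         duplicates: int, noise_frac: float, gap_range) -> None:
        prot_rows = np.concatenate([
            prot_rows, rng.choice(prot_rows, size=duplicates, replace=False)])
        n_assay = len(prot_rows)
        tag = "SL" if platform is Platform.SOMASCAN else "OID"
        assay_ids = [f"{tag}{fluid.name[:1]}{j:05d}" for j in range(n_assay)]
        offs = rng.normal(0.0, d.platform_offset_sd, n_sub)
        bias = rng.normal(0.0, d.assay_bias_sd, n_assay)
        is_noise = np.zeros(n_assay, dtype=bool)
        if noise_frac > 0:
            # anchors are by construction proteins quantified well on every
            # platform, so the pure-noise class only hits non-anchor assays
            is_noise = (rng.random(n_assay) < noise_frac) & (prot_rows >= d.n_anchor)
        gaps = rng.uniform(*gap_range, n_assay)
        # anchor the noise floor to the assay's expected median signal so the
        # planted S:N is exactly 2^gap - 1 regardless of protein identity
        med_lat = np.median(latent[fluid].to_numpy()[:, prot_rows], axis=0)
        floor = med_lat + bias - gaps
        snr_noise = rng.uniform(*d.noise_snr_range, n_assay)

        sig = latent[fluid].to_numpy()[:, prot_rows] + bias + offs[:, None] \
            + rng.normal(0.0, d.measurement_noise_sd, (n_sub, n_assay))
        noise_sig = floor + np.log2(1.0 + snr_noise) \
            + rng.normal(0.0, d.buffer_sd, (n_sub, n_assay))
        log2_obs = np.where(is_noise, noise_sig, sig)
        buf = floor + rng.normal(0.0, d.buffer_sd, (d.n_buffer, n_assay))
        lod = floor + 3.0 * d.buffer_sd

        scale = Scale.LOG2 if platform is Platform.OLINK else Scale.LINEAR
        vals = log2_obs if scale is Scale.LOG2 else np.exp2(log2_obs)
        mat = MeasurementMatrix(pd.DataFrame(vals, index=subjects, columns=assay_ids),
                                scale=scale)
        mat = inject_missingness(mat, pd.Series(lod, index=assay_ids),
                                 qc_rate=d.qc_flag_rate, rng=rng)
        key = (platform, fluid)
        matrices[key] = mat
        panel = ["P1" if j % 2 == 0 else "P2" for j in range(n_assay)]
        metas[key] = [AssayMeta(assay_id=a, platform=platform,
                                uniprot=uniprots[p], gene_symbol=symbols[p],
                                fluid=fluid, panel_or_batch=panel[j])
                      for j, (a, p) in enumerate(zip(assay_ids, prot_rows))]
        bvals = buf if scale is Scale.LOG2 else np.exp2(buf)
        buffers[key] = pd.DataFrame(
            bvals, index=[f"BUFFER{i:02d}" for i in range(d.n_buffer)],
            columns=assay_ids)
        platform_offsets[key] = pd.Series(offs, index=subjects)
        noise_assays[key] = pd.Index(np.array(assay_ids)[is_noise])
        lods_truth[key] = pd.Series(lod, index=assay_ids)
        protein_of_assay[key] = pd.Series([symbols[p] for p in prot_rows],
                                          index=assay_ids)
        if platform is Platform.OLINK:
            olink_lods[fluid] = pd.Series(lod, index=assay_ids)

    def tmt_dataset(fluid: Fluid) -> None:
        prot_rows = tmt_idx
        assay_ids = [f"MS{fluid.name[:1]}{symbols[p]}" for p in prot_rows]
        n_assay = len(prot_rows)
        n_batches = int(np.ceil(n_sub / d.batch_size))
        sample_channel = {}
        gis_channels = {}
        for b in range(n_batches):
            batch = f"b{b + 1}"
            members = subjects[b * d.batch_size:(b + 1) * d.batch_size]
            for c, s in enumerate(members):
                sample_channel[s] = (batch, f"ch{c + 1:02d}")
            gis_channels[batch] = ["ch00"]
        bdesign = BatchDesign(sample_channel, gis_channels)

        offs = rng.normal(0.0, d.platform_offset_sd, n_sub)
        beff = rng.normal(0.0, d.batch_effect_sd, (n_batches, n_assay))
        lat = latent[fluid].to_numpy()[:, prot_rows]
        gis_latent = lat.mean(axis=0)  # GIS = pooled all-sample average

        all_ids = list(subjects) + [f"GIS:b{b + 1}:ch00" for b in range(n_batches)]
        vals = np.full((len(all_ids), n_assay), np.nan)
        batch_of = np.array([int(bdesign.batch_of(s)[1:]) - 1 for s in subjects])
        noise = rng.normal(0.0, d.measurement_noise_sd, (len(all_ids), n_assay))
        vals[:n_sub] = lat + beff[batch_of] + offs[:, None] + noise[:n_sub]
        for b in range(n_batches):
            vals[n_sub + b] = gis_latent + beff[b] + noise[n_sub + b]
        # whole-batch dropouts
        drop = rng.random((n_batches, n_assay)) < d.tmt_batch_missing_rate
        for b in range(n_batches):
            rows = np.flatnonzero(batch_of == b).tolist() + [n_sub + b]
            vals[np.ix_(rows, np.flatnonzero(drop[b]))] = np.nan
        mat = MeasurementMatrix(pd.DataFrame(np.where(np.isfinite(vals), np.exp2(vals), np.nan),
                                             index=all_ids, columns=assay_ids),
                                scale=Scale.LINEAR)
        key = (Platform.TMTMS, fluid)
        matrices[key] = mat
        metas[key] = [AssayMeta(assay_id=a, platform=Platform.TMTMS,
                                uniprot=uniprots[p], gene_symbol=symbols[p],
                                fluid=fluid, panel_or_batch="tmt")
                      for a, p in zip(assay_ids, prot_rows)]
        batch_designs[fluid] = bdesign
        platform_offsets[key] = pd.Series(offs, index=subjects)
        batch_effects[fluid] = pd.DataFrame(
            beff, index=[f"b{b + 1}" for b in range(n_batches)], columns=assay_ids)
        noise_assays[key] = pd.Index([])
        lods_truth[key] = pd.Series(np.nan, index=assay_ids)
        protein_of_assay[key] = pd.Series([symbols[p] for p in prot_rows],
                                          index=assay_ids)

    for fluid in fluids:
        noise_frac = d.soma_csf_noise_frac if fluid is Fluid.CSF else 0.0
        gap = d.clean_gap_range if fluid is Fluid.CSF else d.other_gap_range
        affinity_dataset(Platform.SOMASCAN, fluid, soma_idx,
                         d.n_soma_duplicates, noise_frac, gap)
        affinity_dataset(Platform.OLINK, fluid, olink_idx,
                         d.n_olink_duplicates, 0.0, d.other_gap_range)
        tmt_dataset(fluid)

    truth = GroundTruth(
        module_of_protein=pd.Series(module_of, index=proteins),
        ad_effect_log2=ad_effect,
        platform_offsets=platform_offsets,
        batch_effects=batch_effects,
        noise_assays=noise_assays,
        lod_log2=lods_truth,
        protein_of_assay=protein_of_assay,
        latent_log2=latent,
        module_scores=pd.DataFrame(shifted_scores, index=subjects,
                                   columns=[f"m{m + 1}" for m in range(d.n_modules)]),
    )
    return SimulatedCohort(matrices=matrices, metas=metas, buffers=buffers,
                           olink_lods=olink_lods, traits=traits,
                           batch_designs=batch_designs, truth=truth, design=d)


def inject_missingness(matrix: MeasurementMatrix, lod_log2: pd.Series,
                       qc_rate: float = 0.0,
                       rng: np.random.Generator | None = None) -> MeasurementMatrix:
    """Mark below-LOD cells (value retained) and sprinkle random QC flags.

    ``lod_log2`` is per-assay on the log2 scale; cells are compared on
    log2 regardless of the matrix's declared scale. Cells already
    NOT_MEASURED stay that way.
    """
    rng = rng or np.random.default_rng(0)
    vals = matrix.values.to_numpy().copy()
    stat = matrix.status.to_numpy().copy()
    if matrix.scale is Scale.LOG2:
        log2v = vals
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            log2v = np.log2(np.where(vals > 0, vals, np.nan))
    lods = lod_log2.reindex(matrix.assays).to_numpy()
    with np.errstate(invalid="ignore"):
        below = (log2v < lods) & (stat == int(Status.OBSERVED))
    stat[below] = int(Status.BELOW_LOD)
    if qc_rate > 0:
        qc = (rng.random(stat.shape) < qc_rate) & np.isin(
            stat, (int(Status.OBSERVED), int(Status.BELOW_LOD)))
        stat[qc] = int(Status.QC_FLAGGED)
        vals[qc] = np.nan
    return MeasurementMatrix(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        pd.DataFrame(stat, index=matrix.values.index, columns=matrix.values.columns),
        matrix.scale)
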