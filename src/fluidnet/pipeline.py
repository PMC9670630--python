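"""End-to-end pipeline: QC -> harmonize -> abundance -> network -> cross-network.

Runs either on a simulated cohort (given a seed) or on user-supplied
platform tables, writing every intermediate as a flat file and logging
each filter's before/after accounting.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import crossnet as cn
from . import network as nw
from . import qc as qcmod
from .harmonize import HarmonizedMatrix, tampor_batch_correct, transposed_tampor
from .io import write_matrix_tsv, write_traits
from .model import (
    Fluid, MeasurementMatrix, PipelineConfig, Platform, Scale, Status,
)
from .synth import SimulatedCohort, simulate_cohort

__all__ = ["run_pipeline", "qc_stage", "harmonize_stage", "PipelineError"]

log = logging.getLogger("fluidnet")

TRAIT_COLS_FOR_CORR = ["MoCA", "CSF_Abeta42", "CSF_Ttau", "CSF_pTau181",
                       "Abeta42_Ttau_ratio", "age"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


def _complete_case(matrix: MeasurementMatrix) -> MeasurementMatrix:
    """Keep assays with a numeric value (observed or below-LOD) in every sample."""
    ok = matrix.numeric_mask().all(axis=0)
    return matrix.subset_assays([a for a in matrix.assays if ok[a]])


def qc_stage(cohort: SimulatedCohort, config: PipelineConfig):
    """Per-platform QC: LOD flagging, missingness filter, duplicate
    reduction, and the empirical S:N threshold for SomaScan CSF."""
    reports = []
    filtered: dict[tuple[Platform, Fluid], MeasurementMatrix] = {}
    metas: dict[tuple[Platform, Fluid], list] = {}
    profiles: dict[tuple[Platform, Fluid], qcmod.NoiseProfile] = {}
    snr_curve = None
    snr_threshold = None

    for key, matrix in cohort.matrices.items():
        platform, fluid = key
        meta = cohort.metas[key]
        if platform is Platform.TMTMS:
            filtered[key] = matrix
            metas[key] = meta
            continue
        buffer = cohort.buffers[key]
        profile = qcmod.compute_snr(matrix, buffer)
        profiles[key] = profile
        supplied = cohort.olink_lods.get(fluid) if platform is Platform.OLINK else None
        lods = qcmod.compute_lod(buffer, matrix.scale, supplied=supplied)
        matrix = qcmod.apply_lod(matrix, lods)
        matrix, rep = qcmod.filter_missingness(matrix, config.missingness_max_frac)
        rep.stage = f"missingness_{platform.value}_{fluid.value}"
        reports.append(rep)
        log.info("%s %s: missingness filter %d -> %d assays",
                 platform.value, fluid.value, rep.assays_before, rep.assays_after)
        matrix, rep, meta = qcmod.reduce_duplicate_assays(matrix, meta)
        rep.stage = f"duplicates_{platform.value}_{fluid.value}"
        reports.append(rep)
        log.info("%s %s: duplicate reduction %d -> %d assays",
                 platform.value, fluid.value, rep.assays_before, rep.assays_after)
        filtered[key] = matrix
        metas[key] = meta

    # empirical S:N threshold for SomaScan CSF against the other platforms
    key = (Platform.SOMASCAN, Fluid.CSF)
    if key in filtered:
        others = [(filtered[(Platform.OLINK, Fluid.CSF)], metas[(Platform.OLINK, Fluid.CSF)]),
                  (filtered[(Platform.TMTMS, Fluid.CSF)], metas[(Platform.TMTMS, Fluid.CSF)])]
        snr_threshold, snr_curve = qcmod.select_snr_threshold(
            filtered[key], metas[key], profiles[key], others, config.snr_grid)
        snr = profiles[key]["snr"]
        keep = [a for a in filtered[key].assays
                if np.isfinite(snr.get(a, np.nan)) and snr[a] >= snr_threshold]
        removed = {a: f"snr_below_{snr_threshold}" for a in filtered[key].assays
                   if a not in set(keep)}
        rep = qcmod.FilterReport("snr_threshold_SomaScan_CSF",
                                 len(filtered[key].assays), len(keep), removed)
        reports.append(rep)
        log.info("SomaScan CSF: S:N threshold %.3g keeps %d of %d assays",
                 snr_threshold, rep.assays_after, rep.assays_before)
        filtered[key] = filtered[key].subset_assays(keep)
        metas[key] = [m for m in metas[key] if m.assay_id in set(keep)]

    return filtered, metas, profiles, reports, snr_threshold, snr_curve


def harmonization_blocks(filtered, metas, cohort: SimulatedCohort,
                         fluid: Fluid) -> dict:
    """Per-platform complete-case blocks fed to transposed TAMPOR for one
    fluid; the TMT block is TAMPOR batch-corrected first."""
    blocks = {}
    for platform in (Platform.SOMASCAN, Platform.OLINK, Platform.TMTMS):
        key = (platform, fluid)
        if key not in filtered:
            continue
        matrix, meta = filtered[key], metas[key]
        if platform is Platform.TMTMS:
            _, clean, dropped = tampor_batch_correct(
                matrix, cohort.batch_designs[fluid])
            if dropped:
                log.info("TMT %s: %d proteins without GIS dropped",
                         fluid.value, len(dropped))
            clean_cc = clean.dropna(axis=1)
            matrix = MeasurementMatrix(clean_cc, scale=Scale.LINEAR)
            meta = [m for m in meta if m.assay_id in set(clean_cc.columns)]
        matrix = _complete_case(matrix)
        meta = [m for m in meta if m.assay_id in set(matrix.assays)]
        blocks[platform] = (matrix, meta)
        log.info("harmonize %s: %s contributes %d complete assays",
                 fluid.value, platform.value, len(matrix.assays))
    return blocks


def harmonize_stage(filtered, metas, cohort: SimulatedCohort):
    """TAMPOR-correct TMT, restrict to complete cases, run transposed TAMPOR."""
    harmonized: dict[Fluid, HarmonizedMatrix] = {}
    for fluid in (Fluid.CSF, Fluid.PLASMA):
        blocks = harmonization_blocks(filtered, metas, cohort, fluid)
        harmonized[fluid] = transposed_tampor(blocks)
        log.info("harmonized %s: %d samples x %d labels (%d anchors)",
                 fluid.value, *harmonized[fluid].values.shape,
                 len(harmonized[fluid].anchor_labels))
    return harmonized


def run_pipeline(config: PipelineConfig | None = None, seed: int | None = None,
                 cohort: SimulatedCohort | None = None,
                 out_dir: str | Path = "fluidnet_run") -> dict:
    """Execute the full analysis and write artifacts under ``out_dir``.

    Provide either ``cohort`` (real or pre-simulated inputs) or ``seed``
    to simulate the default design. Returns a dict of in-memory results.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, seed, cohort, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, seed, cohort, out: Path) -> dict:
    if cohort is None:
        if seed is None:
            seed = config.seed
        log.info("simulating default cohort, seed=%d", seed)
        cohort = simulate_cohort(seed=seed)
    groups = cohort.traits.group_labels()
    write_traits(out / "traits.csv", cohort.traits)

    # ---- qc ----------------------------------------------------------------
    try:
        filtered, metas, profiles, reports, snr_threshold, snr_curve = \
            qc_stage(cohort, config)
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc
    pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
        out / "filter_report.tsv", sep="\t", index=False)
    for (platform, fluid), prof in profiles.items():
        prof.table.to_csv(out / f"noise_profile_{platform.value}_{fluid.value}.tsv",
                          sep="\t", float_format="%.10g")
    if snr_curve is not None:
        snr_curve.to_csv(out / "snr_threshold_curve.tsv", sep="\t",
                         index=False, float_format="%.10g")

    # ---- harmonize ----------------------------------------------------------
    try:
        harmonized = harmonize_stage(filtered, metas, cohort)
    except Exception as exc:
        raise PipelineError("harmonize", str(exc)) from exc
    for fluid, hm in harmonized.items():
        write_matrix_tsv(out / f"harmonized_{fluid.value}.tsv", hm.values)
        (out / f"anchors_{fluid.value}.txt").write_text(
            "\n".join(hm.anchor_labels) + "\n")

    # ---- abundance ----------------------------------------------------------
    diff_results = {}
    try:
        for (platform, fluid), matrix in filtered.items():
            res = ab.differential_abundance(matrix, groups)
            diff_results[(platform, fluid)] = res
            res.to_csv(out / f"differential_{fluid.value}_{platform.value}.tsv",
                       sep="\t", float_format="%.10g")
    except Exception as exc:
        raise PipelineError("abundance", str(exc)) from exc

    # ---- networks -----------------------------------------------------------
    networks = {}
    trait_cors = {}
    try:
        for fluid, hm in harmonized.items():
            params = config.network_params(fluid)
            outliers = nw.detect_sample_outliers(hm.values)
            if outliers:
                log.info("network %s: connectivity outliers flagged: %s",
                         fluid.value, outliers)
            model = nw.build_network(hm.values, params)
            networks[fluid] = model
            log.info("network %s: %d modules, %d of %d labels assigned",
                     fluid.value, len(model.modules),
                     int((model.assignments != 0).sum()), len(model.assignments))
            rtab, ptab, r_crit = nw.correlate_with_traits(
                model.eigenproteins, cohort.traits.df[TRAIT_COLS_FOR_CORR])
            trait_cors[fluid] = (rtab, ptab, r_crit)
            with open(out / f"network_{fluid.value}.json", "w") as fh:
                json.dump({"params": vars(params),
                           "assignments": {l: int(m) for l, m in
                                           model.assignments.items()},
                           "converged": model.converged}, fh, indent=1)
            model.kme.to_csv(out / f"kme_{fluid.value}.tsv", sep="\t",
                             float_format="%.10g")
            model.eigenproteins.to_csv(out / f"eigenproteins_{fluid.value}.tsv",
                                       sep="\t", float_format="%.10g")
            rtab.to_csv(out / f"module_trait_cor_{fluid.value}.tsv", sep="\t",
                        float_format="%.10g")
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc

    # ---- cross-network ------------------------------------------------------
    try:
        crossnet_out = _crossnet(config, harmonized, networks, groups, out)
    except Exception as exc:
        raise PipelineError("crossnet", str(exc)) from exc

    return {"cohort": cohort, "filtered": filtered, "metas": metas,
            "harmonized": harmonized, "networks": networks,
            "differential": diff_results, "trait_correlations": trait_cors,
            "snr_threshold": snr_threshold, **crossnet_out}


def _symbol_sets(model: nw.NetworkModel) -> dict[int, set]:
    from .model import parse_label
    out: dict[int, set] = {}
    for label, mid in model.assignments.items():
        if mid == 0:
            continue
        out.setdefault(mid, set()).add(parse_label(label).symbol)
    return out


def _crossnet(config, harmonized, networks, groups, out: Path) -> dict:
    from .model import parse_label
    csf, plasma = networks[Fluid.CSF], networks[Fluid.PLASMA]
    sym_csf = _symbol_sets(csf)
    sym_plasma = _symbol_sets(plasma)
    bg = ({parse_label(l).symbol for l in harmonized[Fluid.CSF].labels}
          & {parse_label(l).symbol for l in harmonized[Fluid.PLASMA].labels})
    ora = cn.module_ora(sym_csf, sym_plasma, bg) if sym_csf and sym_plasma \
        else pd.DataFrame()
    if len(ora):
        ora.to_csv(out / "ora_CSF_vs_plasma.tsv", sep="\t", index=False,
                   float_format="%.10g")

    # map CSF module members onto plasma labels, then preservation + synthetic
    # eigenproteins + cross-fluid slopes
    src = pd.DataFrame(
        [(l, parse_label(l).uniprot, parse_label(l).symbol)
         for l in csf.assignments.index],
        columns=["label", "uniprot", "gene_symbol"]).set_index("label")
    mapping = cn.map_labels(src, harmonized[Fluid.PLASMA].labels)
    mapped = mapping["target_label"].dropna()

    ref_vals = harmonized[Fluid.CSF].values
    test_vals = harmonized[Fluid.PLASMA].values.rename(
        columns={v: k for k, v in mapped.items()})
    test_vals = test_vals.loc[:, ~test_vals.columns.duplicated()]
    pres = cn.module_preservation(
        ref_vals, csf.assignments, test_vals,
        n_perm=config.preservation_permutations, seed=config.seed,
        beta=config.network_csf.beta)
    pres.table.to_csv(out / "preservation_CSF_in_plasma.tsv", sep="\t",
                      float_format="%.10g")

    synth_rows = []
    synth_eig = {}
    for mid in csf.modules:
        members = [mapped[l] for l in csf.members(mid) if l in mapped.index]
        members = list(dict.fromkeys(members))
        if len(members) < 2:
            continue
        scores, t, p = cn.synthetic_eigenprotein(
            harmonized[Fluid.PLASMA].values, members, groups)
        synth_eig[mid] = scores
        synth_rows.append((mid, len(members), t, p))
    synth = pd.DataFrame(synth_rows, columns=["module", "n_mapped", "t", "p"])
    synth.to_csv(out / "synthetic_eigenproteins.tsv", sep="\t", index=False,
                 float_format="%.10g")

    zres = None
    if synth_eig:
        plasma_eig = pd.DataFrame(synth_eig)
        shared = [m for m in csf.eigenproteins.columns if m in plasma_eig.columns]
        zres = cn.zslope(csf.eigenproteins[shared], plasma_eig[shared], groups)
        zres.table.to_csv(out / "zslope.tsv", sep="\t", float_format="%.10g")
    return {"ora": ora, "preservation": pres, "synthetic_eigenproteins": synth,
            "zslope": zres, "mapping": mapping}
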