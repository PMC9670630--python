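import numpy as np
import pandas as pd
import pytest

from fluidnet.model import Fluid, MeasurementMatrix, Platform, Scale, Status
from fluidnet.qc import (
    censor_depletion_affected, compute_lod, compute_snr, apply_lod,
    filter_missingness, match_assays_across_platforms,
    reduce_duplicate_assays, select_snr_threshold,
)
from conftest import make_matrix, make_meta


def buffer_frame(values, assays):
    values = np.atleast_2d(values)
    return pd.DataFrame(values, columns=assays,
                        index=[f"BUFFER{i:02d}" for i in range(len(values))])


class TestSnr:
    @pytest.mark.parametrize("signal,expected", [
        (145.0, 0.45),   # (145 - 100) / 100
        (100.0, 0.0),
        (50.0, -0.5),    # S:N below zero is legal
    ])
    def test_snr_at_median_sample_signal(self, signal, expected):
        m = make_matrix(np.full((5, 1), signal), assays=["A"])
        buf = buffer_frame(np.full((4, 1), 100.0), ["A"])
        prof = compute_snr(m, buf)
        assert prof["snr"]["A"] == pytest.approx(expected)

    def test_missing_buffer_flagged_not_dropped(self):
        m = make_matrix(np.full((5, 2), 100.0), assays=["A", "B"])
        buf = buffer_frame(np.full((3, 1), 10.0), ["A"])
        prof = compute_snr(m, buf)
        assert np.isfinite(prof["snr"]["A"])
        assert np.isnan(prof["snr"]["B"]) and prof["n_buffer"]["B"] == 0

    def test_nonpositive_buffer_median_error(self):
        m = make_matrix(np.full((3, 1), 5.0), assays=["A"])
        buf = buffer_frame(np.full((3, 1), 0.0), ["A"])
        with pytest.raises(ValueError, match="buffer median"):
            compute_snr(m, buf)

    def test_matches_brute_force_on_random_fixture(self, rng):
        m = make_matrix(np.exp2(rng.normal(8, 2, (10, 6))))
        buf = buffer_frame(np.exp2(rng.normal(4, 0.5, (5, 6))), m.assays)
        prof = compute_snr(m, buf)
        for a in m.assays:
            bmed = np.median(buf[a])
            expect = (np.median(m.values[a]) - bmed) / bmed
            assert prof["snr"][a] == pytest.approx(expect, abs=1e-12)
            blog = np.log2(buf[a])
            assert prof["lod_log2"][a] == pytest.approx(
                np.median(blog) + 3 * np.std(blog, ddof=1), abs=1e-12)


class TestLod:
    def test_zero_spread_buffer(self):
        buf = buffer_frame(np.exp2(np.array([[6.0], [6.0], [6.0]])), ["A"])
        assert compute_lod(buf)["A"] == pytest.approx(6.0)

    def test_three_point_buffer(self):
        buf = buffer_frame(np.exp2(np.array([[5.0], [6.0], [7.0]])), ["A"])
        assert compute_lod(buf)["A"] == pytest.approx(9.0)  # 6 + 3*1

    def test_supplied_lod_takes_precedence(self):
        buf = buffer_frame(np.exp2(np.array([[5.0], [7.0]])), ["A"])
        lods = compute_lod(buf, supplied=pd.Series({"A": 12.5}))
        assert lods["A"] == 12.5

    def test_single_replicate_flagged_nan(self):
        buf = buffer_frame([[64.0]], ["A"])
        assert np.isnan(compute_lod(buf)["A"])

    def test_below_lod_value_preserved(self):
        m = make_matrix([[2 ** 8.9], [2 ** 10.0]], assays=["A"])
        out = apply_lod(m, pd.Series({"A": 9.0}))
        assert out.status.iloc[0, 0] == Status.BELOW_LOD
        assert out.status.iloc[1, 0] == Status.OBSERVED
        assert out.values.iloc[0, 0] == pytest.approx(2 ** 8.9)


class TestMissingnessFilter:
    @pytest.mark.parametrize("n_missing,kept", [(27, True), (28, False),
                                                (0, True)])
    def test_27_of_36_boundary(self, n_missing, kept):
        """Up to 75% (27/36) missing tolerated: measured in >= 9 subjects."""
        status = np.full((36, 1), int(Status.OBSERVED))
        status[:n_missing, 0] = int(Status.BELOW_LOD)
        vals = np.full((36, 1), 100.0)
        m = make_matrix(vals, status=status)
        out, report = filter_missingness(m, 0.75)
        assert (len(out.assays) == 1) is kept
        assert report.assays_before - report.assays_after == len(report.removed)

    def test_zero_budget_removes_any_missing(self):
        status = np.full((6, 2), int(Status.OBSERVED))
        status[0, 1] = int(Status.NOT_MEASURED)
        vals = np.ones((6, 2))
        vals[0, 1] = np.nan
        m = make_matrix(vals, status=status)
        out, report = filter_missingness(m, max_frac=1e-9)
        assert out.assays == ["A0"]

    def test_report_counts_conserved_across_chain(self, small_cohort):
        key = (Platform.SOMASCAN, Fluid.CSF)
        m = small_cohort.matrices[key]
        m1, rep1 = filter_missingness(m, 0.75)
        m2, rep2, _ = reduce_duplicate_assays(m1, small_cohort.metas[key])
        assert rep1.assays_before == len(m.assays)
        assert rep1.assays_after == rep2.assays_before
        assert rep2.assays_after + len(rep1.removed) + len(rep2.removed) \
            == len(m.assays)


class TestSnrThreshold:
    def _profile_from(self, m, snrs):
        import fluidnet.qc as qcmod
        table = pd.DataFrame({"snr": snrs}, index=m.assays)
        return qcmod.NoiseProfile(table)

    def _paired_set(self, rng, snrs, noise_mask):
        n, p = 30, len(snrs)
        latent = rng.normal(10, 1, (n, p))
        soma = latent + rng.normal(0, 0.3, (n, p))
        soma[:, noise_mask] = rng.normal(0, 0.3, (n, noise_mask.sum()))
        other = latent + rng.normal(0, 0.3, (n, p))
        mA = make_matrix(np.exp2(soma), assays=[f"S{i}" for i in range(p)])
        mB = make_matrix(np.exp2(other), assays=[f"O{i}" for i in range(p)])
        metaA = [make_meta(f"S{i}", uniprot=f"P{i}") for i in range(p)]
        metaB = [make_meta(f"O{i}", platform=Platform.OLINK, uniprot=f"P{i}")
                 for i in range(p)]
        return mA, metaA, mB, metaB

    def test_flat_profile_returns_grid_minimum(self, rng):
        snrs = np.full(20, 5.0)
        mA, metaA, mB, metaB = self._paired_set(rng, snrs,
                                                np.zeros(20, dtype=bool))
        thr, curve = select_snr_threshold(mA, metaA, self._profile_from(mA, snrs),
                                          [(mB, metaB)], grid=[0, 0.5, 1, 2])
        assert thr == 0  # tie -> smallest maximizing cutoff

    def test_single_element_grid(self, rng):
        snrs = np.full(10, 5.0)
        mA, metaA, mB, metaB = self._paired_set(rng, snrs,
                                                np.zeros(10, dtype=bool))
        thr, _ = select_snr_threshold(mA, metaA, self._profile_from(mA, snrs),
                                      [(mB, metaB)], grid=[0.45])
        assert thr == 0.45

    def test_planted_noise_boundary_recovered(self, rng):
        """Assays planted below S:N 0.5 are pure noise; the selected cutoff
        excludes them and lands at the first grid point past the boundary."""
        snrs = np.concatenate([rng.uniform(0.0, 0.4, 15),
                               rng.uniform(2.0, 9.0, 25)])
        noise_mask = snrs < 0.5
        mA, metaA, mB, metaB = self._paired_set(rng, snrs, noise_mask)
        grid = [0, 0.15, 0.25, 0.35, 0.45, 0.5, 0.625, 1, 2]
        thr, curve = select_snr_threshold(mA, metaA, self._profile_from(mA, snrs),
                                          [(mB, metaB)], grid=grid)
        assert thr in (0.45, 0.5, 0.625)

    def test_no_paired_proteins_error(self, rng):
        snrs = np.full(3, 5.0)
        mA, metaA, mB, metaB = self._paired_set(rng, snrs,
                                                np.zeros(3, dtype=bool))
        with pytest.raises(ValueError, match="paired"):
            select_snr_threshold(mA, metaA, self._profile_from(mA, snrs),
                                 [(mB, metaB)], grid=[0.45])


class TestDuplicateReduction:
    def test_higher_signal_wins_between_twins(self, rng):
        base = rng.normal(10, 1, 12)
        m = make_matrix(np.exp2(np.column_stack([base, base + 1.0])),
                        assays=["low", "high"])
        metas = [make_meta("low", uniprot="P1"), make_meta("high", uniprot="P1")]
        out, report, kept = reduce_duplicate_assays(m, metas)
        assert out.assays == ["high"]
        assert report.removed == {"low": "duplicate_of_high"}

    def test_anticorrelated_replicate_loses(self, rng):
        base = rng.normal(10, 1, 12)
        cols = np.column_stack([base, base + rng.normal(0, 0.05, 12), -base])
        m = make_matrix(np.exp2(cols - cols.min() + 1),
                        assays=["a", "b", "anti"])
        metas = [make_meta(x, uniprot="P1") for x in ("a", "b", "anti")]
        out, report, _ = reduce_duplicate_assays(m, metas)
        assert out.assays[0] in ("a", "b")
        assert "anti" in report.removed

    def test_no_duplicates_identity(self, rng):
        m = make_matrix(np.exp2(rng.normal(10, 1, (5, 3))))
        metas = [make_meta(a, uniprot=f"P{i}") for i, a in enumerate(m.assays)]
        out, report, _ = reduce_duplicate_assays(m, metas)
        assert out.assays == m.assays and not report.removed


class TestCrossPlatformMatching:
    def test_uniprot_beats_symbol(self):
        metaA = [make_meta("a1", uniprot="P1", symbol="G1"),
                 make_meta("a2", uniprot="P9", symbol="G2")]
        metaB = [make_meta("b1", platform=Platform.OLINK, uniprot="P1",
                           symbol="G2")]
        pairs = match_assays_across_platforms(metaA, metaB)
        assert pairs == [("a1", "b1")]

    def test_best_correlated_somamer_selected(self, rng):
        truth = rng.normal(0, 1, 20)
        good = truth + rng.normal(0, 0.3, 20)
        bad = rng.normal(0, 1, 20)
        mA = make_matrix(np.exp2(np.column_stack([good, bad]) + 10),
                         assays=["good", "bad"])
        mB = make_matrix(np.exp2(truth[:, None] + 10), assays=["olk"])
        metaA = [make_meta("good", uniprot="P1"), make_meta("bad", uniprot="P1")]
        metaB = [make_meta("olk", platform=Platform.OLINK, uniprot="P1")]
        pairs = match_assays_across_platforms(metaA, metaB, mA, mB)
        assert pairs == [("good", "olk")]

    def test_disjoint_metadata_empty(self):
        metaA = [make_meta("a", uniprot="P1")]
        metaB = [make_meta("b", platform=Platform.OLINK, uniprot="P2")]
        assert match_assays_across_platforms(metaA, metaB) == []


class TestDepletionCensoring:
    def _pair(self, rng, rho_sign=1.0, flip_direction=False, n=36):
        groups = pd.Series(["AD"] * (n // 2) + ["CT"] * (n // 2),
                           index=[f"s{i}" for i in range(n)])
        shift = np.where(groups == "AD", 0.5, 0.0)
        base = rng.normal(10, 1, n) + shift
        dep = base + rng.normal(0, 0.2, n)
        undep = rho_sign * base + rng.normal(0, 0.2, n)
        if flip_direction:
            undep = undep - 2 * np.where(groups == "AD", shift, 0.0)
        mk = lambda v, aid: make_matrix(np.exp2(v[:, None]),
                                        samples=list(groups.index),
                                        assays=[aid])
        return (mk(dep, "d1"), [make_meta("d1", platform=Platform.TMTMS,
                                          uniprot="P1")],
                mk(undep, "u1"), [make_meta("u1", platform=Platform.TMTMS,
                                            uniprot="P1")], groups)

    def test_negative_rho_censored(self, rng):
        dep, md, undep, mu, groups = self._pair(rng, rho_sign=-1.0)
        censored, report, detail = censor_depletion_affected(
            dep, md, undep, mu, groups)
        assert censored == ["P1"]

    def test_discordant_direction_censored(self, rng):
        dep, md, undep, mu, groups = self._pair(rng, flip_direction=True)
        censored, *_ = censor_depletion_affected(dep, md, undep, mu, groups)
        assert censored == ["P1"]

    def test_concordant_retained(self, rng):
        dep, md, undep, mu, groups = self._pair(rng)
        censored, report, detail = censor_depletion_affected(
            dep, md, undep, mu, groups)
        assert censored == []
        assert detail.loc[0, "rho"] > 0.5

    def test_ineligible_skipped_not_censored(self, rng):
        dep, md, undep, mu, groups = self._pair(rng, n=8)  # < 9 pairs
        censored, report, detail = censor_depletion_affected(
            dep, md, undep, mu, groups)
        assert censored == [] and report.skipped == ["P1"]

    def test_false_censor_rate_controlled(self, rng):
        """Concordant proteins with rho >= 0.5 are censored in < 5% of cases."""
        n, p = 36, 200
        groups = pd.Series(["AD"] * 18 + ["CT"] * 18,
                           index=[f"s{i}" for i in range(n)])
        base = rng.normal(10, 1, (n, p)) + np.where(groups == "AD", 0.8,
                                                    0.0)[:, None]
        dep = base + rng.normal(0, 0.5, (n, p))
        undep = base + rng.normal(0, 0.5, (n, p))
        md = [make_meta(f"d{i}", platform=Platform.TMTMS, uniprot=f"P{i}")
              for i in range(p)]
        mu = [make_meta(f"u{i}", platform=Platform.TMTMS, uniprot=f"P{i}")
              for i in range(p)]
        mdep = make_matrix(np.exp2(dep), samples=list(groups.index),
                           assays=[f"d{i}" for i in range(p)])
        mund = make_matrix(np.exp2(undep), samples=list(groups.index),
                           assays=[f"u{i}" for i in range(p)])
        censored, report, detail = censor_depletion_affected(
            mdep, md, mund, mu, groups)
        strong = detail[detail["rho"] >= 0.5]
        assert len(strong) > 100
        assert strong["censored"].mean() < 0.05
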