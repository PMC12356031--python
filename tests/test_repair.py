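"""Pathway routing, misrepair pairing, repair outcomes and cell fate."""

import numpy as np
import pytest

import letrbe as L
from letrbe.repair import (
    CORRECT,
    MISREPAIRED,
    UNREPAIRED,
    PathwayStatus,
    RepairOutcome,
    _cell_rngs,
    misrepair_pairing,
    simulate_repair_outcome,
)


def _phenotype(**kw):
    return L.CellPhenotype(label="custom", **kw)


def _photon_breaks(dose, rng, geom, yield_=35.0, complex_fraction=0.25):
    params = L.InductionParams(dsb_yield=yield_, complex_fraction=complex_fraction)
    d = L.sample_breaks(dose, L.QUALITY_PRESETS["xray"], geom, params, rng)
    return L.assign_complexity(d, complex_fraction, rng)


class TestAssignPathway:
    def test_wild_type_g1_is_functional_nhej(self, wild_type):
        assert L.assign_pathway(False, wild_type, "G1") == ("nhej", PathwayStatus.FUNCTIONAL)
        assert L.assign_pathway(True, wild_type, "G1") == ("nhej", PathwayStatus.FUNCTIONAL)

    def test_complex_only_defect_spares_simple_breaks(self):
        artemis = L.PHENOTYPE_PRESETS["artemis"]
        assert L.assign_pathway(False, artemis, "G1") == ("nhej", PathwayStatus.FUNCTIONAL)

    def test_complex_only_defect_reroutes_complex_to_backup(self):
        artemis = L.PHENOTYPE_PRESETS["artemis"]
        pathway, status = L.assign_pathway(True, artemis, "G1")
        assert pathway == "alt_ej"
        assert status is PathwayStatus.FUNCTIONAL

    def test_complex_in_s_phase_routes_to_hr(self, wild_type, rng):
        # default routing (no rng) sends complex S/G2 breaks to HR
        assert L.assign_pathway(True, wild_type, "S")[0] == "hr"

    def test_hr_defective_complex_break_falls_to_backup(self):
        brca1 = L.PHENOTYPE_PRESETS["brca1"]
        assert L.assign_pathway(True, brca1, "G2")[0] == "alt_ej"

    def test_total_knockout_is_unrepairable(self):
        dead = _phenotype(nhej=PathwayStatus.DEFECTIVE, alt_ej=PathwayStatus.DEFECTIVE)
        pathway, status = L.assign_pathway(False, dead, "G1")
        assert pathway == "none"
        assert status is PathwayStatus.DEFECTIVE

    def test_unknown_phase(self, wild_type):
        with pytest.raises(ValueError, match="phase"):
            L.assign_pathway(False, wild_type, "M")


class TestMisrepairPairing:
    def test_single_break_never_misrepairs(self, kinetics, rng):
        partner = misrepair_pairing(np.zeros((1, 3)), kinetics, rng)
        assert partner.tolist() == [-1]

    def test_coincident_pair_with_matched_self_weight(self):
        # two breaks at the same position, w_self = kernel weight (=1):
        # misrepair probability is exactly 1/2
        params = L.KineticsParams(w_self=1.0)
        pos = np.zeros((2, 3))
        hits = 0
        n = 4000
        rng = np.random.default_rng(5)
        for _ in range(n):
            partner = misrepair_pairing(pos, params, rng)
            hits += partner[0] >= 0
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_pairing_is_symmetric(self, kinetics, rng):
        pos = rng.random((30, 3))
        partner = misrepair_pairing(pos, kinetics, rng)
        for i, j in enumerate(partner):
            if j >= 0:
                assert partner[j] == i

    def test_three_break_frequencies_match_enumeration(self):
        """Empirical pairing frequencies vs exhaustive enumeration of the
        greedy sequential process on a fixed 3-break configuration."""
        params = L.KineticsParams(sigma_misrepair=0.35, w_self=2.0)
        pos = np.array([[0.0, 0, 0], [0.3, 0, 0], [0.0, 0.5, 0]])
        d2 = ((pos[:, None] - pos[None, :]) ** 2).sum(-1)
        K = np.exp(-d2 / (2 * params.sigma_misrepair**2))
        w01, w02, w12 = K[0, 1], K[0, 2], K[1, 2]
        w = params.w_self
        s0 = w01 + w02
        expected = {
            (0, 1): w01 / (w + s0),
            (0, 2): w02 / (w + s0),
            (1, 2): (w / (w + s0)) * (w12 / (w + w12)),
        }
        counts = dict.fromkeys(expected, 0)
        none = 0
        n = 10_000
        rng = np.random.default_rng(42)
        for _ in range(n):
            partner = misrepair_pairing(pos, params, rng)
            if partner[0] == 1:
                counts[(0, 1)] += 1
            elif partner[0] == 2:
                counts[(0, 2)] += 1
            elif partner[1] == 2:
                counts[(1, 2)] += 1
            else:
                none += 1
        for pair, p in expected.items():
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(counts[pair] / n - p) < 3 * sigma, pair
        p_none = 1 - sum(expected.values())
        assert abs(none / n - p_none) < 3 * np.sqrt(p_none * (1 - p_none) / n)


class TestSimulateRepairOutcome:
    def test_counts_conserved(self, geom, kinetics, wild_type):
        rng = np.random.default_rng(9)
        for _ in range(30):
            dsbs = _photon_breaks(rng.uniform(0.5, 6), rng, geom)
            out = simulate_repair_outcome(dsbs, wild_type, kinetics, rng)
            assert out.n_correct + out.n_misrepaired + out.n_unrepaired == len(dsbs)
            assert out.n_inter_events + out.n_intra_events == out.n_misrepaired // 2

    def test_zero_dose_all_zero(self, geom, kinetics, wild_type, rng):
        dsbs = _photon_breaks(0.0, rng, geom)
        out = simulate_repair_outcome(dsbs, wild_type, kinetics, rng)
        assert out.n_total == 0

    def test_forced_backup_failure_leaves_all_unrepaired(self, geom, kinetics, rng):
        lig4_like = _phenotype(nhej=PathwayStatus.DEFECTIVE, alt_ej_failure_prob=1.0)
        dsbs = _photon_breaks(2.0, rng, geom)
        out = simulate_repair_outcome(dsbs, lig4_like, kinetics, rng, phase="G1")
        assert out.n_unrepaired == len(dsbs)

    def test_misrepair_fraction_matches_pairwise_expectation(self, geom, wild_type):
        """MC misrepair frequency vs the per-configuration sum of pairwise
        misrepair probabilities S_i/(w_self+S_i) over the same geometry."""
        params = L.KineticsParams()
        rng = np.random.default_rng(17)
        total = mis = expected = 0.0
        for _ in range(200):
            dsbs = _photon_breaks(2.0, rng, geom, complex_fraction=0.0)
            n = len(dsbs)
            if n < 2:
                continue
            d2 = ((dsbs.positions[:, None] - dsbs.positions[None, :]) ** 2).sum(-1)
            K = np.exp(-d2 / (2 * params.sigma_misrepair**2))
            np.fill_diagonal(K, 0.0)
            s = K.sum(axis=1)
            expected += (s / (params.w_self + s)).sum()
            out = simulate_repair_outcome(dsbs, wild_type, params, rng, phase="G1")
            mis += out.n_misrepaired
            total += n
        frac_mc = mis / total
        frac_expected = expected / total
        sigma = np.sqrt(frac_expected * (1 - frac_expected) / total)
        assert abs(frac_mc - frac_expected) < 3 * sigma + 0.003

    def test_misrepair_fraction_non_decreasing_in_let(self, geom, kinetics, wild_type):
        fracs = []
        for q in L.QUALITY_ORDER:
            tot = mis = 0
            for j in range(300):
                rng = np.random.default_rng([23, j])
                params = L.InductionParams()
                d = L.sample_breaks(2.0, L.QUALITY_PRESETS[q], geom, params, rng)
                d = L.assign_complexity(d, params.complex_fraction, rng)
                out = simulate_repair_outcome(d, wild_type, kinetics, rng, phase="G1")
                tot += out.n_total
                mis += out.n_misrepaired
            fracs.append(mis / tot)
        sigmas = [np.sqrt(f * (1 - f) / 300 / 70) for f in fracs]
        for i in range(len(fracs) - 1):
            assert fracs[i + 1] >= fracs[i] - 3 * np.hypot(sigmas[i], sigmas[i + 1])

    def test_bit_identical_under_seed(self, geom, kinetics, wild_type):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            dsbs = _photon_breaks(2.0, rng, geom)
            outs.append(simulate_repair_outcome(dsbs, wild_type, kinetics, rng))
        np.testing.assert_array_equal(outs[0].labels, outs[1].labels)
        np.testing.assert_array_equal(outs[0].partner, outs[1].partner)


class TestCellSurvivalProbability:
    def _outcome(self, n_mis=0, n_unrep=0, inter=0, intra=0):
        empty = np.empty(0, dtype=np.int64)
        return RepairOutcome(
            n_correct=0, n_misrepaired=n_mis, n_unrepaired=n_unrep,
            n_inter_events=inter, n_intra_events=intra,
            labels=empty, pathways=empty, partner=empty, rates=np.empty(0),
            phase="G1",
        )

    def test_no_damage_survives(self, wild_type, kinetics):
        assert L.cell_survival_probability(self._outcome(), wild_type, kinetics) == 1.0

    def test_unrepaired_closed_form(self, kinetics):
        # two unrepaired breaks at lethality 1/2 each, checkpoint off
        p53_like = _phenotype(g1_checkpoint_activity=0.0)
        params = L.KineticsParams(p_lethal_unrepaired=0.5)
        out = self._outcome(n_unrep=2)
        assert L.cell_survival_probability(out, p53_like, params) == pytest.approx(0.25)

    def test_checkpoint_null_survives_more(self, kinetics):
        out = self._outcome(n_mis=4, n_unrep=1, inter=2)
        wt = _phenotype(g1_checkpoint_activity=1.0)
        p53_like = _phenotype(g1_checkpoint_activity=0.0)
        assert (
            L.cell_survival_probability(out, p53_like, kinetics)
            > L.cell_survival_probability(out, wt, kinetics)
        )

    def test_inter_more_lethal_than_intra(self, wild_type, kinetics):
        inter = self._outcome(n_mis=2, inter=1)
        intra = self._outcome(n_mis=2, intra=1)
        assert (
            L.cell_survival_probability(inter, wild_type, kinetics)
            < L.cell_survival_probability(intra, wild_type, kinetics)
        )


class TestFociTimecourse:
    def test_time_zero_equals_initial_resolvable(self, geom, kinetics, wild_type, rng):
        dsbs = _photon_breaks(2.0, rng, geom)
        tc = L.expected_foci_timecourse(
            dsbs, wild_type, kinetics, [0.0, 1.0], n_reps=5, rng=rng
        )
        assert tc.mean_foci[0] == L.count_resolvable_foci(dsbs, 0.5)

    def test_total_knockout_flat_course(self, geom, kinetics, rng):
        dead = _phenotype(
            nhej=PathwayStatus.DEFECTIVE, hr=PathwayStatus.DEFECTIVE,
            alt_ej=PathwayStatus.DEFECTIVE,
        )
        dsbs = _photon_breaks(2.0, rng, geom)
        tc = L.expected_foci_timecourse(
            dsbs, dead, kinetics, [1.0, 8.0, 24.0], n_reps=10, rng=rng
        )
        assert np.all(tc.mean_foci == tc.mean_foci[0])

    def test_pure_fast_pathway_is_exponential(self, geom, rng, wild_type):
        # simple breaks only, misrepair disabled, no optical merging:
        # the mean course is N0 * exp(-rate_fast * t)
        params = L.KineticsParams(w_self=1e12)
        dsbs = _photon_breaks(2.0, rng, geom, complex_fraction=0.0)
        times = np.array([0.5, 1.0, 2.0])
        tc = L.expected_foci_timecourse(
            dsbs, wild_type, params, times, resolution=1e-6, n_reps=400,
            rng=rng, phase="G1",
        )
        expected = len(dsbs) * np.exp(-params.rate_fast * times)
        np.testing.assert_allclose(tc.mean_foci, expected, atol=4 * np.max(tc.sem) + 0.5)

    def test_unsorted_times_rejected(self, geom, kinetics, wild_type, rng):
        dsbs = _photon_breaks(1.0, rng, geom)
        with pytest.raises(ValueError):
            L.expected_foci_timecourse(dsbs, wild_type, kinetics, [2.0, 1.0], rng=rng)


class TestPredictSurvivalCurve:
    def test_zero_dose_survival_is_one(self, wild_type, xray):
        curve = L.predict_survival_curve(wild_type, xray, [0.0], n_cells=100, seed=0)
        assert curve.sf_mean.tolist() == [1.0]

    def test_empty_dose_list_rejected(self, wild_type, xray):
        with pytest.raises(ValueError):
            L.predict_survival_curve(wild_type, xray, [], n_cells=100, seed=0)

    def test_survival_non_increasing_in_dose(self, wild_type, xray):
        curve = L.predict_survival_curve(
            wild_type, xray, [0, 1, 2, 4], n_cells=300, seed=2
        )
        for i in range(len(curve) - 1):
            tol = 3 * np.hypot(curve.sf_err[i], curve.sf_err[i + 1])
            assert curve.sf_mean[i + 1] <= curve.sf_mean[i] + tol

    def test_wild_type_dominates_knockouts(self, xray):
        wt_curve = L.predict_survival_curve(
            L.PHENOTYPE_PRESETS["wild_type"], xray, [0, 2, 4], n_cells=300, seed=3
        )
        for label in ("lig4", "brca1", "artemis"):
            ko = L.predict_survival_curve(
                L.PHENOTYPE_PRESETS[label], xray, [0, 2, 4], n_cells=300, seed=3
            )
            for i in range(1, 3):
                tol = 3 * np.hypot(wt_curve.sf_err[i], ko.sf_err[i])
                assert ko.sf_mean[i] <= wt_curve.sf_mean[i] + tol

    def test_deterministic_under_seed(self, wild_type, xray):
        a = L.predict_survival_curve(wild_type, xray, [0, 2], n_cells=100, seed=4)
        b = L.predict_survival_curve(wild_type, xray, [0, 2], n_cells=100, seed=4)
        np.testing.assert_array_equal(a.sf_mean, b.sf_mean)


def test_phenotype_presets_complete():
    assert set(L.PHENOTYPE_PRESETS) == set(L.SENSITIVITY_ORDER)
    atm = L.PHENOTYPE_PRESETS["atm"]
    assert atm.g1_checkpoint_activity == 0.0
    assert L.PHENOTYPE_PRESETS["dnapk"].nhej is PathwayStatus.COMPLEX_ONLY_DEFECTIVE
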