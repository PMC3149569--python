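"""Decomposition, matching and spatial-filter tests against planted truth."""

import itertools

import numpy as np
import pytest

from erpic import (
    DegenerateInputError,
    ICADecomposition,
    InvalidInputError,
    MatchCriteria,
    apply_spatial_filters,
    average_reference,
    exclude_artifact_ics,
    grand_average,
    match_components,
    run_ica,
    stack_for_ica,
    unstack,
)
from erpic.cohort import ERPCohort, SET_CONDITIONS
from erpic.ica import _pearson_matrix
from erpic.pipeline import eog_template

from conftest import pair_by_correlation


class TestAverageReference:
    def test_constant_offsets_closed_form(self):
        v = np.arange(5, dtype=float)
        erp = np.tile(v[:, None], (1, 10))
        out = average_reference(erp)
        np.testing.assert_allclose(out, (v - v.mean())[:, None] * np.ones(10))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        erp = rng.normal(size=(19, 250))
        once = average_reference(erp)
        np.testing.assert_allclose(average_reference(once), once, atol=1e-12)

    def test_column_means_vanish(self):
        rng = np.random.default_rng(1)
        out = average_reference(rng.normal(size=(19, 250)))
        assert np.abs(out.mean(axis=0)).max() < 1e-10

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            average_reference(np.ones((1, 250)))


class TestGrandAverage:
    def test_equals_loop_mean(self, default_cohort):
        cohort, _, _ = default_cohort
        ga = grand_average(cohort, "nogo", "case")
        ids = [s.id for s in cohort.subjects if s.group == "case"]
        loop = sum(cohort.get(i, "nogo") for i in ids) / len(ids)
        np.testing.assert_allclose(ga, loop, atol=1e-12)

    def test_identical_subjects(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        ga = grand_average(cohort, "go", "control")
        np.testing.assert_allclose(ga, cohort.subset("control").data[0, 0])

    def test_symmetric_pair_cancels(self, montage):
        from erpic.cohort import Subject

        a = np.random.default_rng(3).normal(size=(4, 19, 250))
        data = np.stack([a, -a])
        cohort = ERPCohort(
            [Subject("s1", "control"), Subject("s2", "control")], data, montage
        )
        np.testing.assert_allclose(
            grand_average(cohort, "go", "all"), np.zeros((19, 250)), atol=1e-12
        )

    def test_empty_selection_rejected(self, montage):
        from erpic.cohort import Subject

        cohort = ERPCohort(
            [Subject("s1", "control")], np.zeros((1, 4, 19, 250)), montage
        )
        with pytest.raises(InvalidInputError):
            grand_average(cohort, "go", "case")


class TestStacking:
    def test_shape_and_round_trip(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        two = ERPCohort(cohort.subjects[:2], cohort.data[:2], cohort.montage)
        stacked = stack_for_ica(two, "continue")
        assert stacked.matrix.shape == (19, 2 * 2 * 250)
        blocks = unstack(stacked)
        for (sid, cond), mat in blocks.items():
            np.testing.assert_array_equal(mat, two.get(sid, cond))

    def test_block_index_arithmetic(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        stacked = stack_for_ica(cohort, "continue")
        sid = cohort.subjects[1].id
        np.testing.assert_array_equal(
            stacked.block(sid, "nogo"), cohort.get(sid, "nogo")
        )
        # subject-major, condition-within-subject layout
        assert stacked.blocks[2][:2] == (sid, "go")
        assert stacked.blocks[3][:2] == (sid, "nogo")

    def test_missing_condition_rejected(self, montage):
        from erpic.cohort import Subject

        cohort = ERPCohort(
            [Subject("s1", "control")], np.zeros((1, 2, 19, 250)), montage,
            conditions=("go", "nogo"),
        )
        with pytest.raises(InvalidInputError):
            stack_for_ica(cohort, "discontinue")


class TestRunICA:
    def test_recovers_planted_sources_noiseless(self, noiseless_cohort):
        """Exhaustive-pairing oracle: 3-source mixture, all |r| >= 0.99."""
        cohort, truth, _ = noiseless_cohort
        stacked = stack_for_ica(cohort, "continue")
        decomp = run_ica(stacked, 3, seed=0)
        best = -np.inf
        for perm in itertools.permutations(range(3)):
            r = [
                abs(np.corrcoef(truth.mixing[:, k], decomp.topographies[:, p])[0, 1])
                for k, p in enumerate(perm)
            ]
            best = max(best, min(r))
        assert best >= 0.99

    def test_filters_times_topographies_is_identity(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        prod = decomp.filters @ decomp.topographies
        np.testing.assert_allclose(prod, np.eye(3), atol=1e-6)

    def test_single_source_identifiable(self, montage):
        rng = np.random.default_rng(4)
        topo = rng.normal(size=19)
        topo /= np.linalg.norm(topo)
        s = np.sin(np.linspace(0, 20, 600)) ** 3
        X = np.outer(topo, s)
        decomp = run_ica(X, 1, seed=1)
        r = np.corrcoef(topo, decomp.topographies[:, 0])[0, 1]
        assert abs(r) >= 0.999

    def test_polarity_and_norm_convention(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        norms = np.linalg.norm(decomp.topographies, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        peaks = np.argmax(np.abs(decomp.topographies), axis=0)
        assert np.all(decomp.topographies[peaks, np.arange(3)] > 0)
        np.testing.assert_array_equal(decomp.sites, peaks)

    def test_deterministic_given_seed(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        stacked = stack_for_ica(cohort, "continue")
        d1 = run_ica(stacked, 3, seed=7)
        d2 = run_ica(stacked, 3, seed=7)
        np.testing.assert_array_equal(d1.topographies, d2.topographies)
        np.testing.assert_array_equal(d1.filters, d2.filters)

    def test_rank_deficient_input_named(self):
        rng = np.random.default_rng(5)
        X = np.outer(rng.normal(size=19), rng.normal(size=600))
        X += np.outer(rng.normal(size=19), rng.normal(size=600))
        with pytest.raises(DegenerateInputError, match="rank 2"):
            run_ica(X, 3, seed=0)

    def test_infomax_agrees_with_fastica(self, noiseless_cohort):
        """Independent algorithm cross-check on the same planted mixture."""
        pytest.importorskip("mne")
        cohort, truth, _ = noiseless_cohort
        stacked = stack_for_ica(cohort, "continue")
        d_info = run_ica(stacked, 3, seed=0, algorithm="infomax")
        pairs, r = pair_by_correlation(truth.mixing, d_info.topographies)
        assert min(abs(r[i, j]) for i, j in pairs) >= 0.98


class TestArtifactExclusion:
    def test_empty_template_list_is_identity(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        out = exclude_artifact_ics(decomp, [], 0.8)
        assert out is decomp

    def test_own_topography_template_removes_ic(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        out = exclude_artifact_ics(decomp, [decomp.topographies[:, 1]], 0.9)
        assert out.n_ics == 2
        assert len(out.exclusions) == 1
        assert out.exclusions[0][2] >= 0.9

    def test_planted_eog_source_removed_genuine_kept(self, montage):
        """A fronto-polar source is excluded; genuine sources survive."""
        from erpic import CohortParams, simulate_cohort
        from erpic.synthetic import Deflection, SourceSpec

        def src(name, center, lat):
            return SourceSpec(
                name, center,
                {"go": (Deflection(+1, lat, 25, 5.0),),
                 "nogo": (Deflection(-1, lat + 40, 25, 4.0),)},
                smoothness=0.5,
            )

        specs = [src("a", "Pz", 120), src("b", "C3", 280), src("c", "O2", 430)] + [
            SourceSpec(
                "eog", "Fp1",
                {"go": (Deflection(+1, 600, 70, 8.0),),
                 "nogo": (Deflection(+1, 640, 70, 8.0),)},
                smoothness=0.6,
            )
        ]
        params = CohortParams(
            n_per_group=4, n_sources=4, noise_sd=0.0,
            subject_latency_jitter_sd=0.0, subject_amplitude_sd=0.0, seed=23,
        )
        from erpic import make_topographies

        rng = np.random.default_rng(23)
        genuine = make_topographies(montage, 3, seed=23,
                                    centers=["Pz", "C3", "O2"], smoothness=0.5)
        eog = eog_template(montage) + 0.05 * rng.normal(size=19)
        mixing = np.column_stack([genuine, eog / np.linalg.norm(eog)])
        cohort, truth = simulate_cohort(params, specs, montage, mixing=mixing)
        decomp = run_ica(stack_for_ica(cohort, "continue"), 4, seed=0)
        out = exclude_artifact_ics(decomp, [eog_template(montage)], 0.8)
        assert out.n_ics == 3
        # the removed IC is the planted EOG source, not a genuine one
        pairs, r = pair_by_correlation(truth.mixing[:, :3], out.topographies)
        assert min(abs(r[i, j]) for i, j in pairs) >= 0.98


def _decomp_from(topos, curves_by_cond, set_id="continue", montage=None):
    filters = np.linalg.pinv(topos)
    sites = np.argmax(np.abs(topos), axis=0)
    return ICADecomposition(
        topographies=topos, filters=filters,
        grand_activations=curves_by_cond, sites=sites,
        set_id=set_id, montage=montage,
    )


class TestMatching:
    def _random_decomp(self, seed, n_ics=4):
        rng = np.random.default_rng(seed)
        topos = rng.normal(size=(19, n_ics))
        topos /= np.linalg.norm(topos, axis=0)
        curves = {
            c: rng.normal(size=(n_ics, 250)) for c in SET_CONDITIONS["continue"]
        }
        return _decomp_from(topos, curves)

    def test_self_match_is_identity(self):
        d = self._random_decomp(0)
        res = match_components(d, d)
        assert [(p.index_a, p.index_b) for p in res.pairs] == [(i, i) for i in range(4)]
        assert all(np.isclose(p.r_topography, 1.0) for p in res.pairs)
        assert all(
            np.isclose(r, 1.0) for p in res.pairs for r in p.r_curves.values()
        )

    def test_orthogonal_topographies_unmatched(self):
        d = self._random_decomp(1)
        q, _ = np.linalg.qr(np.random.default_rng(2).normal(size=(19, 8)))
        a = _decomp_from(q[:, :4], d.grand_activations)
        b = _decomp_from(q[:, 4:], d.grand_activations)
        res = match_components(a, b)
        assert res.pairs == ()
        assert res.unmatched_a == (0, 1, 2, 3)

    def test_noisy_copy_recovered_and_r_equals_pearson(self):
        d = self._random_decomp(3)
        rng = np.random.default_rng(4)
        perm = [2, 0, 3, 1]
        topos_b = d.topographies[:, perm] + 0.05 * rng.normal(size=(19, 4))
        curves_b = {
            c: a[perm] + 0.1 * rng.normal(size=a.shape)
            for c, a in d.grand_activations.items()
        }
        b = _decomp_from(topos_b / np.linalg.norm(topos_b, axis=0), curves_b)
        res = match_components(d, b)
        assert {(p.index_a, p.index_b) for p in res.pairs} == {
            (perm[j], j) for j in range(4)
        }
        for p in res.pairs:
            manual = np.corrcoef(
                d.topographies[:, p.index_a], b.topographies[:, p.index_b]
            )[0, 1]
            assert np.isclose(p.r_topography, manual)

    def test_assignment_matches_brute_force(self):
        """Exhaustive search over all partial pairings, n_ics = 4."""
        d = self._random_decomp(5)
        rng = np.random.default_rng(6)
        topos_b = d.topographies + 0.6 * rng.normal(size=(19, 4))
        topos_b /= np.linalg.norm(topos_b, axis=0)
        curves_b = {
            c: a + 0.6 * rng.normal(size=a.shape)
            for c, a in d.grand_activations.items()
        }
        b = _decomp_from(topos_b, curves_b)
        crit = MatchCriteria(0.5, 0.5)
        res = match_components(d, b, crit)

        r_topo = _pearson_matrix(d.topographies, b.topographies)
        r_curv = {
            c: _pearson_matrix(d.grand_activations[c].T, b.grand_activations[c].T)
            for c in SET_CONDITIONS["continue"]
        }
        adm = r_topo > 0.5
        for c in r_curv:
            adm &= r_curv[c] > 0.5
        best_w, best_set = -1.0, None
        idx = range(4)
        for k in range(5):
            for rows in itertools.combinations(idx, k):
                for cols in itertools.permutations(idx, k):
                    if all(adm[i, j] for i, j in zip(rows, cols)):
                        w = sum(abs(r_topo[i, j]) for i, j in zip(rows, cols))
                        if w > best_w:
                            best_w = w
                            best_set = set(zip(rows, cols))
        got = {(p.index_a, p.index_b) for p in res.pairs}
        got_w = sum(abs(r_topo[i, j]) for i, j in got)
        assert np.isclose(got_w, best_w)
        assert got == best_set

    def test_symmetry(self):
        d = self._random_decomp(7)
        rng = np.random.default_rng(8)
        topos_b = d.topographies + 0.4 * rng.normal(size=(19, 4))
        topos_b /= np.linalg.norm(topos_b, axis=0)
        curves_b = {
            c: a + 0.3 * rng.normal(size=a.shape)
            for c, a in d.grand_activations.items()
        }
        b = _decomp_from(topos_b, curves_b)
        ab = match_components(d, b)
        ba = match_components(b, d)
        assert {(p.index_a, p.index_b) for p in ab.pairs} == {
            (p.index_b, p.index_a) for p in ba.pairs
        }

    def test_set_mismatch_rejected(self):
        a = self._random_decomp(9)
        b = self._random_decomp(10)
        object.__setattr__ if False else setattr(b, "set_id", "discontinue")
        with pytest.raises(InvalidInputError):
            match_components(a, b)


class TestSpatialFilters:
    def test_pulse_back_projection(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        i, site = 1, int(decomp.sites[1])
        pulse = np.zeros((19, 250))
        pulse += np.outer(decomp.topographies[:, i], np.eye(250)[50])
        curves = apply_spatial_filters(decomp, pulse, site)
        expected = decomp.topographies[site, i]
        assert np.isclose(curves[i, 50], expected, atol=1e-8)
        others = np.delete(curves, i, axis=0)
        assert np.abs(others).max() < 1e-8

    def test_zero_erp_gives_zero_curves(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        np.testing.assert_array_equal(
            apply_spatial_filters(decomp, np.zeros((19, 250))), np.zeros((3, 250))
        )

    def test_linearity(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 19, 250))
        lhs = apply_spatial_filters(decomp, 2.0 * x + 3.0 * y)
        rhs = 2.0 * apply_spatial_filters(decomp, x) + 3.0 * apply_spatial_filters(
            decomp, y
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_unknown_site_rejected(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        decomp = run_ica(stack_for_ica(cohort, "continue"), 3, seed=0)
        with pytest.raises(InvalidInputError):
            apply_spatial_filters(decomp, np.zeros((19, 250)), 99)
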