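import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import covariance_overlap_bruteforce
from sigdyn.enm import build_gnm, gnm_msf
from sigdyn.signature_dynamics import (
    ModeSpectrum,
    ensemble_gnm,
    match_modes,
    reference_spectrum,
    regime_msf,
    signature_profile,
    spectral_distance_matrix,
    spectral_overlap,
)


def _random_spectrum(rng, n_modes=4, n=10, mid="s"):
    """Random orthonormal mode set with ascending positive eigenvalues."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n_modes)))
    lam = np.sort(rng.uniform(0.5, 5.0, n_modes))
    return ModeSpectrum(mid, lam, q.T.copy())


class TestEnsembleGnm:
    def test_identical_members_identical_spectra(self, two_state):
        spec, ens, _ = two_state
        from dataclasses import replace

        coords = np.repeat(spec.template.ca_coords[None], 3, axis=0)
        clones = replace(
            ens,
            coords=coords,
            mask=np.ones((3, ens.n_positions), dtype=bool),
            occupancy=np.ones(ens.n_positions),
            member_ids=["a", "b", "c"],
            labels=["none"] * 3,
            species=[""] * 3,
        )
        spectra = ensemble_gnm(clones)
        assert len(spectra) == 3
        np.testing.assert_allclose(spectra[0].eigenvalues, spectra[1].eigenvalues)

    def test_small_perturbations_small_eigenvalue_shift(self, bundle):
        from dataclasses import replace
        from sigdyn.synthetic_data import PlantedEnsembleSpec, plant_ensemble, smooth_random_modes

        spec = PlantedEnsembleSpec(
            template=bundle,
            modes=smooth_random_modes(bundle, 2, seed=8),
            variances=np.array([0.05, 0.02]),
            noise_sd=0.02,
            n_members=5,
            seed=8,
        )
        spectra = ensemble_gnm(plant_ensemble(spec))
        base = build_gnm(bundle.ca_coords).eigenvalues
        for s in spectra:
            rel = np.abs(s.eigenvalues - base) / base
            assert rel.max() < 0.5  # continuity: tiny displacement, bounded shift

    def test_disconnected_member_dropped_with_warning(self, bundle, caplog):
        from dataclasses import replace
        from sigdyn.synthetic_data import _ensemble_from_coords

        coords = np.repeat(bundle.ca_coords[None], 3, axis=0).copy()
        coords[1] *= 10.0  # scaled copy loses all contacts at the cutoff
        ens = _ensemble_from_coords(bundle, coords, ["a", "bad", "c"], ["none"] * 3)
        import logging

        with caplog.at_level(logging.WARNING):
            spectra = ensemble_gnm(ens)
        assert [s.member_id for s in spectra] == ["a", "c"]
        with pytest.raises(ValueError):
            ensemble_gnm(ens, on_disconnected="error")


class TestMatchModes:
    def test_self_match_is_identity_with_positive_signs(self, bundle):
        model = build_gnm(bundle.ca_coords)
        spec = ModeSpectrum("x", model.eigenvalues, model.eigenvectors)
        matched = match_modes(spec, spec, k_max=20)
        np.testing.assert_array_equal(matched.matched_order, np.arange(20))
        np.testing.assert_array_equal(matched.match_signs, 1.0)

    def test_negated_eigenvectors_get_negative_signs(self, bundle):
        model = build_gnm(bundle.ca_coords)
        ref = ModeSpectrum("ref", model.eigenvalues, model.eigenvectors)
        neg = ModeSpectrum("neg", model.eigenvalues, -model.eigenvectors)
        matched = match_modes(neg, ref, k_max=10)
        np.testing.assert_array_equal(matched.matched_order, np.arange(10))
        np.testing.assert_array_equal(matched.match_signs, -1.0)

    @pytest.mark.parametrize("method", ["greedy", "optimal"])
    def test_swapped_modes_recovered(self, bundle, method):
        model = build_gnm(bundle.ca_coords)
        ref = ModeSpectrum("ref", model.eigenvalues, model.eigenvectors)
        swapped_vecs = model.eigenvectors.copy()
        swapped_vecs[[0, 1]] = swapped_vecs[[1, 0]]
        swapped = ModeSpectrum("swap", model.eigenvalues, swapped_vecs)
        matched = match_modes(swapped, ref, k_max=5, method=method)
        np.testing.assert_array_equal(matched.matched_order, [1, 0, 2, 3, 4])

    def test_matching_beats_random_permutation_on_noisy_ensemble(self, two_state):
        _, ens, matched = two_state
        rng = np.random.default_rng(0)
        k = 20
        better = 0
        for s in matched[:10]:
            ref_vecs = matched[0].eigenvectors[:k]
            got = np.abs(
                np.einsum("kn,kn->k", s.eigenvectors[s.matched_order[:k]], ref_vecs)
            ).mean()
            perm = rng.permutation(s.n_modes)[:k]
            rand = np.abs(
                np.einsum("kn,kn->k", s.eigenvectors[perm], ref_vecs)
            ).mean()
            better += got >= rand
        assert better >= 9


class TestSpectralOverlap:
    def test_self_overlap_is_one(self, bundle):
        model = build_gnm(bundle.ca_coords)
        spec = ModeSpectrum("x", model.eigenvalues, model.eigenvectors)
        assert spectral_overlap(spec, spec, 1, 20) == pytest.approx(1.0)

    def test_orthogonal_equal_variance_single_modes_give_zero(self):
        a = ModeSpectrum("a", np.array([2.0]), np.array([[1.0, 0, 0, 0]]))
        b = ModeSpectrum("b", np.array([2.0]), np.array([[0.0, 1.0, 0, 0]]))
        assert spectral_overlap(a, b, 1, 1) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(12)
        a = _random_spectrum(rng, 4, 10, "a")
        b = _random_spectrum(rng, 4, 10, "b")
        oracle = covariance_overlap_bruteforce(
            a.eigenvalues, a.eigenvectors, b.eigenvalues, b.eigenvectors
        )
        assert spectral_overlap(a, b, 1, 4) == pytest.approx(oracle, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_sign_flips_and_mode_reordering(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_spectrum(rng, 5, 12, "a")
        b = _random_spectrum(rng, 5, 12, "b")
        base = spectral_overlap(a, b, 1, 5)
        perm = rng.permutation(5)
        signs = rng.choice([-1.0, 1.0], 5)
        shuffled = ModeSpectrum(
            "b2", b.eigenvalues[perm], signs[:, None] * b.eigenvectors[perm]
        )
        assert spectral_overlap(a, shuffled, 1, 5) == pytest.approx(base, abs=1e-10)

    def test_invalid_window_rejected(self):
        rng = np.random.default_rng(0)
        a = _random_spectrum(rng)
        with pytest.raises(ValueError, match="window"):
            spectral_overlap(a, a, 3, 2)


class TestSpectralDistanceMatrix:
    def test_metric_axioms_on_synthetic_ensemble(self, two_state):
        _, _, matched = two_state
        mat = spectral_distance_matrix(matched[:8], 1, 20)
        v = mat.values
        np.testing.assert_allclose(np.diag(v), 0.0, atol=1e-6)
        np.testing.assert_allclose(v, v.T)
        assert (v >= 0).all() and (v <= np.pi / 2 + 1e-9).all()

    def test_entries_are_arccos_of_overlap(self, two_state):
        _, _, matched = two_state
        mat = spectral_distance_matrix(matched[:4], 1, 20)
        expected = np.arccos(spectral_overlap(matched[1], matched[3], 1, 20))
        assert mat.values[1, 3] == pytest.approx(expected, abs=1e-12)

    def test_orthogonal_single_mode_pair_at_right_angle(self):
        a = ModeSpectrum("a", np.array([1.0]), np.array([[1.0, 0, 0]]))
        b = ModeSpectrum("b", np.array([1.0]), np.array([[0.0, 1.0, 0]]))
        mat = spectral_distance_matrix([a, b], 1, 1)
        assert mat.values[0, 1] == pytest.approx(np.pi / 2)


class TestSignatureProfile:
    def test_identical_members_zero_variance(self, bundle):
        model = build_gnm(bundle.ca_coords)
        spec = ModeSpectrum("x", model.eigenvalues, model.eigenvectors)
        matched = [match_modes(spec, spec, k_max=60) for _ in range(3)]
        prof = signature_profile(matched, "global")
        np.testing.assert_allclose(prof.variance_msf, 0.0, atol=1e-15)
        single = regime_msf(matched[0], "global")
        np.testing.assert_allclose(prof.mean_msf, single)
        np.testing.assert_allclose(prof.min_msf, prof.max_msf)

    def test_hand_computed_mean_min_max_on_toy_chain(self):
        # P3 chain, both nonzero modes: hand eigendecomposition gives
        # MSF = (5/9, 2/9, 5/9) at gamma 1 and half that at gamma 2; the
        # "fastest" regime covers both modes, so the raw-profile envelope
        # follows by direct arithmetic
        chain = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        m1 = build_gnm(chain, cutoff=5.0, gamma=1.0)
        m2 = build_gnm(chain, cutoff=5.0, gamma=2.0)
        specs = [
            ModeSpectrum("a", m1.eigenvalues, m1.eigenvectors),
            ModeSpectrum("b", m2.eigenvalues, m2.eigenvectors),
        ]
        prof = signature_profile(specs, "fastest", normalize=False)
        hand = np.array([5 / 9, 2 / 9, 5 / 9])
        np.testing.assert_allclose(prof.max_msf, hand, atol=1e-12)
        np.testing.assert_allclose(prof.min_msf, hand / 2, atol=1e-12)
        np.testing.assert_allclose(prof.mean_msf, 0.75 * hand, atol=1e-12)
        np.testing.assert_allclose(prof.variance_msf, (hand / 4) ** 2, atol=1e-12)

    def test_two_state_global_variance_peaks_in_planted_segment(self, two_state):
        spec, _, matched = two_state
        inactive = [s for s in matched if s.member_id.startswith("inactive")]
        prof = signature_profile(inactive, "global")
        start, stop = spec.segment
        assert start <= int(np.argmax(prof.variance_msf)) < stop

    def test_regimes_cover_expected_mode_counts(self, two_state):
        _, _, matched = two_state
        for regime, n_modes in [("global", 3), ("lf", 17), ("ltif", 40)]:
            prof = signature_profile(matched, regime)
            prof.validate()
            assert prof.n_members == len(matched)
        fast = signature_profile(matched, "fastest")
        assert fast.mean_msf.sum() == pytest.approx(1.0)

    def test_member_without_enough_modes_skipped(self):
        rng = np.random.default_rng(3)
        small = _random_spectrum(rng, 2, 30, "small")
        small.matched_order = np.arange(2)
        small.match_signs = np.ones(2)
        with pytest.raises(ValueError, match="no member covers"):
            signature_profile([small], "global")


class TestReferenceSpectrum:
    def test_restricts_to_ensemble_positions(self, two_state):
        spec, ens, _ = two_state
        ref = reference_spectrum(spec.template, ens)
        assert ref.n_positions == ens.n_positions
        direct = build_gnm(spec.template.ca_coords)
        np.testing.assert_allclose(ref.eigenvalues, direct.eigenvalues)
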