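import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import quaternion_superposition_rmsd, random_rotation
from sigdyn.ensemble_align import (
    build_mapped_ensemble,
    impute_missing,
    iterative_superpose,
    kabsch_superpose,
    map_to_reference,
)
from sigdyn.structure_io import StructureRecord


def _record(mid, seq, coords=None, **kw):
    n = len(seq)
    if coords is None:
        coords = np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])
        coords = coords + np.array([0.0, 0.1, 0.0]) * (np.arange(n)[:, None] % 2)
    return StructureRecord(mid, "A", [str(i + 1) for i in range(n)], seq, coords, **kw)


class TestMapToReference:
    def test_self_alignment_is_identity(self):
        rec = _record("a", "ACDEFGHIKL")
        amap = map_to_reference(rec, rec)
        np.testing.assert_array_equal(amap.pairs[:, 0], amap.pairs[:, 1])
        assert amap.identity_fraction == 1.0

    def test_single_deletion_skips_reference_position(self):
        # optimal global alignment of ACEFG onto ACDEFG deletes the D column:
        # member 0,1,2,3,4 pair with reference 0,1,3,4,5
        ref = _record("ref", "ACDEFG")
        mem = _record("mem", "ACEFG")
        amap = map_to_reference(mem, ref)
        np.testing.assert_array_equal(amap.pairs[:, 0], [0, 1, 2, 3, 4])
        np.testing.assert_array_equal(amap.pairs[:, 1], [0, 1, 3, 4, 5])
        assert amap.identity_fraction == 1.0

    def test_low_identity_flagged_unmappable(self):
        ref = _record("ref", "ACDEFGHIKLMNPQRSTVWY")
        mem = _record("mem", "XXXXXXXXXXXXXXXXXXXX")
        assert not map_to_reference(mem, ref).mappable


class TestKabsch:
    def test_identical_sets_give_identity_and_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)
        assert rmsd < 1e-12

    def test_recovers_inverse_of_applied_rotation(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((10, 3)) * 4
        angle = np.pi / 2
        applied = np.array(
            [[np.cos(angle), -np.sin(angle), 0], [np.sin(angle), np.cos(angle), 0], [0, 0, 1]]
        )
        rot, _, rmsd = kabsch_superpose(pts @ applied.T, pts)
        np.testing.assert_allclose(rot, applied.T, atol=1e-9)
        assert rmsd < 1e-9

    def test_matches_quaternion_oracle_on_fixed_sets(self):
        a = np.array([[0.0, 0, 0], [3.8, 0, 0], [5.0, 2.5, 0], [6.0, 2.0, 3.0]])
        b = np.array([[0.2, 0, 0], [3.5, 0.4, 0], [5.5, 2.0, 0.3], [5.8, 2.4, 2.6]])
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            quaternion_superposition_rmsd(a, b), abs=1e-9
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_pre_rotation_of_either_set(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((7, 3)) * 3
        b = rng.standard_normal((7, 3)) * 3
        base = kabsch_superpose(a, b)[2]
        r = random_rotation(rng)
        assert kabsch_superpose(a @ r.T, b)[2] == pytest.approx(base, abs=1e-9)
        assert kabsch_superpose(a, b @ r.T + 2.0)[2] == pytest.approx(base, abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_weights_validated(self):
        pts = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(ValueError, match="weights"):
            kabsch_superpose(pts, pts, weights=np.zeros(5))


class TestBuildMappedEnsemble:
    def test_identical_copies_full_occupancy(self, bundle):
        recs = [
            _record(f"m{i}", bundle.residue_codes, bundle.ca_coords.copy())
            for i in range(3)
        ]
        ens = build_mapped_ensemble(recs, bundle, occupancy_threshold=0.9)
        assert ens.n_members == 3
        assert ens.n_positions == len(bundle)
        np.testing.assert_allclose(ens.occupancy, 1.0)

    @pytest.mark.parametrize(
        "threshold,expect_dropped", [(0.9, True), (0.75, False)]
    )
    def test_occupancy_threshold_controls_position_drop(self, bundle, threshold, expect_dropped):
        recs = []
        for i in range(10):
            if i < 8:
                recs.append(_record(f"m{i}", bundle.residue_codes, bundle.ca_coords.copy()))
            else:
                # drop one residue -> that position resolved in 8/10 members
                keep = np.ones(len(bundle), dtype=bool)
                keep[100] = False
                recs.append(
                    StructureRecord(
                        f"m{i}", "A",
                        [bundle.residue_ids[j] for j in np.flatnonzero(keep)],
                        "".join(bundle.residue_codes[j] for j in np.flatnonzero(keep)),
                        bundle.ca_coords[keep],
                    )
                )
        ens = build_mapped_ensemble(recs, bundle, occupancy_threshold=threshold)
        if expect_dropped:
            assert ens.n_positions == len(bundle) - 1
        else:
            assert ens.n_positions == len(bundle)
            assert ens.occupancy[100] == pytest.approx(0.8)

    def test_too_few_members_rejected(self, bundle):
        with pytest.raises(ValueError, match="at least 2"):
            build_mapped_ensemble(
                [_record("only", bundle.residue_codes, bundle.ca_coords)], bundle
            )


class TestIterativeSuperpose:
    def _rigidly_scattered(self, bundle, m=5, seed=3):
        rng = np.random.default_rng(seed)
        recs = [_record(bundle.member_id, bundle.residue_codes, bundle.ca_coords.copy())]
        for i in range(m - 1):
            r = random_rotation(rng)
            t = rng.standard_normal(3) * 20
            recs.append(_record(f"m{i}", bundle.residue_codes, bundle.ca_coords @ r.T + t))
        return build_mapped_ensemble(recs, bundle)

    def test_rigid_motions_removed_exactly(self, bundle):
        ens = iterative_superpose(self._rigidly_scattered(bundle))
        assert ens.superposed
        spread = ens.coords - ens.coords.mean(axis=0)
        assert np.abs(spread).max() < 1e-6

    def test_single_pass_equals_direct_kabsch(self, bundle):
        ens = self._rigidly_scattered(bundle, m=2)
        out = iterative_superpose(ens, tol=np.inf, max_iter=1)
        ref_idx = out.member_index(bundle.member_id)
        other = 1 - ref_idx
        rot, trans, _ = kabsch_superpose(
            ens.coords[other], ens.coords[ref_idx]
        )
        direct = ens.coords[other] @ rot.T + trans
        # after one mean pass the member still coincides with direct Kabsch
        np.testing.assert_allclose(out.coords[other], direct, atol=1e-6)

    def test_superposed_rmsd_not_larger_than_unsuperposed(self, two_state):
        _, ens, _ = two_state
        rng = np.random.default_rng(0)
        shaken = ens.coords + 0  # copy
        for k in range(ens.n_members):
            r = random_rotation(rng)
            shaken[k] = ens.coords[k] @ r.T + rng.standard_normal(3)
        from dataclasses import replace

        messy = replace(ens, coords=shaken, superposed=False)
        tidy = iterative_superpose(messy)
        for a, b in [(0, 5), (3, 30), (12, 39)]:
            before = np.sqrt(((messy.coords[a] - messy.coords[b]) ** 2).sum(axis=1).mean())
            after = np.sqrt(((tidy.coords[a] - tidy.coords[b]) ** 2).sum(axis=1).mean())
            assert after <= before + 1e-9


class TestImpute:
    def test_mean_fill_and_flags(self, bundle):
        keep = np.ones(len(bundle), dtype=bool)
        keep[50] = False
        partial = StructureRecord(
            "part", "A",
            [bundle.residue_ids[j] for j in np.flatnonzero(keep)],
            "".join(bundle.residue_codes[j] for j in np.flatnonzero(keep)),
            bundle.ca_coords[keep],
        )
        full = [_record(f"m{i}", bundle.residue_codes, bundle.ca_coords.copy()) for i in range(8)]
        ens = build_mapped_ensemble(full + [partial], bundle, occupancy_threshold=0.8)
        ens = iterative_superpose(ens)
        filled = impute_missing(ens)
        assert filled.imputed
        assert np.isfinite(filled.coords).all()
        k = filled.member_index("part")
        j = filled.position_ids.index(bundle.residue_ids[50])
        np.testing.assert_allclose(
            filled.coords[k, j],
            filled.coords[[i for i in range(9) if i != k], j].mean(axis=0),
            atol=1e-9,
        )
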