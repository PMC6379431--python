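"""Kabsch superposition, iterative core selection, displacement profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claudinkit import (
    RigidTransform,
    StructureModel,
    core_superpose,
    displacement_profile,
    kabsch,
)
from claudinkit.errors import (
    EmptySelectionError,
    InsufficientPointsError,
    NonConvergenceError,
    ValidationError,
)
from tests.conftest import random_rotation


def brute_force_rmsd(P, Q, n_grid=40):
    """Minimum RMSD over a dense rotation grid (independent oracle)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    A, B = P - pc, Q - qc
    best = np.inf
    angles = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    betas = np.linspace(0.0, np.pi, n_grid // 2 + 1)
    for a in angles:
        Ra = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        for b in betas:
            Rb = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
            for g in angles:
                Rg = np.array([[np.cos(g), -np.sin(g), 0], [np.sin(g), np.cos(g), 0], [0, 0, 1]])
                R = Ra @ Rb @ Rg
                rmsd = np.sqrt(np.mean(np.sum((B @ R.T - A) ** 2, axis=1)))
                if rmsd < best:
                    best = rmsd
    return best


class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(size=(8, 3))
        T, rmsd = kabsch(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_transform(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(12, 3)) * 5.0
        R0 = random_rotation(rng)
        t0 = rng.normal(size=3) * 10.0
        Q = (P - t0) @ R0  # so that R0.T @ Q + t0 = P
        T, rmsd = kabsch(P, Q)
        assert rmsd <= 1e-9
        assert np.allclose(T.apply(Q), P, atol=1e-9)

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(99)
        P = rng.normal(size=(5, 3)) * 3.0
        Q = rng.normal(size=(5, 3)) * 3.0
        _, rmsd = kabsch(P, Q)
        grid_best = brute_force_rmsd(P, Q)
        # Kabsch is the true minimum; the grid can only overshoot, and by no
        # more than its resolution allows
        assert rmsd <= grid_best + 1e-12
        assert grid_best - rmsd < 0.5

    def test_rotation_always_proper(self, rng):
        for _ in range(10):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            T, _ = kabsch(P, Q)
            assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_suppressed_for_mirrored_input(self, rng):
        P = rng.normal(size=(10, 3))
        Q = P * np.array([-1.0, 1.0, 1.0])  # mirror image
        T, rmsd = kabsch(P, Q)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.0

    def test_collinear_degenerate_rmsd_exact(self):
        P = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        Q = np.outer(np.arange(5.0), [0.0, 1.0, 0.0])
        T, rmsd = kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_improper_rotation_rejected_by_type(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))


class TestCoreSuperpose:
    def test_identical_models(self, helix30):
        result = core_superpose(helix30, helix30, ("A", "A"), range(1, 31))
        assert result.core_residues == set(range(1, 31))
        assert result.core_rmsd == pytest.approx(0.0, abs=1e-12)
        assert result.iterations == 1
        assert result.rejected_residues == set()

    def test_domain_pair_core_converges_to_true_core(self, domain_pair_5A):
        pair = domain_pair_5A
        result = core_superpose(
            pair.model_a, pair.model_b, ("A", "A"),
            pair.core_residues | pair.mobile_residues,
        )
        assert result.core_residues <= pair.core_residues
        assert result.core_rmsd <= 1e-9
        assert pair.mobile_residues <= result.rejected_residues

    def test_large_threshold_accepts_everything(self, domain_pair_5A):
        pair = domain_pair_5A
        result = core_superpose(
            pair.model_a, pair.model_b, ("A", "A"),
            pair.core_residues | pair.mobile_residues,
            reject_threshold=100.0,
        )
        assert result.iterations == 1
        assert result.rejected_residues == set()

    def test_idempotent_on_converged_core(self, domain_pair_5A):
        pair = domain_pair_5A
        first = core_superpose(
            pair.model_a, pair.model_b, ("A", "A"),
            pair.core_residues | pair.mobile_residues,
        )
        second = core_superpose(
            pair.model_a, pair.model_b, ("A", "A"), first.core_residues
        )
        assert np.allclose(first.transform.rotation, second.transform.rotation, atol=1e-9)
        assert np.allclose(
            first.transform.translation, second.transform.translation, atol=1e-9
        )

    def test_scrambled_model_fails_with_trace(self, helix30, rng):
        scrambled_coords = rng.permutation(
            np.array([a.position for a in helix30.atoms])
        ) + rng.normal(scale=8.0, size=(30, 3))
        atoms = [
            a.with_b_factor(a.b_factor) for a in helix30.atoms
        ]
        moved = [
            type(a)(a.chain_id, a.residue_number, a.insertion_code, a.residue_name,
                    a.atom_name, a.altloc, a.occupancy, a.b_factor, c, a.element)
            for a, c in zip(atoms, scrambled_coords)
        ]
        broken = StructureModel("scrambled", moved)
        with pytest.raises(NonConvergenceError) as exc:
            core_superpose(helix30, broken, ("A", "A"), range(1, 31), reject_threshold=0.5)
        assert len(exc.value.trace) >= 1

    def test_noisy_pair_rmsd_band_and_reproducibility(self, helix30):
        from claudinkit import HelixSpec, make_domain_pair, make_ideal_helix

        mobile = make_ideal_helix(
            HelixSpec(n_residues=15, origin=(12.0, 0.0, 0.0)), chain="A", start_residue=41
        )
        runs = []
        for _ in range(2):
            pair = make_domain_pair(
                helix30, mobile, translation=(5.0, 0.0, 0.0), noise_sd=0.2, seed=11
            )
            result = core_superpose(
                pair.model_a, pair.model_b, ("A", "A"),
                pair.core_residues | pair.mobile_residues,
            )
            runs.append(result.core_rmsd)
        assert runs[0] == runs[1]  # bit-identical across runs at the same seed
        assert 0.1 <= runs[0] <= 0.4


class TestDisplacementProfile:
    def test_identical_models_all_zero(self, helix30):
        result = core_superpose(helix30, helix30, ("A", "A"), range(1, 31))
        prof = displacement_profile(helix30, helix30, result, range(1, 31))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in prof.displacements.values())

    def test_translation_plateau(self, domain_pair_5A):
        pair = domain_pair_5A
        result = core_superpose(
            pair.model_a, pair.model_b, ("A", "A"),
            pair.core_residues | pair.mobile_residues,
        )
        prof = displacement_profile(
            pair.model_a, pair.model_b, result, pair.mobile_residues
        )
        assert all(
            v == pytest.approx(5.0, abs=0.01) for v in prof.displacements.values()
        )
        assert prof.max_shift[1] == pytest.approx(5.0, abs=0.01)

    def test_rigid_copy_displacement_below_tolerance(self, helix30, rng):
        R = random_rotation(rng)
        t = rng.normal(scale=15.0, size=3)
        moved = helix30.transformed(R, t)
        result = core_superpose(helix30, moved, ("A", "A"), range(1, 31))
        prof = displacement_profile(helix30, moved, result, range(1, 31))
        assert max(prof.displacements.values()) <= 1e-6

    def test_truth_matches_profile(self, domain_pair_5A):
        pair = domain_pair_5A
        result = core_superpose(
            pair.model_a, pair.model_b, ("A", "A"), pair.core_residues
        )
        prof = displacement_profile(
            pair.model_a, pair.model_b, result, pair.mobile_residues
        )
        for res, truth in pair.true_displacement.items():
            assert prof.displacements[res] == pytest.approx(truth, abs=1e-6)

    def test_empty_overlap_raises(self, helix30):
        result = core_superpose(helix30, helix30, ("A", "A"), range(1, 31))
        with pytest.raises(EmptySelectionError):
            displacement_profile(helix30, helix30, result, range(200, 210))

    def test_max_over_subset(self, domain_pair_5A):
        pair = domain_pair_5A
        result = core_superpose(pair.model_a, pair.model_b, ("A", "A"), pair.core_residues)
        prof = displacement_profile(
            pair.model_a, pair.model_b, result,
            pair.core_residues | pair.mobile_residues,
        )
        _, core_max = prof.max_over(pair.core_residues)
        _, mobile_max = prof.max_over(pair.mobile_residues)
        assert core_max < 0.01 < mobile_max


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_kabsch_rotation_proper_property(seed):
    """The fitted rotation is always proper, whatever the point clouds."""
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(7, 3)) * 4.0
    Q = rng.normal(size=(7, 3)) * 4.0
    T, rmsd = kabsch(P, Q)
    assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
    assert rmsd >= 0.0
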