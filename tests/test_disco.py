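"""DISCO rotation: targets, majorization, deviations, target selection."""

import numpy as np
import pytest

from discosca.blocks import BlockMatrix, LinkedBlocks
from discosca.disco import (DiscoResult, build_target, disco_rotate,
                            enumerate_targets, select_target, target_deviation)
from discosca.metrics import recovery_report
from discosca.sca import SCAModel, sca
from tests.conftest import make_pair


class TestTargets:
    def test_mask_layout_one_specific_each_plus_common(self):
        # 2 blocks of 3 and 2 rows; statuses ({0}, {1}, {0,1})
        target = build_target([{0}, {1}, {0, 1}], [0, 3, 5])
        expected = np.zeros((5, 3))
        expected[3:, 0] = 1  # block-2 rows of the block-1-specific component
        expected[:3, 1] = 1  # block-1 rows of the block-2-specific component
        np.testing.assert_array_equal(target.mask, expected)
        assert target.label() == "d1=1,d2=1,common=1"

    def test_all_common_mask_is_zero(self):
        target = build_target([{0, 1}] * 4, [0, 3, 5])
        assert not target.mask.any()

    def test_empty_status_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_target([{0}, set()], [0, 3, 5])

    @pytest.mark.parametrize("R,expected", [(1, 3), (5, 21), (6, 28)])
    def test_enumeration_count(self, R, expected):
        assert len(enumerate_targets(R, 2)) == expected

    def test_enumeration_closed_form_vs_brute_force(self):
        for R in range(1, 11):
            brute = {(d1, d2) for d1 in range(R + 1) for d2 in range(R + 1)
                     if d1 + d2 <= R}
            targets = enumerate_targets(R, 2)
            counts = {tuple(sum(1 for st in t if st == frozenset({k}))
                            for k in range(2)) for t in targets}
            assert counts == brute
            assert len(targets) == (R + 1) * (R + 2) // 2 == len(brute)


def _model_from_factors(T1, T2, P, singvals=None):
    T = np.vstack([T1, T2])
    m = SCAModel(block_factor=T, shared_factor=P,
                 singvals=singvals if singvals is not None
                 else np.linalg.norm(T, axis=0),
                 R=T.shape[1], block_row_offsets=[0, len(T1), len(T)],
                 block_ss=[float((T1**2).sum()), float((T2**2).sum())],
                 total_ss=float((T**2).sum()))
    m.vaf = m.vaf_table()
    return m


class TestRotation:
    def test_already_matching_model_has_zero_objective(self, rng):
        # block factor already satisfies a (d1=1, d2=1) pattern
        T1 = np.array([[2.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        T2 = np.array([[0.0, 1.5], [0.0, -0.5]])
        P, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        model = _model_from_factors(T1, T2, P)
        target = build_target([{0}, {1}], model.block_row_offsets)
        res = disco_rotate(model, target, seed=1)
        assert res.objective < 1e-20
        np.testing.assert_allclose(np.abs(res.B), np.eye(2), atol=1e-8)

    def test_rotation_matrix_orthogonal_and_vaf_invariant(self, random_blocks):
        model = sca(random_blocks, 3)
        target = build_target([{0}, {1}, {0, 1}], random_blocks)
        res = disco_rotate(model, target, seed=2)
        np.testing.assert_allclose(res.B.T @ res.B, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.rotated.vaf.block_totals,
                                   model.vaf.block_totals, atol=1e-10)

    def test_objective_trajectory_nonincreasing(self, random_blocks):
        model = sca(random_blocks, 3)
        target = build_target([{0}, {0}, {1}], random_blocks)
        res = disco_rotate(model, target, seed=3)
        traj = np.asarray(res.objective_trajectory)
        assert (np.diff(traj) <= 1e-12 * max(1.0, traj[0])).all()

    def test_givens_grid_search_oracle_at_rank_2(self, rng):
        """For R=2 every orthogonal B is a rotation (up to column signs that
        leave the objective unchanged), so a dense angle grid is an
        independent optimum oracle."""
        for trial in range(3):
            T1 = rng.standard_normal((5, 2))
            T2 = rng.standard_normal((4, 2))
            P, _ = np.linalg.qr(rng.standard_normal((6, 2)))
            model = _model_from_factors(T1, T2, P)
            target = build_target([{0}, {1}], model.block_row_offsets)
            res = disco_rotate(model, target, seed=trial)
            T, W = model.block_factor, target.mask
            thetas = np.linspace(0, 2 * np.pi, 100000, endpoint=False)
            cos, sin = np.cos(thetas), np.sin(thetas)
            Bs = np.empty((thetas.size, 2, 2))
            Bs[:, 0, 0], Bs[:, 0, 1] = cos, -sin
            Bs[:, 1, 0], Bs[:, 1, 1] = sin, cos
            obj = ((W[None] * np.einsum("ij,njk->nik", T, Bs)) ** 2).sum((1, 2))
            assert res.objective <= obj.min() + 1e-6

    def test_noise_free_known_structure_recovered(self, noise_free_221):
        pair = noise_free_221
        model = sca(pair.blocks, 5)
        target = build_target(pair.truth["statuses"], pair.blocks)
        res = disco_rotate(model, target, seed=0)
        assert res.objective < 1e-12
        rot = res.rotated
        rep = recovery_report(
            {"V": pair.truth["V"], "U1": pair.truth["U1"], "U2": pair.truth["U2"]},
            {"V": rot.shared_factor, "U1": rot.block_rows(0), "U2": rot.block_rows(1)},
            exclude_zero_signal={"U1": pair.spec.imposed_vaf[:, 0] > 0,
                                 "U2": pair.spec.imposed_vaf[:, 1] > 0})
        for phi in rep.values():
            assert phi > 1 - 1e-6

    def test_dimension_mismatch_rejected(self, random_blocks):
        model = sca(random_blocks, 3)
        target = build_target([{0}, {1}], [0, 6, 11])  # R=2 target, R=3 model
        with pytest.raises(ValueError, match="mask shape"):
            disco_rotate(model, target)


class TestDeviation:
    def test_exactly_realized_target_deviates_zero(self, noise_free_221):
        model = sca(noise_free_221.blocks, 5)
        target = build_target(noise_free_221.truth["statuses"],
                              noise_free_221.blocks)
        res = disco_rotate(model, target, seed=0)
        assert res.deviations.max_deviation < 1e-8

    def test_crafted_leakage_and_imbalance(self):
        """Distinctive component leaking 0.07 into the absent block and a
        common component with block VAFs 0.30/0.20 -> deviations (0.07, 0.10)."""
        T1 = np.array([[np.sqrt(0.50), np.sqrt(0.30)], [0.0, 0.0]])
        T2 = np.array([[np.sqrt(0.07), 0.0], [0.0, np.sqrt(0.20)]])
        model = _model_from_factors(T1, T2, np.eye(2))
        model.block_ss = [1.0, 1.0]  # proportions relative to full block SS
        target = build_target([{0}, {0, 1}], model.block_row_offsets)
        res = DiscoResult(B=np.eye(2), rotated=model, target=target,
                          objective_trajectory=[0.0], converged=True,
                          n_restarts_used=0)
        dev = target_deviation(res)
        np.testing.assert_allclose(dev.per_component, [0.07, 0.10], atol=1e-12)
        assert dev.max_deviation == pytest.approx(0.10)


class TestSelectTarget:
    def test_noise_free_221_structure_selected(self, noise_free_221):
        model = sca(noise_free_221.blocks, 5)
        best, table = select_target(model, seed=0)
        assert best.target.counts() == (2, 2, 1)
        assert best.deviations.max_deviation < 1e-8
        assert len(table) == 21

    def test_deviation_table_covers_all_targets(self, random_blocks):
        model = sca(random_blocks, 2)
        best, table = select_target(model, n_restarts=3, seed=0)
        assert len(table) == 6
        assert best.deviations.max_deviation == pytest.approx(
            min(row["max_deviation"] for row in table))


def _status_string(statuses):
    return ["c" if len(st) == 2 else ("d1" if 0 in st else "d2")
            for st in statuses]


@pytest.mark.parametrize("R", [1, 2, 3, 4])
def test_exact_recovery_for_every_generatable_target(R):
    """Noise-free data generated under each enumerated target must lead
    select_target back to that target with perfect recovery.

    Targets leaving one block without any signal cannot be generated at
    all; targets mixing commons with distinctives in only one block cannot
    be realized with zero deviation (per-block VAF proportions each sum to
    one), but the generating target must still win.
    """
    for statuses in enumerate_targets(R, 2):
        kinds = _status_string(statuses)
        present1 = any(s in ("d1", "c") for s in kinds)
        present2 = any(s in ("d2", "c") for s in kinds)
        if not (present1 and present2):
            continue  # a block with zero signal is not a data set
        pair = make_pair(kinds, dims=(12, 10, 8), seed=R * 100 + len(kinds))
        model = sca(pair.blocks, R)
        n_c = sum(1 for s in kinds if s == "c")
        n_d1 = sum(1 for s in kinds if s == "d1")
        n_d2 = sum(1 for s in kinds if s == "d2")
        balanced = (n_c == 0) or (n_d1 > 0 and n_d2 > 0) or (n_d1 == n_d2 == 0)
        if balanced:
            best, _ = select_target(model, n_restarts=4, seed=0)
            assert best.target.counts() == (n_d1, n_d2, n_c), kinds
            assert best.deviations.max_deviation < 1e-8, kinds
            rotated = best.rotated
        else:
            # zero deviation unrealizable and selection among ties ambiguous:
            # rotation to the generating target must still recover the truth
            res = disco_rotate(model, build_target(pair.truth["statuses"],
                                                   pair.blocks), seed=0)
            rotated = res.rotated
        rep = recovery_report(
            {"V": pair.truth["V"]}, {"V": rotated.shared_factor})
        assert rep["V"] > 1 - 1e-6, kinds
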