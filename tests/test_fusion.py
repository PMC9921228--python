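"""Group reduction, balanced concatenation, joint fit, back-reconstruction."""

import warnings

import numpy as np
import pytest

import jcmica as j
from jcmica.fusion import (
    back_reconstruct,
    concatenate_modalities,
    fit_joint_cmica,
    group_average_maps,
    group_reduce,
    load_model,
    save_model,
)
from jcmica.ica import joint_whiten, run_ica
from jcmica.subject import (
    explicit_fc_matrix,
    reduce_subject_fc,
    reduce_subject_sc,
    temporal_normalize,
)
from scipy.linalg import subspace_angles


def _fc_subject(rng, t=40, v=30, r=5, subject_id=""):
    x = temporal_normalize(rng.standard_normal((t, v)))
    return reduce_subject_fc(x, r, subject_id=subject_id)


class TestGroupReduce:
    def test_single_subject_spans_subject_basis(self, rng):
        red = _fc_subject(rng)
        group = group_reduce([red], m=5)
        angles = subspace_angles(group.group_basis, red.basis_u)
        assert angles.max() < 1e-8

    def test_two_identical_subjects_double_eigenvalues(self, rng):
        red = _fc_subject(rng)
        single = group_reduce([red], m=5)
        double = group_reduce([red, red], m=5)
        np.testing.assert_allclose(
            double.group_sing**2, 2.0 * single.group_sing**2, rtol=1e-10
        )

    def test_mixed_modalities_rejected(self, rng):
        fc = _fc_subject(rng)
        from jcmica.volume_io import BrainMask, StructuralConnectivity

        mask = BrainMask(np.ones((30, 1, 1), dtype=bool))
        maskb = BrainMask(np.ones((20, 1, 1), dtype=bool))
        sc = reduce_subject_sc(
            StructuralConnectivity(rng.poisson(2.0, (30, 20)).astype(float), mask, maskb), 5
        )
        with pytest.raises(ValueError, match="mixed modalities"):
            group_reduce([fc, sc], m=4)

    def test_order_too_large_rejected(self, rng):
        red = _fc_subject(rng, r=3)
        with pytest.raises(ValueError, match="out of range"):
            group_reduce([red], m=4)

    def test_partitions_reassemble_cobasis(self, rng):
        subs = [_fc_subject(rng) for _ in range(3)]
        group = group_reduce(subs, m=15)  # full rank: n_subjects * r
        assert len(group.subject_partitions) == 3
        assert all(p.shape == (5, 15) for p in group.subject_partitions)
        # at full order the factors reproduce the stacked subject bases
        stacked = np.vstack([s.basis_u.T for s in subs])
        co = np.vstack(group.subject_partitions)
        recon = co @ np.diag(group.group_sing) @ group.group_basis.T
        assert np.linalg.norm(stacked - recon) / np.linalg.norm(stacked) < 1e-10


class TestConcatenateModalities:
    def _pair(self, rng, m=5):
        fc = group_reduce([_fc_subject(rng, v=50) for _ in range(2)], m=m)
        from jcmica.volume_io import BrainMask, StructuralConnectivity

        mask = BrainMask(np.ones((50, 1, 1), dtype=bool))
        maskb = BrainMask(np.ones((40, 1, 1), dtype=bool))
        sc_subs = [
            reduce_subject_sc(
                StructuralConnectivity(rng.poisson(2.0, (50, 40)).astype(float), mask, maskb), 5
            )
            for _ in range(2)
        ]
        sc = group_reduce(sc_subs, m=m)
        return fc, sc

    def test_block_structure(self, rng):
        fc, sc = self._pair(rng)
        joint, order = concatenate_modalities(fc, sc)
        assert joint.shape == (10, 50)
        assert order.block("FC") == slice(0, 5)
        assert order.block("SC") == slice(5, 10)

    def test_rows_have_unit_power_after_balancing(self, rng):
        fc, sc = self._pair(rng)
        joint, order = concatenate_modalities(fc, sc)
        power = (joint**2).sum(axis=1) / (joint.shape[1] - 1)
        np.testing.assert_allclose(power, 1.0, atol=1e-10)

    def test_degenerate_modality_rejected(self, rng):
        fc, sc = self._pair(rng)
        import dataclasses

        dead = dataclasses.replace(sc, group_sing=np.zeros_like(sc.group_sing))
        with pytest.raises(ValueError, match="cannot whiten"):
            concatenate_modalities(fc, dead)

    def test_mask_mismatch_rejected(self, rng):
        fc, _ = self._pair(rng)
        _, sc = self._pair(rng)
        import dataclasses

        bad = dataclasses.replace(sc, group_basis=sc.group_basis[:-1])
        with pytest.raises(ValueError, match="voxel count"):
            concatenate_modalities(fc, bad)


class TestFitJointCmica:
    def test_single_subject_rejected(self, truth):
        fmri, sc = j.simulate_cohort(truth, 1, t_len=60, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            fit_joint_cmica(fmri, sc, subject_r=4, m_per_modality=4)

    def test_unpaired_lists_rejected(self, truth):
        fmri, sc = j.simulate_cohort(truth, 3, t_len=60, seed=0)
        with pytest.raises(ValueError, match="paired"):
            fit_joint_cmica(fmri, sc[:2], subject_r=4, m_per_modality=4)

    def test_deterministic_given_seed(self, truth):
        fmri, sc = j.simulate_cohort(truth, 4, t_len=120, seed=5)
        kw = dict(subject_r=4, m_per_modality=3, icasso_runs=3, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_joint_cmica(fmri, sc, **kw)
            b = fit_joint_cmica(fmri, sc, **kw)
        np.testing.assert_allclose(a.aggregate_S, b.aggregate_S, atol=1e-10)
        np.testing.assert_allclose(a.demix_w, b.demix_w, atol=1e-10)

    def test_shared_sources_recovered(self, truth, fitted):
        model, _ = fitted
        _, _, corrs = j.align_components(model.aggregate_S, truth.S_true)
        assert min(corrs[k] for k in truth.shared_ids) >= 0.95

    def test_aggregate_sources_unit_variance(self, fitted):
        model, _ = fitted
        np.testing.assert_allclose(
            model.aggregate_S.std(axis=1, ddof=1), 1.0, atol=1e-10
        )

    def test_modality_contributions_sum_to_aggregate(self, fitted):
        model, _ = fitted
        total = model.modality_contribution("FC") + model.modality_contribution("SC")
        np.testing.assert_allclose(total, model.aggregate_S, atol=1e-10)

    def test_swapping_block_order_preserves_sources(self, truth):
        """Concatenating SC-first permutes bookkeeping, not the sources."""
        fmri, sc = j.simulate_cohort(truth, 6, t_len=200, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            red_fc = [
                reduce_subject_fc(temporal_normalize(s.data), 4) for s in fmri
            ]
            red_sc = [reduce_subject_sc(c, 4) for c in sc]
            gfc = group_reduce(red_fc, 4)
            gsc = group_reduce(red_sc, 4)
            ab, _ = concatenate_modalities(gfc, gsc)
            ba, _ = concatenate_modalities(gsc, gfc)
            run_ab = run_ica(joint_whiten(ab)[0], seed=0)
            run_ba = run_ica(joint_whiten(ba)[0], seed=0)
        _, _, corrs = j.align_components(run_ab.sources, run_ba.sources)
        assert corrs.min() > 0.99


class TestBackReconstruct:
    def test_subject_mean_equals_modality_contribution(self, fitted):
        model, reduced = fitted
        for mod in ("FC", "SC"):
            maps = [
                back_reconstruct(model, reduced[mod][k], mod, k)
                for k in range(model.n_subjects)
            ]
            mean_s = np.mean([m.S_k for m in maps], axis=0)
            contrib = model.modality_contribution(mod)
            err = np.linalg.norm(mean_s - contrib) / np.linalg.norm(contrib)
            assert err < 1e-6

    def test_reconstruction_close_to_subject_truncation(self, truth, cohort, fitted):
        model, reduced = fitted
        fmri, sc = cohort
        for mod in ("FC", "SC"):
            for k in (0, 5):
                red = reduced[mod][k]
                maps = back_reconstruct(model, red, mod, k)
                if mod == "FC":
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ck = explicit_fc_matrix(temporal_normalize(fmri[k].data))
                else:
                    ck = sc[k].to_dense().T
                u, s, vh = np.linalg.svd(ck, full_matrices=False)
                r = red.r
                floor = np.linalg.norm(ck - (u[:, :r] * s[:r]) @ vh[:r])
                err = np.linalg.norm(ck - maps.R_k @ maps.S_k)
                assert err <= 1.05 * floor

    def test_connectivity_maps_match_generative_oracles(self, truth, fitted):
        """Functional R maps are seed-based correlation maps of the source
        ROI, so the reference is the analytic correlation profile implied
        by the generator; structural R maps should reproduce the planted
        tracts.  Group-averaged maps must match closely; single-subject
        maps are noisier estimates and only need to resemble the oracle."""
        from jcmica.synthetic import analytic_fc_correlation

        model, reduced = fitted
        perm, _, _ = j.align_components(model.aggregate_S, truth.S_true)
        fc_maps = [
            back_reconstruct(model, reduced["FC"][k], "FC", k)
            for k in range(model.n_subjects)
        ]
        _, r_mean_fc = group_average_maps(model, fc_maps, "FC")
        c_mean = np.mean(
            [analytic_fc_correlation(truth, s, 0.5) for s in range(10)], axis=0
        )
        sc_maps = [
            back_reconstruct(model, reduced["SC"][k], "SC", k)
            for k in range(model.n_subjects)
        ]
        _, r_mean_sc = group_average_maps(model, sc_maps, "SC")
        sc_ids = list(truth.sc_expressed_ids)
        for k_true in truth.shared_ids:
            comp = perm[k_true]
            support = truth.S_true[k_true] > 0
            seedmap = c_mean[:, support].mean(axis=1)
            assert abs(np.corrcoef(r_mean_fc[:, comp], seedmap)[0, 1]) > 0.9
            tract = truth.B_sc[sc_ids.index(k_true)]
            assert abs(np.corrcoef(r_mean_sc[:, comp], tract)[0, 1]) > 0.9
            # single-subject estimates carry subject-level noise
            c_sub = analytic_fc_correlation(truth, 0, 0.5)
            sub_seed = c_sub[:, support].mean(axis=1)
            assert abs(np.corrcoef(fc_maps[0].R_k[:, comp], sub_seed)[0, 1]) > 0.6

    def test_unknown_subject_rejected(self, fitted):
        model, reduced = fitted
        with pytest.raises(ValueError, match="not part of the fit"):
            back_reconstruct(model, reduced["FC"][0], "FC", 99)

    def test_identical_subjects_collapse_to_group(self, rng):
        """With identical subjects every S_k equals the group contribution."""
        t = j.make_ground_truth((8, 8, 4), (8, 8, 4), 2, 1, 1, seed=13)
        fmri, sc = j.simulate_cohort(t, 1, t_len=100, seed=4)
        fmri = [fmri[0], fmri[0]]
        sc = [sc[0], sc[0]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, reduced = fit_joint_cmica(
                fmri, sc, subject_r=3, m_per_modality=3, icasso_runs=3,
                seed=2, return_reduced=True,
            )
        for mod in ("FC", "SC"):
            for k in range(2):
                maps = back_reconstruct(model, reduced[mod][k], mod, k)
                np.testing.assert_allclose(
                    maps.S_k, model.modality_contribution(mod), atol=1e-8
                )


class TestGroupAverageMaps:
    def test_mean_matches_manual_average(self, fitted):
        model, reduced = fitted
        maps = [
            back_reconstruct(model, reduced["FC"][k], "FC", k)
            for k in range(model.n_subjects)
        ]
        s_mean, r_mean = group_average_maps(model, maps, "FC")
        np.testing.assert_array_equal(s_mean, np.mean([m.S_k for m in maps], axis=0))
        np.testing.assert_array_equal(r_mean, np.mean([m.R_k for m in maps], axis=0))

    def test_missing_subject_rejected(self, fitted):
        model, reduced = fitted
        maps = [back_reconstruct(model, reduced["FC"][0], "FC", 0)]
        with pytest.raises(ValueError, match="all"):
            group_average_maps(model, maps, "FC")


def test_model_hdf5_round_trip(tmp_path, fitted):
    model, _ = fitted
    save_model(model, tmp_path / "model.h5")
    back = load_model(tmp_path / "model.h5")
    np.testing.assert_array_equal(back.aggregate_S, model.aggregate_S)
    np.testing.assert_array_equal(back.demix_w, model.demix_w)
    assert back.concat_order == model.concat_order
    np.testing.assert_array_equal(
        back.stability.cluster_quality, model.stability.cluster_quality
    )
    for mod in ("FC", "SC"):
        np.testing.assert_array_equal(
            back.reductions[mod].group_basis, model.reductions[mod].group_basis
        )


def test_full_order_fit_separates_modality_specific_sources(truth, cohort):
    """At full symmetric order every planted source is recovered and the
    contribution ratio cleanly separates shared from modality-specific."""
    fmri, sc = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_joint_cmica(
            fmri, sc, subject_r=6, m_per_modality=6, icasso_runs=10, seed=17
        )
    ratios = j.contribution_ratio(model)[:, 0]
    est = model.aggregate_S
    for k in range(truth.k_total):
        cs = np.array([abs(np.corrcoef(truth.S_true[k], e)[0, 1]) for e in est])
        comp = int(cs.argmax())
        if k in truth.shared_ids:
            assert cs.max() >= 0.95
            assert 0.2 <= ratios[comp] <= 0.8
        elif k in truth.fc_only_ids:
            assert cs.max() >= 0.9
            assert ratios[comp] > 0.8
        else:
            assert cs.max() >= 0.9
            assert ratios[comp] < 0.2
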