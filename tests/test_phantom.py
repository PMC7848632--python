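import numpy as np
import pytest

from pardti.morphometry import jacobian_determinant, log_jacobian
from pardti.phantom import (
    CohortConfig,
    EffectSpec,
    TissueParams,
    apply_group_effect,
    assign_tissue_truth,
    make_atrophy_warp,
    make_phantom_labels,
    simulate_cohort,
    simulate_dwi,
    _cerebellar_adjacent_mean_fpar,
)
from pardti.tensors import _fa_md_batch


class TestLabels:
    def test_all_regions_nonempty_default_shape(self):
        lab = make_phantom_labels((32, 32, 32))
        for name, lid in lab.names.items():
            assert np.any(lab.labels == lid), name

    def test_ring_is_tissue_bordering_csf(self, labels24):
        ring = labels24.csf_adjacent
        assert not np.any(ring & ~labels24.tissue_mask)
        # every ring voxel has a face neighbour outside tissue
        t = np.pad(labels24.tissue_mask, 1, constant_values=False)
        for idx in np.argwhere(ring)[::50]:
            i, j, k = idx + 1
            nbrs = [t[i - 1, j, k], t[i + 1, j, k], t[i, j - 1, k],
                    t[i, j + 1, k], t[i, j, k - 1], t[i, j, k + 1]]
            assert not all(nbrs)

    def test_deterministic(self):
        a = make_phantom_labels((24, 24, 24), seed=5)
        b = make_phantom_labels((24, 24, 24), seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.csf_adjacent, b.csf_adjacent)

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError, match="24"):
            make_phantom_labels((16, 16, 16))


class TestTissueTruth:
    def test_wm_anisotropic_gm_isotropic(self, labels24, truth24):
        wm = (labels24.region_mask("cerebrum-wm")
              | labels24.region_mask("cerebellum-wm")
              | labels24.region_mask("brainstem"))
        gm = (labels24.region_mask("cerebrum-gm")
              | labels24.region_mask("thalamus"))
        fa_wm, _ = _fa_md_batch(truth24.d_par[wm])
        fa_gm, _ = _fa_md_batch(truth24.d_par[gm])
        assert fa_wm.min() >= 0.4
        assert fa_gm.max() <= 0.2
        assert fa_wm.min() > 0.2  # the conventional WM criterion

    def test_csf_has_no_parenchyma(self, labels24, truth24):
        assert np.all(truth24.f_par[labels24.region_mask("csf")] == 0)

    def test_zero_jitter_reproduces_nominal(self, labels24):
        t = assign_tissue_truth(labels24, jitter=0.0)
        wm = labels24.region_mask("cerebrum-wm")
        assert np.allclose(t.f_par[wm], 0.95)
        lam = np.linalg.eigvalsh(
            np.array([[1.5e-3, 0, 0], [0, 0.35e-3, 0], [0, 0, 0.35e-3]])
        )
        fa, md = _fa_md_batch(t.d_par[wm])
        assert np.allclose(md, lam.mean(), rtol=1e-12)

    def test_eigenvalue_cap_enforced(self, labels24):
        bad = {"cerebrum-gm": TissueParams((3.1e-3,) * 3, 0.9)}
        with pytest.raises(ValueError, match="cap"):
            assign_tissue_truth(labels24, tissue_params=bad)


class TestGroupEffect:
    def test_null_effect_is_identity(self, truth24):
        spec = EffectSpec(pvf_drop=0.0, pvf_drop_sd=0.0, pmd_scale=0.0,
                          pmd_scale_sd=0.0, pfa_drop=0.0, pfa_drop_sd=0.0)
        pat = apply_group_effect(truth24, spec, seed=3)
        assert np.array_equal(pat.f_par, truth24.f_par)
        assert np.allclose(pat.d_par, truth24.d_par, atol=1e-15)

    def test_focal_pvf_drop_and_spared_deep_wm(self, labels24, truth24):
        spec = EffectSpec(pvf_drop_sd=0.0, pmd_scale_sd=0.0, pfa_drop_sd=0.0)
        pat = apply_group_effect(truth24, spec, seed=3)
        focal = labels24.csf_adjacent & (
            labels24.region_mask("cerebellum-gm")
            | labels24.region_mask("cerebellum-wm")
        )
        delta = pat.f_par[focal] - truth24.f_par[focal]
        assert np.mean(delta) == pytest.approx(-0.25, abs=1e-10)
        deep = labels24.region_mask("cerebrum-wm") & ~labels24.csf_adjacent
        assert np.max(np.abs(pat.f_par[deep] - truth24.f_par[deep])) < 0.01

    def test_diffuse_md_and_fa_shifts(self, labels24, truth24):
        spec = EffectSpec(pvf_drop_sd=0.0, pmd_scale_sd=0.0, pfa_drop_sd=0.0)
        pat = apply_group_effect(truth24, spec, seed=3)
        deep = labels24.region_mask("cerebrum-wm") & ~labels24.csf_adjacent
        fa0, md0 = _fa_md_batch(truth24.d_par[deep])
        fa1, md1 = _fa_md_batch(pat.d_par[deep])
        assert np.median(md1 / md0) == pytest.approx(1.10, abs=0.01)
        assert np.median(fa1 - fa0) == pytest.approx(-0.08, abs=0.01)

    def test_out_of_bounds_effects_are_clipped_and_counted(self, truth24):
        spec = EffectSpec(pvf_drop=-1.5, pvf_drop_sd=0.0)
        pat = apply_group_effect(truth24, spec, seed=3)
        assert pat.n_clipped > 0
        assert pat.f_par.min() >= 0.0


class TestAtrophyWarp:
    def test_zero_contraction_zero_field(self, labels24):
        u = make_atrophy_warp(labels24, contraction=0.0, seed=0, jitter=0.0)
        assert np.all(u == 0)

    def test_patient_warp_shrinks_cerebellum_only(self, labels24):
        u = make_atrophy_warp(labels24, contraction=0.15, seed=0)
        lj = log_jacobian(u)
        cb = (labels24.region_mask("cerebellum-gm")
              | labels24.region_mask("cerebellum-wm"))
        deep = labels24.region_mask("cerebrum-wm") & ~labels24.csf_adjacent
        assert lj[cb].mean() < 0
        assert abs(lj[deep].mean()) < 0.02

    def test_invertible_across_range(self, labels24):
        for c in (-0.1, 0.3, 0.45):
            det = jacobian_determinant(
                make_atrophy_warp(labels24, contraction=c, seed=1)
            )
            assert det.min() > 0

    def test_contraction_bounds(self, labels24):
        with pytest.raises(ValueError):
            make_atrophy_warp(labels24, contraction=0.6)


class TestSimulateDwi:
    def test_infinite_snr_is_exact_forward_model(self, scheme, truth24):
        a = simulate_dwi(truth24, scheme, snr=np.inf)
        b = simulate_dwi(truth24, scheme, snr=np.inf, seed=9)
        assert np.array_equal(a, b)
        # spot-check one WM voxel against the voxelwise forward model
        from pardti import predict_dual
        from pardti.tensors import vec6_to_tensor

        idx = tuple(np.argwhere(truth24.labels.region_mask("cerebrum-wm"))[0])
        expect = predict_dual(1000.0, truth24.f_par[idx],
                              vec6_to_tensor(truth24.d_par[idx]), scheme)
        assert np.allclose(a[idx], expect, rtol=1e-12)

    def test_deterministic_per_seed(self, scheme, truth24):
        a = simulate_dwi(truth24, scheme, snr=30, seed=4)
        b = simulate_dwi(truth24, scheme, snr=30, seed=4)
        c = simulate_dwi(truth24, scheme, snr=30, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rician_b0_bias_small_in_csf(self, scheme, labels24, truth24):
        # at SNR >= 20 the Rician mean at b0 is within 1% of S0
        dwi = simulate_dwi(truth24, scheme, snr=20, seed=6)
        csf = labels24.region_mask("csf")
        b0_mean = dwi[csf][:, scheme.b0_mask].mean()
        assert abs(b0_mean / 1000.0 - 1.0) < 0.01


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(CohortConfig(shape=(24, 24, 24), snr=40.0), seed=21)


class TestCohort:
    def test_group_sizes(self, small_cohort):
        counts = small_cohort.table.groupby("group").size()
        assert counts["HV"] == 14
        assert counts["SCA7"] == 13

    def test_patients_symptomatic_hv_blank(self, small_cohort):
        t = small_cohort.table
        assert np.all(t.loc[t.group == "SCA7", "sara"] > 0)
        assert t.loc[t.group == "HV", "sara"].isna().all()

    def test_sara_tracks_truth_cerebellar_pvf(self, small_cohort):
        pat = small_cohort.table[small_cohort.table.group == "SCA7"]
        fp = [_cerebellar_adjacent_mean_fpar(s.truth)
              for s in small_cohort.subjects if s.group == "SCA7"]
        r = np.corrcoef(fp, pat.sara)[0, 1]
        assert r < -0.3

    def test_deterministic(self):
        cfg = CohortConfig(shape=(24, 24, 24), n_hv=3, n_patients=3)
        a = simulate_cohort(cfg, seed=8)
        b = simulate_cohort(cfg, seed=8)
        assert a.table.equals(b.table)
        assert np.array_equal(a.subjects[0].dwi, b.subjects[0].dwi)
        assert np.array_equal(a.subjects[-1].warp, b.subjects[-1].warp)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            simulate_cohort(CohortConfig(n_hv=2, n_patients=5), seed=0)

    def test_on_disk_layout(self, tmp_path):
        cfg = CohortConfig(shape=(24, 24, 24), n_hv=3, n_patients=3, snr=20)
        simulate_cohort(cfg, seed=2, out_dir=tmp_path)
        assert (tmp_path / "cohort.tsv").exists()
        assert (tmp_path / "labels.nii.gz").exists()
        assert (tmp_path / "scheme.bval").exists()
        assert (tmp_path / "HV01" / "dwi.nii.gz").exists()
        assert (tmp_path / "SCA701" / "warp.nii.gz").exists()
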