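"""Phantom generator: geometry, diameter law, coupling dial, rendering."""

import numpy as np
import pytest
from scipy import stats

from qlsm.phantom import (
    Compartment,
    PhantomSpec,
    couple_nerves_to_vessels,
    generate_bone_shell,
    generate_phantom,
    grow_tube_network,
    sample_nerve_diameters,
)

from conftest import small_spec


class TestBoneShell:
    def test_flat_slab_layers_symmetric(self):
        gt = generate_bone_shell(small_spec())
        n_peri = (gt.compartment_map == Compartment.PERIOSTEAL).sum()
        n_dura = (gt.compartment_map == Compartment.DURAL).sum()
        assert abs(n_peri - n_dura) <= 0.01 * n_peri

    def test_compartments_partition_volume(self):
        spec = small_spec(shell_curvature=5e-4)
        gt = generate_bone_shell(spec)
        counts = np.bincount(gt.compartment_map.ravel(), minlength=5)
        assert counts.sum() == np.prod(spec.volume_shape_vox)
        peri = gt.compartment_map == Compartment.PERIOSTEAL
        dura = gt.compartment_map == Compartment.DURAL
        assert not (peri & dura).any()
        assert not (peri & gt.bone_mask).any() and not (dura & gt.bone_mask).any()

    def test_layer_thickness_in_voxels(self):
        # 13 um layer at dz=2.5 -> 5-6 voxels thick along the slab normal
        spec = small_spec(layer_thickness_um=13.0)
        gt = generate_bone_shell(spec)
        column = gt.compartment_map[:, 48, 48]
        n_peri = (column == Compartment.PERIOSTEAL).sum()
        assert 5 <= n_peri <= 6

    def test_shell_too_thick_raises(self):
        with pytest.raises(ValueError, match="does not fit"):
            generate_bone_shell(small_spec(shell_thickness_um=200.0))


class TestDiameterLaw:
    def test_sample_mean_matches_reported_value(self, rng):
        d = sample_nerve_diameters(PhantomSpec(), 1000, rng)
        assert d.mean() == pytest.approx(4.013, abs=0.2)

    def test_truncation_bound(self, rng):
        d = sample_nerve_diameters(PhantomSpec(), 2000, rng)
        assert d.min() > 0.5

    def test_ks_against_truncated_normal(self, rng):
        spec = PhantomSpec()
        d = sample_nerve_diameters(spec, 1000, rng)
        a = (0.5 - 4.013) / 1.57
        res = stats.kstest(d, stats.truncnorm(a, np.inf, loc=4.013, scale=1.57).cdf)
        assert res.pvalue > 0.01


class TestGrowth:
    def test_zero_density_gives_empty_network(self, rng):
        spec = small_spec()
        gt = generate_bone_shell(spec)
        allowed = gt.compartment_map == Compartment.PERIOSTEAL
        assert grow_tube_network(spec, allowed, "nerve", density_target=0.0, rng=rng) == []

    def test_empty_region_raises(self, rng):
        spec = small_spec()
        with pytest.raises(ValueError, match="empty"):
            grow_tube_network(spec, np.zeros(spec.volume_shape_vox, bool), "vessel", rng=rng)

    def test_growth_confined_to_region(self, rng):
        spec = small_spec()
        gt = generate_bone_shell(spec)
        allowed = (gt.compartment_map == Compartment.PERIOSTEAL) | (gt.compartment_map == Compartment.DURAL)
        net = grow_tube_network(spec, allowed, "vessel", density_target=0.02, rng=rng)
        sp = np.asarray(spec.voxel_spacing_um)
        for pl in net:
            idx = np.rint(pl.points_um / sp).astype(int)
            assert allowed[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_fixed_seed_reproducible(self):
        spec = small_spec(rng_seed=3)
        gt = generate_bone_shell(spec)
        allowed = gt.compartment_map == Compartment.DURAL
        a = grow_tube_network(spec, allowed, "nerve", density_target=0.02, rng=np.random.default_rng(5))
        b = grow_tube_network(spec, allowed, "nerve", density_target=0.02, rng=np.random.default_rng(5))
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.points_um, pb.points_um)
            np.testing.assert_array_equal(pa.radius_um, pb.radius_um)


class TestCoupling:
    def test_rho_zero_is_identity(self, small_phantom):
        spec, _, gt = small_phantom
        nerves = gt.networks["nerve"]
        out = couple_nerves_to_vessels(nerves, gt.networks["P2"], 0.0, spec)
        for a, b in zip(nerves, out):
            np.testing.assert_array_equal(a.points_um, b.points_um)

    def test_empty_type_h_raises(self, small_phantom):
        spec, _, gt = small_phantom
        with pytest.raises(ValueError, match="type-H"):
            couple_nerves_to_vessels(gt.networks["nerve"], [], 0.5, spec)

    def test_dial_monotone_in_rho(self):
        fracs = []
        for rho in (0.2, 0.5, 0.9):
            _, gt = generate_phantom(small_spec(coupling_rho=rho, rng_seed=11))
            fracs.append(gt.association_fraction_truth()["P2"])
        assert fracs[0] <= fracs[1] <= fracs[2]

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_dial_fidelity_full_size(self, rho):
        """Ground-truth association fraction lands on the dial within 0.05
        (full-size phantom, >= 500 segments)."""
        _, gt = generate_phantom(PhantomSpec(coupling_rho=rho, rng_seed=1))
        table = gt.nerve_segment_table
        assert len(table) >= 500
        assert gt.association_fraction_truth()["P2"] == pytest.approx(rho, abs=0.05)


class TestRendering:
    def test_noise_free_maxima_inside_structures(self, small_phantom_noise_free):
        _, channels, gt = small_phantom_noise_free
        nerve = channels["nerve"].data
        peak = nerve == nerve.max()
        assert (gt.occupancy["nerve"][peak] > 0).all()

    def test_p1_only_phantom_has_no_emcn_signal(self):
        spec = small_spec(
            vessel_density_target=(0.03, 0.0, 0.0),
            nerve_density_target=0.0,
            coupling_rho=0.0,
            noise_gaussian_sd=0.0,
            noise_poisson_scale=0.0,
            background_gradient=0.0,
            rng_seed=2,
        )
        channels, gt = generate_phantom(spec)
        assert gt.occupancy["P1"].max() > 0
        assert channels["emcn"].data.max() <= spec.intensity_levels["emcn"]["background"]

    def test_intensity_ordering_validated(self):
        spec = small_spec()
        spec.intensity_levels["cd31"]["lo"] = 500.0  # lo above hi
        with pytest.raises(ValueError, match="hi > lo > background"):
            spec.validate()

    def test_rendered_density_near_target(self):
        # density dials are honored within 10% at the default volume size
        # (in tiny volumes the minimum-tree-size floor quantizes them)
        spec = PhantomSpec(coupling_rho=0.5, rng_seed=1)
        _, gt = generate_phantom(spec)
        got = gt.true_densities["of_layer_region"]["nerve"]
        assert got == pytest.approx(spec.nerve_density_target, rel=0.10)

    def test_bit_identical_given_seed(self):
        spec = small_spec(coupling_rho=0.4, rng_seed=9)
        ch1, gt1 = generate_phantom(spec)
        ch2, gt2 = generate_phantom(small_spec(coupling_rho=0.4, rng_seed=9))
        for name in ch1:
            np.testing.assert_array_equal(ch1[name].data, ch2[name].data)
        np.testing.assert_array_equal(gt1.nerve_label, gt2.nerve_label)
        np.testing.assert_array_equal(gt1.vessel_label, gt2.vessel_label)

    def test_vessel_phenotypes_mutually_exclusive(self, small_phantom):
        _, _, gt = small_phantom
        # by construction the label volume holds one phenotype per voxel;
        # check the occupancies do not both claim a labeled voxel deep inside
        assert set(np.unique(gt.vessel_label)) <= {0, 1, 2, 3}


class TestSpecValidation:
    def test_density_out_of_range(self):
        with pytest.raises(ValueError):
            small_spec(nerve_density_target=1.5)

    def test_vessel_density_sum_cap(self):
        with pytest.raises(ValueError, match="0.5"):
            small_spec(vessel_density_target=(0.3, 0.2, 0.1))

    def test_yaml_roundtrip(self, tmp_path):
        spec = small_spec(rng_seed=42, coupling_rho=0.3)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = PhantomSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.to_dict() == spec.to_dict()
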