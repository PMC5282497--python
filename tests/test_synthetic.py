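"""Generator contracts: volumes, planted fractions, clusters, determinism."""

import numpy as np
import pytest

from spermtopo import (
    FractionTargetError,
    SyntheticSpec,
    make_nucleus,
    render_spots,
    sample_spot_positions,
    simulate_cell,
    simulate_cohort,
)
from spermtopo.topology import assign_longitudinal, assign_radial
from spermtopo.types import VoxelImage


def test_default_semi_axes_reproduce_reported_volumes(default_spec):
    a, b, c = default_spec.semi_axes_treated
    v_treated = 4 / 3 * np.pi * a * b * c
    assert abs(v_treated - 153.9) / 153.9 < 0.001
    a, b, c = default_spec.semi_axes_untreated
    v_untreated = 4 / 3 * np.pi * a * b * c
    assert abs(v_untreated - 62.83) / 62.83 < 0.01


def test_mask_volume_matches_analytic_within_2pct(treated_nucleus):
    _, nuc = treated_nucleus
    assert abs(nuc.mask_volume() - nuc.volume) / nuc.volume < 0.02


def test_degenerate_semi_axis_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(semi_axes_treated=(4.08, 0.0, 3.0))


def test_fraction_triples_validated():
    with pytest.raises(ValueError, match="sum to 1"):
        SyntheticSpec(radial_fractions=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SyntheticSpec(telomere_cluster_sizes={2: 0.6, 4: 0.6})


def test_grid_too_small_names_axis():
    spec = SyntheticSpec(noise_sd=0.0)
    with pytest.raises(ValueError, match="semi-axis a"):
        make_nucleus(spec, shape=(94, 80, 40))


def test_tail_landmark_at_long_axis_pole(treated_nucleus):
    _, nuc = treated_nucleus
    assert nuc.length_L == pytest.approx(8.16)
    assert nuc.widest_diameter_D == pytest.approx(6.0)
    assert np.linalg.norm(nuc.head_point - nuc.tail_point) == pytest.approx(8.16)


def test_spot_labels_consistent_with_topology_assigners(treated_nucleus):
    """Stored ground-truth regions equal those recomputed from coordinates."""
    _, nuc = treated_nucleus
    spec = SyntheticSpec()
    spots = sample_spot_positions(nuc, spec, "pantelomere", seed=5)
    geom = nuc.geometry
    for s in spots:
        d = float(geom.distance_to_surface(s.position[None, :])[0])
        assert assign_radial(d, nuc.widest_diameter_D).region == s.radial_region
        la = assign_longitudinal(s.position, nuc.tail_point, nuc.head_point)
        assert la.region == s.longitudinal_region
        # strictly inside the nucleus ellipsoid
        assert geom.contains(s.position[None, :])[0]


def test_pure_periphery_targets_put_every_spot_near_the_edge(treated_nucleus):
    _, nuc = treated_nucleus
    spec = SyntheticSpec(
        radial_fractions=(1.0, 0.0, 0.0),
        n_telomere_units=40,
        telomere_cluster_sizes={1: 1.0},
    )
    spots = sample_spot_positions(nuc, spec, "pantelomere", seed=1)
    d = nuc.geometry.distance_to_surface(np.array([s.position for s in spots]))
    assert np.all(d < nuc.widest_diameter_D / 2 / 3)


def test_large_sample_fractions_converge_to_targets(treated_nucleus):
    _, nuc = treated_nucleus
    spec = SyntheticSpec(
        n_telomere_units=10_000,
        telomere_cluster_sizes={1: 1.0},
        nonrender_fraction_target=0.0,
    )
    spots = sample_spot_positions(nuc, spec, "pantelomere", seed=11)
    rad = np.array(
        [["periphery", "intermediate", "interior"].index(s.radial_region) for s in spots]
    )
    lon = np.array(
        [["tail", "mid", "head"].index(s.longitudinal_region) for s in spots]
    )
    for idx, target in zip(np.bincount(rad) / len(spots), spec.radial_fractions):
        assert abs(idx - target) < 0.02
    for idx, target in zip(np.bincount(lon) / len(spots), spec.longitudinal_fractions):
        assert abs(idx - target) < 0.02


def test_cluster_members_stay_within_jitter(treated_nucleus):
    _, nuc = treated_nucleus
    spec = SyntheticSpec(
        n_telomere_units=40,
        telomere_cluster_sizes={4: 1.0},
        cluster_jitter=0.1,
    )
    spots = sample_spot_positions(nuc, spec, "pantelomere", seed=2)
    by_cluster = {}
    for s in spots:
        by_cluster.setdefault(s.cluster_id, []).append(s.position)
    for members in by_cluster.values():
        assert len(members) == 4
        members = np.array(members)
        pairwise = np.linalg.norm(members[:, None] - members[None, :], axis=-1)
        assert pairwise.max() < 0.3


def test_unattainable_joint_target_reports_achieved_fractions():
    # In a sphere the interior (central ball of radius R/3) and the head
    # third of the axis are disjoint, so (interior, head) cannot be placed.
    spec = SyntheticSpec(
        semi_axes_treated=(3.0, 3.0, 3.0),
        radial_fractions=(0.0, 0.0, 1.0),
        longitudinal_fractions=(0.0, 0.0, 1.0),
        n_telomere_units=2,
        telomere_cluster_sizes={1: 1.0},
        noise_sd=0.0,
    )
    _, nuc = make_nucleus(spec)
    with pytest.raises(FractionTargetError) as err:
        sample_spot_positions(nuc, spec, "pantelomere", seed=0)
    assert err.value.achieved_radial.sum() > 0


def test_nonrender_flag_fraction_is_binomial(treated_nucleus):
    _, nuc = treated_nucleus
    spec = SyntheticSpec(
        n_telomere_units=1000,
        telomere_cluster_sizes={2: 0.5, 4: 0.5},
        nonrender_fraction_target=0.264,
    )
    spots = sample_spot_positions(nuc, spec, "pantelomere", seed=9)
    flagged = sum(1 for s in spots if not s.renderable)
    assert abs(flagged - 264) <= 30


def test_render_zero_spots_is_noise_only(treated_nucleus):
    img, nuc = treated_nucleus
    spec = SyntheticSpec(noise_sd=0.0, tail_background_amplitude=0.0)
    blank = VoxelImage(np.zeros_like(img.data), spec.voxel_size, channel="pantelomere")
    out = render_spots(blank, [], spec, seed=0)
    assert np.array_equal(out.data, blank.data)


def test_render_single_clean_spot_peaks_at_its_voxel(treated_nucleus):
    img, nuc = treated_nucleus
    spec = SyntheticSpec(noise_sd=0.0, tail_background_amplitude=0.0)
    one_spot_spec = SyntheticSpec(
        n_telomere_units=1,
        telomere_cluster_sizes={1: 1.0},
        nonrender_fraction_target=0.0,
    )
    spots = sample_spot_positions(nuc, one_spot_spec, "pantelomere", seed=4)
    blank = VoxelImage(np.zeros_like(img.data), spec.voxel_size, channel="pantelomere")
    out = render_spots(blank, spots, spec, seed=0)
    peak_idx = np.unravel_index(np.argmax(out.data), out.data.shape)
    vs = np.asarray(spec.voxel_size)
    peak_phys = ((np.asarray(peak_idx) + 0.5) * vs)[::-1]
    assert np.linalg.norm(peak_phys - spots[0].position) < np.sqrt(3) * 0.1


def test_undersampled_psf_warns(treated_nucleus):
    img, nuc = treated_nucleus
    spec = SyntheticSpec(psf_sigma=0.02, noise_sd=0.0)
    blank = VoxelImage(np.zeros_like(img.data), spec.voxel_size)
    with pytest.warns(UserWarning, match="undersampled"):
        render_spots(blank, [], spec, seed=0)


def test_simulate_cell_is_deterministic():
    spec = SyntheticSpec()
    a = simulate_cell(spec, cell_index=3, channels=("pantelomere",), render=False)
    b = simulate_cell(spec, cell_index=3, channels=("pantelomere",), render=False)
    assert len(a.spots) == len(b.spots)
    for sa, sb in zip(a.spots, b.spots):
        assert np.array_equal(sa.position, sb.position)
        assert sa.renderable == sb.renderable
        assert sa.radial_region == sb.radial_region


def test_cohort_manifest_and_reproducibility(tmp_path):
    spec = SyntheticSpec(
        n_subjects=1, cells_per_subject=1, n_telomere_units=8,
        telomere_cluster_sizes={2: 1.0},
    )
    m1, gt1 = simulate_cohort(spec, out_dir=tmp_path / "a", channels=("pantelomere",))
    assert len(m1) == 1
    spec2 = SyntheticSpec(
        n_subjects=2, cells_per_subject=3, n_telomere_units=8,
        telomere_cluster_sizes={2: 1.0},
    )
    m2, gt2 = simulate_cohort(spec2, channels=("pantelomere",))
    assert len(m2) == 6
    # byte-identical tables on re-run with the same spec
    _, gt2b = simulate_cohort(spec2, channels=("pantelomere",))
    assert gt2.to_csv(index=False) == gt2b.to_csv(index=False)
    # refuse to clobber an existing non-empty output directory
    with pytest.raises(FileExistsError):
        simulate_cohort(spec, out_dir=tmp_path / "a", channels=("pantelomere",))
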