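"""Segmentation, signal detection and axis measurement."""

import numpy as np
import pytest

from spermtopo import SyntheticSpec, make_nucleus, render_spots, sample_spot_positions
from spermtopo.segmentation import detect_signals, measure_axes, segment_nucleus
from spermtopo.types import VoxelImage


def test_segmented_volume_matches_reported_treated_mean(treated_nucleus):
    img, _ = treated_nucleus
    nuc = segment_nucleus(img)
    assert abs(nuc.volume - 153.9) / 153.9 < 0.02


def test_treated_untreated_volume_ratio_is_2_4():
    spec = SyntheticSpec(noise_sd=0.0)
    img_t, _ = make_nucleus(spec, treated=True)
    img_u, _ = make_nucleus(spec, treated=False)
    ratio = segment_nucleus(img_t).volume / segment_nucleus(img_u).volume
    assert ratio == pytest.approx(2.4, abs=0.1)


def test_empty_image_raises_empty_mask():
    img = VoxelImage(np.zeros((20, 20, 20)), (0.1, 0.1, 0.1), "dapi")
    with pytest.raises(ValueError, match="empty mask"):
        segment_nucleus(img, threshold=10.0)


def test_two_comparable_nuclei_raise():
    data = np.zeros((20, 40, 40), dtype=np.float32)
    data[5:15, 5:15, 5:15] = 200.0
    data[5:15, 25:35, 25:35] = 200.0
    img = VoxelImage(data, (0.1, 0.1, 0.1), "dapi")
    with pytest.raises(ValueError, match="multiple comparable components"):
        segment_nucleus(img, threshold=100.0)


def test_mask_volume_monotone_in_threshold(treated_nucleus):
    img, _ = treated_nucleus
    vols = [
        segment_nucleus(img, threshold=thr).volume for thr in (50.0, 100.0, 150.0)
    ]
    assert vols[0] >= vols[1] >= vols[2]


def _blank_like(img, spec, channel="pantelomere"):
    return VoxelImage(np.zeros_like(img.data), spec.voxel_size, channel=channel)


def test_single_clean_spot_recovered_within_one_voxel(treated_nucleus):
    img, truth = treated_nucleus
    spec = SyntheticSpec(noise_sd=0.0, tail_background_amplitude=0.0)
    one = SyntheticSpec(
        n_telomere_units=1, telomere_cluster_sizes={1: 1.0},
        nonrender_fraction_target=0.0,
    )
    spots = sample_spot_positions(truth, one, "pantelomere", seed=3)
    fish = render_spots(_blank_like(img, spec), spots, spec, seed=0)
    signals, n_nr = detect_signals(fish, truth)
    rendered = [s for s in signals if s.rendered]
    assert len(rendered) == 1
    assert n_nr == 0
    assert np.linalg.norm(rendered[0].centroid - spots[0].position) < np.sqrt(3) * 0.1


def test_no_false_positives_without_noise(treated_nucleus):
    img, truth = treated_nucleus
    spec = SyntheticSpec(noise_sd=0.0, tail_background_amplitude=0.0)
    fish = render_spots(_blank_like(img, spec), [], spec, seed=0)
    signals, n_nr = detect_signals(fish, truth)
    assert signals == [] and n_nr == 0


def test_close_spots_merge_into_one_rendered_signal(treated_nucleus):
    """Two Gaussians 0.1 um apart overlap above threshold -> one component."""
    img, truth = treated_nucleus
    spec = SyntheticSpec(noise_sd=0.0, tail_background_amplitude=0.0, psf_sigma=0.2)
    from spermtopo.synthetic import GroundTruthSpot

    center = (truth.tail_point + truth.head_point) / 2
    spots = [
        GroundTruthSpot("c", "pantelomere", center, 0, "interior", "mid", True),
        GroundTruthSpot("c", "pantelomere", center + [0.1, 0, 0], 0, "interior", "mid", True),
    ]
    fish = render_spots(_blank_like(img, spec), spots, spec, seed=0)
    signals, _ = detect_signals(fish, truth)
    assert sum(s.rendered for s in signals) == 1


def test_detected_count_never_exceeds_planted(treated_nucleus):
    img, truth = treated_nucleus
    spec = SyntheticSpec(noise_sd=0.0, tail_background_amplitude=0.0)
    spots = sample_spot_positions(truth, spec, "pantelomere", seed=6)
    fish = render_spots(_blank_like(img, spec), spots, spec, seed=0)
    signals, _ = detect_signals(fish, truth)
    assert len(signals) <= len(spots)


def test_mismatched_grids_raise(treated_nucleus):
    img, truth = treated_nucleus
    bad = VoxelImage(np.zeros((5, 5, 5)), img.voxel_size, "pantelomere")
    with pytest.raises(ValueError, match="grids differ"):
        detect_signals(bad, truth)


# -- axis measurement -------------------------------------------------------

def test_axes_of_treated_ellipsoid(treated_nucleus):
    _, truth = treated_nucleus
    head, L, D = measure_axes(truth, truth.tail_point)
    assert L == pytest.approx(8.16, abs=0.1)
    assert D == pytest.approx(6.0, abs=0.1)
    # the apex of a prolate spheroid is flat, so the farthest surface voxel
    # may sit slightly off-axis; the axis direction itself stays accurate
    axis = (head - truth.tail_point) / L
    true_axis = (truth.head_point - truth.tail_point) / 8.16
    assert float(np.dot(axis, true_axis)) > 0.999


def test_axes_of_sphere(sphere_nucleus):
    head, L, D = measure_axes(sphere_nucleus, sphere_nucleus.tail_point)
    assert L == pytest.approx(6.0, abs=0.1)
    assert D == pytest.approx(6.0, abs=0.1)


def test_axes_rotation_invariant():
    spec = SyntheticSpec(noise_sd=0.0)
    _, n0 = make_nucleus(spec, rotation_deg=0.0)
    _, n35 = make_nucleus(spec, rotation_deg=35.0)
    _, L0, D0 = measure_axes(n0, n0.tail_point)
    _, L35, D35 = measure_axes(n35, n35.tail_point)
    assert L35 == pytest.approx(L0, abs=0.1)
    assert D35 == pytest.approx(D0, abs=0.1)


def test_axes_reject_tail_far_from_surface(treated_nucleus):
    _, truth = treated_nucleus
    center = (truth.tail_point + truth.head_point) / 2
    with pytest.raises(ValueError, match="tail point"):
        measure_axes(truth, center)
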