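"""Region assignment: distance transform sampling, binning, partitioning."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from spermtopo.topology import (
    LONGITUDINAL_REGIONS,
    RADIAL_REGIONS,
    assign_longitudinal,
    assign_radial,
    cell_region_counts,
    distance_map,
    distance_to_edge,
)
from spermtopo.types import FishSignal, NucleusModel


@pytest.mark.parametrize(
    "d, expected",
    [(0.5, "periphery"), (1.5, "intermediate"), (2.5, "interior"),
     (0.0, "periphery"), (1.0, "intermediate"), (2.0, "interior"), (3.0, "interior")],
)
def test_radial_thirds_of_radius(d, expected):
    assert assign_radial(d, 6.0).region == expected


def test_radial_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamping"):
        ra = assign_radial(3.5, 6.0)
    assert ra.normalized_r == 1.0
    assert ra.region == "interior"


def test_radial_rejects_bad_inputs():
    with pytest.raises(ValueError):
        assign_radial(-0.1, 6.0)
    with pytest.raises(ValueError):
        assign_radial(1.0, 0.0)


@pytest.mark.parametrize(
    "s, expected", [(1.0, "tail"), (4.5, "mid"), (8.9, "head")]
)
def test_longitudinal_thirds_of_axis(s, expected):
    tail = np.zeros(3)
    head = np.array([9.0, 0.0, 0.0])
    la = assign_longitudinal(np.array([s, 0.0, 0.0]), tail, head)
    assert la.region == expected
    assert la.length_L == pytest.approx(9.0)


def test_longitudinal_works_in_2d():
    la = assign_longitudinal(
        np.array([1.0, 0.5]), np.zeros(2), np.array([9.0, 0.0])
    )
    assert la.region == "tail"


def test_longitudinal_clamps_outliers_with_warning():
    with pytest.warns(UserWarning, match="clamping"):
        la = assign_longitudinal(
            np.array([9.9, 0.0, 0.0]), np.zeros(3), np.array([9.0, 0.0, 0.0])
        )
    assert la.normalized_t == 1.0


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    d=stn.floats(min_value=0.0, max_value=3.0),
    s=stn.floats(min_value=0.0, max_value=9.0),
)
def test_every_signal_falls_in_exactly_one_region(d, s):
    ra = assign_radial(d, 6.0)
    la = assign_longitudinal(
        np.array([s, 0.0, 0.0]), np.zeros(3), np.array([9.0, 0.0, 0.0])
    )
    assert sum(ra.region == r for r in RADIAL_REGIONS) == 1
    assert sum(la.region == r for r in LONGITUDINAL_REGIONS) == 1


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    d=stn.floats(min_value=0.0, max_value=2.99),
    scale=stn.floats(min_value=0.2, max_value=5.0),
)
def test_scale_invariance_of_region_assignment(d, scale):
    assert assign_radial(d, 6.0).region == assign_radial(d * scale, 6.0 * scale).region


def test_distance_at_sphere_center(sphere_nucleus):
    nuc = sphere_nucleus
    center = (nuc.tail_point + nuc.head_point) / 2
    d = distance_to_edge(nuc.mask, nuc.voxel_size, center)
    assert d == pytest.approx(3.0, abs=0.05)


def test_distance_near_surface_is_small(sphere_nucleus):
    nuc = sphere_nucleus
    center = (nuc.tail_point + nuc.head_point) / 2
    p = center + np.array([2.95, 0.0, 0.0])
    d = distance_to_edge(nuc.mask, nuc.voxel_size, p)
    assert d <= np.sqrt(3) * 0.1 + 0.06


def test_distance_outside_mask_raises(sphere_nucleus):
    nuc = sphere_nucleus
    with pytest.raises(ValueError, match="outside"):
        distance_to_edge(nuc.mask, nuc.voxel_size, nuc.tail_point - [1, 0, 0])


def test_anisotropic_distance_matches_isotropic():
    # same 3-um sphere, (0.2, 0.1, 0.1) voxels: centre value within one voxel
    h = (0.2, 0.1, 0.1)
    shape = (int(6.8 / h[0]), int(6.8 / h[1]), int(6.8 / h[2]))
    ctr = np.array([shape[2] * h[2], shape[1] * h[1], shape[0] * h[0]]) / 2
    zc = (np.arange(shape[0]) + 0.5) * h[0] - ctr[2]
    yc = (np.arange(shape[1]) + 0.5) * h[1] - ctr[1]
    xc = (np.arange(shape[2]) + 0.5) * h[2] - ctr[0]
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    mask = X**2 + Y**2 + Z**2 <= 9.0
    d = distance_to_edge(mask, h, ctr)
    assert d == pytest.approx(3.0, abs=0.2)


def test_cell_region_counts_partition(sphere_nucleus):
    nuc = sphere_nucleus
    center = (nuc.tail_point + nuc.head_point) / 2
    sigs = [
        FishSignal("pantelomere", center + [2.9, 0, 0], 3, 10.0, True),   # periphery
        FishSignal("pantelomere", center + [1.5, 0, 0], 3, 10.0, True),   # intermediate
        FishSignal("pantelomere", center, 3, 10.0, True),                 # interior
    ]
    out = cell_region_counts(sigs, nuc)
    assert out["pantelomere"]["radial_counts"].tolist() == [1, 1, 1]
    assert out["pantelomere"]["longitudinal_counts"].sum() == 3
    assert out["pantelomere"]["radial_fractions"].sum() == pytest.approx(1.0)


def test_cell_region_counts_zero_signals_flagged(sphere_nucleus):
    out = cell_region_counts([], sphere_nucleus)
    assert out == {}
    nr = [FishSignal("NOR", sphere_nucleus.tail_point + [0.5, 0, 0], 0, 5.0, False)]
    out = cell_region_counts(nr, sphere_nucleus)
    assert out["NOR"]["radial_fractions"] is None
    assert out["NOR"]["longitudinal_counts"].sum() == 1
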