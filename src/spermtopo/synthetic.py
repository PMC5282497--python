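"""Synthetic sperm-nucleus images and ground-truth FISH spot tables.

The generator emulates the measured properties of DTT-decondensed human sperm
nuclei: an ellipsoidal DAPI-stained nucleus (treated mean volume ~153.9 um^3,
untreated ~62.83 um^3, a 2.4-fold swelling), a tail attachment landmark at one
pole of the long axis, telomere units aggregated into small clusters,
~7 centromere chromocenters, probe signals (NOR, centromeres 1/5/19) anchored
at chromocenters, a tail-proximal background gradient, PSF blur and read
noise.  A configurable fraction of telomere clusters is made too dim to pass
the rendering gate so that the detector - not a bookkeeping flag - excludes
them, emulating the reported 26.4% of telomeres that could not be rendered.

Radial (periphery/intermediate/interior) and longitudinal (tail/mid/head)
placement fractions are planted exactly by rejection sampling: each cluster
seed draws a target (radial, longitudinal) region pair from the configured
marginals and uniform positions inside the ellipsoid are drawn until one falls
in both regions.  Every spot stores the region labels recomputed from its own
final position, so ground truth and the assignment logic cannot drift apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import EllipsoidGeometry, rotation_matrix_z
from .topology import (
    LONGITUDINAL_REGIONS,
    RADIAL_REGIONS,
    longitudinal_region_indices,
    radial_region_indices,
)
from .types import NucleusModel, VoxelImage

FISH_CHANNELS = ("pantelomere", "pancentromere", "NOR", "cen_1_5_19")


class FractionTargetError(RuntimeError):
    """Joint region targets could not be met by rejection sampling."""

    def __init__(self, target, achieved_radial, achieved_longitudinal):
        self.target = target
        self.achieved_radial = achieved_radial
        self.achieved_longitudinal = achieved_longitudinal
        super().__init__(
            f"could not place a spot in region pair {target}; achieved "
            f"radial fractions {np.round(achieved_radial, 4)} and "
            f"longitudinal fractions {np.round(achieved_longitudinal, 4)}"
        )


@dataclass
class SyntheticSpec:
    """Free parameters of the synthetic cohort.

    Defaults encode the study conditions: 10 subjects x 30 cells, treated
    (DTT-swollen) nuclei whose analytic volume matches the 153.9 um^3 mean,
    92 telomere units (2 per chromatid arm end x 46 chromosomes), 7
    chromocenters, radial fractions back-derived from the reported telomere
    distribution and longitudinal fractions equal to the printed 3D telomere
    percentages, and a 26.4% non-renderable telomere target.
    """

    n_subjects: int = 10
    cells_per_subject: int = 30
    semi_axes_treated: Tuple[float, float, float] = (4.08, 3.00, 3.00)
    semi_axes_untreated: Tuple[float, float, float] = (3.03, 2.23, 2.23)
    voxel_size: Tuple[float, float, float] = (0.1, 0.1, 0.1)  # (dz, dy, dx) um
    radial_fractions: Tuple[float, float, float] = (0.42, 0.45, 0.13)
    longitudinal_fractions: Tuple[float, float, float] = (0.2481, 0.5042, 0.2477)
    n_telomere_units: int = 92
    telomere_cluster_sizes: Dict[int, float] = field(default_factory=lambda: {4: 1.0})
    n_chromocenters: int = 7
    n_centromere_units: int = 46
    n_nor_signals: int = 3
    n_cen_1_5_19_signals: int = 3
    cluster_jitter: float = 0.15  # um, members scatter within this radius
    probe_jitter: float = 0.2  # um, probe offset from its anchor chromocenter
    psf_sigma: float = 0.1  # um
    noise_sd: float = 5.0  # intensity units
    spot_amplitude: float = 200.0
    dapi_amplitude: float = 200.0
    dim_amplitude_range: Tuple[float, float] = (70.0, 130.0)
    tail_background_amplitude: float = 10.0
    tail_background_length: float = 1.5  # um decay length from the tail pole
    nonrender_fraction_target: float = 0.264
    grid_margin: float = 0.6  # um of empty space around the ellipsoid
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "cells_per_subject", "n_telomere_units",
                     "n_chromocenters", "n_centromere_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("semi_axes_treated", "semi_axes_untreated", "voxel_size"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"all entries of {name} must be positive")
        for name in ("radial_fractions", "longitudinal_fractions"):
            fr = getattr(self, name)
            if len(fr) != 3 or any(f < 0 for f in fr):
                raise ValueError(f"{name} must be three non-negative numbers")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(fr)}")
        sizes = self.telomere_cluster_sizes
        if not sizes or any(k < 1 for k in sizes) or any(p < 0 for p in sizes.values()):
            raise ValueError("telomere_cluster_sizes must map sizes>=1 to weights>=0")
        if abs(sum(sizes.values()) - 1.0) > 1e-9:
            raise ValueError("telomere cluster-size distribution must sum to 1")
        if not 0.0 <= self.nonrender_fraction_target < 1.0:
            raise ValueError("nonrender_fraction_target must lie in [0, 1)")


@dataclass
class GroundTruthSpot:
    """One planted FISH unit with its exact region labels."""

    cell_id: str
    channel: str
    position: np.ndarray  # (x, y, z) um
    cluster_id: int
    radial_region: str
    longitudinal_region: str
    renderable: bool

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


# ---------------------------------------------------------------------------
# nucleus rasterisation
# ---------------------------------------------------------------------------

def make_nucleus(
    spec: SyntheticSpec,
    treated: bool = True,
    seed: Optional[int] = None,
    rotation_deg: float = 0.0,
    shape: Optional[Tuple[int, int, int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[VoxelImage, NucleusModel]:
    """Rasterise a DAPI-like ellipsoidal nucleus.

    Returns the intensity image (smooth edge falloff from PSF blur plus read
    noise) and a :class:`NucleusModel` whose mask is the exact analytic
    ellipsoid and whose landmarks/axes/volume are analytic (L = 2a,
    D = 2 max(b, c), V = 4/3 pi a b c).
    """
    semi = spec.semi_axes_treated if treated else spec.semi_axes_untreated
    rot = rotation_matrix_z(np.deg2rad(rotation_deg)) if rotation_deg else None
    dz, dy, dx = spec.voxel_size

    a, b, c = semi
    if rot is None:
        half = np.array([a, b, c]) + spec.grid_margin  # (x, y, z)
    else:
        r = max(a, b)
        half = np.array([r, r, c]) + spec.grid_margin
    need_shape = tuple(
        int(np.ceil(2 * h / d))
        for h, d in zip(half[::-1], (dz, dy, dx))  # (z, y, x) order
    )
    if shape is None:
        shape = need_shape
    else:
        for ax_name, need, have in zip("zyx", need_shape, shape):
            if need > have:
                phys_ax = {"z": "c", "y": "b", "x": "a"}[ax_name]
                raise ValueError(
                    f"ellipsoid semi-axis {phys_ax} (+margin) needs {need} "
                    f"voxels along {ax_name} but the grid has {have}"
                )

    center = np.array([shape[2] * dx, shape[1] * dy, shape[0] * dz]) / 2.0
    geom = EllipsoidGeometry(center=center, semi_axes=semi, rotation=rot)

    zc = (np.arange(shape[0]) + 0.5) * dz - center[2]
    yc = (np.arange(shape[1]) + 0.5) * dy - center[1]
    xc = (np.arange(shape[2]) + 0.5) * dx - center[0]
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    if rot is None:
        q2 = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2
    else:
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) @ rot
        q2 = (
            (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2
        ).reshape(shape)
    mask = q2 <= 1.0

    sigma_vox = [spec.psf_sigma / d for d in (dz, dy, dx)]
    data = ndimage.gaussian_filter(
        mask.astype(np.float32) * spec.dapi_amplitude, sigma=sigma_vox
    )
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(
            np.float32
        )

    image = VoxelImage(data, spec.voxel_size, channel="dapi")
    model = NucleusModel(
        mask=mask,
        voxel_size=spec.voxel_size,
        tail_point=geom.tail_point,
        head_point=geom.head_point,
        length_L=geom.length_L,
        widest_diameter_D=geom.widest_diameter_D,
        volume=geom.volume,
        geometry=geom,
    )
    return image, model


# ---------------------------------------------------------------------------
# region-conditioned placement
# ---------------------------------------------------------------------------

def _labeled_uniform(geom: EllipsoidGeometry, rng, n: int):
    pts = geom.sample_uniform(rng, n)
    d = geom.distance_to_surface(pts)
    ridx = radial_region_indices(d, geom.widest_diameter_D / 2.0)
    lidx = longitudinal_region_indices(geom.axial_position(pts), geom.length_L)
    return pts, ridx, lidx


def _conditioned_positions(
    geom: EllipsoidGeometry,
    rng: np.random.Generator,
    targets: Sequence[Tuple[int, int]],
    max_draws: int = 2_000_000,
    batch: int = 4096,
) -> np.ndarray:
    """Uniform-in-ellipsoid positions conditioned on (radial, longitudinal) bins."""
    needed: Dict[Tuple[int, int], int] = {}
    for t in targets:
        needed[t] = needed.get(t, 0) + 1
    pools: Dict[Tuple[int, int], List[np.ndarray]] = {t: [] for t in needed}
    drawn = 0
    r_hist = np.zeros(3)
    l_hist = np.zeros(3)
    while any(len(pools[t]) < k for t, k in needed.items()):
        if drawn >= max_draws:
            bad = [t for t, k in needed.items() if len(pools[t]) < k]
            raise FractionTargetError(
                bad[0], r_hist / max(drawn, 1), l_hist / max(drawn, 1)
            )
        pts, ridx, lidx = _labeled_uniform(geom, rng, batch)
        drawn += batch
        r_hist += np.bincount(ridx, minlength=3)
        l_hist += np.bincount(lidx, minlength=3)
        for p, ri, li in zip(pts, ridx, lidx):
            key = (int(ri), int(li))
            if key in pools and len(pools[key]) < needed[key]:
                pools[key].append(p)
    out = []
    counters = {t: 0 for t in needed}
    for t in targets:
        out.append(pools[t][counters[t]])
        counters[t] += 1
    return np.asarray(out)


def _spot_labels(geom: EllipsoidGeometry, position: np.ndarray) -> Tuple[str, str]:
    d = float(geom.distance_to_surface(position[None, :])[0])
    ri = int(radial_region_indices(d, geom.widest_diameter_D / 2.0))
    li = int(
        longitudinal_region_indices(
            float(geom.axial_position(position[None, :])[0]), geom.length_L
        )
    )
    return RADIAL_REGIONS[ri], LONGITUDINAL_REGIONS[li]


def _jitter_inside(
    geom: EllipsoidGeometry,
    rng: np.random.Generator,
    seed_pos: np.ndarray,
    jitter: float,
    n: int,
    target: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Scatter ``n`` members within ``jitter`` of a seed, strictly inside.

    With ``target`` set, members are additionally redrawn until they fall in
    the same (radial, longitudinal) region pair the seed was conditioned on,
    so cluster scatter cannot leak probability mass across region boundaries
    and planted fractions stay exact at the spot level.  The jitter radius
    shrinks toward the (valid) seed if a draw keeps failing, so the loop
    terminates; as a last resort the member sits on the seed itself.
    """
    out = np.empty((n, 3))
    R = geom.widest_diameter_D / 2.0
    for i in range(n):
        r = jitter
        placed = False
        for _ in range(200):
            v = rng.normal(size=3)
            v *= rng.uniform() ** (1 / 3) * r / np.linalg.norm(v)
            p = seed_pos + v
            if not geom.contains(p[None, :])[0]:
                r *= 0.8
                continue
            if target is not None:
                d = geom.distance_to_surface(p[None, :])[0]
                ri = int(radial_region_indices(d, R))
                li = int(
                    longitudinal_region_indices(
                        float(geom.axial_position(p[None, :])[0]), geom.length_L
                    )
                )
                if (ri, li) != target:
                    r *= 0.8
                    continue
            out[i] = p
            placed = True
            break
        if not placed:
            out[i] = seed_pos
    return out


def _draw_cluster_sizes(
    rng: np.random.Generator, total: int, size_dist: Dict[int, float]
) -> List[int]:
    sizes = sorted(size_dist)
    probs = np.array([size_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    out: List[int] = []
    remaining = total
    while remaining > 0:
        s = int(rng.choice(sizes, p=probs))
        s = min(s, remaining)
        out.append(s)
        remaining -= s
    return out


def sample_spot_positions(
    nucleus: NucleusModel,
    spec: SyntheticSpec,
    channel: str,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    cell_id: str = "cell",
    anchors: Optional[np.ndarray] = None,
) -> List[GroundTruthSpot]:
    """Plant ground-truth spots for one channel of one cell.

    * ``pantelomere``: cluster seeds (dimer/tetramer mix) placed at the
      configured radial x longitudinal fractions, members scattered within
      ``cluster_jitter``; whole clusters are flagged non-renderable with
      probability ``nonrender_fraction_target`` (co-located members merge into
      one blob at imaging resolution, so renderability is a cluster property).
    * ``pancentromere``: ``n_chromocenters`` chromocenter seeds at the same
      fractions, centromere units divided evenly among them.
    * ``NOR`` / ``cen_1_5_19``: one signal per probe copy; each picks an
      anchor chromocenter uniformly at random when ``anchors`` is given
      (within ``probe_jitter``), otherwise falls back to fraction-conditioned
      placement.
    """
    geom: EllipsoidGeometry = nucleus.geometry
    if geom is None:
        raise ValueError("spot sampling needs a synthetic nucleus with geometry")
    if rng is None:
        rng = np.random.default_rng(seed)

    if channel == "pantelomere":
        sizes = _draw_cluster_sizes(rng, spec.n_telomere_units, spec.telomere_cluster_sizes)
        renderable_flags = rng.uniform(size=len(sizes)) >= spec.nonrender_fraction_target
    elif channel == "pancentromere":
        k, n = spec.n_chromocenters, spec.n_centromere_units
        sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
        renderable_flags = np.ones(len(sizes), dtype=bool)
    elif channel in ("NOR", "cen_1_5_19"):
        n = spec.n_nor_signals if channel == "NOR" else spec.n_cen_1_5_19_signals
        sizes = [1] * n
        renderable_flags = np.ones(n, dtype=bool)
    else:
        raise ValueError(f"unknown channel {channel!r}")

    targets: List[Optional[Tuple[int, int]]]
    if channel in ("NOR", "cen_1_5_19") and anchors is not None and len(anchors):
        choice = rng.integers(0, len(anchors), size=len(sizes))
        seeds = np.asarray(anchors)[choice]
        seeds = np.array(
            [
                _jitter_inside(geom, rng, s, spec.probe_jitter, 1)[0]
                for s in seeds
            ]
        )
        targets = [None] * len(sizes)
    else:
        rtar = rng.choice(3, size=len(sizes), p=spec.radial_fractions)
        ltar = rng.choice(3, size=len(sizes), p=spec.longitudinal_fractions)
        targets = list(zip(map(int, rtar), map(int, ltar)))
        seeds = _conditioned_positions(geom, rng, targets)

    spots: List[GroundTruthSpot] = []
    for cid, (size, seed_pos, okflag, tgt) in enumerate(
        zip(sizes, seeds, renderable_flags, targets)
    ):
        members = (
            seed_pos[None, :]
            if size == 1
            else _jitter_inside(
                geom, rng, seed_pos, spec.cluster_jitter, size, target=tgt
            )
        )
        for m in members:
            rr, lr = _spot_labels(geom, m)
            spots.append(
                GroundTruthSpot(
                    cell_id=cell_id,
                    channel=channel,
                    position=m,
                    cluster_id=cid,
                    radial_region=rr,
                    longitudinal_region=lr,
                    renderable=bool(okflag),
                )
            )
    return spots


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_spots(
    image: VoxelImage,
    spots: Sequence[GroundTruthSpot],
    spec: SyntheticSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    tail_point: Optional[np.ndarray] = None,
) -> VoxelImage:
    """Add PSF-blurred spot blobs, tail background and read noise to a channel.

    Renderable spots each contribute a Gaussian blob of peak
    ``spot_amplitude``.  A non-renderable cluster shares a single dim total
    amplitude (``dim_amplitude_range``) among its members so that its combined
    blob stays below the rendering threshold but above the presence threshold.
    An additive exponential background decays from the tail pole.  Gaussian
    read noise is added last.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.psf_sigma < 0.5 * min(image.voxel_size):
        warnings.warn(
            f"psf_sigma={spec.psf_sigma} um is under half a voxel; the PSF is "
            "undersampled",
            stacklevel=2,
        )
    data = np.array(image.data, dtype=np.float32, copy=True)
    dz, dy, dx = image.voxel_size
    shape = data.shape

    dim_total: Dict[int, float] = {}
    for s in spots:
        if not s.renderable and s.cluster_id not in dim_total:
            dim_total[s.cluster_id] = rng.uniform(*spec.dim_amplitude_range)
    dim_members: Dict[int, int] = {}
    for s in spots:
        if not s.renderable:
            dim_members[s.cluster_id] = dim_members.get(s.cluster_id, 0) + 1

    sig = spec.psf_sigma
    ext = [int(np.ceil(4 * sig / d)) for d in (dz, dy, dx)]
    for s in spots:
        x, y, z = s.position
        if not (
            0 <= x <= shape[2] * dx and 0 <= y <= shape[1] * dy and 0 <= z <= shape[0] * dz
        ):
            raise ValueError(f"spot position {s.position} outside the grid")
        amp = (
            spec.spot_amplitude
            if s.renderable
            else dim_total[s.cluster_id] / dim_members[s.cluster_id]
        )
        ci = [z / dz - 0.5, y / dy - 0.5, x / dx - 0.5]  # fractional (z, y, x)
        lo = [max(int(np.floor(c)) - e, 0) for c, e in zip(ci, ext)]
        hi = [min(int(np.ceil(c)) + e + 1, n) for c, e, n in zip(ci, ext, shape)]
        zz = (np.arange(lo[0], hi[0]) - ci[0]) * dz
        yy = (np.arange(lo[1], hi[1]) - ci[1]) * dy
        xx = (np.arange(lo[2], hi[2]) - ci[2]) * dx
        r2 = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        )
        data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * np.exp(
            -r2 / (2 * sig**2)
        ).astype(np.float32)

    if tail_point is not None and spec.tail_background_amplitude > 0:
        tx, ty, tz = np.asarray(tail_point, dtype=float)
        zz = ((np.arange(shape[0]) + 0.5) * dz - tz) ** 2
        yy = ((np.arange(shape[1]) + 0.5) * dy - ty) ** 2
        xx = ((np.arange(shape[2]) + 0.5) * dx - tx) ** 2
        dist = np.sqrt(
            zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
        )
        data += (
            spec.tail_background_amplitude
            * np.exp(-dist / spec.tail_background_length)
        ).astype(np.float32)

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    return VoxelImage(data, image.voxel_size, channel=image.channel)


# ---------------------------------------------------------------------------
# whole cells and cohorts
# ---------------------------------------------------------------------------

@dataclass
class CellSim:
    """One simulated cell: nucleus, channel images and ground truth."""

    cell_id: str
    subject: int
    seed_entropy: tuple
    nucleus: NucleusModel
    dapi: VoxelImage
    images: Dict[str, VoxelImage]
    spots: List[GroundTruthSpot]


def simulate_cell(
    spec: SyntheticSpec,
    cell_id: str = "S01_C001",
    subject: int = 1,
    cell_index: int = 1,
    treated: bool = True,
    channels: Sequence[str] = FISH_CHANNELS,
    render: bool = True,
) -> CellSim:
    """Simulate one cell with per-channel deterministic substreams.

    The per-cell seed is derived from ``(spec.seed, subject, cell_index)``
    via ``numpy``'s ``SeedSequence`` spawning, so cohorts are reproducible
    cell-by-cell and ground truth does not depend on whether images are
    rendered.
    """
    key = (int(spec.seed), int(subject), int(cell_index))
    ss = np.random.SeedSequence(entropy=key[0], spawn_key=key[1:])
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("nucleus",)
            + tuple(f"place_{c}" for c in FISH_CHANNELS)
            + tuple(f"render_{c}" for c in FISH_CHANNELS),
            ss.spawn(1 + 2 * len(FISH_CHANNELS)),
        )
    }

    dapi, nucleus = make_nucleus(spec, treated=treated, rng=streams["nucleus"])

    spots: List[GroundTruthSpot] = []
    per_channel: Dict[str, List[GroundTruthSpot]] = {}
    chromo_anchors: Optional[np.ndarray] = None
    order = [c for c in FISH_CHANNELS if c in channels]
    # chromocenters must exist before anchored probes
    if any(c in order for c in ("NOR", "cen_1_5_19")) and "pancentromere" not in order:
        order = ["pancentromere"] + order
    order.sort(key=lambda c: FISH_CHANNELS.index(c))
    for ch in order:
        ch_spots = sample_spot_positions(
            nucleus,
            spec,
            ch,
            rng=streams[f"place_{ch}"],
            cell_id=cell_id,
            anchors=chromo_anchors,
        )
        per_channel[ch] = ch_spots
        if ch == "pancentromere":
            seen = {}
            for s in ch_spots:
                seen.setdefault(s.cluster_id, []).append(s.position)
            chromo_anchors = np.array(
                [np.mean(v, axis=0) for _, v in sorted(seen.items())]
            )
        if ch in channels:
            spots.extend(ch_spots)

    images: Dict[str, VoxelImage] = {}
    if render:
        blank = VoxelImage(
            np.zeros_like(dapi.data), spec.voxel_size, channel=""
        )
        for ch in channels:
            img = replace(blank, channel=ch)
            images[ch] = render_spots(
                img,
                per_channel[ch],
                spec,
                rng=streams[f"render_{ch}"],
                tail_point=nucleus.tail_point,
            )

    return CellSim(
        cell_id=cell_id,
        subject=subject,
        seed_entropy=key,
        nucleus=nucleus,
        dapi=dapi,
        images=images,
        spots=spots,
    )


def iter_cohort_cells(
    spec: SyntheticSpec,
    channels: Sequence[str] = FISH_CHANNELS,
    treated: bool = True,
    render: bool = True,
) -> Iterator[CellSim]:
    """Yield every cell of the cohort, one at a time (bounded memory)."""
    for s in range(1, spec.n_subjects + 1):
        for c in range(1, spec.cells_per_subject + 1):
            yield simulate_cell(
                spec,
                cell_id=f"S{s:02d}_C{c:03d}",
                subject=s,
                cell_index=c,
                treated=treated,
                channels=channels,
                render=render,
            )


def simulate_cohort(
    spec: SyntheticSpec,
    out_dir=None,
    channels: Sequence[str] = FISH_CHANNELS,
    treated: bool = True,
    write_images: bool = False,
    overwrite: bool = False,
):
    """Simulate the full cohort and (optionally) persist it.

    Returns ``(manifest, ground_truth)`` pandas frames.  With ``out_dir`` the
    ground truth and manifest are written as CSV and, if ``write_images`` is
    set, every channel of every cell is written as a TIFF stack with a JSON
    voxel-size sidecar.  Per-cell seeds derive deterministically from
    ``spec.seed``, so re-running with the same spec reproduces byte-identical
    tables.  An existing non-empty ``out_dir`` is refused unless
    ``overwrite`` is set.
    """
    import pandas as pd

    from .io import ground_truth_to_frame, save_stack

    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(
                f"output directory {out_dir} is not empty (pass overwrite=True)"
            )
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    all_spots: List[GroundTruthSpot] = []
    for cell in iter_cohort_cells(
        spec, channels=channels, treated=treated, render=write_images
    ):
        all_spots.extend(cell.spots)
        tail, head = cell.nucleus.tail_point, cell.nucleus.head_point
        row = {
            "cell_id": cell.cell_id,
            "subject": cell.subject,
            "seed_entropy": "-".join(map(str, cell.seed_entropy)),
            "treated": treated,
            "n_spots": len(cell.spots),
            "voxel_size_um": "x".join(f"{v:g}" for v in spec.voxel_size),
            "tail_x": tail[0], "tail_y": tail[1], "tail_z": tail[2],
            "head_x": head[0], "head_y": head[1], "head_z": head[2],
        }
        if out_dir is not None and write_images:
            for ch, img in cell.images.items():
                path = out_dir / f"{cell.cell_id}_{ch}.tiff"
                save_stack(img, path)
                row[f"path_{ch}"] = path.name
            dapi_path = out_dir / f"{cell.cell_id}_dapi.tiff"
            save_stack(cell.dapi, dapi_path)
            row["path_dapi"] = dapi_path.name
        manifest_rows.append(row)

    manifest = pd.DataFrame(manifest_rows)
    ground_truth = ground_truth_to_frame(all_spots)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, ground_truth
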