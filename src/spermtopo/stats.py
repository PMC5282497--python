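"""Randomness and reproducibility statistics.

The primary inferential tool is the Pearson chi-squared goodness-of-fit test
of region counts against a null of spatial randomness.  Two nulls are
offered and always reportable side by side:

* ``equal_thirds`` - each region expected to hold one third of the signals
  (the reading consistent with the source study's p-values, even though the
  thirds-of-radius regions are not of equal volume);
* ``monte_carlo_volume`` - region fractions of uniform random points inside
  the actual nuclear mask, i.e. a volume-weighted geometric null.

Method agreement (3D vs 2D) uses a two-tailed paired t-test on per-subject
values; between-subject reproducibility uses a chi-squared test of
homogeneity on the subject x region count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .topology import distance_map, radial_region_indices, sample_distance_map
from .types import NucleusModel


@dataclass
class GofResult:
    observed: np.ndarray
    expected_fractions: np.ndarray
    chi2: float
    degrees_of_freedom: int
    p_value: float
    null_kind: str = "equal_thirds"


@dataclass
class MonteCarloNull:
    fractions: np.ndarray
    standard_errors: np.ndarray
    n_points: int


@dataclass
class MethodComparisonResult:
    values_3d: np.ndarray
    values_2d: np.ndarray
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass
class HomogeneityResult:
    chi2: float
    df: int
    p_value: float
    n_subjects: int
    dropped_rows: Tuple[int, ...] = ()


def chisq_gof(
    counts: Sequence[int],
    expected_fractions: Optional[Sequence[float]] = None,
    null_kind: str = "equal_thirds",
) -> GofResult:
    """Pearson chi-squared goodness of fit with df = k - 1.

    ``expected_fractions`` defaults to equal occupancy.  Warns when any
    expected count falls below 5 (chi-squared approximation unreliable).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count is zero; nothing to test")
    k = len(counts)
    if expected_fractions is None:
        expected_fractions = np.full(k, 1.0 / k)
    expected_fractions = np.asarray(expected_fractions, dtype=float)
    if len(expected_fractions) != k:
        raise ValueError("counts and expected fractions differ in length")
    if np.any(expected_fractions <= 0):
        raise ValueError("expected fractions must all be positive")
    if abs(expected_fractions.sum() - 1.0) > 1e-9:
        raise ValueError("expected fractions must sum to 1")
    expected = total * expected_fractions
    if np.any(expected < 5):
        warnings.warn(
            "some expected counts are below 5; the chi-squared approximation "
            "may be unreliable",
            stacklevel=2,
        )
    chi2, p = sps.chisquare(counts, f_exp=expected)
    return GofResult(
        observed=counts.astype(int),
        expected_fractions=expected_fractions,
        chi2=float(chi2),
        degrees_of_freedom=k - 1,
        p_value=float(p),
        null_kind=null_kind,
    )


def monte_carlo_region_null(
    nucleus: NucleusModel,
    n_points: int = 100_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> MonteCarloNull:
    """Volume-weighted radial null: region fractions of uniform mask points.

    Points are drawn uniformly over the mask volume (random mask voxel plus a
    uniform within-voxel offset), their distances to the border taken from the
    distance transform, and regions assigned exactly as for real signals.
    Standard errors are binomial.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if nucleus.widest_diameter_D is None:
        raise ValueError("nucleus needs a widest-diameter measurement")
    if rng is None:
        rng = np.random.default_rng(seed)
    vs = np.asarray(nucleus.voxel_size)
    vox = np.argwhere(nucleus.mask)
    pick = rng.integers(0, len(vox), size=n_points)
    idx = vox[pick] + rng.uniform(-0.5, 0.5, size=(n_points, 3))
    pts = ((idx + 0.5) * vs)[:, ::-1]  # (z,y,x) indices -> (x,y,z) um
    edt = distance_map(nucleus.mask, nucleus.voxel_size)
    d = sample_distance_map(edt, nucleus.voxel_size, pts)
    regions = radial_region_indices(d, nucleus.widest_diameter_D / 2.0)
    frac = np.bincount(regions, minlength=3) / n_points
    se = np.sqrt(frac * (1 - frac) / n_points)
    return MonteCarloNull(fractions=frac, standard_errors=se, n_points=n_points)


def paired_method_comparison(
    values_3d: Sequence[float], values_2d: Sequence[float]
) -> MethodComparisonResult:
    """Two-tailed paired t-test on per-subject 3D vs 2D values.

    Identical vectors give p = 1 by convention; zero variance of the
    differences with a non-zero mean is reported as a degenerate case
    (|t| = inf, p = 0) rather than an error.
    """
    a = np.asarray(values_3d, dtype=float)
    b = np.asarray(values_2d, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired comparison needs at least two pairs")
    diff = a - b
    mean = float(diff.mean())
    if np.allclose(diff, diff[0]):
        if mean == 0.0:
            return MethodComparisonResult(a, b, 0.0, 0.0, n - 1, 1.0)
        t = np.inf if mean > 0 else -np.inf
        return MethodComparisonResult(a, b, mean, t, n - 1, 0.0, degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return MethodComparisonResult(a, b, mean, float(t), n - 1, float(p))


def subject_homogeneity(
    subject_by_region_counts: np.ndarray,
) -> HomogeneityResult:
    """Chi-squared test of homogeneity across subjects (no continuity correction).

    Rows are subjects, columns regions; zero rows are dropped with a warning.
    df = (S - 1)(k - 1).
    """
    table = np.asarray(subject_by_region_counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a 2D subject x region count table")
    row_tot = table.sum(axis=1)
    dropped = tuple(int(i) for i in np.where(row_tot == 0)[0])
    if dropped:
        warnings.warn(
            f"dropping all-zero subject rows {list(dropped)}", stacklevel=2
        )
        table = table[row_tot > 0]
    if table.shape[0] < 2:
        raise ValueError("homogeneity test needs at least two non-empty subjects")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return HomogeneityResult(
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        n_subjects=table.shape[0],
        dropped_rows=dropped,
    )
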