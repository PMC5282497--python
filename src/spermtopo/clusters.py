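"""Cluster counting and chromocenter colocalization.

Telomeres and centromeres aggregate in sperm nuclei; clusters are formed by
single-linkage agglomeration of signal centroids at a merge radius (default
0.3 um, about the lateral resolution limit).  Probe signals (NOR,
centromeres 1/5/19) are associated with their nearest chromocenter within a
proximity radius, and an exact combinatorial null - each signal independently
and uniformly assigned to one of the chromocenters - gives the chance
distribution of the number of distinct chromocenters hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .types import FishSignal

MERGE_RADIUS = 0.3  # um
PROXIMITY = 0.5  # um


@dataclass
class ClusterRecord:
    cell_id: str
    channel: str
    cluster_id: int
    member_centroids: np.ndarray
    merged_centroid: np.ndarray
    size: int


@dataclass
class ColocalizationRecord:
    cell_id: str
    probe_set: str
    n_discrete_signals: int
    n_distinct_chromocenters_associated: int
    all_in_one: bool
    shares_chromocenter_with_other_probe_set: Optional[bool] = None
    n_unassociated: int = 0
    no_chromocenters: bool = False
    assigned_chromocenters: Tuple[int, ...] = ()


def _positions(signals: Union[Sequence[FishSignal], np.ndarray]) -> np.ndarray:
    if isinstance(signals, np.ndarray):
        return np.atleast_2d(signals)
    return np.array([s.centroid for s in signals], dtype=float).reshape(
        len(list(signals)), -1
    )


def count_clusters(
    signals: Union[Sequence[FishSignal], np.ndarray],
    merge_radius: float = MERGE_RADIUS,
    cell_id: str = "",
    channel: str = "",
) -> List[ClusterRecord]:
    """Single-linkage clusters of signal centroids at ``merge_radius``.

    Two signals are linked when their centroids are within ``merge_radius``
    (inclusive); linkage is transitive.  ``merge_radius = 0`` returns one
    cluster per signal.
    """
    if merge_radius < 0:
        raise ValueError("merge_radius must be >= 0")
    signals = list(signals) if not isinstance(signals, np.ndarray) else signals
    pos = _positions(signals)
    n = len(pos)
    if n == 0:
        return []
    if not channel and not isinstance(signals, np.ndarray):
        channels = {s.channel for s in signals}
        channel = channels.pop() if len(channels) == 1 else "mixed"
    if merge_radius == 0:
        comp = np.arange(n)
    else:
        pairs = cKDTree(pos).query_pairs(merge_radius, output_type="ndarray")
        ij = np.concatenate([pairs, pairs[:, ::-1]]) if len(pairs) else np.empty((0, 2), int)
        graph = coo_matrix(
            (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n)
        )
        _, comp = connected_components(graph, directed=False)
    records = []
    for cid in range(comp.max() + 1):
        members = pos[comp == cid]
        records.append(
            ClusterRecord(
                cell_id=cell_id,
                channel=channel,
                cluster_id=cid,
                member_centroids=members,
                merged_centroid=members.mean(axis=0),
                size=len(members),
            )
        )
    return records


def associate_with_chromocenters(
    probe_signals: Union[Sequence[FishSignal], np.ndarray],
    chromocenter_clusters: Sequence[ClusterRecord],
    proximity: float = PROXIMITY,
    cell_id: str = "",
    probe_set: str = "",
) -> ColocalizationRecord:
    """Assign each probe signal to its nearest chromocenter within ``proximity``.

    Signals beyond ``proximity`` of every chromocenter stay unassociated and
    do not contribute to the distinct-chromocenter count.  A cell with no
    chromocenters yields a flagged record, not an error.
    """
    pos = _positions(probe_signals)
    n = len(pos)
    if not chromocenter_clusters:
        return ColocalizationRecord(
            cell_id=cell_id,
            probe_set=probe_set,
            n_discrete_signals=n,
            n_distinct_chromocenters_associated=0,
            all_in_one=False,
            n_unassociated=n,
            no_chromocenters=True,
        )
    centers = np.array([c.merged_centroid for c in chromocenter_clusters])
    assigned: List[int] = []
    unassoc = 0
    for p in pos:
        d = np.linalg.norm(centers - p, axis=1)
        j = int(np.argmin(d))
        if d[j] <= proximity:
            assigned.append(chromocenter_clusters[j].cluster_id)
        else:
            unassoc += 1
    distinct = sorted(set(assigned))
    return ColocalizationRecord(
        cell_id=cell_id,
        probe_set=probe_set,
        n_discrete_signals=n,
        n_distinct_chromocenters_associated=len(distinct),
        all_in_one=(len(distinct) == 1 and unassoc == 0 and n >= 1),
        n_unassociated=unassoc,
        assigned_chromocenters=tuple(distinct),
    )


def colocalize_pair(
    probe_a: Union[Sequence[FishSignal], np.ndarray],
    probe_b: Union[Sequence[FishSignal], np.ndarray],
    chromocenter_clusters: Sequence[ClusterRecord],
    proximity: float = PROXIMITY,
    cell_id: str = "",
    probe_sets: Tuple[str, str] = ("NOR", "cen_1_5_19"),
) -> Tuple[ColocalizationRecord, ColocalizationRecord]:
    """Associate two probe sets and flag chromocenters hit by both."""
    rec_a = associate_with_chromocenters(
        probe_a, chromocenter_clusters, proximity, cell_id, probe_sets[0]
    )
    rec_b = associate_with_chromocenters(
        probe_b, chromocenter_clusters, proximity, cell_id, probe_sets[1]
    )
    shared = bool(
        set(rec_a.assigned_chromocenters) & set(rec_b.assigned_chromocenters)
    )
    rec_a.shares_chromocenter_with_other_probe_set = shared
    rec_b.shares_chromocenter_with_other_probe_set = shared
    return rec_a, rec_b


# ---------------------------------------------------------------------------
# exact occupancy null
# ---------------------------------------------------------------------------

def _stirling2(n: int, j: int) -> int:
    """Stirling number of the second kind via inclusion-exclusion."""
    if j < 0 or j > n:
        return 0
    total = 0
    for i in range(j + 1):
        total += (-1) ** i * comb(j, i) * (j - i) ** n
    return total // _factorial(j)


def _factorial(j: int) -> int:
    out = 1
    for i in range(2, j + 1):
        out *= i
    return out


def _pmf_stirling(n_signals: int, n_chromocenters: int) -> Dict[int, Fraction]:
    """P(j distinct) = S(n, j) * k! / (k - j)! / k^n, exact."""
    k = n_chromocenters
    denom = k**n_signals
    pmf: Dict[int, Fraction] = {}
    for j in range(1, min(n_signals, k) + 1):
        falling = 1
        for i in range(j):
            falling *= k - i
        pmf[j] = Fraction(_stirling2(n_signals, j) * falling, denom)
    return pmf


def _pmf_enumeration(n_signals: int, n_chromocenters: int) -> Dict[int, Fraction]:
    """Full enumeration over all k^n assignments (small inputs only)."""
    k = n_chromocenters
    counts: Dict[int, int] = {}
    for assign in product(range(k), repeat=n_signals):
        j = len(set(assign))
        counts[j] = counts.get(j, 0) + 1
    total = k**n_signals
    return {j: Fraction(c, total) for j, c in sorted(counts.items())}


def null_colocalization_pmf(
    n_signals: int, n_chromocenters: int
) -> Dict[int, Fraction]:
    """Chance distribution of distinct chromocenters hit by ``n_signals``.

    Under the null each signal independently and uniformly picks one of the
    ``n_chromocenters``.  Exact rational probabilities are returned, computed
    by full enumeration for small inputs and by the Stirling-number closed
    form otherwise (the two routes agree; see the test suite).
    """
    if n_signals < 1 or n_chromocenters < 1:
        raise ValueError("need at least one signal and one chromocenter")
    if n_chromocenters**n_signals <= 300_000:
        return _pmf_enumeration(n_signals, n_chromocenters)
    return _pmf_stirling(n_signals, n_chromocenters)
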