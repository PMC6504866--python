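"""Distance-based species delimitation.

Two delimiters operate on a pairwise distance matrix:

* **Single-linkage threshold clustering** — groups are the connected
  components of the graph whose edges join pairs at distance ≤ threshold.
  This is the clustering core of BOLD's RESL procedure (without its
  proprietary refinement stage) and of "objective clustering" tools.

* **Recursive barcode-gap partitioning** — an ABGD-style procedure.  The
  sorted pairwise distances are scanned for the first significant gap above
  a prior maximal intraspecific distance (PMID); a gap is significant when
  it exceeds X times the mean of the preceding gaps (window of up to 10),
  X being the relative gap width.  The matrix is split by single linkage at
  the gap midpoint and the scan recurses independently inside every
  subgroup, so different groups may end up delimited at different
  thresholds.  The gap-significance rule here is a concrete, documented
  variant of the ABGD heuristic, not a re-implementation of the original
  binary.

Undefined (saturated) distances are treated as +infinity: never an edge,
never a scanned distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .io_formats import Partition

__all__ = [
    "AbgdParams",
    "DEFAULT_PRIOR_GRID",
    "DEFAULT_X_VALUES",
    "single_linkage_partition",
    "detect_gap",
    "abgd_partition",
    "abgd_scan",
]

# Logarithmic prior series from 0.001 to 0.1 (10 steps), the published
# default grid for barcode-gap scanning.
DEFAULT_PRIOR_GRID: tuple[float, ...] = tuple(
    float(v) for v in np.round(np.logspace(-3, -1, 10), 6)
)
DEFAULT_X_VALUES: tuple[float, ...] = (1.0, 1.5)

GAP_WINDOW = 10  # gaps averaged when judging significance


@dataclass(frozen=True)
class AbgdParams:
    """Recursive barcode-gap partitioning parameters."""

    pmid: float
    X: float = 1.5
    max_depth: int = 20

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError("pmid must be > 0")
        if self.X <= 0:
            raise ValueError("X must be > 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def _components(d: np.ndarray, threshold: float) -> np.ndarray:
    """Connected-component labels of the d <= threshold graph (NaN = no edge)."""
    with np.errstate(invalid="ignore"):
        adj = (d <= threshold) & ~np.isnan(d)
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def single_linkage_partition(m: DistanceMatrix, threshold: float) -> Partition:
    """Cluster at a fixed distance threshold (single linkage)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    labels = _components(m.d, threshold)
    assignment = dict(zip(m.ids, (int(v) for v in labels)))
    return Partition(
        method="single-linkage", assignment=assignment, params={"threshold": threshold}
    ).renumbered()


def detect_gap(sorted_dists: np.ndarray, pmid: float, X: float) -> float | None:
    """Locate the first significant gap in an ascending distance list.

    Consecutive gaps g_i = d[i+1] - d[i] are examined only where the gap
    reaches the prior, d[i+1] >= pmid — distances entirely below the prior
    are presumed intraspecific and cannot end a significant gap.  g_i is
    significant when g_i > X * w_i, with w_i the mean of the up-to-10
    preceding gaps (none preceding -> the gap cannot be judged, skip).
    Returns the midpoint of the first significant gap, or None when no gap
    qualifies.
    """
    d = np.asarray(sorted_dists, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        return None
    gaps = np.diff(d)
    for i in range(len(gaps)):
        if d[i + 1] < pmid:
            continue
        lo = max(0, i - GAP_WINDOW)
        if i == lo:
            continue  # no preceding gaps to compare against
        w = float(gaps[lo:i].mean())
        if gaps[i] > X * w:
            return float((d[i] + d[i + 1]) / 2.0)
    return None


def _pairwise_sorted(d: np.ndarray) -> np.ndarray:
    vals = d[np.triu_indices(d.shape[0], k=1)]
    vals = vals[~np.isnan(vals)]
    vals.sort()
    return vals


def abgd_partition(m: DistanceMatrix, p: AbgdParams) -> Partition:
    """Recursive barcode-gap partition of a distance matrix.

    Group ids are assigned in discovery order (depth-first, groups ordered
    by their first member's position in ``m.ids``).
    """
    n = len(m.ids)
    assignment: dict[str, int] = {}
    next_group = itertools.count()

    def recurse(idx: np.ndarray, depth: int) -> None:
        ids_here = [m.ids[i] for i in idx]
        if len(idx) == 1 or depth > p.max_depth:
            g = next(next_group)
            for seq_id in ids_here:
                assignment[seq_id] = g
            return
        sub = m.d[np.ix_(idx, idx)]
        threshold = detect_gap(_pairwise_sorted(sub), p.pmid, p.X)
        if threshold is None:
            g = next(next_group)
            for seq_id in ids_here:
                assignment[seq_id] = g
            return
        labels = _components(sub, threshold)
        if labels.max() == 0:  # gap found but no split at its midpoint
            g = next(next_group)
            for seq_id in ids_here:
                assignment[seq_id] = g
            return
        order: list[int] = []
        for lab in labels:
            if lab not in order:
                order.append(lab)
        for lab in order:
            recurse(idx[labels == lab], depth + 1)

    recurse(np.arange(n), 1)
    return Partition(
        method="abgd-recursive",
        assignment={seq_id: assignment[seq_id] for seq_id in m.ids},
        params={"pmid": p.pmid, "X": p.X},
    )


def abgd_scan(
    m: DistanceMatrix,
    priors: tuple[float, ...] = DEFAULT_PRIOR_GRID,
    x_values: tuple[float, ...] = DEFAULT_X_VALUES,
    max_depth: int = 20,
) -> list[Partition]:
    """One recursive partition per (PMID, X) combination."""
    if not priors or not x_values:
        raise ValueError("priors and x_values must be nonempty")
    out = []
    for x in x_values:
        for pmid in priors:
            out.append(abgd_partition(m, AbgdParams(pmid=pmid, X=x, max_depth=max_depth)))
    return out


def scan_summary(partitions: list[Partition]):
    """(pmid, X, n_groups) rows for a set of scanned partitions."""
    import pandas as pd

    rows = [
        {
            "pmid": p.params.get("pmid"),
            "X": p.params.get("X"),
            "n_groups": p.n_groups,
        }
        for p in partitions
    ]
    return pd.DataFrame(rows, columns=["pmid", "X", "n_groups"])
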