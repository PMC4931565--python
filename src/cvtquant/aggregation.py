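"""Particle-aggregation statistics on EM coordinate fields.

Dodecamer centers picked from negative-stain micrographs are grouped
into assemblies by single-linkage clustering (particles closer than a
link distance belong to one chain), classed as single / double /
triple / multiple (>= 4), and two conditions are compared with
Pearson's chi-squared test on the resulting 2 x k contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial import cKDTree

__all__ = [
    "AssemblyClassCounts",
    "DEFAULT_LINK_DISTANCE",
    "cluster_particles",
    "classify_assemblies",
    "chi_squared_independence",
]

# 18 nm dodecamer diameter plus 20% tolerance for picking jitter.
DEFAULT_LINK_DISTANCE = 21.6

CLASS_NAMES = ("single", "double", "triple", "multiple")


@dataclass
class AssemblyClassCounts:
    """Per-condition counts of assemblies in each size class."""

    condition: str
    single: int
    double: int
    triple: int
    multiple: int
    n_particles: int

    @property
    def n_assemblies(self) -> int:
        return self.single + self.double + self.triple + self.multiple

    def as_array(self) -> np.ndarray:
        return np.array([self.single, self.double, self.triple, self.multiple])


def cluster_particles(
    records: pd.DataFrame, link_distance: float = DEFAULT_LINK_DISTANCE
) -> list[list[int]]:
    """Single-linkage assemblies of particle centers.

    ``records`` needs columns ``micrograph_id, x_nm, y_nm``.  Two
    particles are linked when their center distance is at most
    ``link_distance`` (nm); assemblies are the connected components of
    the link graph, never crossing micrograph boundaries.  Returns
    lists of positional (iloc) indices into ``records``.
    """
    if link_distance <= 0:
        raise ValueError("link_distance must be positive")
    assemblies: list[list[int]] = []
    xy = records[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("particle coordinates must be finite")
    groups = records.groupby("micrograph_id", sort=True).indices
    for mic in sorted(groups):
        idx = np.asarray(groups[mic])
        pts = xy[idx]
        n = len(pts)
        if n == 1:
            assemblies.append([int(idx[0])])
            continue
        tree = cKDTree(pts)
        pairs = tree.query_pairs(link_distance, output_type="ndarray")
        graph = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
        for c in range(n_comp):
            assemblies.append([int(i) for i in idx[labels == c]])
    return assemblies


def classify_assemblies(
    assemblies: list[list[int]], condition: str = ""
) -> AssemblyClassCounts:
    """Class assemblies by size: 1, 2, 3 map to single/double/triple,
    >= 4 to multiple."""
    sizes = np.array([len(a) for a in assemblies], dtype=int)
    return AssemblyClassCounts(
        condition=condition,
        single=int((sizes == 1).sum()),
        double=int((sizes == 2).sum()),
        triple=int((sizes == 3).sum()),
        multiple=int((sizes >= 4).sum()),
        n_particles=int(sizes.sum()),
    )


def chi_squared_independence(
    counts_a: AssemblyClassCounts | np.ndarray,
    counts_b: AssemblyClassCounts | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a 2 x k table.

    No continuity correction; classes empty in both conditions are
    dropped (their expected counts would be zero).  The p-value is the
    upper chi-square tail, reported unfloored.
    """
    row_a = counts_a.as_array() if isinstance(counts_a, AssemblyClassCounts) else np.asarray(counts_a)
    row_b = counts_b.as_array() if isinstance(counts_b, AssemblyClassCounts) else np.asarray(counts_b)
    table = np.vstack([row_a, row_b]).astype(float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("need at least 2 classes with observations")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("each condition needs at least one observation")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
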