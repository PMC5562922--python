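"""From ROI time series to density-thresholded binary undirected networks.

A subject's functional connectivity is the matrix of pairwise Pearson
correlations between region time courses (diagonal set to zero).  Binary
networks are obtained by keeping, at a given connection density d, the
round(d * n(n-1)/2) strongest edges.  Two data-driven rules fix the endpoints
of the density sweep used downstream:

* minimum density — the smallest grid density at which every subject's
  network is fully connected;
* maximum density — the largest fraction of edges such that, for every
  subject, all retained edges survive a per-subject Benjamini-Hochberg FDR
  correction of the correlation p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConnectivityMatrix",
    "DensitySweep",
    "BinaryNetwork",
    "edge_budget",
    "pearson_connectivity",
    "threshold_by_density",
    "build_sweep_networks",
    "find_min_connected_density",
    "find_max_density_fdr",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with elementwise two-sided
    p-values; the diagonal of ``r`` is fixed to zero and the diagonal of
    ``p`` is undefined (NaN)."""

    r: np.ndarray
    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or self.p.shape != (n, n):
            raise ValueError("r and p must be square matrices of equal shape")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("r must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.any(np.diag(self.r) != 0.0):
            raise ValueError("diagonal of r must be exactly zero")
        off = ~np.eye(n, dtype=bool)
        if np.any((self.p[off] < 0) | (self.p[off] > 1)):
            raise ValueError("off-diagonal p-values must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class DensitySweep:
    """Inclusive density grid ``d_min, d_min+step, ..., d_max``.

    The default grid, 24.5% to 30% in steps of 0.5%, has 12 densities.
    """

    d_min: float = 0.245
    d_max: float = 0.300
    step: float = 0.005
    densities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.d_min <= self.d_max < 1:
            raise ValueError("require 0 < d_min <= d_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = int(math.floor((self.d_max - self.d_min) / self.step + 0.5)) + 1
        self.densities = np.round(self.d_min + self.step * np.arange(n), 10)

    def __len__(self) -> int:
        return len(self.densities)


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph at a requested connection density."""

    adjacency: np.ndarray
    density: float

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.dtype != np.uint8:
            self.adjacency = self.adjacency.astype(np.uint8)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric (undirected)")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.all((self.adjacency == 0) | (self.adjacency == 1)):
            raise ValueError("adjacency must be 0/1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def edge_budget(density: float, n_nodes: int) -> int:
    """Number of edges retained at a density: round-half-away-from-zero of
    density * n(n-1)/2."""
    return _round_half_away(density * n_nodes * (n_nodes - 1) / 2)


def pearson_connectivity(timeseries, n_samples: int | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation matrix of region time courses.

    ``timeseries`` is an (n_regions x n_timepoints) array or a
    :class:`~fcnet.cohort.SubjectRecord`.  p-values come from the exact
    t-transform of r with n-2 degrees of freedom, two-sided.  Raises on
    fewer than 3 timepoints or any zero-variance region (named in the
    message).
    """
    ts = getattr(timeseries, "timeseries", timeseries)
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (regions x timepoints)")
    n_regions, n_tp = ts.shape
    if n_tp < 3:
        raise ValueError(f"need at least 3 timepoints, got {n_tp}")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance region(s): {bad.tolist()}")

    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    df = n_tp - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0  # |r| == 1 exactly
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(p, np.nan)
    return ConnectivityMatrix(r=r, p=p, n_samples=n_tp)


def _ranked_edges(cm: ConnectivityMatrix, ranking: str = "signed"):
    """Upper-triangle pairs sorted by decreasing edge strength; ties broken
    by ascending (i, j) for determinism."""
    n = cm.n_regions
    iu, ju = np.triu_indices(n, k=1)
    vals = cm.r[iu, ju]
    if ranking == "absolute":
        key = -np.abs(vals)
    elif ranking == "signed":
        key = -vals
    else:
        raise ValueError("ranking must be 'signed' or 'absolute'")
    order = np.lexsort((ju, iu, key))
    return iu[order], ju[order]


def threshold_by_density(
    cm: ConnectivityMatrix, density: float, ranking: str = "signed"
) -> BinaryNetwork:
    """Binary undirected network keeping the ``edge_budget(density, n)``
    strongest edges (largest signed r by default; ``ranking='absolute'``
    ranks by |r|)."""
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    n = cm.n_regions
    k = edge_budget(density, n)
    if k == 0:
        raise ValueError(f"density {density} yields an empty edge budget for n={n}")
    ei, ej = _ranked_edges(cm, ranking)
    A = np.zeros((n, n), dtype=np.uint8)
    A[ei[:k], ej[:k]] = 1
    A |= A.T
    return BinaryNetwork(adjacency=A, density=density)


def build_sweep_networks(
    cm: ConnectivityMatrix, sweep: DensitySweep, ranking: str = "signed"
) -> list[BinaryNetwork]:
    """One network per sweep density, built from a single edge ranking so
    edge sets are nested across densities."""
    n = cm.n_regions
    ei, ej = _ranked_edges(cm, ranking)
    nets = []
    A = np.zeros((n, n), dtype=np.uint8)
    filled = 0
    for d in sweep.densities:
        k = edge_budget(float(d), n)
        if k == 0:
            raise ValueError(f"density {d} yields an empty edge budget for n={n}")
        if k > filled:
            A[ei[filled:k], ej[filled:k]] = 1
            A[ej[filled:k], ei[filled:k]] = 1
            filled = k
        nets.append(BinaryNetwork(adjacency=A.copy(), density=float(d)))
    return nets


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.n_components = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb
            self.n_components -= 1


def _min_edges_for_connectivity(cm: ConnectivityMatrix, ranking: str) -> int:
    """Smallest top-k edge prefix whose graph is connected."""
    ei, ej = _ranked_edges(cm, ranking)
    uf = _UnionFind(cm.n_regions)
    for k, (a, b) in enumerate(zip(ei, ej), start=1):
        uf.union(int(a), int(b))
        if uf.n_components == 1:
            return k
    raise ValueError("graph never becomes connected (degenerate input)")


def find_min_connected_density(
    cohort_cms: list[ConnectivityMatrix],
    sweep_step: float = 0.005,
    ranking: str = "signed",
) -> float:
    """Smallest density on the step grid at which every subject's thresholded
    network is a single connected component, found by scanning the grid
    upward from the first point with a nonzero edge budget."""
    if not cohort_cms:
        raise ValueError("need at least one subject")
    n = cohort_cms[0].n_regions
    need = max(_min_edges_for_connectivity(cm, ranking) for cm in cohort_cms)
    k = 1
    while k * sweep_step < 1.0:
        d = round(k * sweep_step, 10)
        if edge_budget(d, n) >= need:
            return d
        k += 1
    raise ValueError("no density below 1 connects every subject's network")


def find_max_density_fdr(
    cohort_cms: list[ConnectivityMatrix], q: float = 0.05
) -> float:
    """Largest edge fraction at which every retained edge is FDR-significant
    for every subject.

    Per subject, Benjamini-Hochberg at level ``q`` is applied to the
    n(n-1)/2 unique correlation p-values and the significant fraction is
    recorded; the minimum fraction across subjects is returned, so any
    density at or below it keeps only FDR-surviving edges for the whole
    cohort.
    """
    if not cohort_cms:
        raise ValueError("need at least one subject")
    fracs = []
    for cm in cohort_cms:
        iu = np.triu_indices(cm.n_regions, k=1)
        pvals = cm.p[iu]
        if pvals.size == 0 or np.any(np.isnan(pvals)):
            raise ValueError("p-values missing or not populated")
        reject = multipletests(pvals, alpha=q, method="fdr_bh")[0]
        fracs.append(reject.sum() / pvals.size)
    return float(min(fracs))
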