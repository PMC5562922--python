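"""Degree-matched random networks and normalized global metrics.

The normalized clustering coefficient C_nor and normalized path length
L_nor divide a network's C and L by their means over an ensemble of
degree-preserving randomized versions of the same network (Maslov-Sneppen
double-edge swaps).  Values of C_nor well above 1 with L_nor near 1 are the
small-world signature these analyses look for.

Connectivity is not enforced on rewired graphs — enforcement would bias the
null; disconnected ensemble members contribute their reachable-pair L and
are tallied.  An Erdos-Renyi null (matched n and edge count only) is
available as an alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import BinaryNetwork
from .metrics import characteristic_path_length, clustering_coefficient

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "rewire_degree_preserving",
    "erdos_renyi_match",
    "null_ensemble",
    "normalized_global_metrics",
]


@dataclass
class NullEnsemble:
    """Summary of a randomized-network ensemble."""

    n_random: int
    mean_C_rand: float
    mean_L_rand: float
    C_rand: np.ndarray = field(repr=False)
    L_rand: np.ndarray = field(repr=False)
    n_disconnected: int = 0


def rewire_degree_preserving(
    net: BinaryNetwork,
    n_swaps: int | None = None,
    rng: np.random.Generator | None = None,
) -> BinaryNetwork:
    """Randomize a network by repeated double-edge swaps that preserve every
    node's degree exactly.

    Each attempt picks two edges (a,b), (c,d) and proposes (a,d), (c,b);
    the swap is applied only if it creates no self-loop and no duplicate
    edge.  Failed attempts are skipped (and counted in a debug log).  The
    default budget is 10 * |E| attempts.
    """
    if rng is None:
        rng = np.random.default_rng()
    ei, ej = np.nonzero(np.triu(net.adjacency, k=1))
    m = len(ei)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    # python-native edge bookkeeping: the tight proposal loop is much faster
    # on lists/sets than on per-element numpy indexing
    edges = list(zip(ei.tolist(), ej.tolist()))
    edge_set = set(edges)
    attempts = 10 * m if n_swaps is None else int(n_swaps)

    pick = rng.integers(0, m, size=(attempts, 2)).tolist()
    flip = (rng.random(attempts) < 0.5).tolist()
    accepted = failed = 0
    for (e1, e2), f in zip(pick, flip):
        if e1 == e2:
            failed += 1
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if f:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            failed += 1
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in edge_set or new2 in edge_set:
            failed += 1
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        accepted += 1
    logger.debug("rewiring: %d accepted, %d failed of %d attempts",
                 accepted, failed, attempts)
    n = net.n_nodes
    A = np.zeros((n, n), dtype=np.uint8)
    idx = np.array(edges)
    A[idx[:, 0], idx[:, 1]] = 1
    A |= A.T
    return BinaryNetwork(adjacency=A, density=net.density)


def erdos_renyi_match(
    net: BinaryNetwork, rng: np.random.Generator | None = None
) -> BinaryNetwork:
    """Random graph with the same node and edge count (degrees not matched)."""
    if rng is None:
        rng = np.random.default_rng()
    n = net.n_nodes
    m = net.n_edges
    iu, ju = np.triu_indices(n, k=1)
    chosen = rng.choice(len(iu), size=m, replace=False)
    A = np.zeros((n, n), dtype=np.uint8)
    A[iu[chosen], ju[chosen]] = 1
    A |= A.T
    return BinaryNetwork(adjacency=A, density=net.density)


def null_ensemble(
    net: BinaryNetwork,
    n_random: int = 1000,
    rng: np.random.Generator | None = None,
    null_model: str = "rewire",
    n_swaps: int | None = None,
) -> NullEnsemble:
    """Generate an ensemble of matched random networks and record their C
    and L."""
    if rng is None:
        rng = np.random.default_rng()
    if null_model == "rewire":
        draw = lambda: rewire_degree_preserving(net, n_swaps=n_swaps, rng=rng)
    elif null_model == "erdos_renyi":
        draw = lambda: erdos_renyi_match(net, rng=rng)
    else:
        raise ValueError("null_model must be 'rewire' or 'erdos_renyi'")
    Cs = np.empty(n_random)
    Ls = np.empty(n_random)
    n_disc = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # disconnected members are tallied below
        for i in range(n_random):
            g = draw()
            _, Cs[i] = clustering_coefficient(g)
            Ls[i], conn = characteristic_path_length(g)
            n_disc += not conn
    if n_disc:
        logger.info("%d of %d null networks disconnected (reachable-pair L used)",
                    n_disc, n_random)
    return NullEnsemble(
        n_random=n_random,
        mean_C_rand=float(Cs.mean()),
        mean_L_rand=float(Ls.mean()),
        C_rand=Cs,
        L_rand=Ls,
        n_disconnected=n_disc,
    )


def normalized_global_metrics(
    net: BinaryNetwork,
    ensemble_size: int = 1000,
    rng: np.random.Generator | None = None,
    null_model: str = "rewire",
    n_swaps: int | None = None,
    return_ensemble: bool = False,
):
    """C_nor and L_nor: the network's C and L divided by the ensemble means
    of degree-matched random networks.

    Raises if the ensemble mean clustering is zero (degenerate degree
    sequence); warns if the input itself is disconnected.
    """
    _, C = clustering_coefficient(net)
    L, connected = characteristic_path_length(net)
    if not connected:
        warnings.warn("input network is disconnected; L uses reachable pairs",
                      stacklevel=2)
    ens = null_ensemble(net, n_random=ensemble_size, rng=rng,
                        null_model=null_model, n_swaps=n_swaps)
    if ens.mean_C_rand == 0:
        raise ValueError("ensemble mean clustering is zero (degenerate degree "
                         "sequence); C_nor undefined")
    c_nor = C / ens.mean_C_rand
    l_nor = L / ens.mean_L_rand
    if return_ensemble:
        return c_nor, l_nor, ens
    return c_nor, l_nor
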