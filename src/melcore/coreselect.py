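"""Least-distance stepwise core sampling with multiple clustering.

The sampling unit is the "lowest-level subgroup": a dendrogram node whose
two children are both individual accessions. Each round standardizes the
retained accessions (with statistics frozen from the initial collection),
builds a single-linkage dendrogram on Euclidean distances, and removes
one member from each leaf-leaf pair:

* ``random`` — the removed member is chosen uniformly with a seeded RNG;
* ``preferred`` — a member holding a current-collection maximum or
  minimum of any trait is kept; if both members hold extremes, both are
  kept; if neither does, the member farther from the collection centroid
  (larger mean absolute standardized value) is kept, ties broken by
  lexicographic accession ID.

Singleton subgroups pass unchanged to the next round. Rounds repeat until
the core reaches its target size round(proportion * N); a round that
would undershoot is processed in ascending merge-height order and stopped
exactly at the target, so the closest (least-distance) pairs are thinned
first.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from melcore.containers import ClusterTree, CoreSet, TraitMatrix
from melcore.errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def frozen_statistics(values: np.ndarray, trait_names=None) -> tuple[np.ndarray, np.ndarray]:
    """Column means and sample sds of the initial collection.

    These statistics define the standardized Euclidean metric and are
    frozen: later rounds standardize shrinking subsets against them
    rather than re-estimating, so the distance metric does not drift.
    """
    x = np.asarray(values, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (
            [trait_names[i] for i in zero] if trait_names is not None else list(zero)
        )
        raise ParameterError(f"zero-variance trait(s), cannot standardize: {names}")
    return mean, sd


def standardize(values: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None,
                trait_names=None) -> np.ndarray:
    """(x - mean)/sd per column; `stats` supplies frozen mean/sd."""
    x = np.asarray(values, dtype=float)
    if stats is None:
        stats = frozen_statistics(x, trait_names)
    mean, sd = stats
    return (x - mean) / sd


def single_linkage_cluster(std_matrix: np.ndarray) -> ClusterTree:
    """Single-linkage (nearest-distance) dendrogram on Euclidean distances."""
    x = np.asarray(std_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InsufficientDataError("clustering needs >=2 rows")
    z = linkage(x, method="single", metric="euclidean")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return ClusterTree(n_leaves=x.shape[0], merges=merges)


def lowest_level_pairs(tree: ClusterTree) -> list[tuple[int, int]]:
    """Leaf-leaf merge nodes, in ascending merge-height order.

    Every returned pair is a subgroup of exactly two accessions at the
    lowest level of sorting; leaves absent from all pairs are singleton
    subgroups and pass directly to the next round.
    """
    n = tree.n_leaves
    pairs = [(a, b) for a, b, _ in tree.merges if a < n and b < n]
    return pairs  # merge list is height-sorted already


def _extreme_leaves(values: np.ndarray) -> set[int]:
    """Row indices holding the max or min of any column."""
    ext: set[int] = set()
    for j in range(values.shape[1]):
        col = values[:, j]
        ext.update(np.flatnonzero(col == col.max()))
        ext.update(np.flatnonzero(col == col.min()))
    return ext


def stepwise_core(
    tm: TraitMatrix,
    proportion: float,
    strategy: str = "random",
    seed: int | None = None,
    traits: list[str] | None = None,
) -> CoreSet:
    """Build a core collection of round(proportion * N) accessions.

    Parameters
    ----------
    tm : TraitMatrix
        The initial collection.
    proportion : float in (0, 1]
        Sampling proportion; the core size is round-half-up(p * N), with
        a floor of one accession.
    strategy : {"random", "preferred"}
        How to choose which member of a lowest-level pair is removed.
    seed : int, optional
        RNG seed; consumed only by the random strategy.
    traits : list of str, optional
        Trait subset driving standardization and clustering (default all).

    Notes
    -----
    If a preferred round removes nobody (every pair protected by the
    keep-both-extremes rule), the sampler falls back to forced
    truncation: globally closest pairs are thinned first, still
    preferring to keep extreme holders, and the result is flagged
    ``truncated``.
    """
    if not (0.0 < proportion <= 1.0):
        raise ParameterError(f"proportion must be in (0, 1], got {proportion}")
    if strategy not in ("random", "preferred"):
        raise ParameterError(f"unknown strategy {strategy!r}")
    if tm.n < 2:
        raise InsufficientDataError("core sampling needs N >= 2 accessions")

    trait_names = list(traits) if traits else list(tm.trait_names)
    cols = [tm.trait_names.index(t) for t in trait_names]
    x_full = tm.values[:, cols]
    stats = frozen_statistics(x_full, trait_names)
    index = {a: i for i, a in enumerate(tm.accession_ids)}

    n_total = tm.n
    target = max(1, _round_half_up(proportion * n_total))
    retained = list(tm.accession_ids)
    rng = np.random.default_rng(seed)
    rounds = 0
    stopped_mid = False

    if target == n_total:
        return CoreSet(retained, strategy, proportion, seed, rounds=0)

    def raw(ids):
        return x_full[[index[a] for a in ids]]

    def zscores(ids):
        return standardize(raw(ids), stats)

    def choose_drop(a_id: str, b_id: str, extremes: set[str], z_of: dict[str, np.ndarray]):
        """Return the accession to drop, or None to keep both."""
        if strategy == "random":
            return a_id if rng.integers(2) == 0 else b_id
        a_ext, b_ext = a_id in extremes, b_id in extremes
        if a_ext and b_ext:
            return None
        if a_ext:
            return b_id
        if b_ext:
            return a_id
        da = float(np.abs(z_of[a_id]).mean())
        db = float(np.abs(z_of[b_id]).mean())
        if da > db:
            return b_id
        if db > da:
            return a_id
        return max(a_id, b_id)  # keep the lexicographically smaller ID

    while len(retained) > target:
        z = zscores(retained)
        tree = single_linkage_cluster(z)
        pairs = lowest_level_pairs(tree)
        if not pairs:  # unreachable for n >= 2, kept as a guard
            break
        extremes = {retained[i] for i in _extreme_leaves(raw(retained))}
        z_of = {a: z[i] for i, a in enumerate(retained)}
        drop: set[str] = set()
        for ia, ib in pairs:
            if len(retained) - len(drop) == target:
                stopped_mid = True
                break
            victim = choose_drop(retained[ia], retained[ib], extremes, z_of)
            if victim is not None:
                drop.add(victim)
        if not drop:
            break  # no progress possible by pair rules; force-truncate below
        retained = [a for a in retained if a not in drop]
        rounds += 1

    truncated = False
    while len(retained) > target:
        truncated = True
        z = zscores(retained)
        dist = squareform(pdist(z))
        np.fill_diagonal(dist, np.inf)
        order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
        extremes = {retained[i] for i in _extreme_leaves(raw(retained))}
        z_of = {a: z[i] for i, a in enumerate(retained)}
        victim = None
        for ia, ib in order:
            if ia >= ib:
                continue
            victim = choose_drop(retained[ia], retained[ib], extremes, z_of)
            if victim is not None:
                break
        if victim is None:  # every pair both-extreme: sacrifice the least outlying
            ia, ib = next((p, q) for p, q in order if p < q)
            a_id, b_id = retained[ia], retained[ib]
            da = float(np.abs(z_of[a_id]).mean())
            db = float(np.abs(z_of[b_id]).mean())
            if da < db:
                victim = a_id
            elif db < da:
                victim = b_id
            else:
                victim = max(a_id, b_id)
        retained.remove(victim)
    if truncated:
        logger.info(
            "forced truncation engaged to reach target %d (strategy=%s)", target, strategy
        )

    return CoreSet(
        retained,
        strategy,
        proportion,
        seed,
        rounds=rounds,
        truncated=truncated,
        stopped_mid_round=stopped_mid,
    )
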