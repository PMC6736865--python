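"""Independent brute-force oracles used to cross-check the estimators.

Each oracle is deliberately naive (explicit loops, no shared code with
the implementation) so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

ACGT = set("ACGT")


def brute_usable_columns(sequences: list[str]) -> list[int]:
    length = len(sequences[0])
    cols = []
    for j in range(length):
        if all(s[j] in ACGT for s in sequences):
            cols.append(j)
    return cols


def brute_haplotype_counts(sequences: list[str]) -> list[int]:
    cols = brute_usable_columns(sequences)
    keys = ["".join(s[j] for j in cols) for s in sequences]
    counts: dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return list(counts.values())


def brute_hd(counts: list[int]) -> float:
    n = sum(counts)
    return n / (n - 1) * (1.0 - sum((c / n) ** 2 for c in counts))


def brute_pi(sequences: list[str]) -> float:
    """Mean pairwise difference per usable site, by explicit O(n^2) loops."""
    cols = brute_usable_columns(sequences)
    n = len(sequences)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(sequences[i][c] != sequences[j][c] for c in cols)
    npairs = n * (n - 1) // 2
    return total / npairs / len(cols)


def brute_single_linkage(x: np.ndarray):
    """Naive O(n^3) single-linkage agglomeration on Euclidean distances.

    Returns (heights, partitions): merge heights in order and, after each
    merge, the flat partition as a set of frozensets of leaf indices.
    """
    n = x.shape[0]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    clusters: list[set[int]] = [{i} for i in range(n)]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = min(d[i, j] for i in clusters[a] for j in clusters[b])
                if h < best[0]:
                    best = (h, (a, b))
        h, (a, b) = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        heights.append(h)
        partitions.append({frozenset(c) for c in clusters})
    return heights, partitions


def brute_anova(values: np.ndarray, labels) -> dict[str, float]:
    """Two-pass sums-of-squares one-way ANOVA with the n0 estimator."""
    labels = list(labels)
    groups = {}
    for v, l in zip(values, labels):
        groups.setdefault(l, []).append(float(v))
    k = len(groups)
    n = len(labels)
    grand = sum(values) / n
    ss_among = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values())
    ss_within = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups.values()
    )
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (n - k)
    n0 = (n - sum(len(g) ** 2 for g in groups.values()) / n) / (k - 1)
    return dict(
        ms_among=ms_among,
        ms_within=ms_within,
        n0=n0,
        sigma2_among=max(0.0, (ms_among - ms_within) / n0),
        sigma2_within=ms_within,
    )


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     gap_fraction: float = 0.05) -> list[str]:
    """Random sequences sharing polymorphic columns, with sparse gaps/Ns."""
    alphabet = np.array(list("ACGT"), dtype="U1")
    base = rng.choice(alphabet, size=length)
    rows = np.tile(base, (n, 1))
    n_poly = max(1, length // 10)
    poly = rng.choice(length, size=n_poly, replace=False)
    for c in poly:
        carriers = rng.random(n) < 0.4
        rows[carriers, c] = rng.choice(alphabet)
    mask = rng.random((n, length)) < gap_fraction
    rows[mask] = rng.choice(np.array(["-", "N"]), size=mask.sum())
    return ["".join(r) for r in rows]
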