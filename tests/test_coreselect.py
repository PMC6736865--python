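"""Stepwise core sampling: standardization, clustering, pair extraction,
and the random/preferred selection strategies."""

import numpy as np
import pytest

from melcore import coreselect, synthdata
from melcore.containers import TraitMatrix
from melcore.errors import InsufficientDataError, ParameterError
from oracles import brute_single_linkage


def _matrix(values, trait_names=None, species=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    ids = [f"a{i:02d}" for i in range(n)]
    return TraitMatrix(
        ids, species or ["S"] * n, values,
        trait_names or [f"t{j}" for j in range(values.shape[1])],
    )


class TestStandardize:
    def test_unit_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, size=(40, 3))
        z = coreselect.standardize(x)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_two_point_zscores(self):
        z = coreselect.standardize(np.array([[1.0], [3.0]]))
        assert z[:, 0] == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_frozen_statistics_reused_on_subset(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2))
        stats = coreselect.frozen_statistics(x)
        sub = coreselect.standardize(x[:10], stats)
        # a subset standardized against frozen stats is generally off-center
        assert not np.allclose(sub.mean(axis=0), 0, atol=1e-3)
        assert np.allclose(sub, (x[:10] - stats[0]) / stats[1])

    def test_zero_sd_trait_named(self):
        with pytest.raises(ParameterError, match="flat"):
            coreselect.frozen_statistics(
                np.array([[1.0, 2.0], [1.0, 3.0]]), ["flat", "ok"]
            )


class TestSingleLinkage:
    def test_collinear_points_first_merge(self):
        tree = coreselect.single_linkage_cluster(
            np.array([[0.0], [1.0], [10.0]])
        )
        a, b, h = tree.merges[0]
        assert {a, b} == {0, 1} and h == pytest.approx(1.0)

    def test_duplicates_merge_at_zero_first(self):
        tree = coreselect.single_linkage_cluster(
            np.array([[5.0], [5.0], [1.0], [9.0]])
        )
        a, b, h = tree.merges[0]
        assert {a, b} == {0, 1} and h == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=(n, 3))
            tree = coreselect.single_linkage_cluster(x)
            heights, partitions = brute_single_linkage(x)
            assert np.allclose([h for _, _, h in tree.merges], heights, atol=1e-9)
            # replay merge list into flat partitions and compare
            clusters = {i: frozenset([i]) for i in range(n)}
            for k, (a, b, _) in enumerate(tree.merges):
                merged = clusters.pop(a) | clusters.pop(b)
                clusters[n + k] = merged
                assert set(clusters.values()) == partitions[k]


class TestLowestLevelPairs:
    def test_chain_yields_single_pair(self):
        # points 0,1 close; 2 and 3 successively farther -> chain merges
        tree = coreselect.single_linkage_cluster(
            np.array([[0.0], [1.0], [5.0], [20.0]])
        )
        assert coreselect.lowest_level_pairs(tree) == [(0, 1)]

    def test_perfectly_paired_leaves(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1], [20.0], [20.1]])
        pairs = coreselect.lowest_level_pairs(coreselect.single_linkage_cluster(x))
        assert sorted(tuple(sorted(p)) for p in pairs) == [(0, 1), (2, 3), (4, 5)]

    def test_two_leaves(self):
        tree = coreselect.single_linkage_cluster(np.array([[0.0], [1.0]]))
        assert coreselect.lowest_level_pairs(tree) == [(0, 1)]


class TestStepwiseCore:
    def test_identity_at_full_proportion(self):
        tm = _matrix(np.arange(10.0).reshape(5, 2))
        core = coreselect.stepwise_core(tm, 1.0, "random", seed=0)
        assert core.accession_ids == tm.accession_ids
        assert core.rounds == 0 and not core.truncated

    def test_two_tight_pairs_keep_one_each(self):
        tm = _matrix([[0.0], [0.01], [10.0], [10.01]])
        core = coreselect.stepwise_core(tm, 0.5, "random", seed=3)
        kept = set(core.accession_ids)
        assert len(kept & {"a00", "a01"}) == 1
        assert len(kept & {"a02", "a03"}) == 1

    @pytest.mark.parametrize("proportion", [0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
    @pytest.mark.parametrize("strategy", ["random", "preferred"])
    def test_exact_target_size(self, proportion, strategy):
        cfg = synthdata.TraitSimConfig(
            n_species=1, accessions_per_species=(73,), n_traits=3,
            sigma2_among=0.0, sigma2_within=1.0, trait_means=(5.0, 5.0, 5.0),
            trait_names=("t0", "t1", "t2"), seed=5,
        )
        tm, _ = synthdata.simulate_trait_table(cfg)
        core = coreselect.stepwise_core(tm, proportion, strategy, seed=1)
        assert core.size == int(np.floor(proportion * 73 + 0.5))

    def test_random_strategy_reproducible_and_seed_sensitive(self):
        rng = np.random.default_rng(13)
        tm = _matrix(rng.normal(size=(50, 4)))
        c1 = coreselect.stepwise_core(tm, 0.2, "random", seed=42)
        c2 = coreselect.stepwise_core(tm, 0.2, "random", seed=42)
        c3 = coreselect.stepwise_core(tm, 0.2, "random", seed=43)
        assert c1.accession_ids == c2.accession_ids
        assert set(c1.accession_ids) != set(c3.accession_ids)

    def test_preferred_strategy_deterministic_without_seed(self):
        rng = np.random.default_rng(17)
        tm = _matrix(rng.normal(size=(40, 3)))
        c1 = coreselect.stepwise_core(tm, 0.25, "preferred")
        c2 = coreselect.stepwise_core(tm, 0.25, "preferred")
        assert c1.accession_ids == c2.accession_ids

    def test_preferred_retains_all_trait_extremes(self):
        rng = np.random.default_rng(23)
        for trial in range(10):
            n = int(rng.integers(10, 21))
            tm = _matrix(rng.normal(size=(n, 3)))
            core = coreselect.stepwise_core(tm, 0.5, "preferred")
            if core.truncated:
                continue
            kept = set(core.accession_ids)
            for j in range(3):
                col = tm.values[:, j]
                assert tm.accession_ids[int(np.argmax(col))] in kept
                assert tm.accession_ids[int(np.argmin(col))] in kept

    def test_core_spreads_not_collapses(self):
        # every dropped accession stays close to some retained one
        cfg = synthdata.TraitSimConfig(
            n_species=1, accessions_per_species=(100,), n_traits=5, seed=31,
        )
        tm, _ = synthdata.simulate_trait_table(cfg)
        core = coreselect.stepwise_core(tm, 0.3, "random", seed=0)
        stats = coreselect.frozen_statistics(tm.values)
        z = coreselect.standardize(tm.values, stats)
        kept = tm.rows(core.accession_ids)
        dropped = [i for i in range(tm.n) if i not in set(kept)]
        d = np.sqrt(((z[:, None] - z[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        max_nn_initial = d.min(axis=1).max()
        worst_gap = max(d[i, kept].min() for i in dropped)
        assert worst_gap <= max_nn_initial * len(dropped)  # loose spread bound

    def test_parameter_validation(self):
        tm = _matrix(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ParameterError):
            coreselect.stepwise_core(tm, 0.0, "random", seed=0)
        with pytest.raises(ParameterError):
            coreselect.stepwise_core(tm, 1.5, "random", seed=0)
        with pytest.raises(InsufficientDataError):
            coreselect.stepwise_core(tm.subset(["a00"]), 0.5, "random", seed=0)
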