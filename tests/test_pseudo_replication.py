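from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix
from oracles import binomial_oracle
from thermode.fisher_de import ContingencyTable2x2, fisher_two_sided_p
from thermode.io_formats import CountMatrix, LibraryDescriptor
from thermode.pseudo_replication import (
    SubsamplePartition,
    conditional_binomial_test,
    consensus_calls,
    partition_counts,
)
from thermode.synthetic_data import SimulationConfig, SpeciesSpec, simulate_experiment


class TestPartitionCounts:
    def test_zero_count_splits_to_zeros(self):
        matrix = make_matrix({"L26": [0, 5], "L31": [1, 1]}, genes=["a", "b"])
        partition = partition_counts(matrix, "L26", k=2, seed=1)
        assert partition.matrices[0].counts.at["a", "L26.s1"] == 0
        assert partition.matrices[1].counts.at["a", "L26.s2"] == 0

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=500), min_size=1,
                        max_size=20),
        k=st.integers(min_value=2, max_value=4),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_exact_conservation_any_seed(self, counts, k, seed):
        genes = [f"g{i}" for i in range(len(counts))]
        matrix = make_matrix({"L26": counts, "L31": [1] * len(counts)}, genes=genes)
        partition = partition_counts(matrix, "L26", k=k, seed=seed)
        total = sum(m.counts.iloc[:, 0].to_numpy() for m in partition.matrices)
        assert (total == np.asarray(counts)).all()

    def test_same_seed_reproduces_different_seed_differs(self):
        counts = [100] * 200
        matrix = make_matrix({"L26": counts, "L31": counts},
                             genes=[f"g{i}" for i in range(200)])
        a = partition_counts(matrix, "L26", k=2, seed=9)
        b = partition_counts(matrix, "L26", k=2, seed=9)
        c = partition_counts(matrix, "L26", k=2, seed=10)
        pd.testing.assert_frame_equal(a.counts_frame(), b.counts_frame())
        assert not a.counts_frame().equals(c.counts_frame())

    def test_binomial_split_means(self):
        # 10,000 genes at count 100, k=2: subsample means are within 3
        # standard errors of 50 (se = sqrt(100 * 0.25 / 10000) = 0.05)
        n = 10_000
        matrix = make_matrix({"L26": [100] * n, "L31": [1] * n},
                             genes=[f"g{i}" for i in range(n)])
        partition = partition_counts(matrix, "L26", k=2, seed=3)
        mean = float(partition.matrices[0].counts.iloc[:, 0].mean())
        assert abs(mean - 50.0) < 3 * 0.05

    def test_k_below_two_rejected(self):
        matrix = make_matrix({"L26": [5], "L31": [5]}, genes=["a"])
        with pytest.raises(ValueError, match="k must be >= 2"):
            partition_counts(matrix, "L26", k=1, seed=0)


class TestConditionalBinomialTest:
    def test_balanced_modal_outcome(self):
        assert conditional_binomial_test(5, 5, 1000, 1000) == 1.0

    def test_one_sided_extreme_matches_hand_sum(self):
        # x1 = 10 of 10 under p = 1/2: only the two extremes qualify
        p = conditional_binomial_test(10, 0, 500, 500)
        assert p == pytest.approx(2 / 1024, rel=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            x1, x2 = (int(v) for v in rng.integers(0, 60, size=2))
            if x1 + x2 == 0:
                continue
            n1, n2 = (int(v) for v in rng.integers(100, 5000, size=2))
            ours = conditional_binomial_test(x1, x2, n1, n2)
            assert ours == pytest.approx(binomial_oracle(x1, x2, n1, n2), rel=1e-9)

    def test_agrees_with_fisher_in_large_total_limit(self):
        # hypergeometric -> binomial as totals grow with counts fixed
        rng = np.random.default_rng(13)
        for _ in range(50):
            x1, x2 = (int(v) for v in rng.integers(0, 30, size=2))
            if x1 + x2 == 0:
                continue
            big = 1_000_000
            binomial = conditional_binomial_test(x1, x2, big, big)
            fisher = fisher_two_sided_p(
                ContingencyTable2x2(x1, x2, big - x1, big - x2)
            )
            assert binomial == pytest.approx(fisher, rel=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            conditional_binomial_test(0, 0, 10, 10)
        with pytest.raises(ValueError):
            conditional_binomial_test(1, 1, 0, 10)


def _partition_from_columns(matrix: CountMatrix, columns: list[str],
                            source_id: str) -> SubsamplePartition:
    """Hand-built partition whose subsamples are existing matrix columns."""
    matrices = []
    for i, col in enumerate(columns):
        desc = matrix.descriptor(col)
        sub_id = f"{source_id}.s{i + 1}"
        frame = pd.DataFrame({sub_id: matrix.counts[col].to_numpy()},
                             index=matrix.counts.index)
        frame.index.name = "gene_id"
        matrices.append(CountMatrix(
            counts=frame,
            libraries=[LibraryDescriptor(sub_id, desc.species, desc.stage,
                                         desc.temperature, desc.tissue,
                                         desc.n_pooled)],
        ))
    return SubsamplePartition(source_library_id=source_id, k=len(columns),
                              seed=0, matrices=matrices)


class TestConsensusCalls:
    def _signal_matrix(self):
        rng = np.random.default_rng(21)
        n = 500
        genes = [f"g{i:03d}" for i in range(n)]
        base = rng.integers(100, 1000, size=n)
        low = rng.poisson(base).astype(np.int64)
        high = rng.poisson(base).astype(np.int64)
        low[:10] = (base[:10] * 8)  # strongly low-biased signal genes
        high[:10] = base[:10] // 4
        return make_matrix(
            {"L26": low.tolist(), "L31": high.tolist()}, genes=genes
        )

    def test_identical_pairs_give_consensus_equal_to_pair_set(self):
        matrix = self._signal_matrix()
        # both "subsamples" of each temperature are the same column: every
        # pair yields the same calls, so the consensus equals the pair set
        part_low = _partition_from_columns(matrix, ["L26", "L26"], "L26")
        part_high = _partition_from_columns(matrix, ["L31", "L31"], "L31")
        result = consensus_calls(part_low, part_high, alpha=0.01)
        assert result["consensus"] == result["pair_sets"][0]
        assert result["consensus"]  # the planted signal is found

    def test_direction_inconsistency_excluded(self):
        genes = ["flip", "steady"] + [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(5)
        background = rng.integers(200, 400, size=200)
        # pair 1 sees "flip" low-biased, pair 2 sees it high-biased
        low_1 = [2000, 2000] + background.tolist()
        low_2 = [125, 2000] + background.tolist()
        high_1 = [125, 125] + background.tolist()
        high_2 = [2000, 125] + background.tolist()
        matrix = make_matrix(
            {"A1": low_1, "A2": low_2, "B1": high_1, "B2": high_2},
            genes=genes,
            temps=["low", "low", "high", "high"],
        )
        part_low = _partition_from_columns(matrix, ["A1", "A2"], "A")
        part_high = _partition_from_columns(matrix, ["B1", "B2"], "B")
        result = consensus_calls(part_low, part_high, alpha=0.01)
        assert "flip" in result["pair_sets"][0]
        assert "flip" in result["pair_sets"][1]
        assert "flip" not in result["consensus"]
        assert "steady" in result["consensus"]

    def test_mismatched_k_rejected(self):
        matrix = self._signal_matrix()
        part_low = _partition_from_columns(matrix, ["L26", "L26"], "L26")
        part_high = _partition_from_columns(matrix, ["L31", "L31", "L31"], "L31")
        with pytest.raises(ValueError, match="mismatched k"):
            consensus_calls(part_low, part_high)

    def test_consensus_is_intersection_and_shrinks_with_k(self):
        config = SimulationConfig(
            n_genes=2000,
            stages=(22,),
            species=(SpeciesSpec("TSD", 10, 0.05, {22: 2.0}),),
            depth=400_000,
            dispersion=0.0,
            seed=29,
        )
        matrix, _ = simulate_experiment(config)
        lib_low = matrix.find_library("TSD", 22, "low").library_id
        lib_high = matrix.find_library("TSD", 22, "high").library_id
        sizes = {}
        for k in (2, 3):
            part_low = partition_counts(matrix, lib_low, k=k, seed=101)
            part_high = partition_counts(matrix, lib_high, k=k, seed=202)
            result = consensus_calls(part_low, part_high, alpha=0.01)
            union = set().union(*result["pair_sets"])
            for pair_set in result["pair_sets"]:
                assert result["consensus"] <= pair_set
            assert result["consensus"] <= union
            sizes[k] = len(result["consensus"])
        assert sizes[3] <= sizes[2]
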