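"""Descriptor computation and greedy correlation pruning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casel.descriptors import (
    BASELINE_DESCRIPTORS,
    DescriptorTable,
    compute_descriptors,
    drop_failed_compounds,
    filter_correlated,
    manifest,
)


class TestComputeDescriptors:
    def test_textbook_values_for_methane(self):
        table = compute_descriptors(
            {"methane": "C"}, descriptor_set=["HeavyAtomCount", "MolWt"]
        )
        assert table.values[0, 0] == 1
        assert table.values[0, 1] == pytest.approx(16.043, abs=1e-3)

    def test_duplicate_smiles_give_identical_rows(self):
        table = compute_descriptors(
            [("a", "NS(=O)(=O)c1ccccc1"), ("b", "NS(=O)(=O)c1ccccc1")]
        )
        np.testing.assert_array_equal(table.values[0], table.values[1])

    def test_baseline_manifest_has_118_computable_descriptors(self):
        assert len(BASELINE_DESCRIPTORS) == 118
        table = compute_descriptors({"x": "CC(=O)Nc1nnc(s1)S(N)(=O)=O"})
        assert table.values.shape == (1, 118)
        assert not np.isnan(table.values).any()

    def test_unknown_descriptor_is_hard_error(self):
        with pytest.raises(ValueError, match="unknown descriptors"):
            compute_descriptors({"x": "C"}, descriptor_set=["NotADescriptor"])

    def test_unparseable_smiles_flagged_and_droppable(self):
        table = compute_descriptors(
            [("good", "CCO"), ("bad", "xyz((")],
            descriptor_set=["MolWt"],
        )
        assert "bad" in table.failures
        assert np.isnan(table.values[1, 0])
        cleaned = drop_failed_compounds(table)
        assert cleaned.compound_ids == ["good"]


def _table(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{j}" for j in range(values.shape[1])]
    return DescriptorTable(
        compound_ids=[f"c{i}" for i in range(values.shape[0])],
        descriptor_names=names,
        values=values,
    )


class TestFilterCorrelated:
    def test_perfectly_correlated_column_pruned(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        c = rng.normal(size=30)
        table = _table(np.column_stack([a, 2 * a, c]), ["A", "B", "C"])
        out = filter_correlated(table, 0.95)
        assert out.retained_names == ["A", "C"]
        assert manifest(out)["pruned_names"] == ["B"]

    def test_threshold_one_prunes_nothing_without_duplicates(self):
        rng = np.random.default_rng(2)
        table = _table(rng.normal(size=(20, 6)))
        out = filter_correlated(table, 1.0)
        assert out.retained_names == table.descriptor_names

    def test_anticorrelated_column_pruned(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=25)
        table = _table(np.column_stack([a, -a]), ["A", "negA"])
        assert filter_correlated(table, 0.95).retained_names == ["A"]

    def test_constant_column_retained_and_reported(self):
        rng = np.random.default_rng(4)
        table = _table(
            np.column_stack([rng.normal(size=15), np.full(15, 3.0)]),
            ["A", "const"],
        )
        out = filter_correlated(table, 0.75)
        assert "const" in out.retained_names
        assert out.constant_columns == ["const"]

    def test_missing_values_rejected(self):
        table = _table([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            filter_correlated(table, 0.95)

    @given(st.integers(0, 2**31 - 1), st.integers(5, 25))
    def test_greedy_result_passes_exhaustive_pairwise_check(self, seed, n_cols):
        """Brute-force oracle: retained pairs all below threshold; every pruned
        column hits the threshold against an earlier retained column."""
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(40, n_cols))
        # inject correlated structure so pruning actually happens
        for j in range(1, n_cols, 3):
            base[:, j] = base[:, j - 1] * 0.9 + 0.1 * base[:, j]
        table = _table(base)
        threshold = 0.8
        out = filter_correlated(table, threshold)
        corr = np.corrcoef(base, rowvar=False)
        retained = [j for j in range(n_cols) if not out.pruned_mask[j]]
        for i_pos, i in enumerate(retained):
            for j in retained[i_pos + 1:]:
                assert abs(corr[i, j]) < threshold
        for j in range(n_cols):
            if out.pruned_mask[j]:
                earlier = [i for i in retained if i < j]
                assert any(abs(corr[i, j]) >= threshold for i in earlier)

    def test_pruning_monotonicity(self, features_small, curated_small):
        """Lowering the threshold never retains more descriptors."""
        unique = curated_small.drop_duplicates("compound_id").head(120)
        table = drop_failed_compounds(compute_descriptors(
            list(zip(unique.compound_id, unique.smiles))
        ))
        n_none = len(filter_correlated(table, None).retained_names)
        n_95 = len(filter_correlated(table, 0.95).retained_names)
        n_75 = len(filter_correlated(table, 0.75).retained_names)
        assert n_75 <= n_95 <= n_none == 118

    def test_order_determinism(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(30, 10))
        values[:, 4] = values[:, 2]
        first = filter_correlated(_table(values), 0.95).retained_names
        second = filter_correlated(_table(values), 0.95).retained_names
        assert first == second and "d4" not in first
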