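import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moni.background import (
    ExpressionMatrix,
    counts_to_tpm,
    decorrelate,
    filter_samples,
    split_by_library_type,
)


def make_matrix(values: dict, lengths=None, unit="counts"):
    df = pd.DataFrame(values)
    lengths = lengths or {g: 1000 for g in df.index}
    return ExpressionMatrix(
        values=df.astype(float), gene_lengths=pd.Series(lengths), unit=unit
    )


def make_meta(samples, single_cell=(), library_type="polyA"):
    return pd.DataFrame(
        {
            "library_type": library_type,
            "is_single_cell": [int(s in single_cell) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )


class TestFilterSamples:
    def test_count_floor_is_strict(self):
        # 15,000 exactly is retained; strictly-below removal
        m = make_matrix(
            pd.DataFrame(
                {"s1": [20000.0], "s2": [14999.0], "s3": [15000.0]},
                index=["g1"],
            )
        )
        out = filter_samples(m, make_meta(["s1", "s2", "s3"]))
        assert out.sample_ids == ["s1", "s3"]

    def test_single_cell_dropped_regardless_of_depth(self):
        m = make_matrix(
            pd.DataFrame({"s1": [1e6], "s2": [2e4]}, index=["g1"])
        )
        out = filter_samples(m, make_meta(["s1", "s2"], single_cell={"s1"}))
        assert out.sample_ids == ["s2"]

    def test_all_removed_errors(self):
        m = make_matrix(pd.DataFrame({"s1": [10.0]}, index=["g1"]))
        with pytest.raises(ValueError, match="empty background"):
            filter_samples(m, make_meta(["s1"]))


class TestSplitByLibraryType:
    def test_partition(self):
        df = pd.DataFrame(
            {s: [1.0] for s in ["a", "b", "c", "d", "e"]}, index=["g1"]
        )
        meta = make_meta(list("abcde"))
        meta.loc[["d", "e"], "library_type"] = "total"
        out = split_by_library_type(make_matrix(df), meta)
        assert out["polyA"].sample_ids == ["a", "b", "c"]
        assert out["total"].sample_ids == ["d", "e"]

    def test_all_one_type_gives_empty_other(self):
        df = pd.DataFrame({"a": [1.0]}, index=["g1"])
        out = split_by_library_type(make_matrix(df), make_meta(["a"]))
        assert out["total"].n_samples == 0

    def test_unknown_library_type(self):
        df = pd.DataFrame({"a": [1.0]}, index=["g1"])
        meta = make_meta(["a"])
        meta.loc["a", "library_type"] = "scRNA"
        with pytest.raises(ValueError, match="scRNA"):
            split_by_library_type(make_matrix(df), meta)


class TestDecorrelate:
    def test_duplicate_sample_pruned_uncorrelated_kept(self):
        # s1 and s2 identical (r=1); s3 nearly orthogonal to both
        rng = np.random.default_rng(0)
        base = rng.random(40) * 100
        other = rng.random(40) * 100
        df = pd.DataFrame({"s1": base, "s2": base, "s3": other},
                          index=[f"g{i}" for i in range(40)])
        m = make_matrix(df)
        bg = decorrelate(m, r_max=0.7, seed=5)
        retained = set(bg.retained_order)
        assert len(retained & {"s1", "s2"}) == 1  # exactly one duplicate
        assert "s3" in retained

    def test_two_identical_samples_keep_one(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0]},
                          index=["g1", "g2", "g3"])
        bg = decorrelate(make_matrix(df), seed=1)
        assert len(bg.retained_order) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((30, 8)) * 100,
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(8)])
        m = make_matrix(df)
        a = decorrelate(m, seed=42)
        b = decorrelate(m, seed=42)
        assert a.retained_order == b.retained_order

    def test_pairwise_invariant_on_random_matrices(self):
        """Retained samples are always mutually r < r_max on the count
        scale, across 100 random compendia with planted duplicates."""
        rng = np.random.default_rng(7)
        for trial in range(100):
            n_genes, n_samples = 25, 6
            base = rng.random((n_genes, n_samples)) * 100
            # plant correlated pairs: sample i+1 is a noisy copy of i
            for i in range(0, n_samples - 1, 2):
                base[:, i + 1] = base[:, i] + rng.normal(0, 5, n_genes).clip(-20, 20)
            base = np.abs(base)
            df = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{i}" for i in range(n_samples)])
            m = make_matrix(df)
            bg = decorrelate(m, r_max=0.7, seed=trial)
            kept = df[bg.retained_order].to_numpy()
            for i in range(kept.shape[1]):
                for j in range(i + 1, kept.shape[1]):
                    r = np.corrcoef(kept[:, i], kept[:, j])[0, 1]
                    assert r < 0.7

    def test_zero_variance_sample_never_blocks(self):
        df = pd.DataFrame({"s1": [5.0, 5.0], "s2": [1.0, 9.0]},
                          index=["g1", "g2"])
        bg = decorrelate(make_matrix(df), seed=0)
        assert len(bg.retained_order) == 2


class TestCountsToTpm:
    def test_length_normalization(self):
        m = make_matrix(
            pd.DataFrame({"s1": [10.0, 90.0]}, index=["g1", "g2"]),
            lengths={"g1": 1000, "g2": 9000},
        )
        tpm = counts_to_tpm(m)
        assert tpm.values["s1"].tolist() == pytest.approx([500000.0, 500000.0])

    def test_single_gene_is_one_million(self):
        m = make_matrix(pd.DataFrame({"s1": [7.0]}, index=["g1"]))
        assert counts_to_tpm(m).values.loc["g1", "s1"] == pytest.approx(1e6)

    def test_zero_column_stays_zero(self):
        m = make_matrix(pd.DataFrame({"s1": [0.0, 0.0]}, index=["g1", "g2"]))
        assert counts_to_tpm(m).values["s1"].tolist() == [0.0, 0.0]

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(3)
        m = make_matrix(
            pd.DataFrame(rng.integers(0, 100, (20, 4)).astype(float),
                         index=[f"g{i}" for i in range(20)],
                         columns=list("abcd")),
            lengths={f"g{i}": int(rng.integers(500, 5000)) for i in range(20)},
        )
        sums = counts_to_tpm(m).values.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_zero_gene_length_rejected(self):
        m = make_matrix(pd.DataFrame({"s1": [1.0]}, index=["g1"]),
                        lengths={"g1": 0})
        with pytest.raises(ValueError):
            counts_to_tpm(m)

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(0, 100))
    def test_invariant_to_count_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 1000, 15).astype(float)
        lengths = rng.integers(200, 8000, 15)
        m1 = make_matrix(pd.DataFrame({"s": counts},
                                      index=[f"g{i}" for i in range(15)]),
                         lengths={f"g{i}": int(l) for i, l in enumerate(lengths)})
        m2 = make_matrix(pd.DataFrame({"s": counts * scale},
                                      index=[f"g{i}" for i in range(15)]),
                         lengths={f"g{i}": int(l) for i, l in enumerate(lengths)})
        t1 = counts_to_tpm(m1).values["s"].to_numpy()
        t2 = counts_to_tpm(m2).values["s"].to_numpy()
        assert np.allclose(t1, t2, rtol=1e-9)
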