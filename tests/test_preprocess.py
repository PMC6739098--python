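"""Filtering, rarefaction, aggregation and the CLR transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fcmlink.io import TaxonTable
from fcmlink.preprocess import (
    CompositionMatrix,
    aggregate_taxonomy,
    clr_transform,
    filter_taxa,
    rarefy,
    to_relative,
)


def _table(arr, taxonomy=None):
    arr = np.asarray(arr)
    return TaxonTable(
        pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=[f"t{j}" for j in range(arr.shape[1])],
        ),
        taxonomy,
    )


class TestFilterTaxa:
    def test_prevalence_rule_boundary(self):
        # 10 samples: >= 5 reads in ceil(0.1*10)=1 sample keeps the taxon
        arr = np.zeros((10, 2), dtype=int)
        arr[0, 0] = 5  # exactly at threshold in exactly one sample -> kept
        arr[:, 1] = 4  # 4 reads everywhere -> never reaches min_count
        out = filter_taxa(_table(arr), min_count=5, min_fraction=0.10)
        assert out.taxon_ids == ["t0"]

    def test_zero_fraction_invalid(self):
        with pytest.raises(ValueError):
            filter_taxa(_table(np.ones((3, 2), dtype=int)), min_fraction=0.0)

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="no taxa"):
            filter_taxa(_table(np.ones((4, 3), dtype=int)), min_count=99)


class TestRarefy:
    def test_exact_depth_unchanged_and_deterministic(self):
        arr = np.array([[3, 2], [10, 10]])
        out1 = rarefy(_table(arr), depth=5, seed=3)
        out2 = rarefy(_table(arr), depth=5, seed=3)
        assert out1.counts.sum(axis=1).tolist() == [5, 5]
        np.testing.assert_array_equal(out1.counts.loc["s0"], [3, 2])
        pd.testing.assert_frame_equal(out1.counts, out2.counts)

    def test_under_depth_samples_dropped(self):
        arr = np.array([[1, 1], [50, 50]])
        out = rarefy(_table(arr), depth=10, seed=0)
        assert out.sample_ids == ["s1"]
        with pytest.raises(ValueError):
            rarefy(_table(np.array([[1, 1]])), depth=10, seed=0)

    def test_hypergeometric_expectation(self):
        # taxon share q=0.3 at total 100, depth 40: mean rarefied count -> 12
        arr = np.array([[30, 70]])
        depth, reps = 40, 1000
        vals = [
            rarefy(_table(arr), depth=depth, seed=s).counts.iloc[0, 0]
            for s in range(reps)
        ]
        # hypergeometric variance n*q*(1-q)*(N-n)/(N-1)
        var = depth * 0.3 * 0.7 * (100 - depth) / 99
        se = np.sqrt(var / reps)
        assert abs(np.mean(vals) - 12.0) < 3 * se


class TestAggregate:
    def _tax(self):
        return pd.DataFrame(
            {"phylum": ["P1", "P1", "P2"], "genus": ["g1", "g2", "g3"]},
            index=["t0", "t1", "t2"],
        )

    def test_sums_within_rank(self):
        t = _table(np.array([[3, 4, 1], [0, 2, 5]]), self._tax())
        out = aggregate_taxonomy(t, "phylum")
        assert out.counts.loc["s0", "P1"] == 7
        assert out.counts.loc["s1", "P2"] == 5

    def test_total_conserved_at_every_rank(self, rng):
        arr = rng.integers(0, 50, size=(5, 3))
        t = _table(arr, self._tax())
        for rank in ("phylum", "genus"):
            assert aggregate_taxonomy(t, rank).counts.to_numpy().sum() == arr.sum()

    def test_finest_rank_is_identity(self):
        t = _table(np.array([[3, 4, 1]]), self._tax())
        out = aggregate_taxonomy(t, "genus")
        assert out.n_taxa == 3
        np.testing.assert_array_equal(out.counts.to_numpy(), t.counts.to_numpy())

    def test_unknown_rank(self):
        with pytest.raises(ValueError, match="unknown rank"):
            aggregate_taxonomy(_table(np.ones((2, 3), dtype=int), self._tax()), "family")


class TestRelativeAndClr:
    def test_relative_rows(self):
        comp = to_relative(_table(np.array([[2, 2], [1, 3]])))
        np.testing.assert_allclose(comp.rel.to_numpy(), [[0.5, 0.5], [0.25, 0.75]])

    def test_zero_sum_row_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            to_relative(_table(np.array([[1, 2], [0, 0]])))

    def test_clr_uniform_row_is_zero(self):
        z = clr_transform(pd.DataFrame([[1 / 3] * 3])).z.to_numpy()
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_clr_closed_form(self):
        z = clr_transform(pd.DataFrame([[0.5, 0.25, 0.25]])).z.to_numpy()[0]
        g = (0.5 * 0.25 * 0.25) ** (1 / 3)
        np.testing.assert_allclose(z, np.log([0.5, 0.25, 0.25]) - np.log(g), atol=1e-12)
        np.testing.assert_allclose(z, [0.4621, -0.2310, -0.2310], atol=5e-5)

    def test_zero_replacement_delta(self):
        out = clr_transform(pd.DataFrame([[0.0, 1.0]]))
        assert out.delta == pytest.approx(0.25)  # 1/p^2 with p=2
        np.testing.assert_allclose(out.z.to_numpy()[0], [-0.6931, 0.6931], atol=5e-5)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[1.0]]))

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(
            float,
            (4, 6),
            elements=st.floats(1e-6, 1.0),
        )
    )
    def test_clr_rows_sum_zero_and_scale_invariant(self, mat):
        df = pd.DataFrame(mat)
        z1 = clr_transform(df).z.to_numpy()
        assert np.abs(z1.sum(axis=1)).max() < 1e-9
        z2 = clr_transform(df * 37.5).z.to_numpy()
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_clr_matches_reference_composition_library(self, rng):
        from skbio.stats.composition import clr as skbio_clr

        mat = rng.dirichlet(np.ones(8), size=5)
        mine = clr_transform(pd.DataFrame(mat)).z.to_numpy()
        np.testing.assert_allclose(mine, skbio_clr(mat), atol=1e-10)

    def test_composition_matrix_validates(self):
        with pytest.raises(ValueError):
            CompositionMatrix(pd.DataFrame([[0.5, 0.6]]))
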