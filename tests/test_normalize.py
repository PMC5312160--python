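import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import agoripseq as aq
from agoripseq.normalize import TMMNormalizer, validate_counts
from oracles import cpm_bruteforce, tmm_factor_bruteforce


def _factors(counts, **kw):
    return aq.tmm_factors(counts, **kw).set_index("library_id")["tmm_factor"]


class TestTMMFactors:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]},
                              index=list("wxyz"))
        assert np.allclose(_factors(counts), 1.0)

    def test_pure_depth_scaling_gives_unit_factors(self, rng):
        base = rng.integers(10, 1000, size=50)
        counts = pd.DataFrame(
            {"a": base, "b": 10 * base}, index=[f"g{i}" for i in range(50)]
        )
        assert np.allclose(_factors(counts), 1.0)

    def test_global_scale_invariance(self, toy_counts):
        scaled = (toy_counts * 7).astype(int)
        assert np.allclose(_factors(toy_counts), _factors(scaled))

    def test_toy_matrix_matches_bruteforce_oracle(self, toy_counts):
        f = _factors(toy_counts, ref_library="libA")
        expected = tmm_factor_bruteforce(
            toy_counts["libB"].to_numpy(), toy_counts["libA"].to_numpy()
        )
        # renormalized to geometric mean 1: (1, f) -> (1/sqrt(f), sqrt(f))
        assert abs(f["libB"] - expected / np.sqrt(expected)) < 1e-10
        assert abs(f["libA"] - 1.0 / np.sqrt(expected)) < 1e-10

    def test_random_instances_match_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(30, 120)
            counts = pd.DataFrame(
                {
                    "a": rng.integers(0, 500, size=n),
                    "b": rng.integers(0, 500, size=n),
                },
                index=[f"g{i}" for i in range(n)],
            )
            counts.iloc[0] += 1  # ensure positive totals
            f = _factors(counts, ref_library="a")
            raw = tmm_factor_bruteforce(counts["b"].to_numpy(), counts["a"].to_numpy())
            assert abs(f["b"] - raw / np.sqrt(raw)) < 1e-8

    def test_geometric_mean_is_one(self, small_sim):
        _, counts, _, _ = small_sim
        f = _factors(counts)
        assert abs(np.mean(np.log(f))) < 1e-12

    def test_effective_size_is_total_times_factor(self, toy_counts):
        tab = aq.tmm_factors(toy_counts).set_index("library_id")
        totals = toy_counts.sum(axis=0)
        for lib in toy_counts.columns:
            assert np.isclose(
                tab.loc[lib, "effective_library_size"],
                totals[lib] * tab.loc[lib, "tmm_factor"],
            )

    def test_composition_correction_centers_unchanged_genes(self, rng):
        """5% strongly upregulated genes in one library must not bias the
        normalized log-ratios of the unchanged majority."""
        n = 2000
        base = rng.integers(50, 2000, size=n).astype(float)
        b = base.copy()
        up = rng.choice(n, size=n // 20, replace=False)
        b[up] *= 30
        counts = pd.DataFrame(
            {"a": base.astype(int), "b": b.astype(int)},
            index=[f"g{i}" for i in range(n)],
        )
        tab = aq.tmm_factors(counts)
        cpm = aq.cpm(counts, tab)
        unchanged = np.setdiff1d(np.arange(n), up)
        ratios = np.log2(cpm.iloc[unchanged, 1] / cpm.iloc[unchanged, 0])
        assert abs(np.median(ratios)) < 0.05

    def test_zero_total_library_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="zero total"):
            aq.tmm_factors(counts)

    def test_bad_trim_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="trim_m"):
            TMMNormalizer(trim_m=0.6).fit(toy_counts.T)


class TestCPM:
    def test_unit_definition(self):
        counts = pd.DataFrame({"a": [1]}, index=["g0"])
        norm = pd.DataFrame(
            {"library_id": ["a"], "tmm_factor": [1.0], "effective_library_size": [1e6]}
        )
        assert aq.cpm(counts, norm).iloc[0, 0] == 1.0

    def test_all_zero_gene_is_zero_everywhere(self, small_sim):
        _, counts, _, _ = small_sim
        counts = counts.copy()
        counts.iloc[0] = 0
        tab = aq.tmm_factors(counts)
        assert (aq.cpm(counts, tab).iloc[0] == 0).all()

    def test_matches_cell_by_cell_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"l{i}" for i in range(6)],
        )
        tab = aq.tmm_factors(counts + 1)
        eff = tab.set_index("library_id").loc[counts.columns, "effective_library_size"]
        for prior in (0.0, 0.5, 2.0):
            ours = aq.cpm(counts, tab, prior_count=prior).to_numpy()
            oracle = cpm_bruteforce(counts.to_numpy(), eff.to_numpy(), prior)
            np.testing.assert_allclose(ours, oracle, rtol=1e-12)

    def test_columns_sum_to_million_with_unit_factors(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(30, 3)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abc"),
        )
        norm = pd.DataFrame(
            {
                "library_id": list("abc"),
                "tmm_factor": 1.0,
                "effective_library_size": counts.sum(axis=0).to_numpy(float),
            }
        )
        np.testing.assert_allclose(aq.cpm(counts, norm).sum(axis=0), 1e6)


class TestExpressionFilter:
    def test_all_zero_gene_excluded(self, small_sim):
        _, counts, _, _ = small_sim
        counts = counts.copy()
        counts.iloc[5] = 0
        tab = aq.tmm_factors(counts)
        mask = aq.filter_low_expression(counts, tab)
        assert not mask.iloc[5]

    def test_threshold_is_inclusive(self):
        """A gene averaging exactly 1 CPM is retained (only averages
        strictly below the threshold are excluded)."""
        counts = pd.DataFrame({"a": [1, 999_999]}, index=["lo", "hi"])
        norm = pd.DataFrame(
            {"library_id": ["a"], "tmm_factor": [1.0], "effective_library_size": [1e6]}
        )
        mask = aq.filter_low_expression(counts, norm, min_avg_cpm=1.0)
        assert bool(mask["lo"])

    def test_mask_matches_mean_cpm_oracle(self, small_sim):
        _, counts, _, _ = small_sim
        counts = counts.head(100)
        tab = aq.tmm_factors(counts)
        eff = tab.set_index("library_id").loc[counts.columns, "effective_library_size"]
        oracle = (counts.to_numpy() / eff.to_numpy() * 1e6).mean(axis=1) >= 1.0
        mask = aq.filter_low_expression(counts, tab, min_avg_cpm=1.0)
        np.testing.assert_array_equal(mask.to_numpy(), oracle)


class TestValidation:
    def test_negative_count_rejected(self):
        bad = pd.DataFrame({"a": [1, -2]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="negative count at gene 'g1'"):
            validate_counts(bad)

    def test_duplicate_gene_rejected(self):
        bad = pd.DataFrame({"a": [1, 2]}, index=["g0", "g0"])
        with pytest.raises(ValueError, match="duplicate gene"):
            validate_counts(bad)


@given(st.integers(min_value=2, max_value=50))
def test_scale_invariance_property(multiplier):
    """TMM factors are invariant to a common depth rescaling."""
    counts = pd.DataFrame(
        {"a": [40, 10, 60, 200, 5], "b": [35, 20, 70, 150, 9]},
        index=[f"g{i}" for i in range(5)],
    )
    base = aq.tmm_factors(counts)["tmm_factor"].to_numpy()
    scaled = aq.tmm_factors(counts * multiplier)["tmm_factor"].to_numpy()
    np.testing.assert_allclose(base, scaled, rtol=1e-10)
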