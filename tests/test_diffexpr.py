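"""Differential-expression tests: exact test vs brute-force oracles,
BH vs reference implementations, hand-computed toy tables, planted
recovery, and null calibration at reduced scale."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagdge import (
    SimulationConfig,
    benjamini_hochberg,
    build_tag_index,
    call_degs,
    compute_tpm,
    exact_count_pvalue,
    extract_clean_tags,
    generate_transcriptome,
    generate_truth,
    map_tags,
    pearson_correlation,
    sample_tag_library,
    summarize_degs,
)
from tagdge.errors import DomainError, InputError, UndefinedStatisticError


def brute_force_pvalue(x: int, y: int, n1: int, n2: int, terms: int = 4000) -> float:
    """Independent oracle: direct float recurrence over the conditional pmf.

    P(Y=0|x) = (1+r)^-(x+1); P(Y=j+1) = P(Y=j) * r (x+j+1) / ((j+1)(1+r)).
    """
    r = n2 / n1
    limit = max(terms, y + 200, int(4 * r * (x + 1)) + 200)
    pmf = np.empty(limit)
    pmf[0] = (1.0 + r) ** -(x + 1.0)
    for j in range(limit - 1):
        pmf[j + 1] = pmf[j] * r * (x + j + 1) / ((j + 1) * (1.0 + r))
    lower = pmf[: y + 1].sum()
    upper = pmf[y:].sum()
    return min(1.0, 2.0 * min(lower, upper))


def make_profile(counts: dict[str, int], clean_total: int, library_id="lib"):
    return compute_tpm(counts, clean_total,
                       gene_universe=sorted(counts), library_id=library_id)


class TestComputeTpm:
    def test_zero_count_zero_tpm(self):
        profile = make_profile({"g1": 0, "g2": 10}, 1000)
        assert profile.tpm["g1"] == 0.0

    def test_analytic_value(self):
        profile = make_profile({"g": 35}, 5_000_000)
        assert profile.tpm["g"] == pytest.approx(7.0, rel=1e-12)

    def test_low_expression_below_one_tpm(self):
        # 4 copies at the printed clean-library scale is "extremely low"
        profile = make_profile({"g": 4}, 5_730_194)
        assert profile.tpm["g"] < 1.0

    def test_zero_clean_total_rejected(self):
        with pytest.raises(DomainError):
            make_profile({"g": 1}, 0)

    def test_tpm_sum_bounded(self, profiles):
        for profile in profiles.values():
            assert profile.tpm.sum() <= 1e6 + 1e-6


class TestExactCountPvalue:
    def test_equal_counts_equal_sizes(self):
        assert exact_count_pvalue(5, 5, 100, 100) == pytest.approx(1.0, rel=1e-12)
        assert exact_count_pvalue(0, 0, 10, 10) == pytest.approx(1.0, rel=1e-12)

    def test_geometric_closed_form(self):
        # x=0, equal sizes: upper tail from y is 2^-y, p = 2^-(y-1)
        assert exact_count_pvalue(0, 5, 10**6, 10**6) == pytest.approx(
            0.0625, rel=1e-12
        )

    def test_against_brute_force_example(self):
        p = exact_count_pvalue(3, 12, 10**6, 10**6)
        assert p == pytest.approx(brute_force_pvalue(3, 12, 10**6, 10**6),
                                  rel=1e-10)

    @pytest.mark.parametrize("x,y,ratio", [
        (0, 0, 1.0), (0, 50, 0.5), (200, 3, 2.0), (17, 170, 1.0),
        (1000, 1200, 1.0), (40, 35, 0.5),
    ])
    def test_against_brute_force_grid(self, x, y, ratio):
        n1 = 10**6
        n2 = int(n1 * ratio)
        assert exact_count_pvalue(x, y, n1, n2) == pytest.approx(
            brute_force_pvalue(x, y, n1, n2), rel=1e-10
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            exact_count_pvalue(-1, 2, 10, 10)
        with pytest.raises(DomainError):
            exact_count_pvalue(2, 2, 0, 10)

    @given(
        x=st.integers(0, 300),
        y=st.integers(0, 300),
        n1=st.integers(1000, 2_000_000),
        n2=st.integers(1000, 2_000_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_role_swap_duality(self, x, y, n1, n2):
        # The test conditions on the first count, so swapping roles is not
        # an exact symmetry of the two-sided p. What does hold exactly is
        # the pmf duality P(Y=y|x; r) = P(X=x|y; 1/r) / r, and the swapped
        # p-values agree within the discreteness bound (factor <= ~2).
        from tagdge.diffexpr import _log_pmf
        import numpy as np

        r = n2 / n1
        forward_pmf = _log_pmf(x, np.array([y]), math.log(r), math.log1p(r))[0]
        backward_pmf = _log_pmf(
            y, np.array([x]), math.log(1 / r), math.log1p(1 / r)
        )[0]
        assert forward_pmf == pytest.approx(backward_pmf - math.log(r),
                                            abs=1e-9)

        # at equal sizes the swapped tails are binomial tails at sizes
        # x+y+1 vs x+y, which differ by at most a factor of 2
        forward = exact_count_pvalue(x, y, n1, n1)
        backward = exact_count_pvalue(y, x, n1, n1)
        assert forward <= 2.0 * backward * (1 + 1e-10)
        assert backward <= 2.0 * forward * (1 + 1e-10)

    @given(x=st.integers(0, 100), y=st.integers(0, 100))
    @settings(max_examples=60, deadline=None)
    def test_in_unit_interval(self, x, y):
        p = exact_count_pvalue(x, y, 12345, 54321)
        assert 0.0 <= p <= 1.0


class TestBenjaminiHochberg:
    def test_single_value_identity(self):
        assert benjamini_hochberg([0.5]) == pytest.approx([0.5])

    def test_hand_computed(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_order_preserving(self):
        p = [0.9, 0.001, 0.5, 0.02]
        adjusted = benjamini_hochberg(p)
        assert adjusted[1] == min(adjusted)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=80, deadline=None)
    def test_matches_statsmodels(self, p_values):
        from statsmodels.stats.multitest import multipletests

        ours = benjamini_hochberg(p_values)
        reference = multipletests(p_values, method="fdr_bh")[1]
        assert np.allclose(ours, reference, rtol=1e-12, atol=1e-12)


class TestCallDegs:
    def test_identical_profiles_no_degs(self):
        profile = make_profile({"g1": 10, "g2": 100, "g3": 0}, 1000)
        table = call_degs(profile, profile)
        assert (table["status"] == "ns").all()
        assert len(table) == 2  # g3 zero in both: excluded

    def test_five_gene_hand_computation(self):
        # n1 = n2 = 1000; p-values and BH adjusted values derived by hand:
        #   B: x=10,y=10 -> p=1 (both tails exactly 1/2 at r=1)
        #   C: x=0,y=20 -> upper tail 2^-20, p=2^-19
        #   D: x=0,y=5  -> upper tail 2^-5, p=2^-4
        #   E: x=5,y=0  -> lower tail P(Y<=0|5) = 2^-6, p=2^-5
        #   A excluded (0 in both)
        # BH over sorted [2^-19, 2^-5, 2^-4, 1]:
        #   scaled [2^-17, 2^-5*4/2, 2^-4*4/3, 1] -> cummin from right
        #   -> C=2^-17, E=2^-4, D=2^-4*4/3, B=1
        profile_a = make_profile({"A": 0, "B": 10, "C": 0, "D": 0, "E": 5}, 1000)
        profile_b = make_profile({"A": 0, "B": 10, "C": 20, "D": 5, "E": 0}, 1000)
        table = call_degs(profile_a, profile_b).set_index("gene_id")
        assert "A" not in table.index
        assert table.loc["B", "p_value"] == pytest.approx(1.0, rel=1e-12)
        assert table.loc["C", "p_value"] == pytest.approx(2.0**-19, rel=1e-10)
        assert table.loc["D", "p_value"] == pytest.approx(2.0**-4, rel=1e-10)
        assert table.loc["E", "p_value"] == pytest.approx(2.0**-5, rel=1e-10)
        assert table.loc["C", "fdr"] == pytest.approx(4 * 2.0**-19, rel=1e-10)
        assert table.loc["E", "fdr"] == pytest.approx(2.0**-4, rel=1e-10)
        assert table.loc["D", "fdr"] == pytest.approx(2.0**-4 * 4 / 3, rel=1e-10)
        # C: tpm floored at 1000 for x=0, tpm_b=20000 -> log2 ratio > 1, FDR tiny
        assert table.loc["C", "status"] == "up"
        assert set(table.loc[["B", "D", "E"], "status"]) == {"ns"}

    def test_zero_flooring_gives_finite_ratios(self):
        profile_a = make_profile({"g": 0, "h": 5}, 2000)
        profile_b = make_profile({"g": 40, "h": 5}, 2000)
        table = call_degs(profile_a, profile_b).set_index("gene_id")
        # floor tpm_a at 1e6/2000 = 500; tpm_b = 20000 -> ratio 40
        assert table.loc["g", "log2_ratio"] == pytest.approx(math.log2(40.0))

    def test_mismatched_universes_rejected(self):
        with pytest.raises(InputError):
            call_degs(make_profile({"g": 1}, 10), make_profile({"h": 1}, 10))

    def test_threshold_monotonicity(self, profiles):
        counts = []
        for fdr_t, lfc_t in [(0.05, 0.5), (0.001, 0.5), (0.001, 1.0),
                             (0.0001, 2.0)]:
            table = call_degs(profiles["A"], profiles["B"],
                              fdr_threshold=fdr_t, lfc_threshold=lfc_t)
            counts.append(int((table["status"] != "ns").sum()))
        assert counts == sorted(counts, reverse=True)

    def test_planted_recovery_small_scale(self):
        config = SimulationConfig(
            n_genes=1000, de_fraction=0.1, frac_up=0.5,
            lfc_magnitude_range=(2.0, 4.0), library_depth=200_000, seed=1,
        )
        ref = generate_transcriptome(config)
        truth = generate_truth(config)
        index = build_tag_index(ref)
        prof = {}
        for condition in ("A", "B"):
            reads = sample_tag_library(truth, ref, condition, config)
            lib = extract_clean_tags(reads, library_id=condition)
            prof[condition] = compute_tpm(
                map_tags(lib, index), lib.clean_total, gene_universe=ref.gene_ids
            )
        table = call_degs(prof["A"], prof["B"]).merge(truth, on="gene_id")
        de = table[table["is_de"]]
        null = table[~table["is_de"]]
        called_right = (de["status"] != "ns") & (
            np.sign(de["log2_ratio"]) == np.sign(de["log2_fc"])
        )
        assert called_right.mean() >= 0.90
        assert (null["status"] != "ns").mean() <= 0.02

    def test_null_calibration_small_scale(self):
        type_one = []
        for seed in (1, 2, 3):
            config = SimulationConfig(n_genes=1000, library_depth=200_000,
                                      seed=seed)
            ref = generate_transcriptome(config)
            truth = generate_truth(config)
            index = build_tag_index(ref)
            prof = {}
            for condition in ("A", "B"):
                lib = extract_clean_tags(
                    sample_tag_library(truth, ref, condition, config),
                    library_id=condition,
                )
                prof[condition] = compute_tpm(
                    map_tags(lib, index), lib.clean_total,
                    gene_universe=ref.gene_ids,
                )
            table = call_degs(prof["A"], prof["B"])
            for alpha in (0.05, 0.01):
                bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / len(table))
                assert (table["p_value"] < alpha).mean() <= bound
            assert int((table["status"] != "ns").sum()) == 0
            type_one.append(float((table["p_value"] < 0.05).mean()))
        # the discrete test is conservative on average across seeds
        assert sum(type_one) / len(type_one) <= 0.055


class TestSummarizeDegs:
    def test_empty_table(self):
        table = pd.DataFrame(columns=["gene_id", "log2_ratio", "status"])
        summary = summarize_degs(table)
        assert summary["n_deg"] == 0
        assert summary["pct_up"] == 0.0
        assert not summary["percentages_defined"]

    def test_counts_and_bins(self):
        table = pd.DataFrame(
            {
                "gene_id": list("abcdef"),
                "log2_ratio": [1.5, -2.5, 3.2, 5.0, 13.0, 0.2],
                "status": ["up", "down", "up", "up", "up", "ns"],
            }
        )
        summary = summarize_degs(table)
        assert summary["n_deg"] == 5
        assert summary["n_up"] == 4
        assert summary["pct_up"] == 80.0
        assert summary["fold_bin_counts"] == {
            "1-2": 1, "2-3": 1, "3-4": 1, "4-12": 1, ">=12": 1
        }
        assert summary["n_1_4"] == 3
        assert summary["pct_1_4"] == 60.0


class TestPearsonCorrelation:
    def test_self_correlation(self, profiles):
        assert pearson_correlation(profiles["A"], profiles["A"]) == pytest.approx(1.0)

    def test_doubling_invariance(self):
        profile = make_profile({f"g{i}": (i + 1) * 3 for i in range(10)}, 10_000)
        doubled = make_profile({f"g{i}": (i + 1) * 3 for i in range(10)}, 5_000)
        # the +1 in log2(tpm+1) makes doubling only near-affine
        assert pearson_correlation(profile, doubled) == pytest.approx(1.0, abs=1e-6)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(2)
        counts_a = {f"g{i}": int(c) for i, c in
                    enumerate(rng.integers(1, 500, 10))}
        counts_b = {f"g{i}": int(c) for i, c in
                    enumerate(rng.integers(1, 500, 10))}
        pa = make_profile(counts_a, 100_000)
        pb = make_profile(counts_b, 100_000)
        va = np.log2(pa.tpm.to_numpy() + 1)
        vb = np.log2(pb.tpm.to_numpy() + 1)
        n = len(va)
        expected = (
            (n * (va * vb).sum() - va.sum() * vb.sum())
            / math.sqrt(n * (va**2).sum() - va.sum() ** 2)
            / math.sqrt(n * (vb**2).sum() - vb.sum() ** 2)
        )
        assert pearson_correlation(pa, pb) == pytest.approx(expected, abs=1e-12)

    def test_too_few_genes_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation(make_profile({"g": 5}, 10),
                                make_profile({"g": 5}, 10))
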