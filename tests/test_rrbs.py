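import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylstage.genome import GenomicInterval
from methylstage.records import DMRecord, EARLY_ONSET, GT_SPECIFIC, HYPER, HYPO
from methylstage.rrbs import (
    conversion_efficiency,
    fisher_exact_2x3,
    read_bismark_coverage,
    read_cpg_counts,
    rrbs_coverage_summary,
    rrbs_dmps,
    rrbs_site_dmrs,
    write_cpg_counts,
)
from methylstage.rrbs import test_all_sites as run_site_tests


def freeman_halton_oracle(table) -> Fraction:
    """Brute-force exact p by independent enumeration with rational arithmetic.

    The conditional table probability is the product of per-column binomial
    draws of the first row, normalized by C(N, R1); p sums the probabilities
    of all margin-preserving tables no more probable than the observed one.
    """
    t = [[int(x) for x in row] for row in table]
    r1 = sum(t[0])
    cols = [t[0][j] + t[1][j] for j in range(3)]
    n = sum(cols)
    denom = math.comb(n, r1)

    def prob(a, b, c):
        return Fraction(
            math.comb(cols[0], a) * math.comb(cols[1], b) * math.comb(cols[2], c),
            denom,
        )

    p_obs = prob(*t[0])
    total = Fraction(0)
    for a in range(min(r1, cols[0]) + 1):
        for b in range(min(r1 - a, cols[1]) + 1):
            c = r1 - a - b
            if c <= cols[2]:
                p = prob(a, b, c)
                if p <= p_obs:
                    total += p
    return total


class TestConversionEfficiency:
    def test_at_the_conventional_floor(self):
        assert conversion_efficiency(98, 100) == pytest.approx(0.98)

    def test_perfect_conversion(self):
        assert conversion_efficiency(100, 100) == 1.0

    def test_below_floor_warns(self):
        with pytest.warns(UserWarning):
            assert conversion_efficiency(90, 100) == pytest.approx(0.90)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            conversion_efficiency(0, 0)


class TestFisherExact2x3:
    def test_balanced_table_gives_p_one(self):
        assert fisher_exact_2x3([[5, 5, 5], [5, 5, 5]]) == pytest.approx(1.0)

    def test_empty_column_reduces_to_2x2_fisher(self):
        # [[3,1],[1,3]] classical two-sided Fisher: 34/70
        assert fisher_exact_2x3([[3, 1, 0], [1, 3, 0]]) == pytest.approx(34 / 70)

    def test_extreme_separation_tiny_p(self):
        assert fisher_exact_2x3([[10, 0, 0], [0, 10, 10]]) < 1e-4

    def test_zero_row_single_table_p_one(self):
        assert fisher_exact_2x3([[0, 0, 0], [4, 5, 6]]) == 1.0

    def test_matches_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            t = rng.integers(0, 11, size=(2, 3))
            if t.sum() == 0:
                continue
            expected = float(freeman_halton_oracle(t))
            assert fisher_exact_2x3(t) == pytest.approx(expected, rel=1e-9), t

    @given(
        cells=st.lists(st.integers(0, 12), min_size=6, max_size=6).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_invariant_to_column_permutation_and_row_swap(self, cells):
        t = np.array(cells).reshape(2, 3)
        p0 = fisher_exact_2x3(t)
        for perm in itertools.permutations(range(3)):
            assert fisher_exact_2x3(t[:, perm]) == pytest.approx(p0, rel=1e-9)
        assert fisher_exact_2x3(t[::-1]) == pytest.approx(p0, rel=1e-9)

    def test_monte_carlo_fallback_agrees(self):
        t = [[40, 25, 10], [10, 25, 40]]
        exact = fisher_exact_2x3(t)
        mc = fisher_exact_2x3(t, mc_max_tables=1, mc_replicates=200_000, seed=11)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fisher_exact_2x3([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x3([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            fisher_exact_2x3([[-1, 1, 1], [1, 1, 1]])


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos",
            "gm_meth", "gm_unmeth", "im_meth", "im_unmeth", "gt_meth", "gt_unmeth",
        ],
    )


class TestTestAllSites:
    def test_shallow_sites_excluded_from_m(self):
        table = make_table(
            [
                ("chr1", 100, 2, 3, 10, 10, 10, 10),  # GM depth 5 < 10
                ("chr1", 200, 10, 10, 10, 10, 10, 10),
                ("chr1", 300, 1, 19, 10, 10, 18, 2),
            ]
        )
        res = run_site_tests(table, min_depth=10)
        assert len(res) == 2
        assert res.attrs["n_tested"] == 2
        assert set(res["pos"]) == {200, 300}

    def test_bonferroni_arithmetic(self):
        # p_bonferroni = min(1, p * m)
        table = make_table(
            [("chr1", i * 100, 10, 10, 10, 10, 10, 10) for i in range(5)]
        )
        res = run_site_tests(table, min_depth=10)
        np.testing.assert_allclose(
            res["p_bonferroni"], np.minimum(1.0, res["p_value"] * 5)
        )

    def test_strong_site_significant_after_correction(self):
        rows = [("chr1", i * 100, 10, 10, 10, 10, 10, 10) for i in range(50)]
        rows.append(("chr1", 9_999, 1, 29, 1, 29, 29, 1))
        res = run_site_tests(make_table(rows), min_depth=10)
        hit = res[res["pos"] == 9_999].iloc[0]
        assert hit["significant"]
        assert hit["diff_gt"] > 0.9

    def test_no_sites_warns(self):
        with pytest.warns(UserWarning):
            res = run_site_tests(make_table([("chr1", 1, 1, 1, 1, 1, 1, 1)]), min_depth=10)
        assert len(res) == 0


def site_test_frame(rows):
    """rows: (pos, p, p_bonf, sig, gm, im, gt)"""
    recs = []
    for pos, p, pb, sig, gm, im, gt in rows:
        recs.append(
            {
                "chrom": "chr1", "pos": pos,
                "p_value": p, "p_bonferroni": pb, "significant": sig,
                "gm_level": gm, "im_level": im, "gt_level": gt,
                "diff_im": im - gm, "diff_gt": gt - gm,
            }
        )
    return pd.DataFrame(recs)


class TestSiteDMRs:
    def test_threshold_rule(self):
        tests = site_test_frame([(100, 1e-9, 1e-6, True, 0.10, 0.11, 0.45)])
        calls = rrbs_site_dmrs(tests)
        assert len(calls) == 1
        assert calls[0].direction == HYPER
        assert calls[0].diff == pytest.approx(0.35)

    def test_gt_specific_without_im_change(self):
        tests = site_test_frame([(100, 1e-9, 1e-6, True, 0.10, 0.12, 0.45)])
        calls = rrbs_site_dmrs(tests)
        assert calls[0].comparison == "GT"
        assert calls[0].timing == GT_SPECIFIC

    def test_early_onset_with_concordant_im_change(self):
        tests = site_test_frame([(100, 1e-9, 1e-6, True, 0.10, 0.45, 0.55)])
        calls = rrbs_site_dmrs(tests)
        gt = [c for c in calls if c.comparison == "GT"][0]
        assert gt.timing == EARLY_ONSET

    def test_below_threshold_no_call(self):
        tests = site_test_frame([(100, 1e-9, 1e-6, True, 0.10, 0.25, 0.25)])
        assert rrbs_site_dmrs(tests) == []

    def test_insignificant_sites_ignored(self):
        tests = site_test_frame([(100, 0.5, 1.0, False, 0.1, 0.9, 0.9)])
        assert rrbs_site_dmrs(tests) == []


def site_call(pos, direction=HYPER, timing=GT_SPECIFIC, diff=0.4, p=1e-8):
    return DMRecord(
        region=GenomicInterval("chr1", pos, pos + 1),
        platform="RRBS",
        direction=direction,
        comparison="GT",
        timing=timing,
        diff=diff if direction == HYPER else -diff,
        p_value=p,
        p_adjusted=p * 100,
    )


class TestRrbsDmps:
    # tiny_annotation promoter: chr1 [49,000, 51,000)

    def test_three_sites_make_a_dmp(self, tiny_annotation):
        calls = [site_call(49_100), site_call(49_500), site_call(50_200)]
        dmps = rrbs_dmps(calls, tiny_annotation)
        assert len(dmps) == 1
        assert dmps[0].direction == HYPER
        assert dmps[0].gene_id == "geneA"

    def test_two_sites_are_not_enough(self, tiny_annotation):
        calls = [site_call(49_100), site_call(49_500)]
        assert rrbs_dmps(calls, tiny_annotation) == []

    def test_majority_rule_direction(self, tiny_annotation):
        calls = [site_call(49_100 + i * 50) for i in range(4)] + [
            site_call(50_500, direction=HYPO)
        ]
        dmps = rrbs_dmps(calls, tiny_annotation)
        assert dmps[0].direction == HYPER

    def test_adding_a_site_never_removes_the_dmp(self, tiny_annotation):
        calls = [site_call(49_100), site_call(49_500), site_call(50_200)]
        base = rrbs_dmps(calls, tiny_annotation)
        more = rrbs_dmps(calls + [site_call(50_700)], tiny_annotation)
        assert len(more) >= len(base) == 1

    def test_timing_requires_min_sites_early(self, tiny_annotation):
        calls = [
            site_call(49_100, timing=EARLY_ONSET),
            site_call(49_500, timing=EARLY_ONSET),
            site_call(50_200, timing=GT_SPECIFIC),
        ]
        assert rrbs_dmps(calls, tiny_annotation)[0].timing == GT_SPECIFIC
        calls[2] = site_call(50_200, timing=EARLY_ONSET)
        assert rrbs_dmps(calls, tiny_annotation)[0].timing == EARLY_ONSET


class TestCoverageSummary:
    def test_no_covered_sites(self, tiny_annotation):
        table = make_table([])
        universe = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [100, 49_500, 10_500]})
        res = rrbs_coverage_summary(table, tiny_annotation, universe)
        assert (res["covered_fraction"] == 0).all()

    def test_all_covered(self, tiny_annotation):
        universe = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 49_500]})
        table = make_table(
            [("chr1", 100, 1, 1, 1, 1, 1, 1), ("chr1", 49_500, 2, 2, 2, 2, 2, 2)]
        )
        res = rrbs_coverage_summary(table, tiny_annotation, universe)
        assert (res["covered_fraction"].dropna() == 1.0).all()

    def test_simulated_cgi_fraction_matches_config(self, default_dataset):
        ds = default_dataset
        universe = pd.concat(
            [
                pd.DataFrame({"chrom": c, "pos": p})
                for c, p in ds.cpg_positions.items()
            ],
            ignore_index=True,
        )
        res = rrbs_coverage_summary(ds.rrbs_counts, ds.annotation, universe)
        cgi = res.set_index("region_class").loc["CGIs", "covered_fraction"]
        inter = res.set_index("region_class").loc["intergenic", "covered_fraction"]
        assert cgi == pytest.approx(ds.config.rrbs_covered_frac_cgi, abs=0.03)
        assert inter == pytest.approx(ds.config.rrbs_covered_frac_bg, abs=0.02)
        assert cgi > 3 * inter


class TestIO:
    def test_cpg_count_roundtrip(self, tmp_path):
        table = make_table(
            [("chr1", 100, 1, 2, 3, 4, 5, 6), ("chr2", 7, 0, 9, 8, 7, 6, 5)]
        )
        path = tmp_path / "counts.tsv"
        write_cpg_counts(table, path)
        back = read_cpg_counts(path)
        pd.testing.assert_frame_equal(back, table)

    def test_bismark_merge(self, tmp_path):
        # per-sample 1-based coverage files; site missing from one sample -> 0
        for sample, rows in {
            "gm": [("chr1", 101, 101, 50.0, 5, 5)],
            "im": [("chr1", 101, 101, 80.0, 8, 2), ("chr1", 201, 201, 0.0, 0, 9)],
            "gt": [("chr1", 101, 101, 100.0, 9, 0)],
        }.items():
            pd.DataFrame(rows).to_csv(
                tmp_path / f"{sample}.cov", sep="\t", header=False, index=False
            )
        merged = read_bismark_coverage(
            {s: tmp_path / f"{s}.cov" for s in ("gm", "im", "gt")}
        )
        assert len(merged) == 2
        row = merged[merged["pos"] == 100].iloc[0]
        assert (row["gm_meth"], row["im_meth"], row["gt_meth"]) == (5, 8, 9)
        assert merged[merged["pos"] == 200].iloc[0]["gm_meth"] == 0
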