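"""Normalization, filtering, DE and overlap operations against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexdiff import preprocess, synthetic
from coexdiff.preprocess import (
    bh_fdr,
    cpm,
    filter_low_expression,
    fit_de,
    log_cpm,
    match_cohorts,
    overlap_from_counts,
    overlap_summary,
    select_de,
    tmm_factors,
)
from coexdiff.synthetic import CohortDesign, CountData, GeneratorParams


def make_count_data(mat: np.ndarray, cohorts=None) -> CountData:
    genes = [f"g{i}" for i in range(mat.shape[0])]
    samples = [f"s{j}" for j in range(mat.shape[1])]
    cohorts = cohorts or ["tumorA"] * mat.shape[1]
    meta = pd.DataFrame({"cohort": cohorts, "gleason": 7}, index=samples)
    return CountData(pd.DataFrame(mat, index=genes, columns=samples), meta)


class TestCpm:
    def test_single_sample_definition(self):
        data = make_count_data(np.array([[1], [3]]))
        out = cpm(data)
        assert out.iloc[:, 0].tolist() == [250000.0, 750000.0]

    def test_columns_sum_to_million(self, rng):
        data = make_count_data(rng.integers(0, 100, (50, 8)) + 1)
        assert np.allclose(cpm(data).sum(axis=0), 1e6)

    def test_depth_invariance(self, rng):
        mat = rng.integers(0, 100, (30, 3)) + 1
        doubled = mat.copy()
        doubled[:, 1] *= 2
        a = cpm(make_count_data(mat))
        b = cpm(make_count_data(doubled))
        assert np.allclose(a.iloc[:, 1], b.iloc[:, 1])

    def test_zero_library_names_sample(self):
        data = make_count_data(np.array([[1, 0], [1, 0]]))
        with pytest.raises(ValueError, match="s1"):
            cpm(data)


class TestFilter:
    def test_boundary_fraction_kept(self):
        # CPM > 1 in exactly half the samples meets the >= 0.5 rule
        mat = np.full((1, 98), 0)
        mat[0, :49] = 100
        bg = np.full((9, 98), 1000)
        data = make_count_data(np.vstack([mat, bg]))
        kept = filter_low_expression(data)
        assert "g0" in kept.counts.index

    def test_all_zero_removed(self):
        mat = np.vstack([np.zeros((1, 10)), np.full((4, 10), 50)])
        kept = filter_low_expression(make_count_data(mat))
        assert "g0" not in kept.counts.index

    def test_matches_brute_force(self, rng):
        mat = rng.integers(0, 30, (200, 20))
        mat[:, 0] += 1  # avoid zero library
        data = make_count_data(mat)
        kept = set(filter_low_expression(data).counts.index)
        c = cpm(data)
        expected = {
            g for g in data.counts.index
            if (c.loc[g] > 1.0).sum() >= 0.5 * c.shape[1]
        }
        assert kept == expected


class TestTmm:
    def test_identical_samples_unit_factors(self):
        mat = np.tile(np.arange(1, 51)[:, None], (1, 4))
        f = tmm_factors(make_count_data(mat))
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference(self, rng):
        base = rng.integers(5, 500, (400, 1))
        mat = np.hstack([base, base * 3, base * 7])
        f = tmm_factors(make_count_data(mat))
        assert np.allclose(f, 1.0, atol=0.02)

    def test_asymmetric_inflation_against_direct_formula(self, rng):
        base = rng.integers(20, 500, (400, 2)).astype(float)
        mat = base.copy()
        idx = rng.choice(400, 20, replace=False)
        mat[idx, 1] *= 8  # 5% of genes 8-fold inflated in sample 2
        data = make_count_data(mat.astype(int))
        f = tmm_factors(data)

        # independent direct evaluation of the trimmed weighted mean
        vals = data.counts.to_numpy().astype(float)
        lib = vals.sum(axis=0)
        o, r = vals[:, 1] / lib[1], vals[:, 0] / lib[0]
        pos = (vals[:, 1] > 0) & (vals[:, 0] > 0)
        m = np.log2(o[pos] / r[pos])
        a = 0.5 * np.log2(o[pos] * r[pos])
        w = (lib[1] - vals[pos, 1]) / (lib[1] * vals[pos, 1]) + (
            lib[0] - vals[pos, 0]
        ) / (lib[0] * vals[pos, 0])
        keep = (
            (m >= np.quantile(m, 0.3)) & (m <= np.quantile(m, 0.7))
            & (a >= np.quantile(a, 0.05)) & (a <= np.quantile(a, 0.95))
        )
        expected = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected /= np.sqrt(expected * 1.0)  # geometric-mean rescaling over 2 samples
        assert f.iloc[1] == pytest.approx(expected, rel=0.05)


class TestLogCpm:
    def test_zero_count_value(self):
        # zero count in a library of exactly 1e6 (carried by a second gene)
        data = make_count_data(np.array([[0], [10**6]]))
        out = log_cpm(data, prior_count=0.5)
        assert out.loc["g0", "s0"] == pytest.approx(-1.0000014, abs=1e-5)

    def test_monotone_in_count(self, rng):
        mat = rng.integers(0, 1000, (30, 2))
        out = log_cpm(make_count_data(mat))
        order = np.argsort(mat[:, 0], kind="stable")
        sorted_counts = mat[order, 0]
        sorted_vals = out.iloc[order, 0].to_numpy()
        strict = np.diff(sorted_counts) > 0
        assert (np.diff(sorted_vals)[strict] > 0).all()

    def test_limit_matches_plain_cpm(self, rng):
        mat = rng.integers(1000, 50000, (50, 3))
        data = make_count_data(mat)
        lc = log_cpm(data)
        assert np.allclose(lc, np.log2(cpm(data)), atol=0.01)

    def test_bad_prior(self):
        with pytest.raises(ValueError):
            log_cpm(make_count_data(np.ones((2, 2), int)), prior_count=0)


class TestBhFdr:
    def test_hand_computed(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        # min over j >= i of m * p_(j) / j, at each gene's rank
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            vals = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
            expected[idx] = min(1.0, min(vals))
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)


@pytest.fixture(scope="module")
def de_setup():
    ann = synthetic.generate_annotation(150, 50, 0, seed=9)
    params = GeneratorParams(de_fraction=0.2, modules=())
    data, truth = synthetic.generate_counts(CohortDesign(), ann, params, seed=9)
    data = filter_low_expression(data)
    lc = log_cpm(data, tmm_factors(data))
    return ann, data, truth, lc


class TestFitDe:
    def test_constant_gene_degenerate(self, de_setup):
        ann, data, truth, lc = de_setup
        lc = lc.copy()
        lc.iloc[0] = 3.14
        de = fit_de(lc, data.sample_meta)
        assert de["log2fc"].iloc[0] == 0.0
        assert de["p_raw"].iloc[0] == 1.0

    def test_planted_effects_recovered(self, de_setup):
        ann, data, truth, lc = de_setup
        de = fit_de(lc, data.sample_meta, "tumorA", "normal")
        planted = [g for g in truth.de_genes["tumorA"] if g in de.index]
        sel = (de["log2fc"].abs() > 1) & (de["fdr"] < 0.01)
        assert sel.loc[planted].mean() > 0.9
        # estimated log2fc signs agree with planted signs
        signs = np.sign([truth.de_genes["tumorA"][g] for g in planted])
        assert (np.sign(de.loc[planted, "log2fc"]) == signs).mean() > 0.95

    def test_too_few_samples(self, de_setup):
        ann, data, truth, lc = de_setup
        meta = data.sample_meta.copy()
        meta.loc[meta["cohort"] == "normal", "cohort"] = "gone"
        meta.iloc[0, meta.columns.get_loc("cohort")] = "normal"
        with pytest.raises(ValueError):
            fit_de(lc, meta, "tumorA", "normal")


class TestSelectDe:
    def make_de(self, rows):
        de = pd.DataFrame(rows, columns=["log2fc", "fdr"],
                          index=[f"g{i}" for i in range(len(rows))])
        de["p_raw"] = de["fdr"]
        de["direction"] = np.where(de["log2fc"] >= 0, "up", "down")
        ann = pd.DataFrame(
            {"gene_id": de.index, "biotype": "mRNA"}, index=de.index
        )
        return de, ann

    def test_below_fc_bound_not_selected(self):
        de, ann = self.make_de([(0.9, 0.001)])
        sets = select_de(de, ann)
        assert all(len(v) == 0 for v in sets.values())

    def test_table3_style_row_selected_down(self):
        de, ann = self.make_de([(-2.51, 1.53e-8)])
        sets = select_de(de, ann)
        assert sets["mrna_down"] == ["g0"]

    def test_degenerate_thresholds(self):
        de, ann = self.make_de([(0.1, 0.5), (-0.01, 0.99), (0.0, 0.3)])
        sets = select_de(de, ann, fc_linear=1.0, fdr_max=1.0)
        selected = set().union(*sets.values())
        assert selected == {"g0", "g1"}  # |log2fc| > 0 and fdr < 1

    def test_missing_biotype_error(self):
        de, ann = self.make_de([(2.0, 0.001)])
        with pytest.raises(ValueError):
            select_de(de, ann.drop(index=["g0"]))


class TestOverlap:
    def test_fixture_percentage(self):
        venn = synthetic.load_fixture("venn_counts").set_index("category")
        row = venn.loc["mrna_up"]
        out = overlap_from_counts(int(row["size_a"]), int(row["size_b"]), int(row["shared"]))
        assert out.pct_a_shared == 69.7

    def test_identical_and_disjoint(self):
        a = {"x": ["g1", "g2"]}
        assert overlap_summary(a, a).loc["x", "pct_a_shared"] == 100.0
        out = overlap_summary(a, {"x": ["g3"]})
        assert out.loc["x", "shared"] == 0
        assert out.loc["x", "pct_a_shared"] == 0.0

    def test_shared_bounded(self, rng):
        a = {"x": [f"g{i}" for i in rng.choice(50, 20, replace=False)]}
        b = {"x": [f"g{i}" for i in rng.choice(50, 30, replace=False)]}
        row = overlap_summary(a, b).loc["x"]
        assert row["shared"] <= min(row["size_a"], row["size_b"])


class TestMatchCohorts:
    def make_meta(self, scores):
        return pd.DataFrame(
            {"gleason": scores}, index=[f"s{i}{v}" for i, v in enumerate(scores)]
        )

    def test_stratum_sizes_preserved(self):
        a = self.make_meta([6] * 9 + [7] * 5)
        b = self.make_meta([6] * 20 + [7] * 10)
        sel = match_cohorts(a, b, seed=1)
        assert len(sel) == len(a)
        assert sum(1 for s in sel if b.loc[s, "gleason"] == 6) == 9

    def test_empty_a(self):
        a = self.make_meta([])
        b = self.make_meta([6, 7])
        assert match_cohorts(a, b, seed=1) == []

    def test_deterministic(self):
        a = self.make_meta([6] * 4)
        b = self.make_meta([6] * 30)
        assert match_cohorts(a, b, seed=5) == match_cohorts(a, b, seed=5)

    def test_insufficient_stratum(self):
        a = self.make_meta([6, 6])
        b = self.make_meta([6])
        with pytest.raises(ValueError, match="6"):
            match_cohorts(a, b, seed=0)
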