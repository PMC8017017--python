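"""Filters, the arcsine-WLS site model against an algebraic oracle, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset, make_sheet
from evomethylome import diffmeth
from evomethylome.diffmeth import (adjust_fdr, arcsine_transform,
                                   build_design_matrix, filter_coverage_cg,
                                   filter_sites_ch, fit_site_model, fit_sites,
                                   pairwise_species_tests,
                                   select_and_downsample)


class TestCoverageFilters:
    def test_cg_80_percent_boundary_retained(self):
        sheet = make_sheet([("human", "NeuN", 10)])
        cov = np.array([[5] * 8 + [4, 4]])
        ds = make_dataset(cov, np.zeros_like(cov), sheet)
        assert filter_coverage_cg(ds)[0]  # 8/10 = 0.8 >= 0.8

    def test_all_zero_coverage_removed(self):
        sheet = make_sheet([("human", "NeuN", 5)])
        cov = np.zeros((1, 5), dtype=int)
        ds = make_dataset(cov, cov, sheet)
        assert not filter_coverage_cg(ds)[0]

    def test_cg_matches_brute_force(self):
        rng = np.random.default_rng(5)
        sheet = make_sheet([("human", "NeuN", 5), ("chimpanzee", "NeuN", 5),
                            ("human", "OLIG2", 5)])
        cov = rng.integers(0, 12, size=(30, 15))
        ds = make_dataset(cov, np.zeros_like(cov), sheet)
        got = filter_coverage_cg(ds, min_depth=5, min_frac=0.8)
        for s in range(30):
            expect = True
            for by in ("species", "cell_type"):
                for _, grp in sheet.groupby(by):
                    cols = sheet.index.get_indexer(grp.index)
                    frac = np.mean(cov[s, cols] >= 5)
                    expect &= frac >= 0.8
            assert got[s] == expect, s

    def test_ch_majority_low_coverage_removed(self):
        sheet = make_sheet([("human", "NeuN", 11)])
        cov = np.array([[4] * 6 + [20] * 5])  # 6/11 > 0.5 below 5 reads
        ds = make_dataset(cov, np.zeros_like(cov), sheet, context="CH")
        assert not filter_sites_ch(ds)[0]

    def test_ch_exactly_half_retained(self):
        sheet = make_sheet([("human", "NeuN", 10)])
        cov = np.array([[4] * 5 + [20] * 5])  # 5/10 is not > 0.5
        ds = make_dataset(cov, np.zeros_like(cov), sheet, context="CH")
        assert filter_sites_ch(ds)[0]

    def test_ch_matches_brute_force(self):
        rng = np.random.default_rng(6)
        sheet = make_sheet([("human", "NeuN", 7), ("chimpanzee", "NeuN", 7)])
        cov = rng.integers(0, 10, size=(40, 14))
        ds = make_dataset(cov, np.zeros_like(cov), sheet, context="CH")
        got = filter_sites_ch(ds, min_reads=5)
        labels = sheet["species"] + "_" + sheet["cell_type"]
        for s in range(40):
            removed = False
            for g in labels.unique():
                cols = np.flatnonzero((labels == g).to_numpy())
                if np.mean(cov[s, cols] < 5) > 0.5:
                    removed = True
            assert got[s] == (not removed), s


class TestSelectAndDownsample:
    def sheet(self, n=15, conv=0.998):
        return make_sheet([("macaque", "NeuN", n)], conversion=conv)

    def test_downsamples_to_eleven(self):
        chosen = select_and_downsample(self.sheet(15), seed=0)
        assert len(chosen) == 11 and len(set(chosen)) == 11

    def test_low_conversion_ineligible(self):
        sheet = self.sheet(12)
        sheet.loc[0, "conversion_rate"] = 0.992
        chosen = select_and_downsample(sheet, seed=1)
        assert sheet.loc[0, "sample_id"] not in chosen

    def test_exactly_eleven_seed_independent(self):
        sheet = self.sheet(11)
        assert (select_and_downsample(sheet, seed=1)
                == select_and_downsample(sheet, seed=99))

    def test_insufficient_raises_with_group_name(self):
        with pytest.raises(diffmeth.GroupError, match="macaque"):
            select_and_downsample(self.sheet(15, conv=0.99))


def wls_oracle(meth, total, X, delta=0.5):
    """Independent per-site WLS by sqrt-weight rescaling + lstsq."""
    out = []
    for m_row, t_row in zip(meth, total):
        w = t_row.astype(float)
        keep = w > 0
        y = np.arcsin(2 * (m_row[keep] + delta) / (t_row[keep] + 2 * delta) - 1)
        sw = np.sqrt(w[keep])
        Xw = X[keep] * sw[:, None]
        yw = y * sw
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        df = keep.sum() - X.shape[1]
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
        out.append((beta, np.sqrt(np.diag(cov))))
    return out


class TestSiteModel:
    def two_group_fixture(self):
        sheet = make_sheet([("human", "NeuN", 3), ("human", "OLIG2", 3)])
        sheet["sex"] = "F"          # tiny n: covariates held constant
        sheet["age_class"] = "young"
        total = np.array([[12, 9, 15, 10, 11, 14],
                          [20, 18, 22, 19, 25, 21],
                          [7, 8, 6, 9, 10, 7]])
        meth = np.array([[10, 7, 12, 3, 2, 4],
                         [5, 6, 4, 15, 19, 16],
                         [3, 4, 3, 4, 5, 3]])
        return make_dataset(total * 0 + total, meth, sheet), sheet, total, meth

    def test_identical_groups_zero_statistic(self):
        sheet = make_sheet([("human", "NeuN", 4), ("human", "OLIG2", 4)])
        total = np.full((2, 8), 10)
        meth = np.full((2, 8), 6)
        ds = make_dataset(total, meth, sheet)
        res = fit_site_model(ds, terms=("cell_type",))
        assert np.allclose(res["stat"], 0.0, atol=1e-10)

    def test_matches_algebraic_oracle(self):
        ds, sheet, total, meth = self.two_group_fixture()
        design = build_design_matrix(sheet, ("cell_type",))
        res = fit_sites(ds, design)
        j = design.term_columns["cell_type"]
        oracle = wls_oracle(meth, total, design.X)
        for s in range(3):
            b, se = oracle[s]
            row = res.iloc[s]
            assert row["coef"] == pytest.approx(b[j], rel=1e-8)
            assert row["se"] == pytest.approx(se[j], rel=1e-8)
            assert row["stat"] == pytest.approx(b[j] / se[j], rel=1e-8)

    def test_oracle_on_random_multifactor_designs(self):
        rng = np.random.default_rng(9)
        sheet = make_sheet([("human", "NeuN", 8), ("human", "OLIG2", 8),
                            ("chimpanzee", "NeuN", 8),
                            ("chimpanzee", "OLIG2", 8)])
        sheet["conversion_rate"] = rng.uniform(0.995, 0.999, len(sheet))
        total = rng.integers(5, 30, size=(20, 32))
        meth = rng.binomial(total, 0.6)
        ds = make_dataset(total, meth, sheet)
        design = build_design_matrix(sheet)
        res = fit_sites(ds, design)
        oracle = wls_oracle(meth, total, design.X)
        for term, j in design.term_columns.items():
            stats = res[res["term"] == term]["stat"].to_numpy()
            expect = np.array([b[j] / se[j] for b, se in oracle])
            np.testing.assert_allclose(stats, expect, rtol=1e-8)

    def test_sign_matches_group_difference(self):
        rng = np.random.default_rng(10)
        sheet = make_sheet([("human", "NeuN", 6), ("human", "OLIG2", 6)])
        total = rng.integers(8, 25, size=(30, 12))
        p = np.where(rng.random((30, 1)) < 0.5, 0.3, 0.7)
        p_mat = np.where(np.arange(12) < 6, p, 1 - p)
        meth = rng.binomial(total, p_mat)
        ds = make_dataset(total, meth, sheet)
        res = fit_site_model(ds, terms=("cell_type",))
        gm = ds.group_means()
        diff = gm["human_NeuN"] - gm["human_OLIG2"]
        big = np.abs(diff) > 0.15
        assert (np.sign(res["stat"][big.to_numpy()])
                == np.sign(diff[big])).all()

    @given(st.integers(2, 5))
    @settings(max_examples=10, deadline=None)
    def test_count_scaling_never_flips_sign(self, k):
        # exact invariance holds for the raw arcsine response (delta = 0):
        # y is a function of the proportion alone and all weights scale by k
        rng = np.random.default_rng(12)
        sheet = make_sheet([("human", "NeuN", 5), ("human", "OLIG2", 5)])
        total = rng.integers(4, 15, size=(10, 10))
        meth = rng.binomial(total, rng.random((10, 1)))
        r1 = fit_site_model(make_dataset(total, meth, sheet),
                            terms=("cell_type",), delta=0.0)
        r2 = fit_site_model(make_dataset(total * k, meth * k, sheet),
                            terms=("cell_type",), delta=0.0)
        s1, s2 = r1["stat"].to_numpy(), r2["stat"].to_numpy()
        nz = (np.abs(s1) > 1e-9) & (np.abs(s2) > 1e-9)
        assert (np.sign(s1[nz]) == np.sign(s2[nz])).all()

    def test_power_at_thirty_point_effect(self):
        """Cell-type effect of 0.30, n=11/group, ~20x coverage.

        Frozen Monte-Carlo oracle: with binomial sampling the Wald test
        detects the effect at p < 1e-4 in ~90% of replicates (noncentral-t
        with ~6.5 noncentrality against the 4.5 critical value at ~20 df),
        and at p < 0.01 essentially always.
        """
        rng = np.random.default_rng(13)
        sheet = make_sheet([("human", "NeuN", 11), ("human", "OLIG2", 11)])
        design = build_design_matrix(sheet, ("cell_type",))
        strict = loose = 0
        n_rep = 200
        for _ in range(n_rep):
            total = rng.negative_binomial(10, 10 / 30, size=(1, 22)) + 1
            p = np.where(np.arange(22) < 11, 0.75, 0.45)
            meth = rng.binomial(total, p)
            ds = make_dataset(total, meth, sheet)
            res = fit_sites(ds, design)
            strict += res["p"].iloc[0] < 1e-4
            loose += res["p"].iloc[0] < 1e-2
        assert strict / n_rep >= 0.85
        assert loose / n_rep >= 0.99

    def test_group_entirely_missing_flagged(self):
        sheet = make_sheet([("human", "NeuN", 3), ("human", "OLIG2", 3)])
        sheet["sex"] = "F"
        sheet["age_class"] = "young"
        total = np.array([[10, 12, 9, 0, 0, 0]])
        meth = np.array([[5, 6, 4, 0, 0, 0]])
        ds = make_dataset(total, meth, sheet)
        res = fit_site_model(ds, terms=("cell_type",))
        assert not res["tested"].iloc[0]
        assert np.isnan(res["stat"].iloc[0])


class TestPairwise:
    def three_species_ds(self, rng, effect=0.0):
        sheet = make_sheet([("human", "NeuN", 6), ("chimpanzee", "NeuN", 6),
                            ("macaque", "NeuN", 6)])
        total = rng.integers(10, 30, size=(25, 18))
        p = np.full((25, 18), 0.5)
        p[:, :6] += effect
        meth = rng.binomial(total, p)
        return make_dataset(total, meth, sheet, context="CH"), sheet

    def test_sign_agrees_with_mean_difference(self):
        ds, _ = self.three_species_ds(np.random.default_rng(14), effect=0.25)
        res = pairwise_species_tests(ds, ("human", "chimpanzee"),
                                     cell_type="NeuN")
        strong = np.abs(res["diff"]) > 0.15
        assert (np.sign(res.loc[strong, "stat"])
                == np.sign(res.loc[strong, "diff"])).all()

    def test_equals_restricted_joint_fit(self):
        ds, sheet = self.three_species_ds(np.random.default_rng(15))
        res_pair = pairwise_species_tests(ds, ("chimpanzee", "human"),
                                          cell_type="NeuN")
        ids = sheet.loc[sheet["species"] != "macaque", "sample_id"]
        sub = ds.subset_samples(ids)
        res_joint = fit_site_model(sub, terms=("species",))
        np.testing.assert_allclose(res_pair["stat"], res_joint["stat"],
                                   rtol=1e-10)

    def test_identical_distributions_near_zero(self):
        ds, _ = self.three_species_ds(np.random.default_rng(16))
        res = pairwise_species_tests(ds, ("human", "macaque"),
                                     cell_type="NeuN")
        # Wald statistics behave like null t draws: small on average
        assert np.abs(res["stat"]).mean() < 2.0


class TestFdr:
    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1, 1, 1]), [1, 1, 1])

    def test_hand_computed_bh(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.037])[0] == pytest.approx(0.037)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p_over_rank(self, ps):
        q = adjust_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()
        # monotone in p after sorting
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestArcsine:
    def test_monotone_and_bounded(self):
        t = np.array([10.0] * 5)
        m = np.array([0.0, 2, 5, 8, 10])
        y = arcsine_transform(m, t)
        assert (np.diff(y) > 0).all()
        assert (np.abs(y) < np.pi / 2).all()  # delta keeps ends interior
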