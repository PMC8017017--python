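"""Outgroup mapping, beta regression oracle, classification truth tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from conftest import make_sheet
from evomethylome import polarize
from evomethylome.io_formats import OrthologyMap
from evomethylome.polarize import (classify_celltype_conservation,
                                   classify_ch_dmr, classify_ch_site,
                                   classify_interaction_dmr,
                                   classify_species_dmr, fit_region_beta,
                                   map_to_outgroup, shared_ch_dmrs,
                                   squeeze_unit)


def omap_with(blocks):
    return OrthologyMap(pd.DataFrame(blocks,
                                     columns=["species", "chrom", "start",
                                              "end"]))


CG = pd.DataFrame({"chrom": ["chr1"] * 10, "pos": np.arange(0, 1000, 100)})


class TestMapToOutgroup:
    def test_low_coverage_unclassified(self):
        omap = omap_with([("macaque", "chr1", 0, 400)])
        m = map_to_outgroup({"chrom": "chr1", "start": 0, "end": 1000}, omap, CG)
        assert not m.ok and m.reason == "low_alignment"
        assert m.alignment_coverage == pytest.approx(0.4)

    def test_full_coverage_enough_cg_mapped(self):
        omap = omap_with([("macaque", "chr1", 0, 1000)])
        m = map_to_outgroup({"chrom": "chr1", "start": 0, "end": 1000}, omap, CG)
        assert m.ok and m.n_outgroup_cg == 10

    def test_too_few_outgroup_cg(self):
        omap = omap_with([("macaque", "chr1", 0, 1000)])
        few = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 20, 30]})
        m = map_to_outgroup({"chrom": "chr1", "start": 0, "end": 1000},
                            omap, few)
        assert not m.ok and m.reason == "few_outgroup_cg"

    def test_absent_chrom_reason_code(self):
        omap = omap_with([("macaque", "chr2", 0, 1000)])
        m = map_to_outgroup({"chrom": "chr1", "start": 0, "end": 100}, omap, CG)
        assert not m.ok and m.reason == "chrom_absent"

    def test_coverage_matches_interval_arithmetic_oracle(self):
        rng = np.random.default_rng(31)
        edges = np.sort(rng.choice(10_000, 20, replace=False))
        blocks = [("macaque", "chr1", int(edges[i]), int(edges[i + 1]))
                  for i in range(0, 18, 2)]
        omap = omap_with(blocks)
        for _ in range(20):
            s = int(rng.integers(0, 9000))
            e = s + int(rng.integers(50, 900))
            cov = omap.alignment_coverage("macaque", "chr1", s, e)
            # brute-force over base pairs
            bp = np.zeros(10_000, dtype=bool)
            for _, _, bs, be in blocks:
                bp[bs:be] = True
            assert cov == pytest.approx(bp[s:e].mean())


def beta_loglik(params, y, X):
    k = X.shape[1]
    mu = special.expit(X @ params[:k])
    phi = np.exp(params[k])
    a, b = mu * phi, (1 - mu) * phi
    return -np.sum((a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
                   - special.betaln(a, b))


class TestRegionBeta:
    def test_identical_distributions_no_signal(self):
        rng = np.random.default_rng(32)
        sheet = make_sheet([("human", "NeuN", 8), ("chimpanzee", "NeuN", 8),
                            ("macaque", "NeuN", 8)])
        y = rng.beta(30, 30, len(sheet))
        out = fit_region_beta(y, sheet)
        assert out["converged"]
        for a, b in polarize.CONTRASTS:
            assert out[f"p_{a}_vs_{b}"] > 0.01

    def test_matches_independent_mle(self):
        rng = np.random.default_rng(33)
        sheet = make_sheet([("human", "NeuN", 3), ("chimpanzee", "NeuN", 3)])
        sheet["sex"] = "F"
        sheet["age_class"] = "young"
        y = np.array([0.71, 0.64, 0.69, 0.35, 0.41, 0.38])
        out = fit_region_beta(y, sheet)
        assert out["converged"]
        # independent numeric ML on the identical design
        yy = np.clip(squeeze_unit(y, len(y)), 1e-6, 1 - 1e-6)
        X = np.column_stack([np.ones(6),
                             (sheet["species"] == "human").to_numpy(float)])
        res = optimize.minimize(beta_loglik, x0=np.zeros(3), args=(yy, X),
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        # human vs chimpanzee logit-scale contrast equals +beta_human
        assert out["est_human_vs_chimpanzee"] == pytest.approx(res.x[1],
                                                              abs=1e-6)

    def test_logit_shift_recovered(self):
        rng = np.random.default_rng(34)
        hits = 0
        n_rep = 60
        shift = 1.0
        for _ in range(n_rep):
            sheet = make_sheet([("human", "NeuN", 11),
                                ("chimpanzee", "NeuN", 11)])
            mu_c = special.expit(0.0)
            mu_h = special.expit(shift)
            phi = 60
            y = np.concatenate([
                rng.beta(mu_h * phi, (1 - mu_h) * phi, 11),
                rng.beta(mu_c * phi, (1 - mu_c) * phi, 11)])
            out = fit_region_beta(y, sheet)
            if not out["converged"]:
                continue
            est = out["est_human_vs_chimpanzee"]
            # within a generous CI of the true logit shift
            if abs(est - shift) < 0.8:
                hits += 1
        assert hits / n_rep >= 0.9


def species_stats(h, c, m, q_hc=0.01, q_hm=0.01, q_cm=0.5):
    return {"q_hc": q_hc, "q_hm": q_hm, "q_cm": q_cm,
            "mean_human": h, "mean_chimp": c, "mean_macaque": m}


class TestClassifySpeciesDmr:
    def test_clear_human_hypo(self):
        st = species_stats(0.20, 0.60, 0.62)
        assert classify_species_dmr({"NeuN": st, "OLIG2": st}) == \
            "human_specific_hypo"

    def test_equal_means_unclassified(self):
        st = species_stats(0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
        assert classify_species_dmr({"NeuN": st, "OLIG2": st}) == "unclassified"

    def test_one_celltype_failing_blocks_call(self):
        good = species_stats(0.20, 0.60, 0.62)
        bad = species_stats(0.55, 0.60, 0.62, q_hc=0.5, q_hm=0.5)
        assert classify_species_dmr({"NeuN": good, "OLIG2": bad}) == \
            "unclassified"

    def test_symmetry_human_chimp_swap(self):
        rng = np.random.default_rng(35)
        for _ in range(200):
            h, c, m = rng.random(3)
            qs = rng.choice([0.01, 0.5], 3)
            st = species_stats(h, c, m, *qs)
            sw = {"q_hc": st["q_hc"], "q_hm": st["q_cm"], "q_cm": st["q_hm"],
                  "mean_human": c, "mean_chimp": h, "mean_macaque": m}
            lab = classify_species_dmr({"NeuN": st, "OLIG2": st})
            lab_sw = classify_species_dmr({"NeuN": sw, "OLIG2": sw})
            expect = (lab.replace("human", "X").replace("chimp", "human")
                      .replace("X", "chimp"))
            assert lab_sw == expect, (st, lab, lab_sw)

    def test_truth_table_matches_written_criteria(self):
        """Exhaustive grid over orderings and significance patterns."""
        grid = [0.2, 0.45, 0.48, 0.52, 0.55, 0.8]
        qs = [0.01, 0.5]
        for h in grid:
            for c in grid:
                for m in grid:
                    for q_hc in qs:
                        for q_hm in qs:
                            for q_cm in qs:
                                st = species_stats(h, c, m, q_hc, q_hm, q_cm)
                                got = classify_species_dmr(
                                    {"NeuN": st, "OLIG2": st})
                                expect = self.oracle(h, c, m, q_hc, q_hm, q_cm)
                                assert got == expect, st

    @staticmethod
    def oracle(h, c, m, q_hc, q_hm, q_cm):
        hm, cm = abs(h - m), abs(c - m)
        # human-derived criteria (1)-(3)
        if q_hc < 0.05 and q_hm < 0.05 and hm > cm and hm > 0.05:
            if h < c and h < m:
                return "human_specific_hypo"
            if h > c and h > m:
                return "human_specific_hyper"
        if q_hc < 0.05 and q_cm < 0.05 and cm > hm and cm > 0.05:
            if c < h and c < m:
                return "chimp_specific_hypo"
            if c > h and c > m:
                return "chimp_specific_hyper"
        return "unclassified"

    def test_interaction_single_celltype(self):
        st = species_stats(0.20, 0.60, 0.62)
        out = classify_interaction_dmr(st, "NeuN")
        assert out["evo_class"] == "celltype_restricted_species_change"
        assert out["lineage"] == "human" and out["direction"] == "hypo"
        null = classify_interaction_dmr(
            species_stats(0.5, 0.5, 0.5, 0.5, 0.5, 0.5), "NeuN")
        assert null["evo_class"] == "unclassified"


class TestClassifyCelltypeConservation:
    def test_conserved_when_outgroup_agrees(self):
        assert classify_celltype_conservation(0.5, 0.8, 0.3) == \
            "conserved_celltype"

    def test_outgroup_no_difference(self):
        assert classify_celltype_conservation(0.5, 0.55, 0.55) == "unclassified"

    def test_boundary_sweep_strict_inequality(self):
        for d in (0.10, 0.14, 0.1501, 0.2, 0.3):
            got = classify_celltype_conservation(1.0, 0.5 + d, 0.5)
            assert (got == "conserved_celltype") == (d > 0.15), d
        # exactly at the threshold (representable difference): not conserved
        got = classify_celltype_conservation(1.0, 0.75, 0.5, min_diff=0.25)
        assert got == "unclassified"

    def test_opposite_direction_not_conserved(self):
        assert classify_celltype_conservation(-0.5, 0.8, 0.3) == "unclassified"


class TestClassifyChSite:
    def test_clear_human_hyper(self):
        got = classify_ch_site(0.01, 0.02, 0.80, 0.30, 0.12, 0.10)
        assert got == ("human", "hyper")

    def test_all_nonsignificant_none(self):
        assert classify_ch_site(0.5, 0.5, 0.5, 0.4, 0.2, 0.2) is None

    def test_truth_table_all_patterns(self):
        qs = [0.01, 0.5]
        levels = [0.05, 0.18, 0.32]
        for q_hc in qs:
            for q_hm in qs:
                for q_cm in qs:
                    for h in levels:
                        for c in levels:
                            for m in levels:
                                got = classify_ch_site(q_hc, q_hm, q_cm,
                                                       h, c, m)
                                expect = self.oracle(q_hc, q_hm, q_cm, h, c, m)
                                assert got == expect

    @staticmethod
    def oracle(q_hc, q_hm, q_cm, h, c, m):
        def diff_ok(own, o1, o2):
            if own - o1 > 0.10 and own - o2 > 0.10:
                return "hyper"
            if o1 - own > 0.10 and o2 - own > 0.10:
                return "hypo"
            return None

        if q_hc < 0.05 and q_hm < 0.05 and q_cm >= 0.05:
            d = diff_ok(h, c, m)
            if d:
                return ("human", d)
        if q_hc < 0.05 and q_cm < 0.05 and q_hm >= 0.05:
            d = diff_ok(c, h, m)
            if d:
                return ("chimpanzee", d)
        if q_hm < 0.05 and q_cm < 0.05 and q_hc >= 0.05:
            d = diff_ok(m, h, c)
            if d:
                return ("macaque", d)
        return None


class TestClassifyChDmr:
    def test_clear_human_specific(self):
        assert classify_ch_dmr(0.18, 0.05, 0.04) == "human_specific_hyper"

    def test_boundary_exactly_five_points_not_specific(self):
        assert classify_ch_dmr(0.09, 0.04, 0.04) == "unclassified"

    def test_grid_matches_rule(self):
        for h in np.linspace(0, 0.3, 7):
            for c in np.linspace(0, 0.3, 7):
                m = 0.05
                got = classify_ch_dmr(h, c, m)
                hm, cm = abs(h - m), abs(c - m)
                if hm > 0.05 and hm > cm:
                    expect = ("human_specific_hyper" if h > m
                              else "human_specific_hypo")
                elif cm > 0.05 and cm > hm:
                    expect = ("chimp_specific_hyper" if c > m
                              else "chimp_specific_hypo")
                else:
                    expect = "unclassified"
                assert got == expect, (h, c, m)

    def test_shared_requires_overlap_of_both_outgroup_sets(self):
        hm = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 500],
                           "end": [100, 600]})
        cm = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [80]})
        shared = shared_ch_dmrs(hm, cm)
        assert len(shared) == 1 and shared["start"].iloc[0] == 0
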