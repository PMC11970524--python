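"""Paralog filtering, age binning, specialization rules and enrichment."""

import numpy as np
import pandas as pd
import pytest

from regremodel import paralogs as par
from regremodel import simulate as sim
from regremodel.paralogs import AgeBin, Location, SpecializationMode


def _pairs(rows):
    return pd.DataFrame(rows, columns=["pair_id", "gene_a", "gene_b",
                                       "family_size_a", "family_size_b"])


class TestFamilyFilter:
    def test_boundary_at_20_partners(self):
        pairs = _pairs([("p1", "a", "b", 21, 1), ("p2", "c", "d", 20, 20),
                        ("p3", "e", "f", 1, 25)])
        kept = par.filter_paralog_families(pairs)
        assert list(kept["pair_id"]) == ["p2"]

    def test_empty_input(self):
        assert par.filter_paralog_families(_pairs([])).empty

    def test_missing_family_size_errors(self):
        with pytest.raises(ValueError):
            par.filter_paralog_families(pd.DataFrame({"pair_id": ["p"]}))


class TestAgeBins:
    @pytest.mark.parametrize("age,expected", [
        (500, AgeBin.VERY_ANCIENT),
        (473.3, AgeBin.ANCIENT),        # boundary: inclusive for ancient
        (473.31, AgeBin.VERY_ANCIENT),
        (200, AgeBin.ANCIENT),
        (111, AgeBin.RECENT_VERY_RECENT),  # boundary
        (0, AgeBin.RECENT_VERY_RECENT),
    ])
    def test_boundaries(self, age, expected):
        assert par.assign_age_bin(age) is expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            par.assign_age_bin(-1)

    def test_bins_partition_pairs(self):
        u = sim.gen_paralog_universe(n_pairs=300, seed=0, run_differential=False)
        bins = par.assign_age_bins(u.pairs)
        assert bins.value_counts().sum() == len(u.pairs)
        assert (bins == u.truth["age_bin"].map(AgeBin)).all()


def _toy_universe():
    """Two genes per pair over the 5-condition design with hand-set stats."""
    design = pd.DataFrame([
        {"sample": f"{c}_r{r}", "condition": c, "phase": p}
        for c, p in sim.DEFAULT_CONDITIONS for r in (1, 2)])
    return design


def _diff(rows):
    return pd.DataFrame(rows, columns=["gene", "contrast", "log2_fold_change", "padj"])


def _expr(genes, design, values):
    return pd.DataFrame({s: [values[g] for g in genes] for s in design["sample"]},
                        index=genes)


class TestSpecializationRules:
    def setup_method(self):
        self.design = _toy_universe()
        self.pairs = pd.DataFrame([{"pair_id": "p1", "gene_a": "A", "gene_b": "B"}])

    def _contrasts(self, gene, lfc, padj):
        return [(gene, f"{d}_vs_{v}", lfc, padj)
                for d in ("dia_3d", "dia_6d", "dia_1m")
                for v in ("dev_hb", "dev_1dph")]

    def test_partner_significantly_down(self):
        diff = _diff([("A", "dia_6d_vs_dev_hb", 2.0, 0.01)]
                     + [("A", "dia_3d_vs_dev_hb", 0.1, 0.9)]
                     + [("B", "dia_6d_vs_dev_hb", -1.5, 0.03)])
        expr = _expr(["A", "B"], self.design, {"A": 10.0, "B": 10.0})
        call = par.classify_specialization(self.pairs, diff, expr, self.design)[0]
        assert call.specialized
        assert call.diapause_gene == "A" and call.development_gene == "B"
        assert call.rule_path == "partner_significantly_down"

    def test_partner_median_rule(self):
        diff = _diff([("A", "dia_6d_vs_dev_hb", 2.0, 0.01),
                      ("B", "dia_6d_vs_dev_hb", -0.2, 0.8)])
        expr = _expr(["A", "B"], self.design, {"A": 10.0, "B": 10.0})
        # B higher in development than diapause
        for s in self.design.loc[self.design["phase"] == "development", "sample"]:
            expr.loc["B", s] = 50.0
        call = par.classify_specialization(self.pairs, diff, expr, self.design)[0]
        assert call.specialized and call.rule_path == "partner_median_rule"

    def test_both_up_not_specialized(self):
        diff = _diff([("A", "dia_6d_vs_dev_hb", 2.0, 0.01),
                      ("B", "dia_1m_vs_dev_hb", 1.0, 0.02)])
        expr = _expr(["A", "B"], self.design, {"A": 10.0, "B": 10.0})
        call = par.classify_specialization(self.pairs, diff, expr, self.design)[0]
        assert not call.specialized and call.rule_path == "both_up"

    def test_flat_pair_not_specialized(self):
        diff = _diff([("A", "dia_6d_vs_dev_hb", 0.1, 0.9),
                      ("B", "dia_6d_vs_dev_hb", -0.1, 0.9)])
        expr = _expr(["A", "B"], self.design, {"A": 10.0, "B": 10.0})
        assert not par.classify_specialization(self.pairs, diff, expr, self.design)[0].specialized

    def test_strict_mode_requires_significant_partner(self):
        diff = _diff([("A", "dia_6d_vs_dev_hb", 2.0, 0.01),
                      ("B", "dia_6d_vs_dev_hb", -0.2, 0.8)])
        expr = _expr(["A", "B"], self.design, {"A": 10.0, "B": 10.0})
        for s in self.design.loc[self.design["phase"] == "development", "sample"]:
            expr.loc["B", s] = 50.0
        call = par.classify_specialization(self.pairs, diff, expr, self.design,
                                           mode=SpecializationMode.ALIM_STRICT)[0]
        assert not call.specialized  # median rule unavailable in strict mode

    def test_mouse_mode_requires_both_dev_stages(self):
        # up vs only one of the two development stages is not enough
        diff = _diff(self._contrasts("B", -2.0, 0.01)
                     + [("A", "dia_6d_vs_dev_hb", 2.0, 0.01),
                        ("A", "dia_6d_vs_dev_1dph", 0.1, 0.9)])
        expr = _expr(["A", "B"], self.design, {"A": 10.0, "B": 10.0})
        call = par.classify_specialization(self.pairs, diff, expr, self.design,
                                           mode=SpecializationMode.MOUSE)[0]
        assert not call.specialized
        diff2 = _diff(self._contrasts("B", -2.0, 0.01)
                      + [("A", "dia_6d_vs_dev_hb", 2.0, 0.01),
                         ("A", "dia_6d_vs_dev_1dph", 2.0, 0.01)])
        call2 = par.classify_specialization(self.pairs, diff2, expr, self.design,
                                            mode=SpecializationMode.MOUSE)[0]
        assert call2.specialized

    def test_gene_order_symmetry(self):
        diff = _diff([("A", "dia_6d_vs_dev_hb", 2.0, 0.01),
                      ("B", "dia_6d_vs_dev_hb", -1.5, 0.03)])
        expr = _expr(["A", "B"], self.design, {"A": 10.0, "B": 10.0})
        swapped = pd.DataFrame([{"pair_id": "p1", "gene_a": "B", "gene_b": "A"}])
        a = par.classify_specialization(self.pairs, diff, expr, self.design)[0]
        b = par.classify_specialization(swapped, diff, expr, self.design)[0]
        assert a.specialized == b.specialized
        assert a.diapause_gene == b.diapause_gene == "A"

    def test_missing_gene_named_in_error(self):
        diff = _diff([("A", "dia_6d_vs_dev_hb", 2.0, 0.01)])
        expr = _expr(["A"], self.design, {"A": 10.0})
        with pytest.raises(KeyError, match="B"):
            par.classify_specialization(self.pairs, diff, expr, self.design)


class TestDifferentialStandin:
    def test_null_and_planted(self):
        u = sim.gen_paralog_universe(n_pairs=150, effect_size_log2=2.0,
                                     expression_noise_sd=0.25, seed=3)
        planted_dia = set(u.truth.loc[u.truth["specialized"], "diapause_gene"])
        sig_up = set(u.differential.loc[(u.differential["padj"] < 0.05)
                                        & (u.differential["log2_fold_change"] > 0),
                                        "gene"])
        sens = len(planted_dia & sig_up) / len(planted_dia)
        assert sens >= 0.9

    def test_external_table_is_interchangeable(self):
        u = sim.gen_paralog_universe(n_pairs=60, seed=4)
        external = u.differential.copy()
        a = par.classify_specialization(u.pairs, u.differential, u.expression, u.design)
        b = par.classify_specialization(u.pairs, external, u.expression, u.design)
        assert [c.specialized for c in a] == [c.specialized for c in b]

    def test_too_few_replicates_rejected(self):
        u = sim.gen_paralog_universe(n_pairs=20, seed=5, run_differential=False,
                                     n_replicates_per_condition=2)
        expr = u.expression.drop(columns=["dia_3d_r2"])
        design = u.design[u.design["sample"] != "dia_3d_r2"]
        with pytest.raises(ValueError):
            par.differential_expression_standin(expr.iloc[:, :], design)


class TestBinEnrichment:
    def test_ratios_average_to_one_weighted(self):
        u = sim.gen_paralog_universe(n_pairs=400, seed=6, run_differential=False)
        bins = u.truth["age_bin"].map(AgeBin)
        res = par.bin_enrichment(bins, u.truth["specialized"], n_boot=100, seed=1)
        total = sum(r.enrichment_ratio * r.n_pairs_in_bin / len(u.truth)
                    * (r.expected_fraction and 1) for r in res.values())
        weighted = sum(r.observed_fraction for r in res.values())
        assert weighted == pytest.approx(1.0)
        assert total == pytest.approx(1.0)

    def test_bootstrap_mean_tracks_full_ratio(self):
        u = sim.gen_paralog_universe(
            n_pairs=2000, seed=7, run_differential=False,
            per_bin_specialization_rate=sim.enrichment_rates(
                2.0, {AgeBin.VERY_ANCIENT: 0.25, AgeBin.ANCIENT: 0.35,
                      AgeBin.RECENT_VERY_RECENT: 0.40}, 0.10))
        bins = u.truth["age_bin"].map(AgeBin)
        res = par.bin_enrichment(bins, u.truth["specialized"], n_boot=2000, seed=2)
        for r in res.values():
            boot_mean = float(np.nanmean(r.bootstrap_ratios))
            assert abs(boot_mean - r.enrichment_ratio) / r.enrichment_ratio < 0.02

    def test_shuffled_pairs_destroy_enrichment(self):
        rates = sim.enrichment_rates(2.0, {AgeBin.VERY_ANCIENT: 0.25,
                                           AgeBin.ANCIENT: 0.35,
                                           AgeBin.RECENT_VERY_RECENT: 0.40}, 0.10)
        u = sim.gen_paralog_universe(n_pairs=3000, seed=8, run_differential=False,
                                     per_bin_specialization_rate=rates)
        bins = u.truth["age_bin"].map(AgeBin)
        enriched = par.bin_enrichment(bins, u.truth["specialized"], n_boot=0)
        assert enriched[AgeBin.VERY_ANCIENT].enrichment_ratio > 1.5
        rng = np.random.default_rng(9)
        shuffled = rng.permutation(u.truth["specialized"].to_numpy())
        null = par.bin_enrichment(bins, shuffled, n_boot=0)
        assert abs(null[AgeBin.VERY_ANCIENT].enrichment_ratio - 1.0) < 0.25

    def test_empty_bin_flagged(self):
        bins = pd.Series([AgeBin.ANCIENT] * 10)
        spec = np.ones(10, dtype=bool)
        res = par.bin_enrichment(bins, spec, n_boot=0)
        assert res[AgeBin.VERY_ANCIENT].undefined


class TestLocation:
    def test_same_different_unknown(self):
        assert par.classify_pair_location("chr3", "chr3") is Location.SAME_CHROMOSOME
        assert par.classify_pair_location("chr3", "chr5") is Location.DIFFERENT_CHROMOSOME
        assert par.classify_pair_location("scaffold_12", "chr5") is Location.UNKNOWN
        assert par.classify_pair_location(None, "chr5") is Location.UNKNOWN

    def test_contingency_matches_shared_oracle(self):
        spec = [True] * 40 + [False] * 160
        loc = ([Location.SAME_CHROMOSOME] * 10 + [Location.DIFFERENT_CHROMOSOME] * 30
               + [Location.SAME_CHROMOSOME] * 10 + [Location.DIFFERENT_CHROMOSOME] * 150)
        res = par.compare_location_distribution(spec, loc)
        assert res.statistic == pytest.approx(12.5)  # [[10,30],[10,150]]

    def test_planted_depletion_detected(self):
        rng = np.random.default_rng(10)
        n = 2000
        spec = np.arange(n) < 400
        # odds-ratio ~0.5 depletion of same-chromosome among specialized
        loc = np.where(
            (rng.random(n) < np.where(spec, 0.15, 0.30)),
            Location.SAME_CHROMOSOME.value, Location.DIFFERENT_CHROMOSOME.value)
        res = par.compare_location_distribution(spec, loc)
        assert res.p_value < 0.05


class TestCrossSpecies:
    def test_perfect_and_inverted(self):
        m = pd.DataFrame({"gene_a": ["g1", "g2", "g3", "g4"],
                          "gene_b": ["h1", "h2", "h3", "h4"]})
        lfa = pd.Series([1.0, 2, -1, 3], index=["g1", "g2", "g3", "g4"])
        lfb = pd.Series([2.0, 4, -2, 6], index=["h1", "h2", "h3", "h4"])
        assert par.cross_species_program_correlation(m, lfa, lfb).statistic == \
            pytest.approx(1.0)
        assert par.cross_species_program_correlation(m, lfa, -lfb).statistic == \
            pytest.approx(-1.0)

    def test_planted_rho_recovered(self):
        rng = np.random.default_rng(11)
        n = 500
        z = rng.normal(size=n)
        la = z + rng.normal(scale=1.0, size=n)
        lb = z + rng.normal(scale=1.0, size=n)  # true pearson rho = 0.5
        m = pd.DataFrame({"gene_a": [f"g{i}" for i in range(n)],
                          "gene_b": [f"h{i}" for i in range(n)]})
        res = par.cross_species_program_correlation(
            m, pd.Series(la, index=m["gene_a"]), pd.Series(lb, index=m["gene_b"]))
        assert abs(res.statistic - 0.5) < 0.1

    def test_too_few_orthologs_rejected(self):
        m = pd.DataFrame({"gene_a": ["g1"], "gene_b": ["h1"]})
        with pytest.raises(ValueError):
            par.cross_species_program_correlation(
                m, pd.Series({"g1": 1.0}), pd.Series({"h1": 1.0}))


class TestUniqueGenes:
    def test_set_logic(self):
        focal = {f"g{i}" for i in range(10)}
        maps = {"sp2": {f"g{i}": f"x{i}" for i in range(10)},
                "sp3": {f"g{i}": f"y{i}" for i in range(10)}}
        de = {"nfur": focal, "sp2": {"x0", "x1"}, "sp3": {"y2", "y3"}}
        unique = par.uniquely_regulated_genes(de, "nfur", maps)
        assert unique == {f"g{i}" for i in range(4, 10)}

    def test_empty_others_returns_focal(self):
        de = {"nfur": {"a", "b"}, "sp2": set()}
        maps = {"sp2": {}}
        assert par.uniquely_regulated_genes(de, "nfur", maps) == {"a", "b"}

    def test_fully_shared_returns_empty(self):
        de = {"nfur": {"a"}, "sp2": {"x"}}
        maps = {"sp2": {"a": "x"}}
        assert par.uniquely_regulated_genes(de, "nfur", maps) == set()

    def test_missing_map_rejected(self):
        with pytest.raises(ValueError):
            par.uniquely_regulated_genes({"nfur": {"a"}, "sp2": {"x"}}, "nfur", {})
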