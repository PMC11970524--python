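"""Projection arithmetic, conservation categories, differential-peak
selection and peak annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regremodel import peaks as pk
from regremodel import simulate as sim
from regremodel.intervals import GenomicInterval
from regremodel.peaks import (AlignmentBlockMap, ConservationCategory, RegionType,
                              Role, Stringency)


def _map(rows):
    return AlignmentBlockMap(pd.DataFrame(rows, columns=AlignmentBlockMap.COLUMNS))


class TestProjection:
    def test_plus_strand_offset(self):
        m = _map([("chr1", 100, 200, "sp", "chrA", 1000, 1100, "+")])
        out = m.project_to_species(GenomicInterval("chr1", 120, 150), "sp")
        assert out == [GenomicInterval("chrA", 1020, 1050)]

    def test_minus_strand_reversal(self):
        m = _map([("chr1", 100, 200, "sp", "chrA", 1000, 1100, "-")])
        out = m.project_to_species(GenomicInterval("chr1", 120, 150), "sp")
        # focal left edge maps to target right edge
        assert out == [GenomicInterval("chrA", 1050, 1080)]

    def test_outside_blocks_empty(self):
        m = _map([("chr1", 100, 200, "sp", "chrA", 1000, 1100, "+")])
        assert m.project_to_species(GenomicInterval("chr1", 300, 350), "sp") == []

    def test_split_across_focal_chromosomes(self):
        # species peak spanning two blocks whose focal sides sit on different
        # focal chromosomes: the projection must come back split
        m = _map([("chr1", 100, 200, "sp", "chrA", 1000, 1100, "+"),
                  ("chr2", 700, 800, "sp", "chrA", 1100, 1200, "+")])
        pp = m.project_peak("x", GenomicInterval("chrA", 1050, 1150), "sp")
        assert pp.split and len(pp.focal_intervals) == 2
        assert {iv.chrom for iv in pp.focal_intervals} == {"chr1", "chr2"}

    def test_adjacent_fragments_merge(self):
        # two blocks, adjacent on the target: projection must merge, not split
        m = _map([("chr1", 100, 200, "sp", "chrA", 1000, 1100, "+"),
                  ("chr1", 500, 600, "sp", "chrA", 1100, 1200, "+")])
        ivs = m.project_to_focal(GenomicInterval("chrA", 1050, 1150), "sp")
        assert len(ivs) == 2  # focal sides are disjoint
        pp = m.project_peak("y", GenomicInterval("chrA", 1050, 1150), "sp")
        assert pp.split

    def test_round_trip_identity_random(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            fs = i * 2000
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(("chr1", fs, fs + 1000, "sp", "chrA",
                         10_000 + i * 3000, 11_000 + i * 3000, strand))
        m = _map(rows)
        for _ in range(1000):
            i = int(rng.integers(0, 50))
            s = int(rng.integers(i * 2000, i * 2000 + 900))
            e = int(rng.integers(s + 1, i * 2000 + 1000))
            iv = GenomicInterval("chr1", s, e)
            fwd = m.project_to_species(iv, "sp")
            assert len(fwd) == 1 and fwd[0].length == iv.length
            back = m.project_to_focal(fwd[0], "sp")
            assert back == [iv]

    def test_split_flags_match_bruteforce_oracle(self):
        u = sim.gen_peak_universe(n_peaks=150, split_fraction=0.1, seed=1)
        blocks = u.block_map.blocks
        for sp, df in u.peaks.items():
            if sp == u.focal_species:
                continue
            for r in df.itertuples(index=False):
                pp = u.block_map.project_peak(
                    r.peak_id, GenomicInterval(r.chrom, int(r.start), int(r.end)), sp)
                # oracle: count merged focal fragments by direct interval arithmetic
                sub = blocks[(blocks["species"] == sp)
                             & (blocks["target_chrom"] == r.chrom)
                             & (blocks["target_start"] < r.end)
                             & (blocks["target_end"] > r.start)]
                frags = []
                for b in sub.itertuples(index=False):
                    s = max(int(r.start), b.target_start)
                    e = min(int(r.end), b.target_end)
                    if b.strand == "+":
                        fs = b.focal_start + (s - b.target_start)
                    else:
                        fs = b.focal_start + (b.target_end - e)
                    frags.append((b.focal_chrom, fs, fs + (e - s)))
                frags.sort()
                merged = []
                for c, s, e in frags:
                    if merged and merged[-1][0] == c and s <= merged[-1][2]:
                        merged[-1][2] = max(merged[-1][2], e)
                    else:
                        merged.append([c, s, e])
                assert pp.split == (len(merged) >= 2), r.peak_id


class TestTagConserved:
    peak = GenomicInterval("chr1", 1000, 1400)  # length 400

    def _flags(self, ivs, stringency):
        return pk.tag_conserved(self.peak, {"sp": ivs}, stringency)["sp"]

    def test_one_bp_overlap_relaxed(self):
        assert self._flags([GenomicInterval("chr1", 999, 1001)], Stringency.RELAXED)
        assert not self._flags([GenomicInterval("chr1", 990, 1000)], Stringency.RELAXED)

    def test_strict_25_percent_boundary(self):
        assert not self._flags([GenomicInterval("chr1", 1000, 1080)], Stringency.STRICT)
        assert self._flags([GenomicInterval("chr1", 1000, 1100)], Stringency.STRICT)

    def test_very_strict_50_percent_inclusive(self):
        assert self._flags([GenomicInterval("chr1", 1000, 1200)], Stringency.VERY_STRICT)
        assert not self._flags([GenomicInterval("chr1", 1000, 1199)],
                               Stringency.VERY_STRICT)

    def test_union_coverage_not_double_counted(self):
        ivs = [GenomicInterval("chr1", 1000, 1100), GenomicInterval("chr1", 1050, 1150)]
        assert not self._flags(ivs, Stringency.VERY_STRICT)  # union covers 150/400

    def test_stringency_monotonic_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            ivs = []
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(800, 1500))
                ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(20, 400))))
            fl = {st: self._flags(ivs, st) for st in Stringency}
            assert fl[Stringency.VERY_STRICT] <= fl[Stringency.STRICT] \
                <= fl[Stringency.RELAXED]


class TestConservationCategories:
    roles = {"nfur": Role.FOCAL, "aaus": Role.AFRICAN_KILLIFISH,
             "astr": Role.AFRICAN_KILLIFISH, "olat": Role.OUTGROUP,
             "drer": Role.OUTGROUP}

    def _cat(self, aaus=False, astr=False, olat=False, drer=False):
        flags = {"nfur": True, "aaus": aaus, "astr": astr, "olat": olat, "drer": drer}
        return pk.classify_conservation(flags, self.roles, "nfur")

    def test_focal_only_very_recent(self):
        assert self._cat() is ConservationCategory.VERY_RECENT

    def test_african_only_recent(self):
        assert self._cat(aaus=True) is ConservationCategory.RECENT

    def test_full_depth_ancient(self):
        assert self._cat(aaus=True, drer=True) is \
            ConservationCategory.ANCIENT_VERY_ANCIENT

    def test_outgroup_exception(self):
        # outgroup without any other African killifish still counts as ancient
        assert self._cat(drer=True) is ConservationCategory.ANCIENT_VERY_ANCIENT

    def test_exhaustive_16_combinations_match_oracle(self):
        for combo in itertools.product([False, True], repeat=4):
            aaus, astr, olat, drer = combo
            african, outgroup = aaus or astr, olat or drer
            if outgroup:
                want = ConservationCategory.ANCIENT_VERY_ANCIENT
            elif african:
                want = ConservationCategory.RECENT
            else:
                want = ConservationCategory.VERY_RECENT
            assert self._cat(aaus, astr, olat, drer) is want

    def test_nonfocal_peak_rejected(self):
        with pytest.raises(ValueError):
            pk.classify_conservation({"nfur": False, "aaus": True}, self.roles, "nfur")


class TestPlantedRecovery:
    def test_category_counts_reproduce_planted_proportions(self):
        props = {ConservationCategory.ANCIENT_VERY_ANCIENT: 0.2,
                 ConservationCategory.RECENT: 0.3,
                 ConservationCategory.VERY_RECENT: 0.5}
        u = sim.gen_peak_universe(n_peaks=200, category_proportions=props, seed=3)
        projected = {sp: [] for sp in u.roles if sp != u.focal_species}
        for sp, df in u.peaks.items():
            if sp == u.focal_species:
                continue
            for r in df.itertuples(index=False):
                pp = u.block_map.project_peak(
                    r.peak_id, GenomicInterval(r.chrom, int(r.start), int(r.end)), sp)
                projected[sp].extend(pp.focal_intervals)
        cats = []
        for r in u.peaks[u.focal_species].itertuples(index=False):
            fiv = GenomicInterval(r.chrom, int(r.start), int(r.end))
            flags = pk.tag_conserved(fiv, projected, Stringency.RELAXED)
            flags[u.focal_species] = True
            cats.append(pk.classify_conservation(flags, u.roles, u.focal_species).value)
        assert cats == list(u.truth["category"])
        counts = pd.Series(cats).value_counts(normalize=True)
        for c, p in props.items():
            assert counts[c.value] == pytest.approx(p)

    def test_sequence_category_never_younger_than_accessibility(self):
        u = sim.gen_peak_universe(n_peaks=100, seed=4, exception_fraction=0.1)
        rank = {ConservationCategory.VERY_RECENT: 0, ConservationCategory.RECENT: 1,
                ConservationCategory.ANCIENT_VERY_ANCIENT: 2}
        for i, r in enumerate(u.peaks[u.focal_species].itertuples(index=False)):
            fiv = GenomicInterval(r.chrom, int(r.start), int(r.end))
            seq_cat = pk.classify_sequence_conservation(fiv, u.block_map, u.roles,
                                                        u.focal_species)
            acc_cat = ConservationCategory(u.truth["category"][i])
            assert rank[seq_cat] >= rank[acc_cat]


class TestDiapauseSpecificSelection:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["peak_id", "contrast", "method",
                                           "significant", "log2_fold_change"])

    def _full(self, peak, dia6=(False, False), dia1m=(False, False),
              dev=(False, False), dia_lfc=1.0, dev_lfc=1.0):
        rows = []
        for contrast, flags, lfc in (("dia6_vs_dev", dia6, dia_lfc),
                                     ("dia1m_vs_dev", dia1m, dia_lfc),
                                     ("dev_vs_dev", dev, dev_lfc)):
            for m, f in zip(("deseq2_like", "edger_like"), flags):
                rows.append((peak, contrast, m, f, lfc))
        return rows

    def _select(self, calls, **kw):
        return pk.select_diapause_specific_peaks(
            calls, ["dia6_vs_dev", "dia1m_vs_dev"], "dev_vs_dev", **kw)

    def test_one_method_up_is_enough(self):
        calls = self._calls(self._full("p1", dia6=(True, False)))
        assert self._select(calls) == ["p1"]

    def test_dev_significant_by_both_rejected(self):
        calls = self._calls(self._full("p1", dia6=(True, True), dev=(True, True)))
        assert self._select(calls) == []

    def test_dev_significant_by_one_method_rejected_by_default(self):
        calls = self._calls(self._full("p1", dia6=(True, True), dev=(True, False)))
        assert self._select(calls) == []
        assert self._select(calls, require_both_dev_ns=False) == ["p1"]

    def test_downregulated_in_diapause_not_selected(self):
        calls = self._calls(self._full("p1", dia6=(True, True), dia_lfc=-2.0))
        assert self._select(calls) == []

    def test_missing_contrast_errors(self):
        calls = self._calls([("p1", "dia6_vs_dev", "deseq2_like", True, 1.0)])
        with pytest.raises(ValueError):
            self._select(calls)


class TestGeneAssignment:
    genes = pd.DataFrame([
        {"gene_id": "gA", "chrom": "chr1", "start": 1000, "end": 3000, "strand": "+"},
        {"gene_id": "gB", "chrom": "chr1", "start": 8000, "end": 9000, "strand": "-"},
        {"gene_id": "gC", "chrom": "chr2", "start": 500, "end": 700, "strand": "+"},
    ])

    def test_overlapping_tss_distance_zero(self):
        gene, d = pk.assign_peak_to_gene(GenomicInterval("chr1", 900, 1100), self.genes)
        assert gene == "gA" and d == 0

    def test_minus_strand_tss_is_right_edge(self):
        gene, d = pk.assign_peak_to_gene(GenomicInterval("chr1", 8950, 9100), self.genes)
        assert gene == "gB" and d == 0

    def test_equidistant_tie_break_deterministic(self):
        genes = pd.DataFrame([
            {"gene_id": "gZ", "chrom": "chr1", "start": 2000, "end": 2500, "strand": "+"},
            {"gene_id": "gY", "chrom": "chr1", "start": 4000, "end": 4500, "strand": "+"},
        ])
        # peak midpoint 3000: both TSS 900 bp from the nearest peak edge
        gene, d = pk.assign_peak_to_gene(GenomicInterval("chr1", 2900, 3101), genes)
        assert gene == "gZ"  # smaller start coordinate wins

    def test_agrees_with_bruteforce_scan(self):
        rng = np.random.default_rng(5)
        genes = pd.DataFrame([
            {"gene_id": f"g{i}", "chrom": "chr1",
             "start": int(s), "end": int(s) + 500,
             "strand": "+" if rng.random() < 0.5 else "-"}
            for i, s in enumerate(rng.integers(0, 1_000_000, 60))])
        for _ in range(300):
            s = int(rng.integers(0, 1_000_000))
            peak = GenomicInterval("chr1", s, s + 300)
            gene, d = pk.assign_peak_to_gene(peak, genes)
            best = None
            for row in genes.itertuples(index=False):
                tss = row.start if row.strand == "+" else row.end - 1
                dist = 0 if peak.start <= tss < peak.end else \
                    min(abs(peak.start - tss), abs(peak.end - 1 - tss))
                key = (dist, row.start, row.gene_id)
                best = key if best is None or key < best else best
            assert d == best[0] and gene == best[2]

    def test_empty_annotation_errors(self):
        with pytest.raises(ValueError):
            pk.assign_peak_to_gene(GenomicInterval("chr1", 0, 10),
                                   self.genes.iloc[0:0])


class TestRegionAnnotation:
    genes = pd.DataFrame([
        {"gene_id": "gA", "chrom": "chr1", "start": 10_000, "end": 20_000,
         "strand": "+"},
    ])
    exons = pd.DataFrame([
        {"gene_id": "gA", "chrom": "chr1", "start": 10_000, "end": 10_500},
        {"gene_id": "gA", "chrom": "chr1", "start": 19_000, "end": 20_000},
    ])

    def _annot(self, s, e):
        return pk.annotate_peak_region(GenomicInterval("chr1", s, e),
                                       self.genes, self.exons)

    def test_upstream_window_is_promoter(self):
        assert self._annot(9_800, 9_950) is RegionType.PROMOTER

    def test_intron_outside_windows(self):
        assert self._annot(15_000, 15_200) is RegionType.INTRON

    def test_exon_beats_intron(self):
        assert self._annot(19_100, 19_300) is RegionType.EXON

    def test_distal_intergenic(self):
        assert self._annot(50_000, 50_200) is RegionType.DISTAL_INTERGENIC

    def test_promoter_strand_aware(self):
        genes = pd.DataFrame([{"gene_id": "gB", "chrom": "chr1", "start": 10_000,
                               "end": 20_000, "strand": "-"}])
        exons = self.exons.iloc[0:0]
        # downstream of the minus-strand TSS (right edge): promoter window
        out = pk.annotate_peak_region(GenomicInterval("chr1", 20_100, 20_300),
                                      genes, exons)
        assert out is RegionType.PROMOTER
        # region upstream of the plus-strand start is NOT a minus-strand promoter
        out2 = pk.annotate_peak_region(GenomicInterval("chr1", 9_000, 9_200),
                                       genes, exons)
        assert out2 is RegionType.DISTAL_INTERGENIC
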