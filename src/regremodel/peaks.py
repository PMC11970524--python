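"""Cross-species chromatin-accessibility conservation of ATAC-seq peaks.

Peaks from several species are compared on a single focal genome through a
colinear alignment block map (equal-length, gapless interval correspondences
between the focal genome and each other genome). Non-focal peaks are projected
into focal coordinates; a projection that lands in two or more disjoint focal
loci is flagged *split*. Each focal peak is then tagged conserved per species
at one of three stringencies and classified into an evolutionary category:

* ``VERY_RECENT``          — accessible only in the focal species
* ``RECENT``               — shared with >= 1 other African killifish, no outgroup
* ``ANCIENT_VERY_ANCIENT`` — shared with >= 1 African killifish and >= 1 outgroup;
  peaks shared with an outgroup but no other African killifish are also placed
  here (they cannot be focal-lineage innovations).

The same category logic applies to the underlying sequence, where "conserved"
means the focal peak has an aligned orthologous region in that species.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex, merge_intervals

__all__ = [
    "Role", "Stringency", "ConservationCategory", "RegionType",
    "AlignmentBlockMap", "ProjectedPeak",
    "tag_conserved", "classify_conservation", "classify_sequence_conservation",
    "select_diapause_specific_peaks", "assign_peak_to_gene", "annotate_peak_region",
]


class Role(str, enum.Enum):
    FOCAL = "focal"
    AFRICAN_KILLIFISH = "african_killifish"
    OUTGROUP = "outgroup"


class Stringency(str, enum.Enum):
    """Peak-overlap stringency: any overlap, or >=25% / >=50% of the focal
    peak covered by the species' projected peaks (boundaries inclusive)."""
    RELAXED = "relaxed"
    STRICT = "strict"
    VERY_STRICT = "very_strict"


_COVERAGE_REQUIRED = {Stringency.RELAXED: 0.0, Stringency.STRICT: 0.25,
                      Stringency.VERY_STRICT: 0.5}


class ConservationCategory(str, enum.Enum):
    ANCIENT_VERY_ANCIENT = "ancient_very_ancient"
    RECENT = "recent"
    VERY_RECENT = "very_recent"


class RegionType(str, enum.Enum):
    PROMOTER = "promoter"
    EXON = "exon"
    INTRON = "intron"
    DISTAL_INTERGENIC = "distal_intergenic"


@dataclass(frozen=True)
class ProjectedPeak:
    source_peak_id: str
    species: str
    focal_intervals: tuple
    split: bool


class AlignmentBlockMap:
    """Colinear gapless blocks between the focal genome and other genomes.

    Backed by a DataFrame with columns ``focal_chrom, focal_start, focal_end,
    species, target_chrom, target_start, target_end, strand``. Focal and
    target intervals of a block have equal length; minus-strand blocks map
    focal coordinates onto the reverse strand of the target.
    """

    COLUMNS = ["focal_chrom", "focal_start", "focal_end", "species",
               "target_chrom", "target_start", "target_end", "strand"]

    def __init__(self, blocks: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in blocks.columns]
        if missing:
            raise ValueError(f"block map missing columns {missing}")
        blocks = blocks.reset_index(drop=True)
        flen = blocks["focal_end"] - blocks["focal_start"]
        tlen = blocks["target_end"] - blocks["target_start"]
        if (flen != tlen).any():
            bad = blocks.loc[flen != tlen].index[0]
            raise ValueError(f"block {bad}: focal and target lengths differ")
        if (flen <= 0).any():
            raise ValueError("blocks must have positive length")
        self.blocks = blocks
        self._focal_idx: dict[str, IntervalIndex] = {}
        self._target_idx: dict[str, IntervalIndex] = {}
        for sp, sub in blocks.groupby("species", sort=False):
            self._focal_idx[sp] = IntervalIndex(
                sub.rename(columns={"focal_chrom": "chrom", "focal_start": "start",
                                    "focal_end": "end"}))
            self._target_idx[sp] = IntervalIndex(
                sub.rename(columns={"target_chrom": "chrom", "target_start": "start",
                                    "target_end": "end"}))

    @property
    def species(self) -> list[str]:
        return list(self._focal_idx)

    def project_to_species(self, interval: GenomicInterval, species: str) -> list[GenomicInterval]:
        """Focal -> species projection; adjacent fragments on the target are
        merged, truly disjoint ones stay separate. Empty when unaligned."""
        idx = self._focal_idx.get(species)
        if idx is None:
            return []
        hits = idx.overlapping(interval.chrom, interval.start, interval.end)
        return self._apply(hits, interval, forward=True)

    def project_to_focal(self, interval: GenomicInterval, species: str) -> list[GenomicInterval]:
        """Species -> focal projection (inverse direction)."""
        idx = self._target_idx.get(species)
        if idx is None:
            return []
        hits = idx.overlapping(interval.chrom, interval.start, interval.end)
        return self._apply(hits, interval, forward=False)

    @staticmethod
    def _apply(hits: pd.DataFrame, iv: GenomicInterval, forward: bool) -> list[GenomicInterval]:
        frags: dict[str, list[tuple[int, int]]] = {}
        for row in hits.itertuples(index=False):
            if forward:
                src = (row.chrom, row.start, row.end)  # renamed focal cols
                dst = (row.target_chrom, row.target_start, row.target_end)
            else:
                src = (row.chrom, row.start, row.end)  # renamed target cols
                dst = (row.focal_chrom, row.focal_start, row.focal_end)
            s = max(iv.start, int(src[1]))
            e = min(iv.end, int(src[2]))
            if e <= s:
                continue
            if row.strand == "+":
                ds = int(dst[1]) + (s - int(src[1]))
                de = int(dst[1]) + (e - int(src[1]))
            else:
                ds = int(dst[1]) + (int(src[2]) - e)
                de = int(dst[1]) + (int(src[2]) - s)
            frags.setdefault(dst[0], []).append((ds, de))
        out = []
        for chrom in sorted(frags):
            for s, e in merge_intervals(frags[chrom], min_gap=1):
                out.append(GenomicInterval(chrom, s, e))
        return out

    def project_peak(self, peak_id: str, interval: GenomicInterval,
                     species: str) -> ProjectedPeak:
        """Project a non-focal species peak into focal coordinates."""
        ivs = tuple(self.project_to_focal(interval, species))
        return ProjectedPeak(peak_id, species, ivs, split=len(ivs) >= 2)

    def strand_of(self, interval: GenomicInterval, species: str) -> str | None:
        """Strand of the single block containing a focal interval (None if
        the interval is unaligned or spans multiple blocks)."""
        idx = self._focal_idx.get(species)
        if idx is None:
            return None
        hits = idx.overlapping(interval.chrom, interval.start, interval.end)
        contains = hits[(hits["start"] <= interval.start) & (hits["end"] >= interval.end)]
        if len(contains) != 1:
            return None
        return str(contains.iloc[0]["strand"])


def tag_conserved(focal_peak: GenomicInterval,
                  projected_by_species: dict[str, list[GenomicInterval]],
                  stringency: Stringency = Stringency.RELAXED) -> dict[str, bool]:
    """Conserved flag per species given that species' peaks projected onto
    the focal genome. Coverage (STRICT/VERY_STRICT) is the fraction of the
    focal peak covered by the union of the species' projected peaks."""
    stringency = Stringency(stringency)
    need = _COVERAGE_REQUIRED[stringency]
    flags = {}
    for sp, ivs in projected_by_species.items():
        same_chrom = [(max(iv.start, focal_peak.start), min(iv.end, focal_peak.end))
                      for iv in ivs if iv.chrom == focal_peak.chrom]
        clipped = [(s, e) for s, e in same_chrom if e > s]
        if stringency is Stringency.RELAXED:
            flags[sp] = bool(clipped)
        else:
            covered = sum(e - s for s, e in merge_intervals(clipped))
            flags[sp] = covered / focal_peak.length >= need
    return flags


def classify_conservation(flags: dict[str, bool], roles: dict[str, Role],
                          focal_species: str) -> ConservationCategory:
    """Conservation category of a focal peak from per-species conserved flags.

    A peak shared with an outgroup but with no other African killifish is
    placed in ANCIENT_VERY_ANCIENT: outgroup presence rules out a
    focal-lineage innovation regardless of African-killifish losses.
    """
    if not flags.get(focal_species, True):
        raise ValueError("only focal peaks (focal flag true) are classified")
    african = any(v for s, v in flags.items()
                  if s != focal_species and roles.get(s) == Role.AFRICAN_KILLIFISH)
    outgroup = any(v for s, v in flags.items()
                   if roles.get(s) == Role.OUTGROUP)
    if outgroup:
        return ConservationCategory.ANCIENT_VERY_ANCIENT
    if african:
        return ConservationCategory.RECENT
    return ConservationCategory.VERY_RECENT


def classify_sequence_conservation(focal_peak: GenomicInterval, block_map: AlignmentBlockMap,
                                   roles: dict[str, Role], focal_species: str,
                                   min_coverage: float = 0.0) -> ConservationCategory:
    """Category of the peak's underlying sequence: a species counts as
    conserved when the focal peak has an aligned region to it (>= 1 bp by
    default; ``min_coverage`` reuses the stringency thresholds)."""
    flags = {focal_species: True}
    for sp in block_map.species:
        idx = block_map._focal_idx[sp]
        if min_coverage <= 0:
            flags[sp] = idx.any_overlap(focal_peak.chrom, focal_peak.start, focal_peak.end)
        else:
            flags[sp] = idx.coverage_fraction(
                focal_peak.chrom, focal_peak.start, focal_peak.end) >= min_coverage
    return classify_conservation(flags, roles, focal_species)


def select_diapause_specific_peaks(calls: pd.DataFrame,
                                   diapause_contrasts: list[str],
                                   development_contrast: str,
                                   methods: tuple[str, str] = ("deseq2_like", "edger_like"),
                                   require_both_dev_ns: bool = True) -> list:
    """Diapause-specific peak selection from a two-method differential table.

    ``calls`` columns: peak_id, contrast, method, significant (bool),
    log2_fold_change. A peak is selected iff it is significantly up
    (more open) in >= 1 diapause contrast by >= 1 method AND the
    development-vs-development contrast is non-significant under BOTH methods
    (``require_both_dev_ns=False`` flips to: non-significant under >= 1).
    """
    needed = set(diapause_contrasts) | {development_contrast}
    have = calls.groupby("peak_id")["contrast"].apply(set)
    for pid, cset in have.items():
        if not needed.issubset(cset):
            raise ValueError(f"peak {pid!r} lacks contrasts {sorted(needed - cset)}")
    for m in methods:
        if not (calls["method"] == m).any():
            raise ValueError(f"method {m!r} absent from calls table")

    dia = calls[calls["contrast"].isin(diapause_contrasts)]
    up_any = dia[(dia["significant"]) & (dia["log2_fold_change"] > 0)]["peak_id"].unique()

    dev = calls[calls["contrast"] == development_contrast]
    dev_sig = dev.groupby("peak_id")["significant"].agg(list)
    if require_both_dev_ns:
        dev_ok = dev_sig.map(lambda flags: not any(flags))
    else:
        dev_ok = dev_sig.map(lambda flags: not all(flags))
    selected = [p for p in up_any if bool(dev_ok.get(p, False))]
    return sorted(selected)


def _tss(row) -> int:
    return int(row["start"]) if row.get("strand", "+") != "-" else int(row["end"]) - 1


def assign_peak_to_gene(peak: GenomicInterval, genes: pd.DataFrame) -> tuple[str, int]:
    """Nearest gene by absolute distance from the peak to each gene's TSS
    (0 when the TSS falls inside the peak). Ties break deterministically:
    smaller gene start coordinate, then lexicographic gene id.

    ``genes`` columns: gene_id, chrom, start, end, strand.
    """
    if genes.empty:
        raise ValueError("empty gene annotation")
    sub = genes[genes["chrom"] == peak.chrom]
    if sub.empty:
        sub = genes  # fall back to genome-wide nearest to stay total
    best = None
    for row in sub.itertuples(index=False):
        tss = int(row.start) if getattr(row, "strand", "+") != "-" else int(row.end) - 1
        if peak.start <= tss < peak.end:
            d = 0
        else:
            d = min(abs(peak.start - tss), abs((peak.end - 1) - tss))
        key = (d, int(row.start), str(row.gene_id))
        if best is None or key < best[0]:
            best = (key, str(row.gene_id), d)
    return best[1], best[2]


def annotate_peak_region(peak: GenomicInterval, genes: pd.DataFrame,
                         exons: pd.DataFrame,
                         promoter_window: tuple[int, int] = (-2000, 500)) -> RegionType:
    """Genomic feature class of a peak with precedence
    PROMOTER > EXON > INTRON > DISTAL_INTERGENIC.

    The promoter window is strand-aware around the TSS: (upstream, downstream)
    offsets on the gene's own orientation, default (-2000, +500).
    """
    up, down = promoter_window
    gsub = genes[genes["chrom"] == peak.chrom]
    for row in gsub.itertuples(index=False):
        strand = getattr(row, "strand", "+")
        if strand != "-":
            tss = int(row.start)
            ps, pe = tss + up, tss + down
        else:
            tss = int(row.end) - 1
            ps, pe = tss - down + 1, tss - up + 1
        if max(ps, peak.start) < min(pe, peak.end):
            return RegionType.PROMOTER
    esub = exons[exons["chrom"] == peak.chrom]
    for row in esub.itertuples(index=False):
        if max(int(row.start), peak.start) < min(int(row.end), peak.end):
            return RegionType.EXON
    for row in gsub.itertuples(index=False):
        if max(int(row.start), peak.start) < min(int(row.end), peak.end):
            return RegionType.INTRON
    return RegionType.DISTAL_INTERGENIC
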