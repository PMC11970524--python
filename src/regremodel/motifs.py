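"""PWM log-odds scanning and cross-species conservation of binding sites.

A binding motif is a position probability matrix (PPM) with a per-motif
log-odds detection threshold. A length-n window scores

    sum_i ln( max(p_i[base_i], floor) / 0.25 )

against a uniform background; the window is a hit when the score meets the
threshold. Probabilities are floored at 0.001 before the log so mismatches at
near-degenerate positions stay finite.

For each focal-species hit the aligned region in every other species is
fetched through the alignment block map and re-scored. The verdict per
species is CONSERVED (aligned sequence still meets the threshold),
EXCLUDED_NEARBY (aligned sequence fails, but an identical above-threshold
motif sits within a small window around the aligned region — such sites are
excluded from conservation tallies rather than counted as losses),
NOT_CONSERVED, or ALIGNMENT_ABSENT (no clean single-locus alignment).

Origin of each focal hit is TE_DERIVED when it overlaps an annotated
transposable element by >= 1 bp, MUTATION_DERIVED otherwise; sharing is
SHARED when the site is conserved in >= 1 other species, else FOCAL_ONLY.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex
from .peaks import AlignmentBlockMap

__all__ = [
    "PWM", "MotifHit", "SiteVerdict", "AlignedMotifSite", "Origin", "Sharing",
    "TECoConservation", "MotifOriginCall", "score_sequence", "scan_sequence",
    "information_content", "assess_site_conservation", "summarize_conservation",
    "classify_motif_origin", "reverse_complement",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PROB_FLOOR = 1e-3
BACKGROUND = 0.25

NON_SCORABLE = None  # sentinel for windows containing N


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with a log-odds detection threshold."""

    name: str
    probabilities: np.ndarray  # (n, 4) rows over A, C, G, T
    detection_threshold: float

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probabilities must be an (n, 4) matrix")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("each PWM row must sum to 1 (within 1e-6)")
        object.__setattr__(self, "probabilities", p)
        if self.detection_threshold > self.max_score() + 1e-9:
            raise ValueError("detection threshold exceeds maximum achievable score")

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probabilities.argmax(axis=1))

    def max_score(self) -> float:
        p = np.maximum(self.probabilities, PROB_FLOOR)
        return float(np.log(p.max(axis=1) / BACKGROUND).sum())

    def log_odds(self) -> np.ndarray:
        return np.log(np.maximum(self.probabilities, PROB_FLOOR) / BACKGROUND)


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    species: str
    offset: int
    strand: str
    score: float
    matched_sequence: str


class SiteVerdict(str, enum.Enum):
    CONSERVED = "conserved"
    NOT_CONSERVED = "not_conserved"
    EXCLUDED_NEARBY = "excluded_nearby"
    ALIGNMENT_ABSENT = "alignment_absent"


@dataclass
class AlignedMotifSite:
    hit: MotifHit
    focal_interval: GenomicInterval
    per_species: dict = field(default_factory=dict)  # species -> SpeciesAssessment


@dataclass(frozen=True)
class SpeciesAssessment:
    verdict: SiteVerdict
    aligned_sequence: str | None = None
    score: float | None = None
    passes_threshold: bool = False
    nearby_identical_motif: bool = False


class Origin(str, enum.Enum):
    MUTATION_DERIVED = "mutation_derived"
    TE_DERIVED = "te_derived"


class Sharing(str, enum.Enum):
    FOCAL_ONLY = "focal_only"
    SHARED = "shared"


class TECoConservation(str, enum.Enum):
    TE_AND_MOTIF = "te_and_motif"
    TE_NO_MOTIF = "te_no_motif"
    MOTIF_NO_TE = "motif_no_te"
    NEITHER = "neither"
    NA = "na"


@dataclass(frozen=True)
class MotifOriginCall:
    hit: MotifHit
    origin: Origin
    sharing: Sharing
    te_coconservation: dict  # species -> TECoConservation


# ---------------------------------------------------------------------------
# scoring and scanning

def score_sequence(pwm: PWM, seq: str) -> float | None:
    """Log-odds score of one window; NON_SCORABLE (None) if it contains N."""
    seq = seq.upper()
    if len(seq) != len(pwm):
        raise ValueError(f"sequence length {len(seq)} != motif length {len(pwm)}")
    if "N" in seq:
        return NON_SCORABLE
    lo = pwm.log_odds()
    try:
        idx = [_BASE_INDEX[b] for b in seq]
    except KeyError as exc:
        raise ValueError(f"non-DNA character in sequence: {exc}") from exc
    return float(lo[np.arange(len(pwm)), idx].sum())


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def scan_sequence(pwm: PWM, seq: str, peak_id: str = "", species: str = "",
                  both_strands: bool = True,
                  threshold: float | None = None) -> list[MotifHit]:
    """All windows on + (and optionally the reverse complement) scoring at or
    above the detection threshold. Overlapping hits are all reported; minus-
    strand offsets index the + strand position of the window's left edge."""
    n = len(pwm)
    if len(seq) < n:
        return []
    thr = pwm.detection_threshold if threshold is None else threshold
    lo = pwm.log_odds()
    enc = _encode(seq)
    L = len(seq) - n + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, n)
    valid = (windows >= 0).all(axis=1)
    scores = np.zeros(L)
    ok = np.where(valid)[0]
    if ok.size:
        scores[ok] = lo[np.arange(n)[None, :], windows[ok]].sum(axis=1)
    hits = []
    seq_u = seq.upper()
    for off in np.where(valid & (scores >= thr - 1e-12))[0]:
        hits.append(MotifHit(peak_id, species, int(off), "+",
                             float(scores[off]), seq_u[off:off + n]))
    if both_strands:
        rc_lo = lo[::-1, ::-1]  # score of revcomp window under pwm
        rc_scores = np.zeros(L)
        if ok.size:
            rc_scores[ok] = rc_lo[np.arange(n)[None, :], windows[ok]].sum(axis=1)
        for off in np.where(valid & (rc_scores >= thr - 1e-12))[0]:
            hits.append(MotifHit(peak_id, species, int(off), "-",
                                 float(rc_scores[off]),
                                 reverse_complement(seq_u[off:off + n])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b p log2 p."""
    p = pwm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=1)


# ---------------------------------------------------------------------------
# cross-species assessment

def _fetch(seqs: dict[str, dict[str, str]], species: str, iv: GenomicInterval) -> str | None:
    chroms = seqs.get(species)
    if chroms is None:
        raise KeyError(f"no sequence loaded for species {species!r}")
    seq = chroms.get(iv.chrom)
    if seq is None or iv.end > len(seq):
        return None
    return seq[iv.start:iv.end]


def assess_site_conservation(hit_interval: GenomicInterval, hit: MotifHit,
                             block_map: AlignmentBlockMap,
                             species_sequences: dict[str, dict[str, str]],
                             pwm: PWM, species: list[str],
                             nearby_window: int = 100) -> AlignedMotifSite:
    """Assess a focal hit in every other species.

    The hit interval is projected through the block map. A clean projection
    (single target locus) is fetched, reverse-complemented for minus-strand
    blocks, and re-scored; the nearby-identical-motif scan extends
    ``nearby_window`` bp around the aligned locus.
    """
    site = AlignedMotifSite(hit, hit_interval)
    for sp in species:
        proj = block_map.project_to_species(hit_interval, sp)
        if len(proj) != 1 or proj[0].length != hit_interval.length:
            site.per_species[sp] = SpeciesAssessment(SiteVerdict.ALIGNMENT_ABSENT)
            continue
        target = proj[0]
        strand = block_map.strand_of(hit_interval, sp) or "+"
        aligned = _fetch(species_sequences, sp, target)
        if aligned is None:
            site.per_species[sp] = SpeciesAssessment(SiteVerdict.ALIGNMENT_ABSENT)
            continue
        if strand == "-":
            aligned = reverse_complement(aligned)
        score = score_sequence(pwm, aligned)
        if score is not None and score >= pwm.detection_threshold - 1e-12:
            site.per_species[sp] = SpeciesAssessment(
                SiteVerdict.CONSERVED, aligned, score, passes_threshold=True)
            continue
        # sub-threshold at the aligned position: look for an identical motif nearby
        ws = max(0, target.start - nearby_window)
        chrom_seq = species_sequences[sp].get(target.chrom, "")
        we = min(len(chrom_seq), target.end + nearby_window)
        nearby = bool(chrom_seq) and bool(
            scan_sequence(pwm, chrom_seq[ws:we], both_strands=True))
        verdict = SiteVerdict.EXCLUDED_NEARBY if nearby else SiteVerdict.NOT_CONSERVED
        site.per_species[sp] = SpeciesAssessment(verdict, aligned, score,
                                                 nearby_identical_motif=nearby)
    return site


def summarize_conservation(sites: list[AlignedMotifSite],
                           include_excluded: bool = False) -> dict:
    """Per-species and average conserved fractions.

    Default denominator: CONSERVED + NOT_CONSERVED, with EXCLUDED_NEARBY and
    ALIGNMENT_ABSENT removed (excluded sites are neither wins nor losses).
    ``include_excluded=True`` counts EXCLUDED_NEARBY in the denominator for
    the stricter reading. The average is the unweighted mean over species
    with a defined fraction; a pooled fraction over all sites is reported too.
    """
    if not sites:
        raise ValueError("no sites to summarize")
    per_species: dict[str, float | None] = {}
    counts: dict[str, dict] = {}
    pooled_c = pooled_d = 0
    for site in sites:
        for sp, a in site.per_species.items():
            c = counts.setdefault(sp, {"conserved": 0, "not_conserved": 0,
                                       "excluded_nearby": 0, "alignment_absent": 0})
            c[a.verdict.value] += 1
    for sp, c in counts.items():
        denom = c["conserved"] + c["not_conserved"]
        if include_excluded:
            denom += c["excluded_nearby"]
        per_species[sp] = c["conserved"] / denom if denom else None
        pooled_c += c["conserved"]
        pooled_d += denom
    defined = [f for f in per_species.values() if f is not None]
    return {
        "per_species": per_species,
        "counts": counts,
        "average": float(np.mean(defined)) if defined else None,
        "pooled": pooled_c / pooled_d if pooled_d else None,
    }


def classify_motif_origin(hit_interval: GenomicInterval, hit: MotifHit,
                          te_index: IntervalIndex | None,
                          site: AlignedMotifSite,
                          block_map: AlignmentBlockMap | None = None,
                          species_te: dict[str, IntervalIndex] | None = None) -> MotifOriginCall:
    """Origin (TE- vs mutation-derived) and sharing of a focal hit, plus the
    per-species four-way TE/motif co-conservation when per-species TE
    annotations and the block map are provided.

    Co-conservation at an aligned locus: TE_AND_MOTIF, TE_NO_MOTIF,
    MOTIF_NO_TE, NEITHER; NA when the locus does not align.
    """
    te_overlap = bool(te_index is not None and te_index.any_overlap(
        hit_interval.chrom, hit_interval.start, hit_interval.end))
    origin = Origin.TE_DERIVED if te_overlap else Origin.MUTATION_DERIVED
    shared = any(a.verdict is SiteVerdict.CONSERVED for a in site.per_species.values())
    sharing = Sharing.SHARED if shared else Sharing.FOCAL_ONLY

    coco = {}
    for sp, a in site.per_species.items():
        if a.verdict is SiteVerdict.ALIGNMENT_ABSENT or block_map is None:
            coco[sp] = TECoConservation.NA
            continue
        motif_there = a.verdict is SiteVerdict.CONSERVED
        te_there = False
        if species_te and sp in species_te:
            proj = block_map.project_to_species(hit_interval, sp)
            te_there = any(species_te[sp].any_overlap(iv.chrom, iv.start, iv.end)
                           for iv in proj)
        if te_there and motif_there:
            coco[sp] = TECoConservation.TE_AND_MOTIF
        elif te_there:
            coco[sp] = TECoConservation.TE_NO_MOTIF
        elif motif_there:
            coco[sp] = TECoConservation.MOTIF_NO_TE
        else:
            coco[sp] = TECoConservation.NEITHER
    return MotifOriginCall(hit, origin, sharing, coco)
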