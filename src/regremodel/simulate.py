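"""Seeded synthetic-data generators with planted ground truth.

Every pipeline input — paralog tables with duplication ages, expression
matrices, cross-species peak sets with an alignment block map, motif
universes with per-species sequence states, TE annotations, knockout
expression matrices and lipid concentration tables — can be generated here
with known labels, so each analysis stage is testable end to end without any
external download.

Design rules shared by all generators:

* One explicit ``numpy.random.default_rng(seed)`` per call; identical seed
  and parameters reproduce identical outputs.
* Category/origin fractions are planted as deterministic quotas (exact
  counts, membership drawn by the seeded RNG), so small-n recovery tests are
  exact; a ``stochastic=True`` flag switches to independent Bernoulli draws.
* Expression and concentration noise is log-normal on normalized values:
  the downstream classifiers consume normalized quantities, so count-level
  models add nothing to the logic under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import PWM, scan_sequence, score_sequence
from .paralogs import AgeBin, differential_expression_standin
from .peaks import AlignmentBlockMap, ConservationCategory, Role

__all__ = [
    "ParalogUniverse", "PeakUniverse", "MotifUniverse", "KOExperiment",
    "LipidUniverse", "gen_paralog_universe", "gen_peak_universe",
    "gen_motif_universe", "gen_ko_experiment", "gen_lipid_table",
    "enrichment_rates", "DEFAULT_CONDITIONS",
]

# two development stages, three diapause timepoints
DEFAULT_CONDITIONS = (
    ("dev_hb", "development"), ("dev_1dph", "development"),
    ("dia_3d", "diapause"), ("dia_6d", "diapause"), ("dia_1m", "diapause"),
)

_AGE_RANGES = {AgeBin.VERY_ANCIENT: (473.3, 800.0),
               AgeBin.ANCIENT: (111.0, 473.3),
               AgeBin.RECENT_VERY_RECENT: (0.0, 111.0)}


def _quota_flags(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector with exactly k True entries at RNG-chosen positions."""
    flags = np.zeros(n, dtype=bool)
    if k > 0:
        flags[rng.choice(n, size=min(k, n), replace=False)] = True
    return flags


def enrichment_rates(target_ratio: float, bin_proportions: dict,
                     base_rate: float, enriched_bin=AgeBin.VERY_ANCIENT) -> dict:
    """Per-bin specialization rates that plant a given enrichment ratio.

    The enrichment ratio of a bin is rate_bin / overall_rate. Non-enriched
    bins share ``base_rate``; the enriched bin's rate is solved so its ratio
    equals ``target_ratio``.
    """
    enriched_bin = AgeBin(enriched_bin)
    p_e = bin_proportions[enriched_bin]
    p_rest = 1.0 - p_e
    # y = ratio * (p_e*y + p_rest*x)  =>  y = ratio*p_rest*x / (1 - ratio*p_e)
    denom = 1.0 - target_ratio * p_e
    if denom <= 0:
        raise ValueError("target ratio infeasible for these bin proportions")
    y = target_ratio * p_rest * base_rate / denom
    if y > 1.0:
        raise ValueError("implied rate exceeds 1; lower base_rate or ratio")
    return {b: (y if b == enriched_bin else base_rate) for b in AgeBin}


# ---------------------------------------------------------------------------
# paralog universe

@dataclass
class ParalogUniverse:
    pairs: pd.DataFrame
    expression: pd.DataFrame
    design: pd.DataFrame
    differential: pd.DataFrame
    truth: pd.DataFrame
    params: dict
    seed: int


def gen_paralog_universe(n_pairs: int = 2000,
                         bin_proportions: dict | None = None,
                         per_bin_specialization_rate=0.15,
                         effect_size_log2: float = 2.0,
                         expression_noise_sd: float = 0.25,
                         n_replicates_per_condition: int = 3,
                         seed: int = 0,
                         stochastic: bool = False,
                         run_differential: bool = True,
                         gen_expression: bool = True,
                         fdr: float = 0.05) -> ParalogUniverse:
    """Paralog pairs with planted age bins and specialization labels.

    Specialized pairs get opposing condition effects of ``effect_size_log2``
    (gene A up in every diapause condition, gene B up in development);
    expression is log-normal around a per-gene baseline with
    ``expression_noise_sd`` (log2 units). ``per_bin_specialization_rate`` is
    a scalar or an ``{AgeBin: rate}`` dict.
    """
    rng = np.random.default_rng(seed)
    if bin_proportions is None:
        bin_proportions = {AgeBin.VERY_ANCIENT: 0.25, AgeBin.ANCIENT: 0.35,
                           AgeBin.RECENT_VERY_RECENT: 0.40}
    bin_proportions = {AgeBin(k): v for k, v in bin_proportions.items()}
    if abs(sum(bin_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("bin_proportions must sum to 1")
    if np.isscalar(per_bin_specialization_rate):
        rates = {b: float(per_bin_specialization_rate) for b in AgeBin}
    else:
        rates = {AgeBin(k): float(v) for k, v in per_bin_specialization_rate.items()}
    if any(not (0 <= r <= 1) for r in rates.values()):
        raise ValueError("specialization rates must lie in [0, 1]")

    # deterministic bin quotas
    bins_order = list(AgeBin)
    counts = [int(round(bin_proportions[b] * n_pairs)) for b in bins_order]
    counts[-1] = n_pairs - sum(counts[:-1])
    bin_labels = np.repeat([b.value for b in bins_order], counts)
    rng.shuffle(bin_labels)

    ages = np.empty(n_pairs)
    for b in bins_order:
        mask = bin_labels == b.value
        lo, hi = _AGE_RANGES[b]
        ages[mask] = rng.uniform(lo + 1e-6, hi, size=mask.sum())

    specialized = np.zeros(n_pairs, dtype=bool)
    for b in bins_order:
        idx = np.where(bin_labels == b.value)[0]
        if stochastic:
            specialized[idx] = rng.random(idx.size) < rates[b]
        else:
            k = int(round(rates[b] * idx.size))
            chosen = rng.choice(idx, size=min(k, idx.size), replace=False)
            specialized[chosen] = True

    pair_ids = [f"pair_{i:05d}" for i in range(n_pairs)]
    genes_a = [f"g{i:05d}a" for i in range(n_pairs)]
    genes_b = [f"g{i:05d}b" for i in range(n_pairs)]
    chrom_mat = rng.integers(1, 20, size=(n_pairs, 2))
    pairs = pd.DataFrame({
        "pair_id": pair_ids, "gene_a": genes_a, "gene_b": genes_b,
        "orthogroup_id": [f"OG{i:05d}" for i in range(n_pairs)],
        "duplication_age_mya": ages,
        "chrom_a": [f"chr{c}" for c in chrom_mat[:, 0]],
        "chrom_b": [f"chr{c}" for c in chrom_mat[:, 1]],
        "family_size_a": rng.integers(1, 6, size=n_pairs),
        "family_size_b": rng.integers(1, 6, size=n_pairs),
    })

    samples, cond_rows = [], []
    for cond, phase in DEFAULT_CONDITIONS:
        for r in range(n_replicates_per_condition):
            s = f"{cond}_r{r + 1}"
            samples.append(s)
            cond_rows.append({"sample": s, "condition": cond, "phase": phase})
    design = pd.DataFrame(cond_rows)
    phase_of = {row["sample"]: row["phase"] for row in cond_rows}

    genes = genes_a + genes_b
    if gen_expression:
        base = rng.normal(8.0, 1.0, size=len(genes))
        # planted effects: +effect in diapause for gene A of specialized pairs,
        # +effect in development for gene B
        dia_mask = np.array([phase_of[s] == "diapause" for s in samples])
        effect = np.zeros((len(genes), len(samples)))
        spec_idx = np.where(specialized)[0]
        effect[spec_idx[:, None], np.where(dia_mask)[0][None, :]] += effect_size_log2
        b_rows = n_pairs + spec_idx
        effect[b_rows[:, None], np.where(~dia_mask)[0][None, :]] += effect_size_log2
        noise = rng.normal(0.0, expression_noise_sd, size=effect.shape)
        expression = pd.DataFrame(
            np.exp2(base[:, None] + effect + noise), index=genes, columns=samples)
    else:  # labels-only universes (enrichment calibration) skip the matrix
        expression = pd.DataFrame(index=genes, columns=samples, dtype=float)

    differential = (differential_expression_standin(expression, design, fdr=fdr)
                    if run_differential and gen_expression else pd.DataFrame())

    truth = pd.DataFrame({"pair_id": pair_ids, "age_bin": bin_labels,
                          "specialized": specialized,
                          "diapause_gene": np.where(specialized, genes_a, None),
                          "development_gene": np.where(specialized, genes_b, None)})
    params = dict(n_pairs=n_pairs, effect_size_log2=effect_size_log2,
                  expression_noise_sd=expression_noise_sd,
                  n_replicates_per_condition=n_replicates_per_condition,
                  rates={b.value: r for b, r in rates.items()},
                  bin_proportions={b.value: p for b, p in bin_proportions.items()},
                  stochastic=stochastic)
    return ParalogUniverse(pairs, expression, design, differential, truth, params, seed)


# ---------------------------------------------------------------------------
# peak universe

@dataclass
class PeakUniverse:
    peaks: dict                      # species -> BED DataFrame
    block_map: AlignmentBlockMap
    roles: dict
    focal_species: str
    truth: pd.DataFrame              # per focal peak
    split_truth: pd.DataFrame        # per planted non-focal split peak
    params: dict
    seed: int


def gen_peak_universe(species_roles: dict | None = None,
                      n_peaks: int = 500,
                      category_proportions: dict | None = None,
                      block_length_range: tuple = (800, 1400),
                      peak_length: int = 400,
                      split_fraction: float = 0.0,
                      exception_fraction: float = 0.0,
                      blocks_follow_category: bool = True,
                      seed: int = 0,
                      stochastic: bool = False) -> PeakUniverse:
    """Cross-species peak sets with planted conservation categories.

    Each focal peak is planted into a category by creating (or omitting)
    overlapping peaks — and, when ``blocks_follow_category`` is set,
    alignment blocks — in the other species:

    * very_recent: focal peak only
    * recent: focal + a random non-empty subset of African killifish
    * ancient_very_ancient: focal + African killifish + >= 1 outgroup;
      an ``exception_fraction`` of these carry the outgroup peak but no
      African-killifish peak (the outgroup-exception route)

    ``split_fraction`` of non-focal peaks are planted to straddle two
    alignment blocks whose focal sides are distant, so their projection is
    split between two focal loci.
    """
    rng = np.random.default_rng(seed)
    if species_roles is None:
        species_roles = {"nfur": Role.FOCAL, "aaus": Role.AFRICAN_KILLIFISH,
                         "astr": Role.AFRICAN_KILLIFISH, "olat": Role.OUTGROUP,
                         "drer": Role.OUTGROUP}
    species_roles = {s: Role(r) for s, r in species_roles.items()}
    focal = [s for s, r in species_roles.items() if r is Role.FOCAL]
    if len(focal) != 1:
        raise ValueError("species_roles must contain exactly one FOCAL species")
    focal = focal[0]
    african = [s for s, r in species_roles.items() if r is Role.AFRICAN_KILLIFISH]
    outgroup = [s for s, r in species_roles.items() if r is Role.OUTGROUP]
    if not african or not outgroup:
        raise ValueError("need >= 1 African killifish and >= 1 outgroup species")

    if category_proportions is None:
        category_proportions = {ConservationCategory.ANCIENT_VERY_ANCIENT: 0.2,
                                ConservationCategory.RECENT: 0.3,
                                ConservationCategory.VERY_RECENT: 0.5}
    category_proportions = {ConservationCategory(k): v
                            for k, v in category_proportions.items()}
    if abs(sum(category_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("category_proportions must sum to 1")

    cats = list(category_proportions)
    if stochastic:
        labels = rng.choice([c.value for c in cats], size=n_peaks,
                            p=[category_proportions[c] for c in cats])
    else:
        counts = [int(round(category_proportions[c] * n_peaks)) for c in cats]
        counts[-1] = n_peaks - sum(counts[:-1])
        labels = np.repeat([c.value for c in cats], counts)
        rng.shuffle(labels)

    anc_val = ConservationCategory.ANCIENT_VERY_ANCIENT.value
    anc_idx = np.where(labels == anc_val)[0]
    n_exc = int(round(exception_fraction * anc_idx.size))
    exception = np.zeros(n_peaks, dtype=bool)
    if n_exc:
        exception[rng.choice(anc_idx, size=n_exc, replace=False)] = True

    spacing = 6000
    species_shift = {sp: (i + 1) * 10_000_000
                     for i, sp in enumerate(s for s in species_roles if s != focal)}

    focal_rows, block_rows = [], []
    species_rows = {sp: [] for sp in species_roles if sp != focal}
    presence = {sp: np.zeros(n_peaks, dtype=bool) for sp in species_roles if sp != focal}

    for i in range(n_peaks):
        fstart = 1000 + i * spacing
        fend = fstart + peak_length
        focal_rows.append({"chrom": "chr1", "start": fstart, "end": fend,
                           "peak_id": f"{focal}_peak_{i:05d}"})
        cat = ConservationCategory(labels[i])

        if cat is ConservationCategory.VERY_RECENT:
            with_peak = []
        elif cat is ConservationCategory.RECENT:
            k = int(rng.integers(1, len(african) + 1))
            with_peak = list(rng.choice(african, size=k, replace=False))
        else:  # ancient/very ancient
            ko = int(rng.integers(1, len(outgroup) + 1))
            with_peak = list(rng.choice(outgroup, size=ko, replace=False))
            if not exception[i]:
                ka = int(rng.integers(1, len(african) + 1))
                with_peak += list(rng.choice(african, size=ka, replace=False))

        if blocks_follow_category:
            with_block = list(with_peak)
        else:
            with_block = [s for s in species_roles if s != focal]

        blen = int(rng.integers(block_length_range[0], block_length_range[1] + 1))
        bstart = fstart - (blen - peak_length) // 2
        bstart = max(bstart, 0)
        for sp in with_block:
            strand = "+" if rng.random() < 0.8 else "-"
            tstart = bstart + species_shift[sp]
            block_rows.append({"focal_chrom": "chr1", "focal_start": bstart,
                               "focal_end": bstart + blen, "species": sp,
                               "target_chrom": "chr1", "target_start": tstart,
                               "target_end": tstart + blen, "strand": strand})
            if sp in with_peak:
                presence[sp][i] = True
                # species peak congruent with the focal peak inside the block
                off = fstart - bstart
                if strand == "+":
                    ps = tstart + off
                else:
                    ps = tstart + (blen - off - peak_length)
                species_rows[sp].append({"chrom": "chr1", "start": ps,
                                         "end": ps + peak_length,
                                         "peak_id": f"{sp}_peak_{i:05d}",
                                         "split_planted": False,
                                         "focal_peak": f"{focal}_peak_{i:05d}"})

    # planted split peaks: two adjacent target blocks mapping to distant focal loci
    n_nonfocal = sum(len(v) for v in species_rows.values())
    n_split = int(round(split_fraction * n_nonfocal))
    split_rows = []
    split_species = sorted(species_rows, key=lambda s: -len(species_rows[s]))[0] \
        if species_rows else None
    for j in range(n_split):
        sp = split_species
        base = 900_000_000 + j * 10_000
        f1 = n_peaks * spacing + 10_000 + j * 20_000
        f2 = f1 + 8_000
        L = 600
        block_rows.append({"focal_chrom": "chr1", "focal_start": f1,
                           "focal_end": f1 + L, "species": sp,
                           "target_chrom": "chr1", "target_start": base,
                           "target_end": base + L, "strand": "+"})
        block_rows.append({"focal_chrom": "chr1", "focal_start": f2,
                           "focal_end": f2 + L, "species": sp,
                           "target_chrom": "chr1", "target_start": base + L,
                           "target_end": base + 2 * L, "strand": "+"})
        pid = f"{sp}_split_{j:04d}"
        species_rows[sp].append({"chrom": "chr1", "start": base + L - 100,
                                 "end": base + L + 100, "peak_id": pid,
                                 "split_planted": True, "focal_peak": None})
        split_rows.append({"peak_id": pid, "species": sp, "split": True})

    peaks = {focal: pd.DataFrame(focal_rows)}
    for sp, rows in species_rows.items():
        peaks[sp] = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id",
                                                "split_planted", "focal_peak"])
    block_map = AlignmentBlockMap(
        pd.DataFrame(block_rows, columns=AlignmentBlockMap.COLUMNS))
    truth = pd.DataFrame({
        "peak_id": [r["peak_id"] for r in focal_rows],
        "category": labels, "exception": exception,
        **{f"present_{sp}": presence[sp] for sp in presence},
    })
    params = dict(n_peaks=n_peaks, peak_length=peak_length,
                  split_fraction=split_fraction, exception_fraction=exception_fraction,
                  blocks_follow_category=blocks_follow_category,
                  category_proportions={c.value: p for c, p in category_proportions.items()})
    return PeakUniverse(peaks, block_map, species_roles, focal, truth,
                        pd.DataFrame(split_rows, columns=["peak_id", "species", "split"]),
                        params, seed)


# ---------------------------------------------------------------------------
# motif universe

@dataclass
class MotifUniverse:
    pwm: PWM
    sequences: dict                  # species -> {chrom: str}
    block_map: AlignmentBlockMap
    te_annotation: pd.DataFrame
    hits: pd.DataFrame               # planted focal hit coordinates
    truth: pd.DataFrame
    focal_species: str
    species: list
    params: dict
    seed: int


def _mutate_below_threshold(motif: str, pwm: PWM, rng: np.random.Generator) -> str:
    """Point-mutate a motif instance until its score drops below threshold,
    flipping the currently highest-contributing position to its worst base."""
    from .motifs import reverse_complement, score_sequence

    lo = pwm.log_odds()
    bases = "ACGT"
    seq = list(motif)
    idx = [bases.index(b) for b in seq]
    contrib = np.array([lo[i, idx[i]] for i in range(len(seq))])
    thr = pwm.detection_threshold - 1e-9

    def both_below() -> bool:
        s = "".join(seq)
        fwd = score_sequence(pwm, s)
        rev = score_sequence(pwm, reverse_complement(s))
        return fwd < thr and rev < thr

    for _ in range(2 * len(seq)):
        if both_below():
            break
        i = int(np.argmax(contrib))
        worst = int(np.argmin(lo[i]))
        if worst == idx[i]:  # already worst base here: take next position
            contrib[i] = -np.inf
            continue
        idx[i] = worst
        seq[i] = bases[worst]
        contrib[i] = lo[i, worst]
    return "".join(seq)


def _random_clean_background(length: int, pwm: PWM, rng: np.random.Generator,
                             max_tries: int = 200) -> str:
    """Random sequence with no above-threshold motif hit on either strand."""
    for _ in range(max_tries):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not scan_sequence(pwm, seq, both_strands=True):
            return seq
    raise RuntimeError("could not draw a motif-free background; "
                       "threshold too permissive for this matrix")


def gen_motif_universe(pwm: PWM, n_sites: int = 100,
                       species: list | None = None,
                       conserved_fraction: float = 0.05,
                       te_fraction: float = 0.05,
                       nearby_fraction: float = 0.0,
                       mutation_rate: float = 0.05,
                       region_length: int = 260,
                       motif_offset: int = 100,
                       nearby_offset: int = 30,
                       nearby_window: int = 100,
                       seed: int = 0) -> MotifUniverse:
    """Motif sites planted across species with exact conservation quotas.

    Each site is an aligned region (identity blocks, + strand) carrying the
    motif consensus in the focal species. Per non-focal species the planted
    state is shared across species by site index:

    * ``nearby_fraction`` of sites: motif mutated below threshold, with an
      intact copy planted ``nearby_offset`` bp away (EXCLUDED_NEARBY);
    * ``conserved_fraction`` of the remaining sites: motif intact (CONSERVED);
    * the rest: motif mutated below threshold (NOT_CONSERVED).

    ``te_fraction`` of sites overlap a planted focal TE interval; TE sites
    are drawn from the not-conserved pool, so TE-derived sites are focal-only.
    Background bases outside planted motifs diverge at ``mutation_rate``.
    """
    rng = np.random.default_rng(seed)
    if species is None:
        species = ["aaus", "alim", "olat", "drer"]
    focal = "nfur"
    consensus = pwm.consensus()
    n = len(pwm)
    if motif_offset + n + nearby_offset + n > region_length:
        raise ValueError("region too short for motif + nearby copy")
    cscore = score_sequence(pwm, consensus)
    if cscore is None or cscore < pwm.detection_threshold:
        raise ValueError("consensus scores below the detection threshold; unplantable")

    n_nearby = int(round(nearby_fraction * n_sites))
    n_cons = int(round(conserved_fraction * (n_sites - n_nearby)))
    n_te = int(round(te_fraction * n_sites))
    # site states by index: [conserved | plain not-conserved | nearby-excluded]
    order = rng.permutation(n_sites)
    cons_set = set(order[:n_cons])
    nearby_set = set(order[n_sites - n_nearby:])
    te_pool = [i for i in order[n_cons:n_sites - n_nearby]]
    if n_te > len(te_pool):
        raise ValueError("te_fraction too large for the not-conserved pool")
    te_set = set(te_pool[:n_te])

    focal_chrom = []
    species_chroms = {sp: [] for sp in species}
    hit_rows, truth_rows, te_rows, block_rows = [], [], [], []

    for i in range(n_sites):
        start = i * region_length
        while True:
            bg = _random_clean_background(region_length, pwm, rng)
            focal_region = bg[:motif_offset] + consensus + bg[motif_offset + n:]
            # offsets only: a palindromic motif legitimately hits both strands
            focal_offsets = {h.offset for h in scan_sequence(pwm, focal_region)}
            if focal_offsets == {motif_offset}:
                ok = True
                regions = {}
                for sp in species:
                    sp_bg = _diverge(bg, mutation_rate, rng)
                    if i in cons_set:
                        region = sp_bg[:motif_offset] + consensus + sp_bg[motif_offset + n:]
                        want = {motif_offset}
                    else:
                        broken = _mutate_below_threshold(consensus, pwm, rng)
                        region = sp_bg[:motif_offset] + broken + sp_bg[motif_offset + n:]
                        want = set()
                        if i in nearby_set:
                            pos = motif_offset + nearby_offset
                            region = region[:pos] + consensus + region[pos + n:]
                            want = {pos}
                    got = {h.offset for h in scan_sequence(pwm, region)}
                    if got != want:
                        ok = False
                        break
                    regions[sp] = region
                if ok:
                    break
        focal_chrom.append(focal_region)
        for sp in species:
            species_chroms[sp].append(regions[sp])

        hs, he = start + motif_offset, start + motif_offset + n
        hit_rows.append({"site_id": f"site_{i:04d}", "chrom": "chr1",
                         "start": hs, "end": he, "offset": motif_offset,
                         "strand": "+"})
        for sp in species:
            tstart = start  # identity alignment, same coordinates
            block_rows.append({"focal_chrom": "chr1", "focal_start": start,
                               "focal_end": start + region_length, "species": sp,
                               "target_chrom": "chr1", "target_start": tstart,
                               "target_end": tstart + region_length, "strand": "+"})
        if i in te_set:
            te_rows.append({"chrom": "chr1", "start": hs - 5, "end": he + 5,
                            "family": "planted_TE", "te_class": "DNA"})
        truth_rows.append({"site_id": f"site_{i:04d}",
                           "conserved": i in cons_set,
                           "nearby_excluded": i in nearby_set,
                           "te_derived": i in te_set,
                           "origin": "te_derived" if i in te_set else "mutation_derived",
                           "sharing": "shared" if i in cons_set else "focal_only"})

    sequences = {focal: {"chr1": "".join(focal_chrom)}}
    for sp in species:
        sequences[sp] = {"chr1": "".join(species_chroms[sp])}
    params = dict(n_sites=n_sites, conserved_fraction=conserved_fraction,
                  te_fraction=te_fraction, nearby_fraction=nearby_fraction,
                  mutation_rate=mutation_rate, region_length=region_length,
                  motif_offset=motif_offset, nearby_offset=nearby_offset,
                  nearby_window=nearby_window)
    return MotifUniverse(pwm, sequences, AlignmentBlockMap(pd.DataFrame(block_rows)),
                         pd.DataFrame(te_rows, columns=["chrom", "start", "end",
                                                        "family", "te_class"]),
                         pd.DataFrame(hit_rows), pd.DataFrame(truth_rows),
                         focal, species, params, seed)


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    if mask.any():
        arr[mask] = rng.choice(list("ACGT"), size=int(mask.sum()))
    return "".join(arr)


# ---------------------------------------------------------------------------
# knockout experiment

@dataclass
class KOExperiment:
    expression: dict                 # (genotype, state) -> genes x samples DataFrame
    control_program_lfc: pd.Series   # planted control diapause-vs-development lfc
    ko_effect_lfc: pd.Series         # planted KO-vs-control lfc in diapause
    truth: pd.DataFrame
    params: dict
    seed: int


def gen_ko_experiment(n_genes: int = 500, reversal_coefficient: float = -0.8,
                      noise_sd: float = 0.5, n_embryos_per_group: int = 5,
                      control_lfc_sd: float = 2.0, residual_sd: float = 0.2,
                      seed: int = 0) -> KOExperiment:
    """Knockout transcriptomes with a planted program-reversal coefficient.

    Per gene, the control diapause-vs-development log2 fold change is drawn
    N(0, ``control_lfc_sd``); the knockout-vs-control change in diapause is
    ``reversal_coefficient`` x that value plus N(0, ``noise_sd``). Expression
    matrices for wildtype / scramble / knockout embryos in both states are
    built around these planted effects with per-embryo residual noise.
    """
    if n_embryos_per_group < 3:
        raise ValueError("n_embryos_per_group must be >= 3")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.normal(8.0, 1.0, size=n_genes)
    prog = rng.normal(0.0, control_lfc_sd, size=n_genes)
    ko_lfc = reversal_coefficient * prog + rng.normal(0.0, noise_sd, size=n_genes)

    matrices = {}
    for genotype in ("wildtype", "scramble", "ko"):
        for state in ("development", "diapause"):
            mu = base.copy()
            if state == "diapause":
                mu = mu + prog
                if genotype == "ko":
                    mu = mu + ko_lfc
            cols = [f"{genotype}_{state}_e{j + 1}" for j in range(n_embryos_per_group)]
            vals = np.exp2(mu[:, None] + rng.normal(0.0, residual_sd,
                                                    size=(n_genes, n_embryos_per_group)))
            matrices[(genotype, state)] = pd.DataFrame(vals, index=genes, columns=cols)

    truth = pd.DataFrame({"gene": genes, "control_program_lfc": prog,
                          "ko_effect_lfc": ko_lfc}).set_index("gene")
    params = dict(n_genes=n_genes, reversal_coefficient=reversal_coefficient,
                  noise_sd=noise_sd, n_embryos_per_group=n_embryos_per_group,
                  control_lfc_sd=control_lfc_sd, residual_sd=residual_sd)
    return KOExperiment(matrices, pd.Series(prog, index=genes),
                        pd.Series(ko_lfc, index=genes), truth, params, seed)


# ---------------------------------------------------------------------------
# lipid universe

_CLASS_CHAINS = {"TG": 3, "DG": 2, "MG": 1, "PC": 2, "PE": 2, "PI": 2, "PS": 2,
                 "PG": 2, "LPC": 1, "LPE": 1, "SM": 2, "Cer": 2, "ChE": 1,
                 "FA": 1}

DEFAULT_CLASS_MIX = {"TG": 0.25, "PC": 0.15, "PE": 0.12, "DG": 0.08, "PI": 0.06,
                     "PS": 0.05, "PG": 0.04, "SM": 0.07, "Cer": 0.06, "LPC": 0.04,
                     "LPE": 0.03, "ChE": 0.02, "MG": 0.02, "FA": 0.01}


@dataclass
class LipidUniverse:
    matrix: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame
    params: dict
    seed: int


def gen_lipid_table(n_lipids: int = 431, class_mix: dict | None = None,
                    n_diapause_specific: int | None = None, fold_change: float = 2.0,
                    cv: float = 0.2, n_samples_per_condition: int = 4,
                    planted_class: str | None = None,
                    planted_chain: tuple | None = None,
                    seed: int = 0) -> LipidUniverse:
    """Lipid molar-concentration table with planted diapause-specific species.

    Concentrations are log-normal around a per-lipid baseline with
    coefficient of variation ``cv``; planted lipids are multiplied by
    ``fold_change`` in BOTH diapause conditions only. ``planted_class`` /
    ``planted_chain`` force the planted lipids into one class carrying a
    given chain (e.g. ``("TG", (22, 6))`` for very-long-chain triglycerides).
    """
    if n_diapause_specific is None:
        # the study's own discovery scale: 350 diapause-specific of 431 lipids
        n_diapause_specific = int(round(350 / 431 * n_lipids))
    if not (0 <= n_diapause_specific <= n_lipids):
        raise ValueError("n_diapause_specific must not exceed n_lipids")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng(seed)
    class_mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    total = sum(class_mix.values())
    class_mix = {k: v / total for k, v in class_mix.items()}

    classes = list(class_mix)
    counts = [int(round(class_mix[c] * n_lipids)) for c in classes]
    counts[-1] = max(0, n_lipids - sum(counts[:-1]))
    labels = np.repeat(classes, counts)[:n_lipids]
    if labels.size < n_lipids:
        labels = np.concatenate([labels, np.repeat(classes[0], n_lipids - labels.size)])
    rng.shuffle(labels)

    planted = _quota_flags(n_lipids, n_diapause_specific, rng)
    if planted_class is not None:
        labels = labels.copy()
        labels[planted] = planted_class

    names, seen = [], set()
    for i in range(n_lipids):
        cls = labels[i]
        nch = _CLASS_CHAINS.get(cls, 2)
        while True:
            chains = []
            for _ in range(nch):
                c = int(rng.choice(np.arange(12, 25, 2)))
                d = int(rng.integers(0, min(7, c // 3)))
                chains.append((c, d))
            if planted[i] and planted_chain is not None:
                chains[0] = tuple(planted_chain)
            name = f"{cls}({'/'.join(f'{c}:{d}' for c, d in chains)})"
            if name not in seen:
                seen.add(name)
                names.append(name)
                break

    conditions = ["pre_dia", "dev", "dia_6d", "dia_1m"]
    samples, rows = [], []
    for cond in conditions:
        for r in range(n_samples_per_condition):
            s = f"{cond}_s{r + 1}"
            samples.append(s)
            rows.append({"sample": s, "condition": cond})
    design = pd.DataFrame(rows)

    base = np.exp2(rng.normal(3.0, 1.0, size=n_lipids))
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    dia_cols = np.array([s.startswith("dia_") for s in samples])
    mean_mat = np.tile(base[:, None], (1, len(samples)))
    mean_mat[np.ix_(planted, dia_cols)] *= fold_change
    noise = rng.normal(0.0, sigma, size=mean_mat.shape)
    matrix = pd.DataFrame(mean_mat * np.exp(noise - sigma * sigma / 2),
                          index=names, columns=samples)

    truth = pd.DataFrame({"lipid": names, "lipid_class": labels,
                          "diapause_specific": planted}).set_index("lipid")
    params = dict(n_lipids=n_lipids, n_diapause_specific=n_diapause_specific,
                  fold_change=fold_change, cv=cv,
                  n_samples_per_condition=n_samples_per_condition)
    return LipidUniverse(matrix, design, truth, params, seed)
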