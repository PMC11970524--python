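"""Paralog age binning, diapause-specialization calling and enrichment tests.

A paralog pair is two genes descending from one duplication event with a dated
duplication node. The analysis asks whether pairs in which one gene is
preferentially expressed in diapause and its partner in development
("specialized" pairs) are enriched among old duplications.

Duplication ages are binned into three categories (boundaries in million
years ago, configurable):

* ``VERY_ANCIENT``  — age > 473.3 (shared with all jawed vertebrates or older)
* ``ANCIENT``       — 111 < age <= 473.3 (shared with most teleost fish)
* ``RECENT_VERY_RECENT`` — age <= 111 (killifish-lineage duplications)

Specialization is called from per-contrast differential-expression records
(three diapause timepoints crossed with two development stages): one gene must
be significantly up in diapause in at least one contrast, and the partner
either significantly down in diapause in some contrast or with a higher median
expression in development than in diapause. Enrichment of specialized pairs
per age bin is quantified as observed/expected fraction ratios with a
half-subsample bootstrap and a 2x2 chi-square.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as rstats

__all__ = [
    "AgeBin", "SpecializationMode", "Location", "SpecializationCall",
    "BinEnrichmentResult", "filter_paralog_families", "assign_age_bin",
    "assign_age_bins", "differential_expression_standin",
    "classify_specialization", "classify_all_pairs", "bin_enrichment",
    "classify_pair_location", "compare_location_distribution",
    "cross_species_program_correlation", "uniquely_regulated_genes",
]

DEFAULT_AGE_BOUNDARIES = (111.0, 473.3)


class AgeBin(str, enum.Enum):
    VERY_ANCIENT = "very_ancient"
    ANCIENT = "ancient"
    RECENT_VERY_RECENT = "recent_very_recent"


class SpecializationMode(str, enum.Enum):
    """Rule variants for the three diapause systems.

    NFUR: African turquoise killifish rule — partner significantly down OR
    development median above diapause median. ALIM_STRICT: South American
    killifish rule — partner must be significantly down. MOUSE: up versus
    both development stages (ICM and epiblast) and partner down versus both.
    """

    NFUR = "nfur"
    ALIM_STRICT = "alim_strict"
    MOUSE = "mouse"


class Location(str, enum.Enum):
    SAME_CHROMOSOME = "same_chromosome"
    DIFFERENT_CHROMOSOME = "different_chromosome"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SpecializationCall:
    pair_id: str
    specialized: bool
    diapause_gene: str | None = None
    development_gene: str | None = None
    rule_path: str | None = None
    mode: SpecializationMode = SpecializationMode.NFUR


@dataclass(frozen=True)
class BinEnrichmentResult:
    bin: AgeBin
    n_pairs_in_bin: int
    n_specialized_in_bin: int
    observed_fraction: float
    expected_fraction: float
    enrichment_ratio: float
    bootstrap_ratios: np.ndarray
    chi2_statistic: float
    chi2_p: float
    undefined: bool = False


# ---------------------------------------------------------------------------
# family filter and age bins

def filter_paralog_families(pairs: pd.DataFrame, max_partners: int = 20) -> pd.DataFrame:
    """Drop pairs where either gene has more than ``max_partners`` paralog
    partners (large interconnected families inflate pairwise counts).

    Expects columns ``family_size_a``/``family_size_b`` (or a single
    ``family_size`` applied to both genes).
    """
    if "family_size_a" in pairs.columns:
        fa, fb = pairs["family_size_a"], pairs["family_size_b"]
    elif "family_size" in pairs.columns:
        fa = fb = pairs["family_size"]
    else:
        raise ValueError("pairs table lacks family_size columns")
    if fa.isna().any() or fb.isna().any():
        raise ValueError("family_size contains missing values")
    keep = (fa <= max_partners) & (fb <= max_partners)
    return pairs.loc[keep].reset_index(drop=True)


def assign_age_bin(age_mya: float, boundaries=DEFAULT_AGE_BOUNDARIES) -> AgeBin:
    """Bin one duplication age. Boundary ages fall into the older-edge-exclusive
    convention: exactly 473.3 is ANCIENT, exactly 111 is RECENT_VERY_RECENT."""
    lower, upper = boundaries
    if not math.isfinite(age_mya) or age_mya < 0:
        raise ValueError(f"invalid duplication age {age_mya}")
    if age_mya > upper:
        return AgeBin.VERY_ANCIENT
    if age_mya > lower:
        return AgeBin.ANCIENT
    return AgeBin.RECENT_VERY_RECENT


def assign_age_bins(pairs: pd.DataFrame, boundaries=DEFAULT_AGE_BOUNDARIES) -> pd.Series:
    return pairs["duplication_age_mya"].map(lambda a: assign_age_bin(a, boundaries))


# ---------------------------------------------------------------------------
# differential expression stand-in

def differential_expression_standin(expression: pd.DataFrame, design: pd.DataFrame,
                                    fdr: float = 0.05,
                                    log_offset: float = 0.5) -> pd.DataFrame:
    """Per-gene Welch tests on log2(normalized + offset) values for every
    diapause-condition x development-condition contrast, BH-adjusted across
    genes within each contrast.

    This is the pluggable stand-in for a count-model engine: any externally
    produced table with columns (gene, contrast, log2_fold_change, padj) can
    be substituted downstream.

    ``design`` needs columns ``sample``, ``condition``, ``phase`` with phase
    in {"diapause", "development"}.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    missing = [s for s in design.index if s not in expression.columns]
    if missing:
        raise ValueError(f"samples missing from expression matrix: {missing[:5]}")
    dia_conditions = sorted(design.loc[design["phase"] == "diapause", "condition"].unique())
    dev_conditions = sorted(design.loc[design["phase"] == "development", "condition"].unique())
    if not dia_conditions or not dev_conditions:
        raise ValueError("design must contain both diapause and development conditions")

    log_expr = np.log2(expression + log_offset)
    cond_samples = {c: design.index[design["condition"] == c].tolist()
                    for c in dia_conditions + dev_conditions}
    for c, samples in cond_samples.items():
        if len(samples) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")

    records = []
    for dia in dia_conditions:
        a = log_expr[cond_samples[dia]].to_numpy()
        for dev in dev_conditions:
            b = log_expr[cond_samples[dev]].to_numpy()
            lfc, p = rstats.welch_t_vectorized(a, b)
            padj = np.array(rstats.bh_adjust(p).adjusted)
            records.append(pd.DataFrame({
                "gene": expression.index,
                "contrast": f"{dia}_vs_{dev}",
                "log2_fold_change": lfc,
                "p_value": p,
                "padj": padj,
            }))
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# specialization calling

def _gene_contrast_status(diff: pd.DataFrame, fdr: float):
    """Per gene: significantly-up-in-diapause and down-in-diapause flags,
    overall and per development condition (for the mouse rule)."""
    sig = diff["padj"] < fdr
    up = sig & (diff["log2_fold_change"] > 0)
    down = sig & (diff["log2_fold_change"] < 0)
    dev_of = diff["contrast"].str.rsplit("_vs_", n=1).str[1]
    g = diff.assign(up=up, down=down, dev=dev_of).groupby("gene", sort=False)
    any_up = g["up"].any()
    any_down = g["down"].any()
    per_dev_up = diff.assign(up=up, dev=dev_of).groupby(["gene", "dev"], sort=False)["up"].any()
    per_dev_down = diff.assign(down=down, dev=dev_of).groupby(["gene", "dev"], sort=False)["down"].any()
    return any_up, any_down, per_dev_up, per_dev_down


def classify_specialization(pairs: pd.DataFrame, differential: pd.DataFrame,
                            expression: pd.DataFrame, design: pd.DataFrame,
                            mode: SpecializationMode = SpecializationMode.NFUR,
                            fdr: float = 0.05) -> list[SpecializationCall]:
    """Call diapause specialization for every pair.

    A gene qualifies as the diapause gene if it is significantly upregulated
    (padj < fdr, positive log2 fold change) in at least one diapause-vs-
    development contrast (in MOUSE mode: versus every development stage).
    The partner must oppose it per the mode's rule. If both genes qualify as
    diapause-up the pair is not specialized: specialization requires opposing
    roles.
    """
    design_idx = design.set_index("sample") if "sample" in design.columns else design
    dia_samples = design_idx.index[design_idx["phase"] == "diapause"].tolist()
    dev_samples = design_idx.index[design_idx["phase"] == "development"].tolist()
    any_up, any_down, per_dev_up, per_dev_down = _gene_contrast_status(differential, fdr)
    dev_conditions = sorted(design_idx.loc[design_idx["phase"] == "development",
                                           "condition"].unique())

    med_dia = expression[dia_samples].median(axis=1)
    med_dev = expression[dev_samples].median(axis=1)

    def up_flag(g):
        if mode is SpecializationMode.MOUSE:
            return all(bool(per_dev_up.get((g, d), False)) for d in dev_conditions)
        return bool(any_up.get(g, False))

    def down_flag(g):
        if mode is SpecializationMode.MOUSE:
            return all(bool(per_dev_down.get((g, d), False)) for d in dev_conditions)
        return bool(any_down.get(g, False))

    calls = []
    for row in pairs.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        for g in (a, b):
            if g not in expression.index:
                raise KeyError(f"gene {g!r} missing from expression matrix")
            if g not in any_up.index:
                raise KeyError(f"gene {g!r} missing from differential table")
        a_up, b_up = up_flag(a), up_flag(b)
        call = SpecializationCall(row.pair_id, False, mode=mode)
        if a_up and b_up:
            call = SpecializationCall(row.pair_id, False, rule_path="both_up", mode=mode)
        elif a_up or b_up:
            dia_gene, dev_gene = (a, b) if a_up else (b, a)
            if down_flag(dev_gene):
                call = SpecializationCall(row.pair_id, True, dia_gene, dev_gene,
                                          "partner_significantly_down", mode)
            elif mode is SpecializationMode.NFUR and \
                    med_dev[dev_gene] > med_dia[dev_gene]:
                call = SpecializationCall(row.pair_id, True, dia_gene, dev_gene,
                                          "partner_median_rule", mode)
        calls.append(call)
    return calls


def classify_all_pairs(*args, **kwargs):
    """Alias for :func:`classify_specialization` (whole-table form)."""
    return classify_specialization(*args, **kwargs)


# ---------------------------------------------------------------------------
# bin enrichment

def bin_enrichment(bins: pd.Series, specialized: pd.Series, n_boot: int = 10_000,
                   subsample_fraction: float = 0.5, seed: int | None = None,
                   with_replacement: bool = False) -> dict[AgeBin, BinEnrichmentResult]:
    """Enrichment of specialized pairs per age bin versus the genome average.

    observed fraction = specialized pairs in bin / all specialized pairs;
    expected fraction = pairs in bin / all pairs; ratio = observed/expected.
    The bootstrap re-draws ``subsample_fraction`` of all pairs without
    replacement ``n_boot`` times and recomputes the ratio per draw (counts
    follow a multivariate hypergeometric, sampled directly). The chi-square
    tests the 2x2 table (specialized yes/no) x (in bin yes/no) over pairs.
    """
    bins = pd.Series(bins).reset_index(drop=True)
    spec = np.asarray(specialized, dtype=bool)
    if len(bins) != spec.size:
        raise ValueError("bins and specialized must align")
    n = spec.size
    n_spec = int(spec.sum())
    rng = np.random.default_rng(seed)
    k_draw = math.ceil(subsample_fraction * n)

    results = {}
    for b in AgeBin:
        in_bin = (bins == b).to_numpy()
        n_bin = int(in_bin.sum())
        if n_bin == 0 or n_spec == 0:
            results[b] = BinEnrichmentResult(b, n_bin, 0, math.nan, math.nan, math.nan,
                                             np.empty(0), math.nan, math.nan, undefined=True)
            continue
        n_spec_bin = int((spec & in_bin).sum())
        obs = n_spec_bin / n_spec
        exp = n_bin / n
        ratio = obs / exp

        # four strata: spec&bin, spec&!bin, !spec&bin, !spec&!bin
        colors = np.array([
            n_spec_bin, n_spec - n_spec_bin,
            n_bin - n_spec_bin, n - n_spec - (n_bin - n_spec_bin),
        ])
        if n_boot > 0:
            if with_replacement:
                draws = rng.multinomial(k_draw, colors / n, size=n_boot)
            else:
                draws = rng.multivariate_hypergeometric(colors, k_draw, size=n_boot)
            sb, so, nb = draws[:, 0], draws[:, 1], draws[:, 2]
            with np.errstate(divide="ignore", invalid="ignore"):
                boot = (sb / (sb + so)) / ((sb + nb) / k_draw)
        else:
            boot = np.empty(0)

        table = [[n_spec_bin, n_spec - n_spec_bin],
                 [n_bin - n_spec_bin, n - n_spec - (n_bin - n_spec_bin)]]
        try:
            chi = rstats.chi_square_2x2(table)
            chi_stat, chi_p = chi.statistic, chi.p_value
        except ValueError:  # degenerate margin (e.g. everything specialized)
            chi_stat, chi_p = math.nan, math.nan
        results[b] = BinEnrichmentResult(b, n_bin, n_spec_bin, obs, exp, ratio,
                                         boot, chi_stat, chi_p)
    return results


# ---------------------------------------------------------------------------
# genomic location of pair members

_UNPLACED_MARKERS = ("scaffold", "unplaced", "random", "chrun", "un_")


def classify_pair_location(chrom_a: str | None, chrom_b: str | None) -> Location:
    """Same/different chromosome for the two pair members; genes on unplaced
    scaffolds (or with missing labels) yield UNKNOWN and are excluded from the
    location comparison."""
    def unplaced(c):
        return c is None or (isinstance(c, float) and math.isnan(c)) or \
            any(m in str(c).lower() for m in _UNPLACED_MARKERS)
    if unplaced(chrom_a) or unplaced(chrom_b):
        return Location.UNKNOWN
    return Location.SAME_CHROMOSOME if str(chrom_a) == str(chrom_b) \
        else Location.DIFFERENT_CHROMOSOME


def compare_location_distribution(specialized, locations) -> rstats.TestResult:
    """Contingency test of specialization x same-chromosome membership.

    UNKNOWN locations are excluded. A chi-square on the 2x2 table is used;
    if any cell is empty, Fisher's exact test is the fallback.
    """
    spec = np.asarray(specialized, dtype=bool)
    loc = np.asarray([Location(l).value for l in locations])
    keep = loc != Location.UNKNOWN.value
    spec, loc = spec[keep], loc[keep]
    same = loc == Location.SAME_CHROMOSOME.value
    table = np.array([[int((spec & same).sum()), int((spec & ~same).sum())],
                      [int((~spec & same).sum()), int((~spec & ~same).sum())]])
    if (table == 0).any():
        odds, p = sps.fisher_exact(table)
        return rstats.TestResult(float(odds), float(p), "two_sided",
                                 extra={"method": "fisher_exact", "table": table.tolist()})
    res = rstats.chi_square_2x2(table)
    return rstats.TestResult(res.statistic, res.p_value, "two_sided", 1.0,
                             extra={"method": "chi_square", "table": table.tolist()})


# ---------------------------------------------------------------------------
# cross-species comparisons

def cross_species_program_correlation(ortholog_map: pd.DataFrame, lfc_a: pd.Series,
                                      lfc_b: pd.Series) -> rstats.TestResult:
    """Spearman correlation of diapause log fold changes across orthologs.

    ``ortholog_map`` has columns ``gene_a``/``gene_b`` mapping species A genes
    to species B genes; the correlation runs on orthologs with finite fold
    changes in both species.
    """
    merged = ortholog_map.assign(
        la=ortholog_map["gene_a"].map(lfc_a),
        lb=ortholog_map["gene_b"].map(lfc_b),
    ).dropna(subset=["la", "lb"])
    merged = merged[np.isfinite(merged["la"]) & np.isfinite(merged["lb"])]
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared orthologs with finite fold changes")
    return spearman_with_n(merged["la"].to_numpy(), merged["lb"].to_numpy())


def spearman_with_n(x, y) -> rstats.TestResult:
    res = rstats.spearman_correlation(x, y)
    res.extra.setdefault("n", len(np.asarray(x)))
    return res


def uniquely_regulated_genes(de_sets: dict[str, set], focal: str,
                             ortholog_maps: dict[str, dict]) -> set:
    """Focal-species significant genes whose orthologs are not significant
    (or absent) in every other species.

    ``ortholog_maps[species]`` maps focal gene id -> that species' gene id.
    """
    if focal not in de_sets:
        raise ValueError(f"focal species {focal!r} missing from de_sets")
    others = [s for s in de_sets if s != focal]
    for s in others:
        if s not in ortholog_maps:
            raise ValueError(f"missing ortholog map for species {s!r}")
    unique = set()
    for gene in de_sets[focal]:
        shared = any(ortholog_maps[s].get(gene) in de_sets[s] for s in others)
        if not shared:
            unique.add(gene)
    return unique
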