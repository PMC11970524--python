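"""Lipidomics: name parsing, normalization, diapause-specific classification,
and class / fatty-acid composition summaries.

Lipid species are named ``CLASS(c1:d1/c2:d2/...)`` — e.g. ``TG(16:0/18:1/22:6)``
— or in summed notation ``CLASS(c:d)`` where only total carbons and double
bonds are known; summed chains are kept as a single pseudo-chain and excluded
from per-fatty-acid composition and very-long-chain calls. Ether/plasmalogen
prefixes (``O-``, ``P-``) are preserved on the chain.

Samples span four conditions: pre-diapause, development (diapause escape),
diapause 6 days and diapause 1 month. Per-sample median normalization
(computed over non-TG/DG lipids, applied to every lipid) corrects for
starting-material differences. A lipid is *diapause-specific* when it is
significantly different (Welch's t-test, BH-adjusted within each comparison)
between diapause and development conditions with a consistent direction, but
does not significantly change between the two development conditions.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as rstats

__all__ = ["Chain", "LipidSpecies", "LipidCall", "Condition", "parse_lipid_name",
           "median_normalize", "classify_diapause_lipids", "is_very_long_chain",
           "class_concentrations", "fatty_acid_composition"]

VERY_LONG_CHAIN_CARBONS = 22


class Condition(str, enum.Enum):
    PRE_DIA = "pre_dia"
    DEV = "dev"
    DIA_6D = "dia_6d"
    DIA_1M = "dia_1m"


DIAPAUSE_CONDITIONS = (Condition.DIA_6D, Condition.DIA_1M)
DEVELOPMENT_CONDITIONS = (Condition.PRE_DIA, Condition.DEV)


@dataclass(frozen=True)
class Chain:
    carbons: int
    double_bonds: int
    prefix: str = ""      # "", "O-" (ether) or "P-" (plasmalogen)
    summed: bool = False  # class-level c:d total, not a resolved acyl chain

    def __str__(self) -> str:
        return f"{self.prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    lipid_id: str
    lipid_class: str
    chains: tuple
    name_string: str

    @property
    def summed(self) -> bool:
        return any(c.summed for c in self.chains)

    def format_name(self) -> str:
        return f"{self.lipid_class}({'/'.join(str(c) for c in self.chains)})"


@dataclass(frozen=True)
class LipidCall:
    lipid_id: str
    diapause_specific: bool
    direction: str | None            # "up" | "down" in diapause
    q_values: dict                   # comparison label -> BH-adjusted p


_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\((.+)\)$")
_CHAIN_RE = re.compile(r"^([OP]-)?(\d+):(\d+)$")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a lipid name string into class and chains.

    A single ``c:d`` token is summed notation (one pseudo-chain); slash-
    separated tokens are resolved acyl chains.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable lipid name: {name!r}")
    cls, body = m.group(1), m.group(2)
    tokens = body.split("/")
    chains = []
    for tok in tokens:
        cm = _CHAIN_RE.match(tok.strip())
        if not cm:
            raise ValueError(f"unparseable chain token {tok!r} in {name!r}")
        carbons, dbs = int(cm.group(2)), int(cm.group(3))
        if carbons <= 0:
            raise ValueError(f"chain carbons must be positive in {name!r}")
        chains.append(Chain(carbons, dbs, cm.group(1) or "",
                            summed=len(tokens) == 1))
    return LipidSpecies(name, cls, tuple(chains), name)


def _sample_conditions(design: pd.DataFrame) -> dict[Condition, list[str]]:
    d = design.set_index("sample") if "sample" in design.columns else design
    out = {}
    for cond in Condition:
        out[cond] = d.index[d["condition"] == cond.value].tolist()
    return out


def median_normalize(matrix: pd.DataFrame, lipid_classes: pd.Series,
                     exclude_classes: tuple = ("TG", "DG")) -> pd.DataFrame:
    """Equalize per-sample medians computed over non-excluded lipids.

    The scaling factor (grand median of per-sample medians over non-excluded
    lipids, divided by each sample's own such median) is applied to every
    lipid in the sample, excluded classes included — they are left out only
    of the factor computation. Idempotent.
    """
    keep = ~lipid_classes.loc[matrix.index].isin(exclude_classes)
    if not keep.any():
        raise ValueError("no non-excluded lipids to normalize on")
    sample_medians = matrix.loc[keep].median(axis=0)
    if (sample_medians <= 0).any():
        bad = sample_medians.index[sample_medians <= 0].tolist()
        raise ValueError(f"non-positive sample median for {bad}")
    target = float(sample_medians.median())
    factors = target / sample_medians
    return matrix * factors


def classify_diapause_lipids(matrix: pd.DataFrame, design: pd.DataFrame,
                             alpha: float = 0.05,
                             mode: str = "any_consistent",
                             log_transform: bool = True) -> list[LipidCall]:
    """Diapause-specific lipid calls.

    Welch tests run for every diapause x development condition pair plus the
    development-vs-development pair, BH-adjusted across lipids within each
    comparison. Concentrations are log-transformed first by default:
    lipid intensities are multiplicative (roughly log-normal), so the t-test
    assumptions hold on the log scale. A lipid is diapause-specific iff
    significant in >= 1 diapause-vs-development pair with consistent
    direction across all its significant pairs (``mode="all"`` requires all
    four pairs significant) AND the development pair is non-significant.
    """
    if mode not in ("any_consistent", "all"):
        raise ValueError("mode must be 'any_consistent' or 'all'")
    cond_samples = _sample_conditions(design)
    for cond, samples in cond_samples.items():
        if len(samples) < 2:
            raise ValueError(f"condition {cond.value} has fewer than 2 samples")

    values = np.log(matrix.clip(lower=1e-12)) if log_transform else matrix
    arrays = {c: values[s].to_numpy(dtype=float) for c, s in cond_samples.items()}
    comparisons = [(d, v) for d in DIAPAUSE_CONDITIONS for v in DEVELOPMENT_CONDITIONS]
    dev_pair = (Condition.PRE_DIA, Condition.DEV)

    qtab, lfc_sign = {}, {}
    for a, b in comparisons + [dev_pair]:
        label = f"{a.value}_vs_{b.value}"
        x, y = arrays[a], arrays[b]
        diff, p = rstats.welch_t_vectorized(x, y)
        qtab[label] = np.array(rstats.bh_adjust(p).adjusted)
        lfc_sign[label] = np.sign(diff)

    dev_label = f"{dev_pair[0].value}_vs_{dev_pair[1].value}"
    calls = []
    for i, lipid in enumerate(matrix.index):
        sig_dirs = []
        n_sig = 0
        for a, b in comparisons:
            label = f"{a.value}_vs_{b.value}"
            if qtab[label][i] < alpha:
                n_sig += 1
                sig_dirs.append(lfc_sign[label][i])
        consistent = bool(sig_dirs) and len(set(sig_dirs)) == 1 and sig_dirs[0] != 0
        dev_stable = qtab[dev_label][i] >= alpha
        if mode == "all":
            specific = n_sig == len(comparisons) and consistent and dev_stable
        else:
            specific = consistent and dev_stable
        direction = None
        if specific:
            direction = "up" if sig_dirs[0] > 0 else "down"
        calls.append(LipidCall(str(lipid), specific, direction,
                               {lab: float(q[i]) for lab, q in qtab.items()}))
    return calls


def is_very_long_chain(species: LipidSpecies):
    """True iff any resolved chain has >= 22 carbons; None (undetermined)
    for summed notation, where chain lengths are not resolved."""
    if species.summed:
        return None
    return any(c.carbons >= VERY_LONG_CHAIN_CARBONS for c in species.chains)


def class_concentrations(matrix: pd.DataFrame, lipid_classes: pd.Series) -> pd.DataFrame:
    """Class x sample molar concentration sums."""
    return matrix.groupby(lipid_classes.loc[matrix.index]).sum()


def fatty_acid_composition(matrix: pd.DataFrame, species: dict[str, LipidSpecies],
                           lipid_class: str) -> dict:
    """Per-fatty-acid fraction of a class's chain pool, per sample.

    Every chain occurrence is weighted by its parent lipid's molar
    concentration; fractions over the class's chains sum to 1 per sample.
    Summed-notation lipids are excluded. Also returns the SFA / MUFA / PUFA
    grouping (0, 1, >= 2 double bonds).
    """
    members = [lid for lid in matrix.index
               if lid in species and species[lid].lipid_class == lipid_class
               and not species[lid].summed]
    if not members:
        raise ValueError(f"no resolved-chain lipids in class {lipid_class!r}")
    fa_rows = {}
    for lid in members:
        conc = matrix.loc[lid]
        for chain in species[lid].chains:
            key = str(chain)
            fa_rows[key] = fa_rows.get(key, 0) + conc
    fa = pd.DataFrame(fa_rows).T  # fatty acid x sample
    fractions = fa / fa.sum(axis=0)

    def _sat_group(fa_name: str) -> str:
        db = int(fa_name.split(":")[1])
        return "SFA" if db == 0 else ("MUFA" if db == 1 else "PUFA")

    groups = fractions.groupby([_sat_group(n) for n in fractions.index]).sum()
    return {"fractions": fractions, "saturation": groups}
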