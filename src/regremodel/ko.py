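"""Transcription-factor knockout analysis: DEG calling, program shift,
and paralog-specialization change.

Knockout embryos are compared against two control groups (non-injected
wildtype and scramble-guide injected). A gene is a knockout DEG only when it
is significant at the FDR threshold against BOTH controls with concordant
fold-change sign, which removes injection artifacts.

The *program shift* statistic correlates (Spearman) the knockout-induced
expression change in diapause against the control diapause-vs-development
program over the DEG set: a significant negative correlation means the
knockout pushes diapause embryos toward a development-like transcriptome
(REVERSED), a positive one accentuates the diapause program (ENHANCED), and a
non-significant correlation is NO_EFFECT.

The *specialization shift* asks whether the expression gap between the
diapause-role and development-role genes of specialized paralog pairs changes
under knockout: a two-way ANOVA on per-pair median expression with factors
gene role x genotype, reading the interaction term.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as rstats

__all__ = ["ShiftClass", "ProgramShift", "call_dual_control_degs",
           "program_shift", "specialization_shift"]


class ShiftClass(str, enum.Enum):
    NO_EFFECT = "no_effect"
    ENHANCED = "enhanced"
    REVERSED = "reversed"


@dataclass(frozen=True)
class ProgramShift:
    tf: str
    n_genes: int
    rho: float
    p_value: float
    classification: ShiftClass


_welch_contrast = rstats.welch_t_vectorized


def call_dual_control_degs(ko: pd.DataFrame, scramble: pd.DataFrame,
                           wildtype: pd.DataFrame, fdr: float = 0.1,
                           require_concordant_sign: bool = True,
                           log_offset: float = 0.5) -> pd.DataFrame:
    """Dual-control DEG table: a gene is a DEG iff significant at
    ``fdr`` in both KO-vs-scramble and KO-vs-wildtype (BH within each
    contrast), with the same fold-change sign.

    Inputs are genes x samples matrices of normalized expression for one
    embryonic state; each group needs >= 3 samples.
    """
    for name, df in (("ko", ko), ("scramble", scramble), ("wildtype", wildtype)):
        if df.shape[1] < 3:
            raise ValueError(f"group {name!r} has fewer than 3 samples")
    genes = ko.index
    a = np.log2(ko.to_numpy(dtype=float) + log_offset)
    s = np.log2(scramble.loc[genes].to_numpy(dtype=float) + log_offset)
    w = np.log2(wildtype.loc[genes].to_numpy(dtype=float) + log_offset)
    lfc_s, p_s = _welch_contrast(a, s)
    lfc_w, p_w = _welch_contrast(a, w)
    padj_s = np.array(rstats.bh_adjust(p_s).adjusted)
    padj_w = np.array(rstats.bh_adjust(p_w).adjusted)
    is_deg = (padj_s < fdr) & (padj_w < fdr)
    if require_concordant_sign:
        is_deg &= np.sign(lfc_s) == np.sign(lfc_w)
    return pd.DataFrame({
        "gene": genes, "lfc_vs_scramble": lfc_s, "padj_vs_scramble": padj_s,
        "lfc_vs_wildtype": lfc_w, "padj_vs_wildtype": padj_w, "is_deg": is_deg,
    }).set_index("gene")


def program_shift(ko_vs_control_lfc: pd.Series, control_dia_vs_dev_lfc: pd.Series,
                  tf: str = "", alpha: float = 0.05) -> ProgramShift:
    """Classify the knockout's effect on the diapause program.

    Spearman correlation between the knockout-vs-control fold changes in
    diapause and the control diapause-vs-development fold changes, over
    shared genes with finite values.
    """
    merged = pd.DataFrame({"ko": ko_vs_control_lfc,
                           "prog": control_dia_vs_dev_lfc}).dropna()
    merged = merged[np.isfinite(merged["ko"]) & np.isfinite(merged["prog"])]
    if len(merged) < 3:
        raise ValueError("program_shift requires >= 3 shared genes")
    res = rstats.spearman_correlation(merged["ko"].to_numpy(),
                                      merged["prog"].to_numpy())
    if res.degenerate or res.p_value >= alpha:
        cls = ShiftClass.NO_EFFECT
    elif res.statistic > 0:
        cls = ShiftClass.ENHANCED
    else:
        cls = ShiftClass.REVERSED
    return ProgramShift(tf, len(merged), res.statistic, res.p_value, cls)


def specialization_shift(specialized_pairs: pd.DataFrame,
                         control_diapause: pd.DataFrame,
                         ko_diapause: pd.DataFrame,
                         log_offset: float = 0.5) -> dict:
    """Does knockout change the specialization gap of paralog pairs?

    ``specialized_pairs`` needs columns ``pair_id, diapause_gene,
    development_gene``. For each pair and genotype (control / knockout) the
    median log2 expression across diapause samples is taken for each role
    gene; a two-way ANOVA with factors role x genotype is fitted on the
    per-pair medians and the interaction term tests whether the role gap
    differs between genotypes.

    Returns the ANOVA results plus the estimated gap per genotype.
    """
    if len(specialized_pairs) < 2:
        raise ValueError("specialization_shift requires >= 2 pairs")
    needed = {"pair_id", "diapause_gene", "development_gene"}
    if not needed.issubset(specialized_pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(needed)}")

    rows = []
    for row in specialized_pairs.itertuples(index=False):
        for role, gene in (("diapause_role", row.diapause_gene),
                           ("development_role", row.development_gene)):
            if gene not in control_diapause.index or gene not in ko_diapause.index:
                raise KeyError(f"gene {gene!r} missing from expression matrices")
            for genotype, mat in (("control", control_diapause), ("knockout", ko_diapause)):
                med = float(np.log2(mat.loc[gene].astype(float) + log_offset).median())
                rows.append({"pair_id": row.pair_id, "role": role,
                             "genotype": genotype, "value": med})
    long = pd.DataFrame(rows)
    anova = rstats.two_way_anova(long["value"], long["role"], long["genotype"])
    gaps = (long.pivot_table(index=["pair_id", "genotype"], columns="role",
                             values="value")
            .assign(gap=lambda d: d["diapause_role"] - d["development_role"])
            .groupby("genotype")["gap"].mean())
    return {"anova": anova, "interaction": anova["interaction"],
            "mean_gap": gaps.to_dict(), "table": long}
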