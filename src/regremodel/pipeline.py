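"""Pipeline orchestration: config validation, stage execution, run manifest.

The pipeline binds the analysis stages (paralogs -> peaks -> motifs -> TE ->
KO -> lipids, each optional) over files in the formats the ``io`` module
reads. Configuration is a YAML/dict with per-stage input paths and
thresholds; every run writes a JSON manifest recording parameters, input
hashes, outputs and warnings, so identical config + inputs reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import ko as ko_mod
from . import lipids as lp
from . import motifs as mo
from . import paralogs as par
from . import te as te_mod
from .intervals import GenomicInterval, IntervalIndex
from .peaks import AlignmentBlockMap, Role, Stringency, classify_conservation, tag_conserved

__all__ = ["load_config", "validate_inputs", "run_pipeline"]

STAGE_ORDER = ["paralogs", "peaks", "motifs", "te", "ko", "lipids"]


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "regremodel_out")
    return cfg


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def validate_inputs(config: dict) -> list[dict]:
    """Schema checks for every referenced input; returns machine-readable
    issues (empty list = valid). Report-only: never raises."""
    issues = []

    def issue(stage, path, problem):
        issues.append({"stage": stage, "path": str(path), "problem": problem})

    for stage in STAGE_ORDER:
        section = config.get(stage)
        if not section or not section.get("enabled", True):
            continue
        for key, path in section.items():
            if not isinstance(path, str) or not any(
                    key.endswith(sfx) for sfx in ("_path", "_bed", "_tsv", "_fasta",
                                                  "_file", "_dir")):
                continue
            p = Path(path)
            if not p.exists():
                issue(stage, path, "missing file")
                continue
            try:
                if key.endswith("_bed"):
                    rio.read_bed(p)
                elif key == "block_map_path":
                    rio.read_block_map(p)
                elif key == "pwm_file":
                    for pwm in rio.read_motif_file(p):
                        rows = pwm.probabilities.sum(axis=1)
                        if np.any(np.abs(rows - 1) > 1e-6):
                            issue(stage, path, f"PWM {pwm.name} rows do not sum to 1")
                elif key.endswith("_fasta"):
                    rio.read_fasta(p)
                elif key.endswith("_tsv") or key.endswith("_path"):
                    pd.read_csv(p, sep="\t", nrows=5)
            except Exception as exc:  # report, never raise
                issue(stage, path, f"unreadable: {exc}")
    return issues


# ---------------------------------------------------------------------------
# stage runners (files in, files out)

def _stage_paralogs(cfg: dict, out: Path, seed: int, warnings: list) -> list[str]:
    pairs = pd.read_csv(cfg["pairs_path"], sep="\t")
    expr = rio.read_tsv_matrix(cfg["expression_path"])
    design = pd.read_csv(cfg["design_path"], sep="\t")
    fdr = float(cfg.get("fdr", 0.05))
    mode = par.SpecializationMode(cfg.get("mode", "nfur"))
    pairs = par.filter_paralog_families(pairs, int(cfg.get("max_partners", 20)))
    if "differential_path" in cfg:
        diff = pd.read_csv(cfg["differential_path"], sep="\t")
    else:
        diff = par.differential_expression_standin(expr, design, fdr=fdr)
    calls = par.classify_specialization(pairs, diff, expr, design, mode=mode, fdr=fdr)
    bins = par.assign_age_bins(pairs)
    spec = [c.specialized for c in calls]
    enr = par.bin_enrichment(bins, spec, n_boot=int(cfg.get("n_boot", 10_000)),
                             seed=seed)
    calls_df = pd.DataFrame([{
        "pair_id": c.pair_id, "specialized": c.specialized,
        "diapause_gene": c.diapause_gene, "development_gene": c.development_gene,
        "rule_path": c.rule_path, "age_bin": b.value,
    } for c, b in zip(calls, bins)])
    enr_df = pd.DataFrame([{
        "bin": b.value, "n_pairs": r.n_pairs_in_bin,
        "n_specialized": r.n_specialized_in_bin,
        "observed_fraction": r.observed_fraction,
        "expected_fraction": r.expected_fraction,
        "enrichment_ratio": r.enrichment_ratio, "chi2_p": r.chi2_p,
        "bootstrap_mean": float(np.nanmean(r.bootstrap_ratios)) if r.bootstrap_ratios.size else np.nan,
    } for b, r in enr.items()])
    locs = [par.classify_pair_location(a, b).value
            for a, b in zip(pairs["chrom_a"], pairs["chrom_b"])]
    calls_df["location"] = locs
    n_unknown = locs.count("unknown")
    if n_unknown:
        warnings.append(f"paralogs: {n_unknown} pairs with UNKNOWN location excluded "
                        "from the location comparison")
    loc_res = par.compare_location_distribution(spec, locs)
    (out / "paralog_location_test.json").write_text(json.dumps({
        "statistic": loc_res.statistic, "p_value": loc_res.p_value,
        **loc_res.extra}, default=str, indent=1))
    calls_df.to_csv(out / "specialization_calls.tsv", sep="\t", index=False)
    enr_df.to_csv(out / "bin_enrichment.tsv", sep="\t", index=False)
    return ["specialization_calls.tsv", "bin_enrichment.tsv", "paralog_location_test.json"]


def _stage_peaks(cfg: dict, out: Path, seed: int, warnings: list) -> list[str]:
    roles_df = pd.read_csv(cfg["roles_path"], sep="\t")
    roles = {r["species"]: Role(r["role"]) for _, r in roles_df.iterrows()}
    focal = [s for s, r in roles.items() if r is Role.FOCAL][0]
    block_map = rio.read_block_map(cfg["block_map_path"])
    stringency = Stringency(cfg.get("stringency", "relaxed"))
    beds = {sp: rio.read_bed(p) for sp, p in cfg["peak_beds"].items()}

    projected: dict[str, list[GenomicInterval]] = {sp: [] for sp in beds if sp != focal}
    n_split = 0
    for sp, df in beds.items():
        if sp == focal:
            continue
        for row in df.itertuples(index=False):
            pp = block_map.project_peak(getattr(row, "name", ""), GenomicInterval(
                row.chrom, int(row.start), int(row.end)), sp)
            n_split += pp.split
            projected[sp].extend(pp.focal_intervals)
    rows = []
    for row in beds[focal].itertuples(index=False):
        fiv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        flags = tag_conserved(fiv, projected, stringency)
        flags[focal] = True
        cat = classify_conservation(flags, roles, focal)
        rows.append({"peak_id": getattr(row, "name", f"{row.chrom}:{row.start}"),
                     "category": cat.value,
                     **{f"conserved_{sp}": flags.get(sp, False)
                        for sp in beds if sp != focal}})
    pd.DataFrame(rows).to_csv(out / "peak_conservation.tsv", sep="\t", index=False)
    if n_split:
        warnings.append(f"peaks: {n_split} projected peaks split across focal loci")
    return ["peak_conservation.tsv"]


def _stage_motifs(cfg: dict, out: Path, seed: int, warnings: list) -> list[str]:
    pwms = rio.read_motif_file(cfg["pwm_file"])
    block_map = rio.read_block_map(cfg["block_map_path"])
    sequences = {sp: rio.read_fasta(p) for sp, p in cfg["fasta_paths"].items()}
    focal = cfg["focal_species"]
    species = [s for s in sequences if s != focal]
    window = int(cfg.get("nearby_window", 100))
    peaks_df = rio.read_bed(cfg["peaks_bed"])
    te_df = rio.read_bed(cfg["te_bed"]).rename(columns={"name": "family"}) \
        if "te_bed" in cfg else None
    te_idx = IntervalIndex(te_df[["chrom", "start", "end"]]) if te_df is not None else None

    summary_rows, site_rows = [], []
    for pwm in pwms:
        sites = []
        for row in peaks_df.itertuples(index=False):
            seq = sequences[focal].get(row.chrom, "")
            sub = seq[int(row.start):int(row.end)]
            for hit in mo.scan_sequence(pwm, sub, peak_id=getattr(row, "name", ""),
                                        species=focal):
                hiv = GenomicInterval(row.chrom, int(row.start) + hit.offset,
                                      int(row.start) + hit.offset + len(pwm))
                site = mo.assess_site_conservation(hiv, hit, block_map, sequences,
                                                   pwm, species, nearby_window=window)
                origin = mo.classify_motif_origin(hiv, hit, te_idx, site, block_map)
                sites.append(site)
                site_rows.append({"motif": pwm.name, "peak_id": hit.peak_id,
                                  "chrom": hiv.chrom, "start": hiv.start,
                                  "end": hiv.end, "strand": hit.strand,
                                  "score": hit.score, "origin": origin.origin.value,
                                  "sharing": origin.sharing.value,
                                  **{f"verdict_{sp}": site.per_species[sp].verdict.value
                                     for sp in species}})
        if sites:
            summ = mo.summarize_conservation(sites)
            summary_rows.append({"motif": pwm.name, "n_sites": len(sites),
                                 "average_conserved_fraction": summ["average"],
                                 "pooled_conserved_fraction": summ["pooled"],
                                 **{f"conserved_{sp}": summ["per_species"][sp]
                                    for sp in species}})
        else:
            warnings.append(f"motifs: no hits for {pwm.name}")
    pd.DataFrame(site_rows).to_csv(out / "motif_sites.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "motif_conservation_summary.tsv",
                                      sep="\t", index=False)
    return ["motif_sites.tsv", "motif_conservation_summary.tsv"]


def _stage_te(cfg: dict, out: Path, seed: int, warnings: list) -> list[str]:
    targets = rio.read_bed(cfg["targets_bed"])
    te_df = rio.read_bed(cfg["te_bed"])
    te_df = te_df.rename(columns={"name": "family", "strand": "te_class"})
    kind = te_mod.BackgroundKind(cfg.get("background", "control_loci"))
    chrom_sizes = rio.read_chrom_sizes(cfg["chrom_sizes_path"]) \
        if "chrom_sizes_path" in cfg else None
    if kind is te_mod.BackgroundKind.GENOME:
        bg = te_mod.BackgroundSpec(kind, chrom_sizes=chrom_sizes)
    elif kind is te_mod.BackgroundKind.ALL_CHROMATIN:
        bg = te_mod.BackgroundSpec(kind, intervals=rio.read_bed(cfg["chromatin_bed"]))
    else:
        loci = te_mod.make_control_loci(targets, chrom_sizes or {},
                                        offset=int(cfg.get("offset", 10_000)))
        if loci.attrs.get("n_dropped"):
            warnings.append(f"te: {loci.attrs['n_dropped']} control loci dropped "
                            "past chromosome ends")
        bg = te_mod.BackgroundSpec(kind, intervals=loci)
    res = te_mod.te_family_enrichment(targets, bg, te_df,
                                      alpha=float(cfg.get("alpha", 0.05)))
    res.to_csv(out / "te_enrichment.tsv", sep="\t", index=False)
    return ["te_enrichment.tsv"]


def _stage_ko(cfg: dict, out: Path, seed: int, warnings: list) -> list[str]:
    expr = rio.read_tsv_matrix(cfg["expression_path"])
    samples = pd.read_csv(cfg["samples_path"], sep="\t")
    fdr = float(cfg.get("fdr", 0.1))
    tf = cfg.get("tf", "")

    def group(genotype, state):
        cols = samples.loc[(samples["genotype"] == genotype)
                           & (samples["state"] == state), "embryo_id"]
        return expr[list(cols)]

    ko_dia = group(f"KO:{tf}" if tf else "ko", "diapause")
    scr_dia = group("scramble", "diapause")
    wt_dia = group("wildtype", "diapause")
    degs = ko_mod.call_dual_control_degs(ko_dia, scr_dia, wt_dia, fdr=fdr)
    control_dia = pd.concat([wt_dia, scr_dia], axis=1)
    control_dev = pd.concat([group("wildtype", "development"),
                             group("scramble", "development")], axis=1)
    prog = (np.log2(control_dia + 0.5).mean(axis=1)
            - np.log2(control_dev + 0.5).mean(axis=1))
    ko_lfc = (np.log2(ko_dia + 0.5).mean(axis=1)
              - np.log2(control_dia + 0.5).mean(axis=1))
    deg_genes = degs.index[degs["is_deg"]]
    if len(deg_genes) < 3:
        warnings.append(f"ko: only {len(deg_genes)} DEGs; program shift undefined")
        shift = None
    else:
        shift = ko_mod.program_shift(ko_lfc[deg_genes], prog[deg_genes], tf=tf)
    degs.to_csv(out / "ko_degs.tsv", sep="\t")
    payload = {"tf": tf, "n_degs": int(degs["is_deg"].sum())}
    if shift:
        payload.update({"rho": shift.rho, "p_value": shift.p_value,
                        "classification": shift.classification.value,
                        "n_genes": shift.n_genes})
    (out / "ko_program_shift.json").write_text(json.dumps(payload, indent=1))
    return ["ko_degs.tsv", "ko_program_shift.json"]


def _stage_lipids(cfg: dict, out: Path, seed: int, warnings: list) -> list[str]:
    matrix = rio.read_tsv_matrix(cfg["table_path"])
    design = pd.read_csv(cfg["samples_path"], sep="\t")
    alpha = float(cfg.get("alpha", 0.05))
    mode = cfg.get("mode", "any_consistent")
    species = {}
    for name in matrix.index:
        try:
            species[name] = lp.parse_lipid_name(name)
        except ValueError:
            warnings.append(f"lipids: unparseable name {name!r}, kept unparsed")
    classes = pd.Series({n: (species[n].lipid_class if n in species else "unknown")
                         for n in matrix.index})
    norm = lp.median_normalize(matrix, classes)
    calls = lp.classify_diapause_lipids(norm, design, alpha=alpha, mode=mode)
    rows = []
    for c in calls:
        sp = species.get(c.lipid_id)
        vlc = lp.is_very_long_chain(sp) if sp else None
        rows.append({"lipid": c.lipid_id,
                     "lipid_class": sp.lipid_class if sp else "unknown",
                     "diapause_specific": c.diapause_specific,
                     "direction": c.direction,
                     "very_long_chain": vlc, **c.q_values})
    pd.DataFrame(rows).to_csv(out / "lipid_calls.tsv", sep="\t", index=False)
    lp.class_concentrations(norm, classes).to_csv(out / "lipid_class_sums.tsv", sep="\t")
    return ["lipid_calls.tsv", "lipid_class_sums.tsv"]


_RUNNERS = {"paralogs": _stage_paralogs, "peaks": _stage_peaks,
            "motifs": _stage_motifs, "te": _stage_te, "ko": _stage_ko,
            "lipids": _stage_lipids}


def run_pipeline(config: dict) -> dict:
    """Execute enabled stages in dependency order; returns the run manifest.

    A stage failure aborts the run with a stage-scoped error; outputs of
    completed stages are retained and flagged in the manifest.
    """
    out = Path(config.get("output_dir", "regremodel_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"seed": seed, "stages": {}, "status": "ok"}
    for stage in STAGE_ORDER:
        cfg = config.get(stage)
        if not cfg or not cfg.get("enabled", True):
            continue
        t0 = time.time()
        warnings: list[str] = []
        inputs = {k: _hash_file(v) for k, v in cfg.items()
                  if isinstance(v, str) and Path(v).is_file()}
        try:
            outputs = _RUNNERS[stage](cfg, out, seed, warnings)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": f"{exc}",
                                         "warnings": warnings}
            manifest["status"] = f"failed at {stage}"
            break
        manifest["stages"][stage] = {
            "status": "ok", "inputs": inputs,
            "params": {k: v for k, v in cfg.items() if not isinstance(v, (dict,))},
            "outputs": outputs, "wall_time_s": round(time.time() - t0, 3),
            "warnings": warnings,
        }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
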