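"""Readers and writers for the pipeline's file formats.

Tabular data travel as TSV, intervals as BED (0-based half-open), sequences
as FASTA (Biopython), motifs in a small text format (header line
``> consensus <tab> name <tab> detection_threshold`` followed by one
tab-separated A C G T probability row per position). A RepeatMasker ``.out``
converter and a MAF flattener (gapless-block extraction) are provided for
real-data inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import PWM
from .peaks import AlignmentBlockMap

__all__ = [
    "read_bed", "write_bed", "read_fasta", "write_fasta", "read_tsv_matrix",
    "write_tsv_matrix", "read_block_map", "write_block_map", "read_motif_file",
    "write_motif_file", "read_chrom_sizes", "read_repeatmasker_out",
    "read_maf_blocks", "write_truth_json", "read_truth_json",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED intervals must satisfy start < end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    if "name" not in cols and "peak_id" in df.columns:
        df = df.rename(columns={"peak_id": "name"})
        cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_block_map(path) -> AlignmentBlockMap:
    df = pd.read_csv(path, sep="\t")
    return AlignmentBlockMap(df)


def write_block_map(block_map: AlignmentBlockMap, path) -> None:
    block_map.blocks.to_csv(path, sep="\t", index=False)


def read_motif_file(path) -> list[PWM]:
    """Parse the motif text format; several motifs may share one file."""
    pwms = []
    name = None
    threshold = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(PWM(name, np.array(rows), threshold))
                fields = line[1:].strip().split("\t")
                if len(fields) != 3:
                    raise ValueError(f"malformed motif header: {line!r}")
                name, threshold = fields[1], float(fields[2])
                rows = []
            else:
                vals = [float(v) for v in line.split("\t")]
                if len(vals) != 4:
                    raise ValueError(f"motif row must have 4 probabilities: {line!r}")
                rows.append(vals)
    if name is not None:
        pwms.append(PWM(name, np.array(rows), threshold))
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


def write_motif_file(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.consensus()}\t{pwm.name}\t{pwm.detection_threshold}\n")
            for row in pwm.probabilities:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_repeatmasker_out(path) -> pd.DataFrame:
    """Convert RepeatMasker ``.out`` to a BED-like TE table
    (chrom, start, end, family, te_class). Coordinates in ``.out`` are
    1-based inclusive; converted to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header / blank lines
            chrom, start, end = parts[4], int(parts[5]) - 1, int(parts[6])
            family = parts[9]
            te_class = parts[10] if len(parts) > 10 else ""
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "family": family, "te_class": te_class})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "te_class"])


def read_maf_blocks(path, focal_prefix: str) -> pd.DataFrame:
    """Flatten a MAF alignment into gapless colinear blocks on the focal
    genome, splitting at every gap column.

    Sequence names must follow the ``species.chrom`` MAF convention;
    ``focal_prefix`` selects the reference row. Minus-strand rows are
    converted to forward-strand coordinates per the MAF specification.
    Returns an :class:`AlignmentBlockMap`-compatible DataFrame.
    """
    from Bio import AlignIO

    out = []
    for aln in AlignIO.parse(str(path), "maf"):
        ref = None
        for rec in aln:
            if rec.id.split(".", 1)[0] == focal_prefix:
                ref = rec
                break
        if ref is None:
            continue
        ref_seq = str(ref.seq)
        for rec in aln:
            if rec is ref:
                continue
            sp, chrom = (rec.id.split(".", 1) + [""])[:2]
            seq = str(rec.seq)
            strand = "+" if rec.annotations.get("strand", 1) == 1 else "-"
            src_size = rec.annotations.get("srcSize", 0)
            rpos = ref.annotations["start"]
            tpos = rec.annotations["start"]
            run_r = run_t = None
            run_len = 0

            def flush():
                nonlocal run_r, run_t, run_len
                if run_len > 0:
                    if strand == "+":
                        ts, te = run_t, run_t + run_len
                    else:  # MAF minus-strand start counts from the reverse strand
                        te = src_size - run_t
                        ts = te - run_len
                    out.append({"focal_chrom": ref.id.split(".", 1)[1],
                                "focal_start": run_r, "focal_end": run_r + run_len,
                                "species": sp, "target_chrom": chrom,
                                "target_start": ts, "target_end": te,
                                "strand": strand})
                run_r = run_t = None
                run_len = 0

            for rbase, tbase in zip(ref_seq, seq):
                if rbase != "-" and tbase != "-":
                    if run_len == 0:
                        run_r, run_t = rpos, tpos
                    run_len += 1
                else:
                    flush()
                if rbase != "-":
                    rpos += 1
                if tbase != "-":
                    tpos += 1
            flush()
    return pd.DataFrame(out, columns=AlignmentBlockMap.COLUMNS)


def write_truth_json(truth: pd.DataFrame, params: dict, seed: int, path) -> None:
    payload = {"seed": seed, "params": params,
               "truth": truth.reset_index().to_dict(orient="records")}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
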