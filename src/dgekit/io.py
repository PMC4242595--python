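"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
- genome: FASTA (uppercased on read; pyfaidx-backed)
- annotation: BED-like 6-column TSV -- chrom, start, end, name, score,
  strand; 0-based half-open; ``name`` holds ``transcript_id|gene_id``
  (a bare name doubles as both ids)
- counts: TSV, gene ids in the first column, one library per column
- tags: 2-column TSV, tag sequence then count
- clinical: TSV with a documented header (see CLINICAL_COLUMNS)
- reports/config: JSON (sorted keys) / YAML
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

CLINICAL_COLUMNS = [
    "patient_id", "sex", "age", "t_stage",
    "ALDH2_proportion_pct", "ALDH2_intensity_grade",
    "CCNE1_proportion_pct", "CCNE1_intensity_grade",
    "SMAD3_proportion_pct", "SMAD3_intensity_grade",
    "time", "event",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> chrom -> uppercase sequence."""
    fa = Fasta(str(path), rebuild=True, read_ahead=10_000)
    genome = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    # drop the index file pyfaidx leaves behind; outputs stay text-only
    idx = Path(str(path) + ".fai")
    if idx.exists():
        idx.unlink()
    if not genome:
        raise ValueError(f"{path}: no sequences found")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED6 -> annotation frame (chrom, start, end, transcript_id, strand, gene_id)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{ln}: expected 6 tab-separated columns")
        chrom, start, end, name, _score, strand = parts[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
        if end_i <= start_i:
            raise ValueError(f"{path}:{ln}: end ({end_i}) <= start ({start_i})")
        if strand not in "+-":
            raise ValueError(f"{path}:{ln}: bad strand {strand!r}")
        tx_id, _, gene_id = name.partition("|")
        rows.append(
            {
                "chrom": chrom, "start": start_i, "end": end_i,
                "transcript_id": tx_id, "strand": strand,
                "gene_id": gene_id or tx_id,
            }
        )
    if not rows:
        raise ValueError(f"{path}: empty annotation")
    return pd.DataFrame(rows)


def write_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for _, row in annotation.iterrows():
            name = f"{row['transcript_id']}|{row['gene_id']}"
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t0\t{row['strand']}\n"
            )


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no library columns")
    if not np.issubdtype(df.to_numpy().dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_tags(path: str | Path) -> dict[str, int]:
    """2-column TSV (tag, count) -> tag -> count."""
    out: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'tag<TAB>count'")
        tag, count = parts
        try:
            c = int(count)
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer count {count!r}") from None
        if c < 0:
            raise ValueError(f"{path}:{ln}: negative count")
        out[tag] = out.get(tag, 0) + c
    return out


def write_tags(tags: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for tag in sorted(tags):
            fh.write(f"{tag}\t{tags[tag]}\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV with per-column schema validation."""
    df = pd.read_csv(path, sep="\t")
    errors = []
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing column {col!r}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    for col in ("age", "time"):
        if not np.issubdtype(df[col].dtype, np.number):
            errors.append(f"column {col!r} must be numeric")
    if not errors and (df["time"] <= 0).any():
        errors.append("column 'time' must be positive")
    if not errors and not df["event"].isin([0, 1]).all():
        errors.append("column 'event' must be 0/1")
    if not errors and not df["t_stage"].isin(["T1", "T2", "T3"]).all():
        errors.append("column 't_stage' must be T1/T2/T3")
    for m in ("ALDH2", "CCNE1", "SMAD3"):
        col = f"{m}_intensity_grade"
        if not errors and not df[col].isin([0, 1, 2, 3]).all():
            errors.append(f"column {col!r} must be an integer grade 0-3")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
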