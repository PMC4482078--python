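"""Readers and writers for the artefacts the pipeline touches.

All tabular files are single-header, tab-separated, UTF-8, unquoted.
Floats are serialized with 17 significant digits so write/read round-trips
are exact at double precision. Writers keep the input row order, so output
files are byte-stable for identical input.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "PEPTIDE_COLUMNS",
    "RESULT_COLUMNS",
    "MATRIX_COLUMNS",
    "TRUTH_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "read_result_table",
    "write_result_table",
    "read_matrix_table",
    "write_matrix_table",
    "read_truth_table",
    "write_truth_table",
]

FLOAT_FMT = "%.17g"

PEPTIDE_COLUMNS = ["peptide_id", "protein_id", "replicate_id", "design",
                   "log2_hl", "probability"]
OPTIONAL_PEPTIDE_COLUMNS = ["correct"]
RESULT_COLUMNS = ["protein_id", "mean_log2", "n_reps", "sample_var",
                  "posterior_var", "t", "p", "adj_p", "call"]
MATRIX_COLUMNS = ["protein_id", "replicate_id", "ratio", "n_peptides"]
TRUTH_COLUMNS = ["protein_id", "true_log2_ratio", "bias_class",
                 "copies_per_cell", "n_peptides"]

VALID_CALLS = {"up37", "down37", "ns"}
_FASTA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when a file fails schema or value validation."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a nucleotide FASTA file into ``[(id, sequence), ...]``.

    Sequences are upper-cased; duplicate ids and characters outside
    {A, C, G, T, N} are rejected.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in _FASTA_ALPHABET:
                raise FormatError(
                    f"illegal character {ch!r} at position {pos} "
                    f"in sequence {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# generic TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str],
              optional: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    for col in required:
        if col not in cols:
            raise FormatError(f"missing column {col!r} in {path}")
    allowed = set(required) | set(optional)
    extra = [c for c in cols if c not in allowed]
    if extra:
        raise FormatError(f"unexpected column(s) {extra} in {path}")
    return df


def _to_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        return df[col].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"unparsable value in column {col!r} of {path}: {exc}")


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n")


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide observation table, validating every field.

    Columns: peptide_id, protein_id, replicate_id, design (+1/-1),
    log2_hl (finite float), probability (in [0, 1]); optional boolean
    column ``correct`` (simulation ground truth).
    """
    df = _read_tsv(path, PEPTIDE_COLUMNS, OPTIONAL_PEPTIDE_COLUMNS)
    out = pd.DataFrame({
        "peptide_id": df["peptide_id"],
        "protein_id": df["protein_id"],
        "replicate_id": df["replicate_id"],
    })

    designs = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df["design"]):
        try:
            val = int(raw)
        except ValueError:
            val = 0
        if val not in (1, -1):
            raise FormatError(
                f"unparsable design {raw!r} at row {i + 2} of {path}")
        designs[i] = val
    out["design"] = designs

    log2_hl = _to_float(df, "log2_hl", path)
    if not np.all(np.isfinite(log2_hl)):
        row = int(np.flatnonzero(~np.isfinite(log2_hl))[0]) + 2
        raise FormatError(f"non-finite log2_hl at row {row} of {path}")
    out["log2_hl"] = log2_hl

    prob = _to_float(df, "probability", path)
    bad = (prob < 0) | (prob > 1) | ~np.isfinite(prob)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise FormatError(f"probability outside [0, 1] at row {row} of {path}")
    out["probability"] = prob

    if "correct" in df.columns:
        mapping = {"True": True, "False": False, "1": True, "0": False}
        try:
            out["correct"] = df["correct"].map(lambda s: mapping[s]).astype(bool)
        except KeyError as exc:
            raise FormatError(f"unparsable correct flag {exc} in {path}")
    return out


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = PEPTIDE_COLUMNS + (["correct"] if "correct" in table.columns else [])
    _write_tsv(table[cols], path)


# ---------------------------------------------------------------------------
# moderated-test result tables
# ---------------------------------------------------------------------------

def read_result_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, RESULT_COLUMNS)
    out = pd.DataFrame({"protein_id": df["protein_id"]})
    out["mean_log2"] = _to_float(df, "mean_log2", path)
    out["n_reps"] = df["n_reps"].astype(int)
    for col in ("sample_var", "posterior_var", "t", "p", "adj_p"):
        out[col] = _to_float(df, col, path)
    bad_call = ~df["call"].isin(VALID_CALLS)
    if bad_call.any():
        row = int(np.flatnonzero(bad_call.to_numpy())[0]) + 2
        raise FormatError(f"invalid call at row {row} of {path}")
    out["call"] = df["call"]
    if np.any(out["adj_p"].to_numpy() < out["p"].to_numpy() - 1e-12):
        raise FormatError(f"adj_p < p in {path}")
    return out


def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table[RESULT_COLUMNS], path)


# ---------------------------------------------------------------------------
# protein ratio matrix (long format: one row per non-missing cell)
# ---------------------------------------------------------------------------

def read_matrix_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, MATRIX_COLUMNS)
    out = pd.DataFrame({
        "protein_id": df["protein_id"],
        "replicate_id": df["replicate_id"],
    })
    ratio = _to_float(df, "ratio", path)
    if not np.all(np.isfinite(ratio)):
        raise FormatError(f"non-finite ratio in {path}")
    out["ratio"] = ratio
    out["n_peptides"] = df["n_peptides"].astype(int)
    if (out["n_peptides"] < 1).any():
        raise FormatError(f"non-positive peptide count in {path}")
    return out


def write_matrix_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table[MATRIX_COLUMNS], path)


# ---------------------------------------------------------------------------
# simulation ground truth
# ---------------------------------------------------------------------------

def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, TRUTH_COLUMNS)
    out = pd.DataFrame({"protein_id": df["protein_id"]})
    out["true_log2_ratio"] = _to_float(df, "true_log2_ratio", path)
    bad = ~df["bias_class"].isin(["biased", "unbiased"])
    if bad.any():
        raise FormatError(f"invalid bias_class in {path}")
    out["bias_class"] = df["bias_class"]
    out["copies_per_cell"] = _to_float(df, "copies_per_cell", path)
    out["n_peptides"] = df["n_peptides"].astype(int)
    return out


def write_truth_table(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table[TRUTH_COLUMNS], path)
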