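"""Readers and writers for every table format the toolkit consumes or emits.

Formats (all plain text; peptide positions are 1-based everywhere):

* affinity tables — ``simple_tsv`` dialect with columns
  ``peptide  allele  assay  value_nm``, or an IEDB-export-like CSV dialect
  (``Description``, ``Allele Name``, ``Assay Group``,
  ``Quantitative measurement``);
* prediction tables — TSV with ``peptide  allele`` plus at least one of
  ``predicted_nm``, ``score``, ``rank_pct``; adapters unify every tool's
  orientation to the internal "higher score = stronger binding";
* pseudo-sequence tables — TSV ``allele  pseudo`` (34-mers);
* elution sets — TSV ``peptide  allele  label  dataset``;
* docking tables — TSV ``decoy_id  peptide  allele  reweighted_score`` and
  long-form RMSD pairs ``decoy_i  decoy_j  rmsd``;
* proteomes — FASTA;
* reports — tidy TSV plus a JSON bundle.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AffinityMeasurement,
    AlleleNameError,
    DomainError,
    normalize_allele_name,
    transform_affinity,
)
from .curation import RawRecord
from .elution import ElutionRecord
from .metrics import MetricReport, reports_to_frame
from .pan import PSEUDO_LENGTH
from .structure import PairwiseRMSD, StructureDecoy

__all__ = [
    "read_affinity_table",
    "write_affinity_table",
    "read_prediction_table",
    "read_pseudo_table",
    "load_packaged_pseudo_table",
    "read_elution_table",
    "write_elution_table",
    "read_fasta",
    "write_fasta",
    "read_decoy_scores",
    "read_rmsd_table",
    "write_reports",
]

_IEDB_COLUMNS = {
    "peptide": "Description",
    "allele": "Allele Name",
    "assay": "Assay Group",
    "value": "Quantitative measurement",
}


def read_affinity_table(
    path: str | Path, dialect: str = "simple_tsv"
) -> tuple[list[RawRecord], int]:
    """Parse an affinity table; returns raw records and a parse-failure count.

    Row-level problems (unparseable allele name, missing fields) are counted
    and skipped, never fatal; a missing mandatory column is fatal.  Values
    are kept verbatim (possibly qualitative) — curation decides their fate.
    """
    if dialect == "simple_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        colmap = {"peptide": "peptide", "allele": "allele", "assay": "assay",
                  "value": "value_nm"}
    elif dialect == "iedb_export":
        df = pd.read_csv(path, dtype=str)
        colmap = _IEDB_COLUMNS
    else:
        raise DomainError(f"unknown dialect {dialect!r}; use simple_tsv or iedb_export")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing mandatory column(s) {missing}")

    records: list[RawRecord] = []
    failures = 0
    for _, row in df.iterrows():
        try:
            allele = normalize_allele_name(str(row[colmap["allele"]]))
        except AlleleNameError:
            failures += 1
            continue
        peptide = str(row[colmap["peptide"]]).strip().upper()
        assay = str(row[colmap["assay"]]).strip()
        value = row[colmap["value"]]
        if not peptide or pd.isna(value):
            failures += 1
            continue
        records.append(RawRecord(peptide, allele, assay, value))
    return records, failures


def write_affinity_table(path: str | Path, measurements: Sequence[AffinityMeasurement]) -> None:
    pd.DataFrame(
        {
            "peptide": [m.peptide for m in measurements],
            "allele": [m.allele for m in measurements],
            "assay": [m.assay.value for m in measurements],
            "value_nm": [m.value_nm for m in measurements],
        }
    ).to_csv(path, sep="\t", index=False)


def read_prediction_table(
    path: str | Path,
    predictor: str,
    orientation: str = "affinity_nm",
) -> tuple[pd.DataFrame, int]:
    """Read one external tool's output and unify it to the internal convention.

    ``orientation`` declares what the tool emits:

    * ``affinity_nm`` — a ``predicted_nm`` column; the internal score is its
      normalised log transform (higher = stronger);
    * ``score_high`` — a ``score`` column where larger already means
      stronger; passed through unchanged;
    * ``score_low`` — a ``score`` column where smaller means stronger;
      negated on ingestion;
    * ``rank`` — a ``rank_pct`` column only (usable directly by the elution
      evaluator; the internal score is the negated rank).

    Rows with none of the three value fields are rejected and counted.
    Returns ``(frame, n_rejected)``; the frame has columns
    ``peptide allele predictor score`` plus ``predicted_nm``/``rank_pct``
    when available.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
    for col in ("peptide", "allele"):
        if col not in df.columns:
            raise DomainError(f"{path}: missing mandatory column {col!r}")
    present = [c for c in ("predicted_nm", "score", "rank_pct") if c in df.columns]
    if not present:
        raise DomainError(f"{path}: need at least one of predicted_nm/score/rank_pct")
    value_ok = df[present].notna().any(axis=1)
    n_rejected = int((~value_ok).sum())
    df = df.loc[value_ok].copy()
    df["allele"] = df["allele"].map(normalize_allele_name)
    df["predictor"] = predictor

    if orientation == "affinity_nm":
        if "predicted_nm" not in df.columns:
            raise DomainError("orientation affinity_nm requires a predicted_nm column")
        df["score"] = transform_affinity(df["predicted_nm"].astype(float).to_numpy())
    elif orientation == "score_high":
        if "score" not in df.columns:
            raise DomainError("orientation score_high requires a score column")
        df["score"] = df["score"].astype(float)
    elif orientation == "score_low":
        if "score" not in df.columns:
            raise DomainError("orientation score_low requires a score column")
        df["score"] = -df["score"].astype(float)
    elif orientation == "rank":
        if "rank_pct" not in df.columns:
            raise DomainError("orientation rank requires a rank_pct column")
        df["rank_pct"] = df["rank_pct"].astype(float)
        df["score"] = -df["rank_pct"]
    else:
        raise DomainError(f"unknown orientation {orientation!r}")
    keep = ["peptide", "allele", "predictor", "score"] + [
        c for c in ("predicted_nm", "rank_pct") if c in df.columns
    ]
    return df[keep].reset_index(drop=True), n_rejected


def read_pseudo_table(path: str | Path) -> dict[str, str]:
    """TSV ``allele  pseudo`` -> mapping with canonical allele names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"allele", "pseudo"} <= set(df.columns):
        raise DomainError(f"{path}: pseudo table needs columns 'allele' and 'pseudo'")
    table: dict[str, str] = {}
    for _, row in df.iterrows():
        pseudo = str(row["pseudo"]).strip().upper()
        if len(pseudo) != PSEUDO_LENGTH:
            raise DomainError(
                f"{path}: pseudo-sequence for {row['allele']} has length "
                f"{len(pseudo)}, expected {PSEUDO_LENGTH}"
            )
        table[normalize_allele_name(str(row["allele"]))] = pseudo
    return table


def load_packaged_pseudo_table() -> dict[str, str]:
    """The small packaged pseudo-sequence table.

    NOTE: this is a synthetic stand-in covering a handful of common class-I
    alleles so the examples run out of the box; it is NOT the reference
    binding-pocket table.  Supply your own table for real analyses.
    """
    ref = resources.files("mhcbench").joinpath("data/pseudo_sequences_synthetic.tsv")
    with resources.as_file(ref) as path:
        return read_pseudo_table(path)


def read_elution_table(path: str | Path) -> list[ElutionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"peptide", "allele", "label"}
    if need - set(df.columns):
        raise DomainError(f"{path}: elution table needs columns {sorted(need)}")
    return [
        ElutionRecord(
            str(r["peptide"]).upper(),
            normalize_allele_name(str(r["allele"])),
            str(r["label"]),
            str(r.get("dataset", "")) if "dataset" in df.columns else "",
        )
        for _, r in df.iterrows()
    ]


def write_elution_table(path: str | Path, records: Sequence[ElutionRecord]) -> None:
    pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "allele": [r.allele for r in records],
            "label": [r.label for r in records],
            "dataset": [r.dataset for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()),
        str(path),
        "fasta",
    )


def read_decoy_scores(path: str | Path) -> list[StructureDecoy]:
    df = pd.read_csv(path, sep="\t", dtype={"decoy_id": str, "peptide": str, "allele": str})
    need = {"decoy_id", "peptide", "allele", "reweighted_score"}
    if need - set(df.columns):
        raise DomainError(f"{path}: decoy table needs columns {sorted(need)}")
    return [
        StructureDecoy(r["decoy_id"], r["peptide"], r["allele"], float(r["reweighted_score"]))
        for _, r in df.iterrows()
    ]


def read_rmsd_table(path: str | Path) -> PairwiseRMSD:
    df = pd.read_csv(path, sep="\t", dtype={"decoy_i": str, "decoy_j": str})
    need = {"decoy_i", "decoy_j", "rmsd"}
    if need - set(df.columns):
        raise DomainError(f"{path}: RMSD table needs columns {sorted(need)}")
    return PairwiseRMSD.from_long_table(
        [(r["decoy_i"], r["decoy_j"], float(r["rmsd"])) for _, r in df.iterrows()]
    )


def write_reports(
    reports: Iterable[MetricReport],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    extra: dict | None = None,
) -> pd.DataFrame:
    """Write the tidy report table (TSV) and/or the JSON bundle."""
    frame = reports_to_frame(reports)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        bundle = {"reports": frame.where(pd.notna(frame), None).to_dict("records")}
        if extra:
            bundle.update(extra)
        Path(json_path).write_text(json.dumps(bundle, indent=1, default=float))
    return frame
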