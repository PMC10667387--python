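"""Readers/writers for the formats the toolkit touches.

FASTA via Biopython; primer tables as TSV; gel band observations as CSV;
verdict reports as JSON or TSV. All readers return plain domain objects or
pandas DataFrames and raise :class:`~tetrarms.errors.ParseError` on malformed
input.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, TableStructureError
from .model import (
    SEQUENCE_ALPHABET,
    DesignedMismatch,
    PrimerSpec,
    SampleVerdict,
    SequenceRecord,
    TetraPrimerAssay,
)

logger = logging.getLogger(__name__)

PRIMER_TABLE_COLUMNS = [
    "assay_id",
    "primer_name",
    "role",
    "orientation",
    "sequence",
    "mismatch_positions",
    "mismatch_types",
]
BAND_TABLE_COLUMNS = ["lane_id", "locus_id", "size_bp"]


def _offending_line(path: Path, bad_chars: set[str]) -> int | None:
    """Locate the first FASTA line containing one of ``bad_chars``."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return ln
    return None


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into uppercase :class:`SequenceRecord` objects.

    Order is preserved; mixed-case input is normalised to uppercase; an empty
    file or a non-IUPAC character is a :class:`ParseError` naming the line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}: line 1: not FASTA (expected '>')")
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            ln = _offending_line(path, bad)
            where = f"line {ln}" if ln else f"record {rec.id!r}"
            raise ParseError(
                f"{path}: {where}: illegal sequence character(s) {sorted(bad)}"
            )
        records.append(
            SequenceRecord(id=rec.id, seq=seq, description=rec.description)
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def _parse_mismatches(positions: str, types: str, row_name: str) -> list[DesignedMismatch]:
    positions = (positions or "").strip()
    types = (types or "").strip()
    if not positions and not types:
        return []
    pos_list = [p.strip() for p in positions.split(",") if p.strip()]
    type_list = [t.strip() for t in types.split(",") if t.strip()]
    if len(pos_list) != len(type_list):
        raise ParseError(
            f"primer {row_name!r}: mismatch_positions and mismatch_types "
            "have different lengths"
        )
    out = []
    for p, t in zip(pos_list, type_list):
        try:
            pos = int(p)
        except ValueError as exc:
            raise ParseError(
                f"primer {row_name!r}: bad mismatch position {p!r}"
            ) from exc
        pair = t.replace(".", "-").split("-")
        if len(pair) != 2 or not all(len(b) == 1 for b in pair):
            raise ParseError(f"primer {row_name!r}: bad mismatch type {t!r}")
        try:
            out.append(DesignedMismatch(pos, pair[0].upper(), pair[1].upper()))
        except ValueError as exc:
            raise ParseError(f"primer {row_name!r}: {exc}") from exc
    return out


def read_primer_table(path: str | Path) -> list[TetraPrimerAssay]:
    """Parse a TSV primer table into four-primer assays.

    Required columns: assay_id, primer_name, role, orientation, sequence,
    mismatch_positions, mismatch_types (positions counted from the 3' end,
    terminal base = 1; types written primer-template, e.g. ``C-A``).
    Optional columns: target_allele and per-assay product_o/product_a1/
    product_a2 sizes. Each assay must contain exactly the four
    role/orientation combinations.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in PRIMER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    assays: list[TetraPrimerAssay] = []
    for assay_id, group in df.groupby("assay_id", sort=False):
        if len(group) != 4:
            raise TableStructureError(
                f"{path}: assay {assay_id!r} has {len(group)} primers, expected 4"
            )
        primers = []
        sizes: dict[str, int | None] = {"product_o": None, "product_a1": None, "product_a2": None}
        for _, row in group.iterrows():
            try:
                primer = PrimerSpec(
                    name=row["primer_name"],
                    sequence=row["sequence"],
                    role=row["role"].strip().lower(),
                    orientation=row["orientation"].strip().lower(),
                    designed_mismatches=_parse_mismatches(
                        row["mismatch_positions"],
                        row["mismatch_types"],
                        row["primer_name"],
                    ),
                    target_allele=(row.get("target_allele") or "").strip() or None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
            if primer.role == "inner" and primer.target_allele is None:
                warnings.warn(
                    f"inner primer {primer.name!r} has no 3'-terminal allele "
                    f"annotation; inferring allele {primer.allele!r} from its "
                    "3' base",
                    stacklevel=2,
                )
            primers.append(primer)
            for col in sizes:
                if col in row.index and str(row[col]).strip():
                    sizes[col] = int(float(row[col]))
        try:
            assays.append(
                TetraPrimerAssay(
                    locus_id=str(assay_id),
                    primers=primers,
                    product_o=sizes["product_o"],
                    product_a1=sizes["product_a1"],
                    product_a2=sizes["product_a2"],
                )
            )
        except ValueError as exc:
            raise TableStructureError(f"{path}: {exc}") from exc
    if not assays:
        raise ParseError(f"{path}: primer table is empty")
    return assays


def write_primer_table(assays: Sequence[TetraPrimerAssay], path: str | Path) -> None:
    rows = []
    for assay in assays:
        sizes = {}
        try:
            s = assay.sizes()
            sizes = {"product_o": s["O"], "product_a1": s["A1"], "product_a2": s["A2"]}
        except Exception:
            sizes = {"product_o": "", "product_a1": "", "product_a2": ""}
        for p in assay.primers:
            rows.append(
                {
                    "assay_id": assay.locus_id,
                    "primer_name": p.name,
                    "role": p.role,
                    "orientation": p.orientation,
                    "sequence": p.sequence,
                    "mismatch_positions": ",".join(
                        str(m.pos_from_3prime) for m in p.designed_mismatches
                    ),
                    "mismatch_types": ",".join(
                        f"{m.primer_base}-{m.template_base}"
                        for m in p.designed_mismatches
                    ),
                    "target_allele": p.target_allele or (p.allele or ""),
                    **sizes,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Parse a gel band CSV into a typed, de-duplicated DataFrame.

    Required columns: lane_id, locus_id, size_bp (> 0). Optional:
    declared_label, declared_sex. Duplicate (lane, locus, size) rows are
    dropped with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in BAND_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    try:
        df["size_bp"] = df["size_bp"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric size_bp value: {exc}") from exc
    if (df["size_bp"] <= 0).any():
        bad = df.loc[df["size_bp"] <= 0, "size_bp"].iloc[0]
        raise ParseError(f"{path}: size_bp must be positive (found {bad})")
    if "declared_sex" in df.columns:
        badsex = set(df["declared_sex"]) - {"male", "female", "unknown", ""}
        if badsex:
            raise ParseError(f"{path}: bad declared_sex values {sorted(badsex)}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["lane_id", "locus_id", "size_bp"]).reset_index(
        drop=True
    )
    if len(df) < n0:
        warnings.warn(
            f"{path}: dropped {n0 - len(df)} duplicate band row(s)", stacklevel=2
        )
    return df


def write_band_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_report(
    verdicts: Sequence[SampleVerdict],
    path: str | Path,
    format: str = "json",
) -> None:
    """Serialise sample verdicts to JSON or TSV (round-trippable)."""
    if not verdicts:
        raise ValueError("cannot write a report for an empty verdict list")
    path = Path(path)
    dicts = [v.to_dict() for v in verdicts]
    if format == "json":
        with open(path, "w") as fh:
            json.dump({"verdicts": dicts}, fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        rows = []
        for d in dicts:
            row = dict(d)
            row["locus_calls"] = json.dumps(d["locus_calls"], sort_keys=True)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[SampleVerdict]:
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        out = []
        for _, row in df.iterrows():
            d = row.to_dict()
            d["locus_calls"] = json.loads(d["locus_calls"])
            d["concordant"] = d["concordant"] in ("True", "true", "1")
            for key in ("maternal_lineage", "declared_label"):
                d[key] = d.get(key) or None
            lc = d.get("label_concordance", "")
            d["label_concordance"] = (
                None if lc in ("", "None") else lc in ("True", "true", "1")
            )
            out.append(SampleVerdict.from_dict(d))
        return out
    with open(path) as fh:
        payload = json.load(fh)
    return [SampleVerdict.from_dict(d) for d in payload["verdicts"]]
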