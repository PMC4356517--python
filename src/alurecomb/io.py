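"""File-format plumbing: FASTA, cassette JSON/GFF3, truth/calls TSV.

TSV dialect: tab-separated, UTF-8, LF line endings, mandatory header,
``NA`` for absent values, floats at 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import JunctionCall
from .cassette import AluSequence, Feature, ReporterCassette
from .events import RepairEvent

TRUTH_COLUMNS = [
    "colony_id", "event_class", "crossover_interval", "patch_alleles",
    "left_bp", "right_bp", "deletion_size", "microhomology_len", "detectable",
]

CALLS_COLUMNS = [
    "colony_id", "event_class", "crossover_interval", "patch_alleles",
    "left_bp", "right_bp", "deletion_size", "microhomology_len",
    "genotype_vector", "segment_index", "topology", "breakpoint_ambiguity",
]


def read_fasta(path: str | Path) -> list[AluSequence]:
    return [AluSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as 60-column-wrapped FASTA."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_product_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Product records as (id, sequence); no length floor (NHEJ products vary)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def cassette_to_dict(cassette: ReporterCassette) -> dict:
    return {
        "features": [[f.name, f.start, f.end] for f in cassette.features],
        "sequence": cassette.sequence,
        "detectable_deletion_window": list(cassette.detectable_deletion_window),
    }


def cassette_from_dict(d: dict) -> ReporterCassette:
    return ReporterCassette(
        features=tuple(Feature(name, int(s), int(e)) for name, s, e in d["features"]),
        sequence=d["sequence"],
        detectable_deletion_window=tuple(d["detectable_deletion_window"]),
    )


def write_cassette_json(cassette: ReporterCassette, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cassette_to_dict(cassette), indent=2) + "\n")


def read_cassette_json(path: str | Path) -> ReporterCassette:
    return cassette_from_dict(json.loads(Path(path).read_text()))


def cassette_to_gff3(cassette: ReporterCassette, seqid: str = "reporter_cassette") -> str:
    """GFF3 text for the cassette features (1-based inclusive coordinates)."""
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {len(cassette.sequence)}"]
    for f in cassette.features:
        lines.append(
            "\t".join(
                [seqid, "alurecomb", "region", str(f.start + 1), str(f.end), ".", "+", ".",
                 f"ID={f.name};Name={f.name}"]
            )
        )
    return "\n".join(lines) + "\n"


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _alleles_str(alleles) -> str:
    if alleles is None:
        return "NA"
    return ",".join(str(a) for a in alleles)


def _alleles_parse(text: str):
    if text in ("NA", "", None):
        return None
    return tuple(int(x) for x in str(text).split(","))


def events_to_table(events: Sequence[RepairEvent]) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(events):
        rows.append({
            "colony_id": f"colony_{i + 1:05d}",
            "event_class": e.event_class,
            "crossover_interval": _fmt(e.crossover_interval),
            "patch_alleles": _alleles_str(e.patch_alleles),
            "left_bp": e.left_breakpoint,
            "right_bp": e.right_breakpoint,
            "deletion_size": e.deletion_size,
            "microhomology_len": e.microhomology_len,
            "detectable": e.detectable,
        })
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def calls_to_table(calls: Sequence[JunctionCall], ids: Sequence[str] | None = None) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(calls):
        rows.append({
            "colony_id": ids[i] if ids is not None else f"colony_{i + 1:05d}",
            "event_class": c.event_class,
            "crossover_interval": _fmt(c.crossover_interval),
            "patch_alleles": _alleles_str(c.patch_alleles),
            "left_bp": _fmt(c.left_breakpoint),
            "right_bp": _fmt(c.right_breakpoint),
            "deletion_size": _fmt(c.deletion_size),
            "microhomology_len": _fmt(c.microhomology_len),
            "genotype_vector": _alleles_str(c.genotype_vector),
            "segment_index": _fmt(c.segment_index),
            "topology": _fmt(c.topology),
            "breakpoint_ambiguity": _fmt(c.breakpoint_ambiguity),
        })
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def calls_from_table(df: pd.DataFrame) -> list[JunctionCall]:
    """Rebuild junction calls from a calls TSV (schema-checked)."""
    missing = set(CALLS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calls table is missing columns: {sorted(missing)}")

    def _opt_int(v):
        return None if pd.isna(v) else int(v)

    calls = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(JunctionCall(
                event_class=row.event_class,
                crossover_interval=_opt_int(row.crossover_interval),
                patch_alleles=_alleles_parse(row.patch_alleles) if not pd.isna(row.patch_alleles) else None,
                left_breakpoint=_opt_int(row.left_bp),
                right_breakpoint=_opt_int(row.right_bp),
                deletion_size=_opt_int(row.deletion_size),
                microhomology_len=_opt_int(row.microhomology_len),
                genotype_vector=_alleles_parse(row.genotype_vector) if not pd.isna(row.genotype_vector) else None,
                segment_index=_opt_int(row.segment_index),
                topology=None if pd.isna(row.topology) else str(row.topology),
                breakpoint_ambiguity=_opt_int(row.breakpoint_ambiguity),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"calls table row {row_num}: {exc}") from exc
    return calls


def products_from_events(events: Sequence[RepairEvent]) -> list[tuple[str, str]]:
    return [(f"colony_{i + 1:05d}", e.product_sequence) for i, e in enumerate(events)]
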