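"""Readers and writers for every table the pipeline touches.

Input dialects: BLAST/DIAMOND tabular ("outfmt 6", 12 columns) and a minimal
3-column hit TSV; BED or 1-based closed TSV gene order; two-column TSV maps.
Parsing is line-by-line so every malformed record is reported with its line
number.  Writers emit a fixed column order and sort rows canonically, so
identical inputs always produce byte-identical files.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Iterator
from contextlib import contextmanager
from typing import IO

from .model import (
    BlockMap,
    ConsensusResult,
    GeneOrder,
    HitRecord,
    HubMembership,
    Locus,
    OrthologCall,
    PangenomeCall,
    SyntenyCall,
)

#: Column order of the final ortholog table.
ORTHOLOG_COLUMNS = (
    "query_id",
    "final_reference_id",
    "method",
    "syntenic_flag",
    "consensus_block",
    "synteny_candidate",
    "pangenome_candidate",
    "bbh_candidate",
)

_MISSING = "."


class FormatError(ValueError):
    """A malformed line in an input table, reported with file and line."""


@contextmanager
def _as_lines(source) -> Iterator[tuple[str, IO[str]]]:
    if hasattr(source, "read"):
        yield getattr(source, "name", "<stream>"), source
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            yield str(source), fh


def _data_lines(name: str, fh: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def _parse_float(name: str, lineno: int, field: str, what: str) -> float:
    try:
        return float(field)
    except ValueError:
        raise FormatError(
            f"{name} line {lineno}: non-numeric {what} {field!r}"
        ) from None


def _parse_int(name: str, lineno: int, field: str, what: str) -> int:
    try:
        return int(field)
    except ValueError:
        raise FormatError(
            f"{name} line {lineno}: non-integer {what} {field!r}"
        ) from None


def read_hit_table(
    source,
    dialect: str = "outfmt6",
    collapse: str = "max",
) -> list[HitRecord]:
    """Read a tabular hit table into HSP-collapsed :class:`HitRecord`\\ s.

    Parameters
    ----------
    dialect
        ``outfmt6`` — the standard 12-column BLAST/DIAMOND tabular layout
        (bitscore in column 12); ``minimal`` — 3 columns
        (query, subject, bitscore).
    collapse
        How to aggregate multiple HSP rows for one (query, subject) pair:
        ``max`` keeps the best-scoring HSP (default), ``sum`` adds the
        scores.

    Returns records sorted by (query_id, subject_id), so the result does not
    depend on the input row order.
    """
    if dialect not in ("outfmt6", "minimal"):
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    if collapse not in ("max", "sum"):
        raise ValueError(f"unknown HSP collapse mode {collapse!r}")
    ncol = 12 if dialect == "outfmt6" else 3

    best: dict[tuple[str, str], HitRecord] = {}
    totals: dict[tuple[str, str], float] = {}
    n_lines = 0
    with _as_lines(source) as (name, fh):
        for lineno, fields in _data_lines(name, fh):
            if len(fields) != ncol:
                raise FormatError(
                    f"{name} line {lineno}: expected {ncol} tab-separated "
                    f"columns for dialect {dialect!r}, got {len(fields)}"
                )
            n_lines += 1
            if dialect == "outfmt6":
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    bitscore=_parse_float(name, lineno, fields[11], "bitscore"),
                    percent_identity=_parse_float(
                        name, lineno, fields[2], "percent identity"
                    ),
                    align_length=_parse_int(
                        name, lineno, fields[3], "alignment length"
                    ),
                )
            else:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    bitscore=_parse_float(name, lineno, fields[2], "bitscore"),
                )
            key = (rec.query_id, rec.subject_id)
            totals[key] = totals.get(key, 0.0) + rec.bitscore
            cur = best.get(key)
            if cur is None or rec.bitscore > cur.bitscore:
                best[key] = rec
        if n_lines == 0:
            warnings.warn(f"hit table {name} contains no data lines", stacklevel=2)

    out = []
    for key in sorted(best):
        rec = best[key]
        if collapse == "sum":
            rec = HitRecord(
                rec.query_id,
                rec.subject_id,
                totals[key],
                rec.percent_identity,
                rec.align_length,
            )
        out.append(rec)
    return out


def write_hit_table(hits: Iterable[HitRecord], destination) -> None:
    """Write hits in the minimal 3-column dialect, canonically sorted."""
    rows = sorted(hits, key=lambda h: (h.query_id, h.subject_id))
    with open(destination, "wt", encoding="utf-8", newline="\n") as fh:
        for h in rows:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.bitscore!r}\n")


def read_gene_order(source, fmt: str = "tsv") -> GeneOrder:
    """Read gene positions into a :class:`GeneOrder`.

    ``bed`` is 0-based half-open (chrom, start, end, gene[, score[, strand]]).
    ``tsv`` is 1-based closed (gene, chrom, start, end[, strand]) and is
    converted to 0-based half-open on read.
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"unknown gene-order format {fmt!r}")
    entries: list[Locus] = []
    with _as_lines(source) as (name, fh):
        for lineno, fields in _data_lines(name, fh):
            if fmt == "bed":
                if len(fields) < 4:
                    raise FormatError(
                        f"{name} line {lineno}: BED needs >= 4 columns, "
                        f"got {len(fields)}"
                    )
                chrom, start_s, end_s, gene = fields[:4]
                strand = fields[5] if len(fields) >= 6 else "."
                start = _parse_int(name, lineno, start_s, "start")
                end = _parse_int(name, lineno, end_s, "end")
            else:
                if len(fields) not in (4, 5):
                    raise FormatError(
                        f"{name} line {lineno}: gene-order TSV needs 4 or 5 "
                        f"columns (gene, chrom, start, end[, strand]), "
                        f"got {len(fields)}"
                    )
                gene, chrom = fields[0], fields[1]
                start1 = _parse_int(name, lineno, fields[2], "start")
                end1 = _parse_int(name, lineno, fields[3], "end")
                if start1 < 1:
                    raise FormatError(
                        f"{name} line {lineno}: 1-based start must be >= 1"
                    )
                start, end = start1 - 1, end1
                strand = fields[4] if len(fields) == 5 else "."
            if strand not in ("+", "-"):
                strand = "."
            entries.append(Locus(gene, chrom, start, end, strand))
    return GeneOrder(entries)


def _read_two_columns(source, what: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with _as_lines(source) as (name, fh):
        for lineno, fields in _data_lines(name, fh):
            if len(fields) < 2:
                raise FormatError(
                    f"{name} line {lineno}: {what} needs 2 columns, "
                    f"got {len(fields)}"
                )
            key, value = fields[0], fields[1]
            if key in mapping and mapping[key] != value:
                raise FormatError(
                    f"{name} line {lineno}: conflicting {what} entries for "
                    f"{key!r} ({mapping[key]!r} vs {value!r})"
                )
            mapping[key] = value
    return mapping


def read_block_map(source) -> BlockMap:
    """Read a two-column (reference gene, block label) TSV."""
    return BlockMap(_read_two_columns(source, "block map"))


def read_hub_membership(source) -> HubMembership:
    """Read a two-column (accession gene, hub id) TSV."""
    return HubMembership(_read_two_columns(source, "hub membership"))


def _fmt(value) -> str:
    if value is None:
        return _MISSING
    return str(value)


def _unfmt(field: str) -> str | None:
    return None if field == _MISSING else field


def _write_rows(destination, header: tuple[str, ...], rows: Iterable[tuple]) -> None:
    with open(destination, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_ortholog_table(calls: Iterable[OrthologCall], destination) -> None:
    """Write final ortholog calls as a fixed-order TSV, sorted by query id."""
    rows = sorted(calls, key=lambda c: c.query_id)
    _write_rows(
        destination,
        ORTHOLOG_COLUMNS,
        (
            (
                c.query_id,
                c.reference_id,
                c.method,
                c.syntenic_flag,
                c.consensus_block,
                c.synteny_candidate,
                c.pangenome_candidate,
                c.bbh_candidate,
            )
            for c in rows
        ),
    )


def read_ortholog_table(source) -> list[OrthologCall]:
    calls = []
    with _as_lines(source) as (name, fh):
        for lineno, fields in _data_lines(name, fh):
            if fields[0] == ORTHOLOG_COLUMNS[0]:
                continue
            if len(fields) != len(ORTHOLOG_COLUMNS):
                raise FormatError(
                    f"{name} line {lineno}: expected "
                    f"{len(ORTHOLOG_COLUMNS)} columns, got {len(fields)}"
                )
            calls.append(
                OrthologCall(
                    query_id=fields[0],
                    reference_id=_unfmt(fields[1]),
                    method=fields[2],
                    syntenic_flag=fields[3],
                    consensus_block=_unfmt(fields[4]),
                    synteny_candidate=_unfmt(fields[5]),
                    pangenome_candidate=_unfmt(fields[6]),
                    bbh_candidate=_unfmt(fields[7]),
                )
            )
    return calls


def write_bbh_table(pairs: Iterable[tuple[str, str]], destination) -> None:
    _write_rows(destination, ("query_id", "reference_id"), sorted(pairs))


def read_bbh_table(source) -> set[tuple[str, str]]:
    pairs = set()
    with _as_lines(source) as (name, fh):
        for lineno, fields in _data_lines(name, fh):
            if fields[0] == "query_id":
                continue
            if len(fields) != 2:
                raise FormatError(
                    f"{name} line {lineno}: expected 2 columns, got {len(fields)}"
                )
            pairs.add((fields[0], fields[1]))
    return pairs


def write_synteny_table(calls: Iterable[SyntenyCall], destination) -> None:
    rows = sorted(calls, key=lambda c: c.query_id)
    _write_rows(
        destination,
        ("query_id", "reference_id", "corrected", "consensus_block", "flag"),
        (
            (c.query_id, c.reference_id, int(c.corrected), c.consensus, c.flag)
            for c in rows
        ),
    )


def read_synteny_table(source) -> dict[str, SyntenyCall]:
    calls: dict[str, SyntenyCall] = {}
    with _as_lines(source) as (name, fh):
        for lineno, fields in _data_lines(name, fh):
            if fields[0] == "query_id":
                continue
            if len(fields) != 5:
                raise FormatError(
                    f"{name} line {lineno}: expected 5 columns, got {len(fields)}"
                )
            calls[fields[0]] = SyntenyCall(
                query_id=fields[0],
                reference_id=_unfmt(fields[1]),
                corrected=bool(int(fields[2])),
                consensus=_unfmt(fields[3]),
                flag=fields[4],
            )
    return calls


def write_pangenome_table(calls: Iterable[PangenomeCall], destination) -> None:
    rows = sorted(calls, key=lambda c: c.query_id)
    _write_rows(
        destination,
        ("query_id", "representative", "co_orthologs"),
        (
            (c.query_id, c.representative, ",".join(c.co_orthologs) or None)
            for c in rows
        ),
    )


def read_pangenome_table(source) -> dict[str, PangenomeCall]:
    calls: dict[str, PangenomeCall] = {}
    with _as_lines(source) as (name, fh):
        for lineno, fields in _data_lines(name, fh):
            if fields[0] == "query_id":
                continue
            if len(fields) != 3:
                raise FormatError(
                    f"{name} line {lineno}: expected 3 columns, got {len(fields)}"
                )
            co = fields[2]
            calls[fields[0]] = PangenomeCall(
                query_id=fields[0],
                representative=_unfmt(fields[1]),
                co_orthologs=tuple(co.split(",")) if co != _MISSING else (),
            )
    return calls


def write_consensus_diagnostics(
    order: GeneOrder,
    results: dict[str, ConsensusResult],
    initial_blocks: dict[str, str],
    destination,
) -> None:
    """Per-gene diagnostics: ordinal, initial and consensus blocks, and the
    top-3 decayed block sums at each locus."""
    rows = []
    for loc in order:
        res = results.get(loc.gene_id)
        if res is None:
            continue
        chrom, ordinal = order.ordinal(loc.gene_id)
        top = sorted(res.sums.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
        rows.append(
            (
                loc.gene_id,
                chrom,
                ordinal,
                initial_blocks.get(loc.gene_id),
                res.consensus,
                ";".join(f"{b}={s:.3f}" for b, s in top) or None,
                res.flag,
            )
        )
    _write_rows(
        destination,
        (
            "gene_id",
            "chrom",
            "ordinal",
            "initial_block",
            "consensus_block",
            "top_block_sums",
            "flag",
        ),
        rows,
    )
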