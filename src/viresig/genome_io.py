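"""Genome description tables: VMR-style CSV parsing, FASTA attachment,
multipartite assembly and taxonomic filtering.

A run starts from a table of genome metadata (one row per virus, in the
style of the ICTV Virus Metadata Resource) plus nucleotide sequences in
FASTA. Multipartite (segmented) genomes are concatenated largest segment
first into a single working sequence; segment boundaries are retained so
downstream ORF calling never reads across a concatenation junction.
All coordinates in the package are 0-based, half-open, on this assembled
sequence.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical taxonomy ranks, highest to lowest. Missing ranks are allowed.
CANONICAL_RANKS = (
    "realm",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "subfamily",
    "genus",
    "species",
)

_VALID_NT = set("ACGTN")


class ConfigurationError(ValueError):
    """A run option or input table does not satisfy its contract."""


class EmptyInputError(ValueError):
    """An input file or table contained no usable records."""


class LookupError_(KeyError):
    """A referenced accession could not be resolved."""


@dataclass
class GenomeRecord:
    """One (possibly multipartite) genome plus its taxonomy metadata.

    ``sequence`` is the assembled nucleotide string over {A,C,G,T,N};
    ``segment_boundaries`` are half-open intervals tiling it, ordered by
    decreasing segment length (assembly order).
    """

    id: str
    accessions: list[str]
    name: str = ""
    taxonomy: dict[str, str] = field(default_factory=dict)
    sequence: str = ""
    segment_boundaries: list[tuple[int, int]] = field(default_factory=list)
    is_reference: bool = True
    provisional: bool = False

    def __post_init__(self) -> None:
        self.taxonomy = {
            r: self.taxonomy[r] for r in CANONICAL_RANKS if self.taxonomy.get(r)
        }

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeTable:
    """Ordered collection of :class:`GenomeRecord` with unique ids."""

    records: list[GenomeRecord]
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate genome ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, genome_id: str) -> GenomeRecord:
        for r in self.records:
            if r.id == genome_id:
                return r
        raise KeyError(genome_id)


# ---------------------------------------------------------------------------
# CSV parsing


def _resolve_columns(columns, column_map):
    """Map logical field names to CSV headers (case-insensitive heuristics)."""
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, str] = {}
    column_map = dict(column_map or {})
    for logical, header in column_map.items():
        if header not in columns:
            raise ConfigurationError(
                f"column_map points '{logical}' at missing column {header!r}"
            )
        resolved[logical] = header
    if "accessions" not in resolved:
        for key, orig in lower.items():
            if "accession" in key:
                resolved["accessions"] = orig
                break
    if "name" not in resolved:
        for cand in ("virus name", "name", "virus"):
            if cand in lower:
                resolved["name"] = lower[cand]
                break
    for rank in CANONICAL_RANKS:
        if rank not in resolved and rank in lower:
            resolved[rank] = lower[rank]
    if "id" not in resolved and "id" in lower:
        resolved["id"] = lower["id"]
    return resolved


def parse_vmr(
    path,
    column_map: dict[str, str] | None = None,
    accession_delimiter: str = ";",
    source_label: str | None = None,
) -> GenomeTable:
    """Parse a VMR-style CSV into a :class:`GenomeTable` (sequences unattached).

    Required columns: an accession column, a virus-name column and at least
    one canonical taxonomy rank; resolved case-insensitively or explicitly
    through ``column_map`` ({logical_name: csv_header}, logical names being
    ``accessions``, ``name``, ``id`` and the canonical ranks). Cells listing
    several accessions are split on ``accession_delimiter``.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if df.empty:
        raise EmptyInputError(f"no rows in {path}")
    cols = _resolve_columns(df.columns, column_map)
    if "accessions" not in cols:
        raise ConfigurationError("no accession column found (expected header "
                                 "containing 'accession' or a column_map entry)")
    if "name" not in cols:
        raise ConfigurationError("no virus-name column found")
    if not any(r in cols for r in CANONICAL_RANKS):
        raise ConfigurationError("no taxonomy rank column found")

    records = []
    for idx, row in df.iterrows():
        accs = [a.strip() for a in str(row[cols["accessions"]]).split(accession_delimiter)]
        accs = [a for a in accs if a]
        if not accs:
            raise ConfigurationError(f"row {idx}: empty accession cell")
        taxonomy = {r: str(row[cols[r]]).strip() for r in CANONICAL_RANKS if r in cols}
        gid = str(row[cols["id"]]).strip() if "id" in cols else accs[0]
        is_ref = True
        prov = False
        if "is_reference" in df.columns:
            is_ref = str(row["is_reference"]).strip().lower() not in ("false", "0", "no")
        if "provisional" in df.columns:
            prov = str(row["provisional"]).strip().lower() in ("true", "1", "yes")
        records.append(
            GenomeRecord(
                id=gid,
                accessions=accs,
                name=str(row[cols["name"]]).strip(),
                taxonomy=taxonomy,
                is_reference=is_ref,
                provisional=prov,
            )
        )
    return GenomeTable(records, source_label=source_label or str(path))


def write_vmr(table: GenomeTable, path, accession_delimiter: str = ";") -> None:
    """Write a GenomeTable back to the CSV dialect :func:`parse_vmr` reads."""
    rows = []
    for r in table:
        row = {
            "id": r.id,
            "accession": accession_delimiter.join(r.accessions),
            "virus name": r.name,
        }
        for rank in CANONICAL_RANKS:
            row[rank] = r.taxonomy.get(rank, "")
        row["is_reference"] = str(r.is_reference)
        row["provisional"] = str(r.provisional)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sequence attachment / assembly


def normalize_nt(seq: str) -> str:
    """Upper-case, U->T; IUPAC ambiguity codes other than N become N."""
    s = seq.upper().replace("U", "T")
    if not set(s) <= _VALID_NT:
        bad = sorted(set(s) - _VALID_NT)
        warnings.warn(f"ambiguity codes {bad} mapped to N")
        s = "".join(c if c in _VALID_NT else "N" for c in s)
    return s


def assembly_order(segments: list[str], accessions: list[str]) -> list[int]:
    """Indices of segments in assembly order: largest first, ties by accession."""
    return sorted(range(len(segments)), key=lambda i: (-len(segments[i]), accessions[i]))


def assemble_multipartite(
    segments: list[str], accessions: list[str] | None = None
) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate genome segments largest-to-smallest.

    Equal-length segments are ordered by the lexicographic order of their
    accessions (or of the sequences themselves when no accessions are given).
    Returns the assembled sequence and half-open segment boundaries.
    """
    if not segments:
        raise EmptyInputError("no segments to assemble")
    if any(len(s) == 0 for s in segments):
        raise EmptyInputError("empty segment in assembly")
    if accessions is None:
        accessions = list(segments)
    order = assembly_order(segments, accessions)
    seq_parts = [segments[i] for i in order]
    boundaries = []
    pos = 0
    for part in seq_parts:
        boundaries.append((pos, pos + len(part)))
        pos += len(part)
    return "".join(seq_parts), boundaries


def attach_sequences(table: GenomeTable, fasta_paths) -> GenomeTable:
    """Resolve every record's accessions against FASTA file(s) and assemble.

    Every accession must occur exactly once across the given FASTA files.
    Sequences are normalised (upper case, U->T, non-N ambiguity -> N) and
    multipartite records assembled via :func:`assemble_multipartite`.
    """
    if not isinstance(fasta_paths, (list, tuple)):
        fasta_paths = [fasta_paths]
    seqs: dict[str, str] = {}
    for path in fasta_paths:
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in seqs:
                raise ConfigurationError(f"duplicate FASTA id {rec.id!r}")
            seqs[rec.id] = normalize_nt(str(rec.seq))
    missing = sorted(
        {a for r in table for a in r.accessions if a not in seqs}
    )
    if missing:
        raise LookupError_(f"accessions absent from FASTA: {missing}")
    out = []
    for r in table:
        segs = [seqs[a] for a in r.accessions]
        seq, bounds = assemble_multipartite(segs, r.accessions)
        # store accessions in assembled order so accessions[i] spans bounds[i]
        order = assembly_order(segs, r.accessions)
        accs = [r.accessions[i] for i in order]
        out.append(replace(r, accessions=accs, sequence=seq, segment_boundaries=bounds))
    return GenomeTable(out, source_label=table.source_label)


# ---------------------------------------------------------------------------
# Filtering / representative selection


def _check_ranks(constraints):
    for rank in constraints or {}:
        if rank not in CANONICAL_RANKS:
            raise ConfigurationError(
                f"unknown taxonomy rank {rank!r}; canonical ranks: {CANONICAL_RANKS}"
            )


def filter_vmr(
    table: GenomeTable,
    include: dict[str, str] | None = None,
    exclude: dict[str, str] | None = None,
) -> GenomeTable:
    """Keep records matching all ``include`` and no ``exclude`` constraints.

    Constraints map canonical rank names to required/forbidden taxon names;
    record order is preserved. Empty constraints are the identity.
    """
    _check_ranks(include)
    _check_ranks(exclude)
    include = include or {}
    exclude = exclude or {}
    kept = [
        r
        for r in table
        if all(r.taxonomy.get(k) == v for k, v in include.items())
        and not any(r.taxonomy.get(k) == v for k, v in exclude.items())
    ]
    return GenomeTable(kept, source_label=table.source_label)


def select_representatives(table: GenomeTable, rank: str) -> GenomeTable:
    """One reference genome per distinct taxon at ``rank``.

    The pick is deterministic: the member with the lexicographically
    smallest id represents its taxon. Non-reference (query) records are
    passed through untouched.
    """
    if rank not in CANONICAL_RANKS:
        raise ConfigurationError(f"unknown taxonomy rank {rank!r}")
    refs = [r for r in table if r.is_reference]
    missing = [r.id for r in refs if not r.taxonomy.get(rank)]
    if missing:
        raise ConfigurationError(f"rank {rank!r} missing for records: {missing}")
    best: dict[str, GenomeRecord] = {}
    for r in refs:
        taxon = r.taxonomy[rank]
        if taxon not in best or r.id < best[taxon].id:
            best[taxon] = r
    chosen_ids = {r.id for r in best.values()}
    kept = [r for r in table if not r.is_reference or r.id in chosen_ids]
    return GenomeTable(kept, source_label=table.source_label)


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    """Write id->sequence pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
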