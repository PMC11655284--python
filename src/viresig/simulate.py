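"""Synthetic viral genome sets with planted taxonomy.

Each planted family is defined by a repertoire of seed proteins laid out in
conserved order and strand; genomes of a family carry point-diverged copies
of those proteins, back-translated with per-genome synonymous codon choice
and separated by family-fixed, stop-rich intergenic junctions so that ORFs
never fuse across genes. Point divergence is applied at the amino-acid
level before back-translation, which guarantees the planted ORFs stay
intact at any substitution rate (nucleotide-level mutation would scatter
premature stop codons through the genes). Families may share a small number
of "hallmark" genes; each family is split into two genera whose members
derive from slightly diverged copies of the family seeds.

Optional truncation drops a suffix of selected genomes, emulating
non-coding-complete database records; truncated genomes lose their tail
ORFs and show missing trailing profiles in the barcode output.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeRecord,
    GenomeTable,
    assemble_multipartite,
    assembly_order,
    write_fasta,
    write_vmr,
)
from .profiles import AA

#: Palindromic cassette containing a stop codon in all three frames of both
#: strands; placed in every intergenic junction.
STOP_CASSETTE = "TAAATAAATAAATTTATTTATTTA"

_CODONS: dict[str, list[str]] = {}


def _codon_choices() -> dict[str, list[str]]:
    if not _CODONS:
        from .orfs import _codon_map

        for codon, aa in _codon_map(1).items():
            if aa != "*":
                _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-taxonomy genome set. ``seed`` is mandatory."""

    seed: int
    n_families: int = 4
    genomes_per_family: int = 6
    genes_per_family: int = 5
    shared_genes: int = 1
    gene_length_range: tuple[int, int] = (150, 400)
    substitution_rate: float = 0.05
    n_segments: int = 1
    truncated_fraction: float = 0.0
    truncation_fraction: float = 0.4

    def validate(self) -> None:
        if self.n_families < 1 or self.genomes_per_family < 1 or self.genes_per_family < 1:
            raise ValueError("counts must be >= 1")
        if self.shared_genes < 0:
            raise ValueError("shared_genes must be >= 0")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must lie in [0, 1)")
        if not (0 <= self.truncated_fraction < 1) or not (0 < self.truncation_fraction < 1):
            raise ValueError("truncation fractions must lie in (0, 1)")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid gene length range")
        if self.n_segments < 1 or self.n_segments > self.genes_per_family + self.shared_genes:
            raise ValueError("n_segments must be in [1, total genes]")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return protein
    chars = list(protein)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        alternatives = [a for a in AA if a != chars[i]]
        chars[i] = alternatives[rng.integers(0, 19)]
    return "".join(chars)


def _back_translate(protein: str, codon_draw: np.ndarray) -> str:
    """Back-translate using a fixed per-position synonymous-codon draw.

    ``codon_draw`` is drawn once per family gene slot so that, at
    substitution rate 0, all members of a family share identical
    nucleotide sequences (and hence identical spurious alternate-frame
    ORFs); mutated positions still pick a synonymous codon pseudo-randomly.
    """
    choices = _codon_choices()
    return "".join(
        choices[aa][codon_draw[i] % len(choices[aa])] for i, aa in enumerate(protein)
    )


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_genomes(spec: FixtureSpec) -> tuple[GenomeTable, pd.DataFrame, dict[str, str]]:
    """Generate the genome table, truth labels and FASTA sequences.

    Returns ``(table, truth, fasta)`` where ``truth`` has columns
    genome_id, family, genus, species, truncated, and ``fasta`` maps
    accession -> nucleotide segment sequence (truncation already applied),
    so attaching ``fasta`` to the metadata reproduces the table exactly.
    Deterministic for a given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range

    shared_seeds = [
        _random_protein(rng, int(rng.integers(lo, hi + 1))) for _ in range(spec.shared_genes)
    ]
    records: list[GenomeRecord] = []
    truth_rows = []
    for f in range(spec.n_families):
        family = f"Fam{f + 1:02d}"
        core_seeds = [
            _random_protein(rng, int(rng.integers(lo, hi + 1)))
            for _ in range(spec.genes_per_family)
        ]
        genes = shared_seeds + core_seeds
        strands = ["+" if rng.random() < 0.75 else "-" for _ in genes]
        codon_draws = [rng.integers(0, 64, size=len(g)) for g in genes]
        # family-fixed junctions keep coordinates identical across the
        # family at substitution rate 0
        junctions = [
            _random_nt(rng, int(rng.integers(10, 41)))
            + STOP_CASSETTE
            + _random_nt(rng, int(rng.integers(10, 41)))
            for _ in range(len(genes) + 1)
        ]
        # two genera per family: genus B descends from diverged seed copies
        genus_seeds = {
            "a": genes,
            "b": [_mutate_protein(g, spec.substitution_rate, rng) for g in genes],
        }
        seg_bounds = np.array_split(np.arange(len(genes)), spec.n_segments)
        for v in range(spec.genomes_per_family):
            genus_key = "a" if v < (spec.genomes_per_family + 1) // 2 else "b"
            gid = f"F{f + 1:02d}V{v + 1:02d}"
            seeds = genus_seeds[genus_key]
            segments = []
            for idxs in seg_bounds:
                parts = [junctions[idxs[0]]]
                for gi in idxs:
                    protein = _mutate_protein(seeds[gi], spec.substitution_rate, rng)
                    nt = _back_translate(protein, codon_draws[gi])
                    if strands[gi] == "-":
                        from .orfs import reverse_complement

                        nt = reverse_complement(nt)
                    parts.append(nt)
                    parts.append(junctions[gi + 1])
                segments.append("".join(parts))
            accessions = [
                gid if spec.n_segments == 1 else f"{gid}.seg{si + 1}"
                for si in range(spec.n_segments)
            ]
            seq, bounds = assemble_multipartite(segments, accessions)
            order = assembly_order(segments, accessions)
            accessions = [accessions[i] for i in order]
            genus = f"{family}-{genus_key.upper()}"
            records.append(
                GenomeRecord(
                    id=gid,
                    accessions=accessions,
                    name=f"Synthetic virus {gid}",
                    taxonomy={
                        "family": family,
                        "genus": genus,
                        "species": f"{family.lower()} virus {v + 1}",
                    },
                    sequence=seq,
                    segment_boundaries=bounds,
                )
            )
            truth_rows.append(
                {
                    "genome_id": gid,
                    "family": family,
                    "genus": genus,
                    "species": f"{family.lower()} virus {v + 1}",
                    "truncated": False,
                }
            )
    table = GenomeTable(records, source_label=f"fixture(seed={spec.seed})")
    truth = pd.DataFrame(truth_rows)
    if spec.truncated_fraction > 0:
        table, truncated_ids = inject_incomplete(
            table, spec.truncated_fraction, spec.truncation_fraction, spec.seed + 1
        )
        truth.loc[truth.genome_id.isin(truncated_ids), "truncated"] = True
    fasta = {
        acc: rec.sequence[s:e]
        for rec in table
        for acc, (s, e) in zip(rec.accessions, rec.segment_boundaries)
    }
    return table, truth, fasta


def inject_incomplete(
    table: GenomeTable, fraction: float, trunc_frac: float, seed: int
) -> tuple[GenomeTable, list[str]]:
    """Truncate a random subset of genomes to emulate incomplete records.

    ``fraction`` of the genomes lose their trailing ``trunc_frac`` of
    assembled sequence. Returns the modified table and the truncated ids.
    """
    if not (0 < fraction < 1) or not (0 < trunc_frac < 1):
        raise ValueError("fraction and trunc_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = max(1, round(fraction * len(table)))
    ids = sorted(r.id for r in table)
    chosen = set(rng.choice(ids, size=n, replace=False))
    out = []
    for rec in table:
        if rec.id not in chosen:
            out.append(rec)
            continue
        keep = int(len(rec.sequence) * (1 - trunc_frac))
        bounds = [(s, min(e, keep)) for s, e in rec.segment_boundaries if s < keep] or [
            (0, keep)
        ]
        accs = rec.accessions[: len(bounds)] if rec.segment_boundaries else rec.accessions
        out.append(
            replace(rec, accessions=accs, sequence=rec.sequence[:keep], segment_boundaries=bounds)
        )
    return GenomeTable(out, source_label=table.source_label), sorted(chosen)


def write_fixture(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Emit the fixture as VMR-style CSV + FASTA + truth CSV under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth, fasta = simulate_genomes(spec)
    paths = {
        "vmr": str(outdir / "vmr.csv"),
        "fasta": str(outdir / "genomes.fasta"),
        "truth": str(outdir / "truth.csv"),
    }
    write_vmr(table, paths["vmr"])
    write_fasta(fasta, paths["fasta"])
    truth.to_csv(paths["truth"], index=False)
    return paths
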