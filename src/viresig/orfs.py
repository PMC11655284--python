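"""Six-frame ORF detection and translation.

ORFs are maximal stop-to-stop stretches (sequence/segment ends also act as
delimiters) rather than ATG-anchored genes: viral genomes use a variety of
non-AUG initiation and re-initiation mechanisms, and the downstream profile
comparisons only need the translated coding stretch, not the true start.
ORFs never span a segment-concatenation junction, and reverse-strand ORFs
are reported in forward-strand coordinates on the assembled genome.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .genome_io import ConfigurationError, GenomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ORF:
    """A called open reading frame.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of the assembled genome and exclude the stop codon;
    ``frame`` is the reading frame (0-2) on the ORF's own strand.
    """

    genome_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int
    protein: str

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def __len__(self) -> int:
        return len(self.protein)


def _codon_map(code: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[code]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_CACHE: dict[int, dict[str, str]] = {}


def translate(nt: str, code: int = 1) -> str:
    """Translate a nucleotide string (length divisible by 3) to amino acids.

    Codons containing N (or otherwise untranslatable) become ``X``; stop
    codons translate to ``*`` (used internally only, never emitted in ORF
    proteins).
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    if code not in _CODON_CACHE:
        _CODON_CACHE[code] = _codon_map(code)
    table = _CODON_CACHE[code]
    return "".join(
        table.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3)
    )


def _scan_strand(seq: str, code: int, min_aa: int):
    """Yield (frame, aa_start_codon_index, protein) for one strand of one segment."""
    for frame in range(3):
        usable = len(seq) - frame
        usable -= usable % 3
        if usable <= 0:
            continue
        aa = translate(seq[frame : frame + usable], code)
        start = 0
        for chunk in aa.split("*"):
            if len(chunk) >= min_aa:
                yield frame, start, chunk
            start += len(chunk) + 1


def extract_orfs(
    genome: GenomeRecord, min_aa: int = 100, code: int = 1
) -> list[ORF]:
    """Call ORFs in all six frames of every segment of ``genome``.

    Only ORFs translating to at least ``min_aa`` amino acids are kept
    (the default threshold is 100 aa). Output is sorted by start
    coordinate, then strand.
    """
    if min_aa < 1:
        raise ConfigurationError(f"min_aa must be >= 1, got {min_aa}")
    if not genome.sequence:
        raise ValueError(f"genome {genome.id} has no sequence")
    boundaries = genome.segment_boundaries or [(0, len(genome.sequence))]
    orfs: list[ORF] = []
    for seg_start, seg_end in boundaries:
        seg = genome.sequence[seg_start:seg_end]
        for frame, aa_start, protein in _scan_strand(seg, code, min_aa):
            s = seg_start + frame + 3 * aa_start
            e = s + 3 * len(protein)
            orfs.append(ORF(genome.id, s, e, "+", frame, protein))
        rc = reverse_complement(seg)
        for frame, aa_start, protein in _scan_strand(rc, code, min_aa):
            # coordinates on rc -> mirror back onto the forward strand
            rc_s = frame + 3 * aa_start
            rc_e = rc_s + 3 * len(protein)
            s = seg_start + (len(seg) - rc_e)
            e = seg_start + (len(seg) - rc_s)
            orfs.append(ORF(genome.id, s, e, "-", frame, protein))
    orfs.sort(key=lambda o: (o.start, o.strand, o.frame))
    return orfs


def orf_nucleotides(genome: GenomeRecord, orf: ORF) -> str:
    """Recover the coding nucleotide sequence of an ORF (5'->3' on its strand)."""
    nt = genome.sequence[orf.start : orf.end]
    return nt if orf.strand == "+" else reverse_complement(nt)


def orfs_to_tsv(orfs: list[ORF], path) -> None:
    """Dump called ORFs as a TSV (genome_id, start, end, strand, frame, length_aa)."""
    with open(path, "w") as fh:
        fh.write("genome_id\tstart\tend\tstrand\tframe\tlength_aa\n")
        for o in orfs:
            fh.write(f"{o.genome_id}\t{o.start}\t{o.end}\t{o.strand}\t{o.frame}\t{len(o)}\n")
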