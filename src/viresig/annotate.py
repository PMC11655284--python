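"""Genome annotation against a profile database.

Produces the two signature types the classifier consumes:

* the PPHMM signature table — per genome, the best local-alignment score
  (bits) of any of its ORFs against each profile, with the location of the
  best hit;
* genome organisation models (GOMs) — per genome, the signed midpoint
  coordinate of each hit (sign encodes strand) — and GOM signatures, the
  distance-correlation of a genome's hit-location profile against each
  reference GOM.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import GenomeRecord, GenomeTable
from .orfs import ORF
from .profiles import PPHMMDatabase

DEFAULT_SCORE_CUTOFF = 15.0  # bits


@dataclass(frozen=True)
class HitLocation:
    """Location of the best-scoring ORF for one (genome, profile) pair."""

    start: int
    end: int
    strand: str
    frame: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def signed_midpoint(self) -> float:
        return self.midpoint if self.strand == "+" else -self.midpoint


class EmptySignatureError(ValueError):
    """Filtering removed every profile column."""


@dataclass
class SignatureTable:
    """Genomes x profiles matrix of best-hit scores plus hit locations.

    A zero score means "no hit at or above the cutoff" and has no location;
    every nonzero score has one.
    """

    genome_ids: list[str]
    pphmm_ids: list[str]
    scores: np.ndarray  # (n_genomes, n_pphmms), >= 0
    locations: dict[tuple[str, str], HitLocation] = field(default_factory=dict)
    column_permutation: list[int] | None = None  # set by sort_pphmms

    def row(self, genome_id: str) -> np.ndarray:
        return self.scores[self.genome_ids.index(genome_id)]

    def nonzero_columns(self, genome_id: str) -> list[str]:
        r = self.row(genome_id)
        return [p for p, v in zip(self.pphmm_ids, r) if v > 0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\t" + "\t".join(self.pphmm_ids) + "\n")
            for g, row in zip(self.genome_ids, self.scores):
                fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def scan_signatures(
    genomes: GenomeTable,
    orfs_by_genome: dict[str, list[ORF]],
    db: PPHMMDatabase,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> SignatureTable:
    """Scan every genome's ORFs against every profile.

    The signature value is the best score over the genome's ORFs; scores
    below ``score_cutoff`` are stored as exactly 0 with no location.
    Genomes without ORFs get an all-zero row and a warning (they may not be
    coding-complete).
    """
    if len(db) == 0:
        raise ValueError("empty profile database")
    from .profiles import AA_INDEX  # local import to keep module load light

    genome_ids = [g.id for g in genomes]
    scores = np.zeros((len(genome_ids), len(db)))
    locations: dict[tuple[str, str], HitLocation] = {}

    # pre-encode ORF proteins once
    encoded: dict[str, list[tuple[ORF, np.ndarray]]] = {}
    for gid in genome_ids:
        orfs = orfs_by_genome.get(gid, [])
        if not orfs:
            warnings.warn(f"genome {gid} has no ORFs; flagged possibly non-coding-complete")
        encoded[gid] = [
            (o, np.array([AA_INDEX.get(c, 20) for c in o.protein], dtype=np.intp))
            for o in orfs
        ]

    from ._align import smith_waterman_score
    from .profiles import search_space_correction

    for pi, profile in enumerate(db):
        W = np.hstack([profile.match_scores, np.zeros((profile.n_columns, 1))])
        for gi, gid in enumerate(genome_ids):
            best = 0.0
            best_orf: ORF | None = None
            for orf, q in encoded[gid]:
                raw = smith_waterman_score(
                    np.ascontiguousarray(W[:, q]), profile.gap_open, profile.gap_extend
                )
                s = max(0.0, raw - search_space_correction(profile.n_columns, q.size))
                if s > best:
                    best = s
                    best_orf = orf
            if best >= score_cutoff and best_orf is not None:
                scores[gi, pi] = best
                locations[(gid, profile.pphmm_id)] = HitLocation(
                    best_orf.start, best_orf.end, best_orf.strand, best_orf.frame
                )
    return SignatureTable(genome_ids, list(db.ids), scores, locations)


def remove_singletons(table: SignatureTable, n_min: int) -> SignatureTable:
    """Drop profile columns hit in fewer than ``n_min`` genomes."""
    if n_min < 1:
        raise ValueError(f"n_min must be >= 1, got {n_min}")
    prevalence = (table.scores > 0).sum(axis=0)
    keep = [i for i, c in enumerate(prevalence) if c >= n_min]
    if not keep:
        raise EmptySignatureError("singleton removal dropped every profile column")
    kept_ids = [table.pphmm_ids[i] for i in keep]
    locations = {
        (g, p): loc for (g, p), loc in table.locations.items() if p in set(kept_ids)
    }
    return SignatureTable(
        list(table.genome_ids), kept_ids, table.scores[:, keep].copy(), locations
    )


def sort_pphmms(table: SignatureTable) -> SignatureTable:
    """Reorder profile columns by average-linkage clustering of column correlation.

    Pure permutation: scores are unchanged, only column order moves; the
    permutation applied is recorded on the result. Tables with fewer than
    two columns are returned unchanged.
    """
    from .trees import Dendrogram, linkage_matrix

    n = len(table.pphmm_ids)
    if n < 2:
        return table
    X = table.scores
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[(sd == 0)[:, None] & (sd == 0)[None, :]] = 0.0
    np.fill_diagonal(corr, 1.0)
    D = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage_matrix(D, "average")
    order_ids = Dendrogram(Z, table.pphmm_ids).leaf_order()
    perm = [table.pphmm_ids.index(p) for p in order_ids]
    return SignatureTable(
        list(table.genome_ids),
        order_ids,
        table.scores[:, perm].copy(),
        dict(table.locations),
        column_permutation=perm,
    )


# ---------------------------------------------------------------------------
# Genome organisation models


@dataclass
class GOM:
    """Signed hit-location vector of one genome (sign = strand)."""

    genome_id: str
    locations: dict[str, float]  # pphmm_id -> signed midpoint


@dataclass
class GOMSignature:
    """Distance-correlation of one genome's locations against each reference GOM."""

    genome_id: str
    reference_ids: list[str]
    scores: np.ndarray  # in [0, 1]


def build_gom_database(
    table: SignatureTable, genome_ids: list[str] | None = None
) -> list[GOM]:
    """One GOM per (reference) genome from the signature table's hit locations."""
    ids = genome_ids if genome_ids is not None else list(table.genome_ids)
    goms = []
    for gid in ids:
        locs = {
            p: table.locations[(gid, p)].signed_midpoint
            for p in table.pphmm_ids
            if (gid, p) in table.locations
        }
        goms.append(GOM(genome_id=gid, locations=locs))
    return goms


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Distance correlation (double-centred pairwise-distance form) in [0,1].

    Returns 0 for constant vectors, where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    denom = np.sqrt(dvarx * dvary)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, dcov2) / denom))


def compute_gom_signatures(
    table: SignatureTable, goms: list[GOM], min_shared: int = 2
) -> list[GOMSignature]:
    """GOM signature of every genome in ``table`` against each reference GOM.

    The entry for (genome g, reference r) is the distance correlation of
    the signed midpoints of the profiles present in both; fewer than
    ``min_shared`` shared profiles (or a constant vector) gives 0.
    """
    if not goms:
        raise ValueError("empty GOM database")
    ref_ids = [g.genome_id for g in goms]
    out = []
    for gid in table.genome_ids:
        own = {
            p: table.locations[(gid, p)].signed_midpoint
            for p in table.pphmm_ids
            if (gid, p) in table.locations
        }
        row = np.zeros(len(goms))
        for ri, gom in enumerate(goms):
            shared = [p for p in table.pphmm_ids if p in own and p in gom.locations]
            if len(shared) < min_shared:
                continue
            x = np.array([own[p] for p in shared])
            y = np.array([gom.locations[p] for p in shared])
            row[ri] = distance_correlation(x, y)
        out.append(GOMSignature(genome_id=gid, reference_ids=ref_ids, scores=row))
    return out


def gom_signature_matrix(gsigs: list[GOMSignature]) -> np.ndarray:
    return np.vstack([g.scores for g in gsigs])


def gom_signatures_to_tsv(gsigs: list[GOMSignature], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(gsigs[0].reference_ids) + "\n")
        for g in gsigs:
            fh.write(g.genome_id + "\t" + "\t".join(f"{v:.6g}" for v in g.scores) + "\n")


# ---------------------------------------------------------------------------
# Match-region export


def merge_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extract_match_regions(
    genome: GenomeRecord, table: SignatureTable, pad: int = 0
) -> list[tuple[str, str]]:
    """Contiguous sequence blocks covered by profile hits, as (header, seq).

    Hit spans are padded by ``pad`` nucleotides, clipped to their segment,
    and overlapping spans merged. Headers carry the genome id, the
    contributing profile ids, forward-strand coordinates and strand
    ('.' when merged hits disagree).
    """
    if genome.id not in table.genome_ids:
        raise KeyError(f"genome {genome.id} not in signature table")
    boundaries = genome.segment_boundaries or [(0, len(genome.sequence))]

    def clip(s: int, e: int) -> tuple[int, int]:
        for bs, be in boundaries:
            if bs <= s < be:
                return max(s, bs), min(e, be)
        return max(0, s), min(e, len(genome.sequence))

    hits = []
    for p in table.pphmm_ids:
        loc = table.locations.get((genome.id, p))
        if loc is None:
            continue
        s, e = clip(loc.start - pad, loc.end + pad)
        hits.append((s, e, p, loc.strand))
    records = []
    for s, e in merge_intervals([(h[0], h[1]) for h in hits]):
        members = [h for h in hits if h[0] >= s and h[1] <= e]
        pids = ",".join(h[2] for h in members)
        strands = {h[3] for h in members}
        strand = strands.pop() if len(strands) == 1 else "."
        header = f"{genome.id}|{pids}|{s}-{e}|{strand}"
        records.append((header, genome.sequence[s:e]))
    return records
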