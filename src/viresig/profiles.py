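"""Protein family clustering and profile (PPHMM) database construction.

Translated ORFs are compared all-against-all (local alignment scores or
MinHash k-mer sketches), clustered with a native Markov-clustering (MCL)
implementation, aligned per cluster by progressive profile-profile
alignment, and each cluster alignment is compiled into a position-specific
scoring profile. The profiles are the units against which genomes are
annotated downstream; only best-hit scores and hit locations are consumed,
so match-state emission log-odds with affine gap penalties carry all the
information the framework needs.
"""
from __future__ import annotations

import heapq
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._align import needleman_wunsch_ops, smith_waterman_score
from .genome_io import ConfigurationError
from .trees import linkage_matrix

#: Amino-acid alphabet order used for all profile matrices.
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

#: Standard amino-acid background frequencies (BLOSUM62 marginals).
BACKGROUND = np.array(
    [0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
     0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032]
)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


def _blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in :data:`AA` order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = mat[a, b]
    return out


_B62 = None


def blosum62() -> np.ndarray:
    global _B62
    if _B62 is None:
        _B62 = _blosum62()
    return _B62


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -DEFAULT_GAP_OPEN
    aligner.extend_gap_score = -DEFAULT_GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class ProteinSeq:
    """A translated ORF entering clustering, with provenance."""

    id: str
    genome_id: str
    seq: str


@dataclass
class SimilarityGraph:
    """Undirected weighted similarity graph over protein ids."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # keys sorted (i < j), no self-edges
    method: str

    def weight(self, i: str, j: str) -> float:
        if i == j:
            raise ValueError("no self-edges stored")
        a, b = sorted((i, j))
        return self.edges.get((a, b), 0.0)


@dataclass
class ProteinCluster:
    """One MCL cluster of proteins; singletons are valid clusters."""

    cluster_id: str
    members: list[str]
    provenance: list[tuple[str, str]] = field(default_factory=list)  # (genome_id, protein_id)
    converged: bool = True


def _sanitize(seq: str) -> str:
    return "".join(c if c in AA_INDEX else "X" for c in seq.upper())


# ---------------------------------------------------------------------------
# Pairwise similarity backends


def _minhash_sketch(seq: str, k: int, size: int, seed: int) -> frozenset[int]:
    key = int(seed).to_bytes(8, "little", signed=False)
    hashes = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k].encode()
        h = int.from_bytes(
            hashlib.blake2b(kmer, digest_size=8, key=key).digest(), "little"
        )
        hashes.add(h)
    return frozenset(heapq.nsmallest(size, hashes))


def _sketch_similarity(a: frozenset[int], b: frozenset[int], size: int) -> float:
    if not a or not b:
        return 0.0
    merged = heapq.nsmallest(size, a | b)
    inter = len(set(merged) & a & b)
    return inter / len(merged)


def pairwise_similarity(
    proteins: list[ProteinSeq],
    method: str = "alignment_score",
    threshold: float = 0.25,
    seed: int = 0,
    k: int = 5,
    sketch_size: int = 1000,
) -> SimilarityGraph:
    """All-against-all protein similarity graph.

    ``alignment_score``: local BLOSUM62 alignment score normalised by the
    smaller self-score, giving a weight in [0,1] (1 = identical).
    ``kmer_sketch``: bottom-k MinHash over amino-acid k-mers; the weight is
    the estimated k-mer Jaccard index (1 - sketch distance), deterministic
    for a given ``seed``. Edges with weight below ``threshold`` are omitted.
    """
    if method not in ("alignment_score", "kmer_sketch"):
        raise ConfigurationError(f"unknown similarity method {method!r}")
    if not proteins:
        raise ConfigurationError("no proteins to compare")
    nodes = [p.id for p in proteins]
    seqs = [_sanitize(p.seq) for p in proteins]
    edges: dict[tuple[str, str], float] = {}
    n = len(proteins)
    if method == "alignment_score":
        aligner = _make_aligner("local")
        self_scores = np.array([aligner.score(s, s) for s in seqs])
        for i in range(n):
            for j in range(i + 1, n):
                denom = min(self_scores[i], self_scores[j])
                if denom <= 0:
                    continue
                w = min(1.0, aligner.score(seqs[i], seqs[j]) / denom)
                if w >= threshold:
                    a, b = sorted((nodes[i], nodes[j]))
                    edges[(a, b)] = w
    else:
        sketches = [_minhash_sketch(s, k, sketch_size, seed) for s in seqs]
        for i in range(n):
            for j in range(i + 1, n):
                w = _sketch_similarity(sketches[i], sketches[j], sketch_size)
                if w >= threshold:
                    a, b = sorted((nodes[i], nodes[j]))
                    edges[(a, b)] = w
    return SimilarityGraph(nodes=nodes, edges=edges, method=method)


# ---------------------------------------------------------------------------
# Markov clustering


def markov_cluster(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[ProteinCluster]:
    """Native MCL: expansion (matrix square) + inflation (elementwise power).

    Operates on the column-stochastic transition matrix of the graph with
    unit self-loops. Clusters are the connected components of the non-zero
    structure of the converged matrix; deterministic. On non-convergence a
    warning is emitted and the current clustering returned with
    ``converged=False``.
    """
    if not graph.nodes:
        raise ConfigurationError("empty similarity graph")
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in graph.edges.items():
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        new = M @ M
        new **= inflation
        new[new < prune_below] = 0.0
        new /= new.sum(axis=0, keepdims=True)
        if np.max(np.abs(new - M)) < tol:
            M = new
            converged = True
            break
        M = new
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    structure = csr_matrix((M + M.T) > tol)
    n_comp, labels = connected_components(structure, directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for v, lab in zip(nodes, labels):
        clusters[lab].append(v)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return [
        ProteinCluster(cluster_id=f"C{i + 1:04d}", members=sorted(c), converged=converged)
        for i, c in enumerate(clusters)
    ]


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _profile_freqs(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    F = np.zeros((L, 20))
    for row in rows:
        for i, c in enumerate(row):
            j = AA_INDEX.get(c)
            if j is not None:
                F[i, j] += 1.0
    return F / len(rows)


def _merge_alignments(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    S = FA @ blosum62() @ FB.T
    ops = needleman_wunsch_ops(S, DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == 0:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            i += 1
            j += 1
        elif op == 1:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r in range(len(rows_b)):
                out_b[r].append("-")
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align_cluster(seqs: list[str]) -> list[str]:
    """Progressive multiple alignment of one protein cluster.

    Pairwise global alignment scores give a distance matrix, a UPGMA guide
    tree fixes the merge order, and sub-alignments are merged by
    profile-profile global alignment. Rows are returned in input order;
    the gap symbol is ``-``.
    """
    if not seqs:
        raise ValueError("empty cluster")
    seqs = [_sanitize(s) for s in seqs]
    if len(seqs) == 1:
        return list(seqs)
    aligner = _make_aligner("global")
    n = len(seqs)
    self_scores = [aligner.score(s, s) for s in seqs]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(self_scores[i], self_scores[j])
            sim = aligner.score(seqs[i], seqs[j]) / denom if denom > 0 else 0.0
            D[i, j] = D[j, i] = max(0.0, 1.0 - sim)
    Z = linkage_matrix(D, "average")
    # node id -> (rows, original indices)
    sub: dict[int, tuple[list[str], list[int]]] = {
        i: ([seqs[i]], [i]) for i in range(n)
    }
    for t in range(n - 1):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        rows_a, idx_a = sub.pop(a)
        rows_b, idx_b = sub.pop(b)
        merged_a, merged_b = _merge_alignments(rows_a, rows_b)
        sub[n + t] = (merged_a + merged_b, idx_a + idx_b)
    rows, order = sub[2 * n - 2]
    final = [None] * n
    for row, i in zip(rows, order):
        final[i] = row
    return final  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Profile compilation


@dataclass
class PPHMM:
    """Position-specific scoring profile for one protein family.

    ``probs`` holds per-column emission probabilities (rows sum to 1);
    ``match_scores`` are the corresponding log2 odds against
    ``background``. Local alignment of a protein against the profile with
    affine gap penalties yields a bit-valued similarity score.
    """

    pphmm_id: str
    probs: np.ndarray  # (n_columns, 20)
    background: np.ndarray  # (20,)
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    training_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.match_scores = np.log2(self.probs / self.background[None, :])

    @property
    def n_columns(self) -> int:
        return int(self.probs.shape[0])

    def score(self, protein: str) -> float:
        """Best local-alignment score of ``protein`` against the profile, in bits.

        The raw log-odds score is reduced by log2(n_columns * query length)
        — the usual search-space correction — so that chance maxima of the
        local alignment sit near zero and the score is comparable across
        profile and query lengths. Floored at 0.
        """
        seq = _sanitize(protein)
        W = np.hstack([self.match_scores, np.zeros((self.n_columns, 1))])
        q = np.array([AA_INDEX.get(c, 20) for c in seq], dtype=np.intp)
        if q.size == 0:
            return 0.0
        raw = float(smith_waterman_score(
            np.ascontiguousarray(W[:, q]), self.gap_open, self.gap_extend
        ))
        return max(0.0, raw - search_space_correction(self.n_columns, q.size))


def search_space_correction(n_columns: int, query_len: int) -> float:
    """Bits to subtract from a raw local-alignment maximum.

    The expected chance maximum of a local log-odds alignment grows like
    log2 of the search space (profile columns x query residues); removing
    it centres random-match scores near zero (Karlin-Altschul style, K=1).
    """
    return float(np.log2(max(1, n_columns) * max(1, query_len)))


class DegenerateProfileError(ValueError):
    """Every alignment column was gap-dominated; no profile can be built."""


def build_profile(
    msa: list[str],
    pseudocount: float = 0.1,
    pphmm_id: str = "",
    members: list[str] | None = None,
    max_gap_fraction: float = 0.5,
) -> PPHMM:
    """Compile an aligned protein family into a :class:`PPHMM`.

    Columns with more than ``max_gap_fraction`` gaps are dropped. Emission
    probabilities are (count + pseudocount) / (n_eff + 20 * pseudocount)
    where n_eff counts non-gap, non-ambiguous residues in the column.
    """
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0])
    if any(len(r) != L for r in msa):
        raise ValueError("alignment rows differ in length")
    rows = [r.upper() for r in msa]
    cols = []
    for i in range(L):
        column = [r[i] for r in rows]
        gap_frac = column.count("-") / len(column)
        if gap_frac > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in column:
            j = AA_INDEX.get(c)
            if j is not None:
                counts[j] += 1.0
        n_eff = counts.sum()
        cols.append((counts + pseudocount) / (n_eff + 20.0 * pseudocount))
    if not cols:
        raise DegenerateProfileError("all alignment columns are gap-dominated")
    return PPHMM(
        pphmm_id=pphmm_id,
        probs=np.array(cols),
        background=BACKGROUND.copy(),
        training_members=list(members or []),
    )


@dataclass
class PPHMMDatabase:
    """Ordered collection of profiles with JSON round-tripping."""

    profiles: list[PPHMM]

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, i):
        return self.profiles[i]

    @property
    def ids(self) -> list[str]:
        return [p.pphmm_id for p in self.profiles]

    def to_json(self, path) -> None:
        payload = {
            "alphabet": AA,
            "profiles": [
                {
                    "pphmm_id": p.pphmm_id,
                    "probs": p.probs.tolist(),
                    "background": p.background.tolist(),
                    "gap_open": p.gap_open,
                    "gap_extend": p.gap_extend,
                    "training_members": p.training_members,
                }
                for p in self.profiles
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PPHMMDatabase":
        with open(path) as fh:
            payload = json.load(fh)
        profiles = [
            PPHMM(
                pphmm_id=d["pphmm_id"],
                probs=np.array(d["probs"]),
                background=np.array(d["background"]),
                gap_open=d["gap_open"],
                gap_extend=d["gap_extend"],
                training_members=d["training_members"],
            )
            for d in payload["profiles"]
        ]
        return cls(profiles)


def build_pphmm_database(
    proteins: list[ProteinSeq],
    method: str = "alignment_score",
    threshold: float = 0.25,
    seed: int = 0,
    inflation: float = 2.0,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    pseudocount: float = 0.1,
) -> tuple[PPHMMDatabase, list[ProteinCluster]]:
    """End-to-end profile construction: similarity -> MCL -> MSA -> profiles.

    Clusters are ordered by decreasing size (ties by smallest member id)
    and profiles named PP0001, PP0002, ... in that order.
    """
    graph = pairwise_similarity(proteins, method=method, threshold=threshold, seed=seed)
    clusters = markov_cluster(
        graph, inflation=inflation, prune_below=prune_below, max_iter=max_iter
    )
    by_id = {p.id: p for p in proteins}
    db_profiles = []
    for i, cluster in enumerate(clusters):
        cluster.cluster_id = f"C{i + 1:04d}"
        cluster.provenance = [(by_id[m].genome_id, m) for m in cluster.members]
        msa = align_cluster([by_id[m].seq for m in cluster.members])
        db_profiles.append(
            build_profile(
                msa,
                pseudocount=pseudocount,
                pphmm_id=f"PP{i + 1:04d}",
                members=cluster.members,
            )
        )
    return PPHMMDatabase(db_profiles), clusters
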