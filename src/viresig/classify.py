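"""Composite Jaccard classification: similarity matrices, dendrograms,
bootstrap support, taxon groupings and feature importance.

The headline statistic is the composite Jaccard score (CJS)

    J = sqrt(J_P * J_G)

the geometric mean of the generalized Jaccard indices of two genomes'
profile signatures (J_P) and GOM signatures (J_G), where the generalized
Jaccard index of non-negative vectors a, b is sum(min(a_i,b_i)) /
sum(max(a_i,b_i)). J ranges from 0 (no detectable similarity) to 1
(identity).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import mutual_info_score

from .annotate import (
    GOMSignature,
    SignatureTable,
    build_gom_database,
    compute_gom_signatures,
    gom_signature_matrix,
)
from .genome_io import ConfigurationError
from .trees import Dendrogram, consensus_supports, linkage_matrix, transfer_supports

SCHEMES = ("cjs", "pphmm_only", "shared_ratio_weighted")


def generalized_jaccard(a, b) -> float:
    """Generalized Jaccard index: sum(min) / sum(max) over paired entries.

    Defined as 0 when both vectors are all-zero (no information is treated
    as no detectable similarity).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("entries must be non-negative")
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(a, b).sum() / denom)


def composite_score(j_p: float, j_g: float) -> float:
    """Composite Jaccard score: the geometric mean sqrt(j_p * j_g)."""
    if not (0.0 <= j_p <= 1.0 and 0.0 <= j_g <= 1.0):
        raise ValueError(f"scores must lie in [0,1]: got {j_p}, {j_g}")
    return float(np.sqrt(j_p * j_g))


@dataclass
class SimilarityMatrix:
    """Symmetric genome-by-genome similarity in [0,1] under a named scheme."""

    genome_ids: list[str]
    values: np.ndarray
    scheme: str = "cjs"

    def get(self, g: str, h: str) -> float:
        i, j = self.genome_ids.index(g), self.genome_ids.index(h)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\t" + "\t".join(self.genome_ids) + "\n")
            for g, row in zip(self.genome_ids, self.values):
                fh.write(g + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def build_similarity_matrix(
    table: SignatureTable,
    gsigs: list[GOMSignature] | None = None,
    scheme: str = "cjs",
) -> SimilarityMatrix:
    """Pairwise similarity of all genomes in the signature table.

    ``cjs``: sqrt(J_P * J_G) from profile-signature and GOM-signature rows.
    ``pphmm_only``: J_P alone (recommended for genomes dominated by one
    very large ORF, where organisation carries little information).
    ``shared_ratio_weighted``: J_P * n_shared / max(n_g, n_h), weighting by
    the ratio of shared profiles (for very large genomes).
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if scheme == "cjs":
        if gsigs is None:
            raise ConfigurationError("scheme 'cjs' requires GOM signatures")
        order = {g.genome_id: g for g in gsigs}
        G = np.vstack([order[gid].scores for gid in table.genome_ids])
    n = len(table.genome_ids)
    S = table.scores
    out = np.zeros((n, n))
    nz = S > 0
    for i in range(n):
        out[i, i] = 1.0 if nz[i].any() else 0.0
        for j in range(i + 1, n):
            j_p = generalized_jaccard(S[i], S[j])
            if scheme == "cjs":
                j_g = generalized_jaccard(G[i], G[j])
                v = composite_score(j_p, j_g)
            elif scheme == "pphmm_only":
                v = j_p
            else:
                n_i, n_j = int(nz[i].sum()), int(nz[j].sum())
                n_shared = int((nz[i] & nz[j]).sum())
                v = j_p * (n_shared / max(n_i, n_j)) if max(n_i, n_j) else 0.0
            out[i, j] = out[j, i] = v
    return SimilarityMatrix(list(table.genome_ids), out, scheme)


def build_dendrogram(sim: SimilarityMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative dendrogram on distance D = 1 - similarity (UPGMA default)."""
    n = len(sim.genome_ids)
    if n < 2:
        raise ValueError("need at least 2 genomes for a dendrogram")
    D = np.clip(1.0 - sim.values, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage_matrix(D, method)
    return Dendrogram(Z, list(sim.genome_ids), method=method)


# ---------------------------------------------------------------------------
# Bootstrap


def _resample_table(table: SignatureTable, rng: np.random.Generator) -> SignatureTable:
    """Sample profile columns with replacement (classic bootstrap)."""
    p = len(table.pphmm_ids)
    idx = rng.integers(0, p, size=p)
    new_ids = [f"{table.pphmm_ids[i]}#{k}" for k, i in enumerate(idx)]
    locations = {}
    for k, i in enumerate(idx):
        pid = table.pphmm_ids[i]
        for gid in table.genome_ids:
            loc = table.locations.get((gid, pid))
            if loc is not None:
                locations[(gid, new_ids[k])] = loc
    return SignatureTable(
        list(table.genome_ids), new_ids, table.scores[:, idx].copy(), locations
    )


def bootstrap_support(
    table: SignatureTable,
    n_boot: int = 100,
    support_method: str = "consensus",
    seed: int = 0,
    scheme: str = "cjs",
    method: str = "average",
    min_shared: int = 2,
    gom_reference_ids: list[str] | None = None,
    return_replicates: bool = False,
):
    """Dendrogram with bootstrap support from profile-column resampling.

    Each replicate resamples PPHMM columns with replacement, regenerates
    the GOM database and signatures from the resampled table, rebuilds the
    similarity matrix and tree. Support is either the fraction of
    replicates containing each clade (``consensus``) or the
    transfer-bootstrap expectation (``transfer``).
    """
    if n_boot < 1:
        raise ConfigurationError(f"n_boot must be >= 1, got {n_boot}")
    if support_method not in ("consensus", "transfer"):
        raise ConfigurationError(f"unknown support method {support_method!r}")
    if len(table.pphmm_ids) < 2:
        raise ConfigurationError("need >= 2 profile columns to bootstrap")

    def tree_from(tab: SignatureTable) -> Dendrogram:
        gsigs = None
        if scheme == "cjs":
            goms = build_gom_database(tab, gom_reference_ids)
            gsigs = compute_gom_signatures(tab, goms, min_shared=min_shared)
        sim = build_similarity_matrix(tab, gsigs, scheme=scheme)
        return build_dendrogram(sim, method=method)

    reference = tree_from(table)
    rng = np.random.default_rng(seed)
    replicates = [_resample_table(table, rng) for _ in range(n_boot)]
    rep_trees = [tree_from(t) for t in replicates]
    if support_method == "consensus":
        reference.supports = consensus_supports(reference, rep_trees)
    else:
        reference.supports = transfer_supports(reference, rep_trees)
    if return_replicates:
        return reference, rep_trees
    return reference


# ---------------------------------------------------------------------------
# Groupings and Theil's U


def _entropy(labels) -> float:
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def theils_u(reference, predicted) -> float:
    """Uncertainty coefficient U(reference | predicted) in [0, 1].

    U = (H(ref) - H(ref|pred)) / H(ref) = MI / H(ref). When H(ref) = 0 the
    coefficient is defined as 1 if predictions are also constant, else 0.
    """
    reference = list(reference)
    predicted = list(predicted)
    if len(reference) != len(predicted):
        raise ValueError("label vectors differ in length")
    h_ref = _entropy(reference)
    if h_ref == 0:
        return 1.0 if _entropy(predicted) == 0 else 0.0
    mi = mutual_info_score(reference, predicted)
    return float(min(1.0, mi / h_ref))


@dataclass
class Grouping:
    """Predicted group label per genome, with the threshold used and
    Theil's U against reference labels (both conditioning directions)."""

    labels: dict[str, int]
    threshold: float
    theils_u: float | None = None  # U(reference | predicted)
    theils_u_reverse: float | None = None  # U(predicted | reference)

    def to_csv(self, path, reference_labels=None) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id,group,reference_label\n")
            for g, lab in self.labels.items():
                ref = "" if not reference_labels else reference_labels.get(g, "")
                fh.write(f"{g},{lab},{ref}\n")


def _threshold_grid(tree: Dendrogram) -> list[float]:
    """Candidate cut heights: midpoints between consecutive merge distances."""
    d = np.unique(tree.Z[:, 2])
    grid = [d[0] / 2]
    grid += [(d[i] + d[i + 1]) / 2 for i in range(len(d) - 1)]
    grid.append(d[-1] + 1e-9)
    return grid


def virus_grouping(
    sim: SimilarityMatrix,
    tree: Dendrogram,
    reference_labels: dict[str, str] | None = None,
    threshold: float | None = None,
) -> Grouping:
    """Quantitative taxon groupings by cutting the dendrogram.

    Groups are the connected components of the tree cut at a merge-distance
    threshold. Without an explicit threshold, the cut maximising Theil's U
    against ``reference_labels`` over a grid of candidate heights is
    chosen; ties resolve toward the largest threshold, i.e. the coarsest
    grouping attaining the maximum (finer cuts trivially inflate
    U(ref | pred) — splitting down to singletons always makes the
    prediction perfectly informative about the reference).
    """
    if threshold is None and reference_labels is None:
        raise ConfigurationError("need either a threshold or reference labels")
    if threshold is None:
        scored = []
        for t in _threshold_grid(tree):
            labels = tree.cut(t)
            ids = [g for g in tree.labels if g in reference_labels]
            u = theils_u([reference_labels[g] for g in ids], [labels[g] for g in ids])
            scored.append((u, t, labels))
        u_max = max(u for u, _, _ in scored)
        _, threshold, labels = max(
            (s for s in scored if s[0] >= u_max - 1e-9), key=lambda s: s[1]
        )
    else:
        labels = tree.cut(threshold)
    grouping = Grouping(labels=labels, threshold=float(threshold))
    if reference_labels is not None:
        ids = [g for g in tree.labels if g in reference_labels]
        ref = [reference_labels[g] for g in ids]
        pred = [labels[g] for g in ids]
        grouping.theils_u = theils_u(ref, pred)
        grouping.theils_u_reverse = theils_u(pred, ref)
    return grouping


def pphmm_mutual_information(
    table: SignatureTable,
    groups: Grouping,
    bins: str = "presence",
    n_quantiles: int = 4,
) -> list[tuple[str, float]]:
    """Per-profile feature importance: MI(column; group label), in nats.

    Columns are discretised to presence/absence by default, or into
    ``n_quantiles`` quantile bins (``bins='quantile'``). Returns
    (pphmm_id, importance) sorted by decreasing importance; a single-group
    labelling yields an all-zero vector with a warning.
    """
    missing = [g for g in table.genome_ids if g not in groups.labels]
    if missing:
        raise ValueError(f"grouping does not cover genomes: {missing}")
    labels = [groups.labels[g] for g in table.genome_ids]
    if len(set(labels)) < 2:
        warnings.warn("single predicted group: all importances are zero")
        return sorted(
            ((p, 0.0) for p in table.pphmm_ids), key=lambda x: x[0]
        )
    out = []
    for i, pid in enumerate(table.pphmm_ids):
        col = table.scores[:, i]
        if bins == "presence":
            disc = (col > 0).astype(int)
        elif bins == "quantile":
            edges = np.quantile(col, np.linspace(0, 1, n_quantiles + 1)[1:-1])
            disc = np.searchsorted(edges, col)
        else:
            raise ConfigurationError(f"unknown binning {bins!r}")
        out.append((pid, float(mutual_info_score(labels, disc))))
    out.sort(key=lambda x: (-x[1], x[0]))
    return out


def mutual_information_to_csv(mi: list[tuple[str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("pphmm_id,mutual_information_nats\n")
        for pid, v in mi:
            fh.write(f"{pid},{v:.10g}\n")
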