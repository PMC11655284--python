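"""End-to-end orchestration: configuration, the single-pass pipeline, the
coarse-then-fine two-pass search, and batch utilities.

The pipeline runs genome IO -> ORF calling -> protein clustering/profiles
-> signature annotation -> classification -> outputs, recording a JSON
manifest (config, seed, per-stage counts) alongside the numeric artefacts.
Runs are "fire and forget": a genome whose processing fails is excluded and
reported in the manifest rather than aborting the batch. Identical
configuration and seed reproduce byte-identical numeric outputs.
"""
from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .annotate import (
    build_gom_database,
    compute_gom_signatures,
    extract_match_regions,
    gom_signatures_to_tsv,
    remove_singletons,
    scan_signatures,
    sort_pphmms,
)
from .classify import (
    Grouping,
    bootstrap_support,
    build_dendrogram,
    build_similarity_matrix,
    mutual_information_to_csv,
    pphmm_mutual_information,
    virus_grouping,
)
from .genome_io import (
    ConfigurationError,
    GenomeTable,
    attach_sequences,
    parse_vmr,
    select_representatives,
    write_fasta,
)
from .orfs import extract_orfs, orfs_to_tsv
from .profiles import ProteinSeq, build_pphmm_database
from .viz import barcode_matrix, render_outputs, shared_ratio_matrix

logger = logging.getLogger(__name__)

#: Named parameter presets for common scenarios. "similar" suits closely
#: related genomes (stricter clustering and hit thresholds); "divergent"
#: relaxes them to pick up remote homology; "long-genome" uses the
#: shared-profile weighting scheme that behaves better when genomes carry
#: very many (or very few, very long) ORFs.
PRESETS: dict[str, dict] = {
    "similar": {"similarity_threshold": 0.35, "score_cutoff": 20.0},
    "divergent": {"min_aa": 80, "similarity_threshold": 0.15, "score_cutoff": 10.0},
    "long-genome": {"min_aa": 150, "scheme": "shared_ratio_weighted"},
}


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run.

    The four knobs that matter most in practice: the similarity backend
    (``similarity_method``) and its ``similarity_threshold``, the minimum
    protein length ``min_aa``, and the profile-hit ``score_cutoff`` (bits).
    """

    vmr_path: str | None = None
    fasta_paths: list[str] = field(default_factory=list)
    query_fasta: str | None = None
    outdir: str = "viresig_out"
    # ORF calling
    min_aa: int = 100
    genetic_code: int = 1
    # protein similarity + clustering
    similarity_method: str = "alignment_score"
    similarity_threshold: float = 0.25
    inflation: float = 2.0
    prune_below: float = 1e-5
    mcl_max_iter: int = 200
    pseudocount: float = 0.1
    # annotation
    score_cutoff: float = 15.0
    n_min: int | None = None
    sort_pphmms: bool = False
    min_shared: int = 2
    # classification
    scheme: str = "cjs"
    linkage_method: str = "average"
    n_boot: int = 10
    support_method: str = "consensus"
    support_cutoff: float = 0.7
    grouping_rank: str | None = "family"
    grouping_threshold: float | None = None
    # outputs
    export_match_regions: bool = False
    match_region_pad: int = 0
    render_figures: bool = True
    seed: int = 0
    premade_pipeline: str | None = None

    def __post_init__(self) -> None:
        if self.premade_pipeline:
            if self.premade_pipeline not in PRESETS:
                raise ConfigurationError(
                    f"unknown premade pipeline {self.premade_pipeline!r}; "
                    f"choose from {sorted(PRESETS)}"
                )
            for k, v in PRESETS[self.premade_pipeline].items():
                setattr(self, k, v)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    """Artefacts of one pipeline run."""

    table: GenomeTable
    signature_table: object
    similarity: object
    tree: object
    grouping: Grouping | None
    manifest: dict
    paths: dict[str, str]


def load_inputs(config: RunConfig) -> GenomeTable:
    """Resolve the reference table + FASTA (and optional query FASTA)."""
    if config.vmr_path is None:
        raise ConfigurationError("vmr_path is required")
    table = parse_vmr(config.vmr_path)
    fastas = list(config.fasta_paths)
    if config.query_fasta:
        qtable = fasta_to_input_table(config.query_fasta)
        table = GenomeTable(table.records + qtable.records, source_label=table.source_label)
        fastas.append(config.query_fasta)
    return attach_sequences(table, fastas)


def run_pipeline(config: RunConfig, table: GenomeTable | None = None) -> RunResult:
    """Execute the full workflow and write all artefacts under ``config.outdir``.

    ``table`` may be supplied directly (already attached sequences) to skip
    file IO, e.g. for synthetic fixtures.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = load_inputs(config)
    manifest: dict = {
        "package": "viresig",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "counts": {"genomes_in": len(table)},
        "excluded_genomes": {},
        "zero_orf_genomes": [],
        "timings_s": {},
    }

    # --- ORF extraction (fire-and-forget per genome) -----------------------
    t = time.time()
    orfs_by_genome = {}
    kept_records = []
    for rec in table:
        try:
            orfs = extract_orfs(rec, min_aa=config.min_aa, code=config.genetic_code)
        except Exception as exc:  # noqa: BLE001 - per-genome guard by design
            logger.error("genome %s excluded: %s", rec.id, exc)
            manifest["excluded_genomes"][rec.id] = str(exc)
            continue
        if not orfs:
            manifest["zero_orf_genomes"].append(rec.id)
        orfs_by_genome[rec.id] = orfs
        kept_records.append(rec)
    table = GenomeTable(kept_records, source_label=table.source_label)
    all_orfs = [o for rec in table for o in orfs_by_genome[rec.id]]
    orfs_to_tsv(all_orfs, outdir / "orfs.tsv")
    manifest["counts"]["genomes_kept"] = len(table)
    manifest["counts"]["orfs"] = len(all_orfs)
    manifest["timings_s"]["orf_extraction"] = round(time.time() - t, 3)

    # --- profile database --------------------------------------------------
    t = time.time()
    proteins = [
        ProteinSeq(id=f"{rec.id}|orf{i}", genome_id=rec.id, seq=o.protein)
        for rec in table
        for i, o in enumerate(orfs_by_genome[rec.id])
    ]
    if not proteins:
        raise ConfigurationError("no ORFs called in any genome; nothing to classify")
    db, clusters = build_pphmm_database(
        proteins,
        method=config.similarity_method,
        threshold=config.similarity_threshold,
        seed=config.seed,
        inflation=config.inflation,
        prune_below=config.prune_below,
        max_iter=config.mcl_max_iter,
        pseudocount=config.pseudocount,
    )
    db.to_json(outdir / "pphmm_db.json")
    manifest["counts"]["proteins"] = len(proteins)
    manifest["counts"]["clusters"] = len(clusters)
    manifest["counts"]["pphmms"] = len(db)
    manifest["timings_s"]["profile_construction"] = round(time.time() - t, 3)

    # --- annotation ---------------------------------------------------------
    t = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig = scan_signatures(table, orfs_by_genome, db, score_cutoff=config.score_cutoff)
    if config.n_min:
        sig = remove_singletons(sig, config.n_min)
    if config.sort_pphmms:
        sig = sort_pphmms(sig)
    sig.to_tsv(outdir / "pphmm_signatures.tsv")
    ref_ids = [r.id for r in table if r.is_reference] or list(sig.genome_ids)
    goms = build_gom_database(sig, ref_ids)
    gsigs = compute_gom_signatures(sig, goms, min_shared=config.min_shared)
    gom_signatures_to_tsv(gsigs, outdir / "gom_signatures.tsv")
    manifest["counts"]["pphmms_kept"] = len(sig.pphmm_ids)
    manifest["timings_s"]["annotation"] = round(time.time() - t, 3)

    # --- classification -----------------------------------------------------
    t = time.time()
    sim = build_similarity_matrix(sig, gsigs, scheme=config.scheme)
    if len(sim.genome_ids) >= 2:
        if config.n_boot >= 1 and len(sig.pphmm_ids) >= 2:
            tree = bootstrap_support(
                sig,
                n_boot=config.n_boot,
                support_method=config.support_method,
                seed=config.seed,
                scheme=config.scheme,
                method=config.linkage_method,
                min_shared=config.min_shared,
                gom_reference_ids=ref_ids,
            )
        else:
            tree = build_dendrogram(sim, method=config.linkage_method)
    else:
        raise ConfigurationError("need at least 2 genomes to classify")

    grouping = None
    reference_labels = {
        r.id: r.taxonomy[config.grouping_rank]
        for r in table
        if config.grouping_rank and r.taxonomy.get(config.grouping_rank)
    } or None
    if reference_labels is not None or config.grouping_threshold is not None:
        grouping = virus_grouping(
            sim, tree, reference_labels=reference_labels, threshold=config.grouping_threshold
        )
        grouping.to_csv(outdir / "grouping.csv", reference_labels=reference_labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mi = pphmm_mutual_information(sig, grouping)
        mutual_information_to_csv(mi, outdir / "mutual_information.csv")
        manifest["counts"]["groups"] = len(set(grouping.labels.values()))
        manifest["theils_u"] = grouping.theils_u
    manifest["counts"]["similarity_matrix_shape"] = list(sim.values.shape)
    manifest["timings_s"]["classification"] = round(time.time() - t, 3)

    # --- outputs ------------------------------------------------------------
    t = time.time()
    shared = shared_ratio_matrix(sig)
    barcode = barcode_matrix(sig, table)
    paths = render_outputs(
        sim,
        tree,
        shared,
        barcode,
        outdir,
        support_cutoff=config.support_cutoff,
        render_figures=config.render_figures,
    )
    if config.export_match_regions:
        regions = {}
        for rec in table:
            for header, seq in extract_match_regions(rec, sig, pad=config.match_region_pad):
                regions[header] = seq
        write_fasta(regions, outdir / "match_regions.fasta")
        paths["match_regions"] = str(outdir / "match_regions.fasta")
    manifest["timings_s"]["outputs"] = round(time.time() - t, 3)
    manifest["timings_s"]["total"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = str(outdir / "manifest.json")
    return RunResult(table, sig, sim, tree, grouping, manifest, paths)


def run_two_pass(
    config: RunConfig,
    first_pass_rank: str = "family",
    k_closest: int = 3,
    table: GenomeTable | None = None,
) -> tuple[RunResult, RunResult, list[str]]:
    """Coarse-then-fine search for unclassified query genomes.

    Pass 1 classifies the queries against one representative per taxon at
    ``first_pass_rank``; the ``k_closest`` reference taxa per query (by
    similarity) are pooled, and pass 2 reruns against every member of those
    taxa. Returns (pass1 result, pass2 result, selected taxa).
    """
    if table is None:
        table = load_inputs(config)
    queries = [r for r in table if not r.is_reference]
    if not queries:
        raise ConfigurationError("two-pass search needs at least one query (non-reference) genome")
    outdir = Path(config.outdir)

    pass1_table = select_representatives(table, first_pass_rank)
    cfg1 = replace(config, outdir=str(outdir / "pass1"))
    res1 = run_pipeline(cfg1, table=pass1_table)

    rep_taxon = {
        r.id: r.taxonomy[first_pass_rank] for r in pass1_table if r.is_reference
    }
    taxa_available = sorted(set(rep_taxon.values()))
    if len(taxa_available) < k_closest:
        warnings.warn(
            f"only {len(taxa_available)} taxa available; using all (k_closest={k_closest})"
        )
    selected: set[str] = set()
    for q in queries:
        if q.id not in res1.similarity.genome_ids:
            continue
        ranked = sorted(
            ((res1.similarity.get(q.id, rid), taxon) for rid, taxon in rep_taxon.items()),
            key=lambda x: (-x[0], x[1]),
        )
        selected.update(taxon for _, taxon in ranked[:k_closest])
    pass2_records = [
        r
        for r in table
        if not r.is_reference or r.taxonomy.get(first_pass_rank) in selected
    ]
    cfg2 = replace(config, outdir=str(outdir / "pass2"))
    res2 = run_pipeline(cfg2, table=GenomeTable(pass2_records, source_label=table.source_label))
    return res1, res2, sorted(selected)


def fasta_to_input_table(fasta_path, out_csv=None) -> GenomeTable:
    """Convert a FASTA of unclassified genomes into an input table.

    One provisional, non-reference row per record (id = FASTA id, taxonomy
    blank). Optionally writes the table as CSV in the dialect
    :func:`viresig.genome_io.parse_vmr` reads.
    """
    from .genome_io import GenomeRecord, write_vmr

    ids = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        if rec.id in ids:
            raise ConfigurationError(f"duplicate FASTA id {rec.id!r}")
        ids.append(rec.id)
    if not ids:
        warnings.warn(f"no records in {fasta_path}")
    records = [
        GenomeRecord(id=i, accessions=[i], name=i, is_reference=False, provisional=True)
        for i in ids
    ]
    table = GenomeTable(records, source_label=str(fasta_path))
    if out_csv is not None:
        write_vmr(table, out_csv)
    return table
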