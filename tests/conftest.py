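"""Shared fixtures: small synthetic genome sets and derived pipeline stages.

Session scope keeps the expensive stages (profile construction, signature
scanning) to a single computation per run.
"""
from __future__ import annotations

import numpy as np
import pytest

from viresig.annotate import (
    build_gom_database,
    compute_gom_signatures,
    scan_signatures,
)
from viresig.classify import build_similarity_matrix
from viresig.orfs import extract_orfs
from viresig.profiles import ProteinSeq, build_pphmm_database
from viresig.simulate import FixtureSpec, simulate_genomes


@pytest.fixture(scope="session")
def small_fixture():
    """Two disjoint planted families x two genomes, no divergence."""
    spec = FixtureSpec(
        seed=7,
        n_families=2,
        genomes_per_family=2,
        genes_per_family=3,
        shared_genes=0,
        substitution_rate=0.0,
    )
    table, truth, fasta = simulate_genomes(spec)
    return spec, table, truth, fasta


@pytest.fixture(scope="session")
def small_run(small_fixture):
    """ORFs, profile DB, signatures, GOM signatures and CJS matrix."""
    _, table, truth, _ = small_fixture
    orfs = {r.id: extract_orfs(r) for r in table}
    proteins = [
        ProteinSeq(f"{r.id}|orf{i}", r.id, o.protein)
        for r in table
        for i, o in enumerate(orfs[r.id])
    ]
    db, clusters = build_pphmm_database(proteins)
    sig = scan_signatures(table, orfs, db)
    goms = build_gom_database(sig)
    gsigs = compute_gom_signatures(sig, goms)
    sim = build_similarity_matrix(sig, gsigs)
    return {
        "table": table,
        "truth": truth,
        "orfs": orfs,
        "db": db,
        "clusters": clusters,
        "sig": sig,
        "goms": goms,
        "gsigs": gsigs,
        "sim": sim,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
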