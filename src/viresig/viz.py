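"""Explainability outputs: similarity heatmap, shared-profile ratio matrix
and the barcode heatmap of normalised profile positions.

The numeric matrices (emitted as TSV) are the authoritative artefacts; the
rendered figures are a convenience view of the same numbers. In the barcode
matrix an absent profile appears as a blank cell, which is the visual
diagnostic for non-coding-complete genomes: truncated genomes lose their
trailing profiles and show a gap where their relatives have colour.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import SignatureTable
from .classify import SimilarityMatrix
from .genome_io import GenomeTable
from .trees import Dendrogram


def shared_ratio_matrix(table: SignatureTable) -> pd.DataFrame:
    """Pairwise count of shared profiles, geometric-mean normalised.

    entry(g, h) = n_shared / sqrt(n_g * n_h), where n_g is the number of
    profiles assigned to genome g; 0 when either genome has no hits.
    """
    nz = (table.scores > 0).astype(float)
    counts = nz.sum(axis=1)
    shared = nz @ nz.T
    denom = np.sqrt(np.outer(counts, counts))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, shared / denom, 0.0)
    return pd.DataFrame(vals, index=table.genome_ids, columns=table.genome_ids)


@dataclass
class BarcodeMatrix:
    """Genome-by-profile matrix of normalised hit midpoints in [0,1].

    Columns are ordered by the per-profile median position (computed over
    present entries only); missing hits are NaN.
    """

    data: pd.DataFrame
    medians: pd.Series

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


def barcode_matrix(table: SignatureTable, genomes: GenomeTable) -> BarcodeMatrix:
    """Normalised profile midpoint per (genome, profile): |midpoint| / length."""
    lengths = {g.id: len(g.sequence) for g in genomes}
    rows = []
    for gid in table.genome_ids:
        row = {}
        for pid in table.pphmm_ids:
            loc = table.locations.get((gid, pid))
            row[pid] = abs(loc.midpoint) / lengths[gid] if loc is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows, index=table.genome_ids, columns=table.pphmm_ids)
    medians = df.median(axis=0, skipna=True)
    order = medians.sort_values(kind="stable").index
    df = df[order]
    return BarcodeMatrix(data=df, medians=medians[order])


def render_outputs(
    sim: SimilarityMatrix,
    tree: Dendrogram,
    shared: pd.DataFrame,
    barcode: BarcodeMatrix,
    outdir,
    support_cutoff: float = 0.7,
    figure_format: str = "png",
    render_figures: bool = True,
) -> dict[str, str]:
    """Write the numeric TSVs, annotated newick and (optionally) figures.

    All matrices are row/column-ordered by the tree's leaf order.
    Bootstrap supports below ``support_cutoff`` are hidden in the
    annotated newick, following the usual display convention.
    """
    from pathlib import Path

    ids = set(sim.genome_ids)
    if set(tree.labels) != ids or set(shared.index) != ids or set(barcode.data.index) != ids:
        raise ValueError("genome ids of similarity matrix, tree, shared-ratio and barcode inputs disagree")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = tree.leaf_order()
    paths: dict[str, str] = {}

    perm = [sim.genome_ids.index(g) for g in order]
    sim_ord = SimilarityMatrix(order, sim.values[np.ix_(perm, perm)], sim.scheme)
    p = outdir / "similarity_matrix.tsv"
    sim_ord.to_tsv(p)
    paths["similarity_matrix"] = str(p)

    shared_ord = shared.loc[order, order]
    p = outdir / "shared_ratio.tsv"
    shared_ord.to_csv(p, sep="\t", float_format="%.10g")
    paths["shared_ratio"] = str(p)

    p = outdir / "barcode.tsv"
    BarcodeMatrix(barcode.data.loc[order], barcode.medians).to_tsv(p)
    paths["barcode"] = str(p)

    p = outdir / "tree.nwk"
    with open(p, "w") as fh:
        fh.write(tree.newick(include_support=True) + "\n")
    paths["tree"] = str(p)

    p = outdir / "tree_annotated.nwk"
    with open(p, "w") as fh:
        fh.write(tree.newick(include_support=True, support_cutoff=support_cutoff) + "\n")
    paths["tree_annotated"] = str(p)

    if render_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        def heatfig(mat, title, fname, cmap="viridis"):
            fig, ax = plt.subplots(figsize=(6, 5))
            im = ax.imshow(mat, cmap=cmap, vmin=0, vmax=1, aspect="auto", interpolation="nearest")
            ax.set_xticks(range(len(order)))
            ax.set_xticklabels(order, rotation=90, fontsize=5)
            ax.set_yticks(range(len(order)))
            ax.set_yticklabels(order, fontsize=5)
            ax.set_title(title)
            fig.colorbar(im, ax=ax, shrink=0.8)
            fig.tight_layout()
            path = outdir / f"{fname}.{figure_format}"
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return str(path)

        paths["heatmap_figure"] = heatfig(sim_ord.values, f"similarity ({sim.scheme})", "heatmap")
        paths["shared_ratio_figure"] = heatfig(
            shared_ord.values, "shared normalised profile ratio", "shared_ratio"
        )

        bc = barcode.data.loc[order]
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(bc.values, cmap="plasma", vmin=0, vmax=1, aspect="auto", interpolation="nearest")
        ax.set_xticks(range(bc.shape[1]))
        ax.set_xticklabels(bc.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(len(order)))
        ax.set_yticklabels(order, fontsize=5)
        ax.set_title("profile barcode (normalised midpoint)")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        path = outdir / f"barcode.{figure_format}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths["barcode_figure"] = str(path)

    return paths
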