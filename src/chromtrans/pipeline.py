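"""End-to-end runner: read a manifest, execute every stage, write all outputs.

Stages run in method order: region classification, mark assignment, meta-gene
profiles, differential deposition, chromatin states and transitions,
two-condition DEGs, mark x expression integration, preferential-expression
calls, TSS matrices and k-means clustering, TF family enrichment, and
transition enrichment of the preferential genes.  Every output is a TSV (or
BED) plus a provenance JSON carrying the config hash and seed; identical
inputs and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io as cio
from .annotation import build_region_index, peak_region_distribution
from .enrichment import FamilyCatalog, family_enrichment
from .expression import (
    call_deg,
    cluster_by_marks,
    integrate_marks_expression,
    preferential_expression,
)
from .marks import assign_marks, differential_deposition, normalize_tracks
from .metagene import metagene_profile, tss_matrix
from .states import call_states, classify_transitions, transition_counts, transition_enrichment

__all__ = ["run_pipeline"]


def _safe(mark: str) -> str:
    return mark.replace("/", "_")


def run_pipeline(config: cio.PipelineConfig, manifest_path, outdir) -> dict:
    """Run every stage on the manifest's inputs; return the in-memory results.

    Writes one file per stage into ``outdir`` and a ``provenance.json`` with
    the config (and its hash) and seed.  The returned dict holds the
    intermediate objects, keyed the way :func:`chromtrans.simulate.truth_scorecard`
    expects them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = cio.read_manifest(manifest_path, config)
    tissue_a, tissue_b = config.tissues

    genome, genes = cio.read_gff3(inputs["genes"])
    gene_ids = [g.gene_id for g in genes]

    peaks = {
        key: cio.read_peaks(path, mark=key[0], tissue=key[1])
        for key, path in inputs["peaks"].items()
    }
    raw_tracks = {key: cio.read_signal(path) for key, path in inputs["signal"].items()}
    tracks = dict(raw_tracks)
    for mark in config.marks:
        ka, kb = (mark, tissue_a), (mark, tissue_b)
        if tracks[ka].total() > 0 and tracks[kb].total() > 0:
            tracks[ka], tracks[kb] = normalize_tracks(tracks[ka], tracks[kb])

    # -- region classification -------------------------------------------
    index = build_region_index(genes, genome, promoter_bp=config.upstream_bp)
    index.to_bed(outdir / "region_index.bed")
    dist_rows = []
    for (mark, tissue), plist in sorted(peaks.items()):
        if not plist:
            continue
        dist = peak_region_distribution(plist, index)
        for region, row in dist.iterrows():
            dist_rows.append((mark, tissue, region, row.base_weighted, row.count_weighted))
    pd.DataFrame(
        dist_rows, columns=["mark", "tissue", "region", "base_weighted", "count_weighted"]
    ).to_csv(outdir / "region_distribution.tsv", sep="\t", index=False,
             float_format="%.6g")

    # -- mark assignment ----------------------------------------------------
    all_peaks = [p for plist in peaks.values() for p in plist]
    mark_table = assign_marks(
        all_peaks,
        genes,
        upstream_bp=config.upstream_bp,
        genome=genome,
        tracks=tracks,
        min_overlap_fraction=config.min_overlap_fraction,
    )
    mark_table.to_tsv(outdir / "mark_table.tsv")

    # -- meta-gene profiles -------------------------------------------------
    prof_rows = []
    for (mark, tissue), track in sorted(tracks.items()):
        prof = metagene_profile(
            track,
            genes,
            flank_bp=config.metagene_flank_bp,
            flank_bins=config.metagene_flank_bins,
            body_bins=config.metagene_body_bins,
        )
        for label, mean in zip(prof.bin_labels, prof.means):
            prof_rows.append((mark, tissue, label, mean))
    pd.DataFrame(prof_rows, columns=["mark", "tissue", "bin", "mean_signal"]).to_csv(
        outdir / "metagene_profiles.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # -- differential deposition ---------------------------------------------
    differential = {}
    for mark in config.marks:
        res = differential_deposition(
            mark_table,
            mark,
            tissue_a,
            tissue_b,
            tracks[(mark, tissue_a)],
            tracks[(mark, tissue_b)],
            min_fold=config.min_fold,
            pseudocount=config.pseudocount,
        )
        differential[mark] = res
        res.to_tsv(outdir / f"differential_{_safe(mark)}.tsv")

    # -- chromatin states and transitions -------------------------------------
    states = {t: call_states(mark_table, t) for t in config.tissues}
    transitions = classify_transitions(states[tissue_a], states[tissue_b])
    out = transitions.copy()
    out.sort_index().to_csv(outdir / "transitions.tsv", sep="\t", index_label="gene_id")
    transition_counts(transitions).rename("n_genes").to_csv(
        outdir / "transition_counts.tsv", sep="\t", index_label="transition"
    )

    # -- two-condition DEGs ----------------------------------------------------
    expr = pd.read_csv(inputs["expression"], sep="\t", index_col="gene_id")
    deg_a, deg_b = call_deg(
        expr[tissue_a],
        expr[tissue_b],
        fold=config.fold_change_cutoff,
        pseudocount=config.pseudocount,
    )
    pd.DataFrame(
        sorted([(g, tissue_a) for g in deg_a] + [(g, tissue_b) for g in deg_b]),
        columns=["gene_id", "higher_in"],
    ).to_csv(outdir / "deg.tsv", sep="\t", index=False)

    # -- mark x expression integration ---------------------------------------
    venn, venn_lists = integrate_marks_expression(differential["H3K27me3"], deg_a, deg_b)
    venn.to_csv(outdir / "venn_H3K27me3_expression.tsv", sep="\t")
    with open(outdir / "venn_gene_lists.tsv", "w") as fh:
        fh.write("cell\tgene_id\n")
        for cell in sorted(venn_lists):
            for g in sorted(venn_lists[cell]):
                fh.write(f"{cell}\t{g}\n")

    # -- preferential expression on the panel ----------------------------------
    panel = pd.read_csv(inputs["panel"], sep="\t", index_col="gene_id")
    meta = pd.read_csv(inputs["panel_samples"], sep="\t")
    sample_tissue = meta.set_index("sample")["tissue"]
    preferential = preferential_expression(
        panel,
        sample_tissue,
        target=tissue_a,
        p_cutoff=config.preferential_p_cutoff,
    )
    preferential.sort_index().to_csv(
        outdir / "preferential_expression.tsv", sep="\t", index_label="gene_id",
        float_format="%.6g"
    )
    pref_genes = sorted(preferential.index[preferential["preferential"]])

    # -- TSS matrices + k-means clustering of the preferential genes ----------
    results_clusters = None
    if len(pref_genes) >= config.kmeans_k:
        matrices = []
        for (mark, tissue), track in sorted(tracks.items()):
            hm = tss_matrix(
                track,
                genes,
                pref_genes,
                flank_bp=config.cluster_flank_bp,
                bin_bp=config.tss_bin_bp,
                genome=genome,
            )
            hm.to_tsv(outdir / f"tss_matrix_{_safe(mark)}_{tissue}.tsv")
            matrices.append(hm)
        results_clusters = cluster_by_marks(
            matrices, k=config.kmeans_k, seed=config.seed,
            n_restarts=config.kmeans_restarts,
        )
        results_clusters.to_tsv(outdir / "clusters.tsv")

    # -- TF family enrichment ---------------------------------------------------
    catalog = FamilyCatalog.from_tsv(inputs["tf_families"])
    tf_universe = catalog.all_members() & set(gene_ids)
    enr_frames = []
    for mark, res in differential.items():
        for tissue, genes_set in (
            (tissue_a, res.a_preferential),
            (tissue_b, res.b_preferential),
        ):
            query = set(genes_set) & tf_universe
            if not query:
                continue
            df = family_enrichment(query, catalog, universe=tf_universe)
            df.insert(0, "tissue", tissue)
            df.insert(0, "mark", mark)
            enr_frames.append(df)
    if enr_frames:
        pd.concat(enr_frames, ignore_index=True).to_csv(
            outdir / "tf_family_enrichment.tsv", sep="\t", index=False,
            float_format="%.6g"
        )

    # -- transition enrichment of the preferential genes ------------------------
    tr_enr = transition_enrichment(set(pref_genes), transitions)
    tr_enr.to_csv(outdir / "transition_enrichment.tsv", sep="\t", index=False,
                  float_format="%.6g")

    provenance = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "inputs": {
            "genes": str(inputs["genes"]),
            "expression": str(inputs["expression"]),
            "panel": str(inputs["panel"]),
        },
        "n_genes": len(gene_ids),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return {
        "genome": genome,
        "genes": genes,
        "mark_table": mark_table,
        "differential": differential,
        "states": states,
        "transitions": transitions,
        "deg": (deg_a, deg_b),
        "venn": venn,
        "preferential": preferential,
        "clusters": results_clusters.labels if results_clusters else None,
        "transition_enrichment": tr_enr,
    }
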