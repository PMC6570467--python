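"""End-to-end orchestration: simulate -> differential tests -> EC filter ->
KS meta-analysis -> pathway enrichment -> network -> prioritization.

``full_run`` executes the whole workflow on a synthetic compendium and writes
every result table to one output directory. Outputs are a pure function of
the configuration (seed included), so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import bionet, diffstat, ksmeta, litrank, metabofilter, setenrich, synthio
from .synthio import SimConfig

logger = logging.getLogger(__name__)

ALPHA = 0.05
MIN_PER_GROUP = 6
MIN_STUDIES = 3
TANIMOTO_THRESHOLD = 0.7
TOP_N = 50


def load_config(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return SimConfig(**raw)


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> None:
    """Write the simulated compendium and its annotation fixtures as TSV/GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = synthio.simulate_collection(config, "transcript")
    for m in transcripts:
        synthio.write_matrix_tsv(m, outdir / f"transcript_{m.study_id}.tsv")
        synthio.write_labels_tsv(m, outdir / f"labels_{m.study_id}.tsv")
    for platform in ("protein", "metabolite"):
        m, _ = synthio.simulate_study(config, platform, 0)
        synthio.write_matrix_tsv(m, outdir / f"{platform}_S00.tsv")
        synthio.write_labels_tsv(m, outdir / f"labels_{platform}_S00.tsv")
    synthio.write_truth_tsv(truth, outdir / "truth_genes.tsv")
    ann = synthio.simulate_annotations(config)
    synthio.write_ec_tsv(ann.ec_map, outdir / "ec_map.tsv")
    synthio.write_gmt(ann.pathways, outdir / "pathways.gmt")
    synthio.write_fingerprints_tsv(ann.compounds, outdir / "fingerprints.tsv")
    synthio.write_rpairs_tsv(ann.compounds, outdir / "rpairs.tsv")
    synthio.write_counts_tsv(ann.lit_counts, outdir / "lit_counts.tsv")
    ann.protein_gene_map.to_csv(outdir / "protein_gene_map.tsv", sep="\t",
                                index=False)


def full_run(config: SimConfig, outdir: str | Path) -> dict:
    """Run the whole prioritization workflow; returns the result objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diff_dir = outdir / "diff"
    diff_dir.mkdir(exist_ok=True)

    # 1. simulate
    transcripts, truth = synthio.simulate_collection(config, "transcript")
    protein_m, protein_truth = synthio.simulate_study(config, "protein", 0)
    metab_m, metab_truth = synthio.simulate_study(config, "metabolite", 0)
    ann = synthio.simulate_annotations(config)
    synthio.write_truth_tsv(truth, outdir / "truth_genes.tsv")

    # 2. per-study differential statistics
    transcript_diffs = []
    summaries = {}
    for m in transcripts:
        dt = diffstat.run_differential(m, test="welch")
        transcript_diffs.append(dt)
        diffstat.write_diff_tsv(dt, diff_dir / f"transcript_{dt.study_id}.tsv")
        summaries[f"transcript_{dt.study_id}"] = dataclasses.asdict(
            diffstat.summarize_counts(dt, ALPHA))
    protein_kept = diffstat.prevalence_filter(protein_m, MIN_PER_GROUP)
    protein_diff = diffstat.run_differential(protein_kept, test="mwu")
    diffstat.write_diff_tsv(protein_diff, diff_dir / "protein_S00.tsv")
    summaries["protein_S00"] = dataclasses.asdict(
        diffstat.summarize_counts(protein_diff, ALPHA))
    metab_diff = diffstat.run_differential(metab_m, test="mwu")
    diffstat.write_diff_tsv(metab_diff, diff_dir / "metabolite_S00.tsv")
    summaries["metabolite_S00"] = dataclasses.asdict(
        diffstat.summarize_counts(metab_diff, ALPHA))

    # 3. metabolic-gene selection by EC exclusion rules
    ec_ann = metabofilter.annotation_from_frame(ann.ec_map)
    rules = metabofilter.default_rules()
    metabolic_genes = metabofilter.select_metabolic_genes(ec_ann, rules)
    metabofilter.write_gene_set(metabolic_genes, outdir / "metabolic_genes.txt")

    # 4. KS meta-analysis over the metabolic genes
    meta, insufficient = ksmeta.meta_analyze(transcript_diffs, metabolic_genes,
                                             min_studies=MIN_STUDIES)
    ksmeta.write_meta_tsv(meta, outdir / "meta.tsv")
    insufficient.to_csv(outdir / "meta_insufficient.tsv", sep="\t", index=False)

    # 5. multi-omics pathway over-representation (first cohort's omics)
    cohort = transcript_diffs[0].table
    gene_uni = set(cohort["feature"])
    gene_sel = set(cohort.loc[cohort["raw_p"] < ALPHA, "feature"])
    prot_uni = set(protein_diff.table["feature"])
    prot_sel = set(protein_diff.table.loc[
        protein_diff.table["raw_p"] < ALPHA, "feature"])
    met_uni = set(metab_diff.table["feature"])
    met_sel = set(metab_diff.table.loc[
        metab_diff.table["raw_p"] < ALPHA, "feature"])
    pg_map = dict(zip(ann.protein_gene_map["protein"],
                      ann.protein_gene_map["gene"]))
    enrichment, enrich_report = setenrich.multiomics_enrich(
        {"gene": gene_sel, "protein": prot_sel, "metabolite": met_sel},
        {"gene": gene_uni, "protein": prot_uni, "metabolite": met_uni},
        ann.pathways, id_maps={"protein": pg_map})
    setenrich.write_enrich_tsv(enrichment, outdir / "enrichment.tsv")

    # 6. integrated biochemical network (metabolic genes + proteins + compounds)
    net_ec_ann = {g: ec_ann[g] for g in sorted(metabolic_genes)}
    protein_ec = {p: ec_ann[g] for p, g in pg_map.items() if g in net_ec_ann}
    network = bionet.build_network(ann.compounds, net_ec_ann, protein_ec,
                                   [transcript_diffs[0], protein_diff,
                                    metab_diff],
                                   threshold=TANIMOTO_THRESHOLD)
    communities = bionet.detect_communities(network)
    for node, label in communities.items():
        network.nodes[node]["community"] = label
    bionet.export_graph(network, outdir / "network.graphml", fmt="graphml")
    bionet.export_graph(network, outdir / "network.sif", fmt="sif")

    # 7. literature counts and prioritization
    counts = litrank.fetch_counts(sorted(metabolic_genes), source="fixture",
                                  fixture=ann.lit_counts)
    priorities = litrank.prioritize(meta, counts,
                                    diff_gene=transcript_diffs[0],
                                    diff_protein=protein_diff,
                                    protein_gene_map=pg_map,
                                    threshold=litrank.UNDERSTUDIED_DEFAULT,
                                    top_n=TOP_N)
    litrank.write_priority_tsv(priorities, outdir / "priorities.tsv")
    support = litrank.cross_omics_protein_support(protein_diff, meta, counts,
                                                  pg_map, alpha=ALPHA)
    support.to_csv(outdir / "protein_support.tsv", sep="\t", index=False,
                   float_format="%.6g")

    summary = {
        "config": dataclasses.asdict(config),
        "per_study_counts": summaries,
        "n_metabolic_genes": len(metabolic_genes),
        "n_meta_genes": int(len(meta)),
        "n_meta_significant": int((meta["meta_p"] < ALPHA).sum()),
        "n_enriched_pathways": int((enrichment["q"] < ALPHA).sum()),
        "n_unmapped_features": enrich_report.get("n_unmapped", 0),
        "network_nodes": network.number_of_nodes(),
        "network_edges": network.number_of_edges(),
        "n_understudied": int(priorities["understudied"].sum()),
        "n_supported_proteins": int(len(support)),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {
        "truth": truth, "protein_truth": protein_truth,
        "metabolite_truth": metab_truth,
        "transcript_diffs": transcript_diffs, "protein_diff": protein_diff,
        "metabolite_diff": metab_diff, "annotations": ann,
        "metabolic_genes": metabolic_genes, "meta": meta,
        "enrichment": enrichment, "network": network,
        "communities": communities, "counts": counts,
        "priorities": priorities, "protein_support": support,
        "summary": summary,
    }
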