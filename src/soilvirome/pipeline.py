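"""End-to-end synthetic study: curate -> triage -> cluster -> host link ->
AMG screen -> atlas statistics.

`run_study` generates a small synthetic soil-virome survey with known
ground truth, runs the full pipeline on it, writes every intermediate and
final table as TSV/FASTA under an output directory, and returns the key
recovery metrics (planted-cluster ARI, host-assignment accuracy, AMG
category accuracy, occupancy fractions, ...). This is both the package's
smoke test and its worked example.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import align, amg, catalog, cluster, hosts, simulate, stats, triage

__all__ = ["run_study", "adjusted_rand_index"]

_COVARIATES = {
    # field-realistic ranges for soil covariates
    "bulk_density": (0.24, 1.56),
    "cec": (6.8, 71.0),
    "nitrogen": (0.19, 22.4),
    "ph": (4.3, 8.5),
    "soc": (1.9, 510.9),
    "clay": (2.7, 57.1),
}


def adjusted_rand_index(labels_a: dict[str, object], labels_b: dict[str, object]) -> float:
    """ARI between two labelings over the shared key set."""
    from sklearn.metrics import adjusted_rand_score

    keys = sorted(set(labels_a) & set(labels_b))
    if not keys:
        return float("nan")
    return float(
        adjusted_rand_score(
            [str(labels_a[k]) for k in keys], [str(labels_b[k]) for k in keys]
        )
    )


def _make_samples(rng: np.random.Generator, n_keep: int) -> pd.DataFrame:
    rows = []
    for i in range(n_keep):
        row = {
            "sample_id": f"sample{i}",
            "ecosystem_type": "Soil",
            "ecosystem_subtype": "Unclassified",
            "title": f"Grassland soil metagenome {i}",
            "geographic_location": "Prairie site",
            "project_type": "Metagenome",
            "assembled_bp": int(rng.integers(5_000_000, 50_000_000)),
        }
        for cov, (lo, hi) in _COVARIATES.items():
            row[cov] = float(rng.uniform(lo, hi))
        rows.append(row)
    # decoys the curation step must remove
    decoys = [
        {"sample_id": "decoy0", "ecosystem_type": "Deep subsurface"},
        {"sample_id": "decoy1", "ecosystem_subtype": "Wetlands"},
        {"sample_id": "decoy2", "title": "Forest sediment core"},
    ]
    for d in decoys:
        d.setdefault("ecosystem_type", "Soil")
        d.setdefault("ecosystem_subtype", "Unclassified")
        d.setdefault("title", "Soil metagenome")
        d.setdefault("geographic_location", "Site")
        d.setdefault("project_type", "Metagenome")
        d.setdefault("assembled_bp", 1_000_000)
        rows.append(d)
    return pd.DataFrame(rows)


def _make_assessments(
    contigs: dict[str, str], rng: np.random.Generator
) -> list[triage.ViralAssessment]:
    """Realistic classifier output: most genomes accepted across rules,
    a few provirus/low-signal rejects."""
    out = []
    for i, (cid, seq) in enumerate(sorted(contigs.items())):
        mode = i % 8
        a = dict(
            contig_id=cid,
            length=len(seq),
            virus_score=float(rng.uniform(0.5, 0.75)),
            n_hallmarks=0,
            marker_enrichment=float(rng.uniform(0.0, 1.5)),
            checkv_quality="not-determined",
            provirus_flag=False,
            has_dtr=False,
        )
        if mode in (0, 1, 2, 3):  # completeness-based acceptance
            a["checkv_quality"] = rng.choice(["complete", "high", "medium"])
        elif mode == 4 and len(seq) > 10_000:  # long-contig rule
            a["virus_score"] = float(rng.uniform(0.82, 0.98))
            a["n_hallmarks"] = int(rng.integers(1, 3))
        elif mode == 5 and 5_000 < len(seq) <= 10_000:  # mid-length rule
            a["virus_score"] = float(rng.uniform(0.92, 0.99))
            a["n_hallmarks"] = 1
            a["marker_enrichment"] = float(rng.uniform(2.5, 6.0))
        elif mode == 6:
            a["provirus_flag"] = True
        # mode 7 (and mis-sized 4/5): low-signal reject
        out.append(triage.ViralAssessment(**a))
    return out


def _synthetic_aai(
    genome_ids: list[str],
    cluster_of: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """AAI table with genus-level signal inside planted clusters and
    family-level signal between paired clusters (c0-c1, c2-c3, ...)."""
    rows = []
    labels = sorted({cluster_of[g] for g in genome_ids})
    family_of = {lab: i // 2 for i, lab in enumerate(labels)}
    for i, a in enumerate(genome_ids):
        for b in genome_ids[i + 1 :]:
            ca, cb = cluster_of[a], cluster_of[b]
            if ca == cb:
                aai, shared = rng.uniform(42.0, 60.0), rng.uniform(40.0, 90.0)
            elif family_of[ca] == family_of[cb]:
                aai, shared = rng.uniform(22.0, 32.0), rng.uniform(12.0, 18.0)
            else:
                continue
            rows.append(
                {
                    "genome_a": a,
                    "genome_b": b,
                    "aai": float(aai),
                    "shared_gene_fraction": float(shared),
                    "n_hits": 10,
                }
            )
    return pd.DataFrame(rows)


def run_study(
    outdir: str | Path,
    seed: int = 1,
    n_samples: int = 12,
    n_clusters: int = 8,
    cluster_size: int = 5,
    occupancy_shape: tuple[int, int] = (200, 5000),
) -> dict:
    """Run the full pipeline on a generated synthetic study.

    Returns a dict of recovery metrics; writes all inputs/outputs as
    TSV/FASTA under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).spawn(8)
    rng = np.random.default_rng(seeds[0])

    # -- curation ----------------------------------------------------------
    samples = _make_samples(rng, n_samples)
    kept, excluded = catalog.curate_samples(samples)
    catalog.write_tsv(kept, outdir / "samples_kept.tsv")
    catalog.write_tsv(excluded, outdir / "samples_excluded.tsv")
    sample_ids = kept["sample_id"].tolist()

    # -- synthetic genomes + triage ---------------------------------------
    cfg = simulate.SimConfig(
        seed=int(np.random.default_rng(seeds[1]).integers(2**31 - 1)),
        genome_length_range=(5_000, 20_000),
        planted_clusters=[(cluster_size, 97.0, 85.0)] * n_clusters,
    )
    contigs, truth = simulate.make_viral_genomes(cfg)
    catalog.write_fasta(contigs, outdir / "contigs.fasta")
    contig_sample = {
        cid: sample_ids[int(i)]
        for cid, i in zip(sorted(contigs), rng.integers(len(sample_ids), size=len(contigs)))
    }
    assessments = _make_assessments(contigs, rng)
    accepted_ids, decisions = triage.triage_set(assessments)
    catalog.write_tsv(decisions, outdir / "triage_decisions.tsv")
    accepted = {cid: contigs[cid] for cid in accepted_ids}
    catalog.write_fasta(accepted, outdir / "contigs_accepted.fasta")
    lengths = {cid: len(s) for cid, s in accepted.items()}

    # -- species clustering (ANI chain) -----------------------------------
    records = align.local_align_all(accepted)
    ani = align.compute_ani_af(records, lengths)
    catalog.write_tsv(ani, outdir / "ani.tsv")
    votu_graph = cluster.build_votu_graph(ani, sorted(accepted), lengths)
    votus = cluster.leiden_cluster(votu_graph, seed=int(seeds[2].generate_state(1)[0] % 2**31))
    votus.assign_representatives(lengths)
    catalog.write_tsv(votus.to_frame(), outdir / "votu_clusters.tsv")
    votu_ari = adjusted_rand_index(votus.labels, truth.cluster_of)

    # -- genus/family clustering (AAI + MCL) ------------------------------
    aai = _synthetic_aai(sorted(accepted), truth.cluster_of, rng)
    catalog.write_tsv(aai, outdir / "aai.tsv")
    genus, family = cluster.cluster_ranks(aai, sorted(accepted), lengths)
    catalog.write_tsv(genus.to_frame(), outdir / "genus_clusters.tsv")
    catalog.write_tsv(family.to_frame(), outdir / "family_clusters.tsv")
    genus_ari = adjusted_rand_index(genus.labels, truth.cluster_of)
    planted_family = {
        g: sorted({truth.cluster_of[x] for x in accepted}).index(truth.cluster_of[g]) // 2
        for g in accepted
    }
    family_ari = adjusted_rand_index(family.labels, planted_family)

    # -- host linkage ------------------------------------------------------
    spacer_db, lineages = simulate.make_host_db(
        n_hosts=8, spacers_per_host=3, cfg=cfg, hosts_per_genus=2
    )
    catalog.write_fasta(spacer_db.spacers, outdir / "spacers.fasta")
    catalog.write_tsv(lineages, outdir / "host_lineages.tsv")
    implant_rng = np.random.default_rng(seeds[3])
    plan = []
    target_contigs = sorted(accepted)[: min(10, len(accepted))]
    expected_hosts: dict[str, str] = {}  # contig -> planted host genus
    for t, cid in enumerate(target_contigs):
        genus_idx = t % 4
        host_a, host_b = f"host{2 * genus_idx}", f"host{2 * genus_idx + 1}"
        sp_a = f"{host_a}_sp{t % 3}"
        sp_b = f"{host_b}_sp{(t + 1) % 3}"
        pos = 100
        for sp, mm, strand in ((sp_a, 0, "+"), (sp_b, t % 2, "-")):
            plan.append((cid, sp, mm, strand, pos))
            pos += len(spacer_db.spacers[sp]) + 50
        expected_hosts[cid] = f"g{genus_idx}"
    implanted, implant_truth = simulate.implant_protospacers(
        accepted, spacer_db, plan, seed=int(implant_rng.integers(2**31 - 1))
    )
    hits = hosts.spacer_search(spacer_db, implanted, lineages=lineages)
    retained_hits = hosts.filter_hits(hits)
    assignments = hosts.assign_hosts(retained_hits)
    hit_rows = pd.DataFrame([vars(h) | {"lineage": ""} for h in retained_hits])
    catalog.write_tsv(hit_rows, outdir / "spacer_hits.tsv")
    catalog.write_tsv(
        pd.DataFrame([vars(a) for a in assignments]), outdir / "host_assignments.tsv"
    )
    summary = hosts.host_summary(assignments, retained_hits, contig_sample)
    catalog.write_tsv(summary, outdir / "host_summary.tsv")
    assigned = {a.contig_id: a for a in assignments}
    n_correct = sum(
        1
        for cid, g in expected_hosts.items()
        if cid in assigned
        and assigned[cid].rank == "genus"
        and assigned[cid].taxon == g
    )
    host_accuracy = n_correct / len(expected_hosts) if expected_hosts else float("nan")

    # -- AMG screening -----------------------------------------------------
    layout_specs = [
        (["VV-1", "UNCLASSIFIED", "VV-1"], [1]),
        (["VV-1", "HOST", "V*-0"], [2]),
        (["V*-0", "UNCLASSIFIED", "V*-0"], [3]),
        (["UNCLASSIFIED", "VV-1"], [4]),
        (["HOST", "V*-0"], [5]),
    ]
    amg_contigs = sorted(accepted, key=lambda c: -len(accepted[c]))[: len(layout_specs)]
    layouts = {cid: spec[0] for cid, spec in zip(amg_contigs, layout_specs)}
    genes = simulate.make_gene_table(implanted, layouts, cfg.gene_length, cfg.gene_spacing)
    truth_categories: dict[str, int] = {}
    for cid, (layout, cats) in zip(amg_contigs, layout_specs):
        candidates = [
            f"{cid}_g{i}" for i, lab in enumerate(layout) if lab in ("HOST", "UNCLASSIFIED")
        ]
        for gene_id, cat in zip(candidates, cats):
            truth_categories[gene_id] = cat
    pathway_map = {"K01737": ["map00790"], "GT4": ["map00500"], "K10026": ["map00790"]}
    for g in genes:
        if g.marker_label in ("HOST", "UNCLASSIFIED"):
            g.annotations = [("KO", "K01737", 120.0), ("CAZy", "GT4", 90.0)]
    calls, final_amgs = amg.amg_pipeline(genes, pathway_map)
    catalog.write_tsv(amg.genes_to_frame(genes), outdir / "gene_table.tsv")
    catalog.write_tsv(amg.calls_to_frame(calls), outdir / "amg_calls.tsv")
    per_pathway, per_annotation = amg.abundance_tables(final_amgs, contig_sample)
    catalog.write_tsv(per_pathway.reset_index(), outdir / "amg_pathway_abundance.tsv")
    catalog.write_tsv(per_annotation.reset_index(), outdir / "amg_annotation_abundance.tsv")
    call_cat = {c.gene_id: c.category for c in calls}
    amg_accuracy = (
        sum(1 for g, c in truth_categories.items() if call_cat.get(g) == c)
        / len(truth_categories)
        if truth_categories
        else float("nan")
    )

    # -- atlas statistics --------------------------------------------------
    votu_label = votus.labels
    presence = pd.DataFrame(0, index=[f"votu{i}" for i in range(len(votus))], columns=sample_ids)
    for cid in accepted:
        presence.loc[f"votu{votu_label[cid]}", contig_sample[cid]] += 1
    catalog.write_tsv(presence.reset_index(names="attribute"), outdir / "votu_occupancy.tsv")
    study_occ = stats.occupancy_stats(presence)

    occ_seed = int(np.random.default_rng(seeds[4]).integers(2**31 - 1))
    big = simulate.make_occupancy(
        n_samples=occupancy_shape[0], n_attributes=occupancy_shape[1], seed=occ_seed
    )
    atlas_occ = stats.occupancy_stats(big)

    busiest = presence.sum(axis=0).idxmax()
    counts = presence[busiest][presence[busiest] > 0].to_dict()
    total = sum(counts.values())
    depths = sorted({0, total // 4, total // 2, total})
    curve = stats.rarefy(
        counts, depths, n_reps=100, seed=int(np.random.default_rng(seeds[5]).integers(2**31 - 1))
    )
    catalog.write_tsv(curve.to_frame(), outdir / "rarefaction.tsv")

    assembled = dict(zip(kept["sample_id"], kept["assembled_bp"]))
    accum = stats.accumulation_curve(presence, assembled)
    catalog.write_tsv(accum, outdir / "accumulation.tsv")

    cdf = stats.host_ratio_cdf(summary["hit_to_contig_ratio"].tolist())
    catalog.write_tsv(cdf, outdir / "host_ratio_cdf.tsv")

    order_counts = pd.DataFrame(0, index=sorted({r["order"] for r in lineages.to_dict("records")}), columns=sample_ids)
    for h in retained_hits:
        o = h.lineage.get("order")
        s = contig_sample.get(h.contig_id)
        if o and s:
            order_counts.loc[o, s] += 1
    env = kept.set_index("sample_id")[list(_COVARIATES)]
    rho = stats.spearman_host_env(order_counts, env, min_samples=1)
    catalog.write_tsv(rho.reset_index(names="host_order"), outdir / "host_env_spearman.tsv")

    return {
        "n_samples_kept": len(kept),
        "n_genomes": len(contigs),
        "n_accepted": len(accepted),
        "votu_recovery_ari": votu_ari,
        "n_votus": len(votus),
        "genus_recovery_ari": genus_ari,
        "family_recovery_ari": family_ari,
        "n_genus_clusters": len(genus),
        "n_family_clusters": len(family),
        "host_assignment_accuracy": host_accuracy,
        "n_host_assignments": len(assignments),
        "amg_category_accuracy": amg_accuracy,
        "n_final_amgs": len(final_amgs),
        "pct_votus_multisample_study": 100.0 * study_occ["fraction_gt1_sample"],
        "pct_attributes_multisample_atlas_model": 100.0 * atlas_occ["fraction_gt1_sample"],
        "rarefaction_full_depth_richness": curve.mean_richness[-1],
    }
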