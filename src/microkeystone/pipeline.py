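"""End-to-end orchestration: synthesize -> partition -> diversity ->
indicators -> networks -> differential -> integration.

One global seed is expanded deterministically into per-stage seeds, every
stage writes its artifact into the run directory, and a machine-readable
JSON report summarises the run.  Identical configs and seeds produce
byte-identical reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mkio
from .containers import CountTable, SampleMetadata, TraitTable
from .differential import differential_test
from .diversity import alpha_diversity, bray_curtis, pcoa, permanova
from .indicators import indicator_analysis, specificity_occupancy
from .integrate import omics_network, procrustes_test, trait_feature_correlation
from .network import build_network, detect_modules, keystone_nodes, node_centralities, spearman_matrix
from .partition import classify_abundance, prevalence_filter, to_relative_abundance, tmm_factors
from .synthetic import (
    CommunityConfig,
    ExpressionConfig,
    TraitConfig,
    generate_community,
    generate_expression,
    generate_traits,
)

__all__ = ["default_config", "run_pipeline", "stage_seeds"]

STAGES = (
    "synthesize_community",
    "synthesize_expression",
    "synthesize_traits",
    "permanova",
    "indicators",
    "procrustes",
)


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into a deterministic per-stage seed map."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES), dtype=np.uint64)
    return {stage: int(s % (2 ** 31)) for stage, s in zip(STAGES, state)}


def default_config() -> dict:
    return {
        "community": {},          # CommunityConfig overrides
        "expression": {},         # ExpressionConfig overrides
        "rare_cut": 0.001,
        "abundant_cut": 0.01,
        "min_group_prevalence": 0.20,
        "min_total_relabund": 0.025,
        "shannon_log_base": "e",
        "n_permutations": 999,
        "alpha": 0.05,
        "rho_min": 0.6,
        "network_correction": "bh",
        "network_per_group": True,
        "spec_occ_tau": 0.7,
        "diff_pair": ["Control", "HA"],
        "diff_method": "nb_exact",
        "lfc_min": 1.0,
        "fdr_alpha": 0.05,
        "procrustes_axes": 2,
        "omics_r_min": 0.8,
        "omics_alpha": 0.01,
        "trait_r_min": 0.5,
        "trait_alpha": 0.05,
        "trait_cor_min": 0.05,
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = v
    return out


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(
    config: dict | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    counts: CountTable | None = None,
    meta: SampleMetadata | None = None,
    genes: CountTable | None = None,
    traits: TraitTable | None = None,
) -> dict:
    """Run the full analysis chain and return the machine-readable report.

    Without explicit input tables the synthetic generator provides them
    (the default, fully self-contained mode).  If ``outdir`` is given, all
    stage artifacts plus ``report.json`` are written there.
    """
    cfg = _merge(default_config(), config)
    seeds = stage_seeds(seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": seed, "stage_seeds": seeds, "parameters": _round_floats(
        {k: v for k, v in cfg.items() if k not in ("community", "expression")}
    )}

    # --- stage 1: inputs -------------------------------------------------
    truth = None
    if counts is None or meta is None:
        comm_cfg = CommunityConfig(**cfg.get("community", {}))
        counts, meta, truth = generate_community(
            comm_cfg, seed=seeds["synthesize_community"]
        )
        genes = generate_expression(
            truth, ExpressionConfig(**cfg.get("expression", {})),
            seed=seeds["synthesize_expression"],
        )
        traits = generate_traits(truth, TraitConfig(), seed=seeds["synthesize_traits"])
        report["synthetic"] = {
            "hub_id": truth.hub_id,
            "n_indicators": len(truth.indicator_map),
            "n_de_genes": len(truth.de_genes),
            "n_coupled_genes": len(truth.coupling_map),
        }
        if outdir is not None:
            mkio.write_count_table(counts, outdir / "counts.tsv")
            mkio.write_metadata(meta, outdir / "metadata.tsv")
            mkio.write_count_table(genes, outdir / "genes.tsv")
            mkio.write_traits(traits, outdir / "traits.tsv")
            truth.to_json(outdir / "truth.json")
    meta = meta.aligned_to(counts.sample_ids)

    # --- stage 2: partition ---------------------------------------------
    rel = to_relative_abundance(counts)
    filtered = prevalence_filter(
        rel, meta,
        min_group_prevalence=cfg["min_group_prevalence"],
        min_total_relabund=cfg["min_total_relabund"],
    )
    assignment = classify_abundance(
        rel, rare_cut=cfg["rare_cut"], abundant_cut=cfg["abundant_cut"]
    )
    report["partition"] = {
        "n_features": len(rel.feature_ids),
        "n_after_filter": len(filtered.feature_ids),
        "class_counts": assignment.class_counts(),
    }
    if outdir is not None:
        assignment.summary.to_csv(outdir / "classes.tsv", sep="\t")

    # --- stage 3: diversity / ordination --------------------------------
    base = 2.0 if str(cfg["shannon_log_base"]) == "2" else float(np.e)
    diversity = alpha_diversity(counts, log_base=base)
    dist = bray_curtis(rel)
    ordination = pcoa(dist)
    perma = permanova(
        dist, meta, n_permutations=cfg["n_permutations"], seed=seeds["permanova"]
    )
    div_means = diversity.table.groupby(meta.groups).mean()
    report["diversity"] = {
        "shannon_by_group": {g: float(v) for g, v in div_means["shannon"].items()},
        "observed_by_group": {
            g: float(v) for g, v in div_means["observed_features"].items()
        },
        "pcoa_axis1_pct": float(100 * ordination.proportion_explained[0]),
        "pcoa_axis2_pct": float(100 * ordination.proportion_explained[1])
        if len(ordination.proportion_explained) > 1 else 0.0,
        "permanova": {
            "pseudo_f": perma.pseudo_f, "r2": perma.r2, "p": perma.p,
            "n_permutations": perma.n_permutations,
        },
    }
    if outdir is not None:
        diversity.table.to_csv(outdir / "diversity.tsv", sep="\t")
        coords = pd.DataFrame(
            ordination.coordinates[:, :2],
            index=ordination.sample_ids, columns=["PCo1", "PCo2"],
        )
        coords.to_csv(outdir / "pcoa.tsv", sep="\t")

    # --- stage 4: indicators / spec-occ ---------------------------------
    ind = indicator_analysis(
        filtered, meta,
        n_permutations=cfg["n_permutations"], alpha=cfg["alpha"],
        seed=seeds["indicators"],
    )
    spec = specificity_occupancy(filtered, meta, tau=cfg["spec_occ_tau"])
    keys = spec.key_species()
    report["indicators"] = {
        "n_significant": int(ind.table["significant"].sum()),
        "significant": sorted(ind.significant_features()),
        "n_key_species": int(len(keys)),
        "key_species": sorted(
            f"{r.feature_id}@{r.group}" for r in keys.itertuples()
        ),
    }
    if outdir is not None:
        ind.table.to_csv(outdir / "indicators.tsv", sep="\t", index=False)
        spec.table.to_csv(outdir / "spec_occ.tsv", sep="\t", index=False)

    # --- stage 5: co-occurrence networks --------------------------------
    def _network_for(tbl, tag):
        rho, p = spearman_matrix(tbl)
        net = build_network(
            rho, p, rho_min=cfg["rho_min"], alpha=cfg["alpha"],
            correction=cfg["network_correction"],
        )
        net = detect_modules(node_centralities(net))
        ks = keystone_nodes(net)
        if outdir is not None:
            mkio.write_network(net, outdir / f"network_{tag}.tsv")
            net.node_table.to_csv(outdir / f"network_{tag}_nodes.tsv", sep="\t")
            ks.to_csv(outdir / f"keystones_{tag}.tsv", sep="\t", index=False)
        degree_ks = sorted(ks.loc[ks["metric"] == "degree", "node"])
        return {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "n_modules": len({d.get("module") for _, d in net.graph.nodes(data=True)}),
            "keystone_degree": degree_ks,
        }, ks

    networks = {}
    networks["pooled"], pooled_ks = _network_for(filtered, "pooled")
    if cfg["network_per_group"]:
        for g in meta.group_names:
            sub = filtered.subset_samples(meta.samples_in(g))
            networks[g], _ = _network_for(sub, g)
    report["networks"] = networks

    # --- stage 6: differential ------------------------------------------
    pair = tuple(cfg["diff_pair"])
    diff_micro = differential_test(
        counts, meta, pair, method=cfg["diff_method"], mode="microbiome",
        lfc_min=cfg["lfc_min"], alpha=cfg["alpha"], fdr_alpha=cfg["fdr_alpha"],
    )
    report["differential"] = {
        "pair": list(pair),
        "n_significant_asv": int(diff_micro.table["significant"].sum()),
    }
    if outdir is not None:
        diff_micro.table.to_csv(outdir / "differential_asv.tsv", sep="\t", index=False)
    diff_genes = None
    if genes is not None:
        diff_genes = differential_test(
            genes, meta, pair, method=cfg["diff_method"], mode="gene",
            lfc_min=cfg["lfc_min"], alpha=cfg["alpha"], fdr_alpha=cfg["fdr_alpha"],
        )
        report["differential"]["n_significant_genes"] = int(
            diff_genes.table["significant"].sum()
        )
        if outdir is not None:
            diff_genes.table.to_csv(
                outdir / "differential_genes.tsv", sep="\t", index=False
            )

    # --- stage 7: integration -------------------------------------------
    if genes is not None and traits is not None:
        gene_factors = tmm_factors(genes)
        from .differential import normalized_cpm

        gene_cpm = np.log2(normalized_cpm(genes, gene_factors))
        # PCA of gene expression == PCoA of Euclidean distances
        from scipy.spatial.distance import pdist, squareform
        from .diversity import DistanceMatrix

        gdist = DistanceMatrix(
            sample_ids=genes.sample_ids,
            data=squareform(pdist(gene_cpm.to_numpy().T)),
        )
        gene_ord = pcoa(gdist)
        proc = procrustes_test(
            ordination, gene_ord, n_axes=cfg["procrustes_axes"],
            n_permutations=cfg["n_permutations"], seed=seeds["procrustes"],
        )
        report["procrustes"] = {
            "m2": proc.m2, "t": proc.t_stat, "p": proc.p,
            "n_permutations": proc.n_permutations,
        }

        key_taxa = sorted(set(keys["feature_id"]))
        sig_genes = sorted(diff_genes.table.loc[diff_genes.table["significant"], "feature_id"]) if diff_genes is not None else []
        if key_taxa and sig_genes:
            net = omics_network(
                rel.data.loc[key_taxa], gene_cpm.loc[sig_genes], traits,
                r_min=cfg["omics_r_min"], alpha=cfg["omics_alpha"],
                trait_r_min=cfg["trait_r_min"], trait_alpha=cfg["trait_alpha"],
            )
            report["omics_network"] = {
                "n_key_taxa": len(key_taxa),
                "n_selected_genes": len(sig_genes),
                "n_taxa_gene_edges": len(net.edges_between("taxon", "gene")),
                "n_taxa_trait_edges": len(net.edges_between("taxon", "trait")),
                "n_gene_trait_edges": len(net.edges_between("gene", "trait")),
            }
            if outdir is not None:
                mkio.write_network(net, outdir / "omics_network.tsv")
        tfc = trait_feature_correlation(
            gene_cpm, traits, cor_min=cfg["trait_cor_min"], alpha=cfg["alpha"]
        )
        report["trait_gene_filter"] = {"n_pass": int(tfc["pass"].sum())}
        if outdir is not None:
            tfc.to_csv(outdir / "trait_gene_correlation.tsv", sep="\t", index=False)

    report = _round_floats(report)
    if outdir is not None:
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
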