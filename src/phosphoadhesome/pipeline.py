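"""Pipeline orchestration: config, demo fixture generation, run-all.

A run is fully determined by a declarative config (paths + thresholds +
seed); every stage output is a TSV whose header comment names the producing
stage, the config hash and the seed, and a JSON manifest records counts
in and out of each filter.  No stage reads hidden state, so two runs with
the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, kinase, merge, network, simulate, terms
from .io import (
    AdhesomeAnnotation,
    read_adhesome,
    read_edge_list,
    read_phosphosites,
    read_spectral_counts,
    read_term_map,
    write_adhesome,
    write_edge_list,
    write_phosphosites,
    write_term_map,
)

logger = logging.getLogger(__name__)

STAGES = ["normalize", "filter", "merge", "network", "terms", "kinases"]


@dataclass
class PipelineConfig:
    """All inputs and knobs for one reproducible run."""

    counts_path: str
    sites_path: str
    edges_path: str
    out_dir: str
    extra_edges_path: str | None = None
    adhesome_path: str | None = None
    term_map_path: str | None = None
    term_names_path: str | None = None
    kinase_library_path: str | None = None
    matrix_path: str | None = None
    policy: enrichment.ThresholdPolicy = field(default_factory=enrichment.ThresholdPolicy)
    seed_node: str | None = None
    max_hop: int = 3
    restrict_to_detected: bool = True
    alpha: float = 0.05
    min_count: int = 2
    term_variant: str = "ease"
    target_fpr_st: float = 0.02
    target_fpr_y: float = 0.04
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("policy"), dict):
            d["policy"] = enrichment.ThresholdPolicy(**d["policy"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate(self) -> None:
        """Check every referenced input path exists before any stage runs."""
        for name in (
            "counts_path", "sites_path", "edges_path", "extra_edges_path",
            "adhesome_path", "term_map_path", "term_names_path",
            "kinase_library_path", "matrix_path",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config {name}: {value!r} does not exist")


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg: PipelineConfig) -> None:
    header = f"# stage={stage}; config={cfg.config_hash()}; seed={cfg.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to out_dir).

    Stage order: normalize → filter → merge → network → terms → kinases.
    A failure in any stage aborts with the stage named in the exception.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "policy": dataclasses.asdict(config.policy),
        "stages": [],
    }
    summary: list[str] = []
    stage = "setup"
    try:
        matrix = read_spectral_counts(config.counts_path)
        records, site_runs = read_phosphosites(config.sites_path)

        stage = "normalize"
        nsaf = enrichment.normalize(matrix)
        nsaf_out = nsaf.reset_index().rename(columns={"index": "accession"})
        _write_tsv(nsaf_out, out / "nsaf.tsv", stage, config)
        manifest["stages"].append({"name": stage, "n_proteins": len(nsaf)})

        stage = "filter"
        prot_results = enrichment.filter_proteins(
            enrichment.protein_fold_changes(nsaf, matrix, config.policy), config.policy
        )
        site_results, site_threshold = enrichment.filter_sites(
            records, site_runs, config.policy
        )
        prot_pass = enrichment.passing_ids(prot_results)
        site_pass_ids = enrichment.passing_ids(site_results)
        site_pass = [
            r for r in records if f"{r.accession}:{r.position}" in site_pass_ids
        ]
        _write_tsv(
            enrichment.results_frame(prot_results), out / "protein_enrichment.tsv", stage, config
        )
        _write_tsv(
            enrichment.results_frame(site_results), out / "site_enrichment.tsv", stage, config
        )
        manifest["stages"].append(
            {
                "name": stage,
                "proteins_in": len(prot_results),
                "proteins_passing": len(prot_pass),
                "sites_in": len(site_results),
                "sites_passing": len(site_pass),
                "site_fold_threshold": site_threshold,
            }
        )
        summary.append(f"proteins passing subtractive filter: {len(prot_pass)}/{len(prot_results)}")
        summary.append(
            f"sites passing subtractive filter: {len(site_pass)}/{len(site_results)} "
            f"(fold threshold {site_threshold:.2f})"
        )

        stage = "merge"
        catalogue = merge.merge_catalogues(prot_pass, site_pass)
        comp_all = merge.residue_composition(site_pass, label="all_passing")
        venn = {
            "proteomic_only": len(catalogue.proteomic_only),
            "phospho_only": len(catalogue.phospho_only),
            "both": len(catalogue.both),
            "total": catalogue.total,
            "increase_pct": round(catalogue.increase_pct, 1),
        }
        adhesome_summary = None
        if config.adhesome_path:
            annotation = read_adhesome(config.adhesome_path)
            adhesome_summary = merge.crossref_adhesome(catalogue, annotation)
        else:
            annotation = AdhesomeAnnotation(categories={})
        cat_df = pd.DataFrame(
            {
                "accession": sorted(catalogue.all_accessions),
                "compartment": [
                    "proteomic_only"
                    if a in catalogue.proteomic_only
                    else ("phospho_only" if a in catalogue.phospho_only else "both")
                    for a in sorted(catalogue.all_accessions)
                ],
                "n_sites": [
                    len(catalogue.sites_by_protein.get(a, []))
                    for a in sorted(catalogue.all_accessions)
                ],
            }
        )
        _write_tsv(cat_df, out / "merged_catalogue.tsv", stage, config)
        manifest["stages"].append(
            {
                "name": stage,
                "venn": venn,
                "residue_counts": [comp_all.n_s, comp_all.n_t, comp_all.n_y],
                "residue_pct": list(comp_all.percentages()),
                "adhesome": dataclasses.asdict(adhesome_summary) if adhesome_summary else None,
            }
        )
        summary.append(
            f"merged catalogue: {catalogue.total} proteins "
            f"({len(catalogue.phospho_only)} phospho-only; +{venn['increase_pct']}%)"
        )
        pS, pT, pY = comp_all.percentages()
        summary.append(f"residue composition of passing sites: S {pS}% / T {pT}% / Y {pY}%")

        stage = "network"
        edges = read_edge_list(config.edges_path)
        extra = read_edge_list(config.extra_edges_path) if config.extra_edges_path else None
        seed_node = config.seed_node
        hop_rows = []
        if seed_node is not None:
            detected = catalogue.all_accessions | {seed_node}
            graph = network.build_graph(
                edges,
                extra_edges=extra,
                detected=detected,
                sites=site_pass,
                annotation=annotation,
                restrict_to_detected=config.restrict_to_detected,
            )
            decomp = network.hop_distances(graph, seed_node)
            comps = network.hop_composition(decomp, site_pass, max_hop=config.max_hop)
            for k in range(1, config.max_hop + 1):
                band = comps["cumulative"][k]
                pS, pT, pY = band.percentages()
                hop_rows.append(
                    {
                        "band": band.label,
                        "n_proteins": len(decomp.neighbourhood(k)),
                        "n_sites": band.total,
                        "pS": pS,
                        "pT": pT,
                        "pY": pY,
                    }
                )
            _write_tsv(pd.DataFrame(hop_rows), out / "hop_composition.tsv", stage, config)
            network.export_graph(graph, out / "network.graphml", decomp, format="graphml")
            network.export_graph(graph, out / "network.sif", decomp, format="sif")
            manifest["stages"].append(
                {
                    "name": stage,
                    "n_nodes": graph.number_of_nodes(),
                    "n_edges": graph.number_of_edges(),
                    "hop_bands": hop_rows,
                }
            )
            summary.append(
                "cumulative pY% by hop band: "
                + ", ".join(f"<= {r['band'].split('_')[1]} hops: {r['pY']}%" for r in hop_rows)
            )
        else:
            manifest["stages"].append({"name": stage, "skipped": "no seed_node configured"})

        stage = "terms"
        if config.term_map_path:
            term_map = read_term_map(config.term_map_path, names_path=config.term_names_path)
            query = catalogue.phospho_set & term_map.universe
            hits = terms.enrich(
                query,
                term_map,
                alpha=config.alpha,
                min_count=config.min_count,
                variant=config.term_variant,
            )
            tdf = pd.DataFrame(
                [
                    {
                        "term_id": t.term_id,
                        "name": t.name,
                        "count": t.count,
                        "universe_count": t.universe_count,
                        "enrichment": round(t.enrichment_ratio, 3),
                        "p_raw": t.p_raw,
                        "p_corrected": t.p_corrected,
                        "neglog10_p_corrected": round(t.neglog10_p_corrected, 3),
                    }
                    for t in hits
                ],
                columns=[
                    "term_id", "name", "count", "universe_count",
                    "enrichment", "p_raw", "p_corrected", "neglog10_p_corrected",
                ],
            )
            _write_tsv(tdf, out / "enriched_terms.tsv", stage, config)
            manifest["stages"].append(
                {"name": stage, "n_query": len(query), "n_enriched_terms": len(hits)}
            )
            summary.append(f"enriched terms at alpha={config.alpha}: {len(hits)}")
        else:
            manifest["stages"].append({"name": stage, "skipped": "no term map configured"})

        stage = "kinases"
        if True:  # bundled synthetic library is the fallback, so always runs
            models = kinase.load_kinase_library(config.kinase_library_path)
            matrix_tab = kinase.load_substitution_matrix(config.matrix_path)
            rng = np.random.default_rng(config.seed)
            # calibration background: windows of non-passing candidate sites,
            # topped up with simulated proteome windows to the required depth
            background = [
                r.window for r in records if f"{r.accession}:{r.position}" not in site_pass_ids
            ]
            for rclass in ("ST", "Y"):
                have = sum(1 for w in background if w[7] in rclass)
                need = max(0, 500 - have)
                background += kinase.random_background_windows(need, rclass, rng)
            kinase.calibrate_all(
                models,
                background,
                matrix_tab,
                {"ST": config.target_fpr_st, "Y": config.target_fpr_y},
            )
            predictions = kinase.predict(site_pass, models, matrix_tab)
            pdf = pd.DataFrame(
                [
                    {
                        "accession": p.accession,
                        "position": p.position,
                        "kinase": p.kinase_id,
                        "score": round(p.score, 3),
                        "cutoff": round(p.threshold, 3),
                    }
                    for p in predictions
                ],
                columns=["accession", "position", "kinase", "score", "cutoff"],
            )
            _write_tsv(pdf, out / "kinase_predictions.tsv", stage, config)
            n_predicted_sites = len({(p.accession, p.position) for p in predictions})
            manifest["stages"].append(
                {
                    "name": stage,
                    "n_models": len(models),
                    "n_sites_scored": len(site_pass),
                    "n_sites_with_prediction": n_predicted_sites,
                    "thresholds": {m.kinase_id: m.threshold for m in models},
                }
            )
            pct = 100.0 * n_predicted_sites / len(site_pass) if site_pass else 0.0
            summary.append(
                f"sites with a predicted kinase: {n_predicted_sites}/{len(site_pass)} ({pct:.0f}%)"
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    for line in summary:
        logger.info(line)
    return manifest


def make_demo(seed: int, out_dir: str | Path, n_proteins: int = 300) -> PipelineConfig:
    """Generate a complete synthetic input set plus ground truth and config.

    Produces an interactome, a count matrix with designed enriched proteins,
    a phosphosite table with hop-structured residues and planted kinase
    motifs, an adhesome annotation over seed-proximal proteins, and a term
    map containing one designed adhesion-like term — everything the full
    pipeline needs, with the truth recorded alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = simulate.SimulationDesign(
        n_proteins=n_proteins,
        n_enriched=max(10, n_proteins // 5),
        seed=seed,
    )
    graph = simulate.simulate_interactome(n_proteins, attachment_parameter=2, seed=seed)
    seed_node = max(graph.degree, key=lambda kv: kv[1])[0]

    matrix, count_truth = simulate.simulate_counts(design)
    models = kinase.load_kinase_library()
    records, site_truth = simulate.simulate_phosphosites(
        design,
        graph,
        seed_node,
        n_sites=max(100, n_proteins),
        kinase_models=models,
        motif_fraction=0.5,
        mutation_prob=0.1,
        rng=np.random.default_rng(seed + 1),
    )
    runs = matrix.runs

    hops = network.hop_distances(graph, seed_node).hops
    near = sorted(a for a, h in hops.items() if 0 < h <= 2)
    cats = sorted(np.random.default_rng(seed + 2).permutation(near)[: max(20, len(near) // 4)])
    categories = {}
    cat_pool = ["receptor", "adaptor", "actin_regulator", "kinase", "phosphatase", "GEF", "GAP"]
    for i, acc in enumerate(cats):
        categories[acc] = cat_pool[i % len(cat_pool)]
    annotation = AdhesomeAnnotation(categories=categories)

    universe = set(matrix.proteins)
    site_accs = sorted({r.accession for r in records})
    term_rng = np.random.default_rng(seed + 3)
    term_sets: dict[str, set[str]] = {}
    adh_members = set(term_rng.choice(site_accs, size=min(30, len(site_accs)), replace=False))
    adh_members |= set(term_rng.choice(sorted(universe), size=10, replace=False))
    term_sets["T_ADHESION"] = adh_members
    for i in range(12):
        size = int(term_rng.integers(8, 40))
        term_sets[f"T{i:02d}"] = set(term_rng.choice(sorted(universe), size=size, replace=False))
    from .io import TermAnnotationMap

    term_map = TermAnnotationMap(terms=term_sets, universe=universe)

    matrix.write(out / "counts.tsv")
    write_phosphosites(records, runs, out / "sites.tsv")
    write_edge_list(graph, out / "edges.tsv")
    write_adhesome(annotation, out / "adhesome.tsv")
    write_term_map(term_map, out / "terms.tsv")
    count_truth.site_truth = site_truth.site_truth
    count_truth.write(out / "ground_truth.json")
    (out / "seed_node.txt").write_text(seed_node + "\n")

    config = PipelineConfig(
        counts_path=str(out / "counts.tsv"),
        sites_path=str(out / "sites.tsv"),
        edges_path=str(out / "edges.tsv"),
        adhesome_path=str(out / "adhesome.tsv"),
        term_map_path=str(out / "terms.tsv"),
        out_dir=str(out / "results"),
        seed_node=seed_node,
        seed=seed,
    )
    config.write_yaml(out / "config.yaml")
    return config
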