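"""End-to-end orchestration: simulate -> identify-lncrna -> de -> cis-pairs ->
predict-targets -> network -> enrich, from one YAML-able config.

Each stage reads the files written by its predecessors (the same files the
CLI subcommands exchange), records its input/output paths and record counts
in a RunManifest, and the whole run is deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import catalog as cat
from . import cis
from . import enrichment as enr
from . import expression as expr
from . import network as net
from . import simulate as sim
from . import targets as tgt


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_THRESHOLDS: dict[str, float] = {
    "lncrna_length_min": 200,
    "lncrna_min_exons": 2,
    "orf_min": 300,
    "orf_cov_min": 0.35,
    "cis_max_dist": 10_000,
    "trans_r_min": 0.95,
    "de_alpha": 0.05,
    "de_lfc_min": 1.0,
    "pseudocount": 1.0,
    "score_min": 80.0,
    "energy_max": -7.0,
    "min_expr": 0.0,
    "enrich_alpha": 0.05,
}

REQUIRED_KEYS = ("seed", "simulation", "thresholds", "contrasts")


def default_config(seed: int = 0) -> dict[str, Any]:
    """Full default configuration; every threshold is a named key."""
    simulation = dataclasses.asdict(sim.SimulationConfig(seed=seed))
    simulation["groups"] = list(simulation["groups"])
    simulation["term_size_range"] = list(simulation["term_size_range"])
    return {
        "seed": seed,
        "simulation": simulation,
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "contrasts": list(sim.CONTRASTS),
        "random_pairs": 2000,
    }


def load_config(source: str | Path | dict[str, Any]) -> dict[str, Any]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            config = yaml.safe_load(fh)
    else:
        config = dict(source)
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise KeyError(f"missing config keys: {missing}")
    config.setdefault("random_pairs", 2000)
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(config["thresholds"] or {})
    config["thresholds"] = thresholds
    return config


def _config_hash(config: dict[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _simulation_config(config: dict[str, Any]) -> sim.SimulationConfig:
    params = dict(config["simulation"])
    params["groups"] = tuple(params.get("groups", sim.SimulationConfig.groups))
    params["term_size_range"] = tuple(
        params.get("term_size_range", sim.SimulationConfig.term_size_range)
    )
    params.setdefault("seed", config["seed"])
    return sim.SimulationConfig(**params)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict[str, Any]] = field(default_factory=list)

    def record(self, name: str, inputs: list[Path], outputs: list[Path], counts: dict[str, int]) -> None:
        for p in inputs:
            if not Path(p).exists():
                raise PipelineError(f"stage {name}: missing input {p}")
        self.stages.append(
            {
                "name": name,
                "inputs": [str(p) for p in inputs],
                "outputs": [str(p) for p in outputs],
                "n_records": counts,
            }
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )


def _contrast_pair(label: str) -> tuple[str, str]:
    high, low = label.split(":")
    return high, low


def _contrast_tag(label: str) -> str:
    return label.replace(":", "_")


def run_pipeline(
    config: str | Path | dict[str, Any], out_dir: str | Path
) -> RunManifest:
    """Execute all seven stages in dependency order; returns the manifest.

    Raises PipelineError naming the failing stage; partial outputs are left
    in place for inspection.
    """
    config = load_config(config)
    th = config["thresholds"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(config), int(config["seed"]))

    def run_stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage {name} failed: {err}") from err

    # -- 1. simulate --------------------------------------------------------
    def stage_simulate():
        dataset = sim.generate_dataset(_simulation_config(config))
        paths = sim.write_dataset(dataset, out / "data")
        manifest.record(
            "simulate",
            [],
            list(paths.values()),
            {
                "transcripts": len(dataset.catalog),
                "mirnas": len(dataset.mirnas),
                "true_triads": len(dataset.truth.true_triads),
                "samples": len(dataset.design),
            },
        )
        return paths

    data = run_stage("simulate", stage_simulate)

    # -- 2. identify-lncrna -------------------------------------------------
    def stage_identify():
        catalog = cat.load_catalog(data["gtf"], data["transcripts"])
        reports = cat.catalog_reports(
            catalog, orf_min=int(th["orf_min"]), cov_min=float(th["orf_cov_min"])
        )
        lncrna_ids = cat.filter_lncrnas(
            catalog,
            reports,
            length_min=int(th["lncrna_length_min"]),
            min_exons=int(th["lncrna_min_exons"]),
        )
        classes = cat.classify_lncrnas(sorted(lncrna_ids), catalog)
        summary, rows = cat.feature_summary(lncrna_ids, catalog, reports)
        lnc_dir = out / "lncrna"
        lnc_dir.mkdir(exist_ok=True)
        paths = {
            "ids": lnc_dir / "lncrna_ids.tsv",
            "classes": lnc_dir / "classes.tsv",
            "reports": lnc_dir / "coding_potential.tsv",
            "summary": lnc_dir / "summary.tsv",
            "rows": lnc_dir / "features.tsv",
        }
        pd.Series(sorted(lncrna_ids), name="transcript_id").to_csv(
            paths["ids"], sep="\t", index=False
        )
        pd.Series(classes, name="lncrna_class").rename_axis("transcript_id").sort_index().to_frame().to_csv(
            paths["classes"], sep="\t"
        )
        pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "longest_orf_nt": r.longest_orf_nt,
                    "orf_coverage": r.orf_coverage,
                    "hexamer_score": r.hexamer_score,
                    "orf_verdict": r.verdicts["orf"],
                    "hexamer_verdict": r.verdicts["hexamer"],
                }
                for r in sorted(reports.values(), key=lambda r: r.transcript_id)
            ]
        ).to_csv(paths["reports"], sep="\t", index=False)
        pd.Series(summary).rename_axis("statistic").to_frame("value").to_csv(
            paths["summary"], sep="\t"
        )
        rows.to_csv(paths["rows"], sep="\t")
        manifest.record(
            "identify-lncrna",
            [data["gtf"], data["transcripts"]],
            list(paths.values()),
            {
                "lncrnas": len(lncrna_ids),
                "antisense": sum(1 for c in classes.values() if c == "antisense"),
                "intergenic": sum(1 for c in classes.values() if c == "intergenic"),
            },
        )
        return catalog, sorted(lncrna_ids), classes

    catalog, lncrna_ids, _classes = run_stage("identify-lncrna", stage_identify)

    # -- 3. de --------------------------------------------------------------
    def stage_de():
        counts = pd.read_csv(data["counts"], sep="\t", index_col=0)
        design = pd.read_csv(data["design"], sep="\t", index_col=0)["group"]
        lengths = pd.read_csv(data["lengths"], sep="\t", index_col=0)["length"].to_dict()
        matrix = expr.ExpressionMatrix(counts, design, unit="count")
        fpkm = expr.compute_fpkm(matrix, lengths)
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        fpkm_path = de_dir / "fpkm.tsv"
        fpkm.values.to_csv(fpkm_path, sep="\t")
        de_frames = {}
        paths = [fpkm_path]
        n_sig = {}
        for label in config["contrasts"]:
            de = expr.differential_expression(
                fpkm,
                _contrast_pair(label),
                alpha=float(th["de_alpha"]),
                lfc_min=float(th["de_lfc_min"]),
                pseudocount=float(th["pseudocount"]),
            )
            p = de_dir / f"de_{_contrast_tag(label)}.tsv"
            de.to_csv(p, sep="\t")
            paths.append(p)
            de_frames[label] = de
            n_sig[label] = int(de["significant"].sum())
        manifest.record(
            "de",
            [data["counts"], data["design"], data["lengths"]],
            paths,
            {"features": len(counts), **{f"significant_{k}": v for k, v in n_sig.items()}},
        )
        return fpkm, de_frames

    fpkm, de_frames = run_stage("de", stage_de)

    # -- 4. cis-pairs -------------------------------------------------------
    def stage_cis():
        pairs = cis.find_neighbors(catalog, lncrna_ids, max_dist=int(th["cis_max_dist"]))
        gene_expr = cis.gene_level_expression(fpkm.values, catalog)
        orientations = {
            (p.feature_a, p.feature_b): cis.classify_orientation(p, catalog)
            for p in pairs
        }
        with_r, dropped = cis.pair_correlations(pairs, gene_expr)
        coding_genes = sorted(
            {t.gene_id for t in catalog if t.declared_biotype == "protein_coding"}
        )
        null_pairs, null_dropped = cis.random_pair_null(
            gene_expr, coding_genes, int(config["random_pairs"]), int(config["seed"])
        )
        cis_dir = out / "cis"
        cis_dir.mkdir(exist_ok=True)
        pair_path = cis_dir / "pairs.tsv"
        pd.DataFrame(
            [
                {
                    "feature_a": p.feature_a,
                    "feature_b": p.feature_b,
                    "pair_class": p.pair_class,
                    "orientation": orientations.get((p.feature_a, p.feature_b)),
                    "distance": p.distance,
                    "pearson_r": p.pearson_r,
                }
                for p in with_r
            ],
            columns=["feature_a", "feature_b", "pair_class", "orientation", "distance", "pearson_r"],
        ).to_csv(pair_path, sep="\t", index=False)
        summary = {"n_pairs": len(with_r), "n_dropped": dropped, "n_null_dropped": null_dropped}
        null_r = [p.pearson_r for p in null_pairs]
        for klass in ("coding-coding", "lncRNA-coding"):
            r = [p.pearson_r for p in with_r if p.pair_class == klass]
            if len(r) >= 2 and len(null_r) >= 2:
                mean_a, mean_b, p_val = cis.compare_correlation_distributions(r, null_r)
                summary[f"mean_r_{klass}"] = mean_a
                summary[f"p_vs_random_{klass}"] = p_val
        if null_r:
            summary["mean_r_random"] = float(pd.Series(null_r).mean())
        summary_path = cis_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest.record(
            "cis-pairs",
            [data["gtf"]],
            [pair_path, summary_path],
            {"neighbor_pairs": len(with_r), "random_pairs": len(null_pairs)},
        )
        return with_r, null_pairs

    run_stage("cis-pairs", stage_cis)

    # -- 5. predict-targets -------------------------------------------------
    def stage_targets():
        mirnas = sim.load_mirna_fasta(data["mirnas"])
        regions = tgt.target_search_regions(catalog, lncrna_ids)
        sites = tgt.predict_targets(
            mirnas,
            regions,
            score_min=float(th["score_min"]),
            energy_max=float(th["energy_max"]),
        )
        tdir = out / "targets"
        tdir.mkdir(exist_ok=True)
        site_path = tdir / "targets.tsv"
        tgt.sites_to_frame(sites).to_csv(site_path, sep="\t", index=False)
        manifest.record(
            "predict-targets",
            [data["mirnas"], data["gtf"], data["transcripts"]],
            [site_path],
            {"sites": len(sites), "mirnas": len(mirnas)},
        )
        return sites

    sites = run_stage("predict-targets", stage_targets)

    # -- 6. network ---------------------------------------------------------
    def stage_network():
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        coding = set(catalog.coding_ids())
        lnc_set = set(lncrna_ids)
        mirna_ids = {s.mirna_id for s in sites} | {
            m.mirna_id for m in sim.load_mirna_fasta(data["mirnas"])
        }
        all_triads = []
        all_paths = []
        counts = {}
        mm_query_genes: set[str] = set()
        for label in config["contrasts"]:
            directions = expr.de_directions(de_frames[label])
            de_mirnas = {f: d for f, d in directions.items() if f in mirna_ids}
            de_mrnas = {f: d for f, d in directions.items() if f in coding}
            de_lncrnas = {f: d for f, d in directions.items() if f in lnc_set}
            mm = net.negative_mirna_mrna_edges(de_mirnas, de_mrnas, sites, label)
            lm = net.negative_lncrna_mirna_edges(de_lncrnas, de_mirnas, sites, label)
            triads = net.assemble_triads(mm, lm)
            paths = net.export_network(
                mm + lm, triads, net_dir, prefix=f"net_{_contrast_tag(label)}"
            )
            all_paths.extend(paths.values())
            all_triads.extend(triads)
            counts[f"edges_{label}"] = len(mm) + len(lm)
            counts[f"triads_{label}"] = len(triads)
            mm_query_genes |= {e.partner_id for e in mm}
        truth = sim.GroundTruth.from_json(data["truth"])
        evaluation = net.evaluate_triads(all_triads, truth.true_triads)
        eval_path = net_dir / "evaluation.json"
        eval_path.write_text(json.dumps(evaluation, indent=1, sort_keys=True))
        all_paths.append(eval_path)
        manifest.record(
            "network",
            [data["truth"]],
            all_paths,
            {**counts, "triads_total": len(all_triads)},
        )
        return all_triads, sorted(mm_query_genes), evaluation

    _triads, query_genes, _evaluation = run_stage("network", stage_network)

    # -- 7. enrich ----------------------------------------------------------
    def stage_enrich():
        term_map = enr.read_gmt(data["terms"])
        background = sorted({g for _, genes in term_map.values() for g in genes})
        query = [g for g in query_genes if g in set(background)]
        results = enr.enrich(
            query, background, term_map, alpha=float(th["enrich_alpha"])
        )
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        path = enr_dir / "enrichment.tsv"
        enr.enrichment_to_frame(results).to_csv(path, sep="\t", index=False)
        manifest.record(
            "enrich",
            [data["terms"]],
            [path],
            {
                "terms_tested": len(results),
                "significant": sum(r.significant for r in results),
                "query_genes": len(query),
            },
        )

    run_stage("enrich", stage_enrich)

    manifest.to_json(out / "manifest.json")
    return manifest
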