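"""End-to-end orchestration: run every stage and emit one aggregated report.

A run is driven by a small (YAML) configuration with sections::

    seed: 1
    outdir: out
    simulate: {n_proteins: 2000, cv: 0.05, ...}     # or
    inputs: {quant: quant.tsv, sample_map: design.tsv}
    deps: {alpha: 0.05, use_fdr: true, log_transform: true}
    classify: {mode: literal, upper: 1.5, lower: 0.67, band: 0.10}
    trait: {path: trait.csv}                        # or
    trait: {simulate: {means: {P1: 0.47, P2: 0.52, F1: 0.76}, cv: 0.05, n_replicates: 3}}
    term_map: terms.tsv                             # optional
    cluster: {standardize: false}                   # optional

All stage outputs are written as TSV next to a single ``report.json`` that
aggregates the three comparison summaries, the Venn partition, the pattern
summary, the heterosis block and every setting in effect; two runs with the
same configuration and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from contextlib import contextmanager
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .deps import call_deps, significant_ids, summarize_comparison
from .errors import HeteroprotError
from .heterosis import heterosis_from_table, trait_significance
from .patterns import PatternParams, calls_to_frame, classify_all, summarize_patterns
from .sets import cluster_rows, enrich_terms, shared_fraction, venn_partition
from .simulate import SimConfig, simulate_quant, simulate_trait

COMPARISONS = {
    "parent_vs_parent": ("female_parent", "male_parent"),
    "hybrid_vs_female": ("hybrid", "female_parent"),
    "hybrid_vs_male": ("hybrid", "male_parent"),
}


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:  # tag failures with the stage that raised them
        raise HeteroprotError(f"stage {name!r} failed: {exc}") from exc


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise HeteroprotError("run configuration must be a mapping")
    return config


def run_all(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline per ``config``; returns the aggregated report."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "heteroprot_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    with _stage("input"):
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            sim = SimConfig(**sim_kwargs)
            matrix, truth = simulate_quant(sim)
            hio.write_quant_table(matrix, outdir / "quant.tsv", outdir / "sample_map.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        elif "inputs" in config:
            inputs = config["inputs"]
            matrix = hio.read_quant_table(inputs["quant"], inputs["sample_map"])
        else:
            raise HeteroprotError("config needs a 'simulate' or 'inputs' section")
        matrix = matrix.complete_cases()
        n_quantified = matrix.n_proteins

    dep_cfg = dict(config.get("deps") or {})
    alpha = float(dep_cfg.get("alpha", 0.05))
    use_fdr = bool(dep_cfg.get("use_fdr", True))
    log_transform = bool(dep_cfg.get("log_transform", True))

    records, summaries, sig = {}, {}, {}
    with _stage("dep_detection"):
        for name, comparison in COMPARISONS.items():
            rec = call_deps(matrix, comparison, alpha=alpha, use_fdr=use_fdr,
                            log_transform=log_transform)
            rec.to_csv(outdir / f"deps_{name}.tsv", sep="\t", index=False)
            records[name] = rec
            summaries[name] = summarize_comparison(rec, n_quantified)
            sig[name] = significant_ids(rec)

    with _stage("venn"):
        venn = venn_partition(sig["parent_vs_parent"], sig["hybrid_vs_female"],
                              sig["hybrid_vs_male"])
        venn_block = dataclasses.asdict(venn)
        if venn.size("a") > 0:
            venn_block["pct_shared_ab_of_a"] = shared_fraction(venn, ("a", "b"), "a")
            venn_block["pct_shared_ac_of_a"] = shared_fraction(venn, ("a", "c"), "a")

    cls_cfg = dict(config.get("classify") or {})
    params = PatternParams(
        upper_threshold=float(cls_cfg.get("upper", 1.5)),
        lower_threshold=float(cls_cfg.get("lower", 0.67)),
        band=float(cls_cfg.get("band", 0.10)),
        mode=str(cls_cfg.get("mode", "literal")),
    )
    with _stage("pattern_classification"):
        dep_ids = sorted(sig["hybrid_vs_female"] | sig["hybrid_vs_male"])
        pattern_block = None
        calls = classify_all(matrix, dep_ids, params=params)
        if calls:
            calls_to_frame(calls).to_csv(outdir / "pattern_calls.tsv", sep="\t", index=False)
            pattern_block = dataclasses.asdict(summarize_patterns(calls))
        recovery_block = None
        if truth is not None:
            planted = truth[truth["true_pattern"] != "null"]
            recovered = classify_all(matrix, planted["protein_id"], params=params)
            observed = {c.protein_id: c.label for c in recovered}
            label_map = {"over_dominant": "over_dominant_up"}
            expected = {
                row.protein_id: label_map.get(row.true_pattern, row.true_pattern)
                for row in planted.itertuples()
            }
            hits = sum(observed[pid] == expected[pid] for pid in expected)
            recovery_block = {
                "n_nonnull": len(expected),
                "n_recovered": hits,
                "recovery_pct": round(100.0 * hits / len(expected), 2) if expected else None,
            }

    heterosis_block = None
    trait_cfg = config.get("trait")
    if trait_cfg:
        with _stage("trait_heterosis"):
            if "path" in trait_cfg:
                traits = hio.read_trait_table(trait_cfg["path"])
            else:
                sim_t = trait_cfg["simulate"]
                traits = simulate_trait(
                    sim_t["means"], float(sim_t.get("cv", 0.0)),
                    int(sim_t.get("n_replicates", 3)), seed,
                )
            genotypes = trait_cfg.get(
                "genotypes", {"female": "P1", "male": "P2", "hybrid": "F1"}
            )
            result = heterosis_from_table(
                traits, genotypes["female"], genotypes["male"], genotypes["hybrid"]
            )
            pairs = trait_significance(traits, alpha=alpha)
            pairs.to_csv(outdir / "trait_pairs.tsv", sep="\t", index=False)
            heterosis_block = dataclasses.asdict(result)

    enrichment_block = None
    if config.get("term_map"):
        with _stage("enrichment"):
            term_map = hio.read_term_map(config["term_map"])
            de_union = sorted(set().union(*sig.values()))
            enriched = enrich_terms(de_union, matrix.protein_ids, term_map)
            enriched.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            enrichment_block = {"n_terms": int(len(enriched))}

    cluster_block = None
    if config.get("cluster") is not None:
        with _stage("clustering"):
            dep_union = sorted(set().union(*sig.values()))
            if len(dep_union) >= 2:
                dendro = cluster_rows(
                    matrix.values.loc[dep_union],
                    standardize=bool((config.get("cluster") or {}).get("standardize", False)),
                )
                (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
                dendro.merge_table().to_csv(outdir / "merges.tsv", sep="\t", index=False)
                cluster_block = {"n_rows": len(dep_union),
                                 "max_height": float(dendro.heights.max())}

    report = {
        "seed": seed,
        "settings": {
            "alpha": alpha,
            "use_fdr": use_fdr,
            "log_transform": log_transform,
            "classify": dataclasses.asdict(params),
        },
        "n_quantified": n_quantified,
        "comparisons": {k: dataclasses.asdict(v) for k, v in summaries.items()},
        "venn": venn_block,
        "patterns": pattern_block,
        "pattern_recovery": recovery_block,
        "heterosis": heterosis_block,
        "enrichment": enrichment_block,
        "clustering": cluster_block,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
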