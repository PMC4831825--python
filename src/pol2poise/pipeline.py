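"""End-to-end orchestration and summary artifacts.

``run_pipeline`` chains annotations -> coverage -> poising per cell
state, then (with two states) the transition analysis and (with a
genome) the G4 window analysis, writing every intermediate table as TSV
plus a manifest with input digests, row counts and the config snapshot,
sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotations import (
    define_regions,
    filter_genes,
    load_gene_models,
    regions_to_frame,
)
from .config import PipelineConfig
from .coverage import add_densities, build_region_counts, read_bed_reads
from .poising import CLASSES, call_poising
from .quadruplex import (
    count_g4_per_gene,
    hits_to_bed,
    mask_cpg,
    read_bed_intervals,
    scan_g4_both_strands,
)
from .transitions import fold_changes, mannwhitney_with_effect, spearman_partial, transition_matrix

logger = logging.getLogger("pol2poise")


class ConfigurationError(ValueError):
    """A missing or inconsistent key in the run configuration."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def summarize_classes(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per class, plus Pol II+ summary rows.

    Fractions are of all genes; the NP-among-Pol II+ fraction mirrors
    the published per-state summary.
    """
    if len(calls) == 0:
        raise ValueError("summarize_classes requires at least one call")
    n = len(calls)
    rows = []
    for k in CLASSES:
        c = int((calls["klass"] == k).sum())
        rows.append({"metric": f"class_{k}", "count": c, "fraction": c / n})
    n_pos = int((calls["klass"] != "I").sum())
    rows.append({"metric": "polii_positive", "count": n_pos, "fraction": n_pos / n})
    n_np = int((calls["klass"] == "NP").sum())
    rows.append(
        {
            "metric": "np_among_polii_positive",
            "count": n_np,
            "fraction": n_np / n_pos if n_pos else float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["metric", "count", "fraction"])


def _load_expression(path: Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t")
    if "gene_id" not in expr.columns:
        raise ConfigurationError(f"expression table {path} lacks a gene_id column")
    return expr.set_index("gene_id")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full pipeline described by a config mapping or YAML file.

    Required keys: ``genes`` (path), ``format`` (refflat/bed12/gtf) and
    ``states``: a mapping of state name -> {``polii``: [bed...],
    ``igg``: [bed...]}. Optional: ``expression`` (TSV with gene_id +
    timepoint columns), ``expression_states`` (state name -> timepoint
    column), ``genome`` (FASTA), ``cpg`` (BED), ``params`` (PipelineConfig
    overrides). Writes all tables plus ``manifest.json`` into
    ``out_dir`` and returns it.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    for key in ("genes", "format", "states"):
        if key not in config:
            raise ConfigurationError(f"run config is missing required key {key!r}")
    if not config["states"]:
        raise ConfigurationError("run config names no states")
    for name, libs in config["states"].items():
        for lib in ("polii", "igg"):
            if lib not in libs or not libs[lib]:
                raise ConfigurationError(f"state {name!r} is missing {lib!r} read files")

    params = PipelineConfig.from_dict(config.get("params", {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_paths = [Path(config["genes"])]
    for libs in config["states"].values():
        input_paths += [Path(p) for p in libs["polii"]] + [Path(p) for p in libs["igg"]]
    for key in ("expression", "genome", "cpg"):
        if config.get(key):
            input_paths.append(Path(config[key]))
    missing = [str(p) for p in input_paths if not p.exists()]
    if missing:
        raise ConfigurationError(f"missing input files: {missing}")
    digests = {str(p): _sha256(p) for p in input_paths}

    manifest: dict = {
        "version": __version__,
        "params": params.to_dict(),
        "inputs": digests,
        "stages": {},
    }

    # --- annotations ---
    models = load_gene_models(config["genes"], config["format"])
    filtered = filter_genes(models, params)
    regions = [define_regions(m, params) for m in filtered]
    regions_to_frame(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    manifest["stages"]["annotations"] = {
        "transcripts_in": len(models),
        "genes_retained": len(filtered),
    }
    logger.info("annotations: %d transcripts in, %d genes retained", len(models), len(filtered))

    # --- coverage + poising per state ---
    calls: dict[str, pd.DataFrame] = {}
    densities: dict[str, pd.DataFrame] = {}
    for state, libs in config["states"].items():
        polii = [read_bed_reads(p) for p in libs["polii"]]
        igg = [read_bed_reads(p) for p in libs["igg"]]
        counts = build_region_counts(regions, polii, igg)
        dens = add_densities(counts)
        dens.to_csv(out / f"counts_{state}.tsv", sep="\t", index=False)
        state_calls = call_poising(counts, params)
        state_calls.to_csv(out / f"calls_{state}.tsv", sep="\t", index=False)
        summarize_classes(state_calls).to_csv(
            out / f"class_summary_{state}.tsv", sep="\t", index=False
        )
        calls[state] = state_calls
        densities[state] = dens
        manifest["stages"][f"coverage_{state}"] = {
            "genes": len(counts),
            "polii_library": int(counts["polii_library"].iloc[0]),
            "igg_library": int(counts["igg_library"].iloc[0]),
        }
        logger.info("state %s: %d genes counted and classified", state, len(counts))

    expr = _load_expression(Path(config["expression"])) if config.get("expression") else None

    # --- transitions (two states) ---
    state_names = list(config["states"])
    if len(state_names) >= 2:
        a, b = state_names[0], state_names[1]
        counts_m, pct_m = transition_matrix(calls[a], calls[b])
        counts_m.rename_axis("class_a").to_csv(out / "transition_counts.tsv", sep="\t")
        pct_m.rename_axis("class_a").to_csv(out / "transition_row_pct.tsv", sep="\t")

        expr_a = expr_b = None
        if expr is not None and config.get("expression_states"):
            cols = config["expression_states"]
            expr_a = expr[cols[a]] if a in cols else None
            expr_b = expr[cols[b]] if b in cols else None
        records = fold_changes(
            densities[a], densities[b], calls[a], calls[b], expr_a, expr_b, params
        )
        records.to_csv(out / "transitions.tsv", sep="\t", index=False)

        stats_rows = []
        stay_p = records[(records["class_a"] == "P") & (records["class_b"] == "P")]
        p_to_np = records[(records["class_a"] == "P") & (records["class_b"] == "NP")]
        if len(stay_p) and len(p_to_np):
            for col in ("prom_fc", "body_fc"):
                cmp = mannwhitney_with_effect(
                    stay_p[col].to_numpy(), p_to_np[col].to_numpy(), log_transform=True
                )
                stats_rows.append(
                    {
                        "comparison": f"{col}_stayP_vs_PtoNP",
                        "n_x": cmp.n_x,
                        "n_y": cmp.n_y,
                        "u_statistic": cmp.u_statistic,
                        "p_value": cmp.p_value,
                        "cohens_d": cmp.cohens_d,
                        "median_x": cmp.median_x,
                        "median_y": cmp.median_y,
                    }
                )
        if "expr_fc" in records.columns and records["expr_fc"].notna().all() and len(records) >= 4:
            rho_p, part_p = spearman_partial(
                records["expr_fc"], records["prom_fc"], records["body_fc"]
            )
            rho_b, part_b = spearman_partial(
                records["expr_fc"], records["body_fc"], records["prom_fc"]
            )
            stats_rows += [
                {"comparison": "spearman_exprfc_promfc_given_bodyfc", "rho": rho_p, "partial_rho": part_p},
                {"comparison": "spearman_exprfc_bodyfc_given_promfc", "rho": rho_b, "partial_rho": part_b},
            ]
        if stats_rows:
            pd.DataFrame(stats_rows).to_csv(out / "comparisons.tsv", sep="\t", index=False)
        manifest["stages"]["transitions"] = {"genes": len(records)}
    else:
        logger.info("single state: transitions stage skipped")
        manifest["stages"]["transitions"] = "skipped (single state)"

    # --- quadruplex (needs genome) ---
    if config.get("genome"):
        from pyfaidx import Fasta

        fasta = Fasta(str(config["genome"]))
        hits = []
        for chrom in fasta.keys():
            hits += scan_g4_both_strands(str(fasta[chrom][:]), params, chrom=chrom)
        if config.get("cpg"):
            hits = mask_cpg(hits, read_bed_intervals(config["cpg"]))
        hits_to_bed(hits, out / "g4_hits.bed")
        g4_counts = count_g4_per_gene(hits, filtered, params)
        g4_counts.to_csv(out / "g4_counts.tsv", sep="\t", index=False)
        manifest["stages"]["quadruplex"] = {"hits": len(hits), "genes": len(g4_counts)}
        logger.info("quadruplex: %d merged hits", len(hits))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
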