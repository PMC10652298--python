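"""End-to-end pipeline runner, configuration, and report rendering.

A single TOML config drives all stages: (optional) simulation of inputs,
peak/DEG integration, concordance statistics, cross-species enrichment,
and quantal PHP analysis.  Every statistical option lives in the config
with analysis-faithful defaults.  Identical config + seed produces a
byte-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__, ephys, io as sio, simulate, xspecies
from .concordance import concordance_by_scope, concordance_table
from .integrate import (
    assign_primary_cell_type,
    filter_abeta_peaks,
    overlap_with_degs,
    peaks_to_genes,
    per_celltype_direction_counts,
)

__all__ = ["ConfigError", "load_config", "demo_config", "run_pipeline", "render_report"]


class ConfigError(ValueError):
    """The run configuration is incomplete or inconsistent."""


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def demo_config() -> dict:
    """The bundled demonstration configuration (simulated inputs)."""
    text = resources.files("synacet").joinpath("data/demo_config.toml").read_text()
    return tomllib.loads(text)


def _validate_config(config: Mapping) -> None:
    if "simulate" in config:
        return
    inputs = config.get("inputs")
    if not inputs:
        raise ConfigError("config must provide either a [simulate] section or "
                          "an [inputs] section")
    if "integrated" in inputs:
        return
    missing = [k for k in ("peaks", "degs") if k not in inputs]
    if missing:
        raise ConfigError(f"[inputs] must name 'peaks' and 'degs' paths (or a "
                          f"pre-joined 'integrated' table); missing: {missing}")


def _load_inputs(config: Mapping, outdir: Path, log: list[str]) -> dict:
    if "simulate" in config:
        sim = dict(config["simulate"])
        truth_kwargs = dict(sim.pop("truth", {}))
        truth_kwargs.setdefault("seed", int(config.get("seed", 0)))
        if "celltype_degs" in truth_kwargs:
            truth_kwargs["celltype_degs"] = {
                ct: simulate.CellTypeDegProfile(**p)
                for ct, p in truth_kwargs["celltype_degs"].items()}
        truth = simulate.SimulationTruth(**truth_kwargs)
        bundle = simulate.generate_bundle(
            truth,
            n_genes=int(sim.get("n_genes", 2000)),
            n_cells_per_group=int(sim.get("n_cells_per_group", 12)),
            homolog_coverage=float(sim.get("homolog_coverage", 0.85)),
            n_fly_background=int(sim.get("n_fly_background", 2000)))
        simulate.write_bundle(bundle, outdir / "inputs")
        log.append(f"simulate: generated input bundle (seed={truth.seed})")
        return bundle
    paths = dict(config["inputs"])
    annotations_path = paths.pop("annotations", None)
    bundle = dict(sio.read_tables(paths))
    if annotations_path is not None:
        bundle["annotations"] = pd.read_csv(annotations_path, sep="\t")
    log.append(f"inputs: read {sorted(paths)}")
    return bundle


def _df_records(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def run_pipeline(config: Mapping, outdir) -> dict:
    """Execute every stage the config's inputs support.

    Writes stage TSVs, a machine-readable ``summary.json`` and a
    ``run_log.txt`` under ``outdir``; returns the summary dict.
    """
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: list[str] = [f"synacet {__version__}", f"seed: {seed}"]
    summary: dict = {"config_seed": seed, "version": __version__}

    bundle = _load_inputs(config, outdir, log)
    if "truth" in bundle:
        summary["simulate"] = {"truth": simulate.truth_to_dict(bundle["truth"])}

    # ---- integrate -------------------------------------------------------
    integ_cfg = config.get("integrate", {})
    fdr_max = float(integ_cfg.get("fdr_max", 0.05))
    records = None
    if "integrated" in bundle:
        records = bundle["integrated"]
        log.append(f"integrate: using pre-joined table ({len(records)} records)")
        summary["integrate"] = {"n_records": len(records),
                                "n_distinct_genes": len({r.gene_symbol for r in records}),
                                "source": "pre-joined"}
    elif "peaks" in bundle and "degs" in bundle:
        significant = filter_abeta_peaks(bundle["peaks"], fdr_max=fdr_max)
        gene_map = peaks_to_genes(significant)
        records = assign_primary_cell_type(overlap_with_degs(gene_map, bundle["degs"]))
        counts = per_celltype_direction_counts(records)
        sio.write_integrated(records, outdir / "integrated.tsv")
        counts.to_csv(outdir / "direction_counts.tsv", sep="\t", float_format="%.12g")
        summary["integrate"] = {
            "fdr_max": fdr_max,
            "n_peaks_significant": len(significant),
            "n_abeta_genes": len(gene_map),
            "n_records": len(records),
            "n_distinct_genes": len({r.gene_symbol for r in records}),
            "direction_counts": _df_records(counts.reset_index()),
        }
        log.append(f"integrate: {len(gene_map)} amyloid-associated genes, "
                   f"{len(records)} integrated records")

    # ---- concordance -----------------------------------------------------
    if records is not None:
        conc_cfg = config.get("concordance", {})
        results = concordance_by_scope(
            records, p0=float(conc_cfg.get("p0", 0.5)),
            binom_method=conc_cfg.get("binom_method", "minlike"))
        table = concordance_table(results)
        table.to_csv(outdir / "concordance.tsv", sep="\t", index=False,
                     float_format="%.12g")
        scatter = pd.DataFrame([{
            "gene_symbol": r.gene_symbol, "cell_type": r.cell_type,
            "coef_abeta": r.coef_abeta, "log2fc": r.log2fc,
            "same_sign": r.same_sign, "is_primary": r.is_primary,
        } for r in records])
        scatter.to_csv(outdir / "scatter.tsv", sep="\t", index=False,
                       float_format="%.12g")
        summary["concordance"] = _df_records(table)
        log.append("concordance: " + "; ".join(
            f"{r.scope} {r.k_same_sign}/{r.n}" for r in results))

    # ---- cross-species enrichment ---------------------------------------
    xs_cfg = config.get("xspecies", {})
    fly_ct_name = xs_cfg.get("fly_cell_type", "perineurial_glia")
    needed = ("go", "homologs", "human_expression", "fly_expression")
    if all(k in bundle for k in needed) and fly_ct_name in bundle["fly_expression"]:
        top_n = int(xs_cfg.get("top_n", 20))
        n_boot = int(xs_cfg.get("n_boot", 10_000))
        min_frac = float(xs_cfg.get("min_frac_expressed", 0.01))
        keyword = xs_cfg.get("keyword", "synaptic")
        fly_ct = bundle["fly_expression"][fly_ct_name]
        synaptic = xspecies.select_synaptic_genes(bundle["go"], keyword=keyword)
        fly_map = xspecies.resolve_homologs(bundle["homologs"])
        universe = xspecies.expressed_genes(fly_ct, min_frac=min_frac)
        enrich_rows, corr_rows = [], []
        for i, (ct, human_ct) in enumerate(sorted(bundle["human_expression"].items())):
            top = xspecies.top_n_expressed(human_ct, synaptic, n=top_n)
            targets = {fly_map[g] for g in top if g in fly_map} & universe
            if targets and len(universe) > len(targets):
                res = xspecies.enrichment_percentile(
                    targets, fly_ct, universe, n_boot=n_boot,
                    seed=seed * 1000 + i, human_cell_type=ct, n_top=top_n)
                enrich_rows.append(dataclasses.asdict(res))
            for metric in ("mean_expr_vs_mean_expr", "mean_expr_vs_frac_expressing"):
                try:
                    corr = xspecies.xspecies_expression_corr(
                        human_ct, fly_ct, bundle["homologs"], metric=metric)
                except ValueError:
                    continue
                corr_rows.append(dataclasses.asdict(corr))
        pd.DataFrame(enrich_rows).to_csv(outdir / "enrichment.tsv", sep="\t",
                                         index=False, float_format="%.12g")
        pd.DataFrame(corr_rows).to_csv(outdir / "xspecies_corr.tsv", sep="\t",
                                       index=False, float_format="%.12g")
        summary["xspecies"] = {"enrichment": enrich_rows, "correlations": corr_rows,
                               "n_synaptic_genes": len(synaptic)}
        log.append(f"xspecies: {len(enrich_rows)} enrichment results "
                   f"({len(synaptic)} synaptic genes)")

    # ---- quantal PHP -----------------------------------------------------
    if "ephys" in bundle:
        q_cfg = config.get("quantal", {})
        summaries = ephys.summarize_cohort(
            bundle["ephys"], ttest=q_cfg.get("ttest", "welch"),
            alpha=float(q_cfg.get("alpha", 0.05)))
        rows = [dataclasses.asdict(s) for s in summaries]
        phtx_effect = None
        if "truth" in bundle:
            phtx_effect = bundle["truth"].phtx_effect
        elif "phtx_effect" in q_cfg:
            phtx_effect = float(q_cfg["phtx_effect"])
        if phtx_effect is not None:
            for s, row in zip(summaries, rows):
                row["gain_hat"] = ephys.estimate_gain(s, phtx_effect)
        pd.DataFrame(rows).to_csv(outdir / "genotype_summaries.tsv", sep="\t",
                                  index=False, float_format="%.12g")
        summary["quantal"] = {"genotypes": rows}
        if "annotations" in bundle:
            try:
                corr = ephys.php_dysregulation_corr(summaries, bundle["annotations"])
            except ValueError as exc:
                log.append(f"quantal: dysregulation correlations skipped ({exc})")
            else:
                corr.to_csv(outdir / "php_correlations.tsv", sep="\t", index=False,
                            float_format="%.12g")
                summary["quantal"]["dysregulation_correlations"] = _df_records(corr)
        log.append(f"quantal: {len(summaries)} genotypes")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.append("done")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return summary


# ---------------------------------------------------------------------------
# Report rendering


def _fmt_table(rows: list[dict], columns: list[tuple[str, str]]) -> str:
    header = [label for label, _ in columns]
    body = []
    for row in rows:
        line = []
        for _, key in columns:
            v = row.get(key)
            if isinstance(v, float):
                line.append(f"{v:.3g}")
            else:
                line.append("NA" if v is None else str(v))
        body.append(line)
    widths = [max(len(header[i]), *(len(r[i]) for r in body)) if body else len(header[i])
              for i in range(len(header))]
    out = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    out += ["  ".join(c.ljust(w) for c, w in zip(line, widths)) for line in body]
    return "\n".join(out)


def render_report(summary: Mapping) -> str:
    """Human-readable report with the four headline table groups.

    Missing summary blocks are flagged rather than fatal, so a partial run
    still renders what it computed.
    """
    sections: list[str] = ["# Integrative H3K9ac / transcriptome / PHP report", ""]
    missing: list[str] = []

    integ = summary.get("integrate")
    if integ and "direction_counts" in integ:
        sections.append("## Cell-type-specific DEG counts and direction")
        sections.append(
            f"{integ['n_abeta_genes']} amyloid-associated H3K9ac-target genes; "
            f"{integ['n_records']} integrated records over "
            f"{integ['n_distinct_genes']} distinct genes.")
        sections.append(_fmt_table(integ["direction_counts"], [
            ("cell_type", "cell_type"), ("n", "n_total"), ("up", "n_up"),
            ("down", "n_down"), ("%down", "pct_down")]))
        sections.append("")
    else:
        missing.append("integrate")

    conc = summary.get("concordance")
    if conc:
        sections.append("## Sign concordance and correlation by scope")
        sections.append(_fmt_table(conc, [
            ("scope", "scope"), ("n", "n"), ("same-sign", "k_same_sign"),
            ("%same-sign", "pct_same_sign"), ("binom p", "binom_p"),
            ("Pearson r", "pearson_r"), ("p", "pearson_p")]))
        sections.append("")
    else:
        missing.append("concordance")

    xs = summary.get("xspecies")
    if xs:
        sections.append("## Fly perineurial-glia enrichment of top synaptic genes")
        sections.append(_fmt_table(xs.get("enrichment", []), [
            ("human cell type", "human_cell_type"), ("top N", "n_top"),
            ("mapped", "n_mapped"), ("percentile", "percentile")]))
        sections.append("")
        sections.append("## Cross-species expression correlations")
        sections.append(_fmt_table(xs.get("correlations", []), [
            ("human cell type", "human_cell_type"), ("metric", "metric"),
            ("Spearman r", "spearman_r"), ("p", "p"), ("pairs", "n_pairs")]))
        sections.append("")
    else:
        missing.append("xspecies")

    quant = summary.get("quantal")
    if quant:
        sections.append("## Per-genotype PHP metrics (% of -PhTX baseline)")
        sections.append(_fmt_table(quant.get("genotypes", []), [
            ("genotype", "genotype"), ("n-", "n_minus"), ("n+", "n_plus"),
            ("%mEPSP", "pct_mepsp"), ("%EPSP", "pct_epsp"), ("%QC", "pct_qc"),
            ("QC p", "qc_p"), ("PHP intact", "php_intact")]))
        if "dysregulation_correlations" in quant:
            sections.append("")
            sections.append("## PHP impairment vs AD dysregulation magnitude")
            sections.append(_fmt_table(quant["dysregulation_correlations"], [
                ("metric", "metric"), ("versus", "versus"),
                ("Spearman r", "spearman_r"), ("p", "p")]))
        sections.append("")
    else:
        missing.append("quantal")

    if missing:
        sections.append(f"[missing blocks: {', '.join(missing)}]")
    return "\n".join(sections) + "\n"
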