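"""End-to-end orchestration: simulate/load -> localize -> enrich -> qpcr.

A run is driven by a YAML/dict config, writes all result tables plus a
machine-readable ``summary.json`` into the run directory, and is
deterministic given (config, seed): the same inputs produce a byte-identical
summary.  Any stage failure aborts with a stage-named error; artifacts that
were mid-write are left with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import contextlib
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, io_formats, qpcr as qpcr_mod, synthetic
from .enrichment import enrich
from .localization import (
    CLASS_CYTOPLASMIC,
    CLASS_FILTERED,
    CLASS_NUCLEAR,
    LocalizationConfig,
    heatmap_zscore,
    localize,
    volcano_table,
)

logger = logging.getLogger("nucyto")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextlib.contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage %s: done", name)


def config_hash(config: dict[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _atomic_table(df: pd.DataFrame, path: Path, chash: str, index: bool = False) -> None:
    tmp = path.with_name(path.name + ".partial")
    io_formats.write_table(df, tmp, tool_version=__version__, config_hash=chash, index=index)
    tmp.replace(path)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError("stage 'config' failed: run config must be a mapping")
    return config


def _localization_config(config: dict[str, Any]) -> LocalizationConfig:
    section = config.get("localization", {}) or {}
    return LocalizationConfig(
        expression_log2_threshold=float(section.get("threshold", -1.0)),
        alpha=float(section.get("alpha", 0.05)),
        ratio_scale=section.get("scale", "log2"),
        fc_aggregation=section.get("fc_aggregation", "mean_of_ratios"),
        apply_bh=bool(section.get("apply_bh", False)),
        welch=bool(section.get("welch", False)),
    )


def run_all(config: dict[str, Any], outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory.

    Writes results.tsv, volcano.tsv, heatmap.tsv, enrich.tsv, qpcr_fc.tsv,
    summary.json, resolved_config.yaml and run.log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.get("log_level", "INFO"))
    try:
        return _run_all(config, outdir, chash)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_all(config: dict[str, Any], outdir: Path, chash: str) -> Path:
    seed = int(config.get("seed", 0))
    loc_cfg = _localization_config(config)
    qpcr_section = config.get("qpcr", {}) or {}
    enr_section = config.get("enrichment", {}) or {}

    truth = None
    qpcr_table = None
    collection = None

    with _stage("io"):
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            sim_cfg = synthetic.SimulationConfig(seed=seed, **sim_kwargs)
            matrix, sheet, locus_map, truth = synthetic.simulate_dataset(sim_cfg)
            inputs_dir = outdir / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            io_formats.write_expression(matrix, inputs_dir / "matrix.tsv")
            io_formats.write_sample_sheet(sheet, inputs_dir / "samples.tsv")
            io_formats.write_locus_map(locus_map, inputs_dir / "locus_map.tsv")
            synthetic.write_truth(truth, inputs_dir / "truth.tsv")
        else:
            inputs = config.get("inputs")
            if not inputs:
                raise FileNotFoundError("config has neither 'simulate' nor 'inputs'")
            matrix = io_formats.read_expression(inputs["matrix"])
            sheet = io_formats.read_sample_sheet(inputs["samples"])
            locus_map = (
                io_formats.read_locus_map(inputs["locus_map"])
                if inputs.get("locus_map")
                else None
            )
            if inputs.get("gmt"):
                collection = io_formats.read_gmt(inputs["gmt"])
            if inputs.get("cq"):
                qpcr_table = qpcr_mod.read_qpcr(inputs["cq"])

    with _stage("aggregate"):
        if locus_map is not None:
            matrix = io_formats.aggregate_by_gene(matrix, locus_map)

    with _stage("localize"):
        records = localize(matrix, sheet, loc_cfg)
        _atomic_table(records, outdir / "results.tsv", chash)
        _atomic_table(volcano_table(records), outdir / "volcano.tsv", chash)
        significant = records.loc[
            records["class"].isin([CLASS_NUCLEAR, CLASS_CYTOPLASMIC]), "gene"
        ].tolist()
        zscores = heatmap_zscore(matrix, sheet, significant)
        _atomic_table(zscores.reset_index(), outdir / "heatmap.tsv", chash)

    tested = records[records["class"] != CLASS_FILTERED]
    nuclear_genes = records.loc[records["class"] == CLASS_NUCLEAR, "gene"].tolist()
    n_cytoplasmic = int((records["class"] == CLASS_CYTOPLASMIC).sum())

    top_term = None
    with _stage("enrich"):
        if collection is None and truth is not None:
            collection = synthetic.simulate_genesets(
                truth,
                n_sets=int(enr_section.get("n_sets", 20)),
                enriched_set_fraction=float(enr_section.get("enriched_set_fraction", 0.6)),
                seed=seed,
                set_size=int(enr_section.get("set_size", 50)),
            )
        if collection is not None:
            universe = enr_section.get("universe", "tested")
            uni = set(tested["gene"]) if universe == "tested" else collection.universe
            table = enrich(
                nuclear_genes, collection, top_k=int(enr_section.get("top", 10)),
                universe=uni,
            )
            _atomic_table(table, outdir / "enrich.tsv", chash)
            if len(table):
                top_term = str(table["set_name"].iloc[0])

    with _stage("qpcr"):
        if qpcr_table is None and truth is not None:
            n_targets = int(qpcr_section.get("n_targets", 3))
            shifted = truth.loc[
                truth["true_class"] == synthetic.TRUE_NUCLEAR, "gene"
            ].tolist()
            nulls = truth.loc[truth["true_class"] == synthetic.TRUE_NULL, "gene"].tolist()
            targets = shifted[:n_targets] + nulls[:1]
            if targets:
                sim_kwargs = dict(config.get("simulate", {}) or {})
                sim_cfg = synthetic.SimulationConfig(seed=seed, **sim_kwargs)
                if "noise_log2_sd" in qpcr_section:
                    sim_cfg = synthetic.SimulationConfig(
                        seed=seed,
                        **{**sim_kwargs, "noise_log2_sd": float(qpcr_section["noise_log2_sd"])},
                    )
                qpcr_table = synthetic.simulate_qpcr(truth, targets, sim_cfg)
                qpcr_mod.write_qpcr(qpcr_table, outdir / "inputs" / "cq.tsv")
        if qpcr_table is not None:
            fc_table = qpcr_mod.fold_change_table(qpcr_table)
            _atomic_table(fc_table, outdir / "qpcr_fc.tsv", chash)

    with _stage("summary"):
        summary = {
            "config_sha256": chash,
            "n_cytoplasmic": n_cytoplasmic,
            "n_filtered": int((records["class"] == CLASS_FILTERED).sum()),
            "n_nuclear": len(nuclear_genes),
            "n_tested": int(len(tested)),
            "seed": seed,
            "tool_version": __version__,
            "top_enrichment_term": top_term,
        }
        tmp = outdir / "summary.json.partial"
        tmp.write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
        tmp.replace(outdir / "summary.json")
        with open(outdir / "resolved_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)

    logger.info("run complete: %s", outdir)
    return outdir
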