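"""Pipeline orchestration: simulate → quantify → cellstats → stats → report.

Configuration is a YAML/JSON-style mapping validated up front (pre-flight:
all problems are collected and reported together before any stage runs).
Every run writes a provenance block — the fully resolved configuration —
next to its outputs, sufficient to re-run any stage.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import axon_quant, cell_stats, group_stats, refdata
from .image_io import ROISpec, read_cell_table, read_stack, write_cell_table, write_stack
from .synthetic import AxonPhantomSpec, CellTableSpec, generate_axon_stack, generate_cell_table


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration."""

    outdir: str
    seed: int = 0
    simulate: Mapping[str, Any] | None = None
    quantify: Mapping[str, Any] | None = None
    cellstats: Mapping[str, Any] | None = None
    stats: Mapping[str, Any] | None = None
    reproduce: bool = False

    @staticmethod
    def from_mapping(doc: Mapping[str, Any]) -> "PipelineConfig":
        problems = []
        if "outdir" not in doc:
            problems.append("missing required key 'outdir'")
        known = {"outdir", "seed", "simulate", "quantify", "cellstats", "stats", "reproduce"}
        for key in doc:
            if key not in known:
                problems.append(f"unknown config key {key!r}")
        quantify = doc.get("quantify")
        if quantify:
            for path in quantify.get("stacks", []):
                if not os.path.exists(path):
                    problems.append(f"quantify: missing stack file {path!r}")
        cellstats_cfg = doc.get("cellstats")
        if cellstats_cfg:
            table = cellstats_cfg.get("table")
            if table and not os.path.exists(table):
                problems.append(f"cellstats: missing table file {table!r}")
        stats_cfg = doc.get("stats")
        if stats_cfg:
            gpath = stats_cfg.get("groups")
            if gpath and not os.path.exists(gpath):
                problems.append(f"stats: missing groups file {gpath!r}")
        if problems:
            raise ValueError("invalid pipeline config:\n  " + "\n  ".join(problems))
        return PipelineConfig(
            outdir=str(doc["outdir"]),
            seed=int(doc.get("seed", 0)),
            simulate=doc.get("simulate"),
            quantify=doc.get("quantify"),
            cellstats=doc.get("cellstats"),
            stats=doc.get("stats"),
            reproduce=bool(doc.get("reproduce", False)),
        )

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_mapping(yaml.safe_load(fh))


def _summaries_to_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"stratum": s.stratum}
        for a, num, den in zip(s.animals, s.numerators, s.denominators):
            row[f"num_{a}"] = num
            row[f"den_{a}"] = den
        row.update(
            pooled_numerator=s.pooled_numerator,
            pooled_denominator=s.pooled_denominator,
            mean_pct="" if s.mean_pct is None else s.mean_pct,
            sd_pct="" if s.sd_pct is None else s.sd_pct,
            suppressed=s.suppressed,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_reference() -> dict[str, Any]:
    """Recompute every reference summary statistic from the bundled
    per-animal data: distributions, co-labeling, overlap, and the RAD
    group comparison (ANOVA + LSD)."""
    out: dict[str, Any] = {"distribution": {}, "colabel": {}, "overlap": {}, "rad": {}}

    for pop in ("nac", "vta"):
        table = refdata.distribution_cell_table(pop)
        out["distribution"][pop] = {
            axis: cell_stats.distribution_table(table, pop, axis)
            for axis in ("ap_bin", "subregion", "layer")
        }
        out["distribution"][pop]["total_cells"] = int(len(table))

    for pop in ("nac", "vta"):
        out["colabel"][pop] = {}
        for marker in ("calb1", "ctip2", "foxp2"):
            table = refdata.colabel_cell_table(pop, marker)
            out["colabel"][pop][marker] = cell_stats.colabel_proportions(table, pop, marker)

    counts = refdata.OVERLAP_COUNTS
    dbl = counts["double"]
    singles_nac = tuple(n - d for n, d in zip(counts["nac_incl"], dbl))
    singles_vta = tuple(v - d for v, d in zip(counts["vta_incl"], dbl))
    out["overlap"]["summary"] = cell_stats.overlap_from_counts(
        refdata.ANIMALS, singles_nac, singles_vta, dbl, totals=counts["total_printed"]
    )
    out["overlap"]["from_table"] = cell_stats.overlap_statistics(refdata.overlap_cell_table())

    ratios = refdata.rad_ratios_from_densities()
    out["rad"]["ratios_from_densities"] = ratios
    out["rad"]["group_mean_sd"] = {
        g: group_stats.mean_sd(v) for g, v in ratios.items()
    }
    printed = refdata.rad_ratios_printed()
    groups = [group_stats.GroupData(g, v) for g, v in printed.items()]
    anova = group_stats.one_way_anova(groups)
    out["rad"]["levene"] = group_stats.homogeneity_test(groups)
    out["rad"]["anova"] = anova
    out["rad"]["lsd"] = group_stats.lsd_posthoc(groups, anova)
    return out


def _write_reproduction(outdir: str, rep: dict[str, Any]) -> None:
    os.makedirs(outdir, exist_ok=True)
    for pop in ("nac", "vta"):
        for axis in ("ap_bin", "subregion", "layer"):
            rep["distribution"][pop][axis].to_csv(
                os.path.join(outdir, f"distribution_{pop}_{axis}.csv"), index=False
            )
        for marker in ("calb1", "ctip2", "foxp2"):
            _summaries_to_frame(rep["colabel"][pop][marker]).to_csv(
                os.path.join(outdir, f"colabel_{pop}_{marker}.csv"), index=False
            )
    ov = rep["overlap"]["summary"]
    pd.DataFrame(
        {
            "animal": ov.animals,
            "nac_single": ov.nac_single,
            "vta_single": ov.vta_single,
            "double": ov.double,
            "total": ov.totals,
        }
    ).to_csv(os.path.join(outdir, "overlap_counts.csv"), index=False)
    anova = rep["rad"]["anova"]
    summary = {
        "rad_group_mean_sd": {
            g: {"mean": m, "sd": s} for g, (m, s) in rep["rad"]["group_mean_sd"].items()
        },
        "anova": {
            "f": anova.f,
            "df": [anova.df_between, anova.df_within],
            "p": anova.p,
        },
        "levene": {"statistic": rep["rad"]["levene"][0], "p": rep["rad"]["levene"][1]},
        "lsd": [
            {"pair": list(r.pair), "t": r.t, "p": r.p} for r in rep["rad"]["lsd"]
        ],
        "overlap_pct": {
            name: {"mean": v["mean_pct"], "sd": v["sd_pct"]}
            for name, v in ov.ratios.items()
        },
    }
    with open(os.path.join(outdir, "reproduction_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write per-stage outputs.

    Returns the report bundle (a dict of stage results). Raises on the
    first stage error after pre-flight validation has passed.
    """
    os.makedirs(config.outdir, exist_ok=True)
    bundle: dict[str, Any] = {}
    provenance = {
        "seed": config.seed,
        "stages": [
            s
            for s, cfg in [
                ("simulate", config.simulate),
                ("quantify", config.quantify),
                ("cellstats", config.cellstats),
                ("stats", config.stats),
                ("reproduce", config.reproduce or None),
            ]
            if cfg is not None
        ],
        "config": {
            "simulate": dict(config.simulate or {}),
            "quantify": dict(config.quantify or {}),
            "cellstats": dict(config.cellstats or {}),
            "stats": dict(config.stats or {}),
        },
    }

    simulated_stacks: list[str] = []
    if config.simulate is not None:
        sim = dict(config.simulate)
        n_stacks = int(sim.pop("n_stacks", 1))
        make_cells = sim.pop("cell_table", False)
        truth_rows = []
        for i in range(n_stacks):
            spec = AxonPhantomSpec(**{**sim, "seed": config.seed + i})
            stack, truth = generate_axon_stack(spec)
            path = os.path.join(config.outdir, f"stack_{i:03d}.tif")
            write_stack(stack, path)
            simulated_stacks.append(path)
            truth_rows.append(
                {"stack": os.path.basename(path), "true_length_um": truth.total_length_um}
            )
        pd.DataFrame(truth_rows).to_csv(
            os.path.join(config.outdir, "ground_truth.csv"), index=False
        )
        if make_cells:
            table = generate_cell_table(CellTableSpec(seed=config.seed))
            write_cell_table(table, os.path.join(config.outdir, "cells.csv"))
        bundle["simulate"] = {"stacks": simulated_stacks, "truth": truth_rows}

    if config.quantify is not None:
        q = dict(config.quantify)
        paths = list(q.get("stacks", [])) or simulated_stacks
        if not paths:
            raise ValueError("quantify: no stacks given and none simulated")
        roi = ROISpec(**q["roi"]) if "roi" in q else None
        rows = []
        measurements = []
        for path in paths:
            stack = read_stack(path, spacing_override=q.get("spacing"))
            m = axon_quant.measure_stack(
                stack, roi=roi, method=q.get("threshold", "otsu"),
                min_object_vox=int(q.get("min_object_vox", 27)),
            )
            measurements.append(m)
            rows.append(
                {
                    "stack": os.path.basename(path),
                    "axon_length_mm": m.axon_length_mm,
                    "volume_mm3": m.volume_mm3,
                    "density_mm_per_mm3": m.density_mm_per_mm3,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(os.path.join(config.outdir, "stack_measurements.csv"), index=False)
        summary = axon_quant.region_rad(measurements, region=q.get("region", "region"))
        pd.DataFrame(
            [
                {
                    "region": summary.region,
                    "total_length_mm": summary.total_length_mm,
                    "total_volume_mm3": summary.total_volume_mm3,
                    "rad_mm_per_mm3": summary.rad,
                }
            ]
        ).to_csv(os.path.join(config.outdir, "region_summary.csv"), index=False)
        bundle["quantify"] = {"stacks": df, "region": summary}

    if config.cellstats is not None:
        c = dict(config.cellstats)
        table = read_cell_table(c["table"]) if "table" in c else generate_cell_table(
            CellTableSpec(seed=config.seed)
        )
        analysis = c.get("analysis", "distribution")
        pop = c.get("population", "nac")
        if analysis == "distribution":
            res = cell_stats.distribution_table(table, pop, c.get("axis", "layer"))
            res.to_csv(os.path.join(config.outdir, f"distribution_{pop}.csv"), index=False)
        elif analysis == "colabel":
            res = cell_stats.colabel_proportions(table, pop, c["marker"])
            _summaries_to_frame(res).to_csv(
                os.path.join(config.outdir, f"colabel_{pop}_{c['marker']}.csv"), index=False
            )
        elif analysis == "overlap":
            res = cell_stats.overlap_statistics(table)
        else:
            raise ValueError(f"unknown cellstats analysis {analysis!r}")
        bundle["cellstats"] = res

    if config.stats is not None:
        s = dict(config.stats)
        gdf = pd.read_csv(s["groups"])
        groups = [
            group_stats.GroupData(label, tuple(vals["value"]))
            for label, vals in gdf.groupby("group", sort=False)
        ]
        anova = group_stats.one_way_anova(groups)
        pairs = group_stats.lsd_posthoc(groups, anova)
        levene = group_stats.homogeneity_test(groups)
        pd.DataFrame(
            [{"pair": f"{p.pair[0]} vs {p.pair[1]}", "t": p.t, "p": p.p} for p in pairs]
        ).to_csv(os.path.join(config.outdir, "lsd_pairwise.csv"), index=False)
        bundle["stats"] = {"anova": anova, "lsd": pairs, "levene": levene}

    if config.reproduce:
        rep = reproduce_reference()
        _write_reproduction(os.path.join(config.outdir, "reproduction"), rep)
        bundle["reproduce"] = rep

    with open(os.path.join(config.outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return bundle
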