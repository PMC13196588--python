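"""End-to-end orchestration from a single YAML config.

Stages run in dependency order (simulate -> kinetics -> rbg -> fitness ->
mutations -> tnseq); a stage is executed only when its config block is
present, a stage failure aborts the stages after it while preserving
completed outputs, and a provenance manifest (config snapshot, input
digests, seed, versions, per-stage outputs, warnings) is written last.
All randomness is seeded from the single top-level ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import growth_kinetics as gk
from . import resistance_scoring as rs
from . import fitness_metrics as fm
from . import mutation_analysis as ma
from . import tnseq_enrichment as tn
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "kinetics", "rbg", "fitness", "mutations", "tnseq")
TOP_LEVEL_KEYS = {"seed", "outdir", *STAGE_ORDER}


class ConfigError(ValueError):
    """The run config violates the documented schema."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    stages_skipped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    failure: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_config(config_path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(config_path)
    loaded = yaml.safe_load(path.read_text())
    if loaded is None:
        loaded = {}
    if not isinstance(loaded, dict):
        raise ConfigError("config must be a mapping")
    return loaded


def validate_config(config_path) -> list[str]:
    """Validate a run config; returns ALL violations (empty list = ok)."""
    try:
        cfg = _load_config(config_path)
    except ConfigError as exc:
        return [str(exc)]
    violations = []
    for key in cfg:
        if key not in TOP_LEVEL_KEYS:
            violations.append(f"unknown top-level key {key!r}")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        violations.append("seed: must be an integer")
    if "outdir" in cfg and not isinstance(cfg["outdir"], str):
        violations.append("outdir: must be a string path")

    def check_block(name, checks):
        block = cfg.get(name)
        if block is None:
            return
        if not isinstance(block, dict):
            violations.append(f"{name}: must be a mapping")
            return
        for key, (pred, msg) in checks.items():
            if key in block and not pred(block[key]):
                violations.append(f"{name}.{key}: {msg}")

    is_num = lambda v: isinstance(v, (int, float)) and not isinstance(v, bool)
    check_block("kinetics", {
        "blank": (lambda v: is_num(v) and v >= 0, "must be a number >= 0"),
        "window_points": (lambda v: isinstance(v, int) and v >= 3, "must be an int >= 3"),
    })
    check_block("rbg", {
        "n_boot": (lambda v: isinstance(v, int) and v >= 0, "must be an int >= 0"),
        "group_rule": (lambda v: v in ("all", "any"), "must be 'all' or 'any'"),
    })
    check_block("mutations", {
        "min_freq": (lambda v: is_num(v) and 0 <= v < 1, "must be in [0, 1)"),
        "threshold": (lambda v: is_num(v) and 0 < v < 1, "must be in (0, 1)"),
        "dialect": (lambda v: v in ("gd", "tsv"), "must be 'gd' or 'tsv'"),
        "aggregate": (lambda v: v in ("gene", "class"), "must be 'gene' or 'class'"),
        "combine": (lambda v: v in ("max", "sum-capped"),
                    "must be 'max' or 'sum-capped'"),
    })
    check_block("tnseq", {
        "pseudocount": (lambda v: is_num(v) and v > 0, "must be > 0"),
    })
    return violations


def _stage_simulate(cfg, block, outdir, manifest) -> dict[str, str]:
    sim_cfg = sd.SimulationConfig(seed=cfg.get("seed", 0))
    return sd.write_fixtures(sim_cfg, outdir / "fixtures")


def _stage_kinetics(cfg, block, outdir, manifest) -> dict[str, str]:
    path = block["input"]
    manifest.input_digests[str(path)] = _digest(path)
    curves = gk.read_growth_table(path, schema=block.get("schema"))
    summaries = {}
    groups: dict[str, list[float]] = {}
    for curve in curves:
        key = f"{curve.sample_id}|rep{curve.replicate}"
        s = gk.summarize_kinetics(
            curve,
            blank=block.get("blank", 0.0),
            window_points=block.get("window_points", gk.DEFAULT_WINDOW_POINTS),
        )
        summaries[key] = s
        groups.setdefault(str(curve.phage_treatment), []).append(s.auc)
    out = {"kinetics": str(outdir / "kinetics.tsv")}
    gk.write_kinetics_table(summaries, out["kinetics"])
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(usable) >= 2:
        out["auc_comparisons"] = str(outdir / "auc_comparisons.tsv")
        gk.compare_groups_auc(usable).to_csv(out["auc_comparisons"], sep="\t",
                                             index=False)
    return out


def _stage_rbg(cfg, block, outdir, manifest) -> dict[str, str]:
    path = block["input"]
    manifest.input_digests[str(path)] = _digest(path)
    measurements = rs.read_interaction_table(path)
    receptor_map = block.get("receptor_map", {})
    if isinstance(receptor_map, str):
        manifest.input_digests[receptor_map] = _digest(receptor_map)
        receptor_map = yaml.safe_load(Path(receptor_map).read_text())
    matrix = rs.build_rbg_matrix(measurements, receptor_map)

    out = {"rbg_matrix": str(outdir / "rbg_matrix.tsv")}
    matrix.values.to_csv(out["rbg_matrix"], sep="\t")

    values = matrix.values.to_numpy().ravel()
    cal = rs.calibrate_thresholds(
        values[~np.isnan(values)],
        n_boot=block.get("n_boot", 1000),
        seed=cfg.get("seed", 0),
    )
    out["calibration"] = str(outdir / "calibration.json")
    Path(out["calibration"]).write_text(json.dumps({
        "peak_low": cal.peak_low, "peak_high": cal.peak_high,
        "valley": cal.valley, "ci_low": cal.ci_low, "ci_high": cal.ci_high,
        "class_bounds": list(cal.class_bounds), "n_boot": cal.n_boot,
        "bandwidth": cal.bandwidth, "seed": cfg.get("seed", 0),
    }, indent=2))

    classes = matrix.values.map(
        lambda v: "" if pd.isna(v) else rs.classify_resistance(v, cal)
    )
    out["class_matrix"] = str(outdir / "class_matrix.tsv")
    classes.to_csv(out["class_matrix"], sep="\t")

    out["cross_resistance"] = str(outdir / "cross_resistance.tsv")
    rs.cross_resistance_summary(
        matrix, cal, group_rule=block.get("group_rule", "all")
    ).to_csv(out["cross_resistance"], sep="\t", index=False)

    cluster = rs.cluster_rbg_matrix(matrix)
    if cluster.newick is not None:
        out["linkage"] = str(outdir / "strain_linkage.nwk")
        Path(out["linkage"]).write_text(cluster.newick + "\n")
    return out


def _stage_fitness(cfg, block, outdir, manifest) -> dict[str, str]:
    out = {}
    if "competition" in block:
        path = block["competition"]
        manifest.input_digests[str(path)] = _digest(path)
        assays = fm.read_competition_table(path)
        table = fm.summarize_competition(assays)
        table.loc[len(table)] = {"replicate": "mean",
                                 "W": table["W"].mean(), "undefined": False}
        out["competition"] = str(outdir / "competition_fitness.tsv")
        table.to_csv(out["competition"], sep="\t", index=False)
    if "titers" in block:
        path = block["titers"]
        manifest.input_digests[str(path)] = _digest(path)
        df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
        reference = block.get("reference_strain", "WT")
        rows = []
        for (strain, phage), sub in df.groupby(["strain", "phage"]):
            if strain == reference:
                continue
            for r in sub.itertuples():
                ref = df[(df["strain"] == reference) & (df["phage"] == phage)
                         & (df["replicate"] == r.replicate)]
                if ref.empty:
                    continue
                res = fm.efficiency_of_plating(fm.TiterPair(
                    test_titer=float(r.titer),
                    reference_titer=float(ref["titer"].iloc[0]),
                    detection_limit=float(getattr(r, "detection_limit", 0.0)),
                ))
                rows.append({"strain": strain, "phage": phage,
                             "replicate": r.replicate, "eop": res.value,
                             "below_detection": res.below_detection})
        out["eop"] = str(outdir / "eop.tsv")
        pd.DataFrame(rows).to_csv(out["eop"], sep="\t", index=False)
    return out


def _stage_mutations(cfg, block, outdir, manifest) -> dict[str, str]:
    path = block["input"]
    manifest.input_digests[str(path)] = _digest(path)
    records = ma.read_variant_table(path, dialect=block.get("dialect", "tsv"))
    if "ancestor" in block:
        manifest.input_digests[block["ancestor"]] = _digest(block["ancestor"])
        ancestor = ma.read_variant_table(block["ancestor"],
                                         dialect=block.get("dialect", "tsv"))
        records = ma.subtract_background(records, ancestor)
    records = ma.filter_lof_variants(
        records, min_freq=block.get("min_freq", ma.DEFAULT_MIN_FREQ)
    )
    spectrum = ma.mutation_spectrum(records)
    out = {"gene_counts": str(outdir / "spectrum_genes.tsv")}
    spectrum.gene_counts.rename("count").to_csv(out["gene_counts"], sep="\t")
    out["class_counts"] = str(outdir / "spectrum_classes.tsv")
    spectrum.class_counts.rename("count").to_csv(out["class_counts"], sep="\t")

    if any(r.timepoint is not None for r in records):
        traj = ma.build_trajectories(
            [r for r in records if r.timepoint is not None],
            aggregate=block.get("aggregate", "class"),
            combine=block.get("combine", "max"),
        )
        rows = [
            {"key": key, "replicate": rep, "timepoint": tp, "frequency": frame.at[rep, tp]}
            for key, frame in traj.series.items()
            for rep in frame.index for tp in frame.columns
        ]
        out["trajectories"] = str(outdir / "trajectories.tsv")
        pd.DataFrame(rows).to_csv(out["trajectories"], sep="\t", index=False)
        events = ma.detect_sequential_acquisition(
            traj, threshold=block.get("threshold", 0.5)
        )
        out["acquisition_order"] = str(outdir / "acquisition_order.json")
        Path(out["acquisition_order"]).write_text(json.dumps(
            [dataclasses.asdict(e) for e in events], indent=2))
    return out


def _stage_tnseq(cfg, block, outdir, manifest) -> dict[str, str]:
    path = block["input"]
    manifest.input_digests[str(path)] = _digest(path)
    table = tn.read_count_table(path)
    enrich = tn.compute_enrichment(
        table, pseudocount=block.get("pseudocount", tn.DEFAULT_PSEUDOCOUNT)
    )
    out = {"enrichment": str(outdir / "tnseq_enrichment.tsv")}
    enrich.to_csv(out["enrichment"], sep="\t", index=False)
    return out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "kinetics": _stage_kinetics,
    "rbg": _stage_rbg,
    "fitness": _stage_fitness,
    "mutations": _stage_mutations,
    "tnseq": _stage_tnseq,
}

#: Fixture written by the simulate stage that feeds each downstream stage.
_SIMULATED_INPUT = {
    "kinetics": ("input", "growth"),
    "rbg": ("input", "interactions"),
    "fitness": ("competition", "competition"),
    "mutations": ("input", "variants"),
    "tnseq": ("input", "tnseq"),
}


def run_workflow(config_path) -> RunManifest:
    """Execute the configured stages and write ``manifest.json``.

    A stage failure is recorded in the manifest and aborts the stages
    after it; outputs of completed stages are preserved. Raises
    :class:`ConfigError` before any stage runs if the config is invalid.
    """
    violations = validate_config(config_path)
    if violations:
        raise ConfigError("; ".join(violations))
    cfg = _load_config(config_path)
    outdir = Path(cfg.get("outdir", "phage_evo_results"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(config=cfg, seed=cfg.get("seed", 0), version=__version__)
    aborted = False
    for stage in STAGE_ORDER:
        block = cfg.get(stage)
        if block is None:
            manifest.stages_skipped.append(stage)
            continue
        if aborted:
            manifest.stages_skipped.append(stage)
            manifest.warnings.append(f"stage {stage} skipped after upstream failure")
            continue
        if stage in _SIMULATED_INPUT and "simulate" in cfg:
            key, fixture = _SIMULATED_INPUT[stage]
            block.setdefault(key, manifest.stage_outputs["simulate"][fixture])
            if stage == "rbg":
                block.setdefault("receptor_map",
                                 manifest.stage_outputs["simulate"]["receptor_map"])
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = _STAGE_FUNCS[stage](cfg, block, outdir, manifest)
            manifest.warnings.extend(f"{stage}: {w.message}" for w in caught)
            manifest.stage_outputs[stage] = outputs
        except Exception as exc:  # noqa: BLE001 - recorded, downstream aborted
            logger.error("stage %s failed: %s", stage, exc)
            manifest.failure = {"stage": stage, "error": str(exc)}
            aborted = True

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json() + "\n")
    return manifest
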