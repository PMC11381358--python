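"""Config-driven orchestration of the tail analysis stages.

A YAML config names the samples (sample, condition, alignment path), the
gene annotation, and stage parameters; ``run_pipeline`` executes
tail calling → gene assignment/summaries → differential testing →
composition profiling (and, when configured, the metabolic-labeling
kinetics stage), writing every intermediate TSV plus a JSON manifest with
parameters, input checksums and row counts. Files are the interface
between stages, so a run is resumable and each stage independently
testable; reruns with the same config reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, composition, differential, kinetics, tailcall, tailstats

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "min_frac_A": tailcall.DEFAULT_MIN_FRAC_A,
    "min_len": tailcall.DEFAULT_MIN_LEN,
    "min_reads": differential.DEFAULT_MIN_READS,
    "fdr": differential.DEFAULT_FDR,
    "anchor": "three_prime_end",
    "max_pos": None,  # per-anchor default
    "min_qual": kinetics.DEFAULT_MIN_QUAL,
    "end_trim": kinetics.DEFAULT_END_TRIM,
    "t_label": kinetics.DEFAULT_T_LABEL,
}

_RANGES = {
    "min_frac_A": (0.0, 1.0),
    "min_len": (1, 10_000),
    "min_reads": (1, 10**9),
    "fdr": (0.0, 1.0),
    "min_qual": (0, 94),
    "end_trim": (0, 1000),
    "t_label": (1e-9, 1e6),
}


@dataclasses.dataclass
class RunConfig:
    samples: list[dict]  # sample, condition, alignment
    annotation: str
    outdir: str
    params: dict
    conditions: tuple[str, str] | None = None
    isoforms: str | None = None
    timelapse: dict | None = None
    seed: int = 0


class ConfigError(ValueError):
    pass


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, filling parameter defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for key in ("samples", "annotation", "outdir"):
        if key not in raw:
            raise ConfigError(f"missing required config key: {key}")
    samples = raw["samples"]
    if not isinstance(samples, list) or not samples:
        raise ConfigError("samples must be a nonempty list")
    for s in samples:
        for key in ("sample", "condition", "alignment"):
            if key not in s:
                raise ConfigError(f"sample entry missing key: {key}")
        if not Path(s["alignment"]).exists():
            raise ConfigError(f"sample {s['sample']}: alignment not found: {s['alignment']}")
    if not Path(raw["annotation"]).exists():
        raise ConfigError(f"annotation not found: {raw['annotation']}")
    params = dict(DEFAULT_PARAMS)
    params.update(raw.get("params", {}))
    for name, (lo, hi) in _RANGES.items():
        v = params[name]
        if v is not None and not lo <= v <= hi:
            raise ConfigError(f"parameter {name}={v} outside [{lo}, {hi}]")
    if params["anchor"] not in composition.ANCHORS:
        raise ConfigError(f"parameter anchor must be one of {composition.ANCHORS}")
    conditions = raw.get("conditions")
    if conditions is not None:
        if len(conditions) != 2:
            raise ConfigError("conditions must name exactly two condition labels")
        conditions = tuple(conditions)
    iso = raw.get("isoforms")
    if iso is not None and not Path(iso).exists():
        raise ConfigError(f"isoforms table not found: {iso}")
    tl = raw.get("timelapse")
    if tl is not None:
        if "mutation_table" not in tl:
            raise ConfigError("timelapse section requires mutation_table")
        if not Path(tl["mutation_table"]).exists():
            raise ConfigError(f"timelapse mutation_table not found: {tl['mutation_table']}")
    return RunConfig(
        samples=samples, annotation=raw["annotation"], outdir=raw["outdir"],
        params=params, conditions=conditions, isoforms=iso, timelapse=tl,
        seed=int(raw.get("seed", 0)),
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][path.name] = {"rows": int(len(df)), "path": str(path)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "version": __version__,
        "params": {k: v for k, v in p.items()},
        "seed": config.seed,
        "inputs": {s["sample"]: _sha256(s["alignment"]) for s in config.samples},
        "outputs": {},
    }
    stage = "tailcall"
    try:
        tables = []
        for s in config.samples:
            reads = tailcall.read_alignments(s["alignment"], sample=s["sample"])
            t = tailcall.tail_table(reads, p["min_frac_A"], p["min_len"])
            t["condition"] = s["condition"]
            tables.append(t)
        tails = pd.concat(tables, ignore_index=True)
        _write(tails, outdir / "tails.tsv", manifest)

        stage = "tailstats"
        annotation = tailstats.read_annotation(config.annotation)
        assigned = tailstats.assign_to_genes(tails, annotation)
        _write(assigned, outdir / "tails_assigned.tsv", manifest)
        by_cond = dict(tuple(assigned.groupby("condition")))
        summaries = []
        for cond, sub in by_cond.items():
            sub = sub.copy()
            sub["sample"] = cond  # pool replicates per condition
            summaries.append(tailstats.summarize_by_gene(sub))
        _write(pd.concat(summaries, ignore_index=True), outdir / "gene_summaries.tsv", manifest)
        if config.isoforms:
            iso = pd.read_csv(config.isoforms, sep="\t")
            iso_sum = tailstats.summarize_by_isoform(assigned, iso)
            _write(iso_sum, outdir / "isoform_summaries.tsv", manifest)

        stage = "difftails"
        conds = config.conditions or tuple(sorted(by_cond))[:2]
        if len(by_cond) >= 2:
            a, b = conds
            diff = differential.compare_conditions(
                by_cond[a], by_cond[b], min_reads=p["min_reads"], fdr=p["fdr"],
                label_a=a, label_b=b,
            )
            _write(diff, outdir / "difftails.tsv", manifest)

            stage = "composition"
            profiles = [
                composition.build_profile(by_cond[c], p["anchor"], p["max_pos"], condition=c)
                for c in conds
            ]
            _write(pd.concat(profiles, ignore_index=True), outdir / "composition.tsv", manifest)
            pvals = composition.positionwise_test(by_cond[a], by_cond[b], p["anchor"], p["max_pos"])
            _write(pvals, outdir / "composition_pvalues.tsv", manifest)

        if config.timelapse:
            stage = "timelapse"
            mut = pd.read_csv(config.timelapse["mutation_table"], sep="\t")
            fix_p_old = config.timelapse.get("p_old")
            kin = kinetics.fit_gene_kinetics(mut, t_label=p["t_label"], fix_p_old=fix_p_old)
            _write(kin, outdir / "kinetics.tsv", manifest)
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
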