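"""One-config orchestration of the full pipeline.

Stages communicate exclusively through the documented on-disk formats in the
output directory:

    out/
      cohort/            methylomes, sample sheet, layout, truth (simulate)
      calls/             per-sample PMD BED6 (call)
      stats/             frequency track, fraction curve, shuffle summary
      cimp/              per-sample CIMP table + fit JSON
      genes/             gene frequency table + exclusion tests
      profiles/          tile matrix, trees, PCA scores
      manifest.json      config hash, seeds, versions, timestamps
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import PmdCallConfig, call_pmds
from .cimp import cgi_matrix, cimp_inputs, fit_beta_regression
from .genes import exclusion_test, gene_pmd_frequency
from .intervals import IntervalSet
from .io import write_intervals
from .profiles import pmd_binary_cluster, tile_matrix
from .simulate import SimConfig, generate_cohort, write_cohort
from .stats import frequency_fraction_curve, frequency_track, genome_fraction

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"outdir", "seed", "simulate", "call", "stats", "cimp", "genes", "profiles"}


def load_pipeline_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    if "outdir" not in cfg:
        raise ValueError("pipeline config must set 'outdir'")
    return cfg


def _subconfig(cls, block: dict | None, **overrides):
    block = dict(block or {})
    block.update(overrides)
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in block and isinstance(block[f.name], list):
            block[f.name] = tuple(block[f.name])
    return cls(**block)


def run_pipeline(config: dict, config_path: str | None = None) -> dict:
    """Run simulate -> call -> stats -> cimp -> genes -> profiles.

    Returns the manifest dictionary (also written to ``outdir/manifest.json``).
    """
    t_start = time.time()
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "pmdscape_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "config_path": str(config_path) if config_path else None,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"t": round(time.time() - t_start, 2)}

    try:
        # ---- simulate
        _stage("simulate")
        sim = _subconfig(SimConfig, config.get("simulate"), seed=seed)
        cohort = generate_cohort(sim)
        write_cohort(cohort, outdir / "cohort")

        # ---- call
        _stage("call")
        call_cfg = _subconfig(PmdCallConfig, config.get("call"))
        (outdir / "calls").mkdir(exist_ok=True)
        calls: dict[str, IntervalSet] = {}
        for s in cohort.samples:
            pmds = call_pmds(s, cohort.layout, call_cfg)
            calls[s.sample_id] = pmds
            write_intervals(pmds, outdir / "calls" / f"{s.sample_id}.pmds.bed", bed6=True)

        # ---- stats
        _stage("stats")
        stats_cfg = config.get("stats") or {}
        (outdir / "stats").mkdir(exist_ok=True)
        fracs = {sid: genome_fraction(p, cohort.layout) for sid, p in calls.items()}
        pd.Series(fracs, name="genome_fraction").rename_axis("sample_id").to_csv(
            outdir / "stats" / "genome_fraction.tsv", sep="\t")
        track = frequency_track(calls, cohort.layout,
                                tile_bp=int(stats_cfg.get("tile_bp", 30_000)))
        track.df.to_csv(outdir / "stats" / "frequency_track.tsv", sep="\t", index=False)
        curve = frequency_fraction_curve(track)
        curve.rename_axis("freq").to_csv(outdir / "stats" / "fraction_curve.tsv", sep="\t")

        # ---- cimp
        _stage("cimp")
        (outdir / "cimp").mkdir(exist_ok=True)
        matrix = cgi_matrix(cohort.samples, cohort.layout, calls)
        inputs = cimp_inputs(matrix)
        inputs.to_csv(outdir / "cimp" / "cimp_inputs.tsv", sep="\t", index=False)
        fit_info: dict = {"fitted": False}
        if len(inputs) >= 5 and inputs.frac_cgi_in_pmd.nunique() > 1:
            fit = fit_beta_regression(inputs.b_cimp.to_numpy(),
                                      inputs.frac_cgi_in_pmd.to_numpy())
            fit_info = {"fitted": True, **dataclasses.asdict(fit)}
        with open(outdir / "cimp" / "fit.json", "w") as fh:
            json.dump(fit_info, fh, indent=1)

        # ---- genes
        _stage("genes")
        (outdir / "genes").mkdir(exist_ok=True)
        table = gene_pmd_frequency(cohort.layout, calls)
        table.to_csv(outdir / "genes" / "gene_frequency.tsv", sep="\t", index=False)
        tests = {}
        for set_name in cohort.layout.gene_sets:
            try:
                r = exclusion_test(table, set_name)
                tests[set_name] = dataclasses.asdict(r)
            except ValueError as exc:
                tests[set_name] = {"error": str(exc)}
        with open(outdir / "genes" / "exclusion_tests.json", "w") as fh:
            json.dump(tests, fh, indent=1)

        # ---- profiles
        _stage("profiles")
        prof_cfg = config.get("profiles") or {}
        (outdir / "profiles").mkdir(exist_ok=True)
        tiles = tile_matrix(cohort.samples, cohort.layout,
                            tile_bp=int(prof_cfg.get("tile_bp", 10_000)))
        tiles.df.to_csv(outdir / "profiles" / "tile_matrix.tsv", sep="\t")
        if len(cohort.samples) >= 3:
            tree = pmd_binary_cluster(calls, cohort.layout,
                                      tile_bp=int(prof_cfg.get("binary_tile_bp", 5_000)))
            (outdir / "profiles" / "pmd_cluster.nwk").write_text(tree.newick() + "\n")
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["wall_seconds"] = round(time.time() - t_start, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
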