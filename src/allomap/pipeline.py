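"""Configuration validation and the end-to-end synthetic pipeline.

A run config is a flat mapping: a global ``seed``, an output directory, the
ordered ``stages`` to execute, and one parameter map per stage.  Unknown keys
anywhere are rejected before any stage runs.  Every stage derives its own
random stream from the root seed by stage name, writes its outputs under the
output directory, and contributes row counts to a provenance record
(``provenance.json``) that contains no wall-clock information, so a repeated
run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd

from . import __version__, cistrans, haplotag, io as aio, sim, xmap
from ._util import child_rng

log = logging.getLogger("allomap")


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


_STAGES = ("sim", "cistrans", "haplotag", "xmap")

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out", "stages", "sim", "cistrans", "haplotag", "xmap"},
    "sim": {"expression", "haplotag", "deletion"},
    "sim.expression": {f.name for f in dataclasses.fields(sim.ExpressionSimConfig)} - {"seed"},
    "sim.haplotag": {f.name for f in dataclasses.fields(sim.HaplotagSimConfig)} - {"seed"},
    "sim.deletion": {f.name for f in dataclasses.fields(sim.DeletionSimConfig)}
    - {"seed", "chrom_genes"},
    "cistrans": {"alpha", "pseudocount", "lfc_threshold"},
    "haplotag": {"min_support", "gap_threshold", "genome_size", "generations",
                 "correct_detection", "n_bootstrap"},
    "xmap": {"alpha", "min_delta_loglik", "min_fraction_change"},
}


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")

    def check(section: str, mapping: dict) -> None:
        unknown = set(mapping) - _SCHEMA[section]
        if unknown:
            where = section or "top level"
            raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")

    check("", config)
    stages = config.get("stages", list(_STAGES))
    bad = set(stages) - set(_STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s) {sorted(bad)}")
    simcfg = config.get("sim", {})
    check("sim", simcfg)
    for sub in ("expression", "haplotag", "deletion"):
        check(f"sim.{sub}", simcfg.get(sub, {}))
    for stage in ("cistrans", "haplotag", "xmap"):
        check(stage, config.get(stage, {}))
    out = dict(config)
    out["stages"] = list(stages)
    out.setdefault("seed", 0)
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order; return the provenance record."""
    config = validate_config(config)
    out = Path(out_dir or config.get("out", "allomap_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    provenance: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {
            "allomap": __version__,
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    for stage in config["stages"]:
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            rows = _RUNNERS[stage](config, out, seed)
        except (ConfigError, StageError):
            raise
        except Exception as e:
            raise StageError(f"stage {stage} failed: {e}") from e
        log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
        provenance["stages"][stage] = rows
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return provenance


# ---------------------------------------------------------------------------
# Stage runners (each returns per-output row counts)
# ---------------------------------------------------------------------------

def _run_sim(config: dict, out: Path, seed: int) -> dict:
    p = config.get("sim", {})
    ecfg = sim.ExpressionSimConfig(**p.get("expression", {}), seed=seed)
    counts, samples, truth = sim.simulate_expression_panel(ecfg)
    aio.write_counts(counts, out / "expr_counts.tsv")
    aio.write_table(samples, out / "expr_samples.tsv")
    aio.write_table(truth, out / "expr_truth.tsv")

    hcfg = sim.HaplotagSimConfig(**p.get("haplotag", {}), seed=seed)
    obs, variants, htruth = sim.simulate_haplotag_molecules(hcfg)
    aio.write_table(obs, out / "haplotag_obs.tsv")
    aio.write_table(variants, out / "haplotag_variants.tsv")
    aio.write_table(htruth, out / "haplotag_truth.tsv")

    dcfg = sim.DeletionSimConfig(**p.get("deletion", {}), seed=seed)
    dcounts, dsamples, tracks, dtruth = sim.simulate_deletion_panel(dcfg)
    aio.write_counts(dcounts, out / "del_counts.tsv")
    aio.write_table(dsamples, out / "del_samples.tsv")
    aio.write_table(dtruth, out / "del_truth.tsv")
    for line, track in tracks.items():
        aio.write_table(track, out / f"del_track_{line}.tsv")
    return {"expr_genes": len(counts), "haplotag_observations": len(obs),
            "deletion_lines": len(dtruth)}


def _run_cistrans(config: dict, out: Path, seed: int) -> dict:
    p = config.get("cistrans", {})
    counts, samples = aio.read_counts(out / "expr_counts.tsv", out / "expr_samples.tsv")
    result = cistrans.classify_all(
        counts, samples,
        alpha=p.get("alpha", 0.05), pseudocount=p.get("pseudocount", 0.5))
    aio.write_table(result.effects, out / "gene_effects.tsv")
    aio.write_table(result.calls, out / "regulatory_calls.tsv")
    aio.write_table(result.summary, out / "category_summary.tsv")
    kept = cistrans.filter_twofold(result.calls, result.effects,
                                   threshold=p.get("lfc_threshold", 1.0))
    (out / "twofold_genes.txt").write_text("\n".join(kept) + ("\n" if len(kept) else ""))
    return {"genes": len(result.effects), "twofold_genes": len(kept)}


def _run_haplotag(config: dict, out: Path, seed: int) -> dict:
    p = config.get("haplotag", {})
    obs = aio.read_table(out / "haplotag_obs.tsv")
    variants = aio.read_variants(out / "haplotag_variants.tsv")
    calls, stats = haplotag.call_species(obs, variants)
    sites, molecules = haplotag.build_molecules(
        calls, gap_threshold=p.get("gap_threshold", haplotag.DEFAULT_GAP_THRESHOLD))
    rec = haplotag.call_recombinants(sites, min_support=p.get("min_support",
                                                              haplotag.DEFAULT_MIN_SUPPORT))
    aio.write_table(molecules, out / "molecules.tsv")
    aio.write_table(rec, out / "recombinants.tsv")
    if len(molecules):
        est = haplotag.summarize_recombination(
            sites, rec,
            genome_size=p.get("genome_size", 6.2e9),
            generations=p.get("generations", 3.0),
            min_support=p.get("min_support", haplotag.DEFAULT_MIN_SUPPORT),
            correct_detection=p.get("correct_detection", True),
            n_bootstrap=p.get("n_bootstrap", 1000),
            seed=seed,
        )
        with open(out / "rate_estimate.json", "w") as fh:
            json.dump(dataclasses.asdict(est), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return {"molecules": len(molecules), "recombinants": len(rec),
            "dropped_sites": stats["mismatch_base"] + stats["unknown_position"]}


def _run_xmap(config: dict, out: Path, seed: int) -> dict:
    p = config.get("xmap", {})
    truth = aio.read_table(out / "del_truth.tsv")
    bp_calls = []
    rows = []
    for line in truth["line"]:
        track = aio.read_table(out / f"del_track_{line}.tsv")
        call = xmap.fit_breakpoint(
            track, min_delta_loglik=p.get("min_delta_loglik", 10.0),
            min_fraction_change=p.get("min_fraction_change", 0.1))
        if call is not None:
            bp_calls.append(call)
            rows.append((line, call.left_position, call.right_position,
                         call.p_left, call.p_right, call.delta_loglik,
                         call.lost_species))
    aio.write_table(
        pd.DataFrame(rows, columns=["line", "left_position", "right_position",
                                    "p_left", "p_right", "delta_loglik",
                                    "lost_species"]),
        out / "breakpoints.tsv")
    aio.write_bed(bp_calls, out / "breakpoints.bed")

    counts, samples = aio.read_counts(out / "del_counts.tsv", out / "del_samples.tsv")
    autosomal = counts.loc[counts.index.str.startswith("agene")]
    factors = cistrans.compute_size_factors(counts)
    logmat = cistrans.log_expression(autosomal, factors)
    trans = xmap.map_trans_targets(logmat, samples, alpha=p.get("alpha", 0.05))
    aio.write_table(trans, out / "trans_targets.tsv")
    return {"breakpoints": len(rows),
            "species_specific_trans": int(trans["species_specific"].sum())}


_RUNNERS = {"sim": _run_sim, "cistrans": _run_cistrans,
            "haplotag": _run_haplotag, "xmap": _run_xmap}
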