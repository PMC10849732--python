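"""End-to-end driver: simulate → score → map → filter → report.

The pipeline generates one synthetic cohort per genotype arm ('sibling_pool'
and 'null'), scores tonic and impulse traces, maps subtype topography, runs
the cross-genotype comparison statistics and the atlas-filtered DE sweep,
and writes a machine-readable JSON summary.  One explicit seed is fanned out
per stage through named substreams, so identical config + seed reproduces a
byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .errors import InvalidConfigError
from .expression import AtlasDetection, CountMatrix, threshold_sweep
from .groupstats import anova_multcomp, summarize_groups
from .schedules import impulse_schedule, tonic_schedule
from .scoring import score_neurons
from .synthetic import (
    SimConfig,
    simulate_counts_and_atlas,
    simulate_impulse_traces,
    simulate_positions,
    simulate_tonic_traces,
)
from .topography import axis_comparison_report, bootstrap_distribution, manova_separation

log = logging.getLogger("tiltpipe")

GENOTYPE_ARMS = ("sibling_pool", "null")


@dataclass
class RunConfig:
    """Validated run configuration for the end-to-end pipeline."""

    seed: int = 0
    out_dir: str = "tiltpipe_out"
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: tuple[float, ...] = (0, 1, 3, 5, 10, 30, 50)
    alpha: float = 0.05
    lfc_cutoff: float = 2.0
    bootstrap_iterations: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", {})
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_raw) - sim_known
        if bad:
            raise InvalidConfigError(f"unknown sim config keys: {sorted(bad)}")
        if "roi_size_range" in sim_raw:
            sim_raw["roi_size_range"] = tuple(sim_raw["roi_size_range"])
        cfg = cls(sim=SimConfig(**sim_raw), **raw)
        if "thresholds" in raw:
            cfg.thresholds = tuple(raw["thresholds"])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise InvalidConfigError("seed must be an explicit integer (no wall-clock seeding)")
        self.sim.validate()
        if not all(0 <= t <= 100 for t in self.thresholds):
            raise InvalidConfigError("thresholds must lie in [0, 100] percent")


def _round_floats(obj, ndigits: int = 6):
    """Stable rounding so the JSON summary is byte-identical across runs."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on synthetic cohorts and return the JSON-able summary.

    Outputs (scores TSV, coordinates CSV, DE sweep TSV, summary JSON) are
    written under ``config.out_dir``; inputs on disk are never mutated.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info("seed=%d thresholds=%s alpha=%g lfc>%g", config.seed, config.thresholds,
             config.alpha, config.lfc_cutoff)

    summary: dict = {"seed": config.seed, "stages": {}}
    tonic = tonic_schedule(config.sim.frame_rate)
    imp = impulse_schedule(config.sim.frame_rate)

    score_frames = []
    positions = {}
    for arm in GENOTYPE_ARMS:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        traces, truth = simulate_tonic_traces(sim, genotype=arm)
        scores = score_neurons(traces, tonic)
        df = pd.DataFrame(
            {
                "neuron_id": [s.neuron_id for s in scores],
                "genotype": arm,
                "dff_up": [s.dff_up for s in scores],
                "dff_down": [s.dff_down for s in scores],
                "tuning_index": [s.tuning_index for s in scores],
                "subtype": [s.subtype for s in scores],
                "true_subtype": [truth.subtype[s.neuron_id] for s in scores],
            }
        )
        itraces, itruth = simulate_impulse_traces(sim, genotype=arm)
        iscores = score_neurons(itraces, imp)
        idf = pd.DataFrame(
            {
                "neuron_id": [s.neuron_id for s in iscores],
                "dff_impulse": [s.dff_mean for s in iscores],
                "impulse_responsive": [s.responsive for s in iscores],
                "impulse_tuning_index": [s.impulse_tuning_index for s in iscores],
            }
        )
        df = df.merge(idf, on="neuron_id")
        score_frames.append(df)

        pos, _ = simulate_positions(sim, genotype=arm, subtype_of=truth.subtype)
        positions[arm] = pos

        frac = df["subtype"].value_counts(normalize=True)
        summary["stages"].setdefault("scoring", {})[arm] = {
            "n_neurons": len(df),
            "subtype_fractions": {k: float(frac.get(k, 0.0)) for k in ("nose_up", "nose_down", "untuned")},
            "subtype_recovery_accuracy": float((df["subtype"] == df["true_subtype"]).mean()),
            "impulse_responsive_fraction": float(df["impulse_responsive"].mean()),
            "mean_dff_up": float(df.loc[df.subtype == "nose_up", "dff_up"].mean()),
            "mean_dff_down": float(df.loc[df.subtype == "nose_down", "dff_down"].mean()),
        }

    all_scores = pd.concat(score_frames, ignore_index=True)
    all_scores.to_csv(out / "scores.tsv", sep="\t", index=False)

    # topography: subtype separation within the sibling arm, per-axis KS across arms
    sib = positions["sibling_pool"]
    up = sib[sib.label == "nose_up"]
    down = sib[sib.label == "nose_down"]
    stat, p = manova_separation(up, down)
    boot = bootstrap_distribution(
        sib["z_um"].to_numpy(), config.bootstrap_iterations, seed=config.seed, axis="z_um"
    )
    cross = axis_comparison_report(positions["null"], sib)
    summary["stages"]["topography"] = {
        "subtype_manova_wilks": stat,
        "subtype_manova_p": p,
        "bootstrap_mean_of_means": float(boot.sample_means.mean()),
        "cross_genotype_ks": {
            r.axis: {"D": r.ks_D, "p": r.ks_p} for r in cross.itertuples()
        },
    }
    for arm, pos in positions.items():
        tio.write_coordinates(pos, out / f"positions_{arm}.csv")

    # group statistics across genotypes
    gs = summarize_groups(all_scores, ("dff_up", "dff_down", "dff_impulse"), by="genotype")
    gs.to_csv(out / "group_summary.tsv", sep="\t", index=False)
    F, p_anova, pairs = anova_multcomp(
        all_scores["dff_impulse"].to_numpy(), all_scores["genotype"].to_numpy()
    )
    summary["stages"]["group_stats"] = {"impulse_dff_anova_F": F, "impulse_dff_anova_p": p_anova}

    # differential expression with atlas filtering
    counts_df, condition, atlas_df, cluster, gtruth = simulate_counts_and_atlas(
        dataclasses.replace(config.sim, seed=config.seed)
    )
    counts = CountMatrix(counts_df, condition)
    atlas = AtlasDetection(atlas_df, cluster)
    sweep = threshold_sweep(
        counts, atlas, config.thresholds, alpha=config.alpha, lfc_cutoff=config.lfc_cutoff
    )
    sweep.to_csv(out / "de_sweep.tsv", sep="\t", index=False)
    summary["stages"]["expression"] = {
        "thresholds": [
            {
                "threshold_pct": int(r.threshold_pct),
                "universe_size": int(r.universe_size),
                "n_deg": int(r.n_deg),
            }
            for r in sweep.itertuples()
        ]
    }

    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary
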