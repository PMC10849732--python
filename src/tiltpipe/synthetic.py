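"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of the study conditions the pipeline is
built for: tilt-in-place calcium imaging of vestibular projection neurons in
motor-neuron-null larvae and sibling controls, dorsoventrally topographic
soma positions, negative-binomially distributed bulk RNA-seq counts with
planted fold changes, and a binary single-cell detection atlas with a
labelled projection-neuron cluster.

Fluorescence model
------------------
A neuron's raw fluorescence is

    F(t) = roi_size × [ baseline_level × (1 + A·k(t)) + ε(t) ],

where k(t) is a unit-peak single-exponential indicator kernel (GCaMP6s-like,
τ = 1.8 s by default) stepping on at the response onset, A is the response
amplitude in ΔFF units, and ε is i.i.d. Gaussian noise with SD
``baseline_sd`` (a.u.).  ROI size acts multiplicatively so that the scoring
module's ROI normalization is actually exercised.  With zero noise and zero
amplitude every frame equals ``baseline_level × roi_size`` exactly.

All generators are pure functions of (seed, config): the same configuration
always yields byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .scoring import FluorescenceTrace
from .schedules import (
    RESPONSE_WINDOW_S,
    StimulusSchedule,
    TONIC_RESPONSE_DOWN_T,
    TONIC_RESPONSE_UP_T,
    impulse_schedule,
    tonic_schedule,
)

#: subtype mixture matching the sibling-control proportions of the study
#: conditions emulated (46% nose-down, 47% nose-up, 7% untuned).
DEFAULT_SUBTYPE_FRACTIONS: Mapping[str, float] = {
    "nose_up": 0.47,
    "nose_down": 0.46,
    "untuned": 0.07,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic-data generator.

    Defaults describe one genotype arm of the emulated experiment: ~16 fish
    with ~19 imaged neurons each (≈300 neurons), 3 stimulus repeats at
    3 frames/s, responses of ΔFF ≈ 1.5 on a 100 a.u. baseline, bulk counts
    of 2,000 genes in 3 vs 3 samples, and a 1,468-cell detection atlas of
    which 32% form the projection-neuron cluster.
    """

    seed: int = 0
    n_fish_per_genotype: int = 16
    n_neurons_per_fish: int = 19
    subtype_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_FRACTIONS)
    )
    baseline_level: float = 100.0  # a.u.
    baseline_sd: float = 5.0  # a.u. (0.05 in ΔFF units on the default baseline)
    response_amplitude: float = 1.5  # ΔFF units
    impulse_amplitude: float = 0.35  # ΔFF units; impulses are weaker than tilts
    responsive_fraction: float = 0.58  # impulse-responsive share of neurons
    decay_time_constant: float = 1.8  # s, GCaMP6s-like
    frame_rate: float = 3.0  # frames/s
    roi_size_range: tuple[float, float] = (20.0, 80.0)  # μm²
    n_repeats: int = 3
    # soma topography
    dv_range: tuple[float, float] = (0.0, 40.0)  # μm
    dv_overlap: float = 8.0  # μm of dorsoventral overlap between subtypes
    ml_range: tuple[float, float] = (0.0, 40.0)
    rc_range: tuple[float, float] = (0.0, 60.0)
    # bulk counts + atlas
    n_genes: int = 2000
    n_samples_per_condition: int = 3
    mean_count_range: tuple[float, float] = (20.0, 500.0)  # log-uniform support
    nb_dispersion: float = 0.05
    nb_dispersion_lognorm_sigma: float = 0.3  # 0 ⇒ fixed dispersion
    planted_lfc: float = 4.0  # log2 units
    planted_gene_fraction: float = 0.05
    planted_detection_rate: float | None = None  # pin planted genes' atlas rate
    atlas_n_cells: int = 1468
    atlas_projection_fraction: float = 0.32
    detection_rate_distribution: np.ndarray | None = None  # per-gene rates
    detection_beta: tuple[float, float] = (0.3, 1.5)  # drawn when rates not given

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidConfigError("frame_rate must be positive")
        if self.baseline_level <= 0:
            raise InvalidConfigError("baseline_level must be positive")
        if self.baseline_sd < 0 or self.response_amplitude < 0:
            raise InvalidConfigError("baseline_sd and response_amplitude must be ≥ 0")
        if self.decay_time_constant <= 0:
            raise InvalidConfigError("decay_time_constant must be positive")
        if abs(sum(self.subtype_fractions.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("subtype_fractions must sum to 1")
        if not set(self.subtype_fractions) <= {"nose_up", "nose_down", "untuned"}:
            raise InvalidConfigError("unknown subtype in subtype_fractions")
        if self.roi_size_range[0] <= 0 or self.roi_size_range[1] < self.roi_size_range[0]:
            raise InvalidConfigError("roi_size_range must be positive and ordered")
        if not 0 <= self.planted_gene_fraction <= 1:
            raise InvalidConfigError("planted_gene_fraction must lie in [0, 1]")
        if not 0 <= self.responsive_fraction <= 1:
            raise InvalidConfigError("responsive_fraction must lie in [0, 1]")
        if self.n_samples_per_condition < 2:
            raise InvalidConfigError("need at least 2 samples per condition")
        if self.dv_overlap < 0 or self.dv_range[1] <= self.dv_range[0]:
            raise InvalidConfigError("invalid dorsoventral geometry")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """True labels keyed 1:1 to generated entities."""

    subtype: dict[str, str] = field(default_factory=dict)  # neuron_id → subtype
    responsive: dict[str, bool] = field(default_factory=dict)  # neuron_id → impulse
    gene_lfc: dict[str, float] = field(default_factory=dict)  # gene_id → true log2FC
    dv_section: dict[str, int] = field(default_factory=dict)  # neuron_id → section 1..8

    def to_frames(self) -> dict[str, pd.DataFrame]:
        out = {}
        if self.subtype:
            out["subtype"] = pd.DataFrame(
                {"neuron_id": list(self.subtype), "subtype": list(self.subtype.values())}
            )
        if self.responsive:
            out["responsive"] = pd.DataFrame(
                {"neuron_id": list(self.responsive), "responsive": list(self.responsive.values())}
            )
        if self.gene_lfc:
            out["gene_lfc"] = pd.DataFrame(
                {"gene_id": list(self.gene_lfc), "true_lfc": list(self.gene_lfc.values())}
            )
        if self.dv_section:
            out["dv_section"] = pd.DataFrame(
                {"neuron_id": list(self.dv_section), "dv_section": list(self.dv_section.values())}
            )
        return out


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per generator (stable across runs)."""
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def _kernel(times: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Unit-peak exponential-decay transient stepping on at ``onset``."""
    k = np.zeros_like(times)
    on = times >= onset
    k[on] = np.exp(-(times[on] - onset) / tau)
    return k


def _assign_subtypes(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    labels = list(config.subtype_fractions)
    probs = np.array([config.subtype_fractions[l] for l in labels])
    return rng.choice(labels, size=n, p=probs)


def _trace_set(
    config: SimConfig,
    schedule: StimulusSchedule,
    onsets_for: dict[str, tuple[tuple[float, float], ...]],
    labels: np.ndarray,
    rng: np.random.Generator,
    genotype: str,
) -> list[FluorescenceTrace]:
    """Build noisy raw traces given per-label (onset, amplitude) transients."""
    n_frames = schedule.n_frames
    times = np.arange(n_frames) / schedule.frame_rate
    traces: list[FluorescenceTrace] = []
    n_per_fish = config.n_neurons_per_fish
    roi_lo, roi_hi = config.roi_size_range
    for i, lab in enumerate(labels):
        fish = i // n_per_fish
        nid = f"{genotype}_f{fish:02d}_n{i:04d}"
        roi = rng.uniform(roi_lo, roi_hi)
        signal = np.zeros(n_frames)
        for onset, amp in onsets_for[lab]:
            signal += amp * _kernel(times, onset, config.decay_time_constant)
        clean = config.baseline_level * (1.0 + signal)
        for rep in range(1, config.n_repeats + 1):
            noise = rng.normal(0.0, config.baseline_sd, n_frames) if config.baseline_sd else 0.0
            traces.append(
                FluorescenceTrace(
                    neuron_id=nid,
                    fish_id=f"{genotype}_f{fish:02d}",
                    genotype=genotype,
                    repeat_index=rep,
                    roi_size=roi,
                    frames=roi * (clean + noise),
                )
            )
    return traces


def simulate_tonic_traces(
    config: SimConfig, genotype: str = "sibling_pool"
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Simulate tonic-protocol traces with known subtype labels.

    Nose-up neurons carry a transient at the restoration following the
    nose-up tilt, nose-down neurons at the restoration following nose-down,
    and untuned neurons carry equal transients in both windows (so they are
    responsive but non-selective).
    """
    config.validate()
    schedule = tonic_schedule(config.frame_rate)
    rng = _rng(config, f"tonic:{genotype}")
    n = config.n_fish_per_genotype * config.n_neurons_per_fish
    labels = _assign_subtypes(config, rng, n)
    amp = config.response_amplitude
    onsets_for = {
        "nose_up": ((TONIC_RESPONSE_UP_T, amp),),
        "nose_down": ((TONIC_RESPONSE_DOWN_T, amp),),
        "untuned": ((TONIC_RESPONSE_DOWN_T, amp), (TONIC_RESPONSE_UP_T, amp)),
    }
    traces = _trace_set(config, schedule, onsets_for, labels, rng, genotype)
    truth = GroundTruth(
        subtype={tr.neuron_id: str(lab) for tr, lab in zip(traces[:: config.n_repeats], labels)}
    )
    return traces, truth


def simulate_impulse_traces(
    config: SimConfig, genotype: str = "sibling_pool"
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Simulate impulse-protocol traces with known responsive labels.

    Responsive neurons carry equal-amplitude transients after both impulses
    (matching the near-zero impulse selectivity of the emulated data);
    unresponsive neurons carry none.
    """
    config.validate()
    schedule = impulse_schedule(config.frame_rate)
    rng = _rng(config, f"impulse:{genotype}")
    n = config.n_fish_per_genotype * config.n_neurons_per_fish
    resp = rng.random(n) < config.responsive_fraction
    labels = np.where(resp, "responsive", "silent")
    t1, t2 = schedule.impulse_onsets()
    amp = config.impulse_amplitude
    onsets_for = {
        "responsive": ((t1, amp), (t2, amp)),
        "silent": (),
    }
    traces = _trace_set(config, schedule, onsets_for, labels, rng, genotype)
    truth = GroundTruth(
        responsive={tr.neuron_id: bool(r) for tr, r in zip(traces[:: config.n_repeats], resp)}
    )
    return traces, truth


def simulate_positions(
    config: SimConfig,
    genotype: str = "sibling_pool",
    subtype_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate topographic soma coordinates (μm from the dorsomedial origin).

    Nose-up somata are drawn from a dorsal (low-z) band and nose-down from a
    ventral band; the bands overlap by ``dv_overlap`` μm in the middle of the
    dorsoventral range (overlap 0 ⇒ disjoint supports).  Untuned neurons are
    uniform over the whole range.  If ``subtype_of`` is given (e.g. from a
    tonic-trace ground truth), positions are generated for exactly those
    neurons; otherwise fresh neurons are drawn from ``subtype_fractions``.
    """
    config.validate()
    rng = _rng(config, f"positions:{genotype}")
    if subtype_of is None:
        n = config.n_fish_per_genotype * config.n_neurons_per_fish
        labels = _assign_subtypes(config, rng, n)
        ids = [f"{genotype}_p{i:04d}" for i in range(n)]
    else:
        ids = list(subtype_of)
        labels = np.array([subtype_of[i] for i in ids])
    z_lo, z_hi = config.dv_range
    mid = 0.5 * (z_lo + z_hi)
    half = 0.5 * config.dv_overlap
    z = np.empty(len(ids))
    for lab, (lo, hi) in {
        "nose_up": (z_lo, mid + half),  # dorsal band
        "nose_down": (mid - half, z_hi),  # ventral band
        "untuned": (z_lo, z_hi),
    }.items():
        mask = labels == lab
        z[mask] = rng.uniform(lo, hi, mask.sum())
    x = rng.uniform(*config.ml_range, len(ids))
    y = rng.uniform(*config.rc_range, len(ids))
    df = pd.DataFrame(
        {
            "neuron_id": ids,
            "genotype": genotype,
            "label": labels,
            "x_um": x,
            "y_um": y,
            "z_um": z,
        }
    )
    edges = np.linspace(z_lo, z_hi, 9)
    section = np.minimum(np.searchsorted(edges, z, side="right"), 8)
    truth = GroundTruth(
        subtype=dict(zip(ids, labels)),
        dv_section={i: int(s) for i, s in zip(ids, section)},
    )
    return df, truth


def simulate_counts_and_atlas(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate bulk NB counts plus a binary single-cell detection atlas.

    Returns ``(counts, condition, atlas, cluster, truth)`` where ``counts``
    is genes × samples, ``condition`` labels each sample 'null' or
    'sibling', ``atlas`` is a genes × cells 0/1 detection matrix and
    ``cluster`` labels each cell ('projection' or 'other').

    A ``planted_gene_fraction`` share of genes carries a true fold change of
    ±``planted_lfc`` (half up, half down), applied symmetrically about the
    base mean.  Per-gene dispersions are drawn log-normally around
    ``nb_dispersion`` (σ = ``nb_dispersion_lognorm_sigma``; 0 fixes them).
    Atlas detection is Bernoulli per cell with per-gene rates.
    """
    config.validate()
    rng = _rng(config, "counts")
    g, n = config.n_genes, config.n_samples_per_condition
    genes = [f"gene{i:05d}" for i in range(g)]
    samples = [f"null_{j}" for j in range(n)] + [f"sib_{j}" for j in range(n)]
    condition = pd.Series(["null"] * n + ["sibling"] * n, index=samples, name="condition")

    mu = np.exp(rng.uniform(*np.log(config.mean_count_range), g))
    if config.nb_dispersion_lognorm_sigma > 0:
        alpha = np.exp(
            rng.normal(np.log(config.nb_dispersion), config.nb_dispersion_lognorm_sigma, g)
        )
    else:
        alpha = np.full(g, config.nb_dispersion)

    n_planted = int(round(config.planted_gene_fraction * g))
    true_lfc = np.zeros(g)
    planted_idx = rng.choice(g, size=n_planted, replace=False)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    true_lfc[planted_idx] = signs * config.planted_lfc

    mu_null = mu * 2.0 ** (true_lfc / 2.0)
    mu_sib = mu * 2.0 ** (-true_lfc / 2.0)
    r = 1.0 / alpha

    def draw(mu_g: np.ndarray) -> np.ndarray:
        p = r / (r + mu_g)
        return rng.negative_binomial(r[:, None], p[:, None], (g, n))

    counts = pd.DataFrame(
        np.hstack([draw(mu_null), draw(mu_sib)]), index=genes, columns=samples
    )

    # --- detection atlas ---------------------------------------------------
    if config.detection_rate_distribution is not None:
        rates = np.asarray(config.detection_rate_distribution, dtype=float)
        if rates.shape != (g,) or rates.min() < 0 or rates.max() > 1:
            raise InvalidConfigError("detection_rate_distribution must be per-gene rates in [0,1]")
    else:
        rates = rng.beta(*config.detection_beta, g)
    if config.planted_detection_rate is not None:
        rates = rates.copy()
        rates[planted_idx] = config.planted_detection_rate
    cells = [f"cell{i:04d}" for i in range(config.atlas_n_cells)]
    n_proj = int(round(config.atlas_projection_fraction * config.atlas_n_cells))
    cluster = pd.Series(
        ["projection"] * n_proj + ["other"] * (config.atlas_n_cells - n_proj),
        index=cells,
        name="cluster",
    )
    atlas = pd.DataFrame(
        (rng.random((g, config.atlas_n_cells)) < rates[:, None]).astype(np.int8),
        index=genes,
        columns=cells,
    )
    truth = GroundTruth(gene_lfc=dict(zip(genes, true_lfc)))
    return counts, condition, atlas, cluster, truth
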