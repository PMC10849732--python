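"""ΔF/F scoring of tilt-evoked calcium responses.

A neuron's response to a tilt is the change in fluorescence over the first
second of restoration to horizontal, normalized by a baseline period:

    ΔFF = (mean F in response window − baseline mean) / baseline mean

The nose-down response is baselined on the initial 5-s horizontal window; the
nose-up response on the last 3 s of the horizontal segment that follows the
nose-down tilt.  A response is significant when it exceeds two standard
deviations above baseline, with the baseline SD expressed in the same ΔFF
units so the criterion is unit-consistent.

Directional selectivity is the difference of the two ΔFF responses
normalized by their sum, giving an index in ±1 (positive = nose-up
preference).  Negative ΔFF values are clamped at zero first, which keeps the
index bounded; neurons whose |index| falls below 0.1, or which lack a
significant response in the preferred direction, are labelled untuned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, StateError
from .schedules import (
    IMPULSE_BASELINE,
    RESPONSE_WINDOW_S,
    StimulusSchedule,
    TONIC_BASELINE_DOWN,
    TONIC_BASELINE_UP,
    TONIC_RESPONSE_DOWN_T,
    TONIC_RESPONSE_UP_T,
)

GENOTYPES = ("wildtype", "heterozygote", "null", "sibling_pool")
SUBTYPES = ("nose_up", "nose_down", "untuned")

#: minimum |tuning index| for a directional label
TUNING_THRESHOLD = 0.1
#: significance criterion: ΔFF must exceed this many baseline SDs
SIGNIFICANCE_SDS = 2.0


@dataclass
class FluorescenceTrace:
    """One neuron's frame series for one stimulus repeat."""

    neuron_id: str
    fish_id: str
    genotype: str
    repeat_index: int
    roi_size: float  # μm²
    frames: np.ndarray  # fluorescence, a.u.
    normalized: bool = False  # ROI normalization applied?

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise InvalidInputError(f"unknown genotype: {self.genotype!r}")
        if self.roi_size <= 0:
            raise InvalidInputError("roi_size must be positive")
        self.frames = np.asarray(self.frames, dtype=float)


@dataclass
class TiltResponseScore:
    """Per-neuron tonic-tilt response summary."""

    neuron_id: str
    dff_up: float
    dff_down: float
    baseline_mean_up: float
    baseline_mean_down: float
    baseline_sd_up: float  # in ΔFF units
    baseline_sd_down: float
    significant_up: bool
    significant_down: bool
    tuning_index: float = math.nan  # NaN marks the undefined (0, 0) case
    subtype: str = "untuned"
    genotype: str | None = None

    @property
    def tuning_defined(self) -> bool:
        return not math.isnan(self.tuning_index)


@dataclass
class ImpulseResponseScore:
    """Per-neuron impulse response summary."""

    neuron_id: str
    dff_impulses: tuple[float, ...]
    dff_mean: float
    baseline_sd: float  # in ΔFF units
    responsive: bool
    impulse_tuning_index: float = math.nan
    genotype: str | None = None


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Divide frames by ROI size (μm²) to remove magnification effects.

    Returns a new trace; attempting to normalize twice raises
    :class:`StateError` so accidental double scaling cannot pass silently.
    """
    if trace.normalized:
        raise StateError(f"trace {trace.neuron_id} is already ROI-normalized")
    if trace.roi_size <= 0:
        raise InvalidInputError("roi_size must be positive")
    return replace(trace, frames=trace.frames / trace.roi_size, normalized=True)


def _dff(frames: np.ndarray, response: slice, baseline: slice) -> tuple[float, float, float]:
    """Return (dff, baseline_mean, baseline_sd_in_dff_units)."""
    base = frames[baseline]
    b_mean = float(base.mean())
    if b_mean == 0:
        raise DegenerateInputError("baseline mean is zero; ΔFF undefined")
    resp = float(frames[response].mean())
    dff = (resp - b_mean) / b_mean
    # SD of the per-frame ΔFF-transformed baseline samples
    b_sd = float(base.std(ddof=1)) / abs(b_mean)
    return dff, b_mean, b_sd


def extract_tonic_response(
    trace: FluorescenceTrace, schedule: StimulusSchedule
) -> TiltResponseScore:
    """Score one tonic-protocol trace: ΔFF per direction + significance.

    The tuning index and subtype are left for :func:`classify_subtype`
    (typically after :func:`aggregate_repeats`).
    """
    if schedule.kind != "tonic":
        raise InvalidInputError("extract_tonic_response requires a tonic schedule")
    if len(trace.frames) != schedule.n_frames:
        raise InvalidInputError(
            f"trace has {len(trace.frames)} frames but schedule expects {schedule.n_frames}"
        )
    resp_down = schedule.window(TONIC_RESPONSE_DOWN_T, RESPONSE_WINDOW_S)
    base_down = schedule.window(TONIC_BASELINE_DOWN[0], TONIC_BASELINE_DOWN[1] - TONIC_BASELINE_DOWN[0])
    resp_up = schedule.window(TONIC_RESPONSE_UP_T, RESPONSE_WINDOW_S)
    base_up = schedule.window(TONIC_BASELINE_UP[0], TONIC_BASELINE_UP[1] - TONIC_BASELINE_UP[0])

    dff_down, bm_down, bsd_down = _dff(trace.frames, resp_down, base_down)
    dff_up, bm_up, bsd_up = _dff(trace.frames, resp_up, base_up)

    score = TiltResponseScore(
        neuron_id=trace.neuron_id,
        dff_up=dff_up,
        dff_down=dff_down,
        baseline_mean_up=bm_up,
        baseline_mean_down=bm_down,
        baseline_sd_up=bsd_up,
        baseline_sd_down=bsd_down,
        significant_up=dff_up > SIGNIFICANCE_SDS * bsd_up,
        significant_down=dff_down > SIGNIFICANCE_SDS * bsd_down,
        genotype=trace.genotype,
    )
    score.tuning_index = tuning_index(score.dff_up, score.dff_down)
    score.subtype = classify_subtype(score)
    return score


def tuning_index(dff_up: float, dff_down: float) -> float:
    """Directional selectivity: (up − down) / (up + down) on clamped ΔFF.

    Inputs are clamped below at 0 first, so the index lies in [−1, 1];
    positive values mean nose-up preference.  When both clamped inputs are
    zero the index is undefined and NaN is returned as the marker.
    """
    if math.isnan(dff_up) and math.isnan(dff_down):
        raise InvalidInputError("both ΔFF inputs are NaN")
    up = max(0.0, dff_up)
    down = max(0.0, dff_down)
    if up + down == 0.0:
        return math.nan
    return (up - down) / (up + down)


def classify_subtype(score: TiltResponseScore) -> str:
    """Assign nose_up / nose_down / untuned from index and significance.

    Directional labels require |index| ≥ 0.1 *and* a significant response in
    the preferred direction; everything else — including the undefined-index
    marker — is untuned.
    """
    idx = score.tuning_index
    if math.isnan(idx):
        return "untuned"
    if idx >= TUNING_THRESHOLD and score.significant_up:
        return "nose_up"
    if idx <= -TUNING_THRESHOLD and score.significant_down:
        return "nose_down"
    return "untuned"


def extract_impulse_response(
    trace: FluorescenceTrace, schedule: StimulusSchedule
) -> ImpulseResponseScore:
    """Score one impulse-protocol trace.

    Each impulse's ΔFF is measured over the first second after the impulse
    against the 20-s pre-impulse baseline.  The responsive flag applies the
    same 2-SD criterion as the tonic analysis to either impulse; the impulse
    tuning index pairs impulse 1 (numerator-positive) against impulse 2.
    """
    if schedule.kind != "impulse":
        raise InvalidInputError("extract_impulse_response requires an impulse schedule")
    if len(trace.frames) != schedule.n_frames:
        raise InvalidInputError(
            f"trace has {len(trace.frames)} frames but schedule expects {schedule.n_frames}"
        )
    base = schedule.window(IMPULSE_BASELINE[0], IMPULSE_BASELINE[1] - IMPULSE_BASELINE[0])
    dffs = []
    b_sd = 0.0
    for t0 in schedule.impulse_onsets():
        resp = schedule.window(t0, RESPONSE_WINDOW_S)
        dff, _, b_sd = _dff(trace.frames, resp, base)
        dffs.append(dff)
    responsive = any(d > SIGNIFICANCE_SDS * b_sd for d in dffs)
    idx = tuning_index(dffs[0], dffs[1]) if len(dffs) >= 2 else math.nan
    return ImpulseResponseScore(
        neuron_id=trace.neuron_id,
        dff_impulses=tuple(dffs),
        dff_mean=float(np.mean(dffs)),
        baseline_sd=b_sd,
        responsive=responsive,
        impulse_tuning_index=idx,
        genotype=trace.genotype,
    )


def aggregate_repeats(scores: Sequence[TiltResponseScore]) -> TiltResponseScore:
    """Average per-direction ΔFF over stimulus repeats and re-classify.

    Significance is re-evaluated on the aggregated ΔFF against the mean
    baseline SD of the repeats, then the tuning index and subtype are
    recomputed, so three noisy repeats yield one stabilized call.
    """
    if len(scores) == 0:
        raise InvalidInputError("aggregate_repeats requires at least one repeat")
    dff_up = float(np.mean([s.dff_up for s in scores]))
    dff_down = float(np.mean([s.dff_down for s in scores]))
    bsd_up = float(np.mean([s.baseline_sd_up for s in scores]))
    bsd_down = float(np.mean([s.baseline_sd_down for s in scores]))
    agg = TiltResponseScore(
        neuron_id=scores[0].neuron_id,
        dff_up=dff_up,
        dff_down=dff_down,
        baseline_mean_up=float(np.mean([s.baseline_mean_up for s in scores])),
        baseline_mean_down=float(np.mean([s.baseline_mean_down for s in scores])),
        baseline_sd_up=bsd_up,
        baseline_sd_down=bsd_down,
        significant_up=dff_up > SIGNIFICANCE_SDS * bsd_up,
        significant_down=dff_down > SIGNIFICANCE_SDS * bsd_down,
        genotype=scores[0].genotype,
    )
    agg.tuning_index = tuning_index(agg.dff_up, agg.dff_down)
    agg.subtype = classify_subtype(agg)
    return agg


def aggregate_impulse_repeats(scores: Sequence[ImpulseResponseScore]) -> ImpulseResponseScore:
    """Average per-impulse ΔFF over repeats and re-evaluate responsiveness."""
    if len(scores) == 0:
        raise InvalidInputError("aggregate_impulse_repeats requires at least one repeat")
    n_imp = len(scores[0].dff_impulses)
    dffs = tuple(float(np.mean([s.dff_impulses[k] for s in scores])) for k in range(n_imp))
    b_sd = float(np.mean([s.baseline_sd for s in scores]))
    idx = tuning_index(dffs[0], dffs[1]) if n_imp >= 2 else math.nan
    return ImpulseResponseScore(
        neuron_id=scores[0].neuron_id,
        dff_impulses=dffs,
        dff_mean=float(np.mean(dffs)),
        baseline_sd=b_sd,
        responsive=any(d > SIGNIFICANCE_SDS * b_sd for d in dffs),
        impulse_tuning_index=idx,
        genotype=scores[0].genotype,
    )


def score_neurons(
    traces: Iterable[FluorescenceTrace], schedule: StimulusSchedule
) -> list[TiltResponseScore] | list[ImpulseResponseScore]:
    """ROI-normalize, score and aggregate traces grouped by neuron id.

    Traces already flagged as normalized are used as-is.  Returns one
    aggregated score per neuron, in first-appearance order.
    """
    by_neuron: dict[str, list[FluorescenceTrace]] = {}
    for tr in traces:
        by_neuron.setdefault(tr.neuron_id, []).append(tr)
    out = []
    for nid, reps in by_neuron.items():
        reps = [tr if tr.normalized else normalize_trace(tr) for tr in reps]
        if schedule.kind == "tonic":
            per_rep = [extract_tonic_response(tr, schedule) for tr in reps]
            out.append(aggregate_repeats(per_rep))
        else:
            per_rep_i = [extract_impulse_response(tr, schedule) for tr in reps]
            out.append(aggregate_impulse_repeats(per_rep_i))
    return out
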