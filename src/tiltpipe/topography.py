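"""Soma topography: coordinate standardization, bootstrapped spatial
distributions, and the statistics used to compare them.

Coordinates are mediolateral (x), rostrocaudal (y) and dorsoventral (z)
offsets in μm from an anatomical origin — the dorsomedial-most point of the
nucleus, or one corner of a standard-sized bounding box for the motor-nucleus
convention.  The dorsoventral axis is additionally discretized into eight
sections for registration of imaging stacks.

Group comparisons follow common practice for this kind of data: per-axis
two-tailed two-sample Kolmogorov–Smirnov tests, a one-way MANOVA on the full
coordinate matrix (Wilks' lambda by default), Wilcoxon rank-sum tests for
per-fish neuron counts (exact by enumeration when both groups are small),
and bootstrap (100 iterations by default) mean ± SD probability
distributions so no single larva dominates a density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError

ORIGIN_CONVENTIONS = ("tangential_dorsomedial", "nIII_box_corner")
N_DV_SECTIONS = 8
#: coordinate differences at or below this are within registration error (μm)
REGISTRATION_ERROR_UM = 2.0
DEFAULT_BOOTSTRAP_ITERATIONS = 100
DEFAULT_DENSITY_BINS = 20


def standardize_coordinates(
    positions: pd.DataFrame,
    origin_convention: str = "tangential_dorsomedial",
    landmark: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Express coordinates as offsets from the convention's origin.

    ``positions`` needs columns x_um, y_um, z_um.  When ``landmark`` is not
    given, the origin is the per-axis minimum corner of the data (the
    dorsomedial-most point under either convention's axis orientation), so
    translating all raw inputs by a constant leaves the output unchanged.
    """
    if origin_convention not in ORIGIN_CONVENTIONS:
        raise InvalidConfigError(f"unknown origin convention: {origin_convention!r}")
    if len(positions) == 0:
        raise InvalidInputError("no positions to standardize")
    coords = positions[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise InvalidInputError("coordinates must be finite")
    origin = np.asarray(landmark, dtype=float) if landmark is not None else coords.min(axis=0)
    out = positions.copy()
    out[["x_um", "y_um", "z_um"]] = coords - origin
    return out


def assign_dv_section(z: float | np.ndarray, boundaries: np.ndarray) -> int | np.ndarray:
    """Bin dorsoventral depth into sections 1..8 with half-open bins.

    ``boundaries`` are the 9 edges (7 internal cut points plus the outer
    limits), strictly increasing.  A depth exactly on an internal boundary
    goes to the deeper (higher-index) section; depths outside
    [boundaries[0], boundaries[-1]) raise.
    """
    edges = np.asarray(boundaries, dtype=float)
    if edges.ndim != 1 or len(edges) != N_DV_SECTIONS + 1:
        raise InvalidConfigError("need 9 strictly increasing boundaries (7 internal cuts)")
    if not np.all(np.diff(edges) > 0):
        raise InvalidConfigError("boundaries must be strictly increasing")
    zs = np.asarray(z, dtype=float)
    if np.any(zs < edges[0]) or np.any(zs >= edges[-1]):
        raise InvalidInputError("dorsoventral position outside the sectioned range")
    idx = np.searchsorted(edges, zs, side="right")
    return int(idx) if np.isscalar(z) else idx.astype(int)


@dataclass
class BootstrapDistribution:
    """Mean ± SD density over bins from resampled spatial distributions."""

    axis: str
    n_iterations: int
    bin_edges: np.ndarray
    mean_density: np.ndarray
    sd_density: np.ndarray
    sample_means: np.ndarray  # mean of each bootstrap resample
    seed: int


def bootstrap_distribution(
    values: np.ndarray,
    n_iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    axis: str = "z",
    bins: int = DEFAULT_DENSITY_BINS,
    bin_range: tuple[float, float] | None = None,
) -> BootstrapDistribution:
    """Resample ``values`` with replacement and summarize the densities.

    Each of ``n_iterations`` iterations resamples n values with replacement
    and histograms them as a probability density (each iteration integrates
    to 1).  Pass ``bin_range`` to put several groups on shared bins.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InvalidInputError("bootstrap needs at least 2 values")
    if n_iterations < 1:
        raise InvalidConfigError("n_iterations must be ≥ 1")
    rng = np.random.default_rng(seed)
    lo, hi = bin_range if bin_range is not None else (vals.min(), vals.max())
    if lo == hi:  # constant input: give the single bin unit width
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    dens = np.empty((n_iterations, bins))
    means = np.empty(n_iterations)
    for i in range(n_iterations):
        sample = rng.choice(vals, size=vals.size, replace=True)
        dens[i], _ = np.histogram(sample, bins=edges, density=True)
        means[i] = sample.mean()
    sd = dens.std(axis=0, ddof=0)
    # pairwise-summation rounding can make std of a bitwise-constant column
    # minutely nonzero; identical resamples must report exactly zero spread
    sd[np.ptp(dens, axis=0) == 0.0] = 0.0
    return BootstrapDistribution(
        axis=axis,
        n_iterations=n_iterations,
        bin_edges=edges,
        mean_density=dens.mean(axis=0),
        sd_density=sd,
        sample_means=means,
        seed=seed,
    )


def ks_axis_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-tailed two-sample KS test along one spatial axis.

    Returns (D, p) with D = sup |ECDF_a − ECDF_b| and the two-sided
    asymptotic p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def manova_separation(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    axes: tuple[str, ...] = ("x_um", "y_um", "z_um"),
    statistic: str = "wilks",
) -> tuple[float, float]:
    """One-way MANOVA on coordinates with group as the factor.

    Returns (statistic, p) using Wilks' lambda and its F approximation
    (``statistic="pillai"`` selects Pillai's trace).  Wilks' lambda is 1
    exactly when the two group mean vectors coincide (zero between-group
    scatter).  A singular within-group scatter raises
    :class:`DegenerateInputError` — add jitter or drop a collinear axis.
    """
    from statsmodels.multivariate.manova import MANOVA

    def mat(g):
        if isinstance(g, pd.DataFrame):
            return g[list(axes)].to_numpy(dtype=float)
        return np.asarray(g, dtype=float)

    A, B = mat(group_a), mat(group_b)
    k = A.shape[1]
    if B.shape[1] != k:
        raise InvalidInputError("groups must share the same axes")
    if len(A) <= k or len(B) <= k:
        raise InvalidInputError("per-group n must exceed the number of axes")
    scale = max(np.abs(A).max(), np.abs(B).max(), 1.0)
    if np.allclose(A.mean(axis=0), B.mean(axis=0), rtol=0.0, atol=1e-12 * scale):
        # zero between-group scatter: lambda is exactly 1 and no direction
        # separates the groups (the F approximation degenerates here)
        return 1.0, 1.0
    Y = np.vstack([A, B])
    groups = np.array(["a"] * len(A) + ["b"] * len(B))
    df = pd.DataFrame(Y, columns=[f"c{i}" for i in range(k)])
    df["group"] = groups
    lhs = " + ".join(df.columns[:-1])
    try:
        res = MANOVA.from_formula(f"{lhs} ~ group", data=df).mv_test()
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise DegenerateInputError(
            "singular within-group scatter; drop collinear axes or add observations"
        ) from exc
    table = res.results["group"]["stat"]
    row = {"wilks": "Wilks' lambda", "pillai": "Pillai's trace"}.get(statistic)
    if row is None:
        raise InvalidConfigError(f"unknown MANOVA statistic: {statistic!r}")
    stat = float(table.loc[row, "Value"])
    p = float(table.loc[row, "Pr > F"])
    if not np.isfinite(stat):
        raise DegenerateInputError("MANOVA statistic undefined (singular scatter?)")
    return stat, p


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n_a+n_b, n_a) splits.

    Uses midranks, so ties are handled exactly; feasible for n ≤ 10 per
    group (≤ 184,756 splits).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    n_a = len(a)
    w_obs = ranks[: n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = comb(len(pooled), n_a)
    hits = 0
    for idx in combinations(range(len(pooled)), n_a):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def count_comparison(
    counts: dict[str, np.ndarray] | pd.Series,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Pairwise two-tailed Wilcoxon rank-sum tests on per-fish neuron counts.

    ``counts`` maps genotype → per-fish count vector (or a Series of counts
    indexed by genotype).  For pairs where both groups have ≤ ``exact_max_n``
    fish the p-value is exact by enumeration of all rank assignments
    (midranks, so ties are exact); larger pairs use the normal approximation
    with tie correction.  Returns a table with one row per genotype pair.
    """
    if isinstance(counts, pd.Series):
        counts = {g: counts[counts.index == g].to_numpy(dtype=float) for g in counts.index.unique()}
    groups = {g: np.asarray(v, dtype=float) for g, v in counts.items()}
    if len(groups) < 2:
        raise InvalidInputError("need at least two genotypes to compare")
    for g, v in groups.items():
        if v.size < 1:
            raise InvalidInputError(f"genotype {g!r} has no fish")
    rows = []
    for g1, g2 in combinations(groups, 2):
        a, b = groups[g1], groups[g2]
        ranks = stats.rankdata(np.concatenate([a, b]))
        w = float(ranks[: len(a)].sum())
        if len(a) <= exact_max_n and len(b) <= exact_max_n:
            p = _exact_ranksum_p(a, b)
            method = "exact"
        else:
            _, p = stats.ranksums(a, b)
            method = "asymptotic"
        rows.append(
            {"group_a": g1, "group_b": g2, "W": w, "p": float(min(p, 1.0)), "method": method}
        )
    return pd.DataFrame(rows)


def axis_comparison_report(
    positions_a: pd.DataFrame,
    positions_b: pd.DataFrame,
    axes: tuple[str, ...] = ("x_um", "y_um", "z_um"),
) -> pd.DataFrame:
    """Per-axis KS comparison of two position sets, flagging median shifts
    within the stated registration error (≤ 2 μm) rather than suppressing
    them."""
    rows = []
    for ax in axes:
        a = positions_a[ax].to_numpy(dtype=float)
        b = positions_b[ax].to_numpy(dtype=float)
        d, p = ks_axis_test(a, b)
        shift = float(np.median(a) - np.median(b))
        rows.append(
            {
                "axis": ax,
                "ks_D": d,
                "ks_p": p,
                "median_shift_um": shift,
                "within_registration_error": abs(shift) <= REGISTRATION_ERROR_UM,
            }
        )
    return pd.DataFrame(rows)
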