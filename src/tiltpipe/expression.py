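"""Two-group differential expression with reference-atlas detection filtering.

Bulk counts (genes × samples, 'null' vs 'sibling' conditions) are tested
gene-by-gene with a negative-binomial Wald test written for this package:
median-of-ratios size factors, per-gene method-of-moments dispersion
moderated by a fitted mean–dispersion trend, a pseudocount-stabilized log2
fold change, and a Wald statistic from the NB delta-method standard error.
It is a deliberately transparent stand-in for heavier shrinkage-based DE
fitters and is calibrated by simulation in the test suite; p-values are
comparable between runs of this package, not to any external fitter.

Candidate genes are then filtered by how often a reference single-cell atlas
detects them in its projection-neuron cluster.  A gene survives threshold T%
when its detection fraction is at least T/100; the significance criteria are
adjusted p < 0.05 and |log2FC| > 2, with Benjamini–Hochberg adjustment
recomputed on each filtered gene universe (analyses run separately per
threshold, so the adjusted p-values are universe-specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError

#: the detection-fraction ladder, in percent of reference projection neurons
THRESHOLD_LADDER = (0, 1, 3, 5, 10, 30, 50)
#: DE significance criteria
ALPHA = 0.05
LFC_CUTOFF = 2.0
#: numerical guards for the NB test
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Bulk genes × samples integer counts with a condition per sample."""

    counts: pd.DataFrame  # genes × samples
    condition: pd.Series  # sample → {'null', 'sibling'}

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.condition.index]
        if missing:
            raise InvalidInputError(f"samples without a condition label: {missing}")
        self.condition = self.condition.loc[self.counts.columns]
        bad = set(self.condition.unique()) - {"null", "sibling"}
        if bad:
            raise InvalidInputError(f"unknown condition labels: {sorted(bad)}")

    def samples_of(self, cond: str) -> list[str]:
        return list(self.condition.index[self.condition == cond])


@dataclass
class AtlasDetection:
    """Reference genes × cells binary detection with per-cell cluster labels."""

    detection: pd.DataFrame  # genes × cells, 0/1
    cluster: pd.Series  # cell → cluster label

    def __post_init__(self) -> None:
        vals = self.detection.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise InvalidInputError("atlas detection must be binary")
        self.cluster = self.cluster.loc[self.detection.columns]


def detection_fraction(atlas: AtlasDetection, cluster: str = "projection") -> pd.Series:
    """Per-gene fraction of cluster cells with detected expression."""
    cells = atlas.cluster.index[atlas.cluster == cluster]
    if len(cells) == 0:
        raise InvalidInputError(f"cluster {cluster!r} is empty")
    return atlas.detection[cells].mean(axis=1).rename("detection_fraction")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    Each sample's factor is the median across genes of its count divided by
    that gene's geometric mean; only genes with all-positive counts enter
    the median.
    """
    K = counts.to_numpy(dtype=float)
    if (K.sum(axis=0) <= 0).any():
        raise InvalidInputError("every sample needs positive total counts")
    ok = np.all(K > 0, axis=1)
    if not ok.any():
        raise DegenerateInputError("no gene has positive counts in all samples")
    logK = np.log(K[ok])
    log_ratio = logK - logK.mean(axis=1, keepdims=True)
    return pd.Series(np.exp(np.median(log_ratio, axis=0)), index=counts.columns, name="size_factor")


def _dispersion_estimates(q: np.ndarray, n_a: int) -> np.ndarray:
    """Per-gene NB dispersion: method of moments, floored at a fitted trend.

    The gene-wise estimate uses the pooled within-group variance of
    normalized counts.  With few replicates it is noisy, and underestimates
    would inflate the Wald statistic, so each gene's dispersion is floored
    at an α(μ) = a0 + a1/μ trend fit across all genes.
    """
    A, B = q[:, :n_a], q[:, n_a:]
    mbar = q.mean(axis=1)
    w = ((A.shape[1] - 1) * A.var(axis=1, ddof=1) + (B.shape[1] - 1) * B.var(axis=1, ddof=1)) / (
        A.shape[1] + B.shape[1] - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(mbar > 0, (w - mbar) / mbar**2, 0.0)
    mom = np.maximum(mom, DISPERSION_FLOOR)
    X = np.column_stack([np.ones_like(mbar), 1.0 / np.maximum(mbar, 1e-8)])
    coef, *_ = np.linalg.lstsq(X, mom, rcond=None)
    trend = np.maximum(X @ coef, DISPERSION_FLOOR)
    return np.maximum(mom, trend)


def nb_wald_test(counts: CountMatrix) -> pd.DataFrame:
    """Per-gene NB Wald test of 'null' vs 'sibling' conditions.

    Returns a frame indexed by gene with columns ``log2_fold_change``
    (null over sibling, pseudocount 0.5), ``p_value``, ``base_mean`` and
    ``all_zero`` (flagged genes are excluded from testing: their p is NaN).
    """
    null_s = counts.samples_of("null")
    sib_s = counts.samples_of("sibling")
    if len(null_s) < 2 or len(sib_s) < 2:
        raise InvalidInputError("need at least 2 samples per condition")
    ordered = counts.counts[null_s + sib_s]
    sf = size_factors(ordered).to_numpy()
    K = ordered.to_numpy(dtype=float)
    q = K / sf
    all_zero = K.sum(axis=1) == 0

    n_a = len(null_s)
    mA = q[:, :n_a].mean(axis=1)
    mB = q[:, n_a:].mean(axis=1)
    lfc = np.log2((mA + PSEUDOCOUNT) / (mB + PSEUDOCOUNT))
    alpha = _dispersion_estimates(q, n_a)

    def var_log(m: np.ndarray, grp_sf: np.ndarray) -> np.ndarray:
        # delta method: Var(mean of K_j/s_j) with NB Var(K) = μ + α μ²
        var_m = (m[:, None] / grp_sf[None, :] + alpha[:, None] * m[:, None] ** 2).sum(axis=1)
        var_m /= grp_sf.size**2
        return var_m / (m + PSEUDOCOUNT) ** 2

    se = np.sqrt(var_log(mA, sf[:n_a]) + var_log(mB, sf[n_a:])) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[se == 0] = 1.0
    p[all_zero] = np.nan
    lfc[all_zero] = np.nan
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "base_mean": q.mean(axis=1),
            "all_zero": all_zero,
        },
        index=ordered.index,
    )


def bh_adjust(p_values: np.ndarray | pd.Series, m: int | None = None) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up with an explicit universe size ``m``.

    ``m`` defaults to the number of p-values; passing a larger m treats the
    input as the significant tail of a wider universe.  NaNs pass through.
    """
    arr = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(arr)
    pv = arr[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    if m is None:
        m = pv.size
    if m < pv.size:
        raise InvalidConfigError("universe size m cannot be smaller than the number of p-values")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, pv.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.full_like(arr, np.nan)
    out_ok = np.empty_like(pv)
    out_ok[order] = adj
    out[ok] = out_ok
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index, name="p_adjusted")
    return out


@dataclass
class DECandidateTable:
    """Per-gene DE results with detection fractions and pass/fail flags."""

    table: pd.DataFrame  # columns: log2_fold_change, p_value, p_adjusted,
    #                      detection_fraction, passes_significance, ...
    universe_size: int
    threshold: float = 0.0  # percent detection filter already applied

    @property
    def n_significant(self) -> int:
        return int(self.table["passes_significance"].sum())


def build_candidate_table(
    de: pd.DataFrame,
    detection: pd.Series,
    alpha: float = ALPHA,
    lfc_cutoff: float = LFC_CUTOFF,
) -> DECandidateTable:
    """Join DE results with detection fractions and apply BH + significance.

    Genes absent from the atlas get detection 0 (they fall to any positive
    threshold) and are counted in ``n_missing_from_atlas``.  All-zero genes
    are dropped from the testable universe.
    """
    tab = de.loc[~de["all_zero"].astype(bool)].copy() if "all_zero" in de else de.copy()
    missing = tab.index.difference(detection.index)
    det = detection.reindex(tab.index).fillna(0.0)
    tab["detection_fraction"] = det
    tab["p_adjusted"] = bh_adjust(tab["p_value"])
    tab["passes_significance"] = (tab["p_adjusted"] < alpha) & (
        tab["log2_fold_change"].abs() > lfc_cutoff
    )
    tab.attrs["n_missing_from_atlas"] = len(missing)
    return DECandidateTable(table=tab, universe_size=len(tab))


def apply_reference_filter(
    candidates: DECandidateTable,
    threshold: float,
    counts: CountMatrix | None = None,
    alpha: float = ALPHA,
    lfc_cutoff: float = LFC_CUTOFF,
) -> DECandidateTable:
    """Restrict the gene universe to detection_fraction ≥ threshold percent.

    Adjusted p-values are recomputed on the reduced universe, because the
    per-threshold analyses are run separately.  When ``counts`` is supplied
    the NB test itself is re-run on the filtered universe (full re-test,
    re-estimating dispersions); otherwise only the BH adjustment is redone
    on the stored raw p-values.
    """
    if not 0 <= threshold <= 100:
        raise InvalidConfigError("threshold must lie in [0, 100] percent")
    tab = candidates.table
    keep = tab["detection_fraction"] >= threshold / 100.0
    sub = tab.loc[keep].copy()
    if counts is not None and len(sub) > 0:
        refit = nb_wald_test(
            CountMatrix(counts.counts.loc[sub.index], counts.condition)
        )
        sub["log2_fold_change"] = refit["log2_fold_change"]
        sub["p_value"] = refit["p_value"]
    sub["p_adjusted"] = bh_adjust(sub["p_value"])
    sub["passes_significance"] = (sub["p_adjusted"] < alpha) & (
        sub["log2_fold_change"].abs() > lfc_cutoff
    )
    return DECandidateTable(table=sub, universe_size=len(sub), threshold=threshold)


def threshold_sweep(
    counts: CountMatrix,
    atlas: AtlasDetection,
    thresholds: tuple[float, ...] = THRESHOLD_LADDER,
    cluster: str = "projection",
    full_retest: bool = True,
    alpha: float = ALPHA,
    lfc_cutoff: float = LFC_CUTOFF,
) -> pd.DataFrame:
    """Run the DE analysis separately on each detection-filtered universe.

    Returns one row per threshold with the universe size and the number of
    genes passing both significance criteria.  Universe sizes are
    non-increasing in the threshold by construction.
    """
    det = detection_fraction(atlas, cluster)
    base_de = nb_wald_test(counts)
    base = build_candidate_table(base_de, det, alpha, lfc_cutoff)
    rows = []
    for thr in thresholds:
        filt = apply_reference_filter(
            base, thr, counts=counts if full_retest else None, alpha=alpha, lfc_cutoff=lfc_cutoff
        )
        rows.append(
            {
                "threshold_pct": thr,
                "universe_size": filt.universe_size,
                "n_deg": filt.n_significant,
            }
        )
    return pd.DataFrame(rows)
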