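"""Cross-genotype comparison statistics for tilt-response metrics.

One-way ANOVA with Tukey-HSD pairwise comparisons (Bonferroni-corrected
pairwise t-tests available by option), Cohen's d effect sizes, and
mean ± SD group summaries shaped like the per-genotype response tables the
scoring module feeds.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError


def anova_multcomp(
    values: np.ndarray,
    groups: np.ndarray,
    method: str = "tukey",
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus a pairwise multiple-comparison table.

    Returns (F, p, pairwise) where ``pairwise`` has one row per group pair
    with the adjusted p (Tukey HSD by default, ``method="bonferroni"`` for
    corrected pairwise Welch t-tests) and Cohen's d.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise InvalidInputError("ANOVA needs at least two groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            raise InvalidInputError(f"group {g!r} needs at least 2 observations")
    F, p = stats.f_oneway(*samples)

    rows = []
    if method == "tukey":
        res = stats.tukey_hsd(*samples)
        for i, j in combinations(range(len(labels)), 2):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adjusted": float(res.pvalue[i, j]),
                    "cohens_d": cohens_d(samples[i], samples[j]),
                }
            )
    elif method == "bonferroni":
        n_pairs = len(labels) * (len(labels) - 1) // 2
        for i, j in combinations(range(len(labels)), 2):
            _, p_ij = stats.ttest_ind(samples[i], samples[j], equal_var=False)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adjusted": float(min(1.0, p_ij * n_pairs)),
                    "cohens_d": cohens_d(samples[i], samples[j]),
                }
            )
    else:
        raise InvalidInputError(f"unknown multiple-comparison method: {method!r}")
    return float(F), float(p), pd.DataFrame(rows)


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cohen's d with the pooled-SD denominator.

    d = (mean_a − mean_b) / sqrt(((n_a−1)s_a² + (n_b−1)s_b²) / (n_a+n_b−2)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("both groups need at least 2 observations")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise DegenerateInputError("zero pooled SD; Cohen's d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def summarize_groups(
    scores: pd.DataFrame,
    metrics: tuple[str, ...],
    by: str = "genotype",
) -> pd.DataFrame:
    """mean ± SD and n per group per metric (the genotype-table shape).

    ``scores`` is one row per neuron; boolean metrics are summarized as the
    fraction true (e.g. responsive fractions).
    """
    if len(scores) == 0:
        raise InvalidInputError("no scores to summarize")
    rows = []
    for group, sub in scores.groupby(by, sort=False):
        for metric in metrics:
            vals = sub[metric]
            if vals.dtype == bool:
                rows.append(
                    {
                        by: group,
                        "metric": metric,
                        "n": int(vals.notna().sum()),
                        "mean": float(vals.mean()),
                        "sd": float(vals.astype(float).std(ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
            else:
                clean = vals.dropna().astype(float)
                rows.append(
                    {
                        by: group,
                        "metric": metric,
                        "n": int(clean.size),
                        "mean": float(clean.mean()) if clean.size else np.nan,
                        "sd": float(clean.std(ddof=1)) if clean.size > 1 else 0.0,
                    }
                )
    return pd.DataFrame(rows)
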