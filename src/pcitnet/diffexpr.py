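"""Two-group negative-binomial differential expression.

A transparent NB Wald procedure: median-of-ratios size factors, per-gene
method-of-moments dispersion pooled within groups, a Wald test on the log2
ratio of group mean normalized counts with a delta-method standard error,
and Benjamini-Hochberg adjustment. This is a documented simplified
re-implementation of the standard NB workflow — it deliberately has no
dispersion shrinkage, no outlier replacement, and no independent filtering,
so every number it produces can be traced to a closed formula.

Sign convention: by default positive log2 fold change means higher
expression in the subfertile (SFH) group; the convention is a switch
(``positive_group``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .preprocess import GROUPS, CountMatrix

#: Dispersion floor absorbing under-dispersed (sub-Poisson) genes.
DISPERSION_FLOOR = 1e-8

#: Pseudocount stabilizing the fold change at zero group means.
PSEUDOCOUNT = 0.5

_LN2 = np.log(2.0)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, scaled to geometric mean 1.

    ``factor(s) = median over genes g of counts(g, s) / geomean_g`` where
    the median runs over genes with a positive count in every sample.

    Raises
    ------
    ValidationError
        If no gene is positive in all samples (counts too sparse; filter
        low-expression genes first).
    """
    values = counts.counts.to_numpy(dtype=float)
    all_positive = np.all(values > 0, axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no gene has a nonzero count in every sample; size factors are "
            "undefined — apply a stronger low-expression filter first"
        )
    logs = np.log(values[all_positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_ratios = logs - log_geomean
    factors = np.exp(np.median(log_ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def estimate_dispersion(counts: CountMatrix, factors: pd.Series) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    The variance is pooled within groups (squared deviations from each
    group's own mean, divided by ``n_total - n_groups``), so a planted mean
    difference does not inflate the dispersion. With overall mean m and
    pooled variance v, ``alpha = max(floor, (v - m) / m**2)``; the floor
    (1e-8) absorbs under-dispersion, and constant or all-zero genes sit at
    the floor.
    """
    for group in GROUPS:
        if len(counts.samples_in(group)) < 2:
            raise ValidationError(
                f"group {group!r} has < 2 samples; dispersion is undefined"
            )
    norm = counts.counts.to_numpy(dtype=float) / factors.reindex(
        counts.sample_ids
    ).to_numpy()
    mean = norm.mean(axis=1)
    ss = np.zeros(counts.n_genes)
    for group in GROUPS:
        cols = [counts.sample_ids.get_loc(s) for s in counts.samples_in(group)]
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (counts.n_samples - len(GROUPS))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(mean > 0, alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def wald_test(
    counts: CountMatrix,
    positive_group: str = "SFH",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """NB Wald test per gene; returns results without adjusted p values.

    For group mean normalized counts m_ref, m_pos (pseudocount pc):

    - ``log2fc = log2((m_pos + pc) / (m_ref + pc))``
    - ``se = sqrt((1/ln 2)^2 * ((1/m_ref + alpha)/n_ref + (1/m_pos + alpha)/n_pos))``
      (delta-method variance of the log mean of an NB sample; a zero group
      mean gives an infinite se and hence p = 1)
    - two-sided normal p value for ``log2fc / se``.
    """
    if positive_group not in GROUPS:
        raise ValidationError(
            f"positive_group must be one of {GROUPS}, got {positive_group!r}"
        )
    factors = size_factors(counts)
    alpha = estimate_dispersion(counts, factors).to_numpy()
    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()

    ref_group = GROUPS[0] if positive_group == GROUPS[1] else GROUPS[1]
    cols = {
        g: [counts.sample_ids.get_loc(s) for s in counts.samples_in(g)]
        for g in GROUPS
    }
    mu_pos = norm[:, cols[positive_group]].mean(axis=1)
    mu_ref = norm[:, cols[ref_group]].mean(axis=1)
    n_pos = len(cols[positive_group])
    n_ref = len(cols[ref_group])

    # difference of logs rather than log of the ratio: bit-exact
    # antisymmetry under exchange of the two groups
    log2fc = np.log2(mu_pos + pseudocount) - np.log2(mu_ref + pseudocount)
    with np.errstate(divide="ignore"):
        inv_pos = np.where(mu_pos > 0, 1.0 / np.where(mu_pos > 0, mu_pos, 1.0), np.inf)
        inv_ref = np.where(mu_ref > 0, 1.0 / np.where(mu_ref > 0, mu_ref, 1.0), np.inf)
    se = np.sqrt(
        (1.0 / _LN2) ** 2 * ((inv_ref + alpha) / n_ref + (inv_pos + alpha) / n_pos)
    )
    with np.errstate(invalid="ignore"):
        z = np.where(np.isinf(se), 0.0, log2fc / se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se_log2fc": se,
            "p_value": p,
        },
        index=counts.gene_ids,
    )


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    results: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 0.5,
    positive_group: str = "SFH",
) -> pd.DataFrame:
    """Flag DEGs at the inclusive thresholds padj <= padj_max and
    \\|log2fc\\| >= lfc_min, with the direction of the fold-change sign.

    Returns a copy of ``results`` with ``is_deg`` and ``direction``
    (``up_in_SFH`` / ``down_in_SFH`` / ``none`` under the default sign
    convention; labels follow ``positive_group``) columns populated.
    """
    if "padj" not in results.columns:
        raise ValidationError("call_degs requires a populated 'padj' column")
    if positive_group not in GROUPS:
        raise ValidationError(
            f"positive_group must be one of {GROUPS}, got {positive_group!r}"
        )
    out = results.copy()
    out["is_deg"] = (out["padj"] <= padj_max) & (out["log2fc"].abs() >= lfc_min)
    out["direction"] = np.where(
        out["is_deg"],
        np.where(out["log2fc"] > 0, f"up_in_{positive_group}", f"down_in_{positive_group}"),
        "none",
    )
    return out


def de_analysis(
    counts: CountMatrix,
    padj_max: float = 0.05,
    lfc_min: float = 0.5,
    positive_group: str = "SFH",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Full differential-expression table: Wald test, BH adjustment, DEG call."""
    results = wald_test(counts, positive_group=positive_group, pseudocount=pseudocount)
    results["padj"] = bh_adjust(results["p_value"])
    return call_degs(
        results, padj_max=padj_max, lfc_min=lfc_min, positive_group=positive_group
    )


def deg_set(results: pd.DataFrame) -> set[str]:
    """The gene ids flagged as DEGs in a results table."""
    return set(results.index[results["is_deg"]])
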