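"""RT-qPCR fold changes (delta-delta-Ct) and exact Mann-Whitney testing.

The validation arm of the pipeline: cycle-threshold (Ct) values of target
genes are normalized to a housekeeping reference gene per sample
(delta Ct), centered on the calibrator group's mean (delta-delta Ct) and
expressed as fold changes ``2**(-ddCt)``. Group differences are tested
with the two-sample Mann-Whitney U test, exact by complete enumeration
for small samples (ties handled through midranks).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .preprocess import GROUPS

CT_COLUMNS = ("sample_id", "group", "gene", "ct")

#: Largest combined sample size for which the exact enumeration runs.
EXACT_LIMIT = 20


def _ct_wide(ct: pd.DataFrame, gene: str) -> pd.Series:
    sub = ct[ct["gene"] == gene]
    dup = sub["sample_id"][sub["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"duplicate Ct rows for gene {gene!r}, samples {sorted(set(dup))}"
        )
    return sub.set_index("sample_id")["ct"]


def delta_delta_ct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str = "FH",
) -> pd.Series:
    """Per-sample fold change of a target gene by the delta-delta-Ct method.

    ``dCt = Ct_target - Ct_reference`` per sample;
    ``ddCt = dCt - mean(dCt over the calibrator group)``;
    fold change = ``2 ** (-ddCt)``. Input is a long table with columns
    sample_id, group, gene, ct.
    """
    missing_cols = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing_cols:
        raise ValidationError(f"Ct table missing column(s) {missing_cols}")
    if calibrator_group not in GROUPS:
        raise ValidationError(
            f"calibrator_group must be one of {GROUPS}, got {calibrator_group!r}"
        )
    target = _ct_wide(ct, target_gene)
    reference = _ct_wide(ct, reference_gene)
    if len(target) == 0:
        raise ValidationError(f"no Ct rows for target gene {target_gene!r}")
    missing = sorted(set(target.index) - set(reference.index))
    if missing:
        raise ValidationError(
            f"samples missing a reference-gene ({reference_gene!r}) Ct: {missing}"
        )
    groups = ct.drop_duplicates("sample_id").set_index("sample_id")["group"]
    dct = target - reference.reindex(target.index)
    calibrators = [s for s in dct.index if groups.get(s) == calibrator_group]
    if not calibrators:
        raise ValidationError(
            f"no samples of calibrator group {calibrator_group!r} with Ct for "
            f"{target_gene!r}"
        )
    ddct = dct - dct.loc[calibrators].mean()
    fold = 2.0 ** (-ddct)
    fold.name = "fold_change"
    return fold


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x against y via midranks (U1 = R1 - n1(n1+1)/2)."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sample Mann-Whitney U with an exact two-sided p for small n.

    For combined n <= 20 the null distribution of U is enumerated over all
    C(n1+n2, n1) group assignments of the observed (mid)ranks, and the
    two-sided p is ``min(1, 2 * min(P(U <= u), P(U >= u)))``. Larger
    samples fall back to the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    if n1 + n2 > EXACT_LIMIT:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return u, float(res.pvalue)

    ranks = stats.rankdata(np.concatenate([x, y]))
    total = comb(n1 + n2, n1)
    offset = n1 * (n1 + 1) / 2.0
    at_most = 0
    at_least = 0
    tol = 1e-9  # midranks are multiples of 1/2; tolerate float summation
    for subset in combinations(range(n1 + n2), n1):
        u_perm = ranks[list(subset)].sum() - offset
        if u_perm <= u + tol:
            at_most += 1
        if u_perm >= u - tol:
            at_least += 1
    p = min(1.0, 2.0 * min(at_most, at_least) / total)
    return u, p


def validate_targets(
    ct: pd.DataFrame,
    target_genes: list[str],
    reference_gene: str,
    calibrator_group: str = "FH",
) -> pd.DataFrame:
    """Fold-change summary and Mann-Whitney test per target gene.

    Returns one row per target: group means +- SD of the per-sample fold
    changes, the U statistic and the two-sided p value (FH vs SFH
    per-sample fold changes).
    """
    groups = ct.drop_duplicates("sample_id").set_index("sample_id")["group"]
    rows = []
    for gene in target_genes:
        fold = delta_delta_ct(
            ct, gene, reference_gene, calibrator_group=calibrator_group
        )
        fh = fold[[s for s in fold.index if groups.get(s) == "FH"]]
        sfh = fold[[s for s in fold.index if groups.get(s) == "SFH"]]
        u, p = mann_whitney_exact(fh.to_numpy(), sfh.to_numpy())
        rows.append(
            (
                gene,
                fh.mean(),
                fh.std(ddof=1) if len(fh) > 1 else 0.0,
                sfh.mean(),
                sfh.std(ddof=1) if len(sfh) > 1 else 0.0,
                u,
                p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "mean_fc_FH",
            "sd_fc_FH",
            "mean_fc_SFH",
            "sd_fc_SFH",
            "U",
            "p_value",
        ],
    ).set_index("gene")
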