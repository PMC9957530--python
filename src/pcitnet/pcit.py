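"""Partial-correlation-and-information-theory (PCIT) edge significance.

PCIT decides, for every gene pair, whether its correlation survives
comparison against all possible third genes. For an ordered trio (x, y, z)
the three first-order partial correlations are computed, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2)),

and the trio's tolerance is the mean ratio of partial to direct
correlation,

    eps = (1/3) * (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz).

The pair (x, y) is eliminated if, for some third gene z, BOTH

    |r_xy| <= |eps * r_xz|   and   |r_xy| <= |eps * r_yz|

hold (boundary equality counts as eliminated). The significant pairs are
those never eliminated by any trio. Intuitively an edge dies when it is
weak relative to the two edges connecting its endpoints to some common
third gene, on the scale set by how much partial correlations shrink
within that trio.

Conventions for degenerate inputs, fixed here and mirrored exactly by the
naive reference implementation:

- a ratio term whose direct correlation is exactly 0 is skipped and eps
  averages the remaining terms; a trio with all three direct correlations
  0 imposes no elimination;
- a trio containing a unit correlation (a zero denominator in any of the
  three partials) is non-informative: it eliminates nothing.

Both implementations perform the same IEEE-754 operations in the same
order, so their masks agree bit-for-bit; the tests assert exact equality.
The cost is O(p^3) in the number of genes p.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .errors import ValidationError

#: Refuse matrices larger than this unless force=True (O(p^3) cost).
MAX_GENES = 5000


def pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of the rows of a gene x sample array.

    Requires >= 3 samples. Zero-variance rows yield NaN in their row and
    column (the undefined-correlation marker); callers must exclude those
    genes before edge inference. The result is exactly symmetric with a
    unit diagonal for well-defined genes, clipped to [-1, 1].
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("expected a 2-D gene x sample array")
    if values.shape[1] < 3:
        raise ValidationError(
            f"correlation needs >= 3 samples, got {values.shape[1]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.asarray(r, dtype=float)
    if r.ndim == 0:  # single gene
        r = r.reshape(1, 1)
    r = (r + r.T) / 2.0  # enforce exact symmetry
    r = np.clip(r, -1.0, 1.0)
    finite_diag = np.isfinite(np.diag(r))
    r[np.diag_indices_from(r)] = np.where(finite_diag, 1.0, np.nan)
    return r


def correlation_pvalue(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p value for a Pearson correlation under the null r = 0.

    Uses ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of
    freedom; ``|r| = 1`` maps to p = 0. ``n`` is the number of samples and
    must be >= 3.
    """
    if n < 3:
        raise ValidationError(f"correlation p value needs n >= 3, got n={n}")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr[np.isfinite(r_arr)]) > 1):
        raise ValidationError("correlations must lie in [-1, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt((n - 2) / (1.0 - r_arr**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r_arr) == 1.0, 0.0, p)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(p)
    return p


def partial_correlation(
    r_xy: float, r_xz: float, r_yz: float
) -> float:
    """First-order partial correlation of (x, y) given z.

    Returns NaN when a conditioning correlation is +-1 (the degenerate-trio
    signal; such trios are non-informative in :func:`pcit_edges`).
    """
    den = (1.0 - r_xz * r_xz) * (1.0 - r_yz * r_yz)
    if den <= 0.0:
        return math.nan
    return (r_xy - r_xz * r_yz) / math.sqrt(den)


def _check_corr(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.all(np.isfinite(r)):
        raise ValidationError(
            "correlation matrix contains non-finite values; drop zero-"
            "variance genes before PCIT"
        )
    if not np.array_equal(r, r.T):
        raise ValidationError("correlation matrix must be symmetric")
    if np.any(np.abs(r) > 1.0):
        raise ValidationError("correlations must lie in [-1, 1]")
    return r


def pcit_edges(
    r: np.ndarray, force: bool = False
) -> np.ndarray:
    """Boolean significance mask over gene pairs (True = never eliminated).

    Optimized implementation: one vectorized pass per conditioning gene z.
    The diagonal is False; with fewer than 3 genes every off-diagonal pair
    is significant (no trio exists). Set ``force=True`` to run on more
    than ``MAX_GENES`` genes despite the O(p^3) cost.
    """
    r = _check_corr(r)
    p = r.shape[0]
    if p > MAX_GENES and not force:
        raise ValidationError(
            f"{p} genes exceeds the guard of {MAX_GENES} for the O(p^3) "
            "PCIT pass; pass force=True to override"
        )
    significant = np.ones((p, p), dtype=bool)
    np.fill_diagonal(significant, False)
    if p < 3:
        return significant

    eliminated = np.zeros((p, p), dtype=bool)
    one_minus_sq = 1.0 - r * r  # [i, j] = 1 - r_ij^2
    idx = np.arange(p)
    for z in range(p):
        rz = r[:, z]
        omz = one_minus_sq[:, z]  # 1 - r_iz^2
        with np.errstate(divide="ignore", invalid="ignore"):
            d1 = omz[:, None] * omz[None, :]
            d2 = one_minus_sq * omz[None, :]
            d3 = one_minus_sq * omz[:, None]
            t1 = (r - rz[:, None] * rz[None, :]) / np.sqrt(d1)  # r_xy.z
            t2 = (rz[:, None] - r * rz[None, :]) / np.sqrt(d2)  # r_xz.y
            t3 = (rz[None, :] - r * rz[:, None]) / np.sqrt(d3)  # r_yz.x
            q1 = t1 / r
            q2 = t2 / rz[:, None]
            q3 = t3 / rz[None, :]
        informative = (d1 > 0.0) & (d2 > 0.0) & (d3 > 0.0)
        v1 = r != 0.0
        v2 = rz[:, None] != 0.0
        v3 = (rz != 0.0)[None, :].repeat(p, axis=0)
        count = (
            v1.astype(np.int64) + v2.astype(np.int64) + v3.astype(np.int64)
        )
        terms = (
            np.where(v1, q1, 0.0)
            + np.where(v2, q2, 0.0)
            + np.where(v3, q3, 0.0)
        )
        with np.errstate(invalid="ignore"):
            eps = terms / count
        cond = (
            informative
            & (count > 0)
            & (np.abs(r) <= np.abs(eps * rz[:, None]))
            & (np.abs(r) <= np.abs(eps * rz[None, :]))
        )
        cond[:, z] = False
        cond[z, :] = False
        cond[idx, idx] = False
        # The naive loop evaluates each unordered pair once with x < y and
        # the term order q_xy, q_xz, q_yz; floating-point addition is not
        # associative, so mirror the upper triangle instead of trusting
        # cond to be numerically symmetric.
        upper = np.triu(cond, k=1)
        eliminated |= upper | upper.T
    significant &= ~eliminated
    return significant


def pcit_edges_naive(r: np.ndarray) -> np.ndarray:
    """Reference triple-loop PCIT; the oracle the fast path must match.

    Scalar arithmetic, one unordered pair at a time. Kept deliberately
    simple and independent of :func:`pcit_edges`.
    """
    r = _check_corr(r)
    p = r.shape[0]
    significant = np.ones((p, p), dtype=bool)
    np.fill_diagonal(significant, False)
    if p < 3:
        return significant
    for x in range(p):
        for y in range(x + 1, p):
            rxy = r[x, y]
            for z in range(p):
                if z == x or z == y:
                    continue
                rxz = r[x, z]
                ryz = r[y, z]
                d1 = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
                d2 = (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
                d3 = (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
                if d1 <= 0.0 or d2 <= 0.0 or d3 <= 0.0:
                    continue  # unit correlation in the trio: non-informative
                pxy = (rxy - rxz * ryz) / math.sqrt(d1)
                pxz = (rxz - rxy * ryz) / math.sqrt(d2)
                pyz = (ryz - rxy * rxz) / math.sqrt(d3)
                total = 0.0
                count = 0
                if rxy != 0.0:
                    total += pxy / rxy
                    count += 1
                if rxz != 0.0:
                    total += pxz / rxz
                    count += 1
                if ryz != 0.0:
                    total += pyz / ryz
                    count += 1
                if count == 0:
                    continue  # all three direct correlations zero
                eps = total / count
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    significant[x, y] = False
                    significant[y, x] = False
                    break
    return significant
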