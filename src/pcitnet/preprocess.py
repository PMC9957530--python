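"""Count containers, CPM transformation, and low-expression filtering.

The raw input of the pipeline is an integer gene x sample count matrix with
each sample assigned to one of two groups: fertile ("FH") and subfertile
("SFH") heifers. Counts are library-size normalized to counts per million
(CPM) and genes expressed below a CPM threshold in too many samples are
removed before any statistics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: The two condition labels of the design: fertile and subfertile heifers.
GROUPS = ("FH", "SFH")


def _check_labels(counts_cols: pd.Index, groups: pd.Series) -> pd.Series:
    """Validate and align a sample->group mapping with matrix columns."""
    groups = pd.Series(groups)
    if groups.index.has_duplicates:
        dup = groups.index[groups.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in group labels: {dup}")
    missing = [s for s in counts_cols if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    groups = groups.reindex(counts_cols)
    bad = sorted(set(groups) - set(GROUPS))
    if bad:
        raise ValidationError(
            f"unknown group labels {bad}; the design is two-group, "
            f"expected labels {GROUPS}"
        )
    return groups.astype(str)


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample->group assignment.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
        Values must be non-negative integers.
    groups
        Series mapping sample id to "FH" or "SFH"; every column of
        ``counts`` must be labeled.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric integers")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if np.any(values != np.floor(values)):
                g, s = np.argwhere(values != np.floor(values))[0]
                raise ValidationError(
                    f"non-integer count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        self.groups = _check_labels(self.counts.columns, self.groups)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in(self, group: str) -> list[str]:
        """Sample ids belonging to ``group`` ("FH" or "SFH")."""
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
        return [s for s in self.sample_ids if self.groups[s] == group]


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression (CPM) with group labels."""

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.groups = _check_labels(self.values.columns, self.groups)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
        return [s for s in self.sample_ids if self.groups[s] == group]


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization.

    ``value(g, s) = counts(g, s) / colsum(s) * 1e6``; every column of the
    result sums to one million (when the source column is nonzero).

    Raises
    ------
    ValidationError
        If a sample column is all zeros (its library size is undefined).
    """
    colsum = counts.counts.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with all-zero counts, CPM undefined: {list(zero.index)}"
        )
    values = counts.counts.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(values=values, groups=counts.groups)


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    min_fraction: float = 0.5,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove genes expressed below ``cpm_threshold`` CPM in too many samples.

    A gene is kept iff its CPM is >= ``cpm_threshold`` in at least
    ``ceil(min_fraction * n_samples)`` samples (with the default 0.5 and 15
    samples the cutoff is 8). The boundary CPM exactly equal to the
    threshold counts as expressed.

    Returns
    -------
    (filtered, report)
        ``filtered`` preserves the input gene order and the full sample
        set; ``report`` has one row per input gene with columns
        ``n_samples_passing`` and ``kept``.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ConfigurationError(
            f"min_fraction must be in [0, 1], got {min_fraction}"
        )
    expr = cpm(counts)
    n_required = math.ceil(min_fraction * counts.n_samples)
    n_passing = (expr.values >= cpm_threshold).sum(axis=1)
    kept = n_passing >= n_required
    report = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "n_samples_passing": n_passing.to_numpy(),
            "kept": kept.to_numpy(),
        }
    ).set_index("gene_id")
    filtered = CountMatrix(
        counts=counts.counts.loc[kept.to_numpy()], groups=counts.groups
    )
    return filtered, report
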