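"""Hypergeometric over-representation analysis against GMT gene sets.

Generic ORA: a query gene list (DEGs, exclusive hubs, hub neighborhoods)
is tested against each set of a user-supplied collection with the
upper-tail hypergeometric test, with Bonferroni and Benjamini-Hochberg
corrections reported side by side. No annotation database is bundled —
any GMT file (GO, KEGG, custom) works, and the background universe is the
caller's (typically all expressed genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ValidationError


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested in."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")


def read_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate members within a set are deduplicated. Raises a parse error
    naming the offending line number for malformed lines.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: malformed GMT line {lineno}: expected "
                    f"name, description and >= 1 gene, got {len(fields)} field(s)"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(
                    f"{path}: duplicate set name {name!r} at line {lineno}"
                )
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValidationError(
                    f"{path}: set {name!r} at line {lineno} has no genes"
                )
            sets[name] = members
    return GeneSetCollection(sets=sets, universe=universe or set())


def hypergeom_ora(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    Query and set members are trimmed to the universe first. With
    ``M = |universe|``, ``K = |set in universe|``, ``n = |query|`` and
    overlap k, the p value is ``P(X >= k)`` for
    ``X ~ Hypergeom(M, K, n)``. Returns one row per set: set_size,
    overlap, expected, p, padj_bonferroni, padj_bh.
    """
    uni = set(universe) if universe is not None else set(collection.universe)
    if not uni:
        raise ValidationError("a background universe is required")
    trimmed_query = set(query) & uni
    if not trimmed_query:
        raise ValidationError("query is empty after trimming to the universe")
    M = len(uni)
    n = len(trimmed_query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & uni
        K = len(members)
        k = len(trimmed_query & members)
        expected = n * K / M
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, K, k, expected, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap", "expected", "p"]
    ).set_index("set_name")
    out["padj_bonferroni"] = bonferroni(out["p"].to_numpy())
    out["padj_bh"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def bonferroni(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Bonferroni correction: ``min(1, m * p)`` with m = number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)
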