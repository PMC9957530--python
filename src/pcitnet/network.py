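"""Per-group co-expression network construction.

For each group the pipeline computes pairwise Pearson correlations over
that group's samples (on CPM or log2(CPM+1)), runs the PCIT triplet
elimination over the full filtered gene set, and only then applies the
reporting filters: |r| >= r_min, correlation p <= p_max, and the
requirement that at least one endpoint of every edge is a differentially
expressed gene (DEG anchoring). That order — PCIT first, filters second —
matches the pipeline this package implements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .pcit import MAX_GENES, correlation_pvalue, pcit_edges, pearson_matrix
from .preprocess import GROUPS, ExpressionMatrix

EDGE_COLUMNS = ["gene_a", "gene_b", "r", "p_value", "pcit_significant", "deg_anchored"]


@dataclass
class GroupNetwork:
    """Undirected weighted edge list for one group after all filters.

    ``edges`` has columns gene_a, gene_b (lexicographically ordered,
    gene_a < gene_b), r, p_value, pcit_significant, deg_anchored; every
    retained row passed every filter, so the two boolean columns are True
    throughout. ``genes`` records the gene universe the network was built
    over (all filtered genes of the expression matrix, including isolated
    ones), ``n_samples`` the group's sample count.
    """

    group: str
    edges: pd.DataFrame
    genes: pd.Index = field(repr=False)
    n_samples: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> pd.Index:
        """Genes incident to at least one retained edge."""
        return pd.Index(
            sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))
        )

    def degrees(self) -> pd.Series:
        """Distinct-neighbor degree for every gene with >= 1 edge."""
        counts: dict[str, int] = {}
        for a, b in zip(self.edges["gene_a"], self.edges["gene_b"]):
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        return pd.Series(counts, dtype=int).sort_index()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, r=row.r, p_value=row.p_value)
        return g


def build_group_network(
    expr: ExpressionMatrix,
    group: str,
    degs: set[str],
    r_min: float = 0.95,
    p_max: float = 0.05,
    scale: str = "cpm",
    force: bool = False,
) -> GroupNetwork:
    """PCIT network for one group, filtered to DEG-anchored strong edges.

    Parameters
    ----------
    expr
        CPM expression for the full (filtered) gene set, both groups.
    group
        "FH" or "SFH": correlations use only this group's samples.
    degs
        DEG gene ids anchoring the network; edges touching no DEG are
        dropped. An empty set yields an empty network with a warning.
    r_min, p_max
        Edge filters: |r| >= r_min and correlation p <= p_max (inclusive).
    scale
        "cpm" (default) or "log2cpm" (log2(CPM + 1)) as correlation input.
    force
        Override the gene-count guard of the O(p^3) PCIT pass.

    Zero-variance genes (within the group's samples) have undefined
    correlations; they are excluded from edge inference and can never
    appear in an edge.
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    if scale not in ("cpm", "log2cpm"):
        raise ValidationError(f"scale must be 'cpm' or 'log2cpm', got {scale!r}")
    samples = expr.samples_in(group)
    if len(samples) < 3:
        raise ValidationError(
            f"group {group!r} has {len(samples)} samples; correlations need >= 3"
        )
    values = expr.values[samples].to_numpy(dtype=float)
    if scale == "log2cpm":
        values = np.log2(values + 1.0)

    variable = values.std(axis=1) > 0.0
    genes = expr.gene_ids[variable]
    empty = pd.DataFrame(columns=EDGE_COLUMNS)
    if not degs:
        warnings.warn(
            f"empty DEG set: the {group} network is empty by construction",
            stacklevel=2,
        )
        return GroupNetwork(group=group, edges=empty, genes=expr.gene_ids,
                            n_samples=len(samples))
    if len(genes) < 2:
        return GroupNetwork(group=group, edges=empty, genes=expr.gene_ids,
                            n_samples=len(samples))
    if len(genes) > MAX_GENES and not force:
        raise ValidationError(
            f"{len(genes)} genes exceeds the guard of {MAX_GENES} for the "
            "O(p^3) PCIT pass; pass force=True to override"
        )

    r = pearson_matrix(values[variable])
    mask = pcit_edges(r, force=force)
    pvals = correlation_pvalue(r, n=len(samples))

    iu = np.triu_indices(len(genes), k=1)
    keep = (
        mask[iu]
        & (np.abs(r[iu]) >= r_min)
        & (pvals[iu] <= p_max)
    )
    ga = genes.to_numpy()[iu[0][keep]]
    gb = genes.to_numpy()[iu[1][keep]]
    anchored = np.array([a in degs or b in degs for a, b in zip(ga, gb)], dtype=bool)
    lo = np.minimum(ga, gb)
    hi = np.maximum(ga, gb)
    edges = pd.DataFrame(
        {
            "gene_a": lo[anchored],
            "gene_b": hi[anchored],
            "r": r[iu][keep][anchored],
            "p_value": pvals[iu][keep][anchored],
            "pcit_significant": True,
            "deg_anchored": True,
        }
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    if len(edges) == 0:
        edges = empty.copy()
    return GroupNetwork(
        group=group, edges=edges, genes=expr.gene_ids, n_samples=len(samples)
    )


def write_sif(net: GroupNetwork, path) -> None:
    """Cytoscape SIF export: ``gene_a coexp gene_b`` per retained edge."""
    with open(path, "w") as fh:
        for row in net.edges.itertuples(index=False):
            fh.write(f"{row.gene_a}\tcoexp\t{row.gene_b}\n")
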