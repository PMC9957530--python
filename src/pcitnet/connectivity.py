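"""Hub identification, union reference network, differential connectivity.

Degrees come from the filtered per-group networks. Hubs are genes whose
degree is at least mean + 2 SD of the degrees in their group's network.
Connectivity is standardized per group as K = k / max(k); the differential
connectivity of gene i is DK_i = K_SFH,i - K_FH,i over the union gene set
(genes absent from a network carry degree 0), DK is z-scored against its
own empirical mean and SD, and |z| >= 1.96 is called significant — genes
that gained connectivity in one group at the expense of the other, i.e.
the rewired part of the transcriptional network.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .errors import ValidationError
from .network import GroupNetwork

HUB_CLASSES = ("FH_exclusive", "SFH_exclusive", "shared", "none")


def degree_table(net: GroupNetwork, universe=None) -> pd.Series:
    """Gene -> distinct-neighbor degree.

    Without ``universe`` only genes with >= 1 edge appear (an empty network
    gives an empty table, i.e. all degrees zero); with ``universe`` the
    result is reindexed over it with zero fill.
    """
    deg = net.degrees()
    if universe is not None:
        deg = deg.reindex(pd.Index(universe), fill_value=0).astype(int)
    return deg


def find_hubs(degrees: pd.Series, sd_mult: float = 2.0, ddof: int = 1) -> set[str]:
    """Genes with degree >= mean + sd_mult * SD of the degree distribution.

    ``ddof=1`` (sample SD) is the default; ties at the threshold are hubs.
    A degenerate distribution (SD = 0, e.g. all degrees equal) yields an
    empty hub set with a warning.
    """
    if len(degrees) < 2:
        if len(degrees):
            warnings.warn("fewer than 2 genes with edges; no hubs", stacklevel=2)
        return set()
    values = degrees.to_numpy(dtype=float)
    sd = values.std(ddof=ddof)
    if sd == 0.0:
        warnings.warn(
            "degenerate degree distribution (SD = 0); returning no hubs",
            stacklevel=2,
        )
        return set()
    threshold = values.mean() + sd_mult * sd
    return set(degrees.index[values >= threshold])


def classify_hubs(hubs_fh: set[str], hubs_sfh: set[str]) -> pd.Series:
    """Set-algebra hub classification over the union of both hub sets."""
    rows = {}
    for g in hubs_fh | hubs_sfh:
        if g in hubs_fh and g in hubs_sfh:
            rows[g] = "shared"
        elif g in hubs_fh:
            rows[g] = "FH_exclusive"
        else:
            rows[g] = "SFH_exclusive"
    return pd.Series(rows, dtype=object).sort_index()


@dataclass
class UnionNetwork:
    """DyNet-style merge of the two group networks with origin labels.

    ``nodes``: DataFrame (index gene) with column ``origin`` in
    {FH_only, SFH_only, both}; ``edges``: DataFrame with gene_a, gene_b,
    origin labeled the same way.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def union_network(net_fh: GroupNetwork, net_sfh: GroupNetwork) -> UnionNetwork:
    """Union of nodes and edges of the two group networks, origin-labeled."""
    if net_fh.group == net_sfh.group:
        raise ValidationError("union_network needs one network per group")
    e_fh = set(zip(net_fh.edges["gene_a"], net_fh.edges["gene_b"]))
    e_sfh = set(zip(net_sfh.edges["gene_a"], net_sfh.edges["gene_b"]))
    edge_rows = []
    for a, b in sorted(e_fh | e_sfh):
        origin = (
            "both" if (a, b) in e_fh and (a, b) in e_sfh
            else "FH_only" if (a, b) in e_fh
            else "SFH_only"
        )
        edge_rows.append((a, b, origin))
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "origin"])
    n_fh = set(net_fh.nodes)
    n_sfh = set(net_sfh.nodes)
    node_rows = {
        g: (
            "both" if g in n_fh and g in n_sfh
            else "FH_only" if g in n_fh
            else "SFH_only"
        )
        for g in sorted(n_fh | n_sfh)
    }
    nodes = pd.DataFrame({"origin": pd.Series(node_rows, dtype=object)})
    nodes.index.name = "gene_id"
    return UnionNetwork(nodes=nodes, edges=edges)


def differential_connectivity(
    deg_fh: pd.Series,
    deg_sfh: pd.Series,
    z_threshold: float = 1.96,
    hub_sd_mult: float = 2.0,
    hub_ddof: int = 1,
) -> pd.DataFrame:
    """Standardized differential connectivity (DK) with z-score calls.

    Parameters are the per-group degree tables (genes with >= 1 edge; the
    universe is their union and absent genes carry degree 0). Returns one
    row per universe gene: k_FH, k_SFH, K_FH, K_SFH, DK, z,
    dk_significant, hub_FH, hub_SFH, hub_class.

    ``K = k / max(k)`` within each group (0 when the group's network is
    empty); ``DK = K_SFH - K_FH``; ``z = (DK - mean(DK)) / SD(DK)`` with
    sample SD over the universe. If SD(DK) = 0 (e.g. identical networks)
    a warning is issued, z is set to 0 and nothing is significant.
    """
    universe = pd.Index(sorted(set(deg_fh.index) | set(deg_sfh.index)))
    k_fh = deg_fh.reindex(universe, fill_value=0).astype(int)
    k_sfh = deg_sfh.reindex(universe, fill_value=0).astype(int)
    max_fh = int(k_fh.max()) if len(universe) else 0
    max_sfh = int(k_sfh.max()) if len(universe) else 0
    K_fh = k_fh / max_fh if max_fh > 0 else k_fh.astype(float)
    K_sfh = k_sfh / max_sfh if max_sfh > 0 else k_sfh.astype(float)
    dk = K_sfh - K_fh

    if len(universe) >= 2:
        sd = dk.to_numpy().std(ddof=1)
    else:
        sd = 0.0
    if sd == 0.0:
        if len(universe):
            warnings.warn(
                "SD(DK) = 0 (identical connectivity); no significant genes",
                stacklevel=2,
            )
        z = pd.Series(0.0, index=universe)
    else:
        z = (dk - dk.mean()) / sd
    significant = np.abs(z) >= z_threshold if sd > 0 else pd.Series(False, index=universe)

    hubs_fh = find_hubs(deg_fh, sd_mult=hub_sd_mult, ddof=hub_ddof) if len(deg_fh) else set()
    hubs_sfh = find_hubs(deg_sfh, sd_mult=hub_sd_mult, ddof=hub_ddof) if len(deg_sfh) else set()
    hub_class = classify_hubs(hubs_fh, hubs_sfh).reindex(universe, fill_value="none")

    table = pd.DataFrame(
        {
            "k_FH": k_fh,
            "k_SFH": k_sfh,
            "K_FH": K_fh,
            "K_SFH": K_sfh,
            "DK": dk,
            "z": z,
            "dk_significant": significant,
            "hub_FH": [g in hubs_fh for g in universe],
            "hub_SFH": [g in hubs_sfh for g in universe],
            "hub_class": hub_class,
        },
        index=universe,
    )
    table.index.name = "gene_id"
    return table


def compare_networks(
    net_fh: GroupNetwork,
    net_sfh: GroupNetwork,
    z_threshold: float = 1.96,
    hub_sd_mult: float = 2.0,
    hub_ddof: int = 1,
) -> tuple[pd.DataFrame, UnionNetwork]:
    """Connectivity table plus union reference network for two networks."""
    table = differential_connectivity(
        degree_table(net_fh),
        degree_table(net_sfh),
        z_threshold=z_threshold,
        hub_sd_mult=hub_sd_mult,
        hub_ddof=hub_ddof,
    )
    return table, union_network(net_fh, net_sfh)
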