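"""Synthetic two-group RNA-seq counts with planted structure.

The generator emulates the statistical design the downstream analysis
assumes: negative-binomial counts for two groups of heifers (fertile FH,
subfertile SFH), a minority of planted differentially expressed genes
(DEGs), and co-expression modules that are active — i.e. share a latent
factor — in one or both groups. Modules active in exactly one group are the
planted "rewired" structure the differential-connectivity analysis is meant
to recover.

Counts are drawn through a Gaussian copula: correlated standard normals
(one latent factor per module and group) are mapped through the
negative-binomial quantile function gene by gene, which preserves the NB
marginal exactly while inducing rank correlation that rises with the module
loading. Library sizes are drawn uniformly per sample and enter as
multiplicative offsets so that CPM normalization is actually exercised.

Everything is reproducible from ``SimConfig.seed``: a single seed with
fixed per-stage offsets drives baseline abundances, library sizes, module
factors and gene-level noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .preprocess import GROUPS, CountMatrix

# Fixed sub-stream offsets of the single seed (reproducibility when stages
# are re-run or extended).
_STAGE_BASELINE = 0
_STAGE_LIBRARY = 1
_STAGE_FACTORS = 2
_STAGE_NOISE = 3


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    Parameters
    ----------
    gene_indices
        Indices (into the simulated gene list) of the member genes.
        Distinct modules must not share genes.
    active_groups
        Subset of ``("FH", "SFH")`` in which the members share the latent
        factor. A module active in exactly one group is "rewired".
    latent_loading
        Loading of the shared factor, in (0, 1). Pairwise latent
        correlation between members is ``latent_loading ** 2``.
    """

    gene_indices: tuple[int, ...]
    active_groups: tuple[str, ...]
    latent_loading: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_indices", tuple(int(i) for i in self.gene_indices))
        object.__setattr__(self, "active_groups", tuple(self.active_groups))
        if len(set(self.gene_indices)) != len(self.gene_indices):
            raise ConfigurationError("ModuleSpec.gene_indices contains duplicates")
        if len(self.gene_indices) < 2:
            raise ConfigurationError("ModuleSpec.gene_indices needs >= 2 genes")
        bad = [g for g in self.active_groups if g not in GROUPS]
        if bad or not self.active_groups:
            raise ConfigurationError(
                f"ModuleSpec.active_groups must be a nonempty subset of {GROUPS}, "
                f"got {self.active_groups}"
            )
        if not 0.0 < self.latent_loading < 1.0:
            raise ConfigurationError(
                f"ModuleSpec.latent_loading must be in (0, 1), got {self.latent_loading}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-group count simulation.

    Defaults mirror the design the pipeline targets: 8 fertile vs 7
    subfertile samples and ~12,000 expressed genes with a minority of DEGs.
    Tests and examples pass smaller ``n_genes`` explicitly.
    """

    n_genes: int = 12_000
    n_samples_per_group: tuple[int, int] = (8, 7)  # (FH, SFH)
    n_deg: int = 92
    lfc_magnitude: float = 2.0
    modules: tuple[ModuleSpec, ...] = ()
    nb_dispersion: float = 0.05
    mean_log_expression: float = 4.0
    sigma_log_expression: float = 1.0
    library_size_range: tuple[int, int] = (500_000, 1_500_000)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(
            self, "n_samples_per_group", tuple(int(n) for n in self.n_samples_per_group)
        )
        object.__setattr__(
            self, "library_size_range", tuple(int(x) for x in self.library_size_range)
        )
        if self.n_genes <= 0:
            raise ConfigurationError(f"n_genes must be positive, got {self.n_genes}")
        if len(self.n_samples_per_group) != 2 or any(
            n <= 0 for n in self.n_samples_per_group
        ):
            raise ConfigurationError(
                "n_samples_per_group must be a pair of positive integers, "
                f"got {self.n_samples_per_group}"
            )
        if not 0 <= self.n_deg <= self.n_genes:
            raise ConfigurationError(
                f"n_deg must be in [0, n_genes={self.n_genes}], got {self.n_deg}"
            )
        if self.lfc_magnitude < 0:
            raise ConfigurationError(
                f"lfc_magnitude must be >= 0, got {self.lfc_magnitude}"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError(
                f"nb_dispersion must be > 0, got {self.nb_dispersion}"
            )
        if self.sigma_log_expression < 0:
            raise ConfigurationError(
                f"sigma_log_expression must be >= 0, got {self.sigma_log_expression}"
            )
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                "library_size_range must be a pair of positive integers with "
                f"lo <= hi, got {self.library_size_range}"
            )
        seen: set[int] = set()
        for m in self.modules:
            if max(m.gene_indices) >= self.n_genes:
                raise ConfigurationError(
                    f"modules: gene index {max(m.gene_indices)} out of range "
                    f"for n_genes={self.n_genes}"
                )
            overlap = seen.intersection(m.gene_indices)
            if overlap:
                raise ConfigurationError(
                    f"modules: gene sets must be disjoint, shared indices {sorted(overlap)[:5]}"
                )
            seen.update(m.gene_indices)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a simulated count matrix.

    Attributes
    ----------
    genes
        One row per gene (index ``gene_id``) with columns ``is_deg``,
        ``log2fc`` (signed planted effect, positive = higher in SFH),
        ``module`` (module id or ""), and ``rewired`` (member of a module
        active in exactly one group).
    edges
        One row per expected co-expression edge and group: columns
        ``group``, ``gene_a``, ``gene_b``, ``module`` with
        ``gene_a < gene_b``. A pair appears for group g iff both
        endpoints share a module whose active groups include g.
    """

    genes: pd.DataFrame
    edges: pd.DataFrame

    @property
    def deg_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_deg"]])

    @property
    def rewired_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["rewired"]])

    def module_members(self, module_id: str) -> list[str]:
        return list(self.genes.index[self.genes["module"] == module_id])

    def expected_edges(self, group: str) -> set[tuple[str, str]]:
        sub = self.edges[self.edges["group"] == group]
        return set(zip(sub["gene_a"], sub["gene_b"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.genes.equals(other.genes) and self.edges.equals(other.edges)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


def _planted_lfc(config: SimConfig) -> np.ndarray:
    """Signed planted log2 fold changes; the first n_deg genes are DEGs,
    half up in SFH and half down (balanced volcano)."""
    lfc = np.zeros(config.n_genes)
    n_up = (config.n_deg + 1) // 2
    lfc[:n_up] = config.lfc_magnitude
    lfc[n_up : config.n_deg] = -config.lfc_magnitude
    return lfc


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a two-group NB count matrix with planted DEGs and modules.

    Gene baseline abundances are log-normal; expected counts are
    ``library_size * relative_abundance * 2^(+-log2fc/2)`` with the DEG
    effect split symmetrically between the groups so the planted group-mean
    ratio is exactly ``2^log2fc``. Correlation within active modules is
    induced by a per-module, per-sample latent factor on the copula scale:
    ``z = loading * factor + sqrt(1 - loading^2) * noise``.
    """
    n_fh, n_sfh = config.n_samples_per_group
    n_total = n_fh + n_sfh
    gene_width = max(5, len(str(config.n_genes)))
    gene_ids = pd.Index(
        [f"G{i:0{gene_width}d}" for i in range(config.n_genes)], name="gene_id"
    )
    sample_ids = [f"FH_{i + 1:02d}" for i in range(n_fh)] + [
        f"SFH_{i + 1:02d}" for i in range(n_sfh)
    ]
    group_of = pd.Series(
        ["FH"] * n_fh + ["SFH"] * n_sfh, index=pd.Index(sample_ids, name="sample_id")
    )
    is_sfh = (group_of == "SFH").to_numpy()

    # Stage 0: baseline relative abundances (log-normal).
    rng0 = _rng(config, _STAGE_BASELINE)
    abundance = np.exp(
        rng0.normal(config.mean_log_expression, config.sigma_log_expression, config.n_genes)
    )
    rel = abundance / abundance.sum()

    # Stage 1: library sizes, uniform over the configured range.
    rng1 = _rng(config, _STAGE_LIBRARY)
    lo, hi = config.library_size_range
    libsize = rng1.integers(lo, hi + 1, n_total).astype(float)

    # Planted DEG effect, split symmetrically across groups.
    lfc = _planted_lfc(config)
    effect = np.where(
        is_sfh[None, :], 2.0 ** (lfc[:, None] / 2.0), 2.0 ** (-lfc[:, None] / 2.0)
    )
    mu = rel[:, None] * libsize[None, :] * effect

    # Stages 2-3: copula normals with module factors overlaid on noise.
    rng2 = _rng(config, _STAGE_FACTORS)
    rng3 = _rng(config, _STAGE_NOISE)
    z = rng3.standard_normal((config.n_genes, n_total))
    for module in config.modules:
        idx = np.asarray(module.gene_indices)
        lam = module.latent_loading
        for group in GROUPS:  # fixed iteration order keeps draws reproducible
            cols = (group_of == group).to_numpy()
            factor = rng2.standard_normal(cols.sum())
            if group in module.active_groups:
                z[np.ix_(idx, np.flatnonzero(cols))] = (
                    lam * factor[None, :]
                    + np.sqrt(1.0 - lam * lam) * z[np.ix_(idx, np.flatnonzero(cols))]
                )

    u = stats.norm.cdf(z)
    size = 1.0 / config.nb_dispersion  # NB "number of failures" parameter
    p = size / (size + mu)
    counts = stats.nbinom.ppf(u, size, p).astype(np.int64)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        groups=group_of,
    )
    return cm, _ground_truth(config, gene_ids, lfc)


def _ground_truth(
    config: SimConfig, gene_ids: pd.Index, lfc: np.ndarray
) -> GroundTruth:
    module_of = np.full(config.n_genes, "", dtype=object)
    rewired = np.zeros(config.n_genes, dtype=bool)
    edge_rows: list[tuple[str, str, str, str]] = []
    for m, module in enumerate(config.modules):
        mid = f"M{m + 1}"
        idx = np.asarray(module.gene_indices)
        module_of[idx] = mid
        if len(set(module.active_groups)) == 1:
            rewired[idx] = True
        members = sorted(gene_ids[i] for i in module.gene_indices)
        for group in GROUPS:
            if group in module.active_groups:
                for a, b in itertools.combinations(members, 2):
                    edge_rows.append((group, a, b, mid))
    genes = pd.DataFrame(
        {
            "is_deg": lfc != 0.0,
            "log2fc": lfc,
            "module": module_of,
            "rewired": rewired,
        },
        index=gene_ids,
    )
    edges = pd.DataFrame(
        edge_rows, columns=["group", "gene_a", "gene_b", "module"]
    ).sort_values(["group", "gene_a", "gene_b"], ignore_index=True)
    return GroundTruth(genes=genes, edges=edges)


def write_truth(truth: GroundTruth, genes_path, edges_path) -> None:
    """Write the gene and edge truth tables as TSV (lossless round-trip)."""
    truth.genes.to_csv(genes_path, sep="\t")
    truth.edges.to_csv(edges_path, sep="\t", index=False)


def read_truth(genes_path, edges_path) -> GroundTruth:
    """Read truth tables written by :func:`write_truth`."""
    genes = pd.read_csv(genes_path, sep="\t", index_col="gene_id")
    genes["is_deg"] = genes["is_deg"].astype(bool)
    genes["rewired"] = genes["rewired"].astype(bool)
    genes["module"] = genes["module"].fillna("").astype(str)
    genes["log2fc"] = genes["log2fc"].astype(float)
    edges = pd.read_csv(
        edges_path, sep="\t", dtype={"group": str, "gene_a": str, "gene_b": str, "module": str}
    )
    if len(edges) == 0:
        edges = pd.DataFrame(columns=["group", "gene_a", "gene_b", "module"])
    for col in ("group", "gene_a", "gene_b", "module"):
        if col not in edges.columns:
            raise ValidationError(f"edge truth table missing column {col!r}")
    return GroundTruth(genes=genes, edges=edges)


def null_config(**overrides) -> SimConfig:
    """A no-structure configuration (no DEGs, no modules): both groups are
    statistically identical. Convenience for calibration studies."""
    base = SimConfig(n_deg=0, modules=())
    return replace(base, **overrides)
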