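"""Synthetic communities, phylogenies and feature tables with known truth.

The generators emulate the structure of a light-manipulation biofilm study:
a few hundred taxa with strong dominance (log-normal metacommunity), ten
samples per treatment, uneven sequencing depths, and — for the assembly
regimes — phylogenetically conserved niches so that selection is visible to
a nearest-taxon statistic.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import CountTable

REGIMES = ("neutral", "homogeneous_selection", "variable_selection")


@dataclass
class AssemblyScenario:
    """Ground-truth description of a community-assembly simulation.

    ``selection_strength`` is the σ of the Gaussian environmental filter in
    standardised trait units (tip traits are z-scored before filtering, so
    σ = 0.5 admits roughly the closest quarter of the trait range).
    ``trait_sigma`` is the Brownian-motion rate (variance per unit branch
    length) used to evolve the niche trait along the tree.
    """

    regime: str
    n_taxa: int = 300
    n_samples: int = 10
    depth: int = 41737
    selection_strength: float = 0.3
    trait_sigma: float = 1.0
    trait_decay: float = 8.0
    n_blocks: int = 2
    depth_jitter: bool = False
    metacommunity_sigma: float = 1.5
    drift_sigma: float = 1.0
    occupancy: float = 0.5
    immigration: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class NetworkScenario:
    """Planted-module co-occurrence scenario.

    ``rho`` is the target within-module Pearson correlation of taxon
    log-abundances; between-module correlation is ≈ 0 by construction.
    ``noise_sd`` defaults to sqrt(1 − rho) so the within-module correlation
    comes out at rho exactly (factor loading is sqrt(rho)).
    """

    n_taxa: int = 40
    n_modules: int = 2
    rho: float = 0.8
    noise_sd: float | None = None
    n_samples: int = 40
    log_sigma: float = 0.5
    seed: int = 0
    module_of: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.n_samples < 10:
            raise ValueError("need >= 10 samples; correlations are unstable below that")
        if self.n_modules < 1 or self.n_modules > self.n_taxa:
            raise ValueError("n_modules must partition the taxa")
        if self.noise_sd is None:
            self.noise_sd = float(np.sqrt(max(1.0 - self.rho, 0.0)))
        # equal-size contiguous modules (remainder spread over the first ones)
        base, extra = divmod(self.n_taxa, self.n_modules)
        self.module_of = []
        for m in range(self.n_modules):
            self.module_of.extend([m] * (base + (1 if m < extra else 0)))


def simulate_tree(n_taxa: int, seed: int, birth_rate: float = 1.0,
                  prefix: str = "t") -> dendropy.Tree:
    """Ultrametric rooted binary tree from a pure-birth (Yule) process.

    Waiting times between speciation events are exponential with rate
    (number of lineages) × ``birth_rate``; every extant lineage's pendant
    edge grows by each waiting time, and a uniformly chosen lineage splits.
    A final exponential stretch is added after the last split so all branch
    lengths are strictly positive. The deep shared branches this produces
    give Brownian traits genuine clade structure (phylogenetic signal),
    which is what makes selection detectable by nearest-taxon statistics.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root.edge.length = 0.0
    leaves = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    while True:
        wait = float(rng.exponential(1.0 / (len(leaves) * birth_rate)))
        for leaf in leaves:
            leaf.edge.length += wait
        if len(leaves) == n_taxa:
            break
        k = int(rng.integers(len(leaves)))
        parent = leaves.pop(k)
        leaves.insert(k, parent.new_child(edge_length=0.0))
        leaves.insert(k + 1, parent.new_child(edge_length=0.0))
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon = tns.new_taxon(label=f"{prefix}{i}")
    return tree


def brownian_traits(tree: dendropy.Tree, sigma: float, seed: int,
                    decay: float = 0.0) -> pd.Series:
    """Evolve a niche trait along the tree by (early-burst) Brownian motion.

    With ``decay=0`` this is plain Brownian motion at rate ``sigma``² per
    unit branch length. A positive ``decay`` makes the rate fall off as
    exp(−decay · t/height) with time t from the root, concentrating trait
    variance on the deep branches: tip traits then mark deep clades, which
    is the regime in which an environmental filter on the trait produces
    phylogenetically clustered communities. Plain Brownian motion spreads
    half its variance over terminal branches, so trait-similar taxa sit in
    many different clades (convergence) and nearest-taxon statistics barely
    see the filter.
    """
    rng = np.random.default_rng(seed)
    if decay > 0:
        height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        rate = decay / height if height > 0 else 0.0
    value: dict[dendropy.Node, float] = {}
    traits = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[node] = 0.0
        else:
            bl = node.edge.length or 0.0
            if decay > 0 and rate > 0 and bl > 0:
                t1 = node.distance_from_root()
                t0 = t1 - bl
                var = (np.exp(-rate * t0) - np.exp(-rate * t1)) / rate
            else:
                var = bl
            value[node] = value[node.parent_node] + sigma * np.sqrt(var) * rng.normal()
        if node.is_leaf():
            traits[node.taxon.label] = value[node]
    return pd.Series(traits)


def _standardize(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("trait has zero variance across tips")
    return (x - x.mean()) / sd


def simulate_communities(tree: dendropy.Tree, scenario: AssemblyScenario) -> CountTable:
    """Draw sample communities from a shared metacommunity under a regime.

    * ``neutral`` — every sample is a multinomial draw from one log-normal
      metacommunity frequency vector.
    * ``homogeneous_selection`` — a niche trait is evolved on the tree
      (early-burst Brownian motion, see :func:`brownian_traits`), tip traits
      are z-scored, and every sample's metacommunity frequencies are
      reweighted by the same Gaussian filter exp(−(trait − opt)² / 2σ²)
      with a single shared optimum (+1 trait sd). On top of the filter each
      sample experiences ecological drift — random local extinction
      (each taxon retained with probability ``occupancy``) and lognormal
      abundance jitter (sd ``drift_sigma``) — plus a small immigration floor
      ``immigration`` that lets off-optimum taxa enter at low abundance.
      Without drift every sample would carry an identical filtered support
      and the nearest-taxon turnover would be degenerate; without
      immigration the observed pool itself is clade-restricted and a
      tip-shuffling null cannot see the filter at all.
    * ``variable_selection`` — the same machinery, but samples fall into
      ``n_blocks`` contiguous blocks whose optima are placed symmetrically
      at ±max(2σ, 1) trait sd, guaranteeing ≥ 4σ separation between blocks.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < scenario.n_taxa:
        raise ValueError("tree has fewer tips than scenario taxa")
    taxa = labels[: scenario.n_taxa]
    rng = np.random.default_rng(scenario.seed)
    log_abund = rng.normal(0.0, scenario.metacommunity_sigma, size=len(taxa))
    freqs = np.exp(log_abund)
    freqs /= freqs.sum()

    if scenario.regime == "neutral":
        optima = np.zeros(scenario.n_samples)
        weights_per_sample = [freqs] * scenario.n_samples
    else:
        traits = _standardize(
            brownian_traits(tree, scenario.trait_sigma, scenario.seed + 1,
                            decay=scenario.trait_decay)
        ).loc[taxa].to_numpy()
        sigma = scenario.selection_strength
        if sigma == 0:
            raise ValueError("selection_strength must be > 0 for selection regimes")
        if scenario.regime == "homogeneous_selection":
            optima = np.full(scenario.n_samples, 1.0)
        else:
            half = max(2.0 * sigma, 1.0)
            block_opts = np.linspace(-half, half, scenario.n_blocks)
            block_of = np.repeat(
                np.arange(scenario.n_blocks),
                int(np.ceil(scenario.n_samples / scenario.n_blocks)),
            )[: scenario.n_samples]
            optima = block_opts[block_of]
        weights_per_sample = []
        for opt in optima:
            filt = np.exp(-((traits - opt) ** 2) / (2.0 * sigma**2))
            # drift as local extinction + abundance jitter; immigration keeps
            # off-optimum taxa observable at low abundance
            present = rng.random(filt.size) < scenario.occupancy
            w = freqs * (filt * present + scenario.immigration)
            if scenario.drift_sigma > 0:
                w = w * np.exp(rng.normal(0.0, scenario.drift_sigma, size=w.size))
            if w.sum() <= 0 or not np.isfinite(w.sum()):
                raise ValueError(
                    "environmental filter annihilated every taxon; "
                    "increase selection_strength (sigma)"
                )
            weights_per_sample.append(w / w.sum())

    rows = []
    for s in range(scenario.n_samples):
        depth = scenario.depth
        if scenario.depth_jitter:
            depth = int(round(depth * rng.uniform(0.8, 1.2)))
        rows.append(rng.multinomial(depth, weights_per_sample[s]))
    counts = pd.DataFrame(
        np.asarray(rows),
        index=[f"s{i + 1}" for i in range(scenario.n_samples)],
        columns=taxa,
    )
    return CountTable(counts)


def sample_blocks(scenario: AssemblyScenario) -> pd.Series:
    """Block (pseudo-treatment) label per sample, matching simulate_communities."""
    block_of = np.repeat(
        np.arange(scenario.n_blocks),
        int(np.ceil(scenario.n_samples / scenario.n_blocks)),
    )[: scenario.n_samples]
    if scenario.regime != "variable_selection":
        block_of = np.zeros(scenario.n_samples, dtype=int)
    return pd.Series(
        [f"block{b + 1}" for b in block_of],
        index=[f"s{i + 1}" for i in range(scenario.n_samples)],
        name="group",
    )


def simulate_cooccurrence(scenario: NetworkScenario) -> CountTable:
    """Planted-module count table for network-threshold recovery.

    Taxon log-abundance = baseline + log_sigma·(sqrt(rho)·module_factor +
    noise_sd·ε), exponentiated and rounded to counts. Within-module
    log-abundance correlation ≈ rho (for the default noise_sd);
    between-module ≈ 0. The default ``log_sigma`` of 0.5 keeps the
    exponentiation near-linear, so Pearson correlation of the *counts*
    themselves also tracks rho closely.
    """
    rng = np.random.default_rng(scenario.seed)
    n, m = scenario.n_taxa, scenario.n_samples
    module_of = np.asarray(scenario.module_of)
    baseline = rng.normal(4.0, 1.0, size=n)  # natural-log scale, e^4 ≈ 55 counts
    factors = rng.normal(size=(m, scenario.n_modules))
    eps = rng.normal(size=(m, n))
    loading = np.sqrt(scenario.rho)
    logab = baseline[None, :] + scenario.log_sigma * (
        loading * factors[:, module_of] + scenario.noise_sd * eps
    )
    counts = np.round(np.exp(logab)).astype(np.int64)
    df = pd.DataFrame(
        counts,
        index=[f"s{i + 1}" for i in range(m)],
        columns=[f"t{j + 1}" for j in range(n)],
    )
    return CountTable(df)


def simulate_feature_table(
    n_features: int,
    group_sizes: dict[str, int] | Sequence[tuple[str, int]],
    effect_size: float,
    seed: int,
    frac_affected: float = 0.2,
    reference_group: str | None = None,
    direction: str = "decrease",
    log_sigma: float = 0.6,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Log-normal feature table with a planted subset of shifted features.

    A ``frac_affected`` fraction of features has its non-reference group
    means shifted by ``effect_size`` standard deviations (of the log-scale
    noise), downward for ``direction="decrease"``. Returns ``(table, groups,
    truth)`` where ``table`` is samples × features, ``groups`` maps sample →
    group, and ``truth`` lists the genuinely shifted feature ids.

    ``effect_size = 0`` yields an empty truth set: nothing is shifted.
    """
    group_sizes = dict(group_sizes)
    if len(group_sizes) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 3 for n in group_sizes.values()):
        raise ValueError("need at least 3 samples per group")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if reference_group is None:
        reference_group = next(iter(group_sizes))
    if reference_group not in group_sizes:
        raise ValueError(f"reference group {reference_group!r} not among groups")
    rng = np.random.default_rng(seed)
    n_affected = int(round(frac_affected * n_features)) if effect_size > 0 else 0
    truth = [f"f{i + 1}" for i in range(n_affected)]

    sign = {"decrease": -1.0, "increase": +1.0}[direction]
    base_mu = rng.normal(2.0, 1.0, size=n_features)  # per-feature log10-ish scale
    sample_ids, group_labels, rows = [], [], []
    for group, size in group_sizes.items():
        shift = np.zeros(n_features)
        if group != reference_group:
            shift[:n_affected] = sign * effect_size * log_sigma
        block = rng.normal(base_mu + shift, log_sigma, size=(size, n_features))
        rows.append(np.exp(block))
        sample_ids += [f"{group}_{i + 1}" for i in range(size)]
        group_labels += [group] * size
    table = pd.DataFrame(
        np.vstack(rows), index=sample_ids,
        columns=[f"f{i + 1}" for i in range(n_features)],
    )
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    return table, groups, truth
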