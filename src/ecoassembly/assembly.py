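"""β-mean nearest taxon distance (βMNTD) and the β-nearest taxon index (βNTI).

βMNTD between two communities is the (abundance-weighted) mean phylogenetic
distance from each taxon in one community to its closest relative in the
other. βNTI is the z-score of the observed βMNTD against a null distribution
obtained by shuffling taxon labels across the tips of the phylogeny of all
taxa investigated — one shared permutation per randomization, applied to
every sample pair, which is equivalent to permuting the rows and columns of
the patristic distance matrix.

βNTI < −2 is read as homogeneous selection (less phylogenetic turnover than
stochastic expectation), βNTI > +2 as variable selection (more turnover),
and values in between as stochastic assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .containers import CountTable, DistanceMatrix, FormatError
from .io import patristic_distances, tip_labels

STOCHASTIC = "stochastic"
HOMOGENEOUS = "homogeneous_selection"
VARIABLE = "variable_selection"
UNDEFINED = "undefined"


@dataclass
class AssemblyResult:
    """Null-model outcome for one (unordered) sample pair."""

    sample_a: str
    sample_b: str
    beta_mntd_obs: float
    null_mean: float
    null_sd: float
    beta_nti: float  # NaN when the null has zero spread
    assembly_class: str
    n_randomizations: int


@dataclass
class AssemblyResultSet:
    sample_ids: list[str]
    results: list[AssemblyResult]
    weighted: bool
    n_randomizations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_a": r.sample_a,
                    "sample_b": r.sample_b,
                    "beta_mntd_obs": r.beta_mntd_obs,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "beta_nti": r.beta_nti,
                    "assembly_class": r.assembly_class,
                }
                for r in self.results
            ]
        )

    def class_fractions(self) -> pd.Series:
        frame = self.to_frame()
        return frame["assembly_class"].value_counts(normalize=True)


def classify(beta_nti: float) -> str:
    if np.isnan(beta_nti):
        return UNDEFINED
    if beta_nti < -2.0:
        return HOMOGENEOUS
    if beta_nti > 2.0:
        return VARIABLE
    return STOCHASTIC


def _community_arrays(table: CountTable, taxa: list[str], weighted: bool):
    """Per-sample presence index arrays and weight matrix over ``taxa``."""
    counts = table.counts[taxa].to_numpy(dtype=float)
    present = [np.flatnonzero(row > 0) for row in counts]
    for sample, idx in zip(table.sample_ids, present):
        if idx.size == 0:
            raise FormatError(f"sample {sample!r} is empty")
    weights = np.zeros_like(counts)
    for i, idx in enumerate(present):
        if weighted:
            weights[i, idx] = counts[i, idx] / counts[i, idx].sum()
        else:
            weights[i, idx] = 1.0 / idx.size
    return present, weights


def _beta_mntd_matrix(dist: np.ndarray, present: list[np.ndarray],
                      weights: np.ndarray, perm: np.ndarray | None = None) -> np.ndarray:
    """βMNTD for every sample pair under an optional tip permutation.

    ``perm[i]`` gives the tip position whose distances taxon ``i`` adopts;
    permuting labels across tips is exactly a symmetric row/column
    permutation of the patristic matrix.
    """
    n_samples = len(present)
    n_taxa = dist.shape[0]
    # minvec[:, m] = distance from every taxon to its nearest taxon present in m
    minvec = np.empty((n_taxa, n_samples))
    for m, idx in enumerate(present):
        if perm is None:
            minvec[:, m] = dist[:, idx].min(axis=1)
        else:
            minvec[:, m] = dist[np.ix_(perm, perm[idx])].min(axis=1)
    half = weights @ minvec  # half[k, m] = Σ_i w_k(i) · d(i, nearest in m)
    return 0.5 * (half + half.T)


def _observed_setup(table: CountTable, tree: dendropy.Tree, weighted: bool):
    totals = table.sample_totals()
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise FormatError(f"sample(s) with no counts: {empty}")
    observed = [t for t in table.taxon_ids if table.counts[t].sum() > 0]
    if len(observed) < 2:
        raise FormatError("need at least 2 observed taxa")
    tips = set(tip_labels(tree))
    missing = sorted(set(observed) - tips)
    if missing:
        raise KeyError(f"taxa missing from tree: {missing}")
    dist = patristic_distances(tree, observed).values
    present, weights = _community_arrays(table, observed, weighted)
    return observed, dist, present, weights


def beta_mntd(table: CountTable, tree: dendropy.Tree, pair: tuple[str, str],
              weighted: bool = True) -> float:
    """Observed βMNTD between the two samples named in ``pair``.

    βMNTD(k, m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} d(i, j)
                    + Σ_{j∈m} f_jm · min_{i∈k} d(j, i) ]

    where f are within-sample relative abundances (``weighted=True``) or
    1/richness (``weighted=False``) and d is the patristic distance; a taxon
    shared by both communities contributes 0 (its nearest taxon is itself).
    """
    sub = table.select_samples(list(pair))
    _, dist, present, weights = _observed_setup(sub, tree, weighted)
    return float(_beta_mntd_matrix(dist, present, weights)[0, 1])


def beta_nti(table: CountTable, tree: dendropy.Tree, n_rand: int = 1000,
             weighted: bool = True, seed: int = 0) -> AssemblyResultSet:
    """βNTI for every sample pair via tip-label randomization.

    Each of the ``n_rand`` randomizations draws ONE permutation of tip
    labels across the full phylogeny of all observed taxa and recomputes
    βMNTD for every sample pair under it, so pairs share the same null
    draws within a randomization (matching the published procedure).

    A pair whose null distribution has zero spread (e.g. with 2 taxa every
    permutation is equivalent) gets βNTI = NaN and class ``"undefined"``
    rather than a clamped ±∞.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100 for a usable null")
    if table.n_samples < 2:
        raise FormatError("need at least 2 samples")
    observed, dist, present, weights = _observed_setup(table, tree, weighted)
    rng = np.random.default_rng(seed)
    obs = _beta_mntd_matrix(dist, present, weights)

    n_taxa = len(observed)
    iu = np.triu_indices(table.n_samples, k=1)
    null = np.empty((n_rand, iu[0].size))
    for r in range(n_rand):
        perm = rng.permutation(n_taxa)
        null[r] = _beta_mntd_matrix(dist, present, weights, perm)[iu]

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    results = []
    samples = table.sample_ids
    for k, (i, j) in enumerate(zip(*iu)):
        sd = null_sd[k]
        if sd > 0:
            z = (obs[i, j] - null_mean[k]) / sd
        else:
            z = float("nan")
        results.append(
            AssemblyResult(
                sample_a=samples[i],
                sample_b=samples[j],
                beta_mntd_obs=float(obs[i, j]),
                null_mean=float(null_mean[k]),
                null_sd=float(sd),
                beta_nti=float(z),
                assembly_class=classify(z),
                n_randomizations=n_rand,
            )
        )
    return AssemblyResultSet(sample_ids=list(samples), results=results,
                             weighted=weighted, n_randomizations=n_rand)


def assembly_distance_matrix(results: AssemblyResultSet) -> DistanceMatrix:
    """Pack per-pair βNTI scores into a labelled symmetric (signed) matrix.

    This is the matrix that enters distance-matrix (Mantel) regressions
    against compositional or functional dissimilarity. Pairs with an
    undefined βNTI make the export fail: a silent NaN would propagate into
    the permutation correlation unnoticed.
    """
    samples = results.sample_ids
    idx = {s: i for i, s in enumerate(samples)}
    values = np.full((len(samples), len(samples)), np.nan)
    np.fill_diagonal(values, 0.0)
    for r in results.results:
        if np.isnan(r.beta_nti):
            raise FormatError(
                f"pair ({r.sample_a}, {r.sample_b}) has an undefined beta-NTI "
                "(zero null spread); cannot export a score matrix"
            )
        i, j = idx[r.sample_a], idx[r.sample_b]
        values[i, j] = values[j, i] = r.beta_nti
    if np.isnan(values).any():
        raise FormatError("result set does not cover every sample pair")
    return DistanceMatrix(samples, values, signed=True)
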