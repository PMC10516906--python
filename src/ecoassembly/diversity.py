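"""Compositional-profile stage: rarefaction, Bray–Curtis, NMDS, PERMANOVA."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.manifold import MDS

from .containers import CountTable, DistanceMatrix, FormatError

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """NMDS configuration: centered sample coordinates plus Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_restarts: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped with a warning
    (the study rarefies to its own minimum depth, so the case never arises
    there, but the tool must behave predictably). Errors if no sample
    survives. Deterministic given ``seed``; a single multivariate
    hypergeometric draw per sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept_rows = {}
    for sample in table.sample_ids:
        row = table.counts.loc[sample].to_numpy()
        total = int(totals[sample])
        if total < depth:
            logger.warning(
                "dropping sample %s: total %d below rarefaction depth %d",
                sample, total, depth,
            )
            continue
        if total == depth:
            kept_rows[sample] = row
        else:
            kept_rows[sample] = rng.multivariate_hypergeometric(row, depth)
    if not kept_rows:
        raise FormatError(f"every sample falls below rarefaction depth {depth}")
    out = pd.DataFrame.from_dict(kept_rows, orient="index", dtype=np.int64)
    out.columns = table.taxon_ids
    return CountTable(out)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity: Σ|x−y| / Σ(x+y), in [0, 1], per sample pair."""
    if table.n_samples < 2:
        raise FormatError("need at least 2 samples for pairwise distances")
    totals = table.sample_totals()
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise FormatError(f"all-zero sample(s): {empty}")
    condensed = pdist(table.counts.to_numpy(dtype=float), metric="braycurtis")
    from scipy.spatial.distance import squareform

    return DistanceMatrix(table.sample_ids, squareform(condensed))


def nmds(dm: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         max_iter: int = 300, seed: int = 0, eps: float = 1e-7) -> OrdinationResult:
    """Nonmetric multidimensional scaling minimising Kruskal stress-1.

    Runs ``n_restarts`` random initialisations and keeps the lowest-stress
    configuration; each iteration alternates monotone (isotonic) regression
    of disparities with a stress-majorising configuration update. The
    returned coordinates are column-centered.
    """
    if k >= dm.n:
        raise ValueError(f"k={k} must be below the number of samples ({dm.n})")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        eps=eps,
        random_state=int(seed) % (2**32),
        normalized_stress=True,
    )
    coords = model.fit_transform(dm.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    frame = pd.DataFrame(
        coords, index=dm.labels, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coordinates=frame, stress=float(model.stress_),
                            n_restarts=n_restarts)


def permanova(dm: DistanceMatrix, groups: pd.Series | dict, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Distance-based one-way PERMANOVA (Anderson's pseudo-F).

    Group labels are permuted freely (no strata); the p-value uses the
    (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) estimator, so p can never be 0.
    """
    groups = pd.Series(groups)
    missing = [s for s in dm.labels if s not in groups.index]
    if missing:
        raise KeyError(f"sample(s) without a group label: {missing}")
    labels = groups.loc[dm.labels].astype(str)
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        tiny = sizes.index[sizes < 2].tolist()
        raise ValueError(f"group(s) with a single sample: {tiny}")
    sk_dm = SkbioDM(dm.values, ids=dm.labels)
    res = _skbio_permanova(sk_dm, labels.to_numpy(), permutations=n_perm,
                           seed=int(seed) % (2**31))
    # R^2 from the pseudo-F identity: F = (SSA/(a-1)) / (SSW/(N-a))
    f = float(res["test statistic"])
    a, n = len(sizes), dm.n
    r2 = (f * (a - 1)) / (f * (a - 1) + (n - a))
    return PermanovaResult(pseudo_f=f, r_squared=float(r2),
                           p_value=float(res["p-value"]), n_permutations=n_perm)
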