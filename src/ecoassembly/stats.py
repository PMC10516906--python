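"""Inferential stages: Mantel regression, rank-sum screening, ANOVA/Tukey,
Z-scoring, RPKM normalisation and permutation slope tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import mantel as _skbio_mantel
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .containers import DistanceMatrix, FormatError, GeneTable


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    correlation_kind: str
    n_samples: int


@dataclass
class SlopeResult:
    slope: float
    intercept: float
    p_value: float
    n_permutations: int


def mantel(dm_x: DistanceMatrix, dm_y: DistanceMatrix, kind: str = "pearson",
           n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel test between two labelled distance (or score) matrices.

    Matrices are aligned by label (dm_y is reordered to dm_x); the
    correlation is computed over the n(n−1)/2 upper-triangle entries and the
    null permutes rows and columns of one matrix simultaneously. Two-sided
    p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm).
    """
    if kind not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation kind {kind!r}")
    if set(dm_x.labels) != set(dm_y.labels):
        raise FormatError("distance matrices carry different labels")
    if dm_x.n < 4:
        raise FormatError("need at least 4 samples for a Mantel test")
    dm_y = dm_y.reorder(dm_x.labels)
    for name, dm in (("x", dm_x), ("y", dm_y)):
        if np.allclose(dm.condensed(), dm.condensed()[0]):
            raise FormatError(f"matrix {name} is constant; correlation undefined")
    r, p, n = _skbio_mantel(
        SkbioDM(dm_x.values, ids=dm_x.labels),
        SkbioDM(dm_y.values, ids=dm_y.labels),
        method=kind, permutations=n_perm, alternative="two-sided",
        seed=int(seed) % (2**31),
    )
    return MantelResult(r=float(r), p_value=float(p), n_permutations=n_perm,
                        correlation_kind=kind, n_samples=int(n))


def _rank_sum_p(treatment: np.ndarray, reference: np.ndarray,
                alternative: str) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) statistic and p-value.

    Exact distribution for combined n ≤ 12 without ties, otherwise the
    normal approximation with tie correction. ``alternative`` refers to the
    treatment group relative to the reference.
    """
    alt = {"decrease": "less", "increase": "greater", "two_sided": "two-sided"}[alternative]
    pooled = np.concatenate([treatment, reference])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(treatment, reference, alternative=alt, method=method,
                           use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue)


def wilcoxon_screen(features: pd.DataFrame, groups: pd.Series,
                    treatment_group: str, reference_group: str,
                    alternative: str = "decrease",
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature rank-sum screen of a treatment against a reference group.

    The default asks the study's question — which features *decreased* under
    the treatment relative to the reference — and controls the false
    discovery rate across all screened features with Benjamini–Hochberg.

    Returns a DataFrame indexed by feature with group medians, the
    Mann–Whitney U statistic, raw and BH-adjusted p-values, the direction of
    the median difference, and a significance flag at ``alpha``. A feature
    constant across both groups gets p = 1 and a ``constant`` flag.
    """
    if alternative not in ("decrease", "increase", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    groups = groups.loc[features.index]
    for name in (treatment_group, reference_group):
        if (groups == name).sum() < 3:
            raise ValueError(f"group {name!r} needs at least 3 samples")
    trt = features.loc[groups == treatment_group]
    ref = features.loc[groups == reference_group]
    rows = []
    for feature in features.columns:
        t, r = trt[feature].to_numpy(float), ref[feature].to_numpy(float)
        constant = np.unique(np.concatenate([t, r])).size == 1
        if constant:
            stat, p = float("nan"), 1.0
        else:
            stat, p = _rank_sum_p(t, r, alternative)
        med_t, med_r = float(np.median(t)), float(np.median(r))
        rows.append({
            "feature": feature,
            "median_treatment": med_t,
            "median_reference": med_r,
            "statistic": stat,
            "p_raw": p,
            "direction": ("decreased" if med_t < med_r
                          else "increased" if med_t > med_r else "unchanged"),
            "constant": constant,
        })
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p_adjusted"] <= alpha
    return out


def _compact_letter_display(groups: list[str],
                            differs: set[frozenset[str]]) -> dict[str, str]:
    """Insertion algorithm: groups sharing a letter are not significantly
    different; every significant pair ends up with disjoint letter sets."""
    letter_sets: list[set[str]] = [set(groups)]
    for pair in differs:
        a, b = tuple(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for new in (sa, sb):
                    if new and not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
    # absorb redundant subsets, keep deterministic order by first group
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                display[g] += letter
    return display


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    letters: dict[str, str]


def anova_tukey(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray,
                alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD post hoc and a compact letter display.

    Groups sharing a letter do not differ at ``alpha`` — the convention used
    to annotate bar/box plots. Tukey comparisons use the studentized-range
    distribution (statsmodels ``pairwise_tukeyhsd``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=str)
    names, counts = np.unique(groups, return_counts=True)
    if names.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    by_group = [values[groups == g] for g in names]
    if all(np.var(v) == 0 for v in by_group):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    f, p = sps.f_oneway(*by_group)
    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tukey = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    differs = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey.iterrows() if row["reject"]
    }
    letters = _compact_letter_display(list(names), differs)
    return AnovaTukeyResult(f_statistic=float(f), p_value=float(p),
                            tukey=tukey, letters=letters)


def zscore(features: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Z-score each feature across samples: (x − mean)/sd with the n−1 sd.

    For a DataFrame, columns are features and rows samples; a constant
    feature is an error (its Z-score is undefined), named in the message.
    """
    if isinstance(features, pd.Series):
        return zscore(features.to_frame()).iloc[:, 0]
    if features.shape[0] < 2:
        raise ValueError("need at least 2 values per feature")
    sd = features.std(axis=0, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance feature(s): {flat}")
    return (features - features.mean(axis=0)) / sd


def rpkm(genes: GeneTable) -> pd.DataFrame:
    """Reads per kilobase of target per million mapped reads.

    RPKM[g, s] = count / ((length_g / 1000) × (total_mapped_s / 10⁶)).
    """
    if (genes.total_mapped <= 0).any():
        bad = genes.total_mapped.index[genes.total_mapped <= 0].tolist()
        raise FormatError(f"zero total mapped reads for sample(s): {bad}")
    kb = genes.gene_lengths / 1000.0
    millions = genes.total_mapped / 1e6
    return genes.counts.div(kb, axis=0).div(millions, axis=1)


def permutation_slope_test(x: np.ndarray, y: np.ndarray, n_perm: int = 999,
                           seed: int = 0) -> SlopeResult:
    """OLS slope with a permutation test of its significance.

    The null permutes y against x; two-sided
    p = (1 + #{|b_perm| ≥ |b_obs|}) / (1 + n_perm).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; slope undefined")
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom = (xc**2).sum()

    def slope_of(yy: np.ndarray) -> float:
        return float((xc * (yy - yy.mean())).sum() / denom)

    b_obs = slope_of(y)
    intercept = float(y.mean() - b_obs * x.mean())
    count = 0
    for _ in range(n_perm):
        if abs(slope_of(rng.permutation(y))) >= abs(b_obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return SlopeResult(slope=b_obs, intercept=intercept, p_value=p,
                       n_permutations=n_perm)
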