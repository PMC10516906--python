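"""Random-matrix-theory thresholded co-occurrence networks (pMEN style).

The idea: as the correlation cutoff s rises, the eigenvalue nearest-neighbor
spacing distribution (NNSD) of the thresholded correlation matrix undergoes
a transition from Gaussian-orthogonal-ensemble (Wigner–Dyson) statistics —
the signature of a noise-dominated random matrix — to Poisson statistics,
the signature of a system decomposed into independent modules. The smallest
cutoff at which the NNSD becomes (and stays) Poisson-consistent separates
signal correlations from noise and defines the network threshold without
any tunable significance knob on the correlations themselves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .containers import CountTable, FormatError

logger = logging.getLogger(__name__)


@dataclass
class NnsdReport:
    """Spacing statistics of a thresholded correlation matrix.

    Chi-square statistics compare the unfolded-spacing histogram with the
    Poisson form e^{−d} and the GOE Wigner surmise (π d/2)·e^{−π d²/4},
    binned at width 0.1 on [0, 3] plus one open tail bin.
    """

    threshold: float
    spacings: np.ndarray
    n_eigenvalues: int
    chi2_poisson: float
    p_poisson: float
    chi2_goe: float
    p_goe: float

    @property
    def mean_spacing(self) -> float:
        return float(self.spacings.mean())

    @property
    def poisson_like(self) -> bool:
        return self.chi2_poisson < self.chi2_goe


@dataclass
class NetworkModel:
    """Thresholded co-occurrence network with per-node degrees."""

    correlation: pd.DataFrame
    threshold: float
    positive_only: bool
    edges: list[tuple[str, str, float]]
    degrees: dict[str, int] = field(default_factory=dict)
    taxonomy: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.degrees)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def correlation_matrix(table: CountTable, transform: str = "log_relative",
                       prevalence: float = 0.5,
                       pseudo_fraction: float = 0.01) -> pd.DataFrame:
    """Pearson correlation between taxa across samples.

    Taxa present in fewer than ``prevalence`` of the samples are removed
    first (sparse taxa generate spurious perfect correlations). With the
    default ``log_relative`` transform, counts become relative abundances,
    zeros are replaced by ``pseudo_fraction`` × the smallest nonzero
    relative abundance in the table, and log10 is taken before correlating.
    Zero-variance taxa after the transform are excluded with a warning.
    """
    if table.n_samples < 10:
        raise FormatError("need >= 10 samples for a stable correlation matrix")
    if transform not in ("log_relative", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    presence = (table.counts > 0).mean(axis=0)
    kept = presence.index[presence >= prevalence].tolist()
    if len(kept) < 2:
        raise FormatError("prevalence filter removed all but <2 taxa")
    data = table.counts[kept].to_numpy(dtype=float)
    if transform == "log_relative":
        rel = data / data.sum(axis=1, keepdims=True)
        nonzero = rel[rel > 0]
        if nonzero.size == 0:
            raise FormatError("table has no nonzero counts")
        rel[rel == 0] = pseudo_fraction * nonzero.min()
        data = np.log10(rel)
    sd = data.std(axis=0, ddof=1)
    flat = [t for t, s in zip(kept, sd) if s == 0]
    if flat:
        logger.warning("excluding zero-variance taxa: %s", flat)
        keep_mask = sd > 0
        kept = [t for t, ok in zip(kept, keep_mask) if ok]
        data = data[:, keep_mask]
    corr = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=kept, columns=kept)


def _threshold_matrix(matrix: np.ndarray, s: float) -> np.ndarray:
    thresholded = np.where(np.abs(matrix) >= s, matrix, 0.0)
    np.fill_diagonal(thresholded, np.diag(matrix))
    return thresholded


def _unfold(eigenvalues: np.ndarray, n_knots: int = 15) -> np.ndarray:
    """Map eigenvalues to unit mean spacing via a smoothed cumulative count.

    A cubic least-squares spline is fitted to the empirical cumulative
    eigenvalue count (rank vs value) with interior knots at uniform
    quantiles; evaluating the fit at each eigenvalue yields the unfolded
    spectrum. Degenerate eigenvalues are collapsed first — repeated values
    carry no spacing information and would swamp the histogram with zeros.
    """
    eig = np.sort(eigenvalues)
    unique = np.unique(np.round(eig, 10))
    n = unique.size
    if n < 5:
        raise FormatError("too few distinct eigenvalues to unfold")
    ranks = np.arange(1, n + 1, dtype=float)
    k = 3
    n_interior = min(n_knots, max(n - k - 3, 0))
    for knots in range(n_interior, -1, -1):
        if knots == 0:
            spline = interpolate.UnivariateSpline(unique, ranks, k=min(k, n - 1), s=0)
            break
        quantiles = np.linspace(0, 1, knots + 2)[1:-1]
        t = np.quantile(unique, quantiles)
        t = np.unique(t)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spline = interpolate.LSQUnivariateSpline(unique, ranks, t, k=k)
            break
        except ValueError:  # Schoenberg–Whitney violated; use fewer knots
            continue
    unfolded = np.sort(spline(unique))
    return np.diff(unfolded)


_BIN_EDGES = np.append(np.arange(0.0, 3.0 + 1e-9, 0.1), np.inf)


def _poisson_cdf(d: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-d)


def _goe_cdf(d: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-np.pi * d**2 / 4.0)


def _chi2_against(spacings: np.ndarray, cdf) -> tuple[float, float]:
    observed, _ = np.histogram(spacings, bins=_BIN_EDGES)
    edges = _BIN_EDGES.copy()
    edges[-1] = np.inf
    probs = np.diff(cdf(np.minimum(edges, 1e9)))
    expected = probs * spacings.size
    mask = expected > 0
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    dof = int(mask.sum()) - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p


def nnsd(matrix: pd.DataFrame | np.ndarray, s: float,
         min_eigenvalues: int = 20) -> NnsdReport:
    """Nearest-neighbor spacing distribution of the matrix thresholded at s.

    Entries with |r| < s are zeroed (diagonal kept); rows left with no
    off-diagonal connection are removed; the spectrum of the remaining
    symmetric matrix is unfolded and its spacings are tested against the
    Poisson and GOE forms.
    """
    values = np.asarray(matrix, dtype=float)
    thresholded = _threshold_matrix(values, s)
    off = thresholded.copy()
    np.fill_diagonal(off, 0.0)
    connected = np.flatnonzero(np.abs(off).sum(axis=1) > 0)
    if connected.size < min_eigenvalues:
        raise FormatError(
            f"only {connected.size} connected rows at s={s:.2f}; "
            f"need >= {min_eigenvalues} eigenvalues for a stable NNSD"
        )
    sub = thresholded[np.ix_(connected, connected)]
    eigenvalues = np.linalg.eigvalsh(sub)
    spacings = _unfold(eigenvalues)
    chi2_p, p_p = _chi2_against(spacings, _poisson_cdf)
    chi2_g, p_g = _chi2_against(spacings, _goe_cdf)
    return NnsdReport(threshold=float(s), spacings=spacings,
                      n_eigenvalues=int(connected.size),
                      chi2_poisson=chi2_p, p_poisson=p_p,
                      chi2_goe=chi2_g, p_goe=p_g)


def rmt_threshold(matrix: pd.DataFrame | np.ndarray,
                  s_grid: np.ndarray | None = None,
                  criterion: str = "relative",
                  alpha: float = 0.05,
                  persistence_fraction: float = 0.8,
                  min_eigenvalues: int = 20) -> tuple[float, pd.DataFrame]:
    """Scan thresholds for the GOE → Poisson transition.

    Returns the smallest grid value at which the NNSD becomes Poisson-like
    and stays that way for larger thresholds, plus the full scan log
    (s, n_eigenvalues, chi-square and p for both spectral forms).

    ``criterion`` selects the per-threshold decision:

    * ``"relative"`` (default) — Poisson fits the spacing histogram better
      than GOE (chi²_Poisson < chi²_GOE). This is robust at the spectrum
      sizes typical of taxon tables, where the absolute chi-square p-value
      fluctuates strongly between neighbouring grid points.
    * ``"absolute"`` — chi-square goodness-of-fit p against Poisson > alpha.

    Persistence is required at a fraction ``persistence_fraction`` of all
    larger grid values that still yield enough eigenvalues: demanding every
    single larger threshold pass would make the scan fail by chance alone
    (each tail point is an independent noisy test).
    """
    if s_grid is None:
        s_grid = np.round(np.arange(0.30, 0.95 + 1e-9, 0.01), 2)
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any((s_grid <= 0) | (s_grid >= 1)):
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    if criterion not in ("relative", "absolute"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows = []
    for s in s_grid:
        try:
            report = nnsd(matrix, s, min_eigenvalues=min_eigenvalues)
        except FormatError:
            rows.append({"s": s, "n_eigenvalues": np.nan, "chi2_poisson": np.nan,
                         "p_poisson": np.nan, "chi2_goe": np.nan, "p_goe": np.nan})
            continue
        rows.append({"s": s, "n_eigenvalues": report.n_eigenvalues,
                     "chi2_poisson": report.chi2_poisson,
                     "p_poisson": report.p_poisson,
                     "chi2_goe": report.chi2_goe, "p_goe": report.p_goe})
    scan = pd.DataFrame(rows)
    usable = scan.dropna(subset=["p_poisson"])
    if criterion == "relative":
        poisson_like = (usable["chi2_poisson"] < usable["chi2_goe"]).to_numpy()
    else:
        poisson_like = (usable["p_poisson"] > alpha).to_numpy()
    chosen = None
    for i in range(len(usable)):
        if poisson_like[i] and poisson_like[i:].mean() >= persistence_fraction:
            chosen = float(usable["s"].iloc[i])
            break
    if chosen is None:
        raise FormatError(
            "no grid threshold reaches sustained Poisson-like spacing "
            f"statistics; scan log:\n{scan.to_string(index=False)}"
        )
    return chosen, scan


def build_network(matrix: pd.DataFrame, s_star: float,
                  positive_only: bool = False,
                  taxonomy: dict[str, str] | None = None,
                  keep_isolated: bool = False) -> NetworkModel:
    """Materialise the network at threshold ``s_star``.

    Edges are taxon pairs with |r| ≥ s_star (or r ≥ +s_star when
    ``positive_only``, the convention of the positive-interaction subnetwork
    figure). Nodes without any retained edge are dropped unless
    ``keep_isolated``.
    """
    taxa = list(matrix.index)
    values = matrix.to_numpy(dtype=float)
    edges = []
    degrees: dict[str, int] = {t: 0 for t in taxa} if keep_isolated else {}
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            r = values[i, j]
            keep = (r >= s_star) if positive_only else (abs(r) >= s_star)
            if keep:
                edges.append((taxa[i], taxa[j], float(r)))
                degrees[taxa[i]] = degrees.get(taxa[i], 0) + 1
                degrees[taxa[j]] = degrees.get(taxa[j], 0) + 1
    if not edges:
        logger.warning("no edges retained at s*=%.2f; returning an empty model",
                       s_star)
    return NetworkModel(correlation=matrix, threshold=float(s_star),
                        positive_only=positive_only, edges=edges,
                        degrees=degrees, taxonomy=dict(taxonomy or {}))
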