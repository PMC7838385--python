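"""Random-matrix-theory based correlation network inference.

The similarity threshold for the gene co-occurrence network is chosen
from the spectrum of the thresholded |Pearson r| matrix: random matrix
theory predicts that the nearest-neighbour spacing distribution (NNSD)
of unfolded eigenvalues follows the Wigner-Dyson (GOE) form
``P(s) = (pi s / 2) exp(-pi s^2 / 4)`` for an intrinsically correlated
system and the Poisson form ``P(s) = exp(-s)`` once the system decouples
into independent (modular) pieces.  Scanning thresholds upward, the
smallest threshold at which the NNSD becomes — and stays — Poisson is
taken as the similarity threshold st of the network.

Unfolding maps eigenvalues so their local mean spacing is 1.  The
default divides each level gap by the mean gap in a sliding window
(local unfolding), which tracks the sharply multimodal spectral
densities of thresholded matrices; a Gaussian-smoothed empirical
cumulative spectral function and a smoothing-spline fit are available
as alternatives.  Exactly degenerate eigenvalues are collapsed before
unfolding, since they carry no spacing information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from scipy.special import ndtr

from .datatypes import PipelineError, SignalMatrix, StudyDesign
from .synthetic import NETWORK_CATEGORIES

logger = logging.getLogger(__name__)

POISSON, GOE, AMBIGUOUS = "poisson", "goe", "ambiguous"


class ThresholdScanError(PipelineError):
    """No stable Poisson verdict found on the threshold grid."""


def select_common_genes(
    matrix: SignalMatrix,
    design: StudyDesign,
    annotation: pd.DataFrame,
    group: str,
    min_prevalence_fraction: float = 0.5,
    categories: tuple[str, ...] = NETWORK_CATEGORIES,
) -> pd.Index:
    """Genes in the focal categories detected in enough group samples.

    A gene is kept when its category is in ``categories`` and it is
    detected (value > 0) in at least ``ceil(min_prevalence_fraction *
    n_group_samples)`` samples of the group being networked.
    """
    samples = [s for s in matrix.samples if design.group_of_sample(s) == group]
    if not samples:
        raise PipelineError(f"no samples in group {group!r}")
    thr = math.ceil(min_prevalence_fraction * len(samples))
    detected = (matrix.values[samples] > 0).sum(axis=1) >= thr
    in_cat = annotation.loc[matrix.probes, "category"].isin(categories)
    keep = matrix.probes[detected & in_cat.to_numpy()]
    if len(keep) == 0:
        raise PipelineError(
            "no genes pass the prevalence/category selection; "
            "lower min_prevalence_fraction or widen categories"
        )
    return keep


@dataclass
class CorrelationMatrix:
    r: np.ndarray  # gene x gene Pearson r, diag 1
    genes: list[str]
    n_samples: int

    def __post_init__(self) -> None:
        if self.r.shape != (len(self.genes), len(self.genes)):
            raise ValueError("correlation matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def pearson_matrix(values: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlation across samples (genes x samples input).

    Genes with zero variance across samples are dropped with a warning.
    """
    if values.shape[1] < 4:
        raise PipelineError("need >= 4 samples for correlations")
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes", int((~keep).sum()))
    values = values[keep.to_numpy()]
    if len(values) < 2:
        raise PipelineError("fewer than 2 genes with variance")
    r = np.corrcoef(values.to_numpy())
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, [str(g) for g in values.index], values.shape[1])


def threshold_similarity(r: np.ndarray, st: float) -> np.ndarray:
    """|r| kept where |r| >= st, else 0; unit diagonal."""
    s = np.abs(r).copy()
    s[s < st] = 0.0
    np.fill_diagonal(s, 1.0)
    return s


def _collapse_degenerate(eigs: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    eigs = np.sort(eigs)
    keep = [eigs[0]]
    for e in eigs[1:]:
        if e - keep[-1] > tol:
            keep.append(e)
    return np.array(keep)


def unfold_eigenvalues(
    eigs: np.ndarray,
    method: str = "local",
    bandwidth: float | None = None,
    window: int = 5,
) -> np.ndarray:
    """Unfold a (deduplicated, sorted) spectrum; returns spacings.

    ``local`` (default): divide each level gap by the mean gap within a
    sliding window of ``window`` levels on either side — a rank-based
    uniformization of the empirical cumulative spectral function that
    tracks sharply varying (multimodal) spectral densities.
    ``ecdf``: evaluate the Gaussian-broadened empirical cumulative
    spectral function F at each eigenvalue and take spacings of m*F.
    ``spline``: smoothing-spline fit of the empirical staircase.
    """
    m = len(eigs)
    if m < 2:
        return np.array([])
    if method == "local":
        gaps = np.diff(eigs)
        n_gaps = len(gaps)
        spacings = np.empty(n_gaps)
        for i in range(n_gaps):
            lo, hi = max(0, i - window), min(n_gaps, i + window + 1)
            spacings[i] = gaps[i] / gaps[lo:hi].mean()
        return spacings
    if method == "ecdf":
        if bandwidth is None:
            # a few mean level spacings: wide enough to smooth the
            # staircase, narrow enough to track the spectral density
            bandwidth = 2.5 * (eigs[-1] - eigs[0]) / m
        z = (eigs[:, None] - eigs[None, :]) / bandwidth
        F = ndtr(z).mean(axis=1)
        unfolded = m * F
    elif method == "spline":
        stair = (np.arange(m) + 0.5) / m
        spl = UnivariateSpline(eigs, stair, k=3, s=m * 1e-4)
        unfolded = m * np.sort(spl(eigs))
    else:
        raise ValueError(f"unknown unfolding method {method!r}")
    return np.diff(unfolded)


def _poisson_cdf(s: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-s)


def _wigner_cdf(s: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-np.pi * s**2 / 4.0)


def _gof(spacings: np.ndarray, cdf, method: str) -> tuple[float, float]:
    if method == "ks":
        res = stats.kstest(spacings, cdf)
        return float(res.statistic), float(res.pvalue)
    if method == "chisq":
        # bins of width 0.5 out to the 99.9th percentile of the law
        edges = np.arange(0.0, max(3.5, spacings.max()) + 0.5, 0.5)
        observed, _ = np.histogram(spacings, bins=edges)
        expected = np.diff(cdf(edges)) * len(spacings)
        mask = expected > 1e-9
        chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
        dof = max(mask.sum() - 1, 1)
        return chi2, float(stats.chi2.sf(chi2, dof))
    raise ValueError(f"unknown goodness-of-fit method {method!r}")


@dataclass
class NNSDResult:
    st: float
    eigenvalues: np.ndarray  # deduplicated spectrum of the surviving block
    spacings: np.ndarray
    poisson_stat: float | None
    poisson_p: float | None
    wigner_stat: float | None
    wigner_p: float | None
    verdict: str
    n_surviving: int
    degenerate: bool = False

    @property
    def mean_spacing(self) -> float | None:
        return float(self.spacings.mean()) if len(self.spacings) else None


def nnsd_test(
    corr: CorrelationMatrix | np.ndarray,
    st: float,
    gof: str = "ks",
    alpha: float = 0.05,
    unfolding: str = "local",
    min_genes: int = 50,
    allow_small: bool = True,
    min_spacings: int = 10,
) -> NNSDResult:
    """Classify the NNSD of the st-thresholded similarity matrix.

    The matrix is restricted to genes with at least one retained
    off-diagonal entry; isolated genes only add exact eigenvalue-1
    degeneracies.  Verdict: ``poisson`` when the Poisson law is not
    rejected while the Wigner law is, ``goe`` for the converse, else
    ``ambiguous``.  A spectrum with no surviving genes, or too few
    distinct eigenvalues to test, is a fully decoupled system and is
    classified ``poisson`` with ``degenerate=True``.
    """
    r = corr.r if isinstance(corr, CorrelationMatrix) else np.asarray(corr, dtype=float)
    if r.shape[0] < min_genes:
        msg = f"matrix has {r.shape[0]} genes; >= {min_genes} needed for a stable NNSD"
        if not allow_small:
            raise PipelineError(msg)
        logger.warning(msg)
    s = threshold_similarity(r, st)
    off = s - np.diag(np.diag(s))
    surviving = np.flatnonzero((off != 0).any(axis=1))
    if len(surviving) == 0:
        return NNSDResult(st, np.array([]), np.array([]), None, None, None, None,
                          POISSON, 0, degenerate=True)
    sub = s[np.ix_(surviving, surviving)]
    eigs = _collapse_degenerate(np.linalg.eigvalsh(sub))
    spacings = unfold_eigenvalues(eigs, method=unfolding)
    if len(spacings) < min_spacings:
        return NNSDResult(st, eigs, spacings, None, None, None, None,
                          POISSON, len(surviving), degenerate=True)
    p_stat, p_p = _gof(spacings, _poisson_cdf, gof)
    w_stat, w_p = _gof(spacings, _wigner_cdf, gof)
    if p_p >= alpha and w_p < alpha:
        verdict = POISSON
    elif w_p >= alpha and p_p < alpha:
        verdict = GOE
    else:
        verdict = AMBIGUOUS
    return NNSDResult(st, eigs, spacings, p_stat, p_p, w_stat, w_p, verdict, len(surviving))


DEFAULT_GRID = np.round(np.arange(0.30, 1.00, 0.01), 2)


@dataclass
class ThresholdScan:
    grid: np.ndarray
    results: list[NNSDResult]
    selected_st: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "st": [r.st for r in self.results],
                "n_surviving": [r.n_surviving for r in self.results],
                "poisson_p": [r.poisson_p for r in self.results],
                "wigner_p": [r.wigner_p for r in self.results],
                "verdict": [r.verdict for r in self.results],
                "degenerate": [r.degenerate for r in self.results],
            }
        )


def select_threshold(
    corr: CorrelationMatrix,
    grid: np.ndarray = DEFAULT_GRID,
    gof: str = "ks",
    alpha: float = 0.05,
    unfolding: str = "local",
    min_surviving: int = 50,
    successor_tolerance: float = 0.1,
    stability_run: int = 3,
) -> ThresholdScan:
    """Scan thresholds ascending and pick the Poisson transition point.

    Selected st = the smallest grid value with >= ``min_surviving``
    non-isolated genes whose verdict is Poisson, whose next
    ``stability_run`` testable grid values are also Poisson, and for
    which at least ``1 - successor_tolerance`` of all higher testable
    grid values remain Poisson (a small tolerance absorbs isolated
    goodness-of-fit fluctuations at single grid points).  A matrix with
    no off-diagonal |r| reaching the grid minimum is fully decoupled
    everywhere; the grid minimum is returned.  Raises
    :class:`ThresholdScanError` when no stable Poisson verdict exists.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    if not (grid[0] >= 0 and grid[-1] < 1):
        raise ValueError("grid must lie within [0, 1)")
    results = [
        nnsd_test(corr, float(st), gof=gof, alpha=alpha, unfolding=unfolding)
        for st in grid
    ]
    off = np.abs(corr.r - np.diag(np.diag(corr.r)))
    if off.max() < grid[0]:
        return ThresholdScan(grid, results, float(grid[0]))
    testable = [r.n_surviving >= min_surviving for r in results]
    selected = None
    for i, res in enumerate(results):
        if not testable[i] or res.verdict != POISSON:
            continue
        succ = [results[j].verdict for j in range(i + 1, len(results)) if testable[j]]
        run_ok = all(v == POISSON for v in succ[:stability_run])
        frac_ok = (
            not succ
            or sum(v == POISSON for v in succ) / len(succ) >= 1.0 - successor_tolerance
        )
        if run_ok and frac_ok:
            selected = float(res.st)
            break
    if selected is None:
        scan = ThresholdScan(grid, results, float("nan"))
        counts = scan.summary()["verdict"].value_counts().to_dict()
        raise ThresholdScanError(
            f"no stable Poisson verdict on grid (verdict counts: {counts}); "
            "the correlation matrix may lack modular structure"
        )
    return ThresholdScan(grid, results, selected)


@dataclass
class GeneNetwork:
    """Signed thresholded correlation graph (isolated genes excluded)."""

    graph: nx.Graph
    st: float
    metric: str = "pearson"
    empty_warning: bool = False

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def L(self) -> int:
        return self.graph.number_of_edges()

    @property
    def pct_positive(self) -> float:
        if self.L == 0:
            return 0.0
        pos = sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] > 0)
        return 100.0 * pos / self.L

    @property
    def pct_negative(self) -> float:
        return 100.0 - self.pct_positive if self.L else 0.0

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


def build_network(
    corr: CorrelationMatrix,
    st: float,
    annotation: pd.DataFrame | None = None,
) -> GeneNetwork:
    """Edges where |r| >= st, signed by r; isolated genes dropped."""
    if not 0.0 < st < 1.0:
        raise ValueError(f"st must lie in (0, 1), got {st}")
    g = nx.Graph()
    r = corr.r
    n = corr.n_genes
    iu, ju = np.triu_indices(n, 1)
    mask = np.abs(r[iu, ju]) >= st
    for i, j in zip(iu[mask], ju[mask]):
        rij = float(r[i, j])
        g.add_edge(
            corr.genes[i],
            corr.genes[j],
            weight=abs(rij),
            sign=1 if rij > 0 else -1,
            r=rij,
        )
    if annotation is not None:
        for node in g.nodes:
            if node in annotation.index:
                row = annotation.loc[node]
                g.nodes[node].update(
                    gene_family=str(row.get("gene_family", "")),
                    category=str(row.get("category", "")),
                    lineage=str(row.get("lineage", "")),
                )
    empty = g.number_of_edges() == 0
    if empty:
        logger.warning("network at st=%.3f has no edges", st)
    return GeneNetwork(g, st, empty_warning=empty)


def powerlaw_r2(network: GeneNetwork) -> float | None:
    """R^2 of the OLS fit of log10 degree frequency on log10 degree.

    Returns None (flagged undefined) with fewer than 3 distinct degrees.
    """
    degrees = np.array([d for _, d in network.graph.degree()])
    if len(degrees) == 0:
        return None
    ks, freqs = np.unique(degrees, return_counts=True)
    keep = ks > 0
    ks, freqs = ks[keep], freqs[keep]
    if len(ks) < 3:
        logger.warning("power-law fit undefined: %d distinct degrees", len(ks))
        return None
    x, y = np.log10(ks), np.log10(freqs)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot
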