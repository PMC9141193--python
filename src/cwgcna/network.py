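"""Weighted co-expression networks, TOM calibration and the consensus TOM.

Per cohort, gene-gene Pearson correlations are soft-thresholded into an
adjacency ``a_ij = |r_ij|^beta`` (unsigned) or ``a_ij = ((1+r_ij)/2)^beta``
(signed), with beta chosen by the scale-free topology criterion.  The
topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu

upweights pairs that share neighbours.  Before taking the element-wise
minimum across cohorts (the consensus TOM), each cohort's TOM is
calibrated onto the first cohort by quantile matching: the exponent
``e_s = log(Q_ref) / log(Q_s)`` maps cohort s's q-quantile onto the
reference quantile, removing cohort-level scale differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

__all__ = [
    "SoftThresholdReport",
    "AdjacencyMatrix",
    "TOMMatrix",
    "ConsensusTOM",
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency_matrix",
    "tom_similarity",
    "calibrate_toms",
    "consensus_tom",
    "build_consensus",
    "tom_qq_divergence",
]

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


def correlation_matrix(m: ExpressionMatrix | pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlations, pairwise-complete when values are missing.

    Constant genes get zero correlations (with a warning) rather than NaN.
    """
    df = m.values if isinstance(m, ExpressionMatrix) else m
    X = np.asarray(df, dtype=float)
    if np.isnan(X).any():
        r = df.T.corr(min_periods=3).to_numpy()
    else:
        sd = X.std(axis=1)
        if (sd == 0).any():
            warnings.warn("constant gene(s): correlations set to 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X)
    bad = ~np.isfinite(r)
    if bad.any():
        if np.isnan(X).any():
            warnings.warn("undefined correlations (constant genes) set to 0")
        r[bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded network adjacency; diagonal stored as 0."""

    gene_ids: list[str]
    values: np.ndarray
    mode: str
    power: float

    @property
    def connectivity(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass
class TOMMatrix:
    """Topological overlap; diagonal 1, values in [0, 1]."""

    gene_ids: list[str]
    values: np.ndarray
    connectivity: np.ndarray | None = None

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class ConsensusTOM:
    """Per-cohort calibrated TOMs plus their element-wise minimum."""

    per_cohort: list[TOMMatrix]
    consensus: TOMMatrix
    calibration_quantile: float
    calibration_exponents: list[float]

    @property
    def gene_ids(self) -> list[str]:
        return self.consensus.gene_ids


@dataclass
class SoftThresholdReport:
    """Scale-free fit per candidate power and the chosen soft threshold."""

    candidate_powers: list[int]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    target_r2: float
    warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.candidate_powers,
                "signed_r2": self.fit_r2,
                "mean_connectivity": self.mean_connectivity,
            }
        )


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit statistic for a connectivity vector.

    Connectivities are binned into equal-width bins; log10 of the bin
    frequency is regressed on log10 of the bin's mean connectivity, and
    the statistic is -sign(slope) * R^2, so positive values indicate the
    decreasing power-law regime.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k.append(k[mask].mean())
        freq.append(mask.mean())
    if len(mean_k) < 3:
        return 0.0
    x = np.log10(np.asarray(mean_k))
    y = np.log10(np.asarray(freq))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    r2 = 1 - np.sum(resid**2) / ss_tot
    return float(-np.sign(slope) * r2)


def select_power(powers, fit_r2, target_r2: float) -> tuple[int, bool]:
    """Smallest power reaching the target fit, else argmax with a warning flag."""
    for p, r2 in zip(powers, fit_r2):
        if r2 >= target_r2:
            return int(p), False
    return int(powers[int(np.argmax(fit_r2))]), True


def pick_soft_threshold(
    m: ExpressionMatrix,
    powers=DEFAULT_POWERS,
    target_r2: float = 0.8,
    mode: str = "signed",
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Scan candidate soft-threshold powers for scale-free topology fit."""
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    powers = list(powers)
    if not powers:
        raise ValueError("powers must be non-empty")
    r = correlation_matrix(m)
    base = np.abs(r) if mode == "unsigned" else (1 + r) / 2
    np.fill_diagonal(base, 0.0)
    fit, meank = [], []
    for p in powers:
        a = base**p
        k = a.sum(axis=1)
        fit.append(scale_free_fit(k, n_bins=n_bins))
        meank.append(float(k.mean()))
    chosen, warn = select_power(powers, fit, target_r2)
    if warn:
        warnings.warn(
            f"no power reached scale-free fit {target_r2}; using argmax power {chosen}"
        )
    return SoftThresholdReport(powers, fit, meank, chosen, target_r2, warn)


def adjacency_matrix(
    m: ExpressionMatrix, mode: str = "signed", power: float = 6
) -> AdjacencyMatrix:
    """Soft-threshold the correlation matrix into a network adjacency."""
    if power < 1:
        raise ValueError("power must be >= 1")
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    r = correlation_matrix(m)
    if mode == "unsigned":
        a = np.abs(r) ** power
    elif mode == "signed":
        a = ((1 + r) / 2) ** power
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(m.gene_ids, a, mode, power)


def tom_similarity(a: AdjacencyMatrix | np.ndarray, gene_ids=None) -> TOMMatrix:
    """Topological overlap of an adjacency matrix (diagonal 1)."""
    if isinstance(a, AdjacencyMatrix):
        A = a.values
        gene_ids = a.gene_ids
    else:
        A = np.asarray(a, dtype=float)
        A = A.copy()
        np.fill_diagonal(A, 0.0)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(A.shape[0])]
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / denom
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return TOMMatrix(list(gene_ids), tom, connectivity=k)


def calibrate_toms(
    toms: list[TOMMatrix], q: float = 0.95
) -> tuple[list[TOMMatrix], list[float]]:
    """Quantile-calibrate TOMs onto the first cohort.

    The q-quantile is taken as an order statistic (no interpolation) so
    that the monotone power map carries each cohort's quantile exactly
    onto the reference quantile.  Raises if any cohort's q-quantile is 0
    or 1 (power scaling undefined).
    """
    if len(toms) < 2:
        raise ValueError("need at least two TOMs to calibrate")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    genes0 = toms[0].gene_ids
    for t in toms[1:]:
        if t.gene_ids != genes0:
            raise ValueError("TOMs must share an identical gene list")
    quants = [float(np.quantile(t.off_diagonal(), q, method="lower")) for t in toms]
    q_ref = quants[0]
    if not (0 < q_ref < 1):
        raise ValueError(f"reference {q}-quantile {q_ref} outside (0,1)")
    calibrated, exponents = [], []
    for t, q_s in zip(toms, quants):
        if not (0 < q_s < 1):
            raise ValueError(f"{q}-quantile {q_s} outside (0,1): cannot calibrate")
        e = float(np.log(q_ref) / np.log(q_s))
        v = t.values**e
        np.fill_diagonal(v, 1.0)
        calibrated.append(TOMMatrix(t.gene_ids, v, connectivity=t.connectivity))
        exponents.append(e)
    return calibrated, exponents


def consensus_tom(toms: list[TOMMatrix]) -> TOMMatrix:
    """Element-wise minimum of (calibrated) TOMs; diagonal 1."""
    genes0 = toms[0].gene_ids
    for t in toms[1:]:
        if t.gene_ids != genes0:
            raise ValueError("TOMs must share an identical gene list")
    cons = np.minimum.reduce([t.values for t in toms])
    np.fill_diagonal(cons, 1.0)
    return TOMMatrix(genes0, cons)


def build_consensus(toms: list[TOMMatrix], q: float = 0.95) -> ConsensusTOM:
    """Calibrate cohort TOMs at quantile q and take their element-wise minimum."""
    if len(toms) == 1:
        return ConsensusTOM(toms, consensus_tom(toms), q, [1.0])
    calibrated, exponents = calibrate_toms(toms, q=q)
    return ConsensusTOM(calibrated, consensus_tom(calibrated), q, exponents)


def tom_qq_divergence(t1: TOMMatrix, t2: TOMMatrix, n_quantiles: int = 100) -> float:
    """Maximum quantile gap between two TOM value distributions.

    A Kolmogorov-style screen for dataset compatibility: the off-diagonal
    TOM values of each matrix are summarised by quantiles on an evenly
    spaced probability grid and the largest absolute difference is
    returned (0 for identical distributions).
    """
    if n_quantiles < 10:
        raise ValueError("n_quantiles must be >= 10")
    grid = np.linspace(0.0, 1.0, n_quantiles)
    q1 = np.quantile(t1.off_diagonal(), grid)
    q2 = np.quantile(t2.off_diagonal(), grid)
    return float(np.max(np.abs(q1 - q2)))
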