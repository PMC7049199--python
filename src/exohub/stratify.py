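"""Population-structure correction of genotypes and phenotype.

The sample x variant matrix is decomposed into principal axes of variation
(optionally with allele-frequency normalization); every variant column and the
+/-1-coded phenotype are regressed on the retained axes by ordinary least
squares, residuals are taken as the adjusted values, rounded
half-away-from-zero to integers, and capped to [-4, +4].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .filtering import GenotypeMatrix

logger = logging.getLogger(__name__)

CAP_LO, CAP_HI = -4, 4
PHENOTYPE_CODE = {"ASD": 1.0, "SCZ": -1.0}


@dataclass
class AxesOfVariation:
    """Top principal axes of the sample x variant matrix.

    ``scores`` has orthonormal columns (unit norm, mutually orthogonal over
    samples); ``eigenvalues`` are the corresponding covariance eigenvalues.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    n_axes: int
    significance: np.ndarray | None = None

    def __post_init__(self) -> None:
        gram = self.scores.T @ self.scores
        if not np.allclose(gram, np.eye(self.n_axes), atol=1e-8):
            raise ValueError("axis scores must be orthonormal over samples")


@dataclass
class AdjustedMatrix:
    """Integer-valued residual matrix with the adjusted integer phenotype."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    adjusted_phenotype: np.ndarray
    labels: np.ndarray
    variant_to_gene: dict[str, str]
    mode: str = "residual_plus_intercept"

    def __post_init__(self) -> None:
        if self.values.min(initial=0) < CAP_LO or self.values.max(initial=0) > CAP_HI:
            raise ValueError("adjusted values outside the cap range")
        if len(self.adjusted_phenotype) != len(self.sample_ids):
            raise ValueError("one adjusted phenotype per sample required")


def _normalize_columns(X: np.ndarray, normalize: bool) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    if not normalize:
        return Xc
    p = X.mean(axis=0) / 2.0
    scale = np.sqrt(p * (1.0 - p))
    scale[scale == 0] = 1.0
    return Xc / scale


def compute_axes(G: GenotypeMatrix, n_axes: int = 4, normalize: bool = True) -> AxesOfVariation:
    """Top principal axes of variation of the genotype matrix.

    Monomorphic columns are excluded.  Sign convention: within each axis the
    largest-magnitude score entry is made positive (ties broken by sample
    order), so results are deterministic and sample-permutation equivariant.
    """
    n = G.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_axes >= n:
        raise ValueError(f"n_axes={n_axes} must be smaller than the number of samples ({n})")
    X = G.values.astype(float)
    poly = X.std(axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic variant columns; axes undefined")
    Xn = _normalize_columns(X[:, poly], normalize)
    U, s, _ = np.linalg.svd(Xn, full_matrices=False)
    k = min(n_axes, len(s))
    scores = U[:, :k].copy()
    for j in range(k):
        i_star = int(np.argmax(np.abs(scores[:, j])))
        if scores[i_star, j] < 0:
            scores[:, j] = -scores[:, j]
    eigenvalues = (s[:k] ** 2) / (n - 1)
    return AxesOfVariation(scores=scores, eigenvalues=eigenvalues, n_axes=k)


def axis_significance(
    G: GenotypeMatrix,
    n_axes: int = 4,
    normalize: bool = True,
    n_permutations: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-value per axis: share of column-wise permutations of the
    genotype matrix whose corresponding eigenvalue meets or exceeds the
    observed one.  A small-B empirical test, reported but never used for
    automatic axis selection."""
    axes = compute_axes(G, n_axes=n_axes, normalize=normalize)
    rng = np.random.default_rng(seed)
    X = G.values.astype(float)
    exceed = np.zeros(axes.n_axes)
    for _ in range(n_permutations):
        Xp = X.copy()
        for j in range(Xp.shape[1]):
            rng.shuffle(Xp[:, j])
        Xn = _normalize_columns(Xp[:, Xp.std(axis=0) > 0], normalize)
        s = np.linalg.svd(Xn, compute_uv=False)
        ev = (s[: axes.n_axes] ** 2) / (G.n_samples - 1)
        ev = np.pad(ev, (0, axes.n_axes - len(ev)))
        exceed += ev >= axes.eigenvalues
    return (exceed + 1) / (n_permutations + 1)


def _design(axes: AxesOfVariation, n: int) -> np.ndarray:
    if axes.scores.shape[0] != n:
        raise ValueError("axes were computed for a different number of samples")
    design = np.column_stack([np.ones(n), axes.scores])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient axis design; collinear axes effectively dropped")
    return design


def regress_residual(
    column: np.ndarray, axes: AxesOfVariation, mode: str = "residual"
) -> np.ndarray:
    """OLS residual of one per-sample column on the axis scores (with intercept).

    ``mode='residual'`` returns raw residuals; ``mode='residual_plus_intercept'``
    adds the fitted intercept back, removing only the axis effects.
    """
    y = np.asarray(column, dtype=float)
    design = _design(axes, len(y))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if mode == "residual":
        return resid
    if mode == "residual_plus_intercept":
        return resid + beta[0]
    raise ValueError(f"unknown mode {mode!r}")


def round_and_cap(values: np.ndarray, lo: int = CAP_LO, hi: int = CAP_HI) -> np.ndarray:
    """Round half-away-from-zero to the nearest integer, then clamp to [lo, hi]."""
    if lo > hi:
        raise ValueError(f"invalid cap range [{lo}, {hi}]")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be rounded")
    rounded = np.sign(v) * np.floor(np.abs(v) + 0.5)
    return np.clip(rounded, lo, hi).astype(np.int64)


def adjust_dataset(
    G: GenotypeMatrix,
    axes: AxesOfVariation,
    mode: str = "residual_plus_intercept",
) -> AdjustedMatrix:
    """Residual-adjust every variant column and the +/-1-coded phenotype.

    The phenotype is encoded ASD=+1, SCZ=-1 before adjustment so that the
    downstream sign-based class mapping is coherent.  Columns and phenotype go
    through :func:`regress_residual` followed by :func:`round_and_cap`.
    """
    if mode not in ("residual", "residual_plus_intercept"):
        raise ValueError(f"unknown mode {mode!r}")
    Y = G.values.astype(float)
    n = G.n_samples
    design = _design(axes, n)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    if mode == "residual_plus_intercept":
        resid = resid + beta[0][None, :]
    values = round_and_cap(resid)

    ph = np.array([PHENOTYPE_CODE[lab] for lab in G.labels])
    ph_adj = round_and_cap(regress_residual(ph, axes, mode=mode))
    n_flipped = int((np.sign(ph_adj) != np.sign(ph)).sum())
    if n_flipped:
        logger.info("adjusted phenotype changed sign or vanished for %d samples", n_flipped)

    return AdjustedMatrix(
        sample_ids=list(G.sample_ids),
        feature_ids=list(G.variant_ids),
        values=values,
        adjusted_phenotype=ph_adj,
        labels=np.asarray(G.labels),
        variant_to_gene=dict(G.variant_to_gene),
        mode=mode,
    )
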