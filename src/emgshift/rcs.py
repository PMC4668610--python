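"""Feature-space shift quantification: FLD reduction and relative center shift.

To compare how far different feature sets drift under electrode shift on a
common footing, feature vectors are first reduced by a Fisher linear
discriminant (FLD) projection to ``N - 1`` dimensions (``N`` motions).  The
relative center shift (RCS) is then

    RCS = (N-1) * sum_i Maha(mu_i, mu_si; (S_i + S_si)/2)
          -----------------------------------------------------
          sum_i sum_{j != i} Maha(mu_sj, mu_si; (S_sj + S_si)/2)

where ``mu_i, S_i`` are the centroid and covariance of motion ``i`` before
the shift, ``mu_si, S_si`` after, and ``Maha(a, b; S) =
sqrt((a-b)' S^{-1} (a-b))``.  The numerator measures how far each class
center moves; the denominator normalizes by post-shift between-class
separation, so RCS is unitless, affine-invariant and zero exactly when no
centroid moves.  Smaller RCS means the decision boundaries learned before
the shift remain better placed after it.

Covariances are computed in the FLD-reduced space, where they are invertible
with realistic window counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import DataError, InvalidArgumentError, NumericalError
from .features import FeatureMatrix

__all__ = ["FLDProjection", "RCSResult", "fit_fld", "compute_rcs"]

#: Ridge fractions (times trace/d) stabilizing scatter / covariance inverses.
FLD_RIDGE = 1e-6
RCS_RIDGE = 1e-9


@dataclass
class FLDProjection:
    """Linear projection to at most ``N - 1`` discriminant dimensions."""

    matrix: np.ndarray  # (d, out_dim)
    class_labels: tuple[int, ...]
    fitted_on: str = ""

    @property
    def out_dim(self) -> int:
        return self.matrix.shape[1]

    def transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) @ self.matrix


@dataclass
class RCSResult:
    """Relative center shift with its ingredients."""

    value: float
    numerator_mean: float
    denominator_mean: float
    per_motion_center_shift: np.ndarray


def fit_fld(
    features: FeatureMatrix,
    out_dim: "int | None" = None,
    ridge: float = FLD_RIDGE,
) -> FLDProjection:
    """Fit a Fisher linear discriminant projection.

    Columns are the leading generalized eigenvectors of the between-class
    scatter against the (ridge-regularized) within-class scatter, sign-pinned
    so the first nonzero element of each column is positive.  ``out_dim``
    defaults to ``min(N - 1, d)``.
    """
    x = features.values
    labels = np.asarray(features.labels)
    classes = np.unique(labels)
    n_classes, d = len(classes), x.shape[1]
    if n_classes < 2:
        raise InvalidArgumentError("FLD needs at least 2 classes")
    if out_dim is None:
        out_dim = min(n_classes - 1, d)
    if not 1 <= out_dim <= min(n_classes - 1, d):
        raise InvalidArgumentError(
            f"out_dim must be in [1, min(N-1={n_classes - 1}, d={d})], "
            f"got {out_dim}"
        )
    mu = x.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for c in classes:
        xc = x[labels == c]
        if xc.shape[0] < 2:
            raise DataError(f"class {c} has fewer than 2 windows")
        mc = xc.mean(axis=0)
        cen = xc - mc
        sw += cen.T @ cen
        diff = (mc - mu)[:, None]
        sb += xc.shape[0] * (diff @ diff.T)
    sw_r = sw + (ridge * np.trace(sw) / d) * np.eye(d)
    try:
        vals, vecs = scipy.linalg.eigh(sb, sw_r)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            "within-class scatter singular; raise the FLD ridge"
        ) from exc
    order = np.argsort(vals)[::-1][:out_dim]
    proj = vecs[:, order]
    for i in range(proj.shape[1]):
        col = proj[:, i]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * max(np.abs(col).max(), 1e-300))
        if nz.size and col[nz[0]] < 0:
            proj[:, i] = -col
    return FLDProjection(matrix=proj, class_labels=tuple(int(c) for c in classes),
                         fitted_on="pre-shift training features")


def _mahalanobis(diff: np.ndarray, cov: np.ndarray, ridge: float) -> float:
    d = cov.shape[0]
    cov_r = cov + (ridge * np.trace(cov) / d) * np.eye(d)
    try:
        sol = scipy.linalg.solve(cov_r, diff, assume_a="pos")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise NumericalError(
            "averaged class covariance singular; raise the RCS ridge"
        ) from exc
    return float(np.sqrt(max(diff @ sol, 0.0)))


def compute_rcs(
    before: FeatureMatrix,
    after: FeatureMatrix,
    projection: FLDProjection,
    ridge: float = RCS_RIDGE,
) -> RCSResult:
    """Relative center shift between pre- and post-shift feature sets.

    Both sets are projected with the given FLD (fitted on pre-shift training
    features only), then per-motion centroids and covariances feed the RCS
    ratio.  Identical inputs give exactly zero.
    """
    labels_b = np.unique(before.labels)
    labels_a = np.unique(after.labels)
    if not np.array_equal(labels_b, labels_a):
        raise InvalidArgumentError(
            f"label sets differ: {labels_b} vs {labels_a}"
        )
    if len(labels_b) < 2:
        raise InvalidArgumentError("RCS needs at least 2 motions")
    xb = projection.transform(before.values)
    xa = projection.transform(after.values)
    n = len(labels_b)

    mu_b, mu_a, s_b, s_a = {}, {}, {}, {}
    for c in labels_b:
        vb = xb[before.labels == c]
        va = xa[after.labels == c]
        if vb.shape[0] < 2 or va.shape[0] < 2:
            raise DataError(f"motion {c} has fewer than 2 windows")
        mu_b[c], mu_a[c] = vb.mean(axis=0), va.mean(axis=0)
        s_b[c] = np.cov(vb, rowvar=False, ddof=1)
        s_a[c] = np.cov(va, rowvar=False, ddof=1)
        if xb.shape[1] == 1:  # np.cov squeezes 1-D
            s_b[c] = np.atleast_2d(s_b[c])
            s_a[c] = np.atleast_2d(s_a[c])

    shifts = np.array([
        _mahalanobis(mu_b[c] - mu_a[c], 0.5 * (s_b[c] + s_a[c]), ridge)
        for c in labels_b
    ])
    numerator = (n - 1) * shifts.sum()
    denominator = 0.0
    for i in labels_b:
        for j in labels_b:
            if i == j:
                continue
            denominator += _mahalanobis(
                mu_a[j] - mu_a[i], 0.5 * (s_a[j] + s_a[i]), ridge
            )
    if denominator == 0:
        raise DataError("post-shift class centroids coincide; RCS undefined")
    return RCSResult(
        value=float(numerator / denominator),
        numerator_mean=float(shifts.mean()),
        denominator_mean=float(denominator / (n * (n - 1))),
        per_motion_center_shift=shifts,
    )
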