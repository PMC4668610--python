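"""Common spatial patterns (CSP) by simultaneous diagonalization.

Two-class CSP seeks spatial filters ``w`` maximizing the variance ratio
``w' S_j w / w' S_k w`` between the class covariances ``S_j`` and ``S_k``.
It is solved here by whitening the composite covariance ``S_j + S_k`` and
rotating to diagonalize the whitened ``S_j``, which yields a filter matrix
``W`` (rows are filters) with

    W S_j W' = D_j,   W S_k W' = D_k,   D_j + D_k = I,

so the filter with the largest ``D_j`` eigenvalue has the smallest ``D_k``
eigenvalue and vice versa.  The two extreme filters are retained per class
pair; the log-variance of their output components is the CSP feature.

Multiclass problems are decomposed one-versus-one (one bank per unordered
class pair, ``N(N-1)/2`` banks) or one-versus-rest (one bank per class
against the average covariance of the others, ``N`` banks).

Spatial *patterns* — columns of ``W^{-1}`` — map each component back to a
source distribution over electrodes and are the natural visualization of
what a filter listens to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import scipy.linalg

from .exceptions import DataError, InvalidArgumentError, NumericalError
from .features import FeatureMatrix, WindowSet, log_variance

__all__ = [
    "ClassCovariance",
    "SpatialFilterBank",
    "MulticlassCSPModel",
    "class_covariance",
    "fit_two_class_csp",
    "fit_multiclass",
    "csp_transform",
    "spatial_patterns",
    "save_model",
    "load_model",
]

#: Default ridge fraction added to covariance diagonals
#: (``ridge * trace/c * I``); high-channel-count covariances estimated from
#: few windows are frequently ill-conditioned.
DEFAULT_RIDGE = 1e-6

REST_LABEL = -1  # pseudo-label for the pooled "rest" class in OvR banks


@dataclass
class ClassCovariance:
    """Average per-window channel covariance of one motion class."""

    motion: int
    sigma: np.ndarray
    n_windows: int

    @property
    def dim(self) -> int:
        return self.sigma.shape[0]


@dataclass
class SpatialFilterBank:
    """CSP filters for one class pair (or one class versus rest).

    ``W`` rows are spatial filters; ``d_j``/``d_k`` are the component
    variances of the two classes (summing to one element-wise); ``selected``
    holds the indices of the two retained filters (max ``d_j`` first);
    ``patterns`` columns are the corresponding source patterns (``W^{-1}``).
    """

    class_pair: tuple[int, int]
    W: np.ndarray
    d_j: np.ndarray
    d_k: np.ndarray
    selected: tuple[int, int]
    patterns: np.ndarray = field(repr=False)

    @property
    def dim(self) -> int:
        return self.W.shape[0]


@dataclass
class MulticlassCSPModel:
    """Bank collection realizing an OvO or OvR multiclass decomposition."""

    scheme: str  # "OvO" | "OvR"
    banks: list[SpatialFilterBank]
    n_classes: int
    class_labels: tuple[int, ...]
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return 2 * len(self.banks)

    @property
    def dim(self) -> int:
        return self.banks[0].dim

    @property
    def feature_kind(self) -> str:
        return f"CSP-{self.scheme}"


# ---------------------------------------------------------------------------
# covariance estimation


def class_covariance(
    windows: WindowSet, motion: int, ridge: float = 0.0
) -> ClassCovariance:
    """Average of per-window channel covariances for one motion.

    Each window is mean-centered per channel and normalized by ``1/(l-1)``;
    the class covariance is the mean over the motion's windows, optionally
    ridge-regularized with ``ridge * trace/c`` on the diagonal.
    """
    mask = windows.labels == motion
    if not np.any(mask):
        raise DataError(f"no windows for motion {motion}")
    x = windows.windows[mask]
    x = x - x.mean(axis=2, keepdims=True)
    l = x.shape[2]
    flat = x.transpose(1, 0, 2).reshape(x.shape[1], -1)
    sigma = (flat @ flat.T) / ((l - 1) * x.shape[0])
    sigma = 0.5 * (sigma + sigma.T)
    if ridge:
        sigma = sigma + (ridge * np.trace(sigma) / sigma.shape[0]) * np.eye(
            sigma.shape[0]
        )
    return ClassCovariance(motion=int(motion), sigma=sigma,
                           n_windows=int(mask.sum()))


def _pin_signs(W: np.ndarray) -> np.ndarray:
    """Make the first nonzero element of each filter row positive."""
    W = W.copy()
    for i, row in enumerate(W):
        nz = np.flatnonzero(np.abs(row) > 1e-12 * max(np.abs(row).max(), 1e-300))
        if nz.size and row[nz[0]] < 0:
            W[i] = -row
    return W


def fit_two_class_csp(
    sig_j: ClassCovariance, sig_k: ClassCovariance
) -> SpatialFilterBank:
    """Fit a two-class CSP filter bank by simultaneous diagonalization.

    The composite covariance ``S_j + S_k`` is whitened, the whitened ``S_j``
    is diagonalized, and the rotation is mapped back, producing ``W`` scaled
    so that ``W (S_j + S_k) W' = I`` (hence ``D_j + D_k = I`` by
    construction).  Filters are sorted by descending ``d_j``; the retained
    pair is the first (max class-j variance ratio) and last (max class-k)
    filter.  Eigenvector signs are pinned (first nonzero element positive)
    for reproducibility.

    Raises
    ------
    NumericalError
        If the composite covariance is not positive definite — typically
        cured by a larger covariance ridge.
    """
    if sig_j.sigma.shape != sig_k.sigma.shape:
        raise InvalidArgumentError(
            f"covariance dimensions differ: {sig_j.sigma.shape} vs "
            f"{sig_k.sigma.shape}"
        )
    comp = sig_j.sigma + sig_k.sigma
    lam, u = scipy.linalg.eigh(comp)
    if lam[0] <= lam[-1] * 1e-12 or lam[-1] <= 0:
        raise NumericalError(
            "composite covariance is singular; raise the covariance ridge"
        )
    whiten = (u / np.sqrt(lam)).T  # P: P comp P' = I
    s = whiten @ sig_j.sigma @ whiten.T
    s = 0.5 * (s + s.T)
    d, b = scipy.linalg.eigh(s)
    order = np.argsort(d)[::-1]
    d = np.clip(d[order], 0.0, 1.0)
    W = _pin_signs(b[:, order].T @ whiten)
    # patterns: W^{-1} = comp @ W' because W comp W' = I
    patterns = comp @ W.T
    c = W.shape[0]
    return SpatialFilterBank(
        class_pair=(sig_j.motion, sig_k.motion),
        W=W,
        d_j=d,
        d_k=1.0 - d,
        selected=(0, c - 1),
        patterns=patterns,
    )


def fit_multiclass(
    covs: "list[ClassCovariance]", scheme: str = "OvO"
) -> MulticlassCSPModel:
    """Fit OvO or OvR CSP banks from per-class covariances.

    OvO fits one bank per unordered class pair in lexicographic order; OvR
    fits, per class, a bank against the unweighted average of all other
    classes' covariances.  With two classes the two schemes pose the same
    discrimination problem.
    """
    if len(covs) < 2:
        raise InvalidArgumentError("need at least 2 classes")
    dims = {c.dim for c in covs}
    if len(dims) != 1:
        raise InvalidArgumentError(f"covariance dimensions differ: {dims}")
    covs = sorted(covs, key=lambda c: c.motion)
    labels = tuple(c.motion for c in covs)
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError("duplicate class labels")
    scheme = scheme.upper().replace("OVO", "OvO").replace("OVR", "OvR")
    if scheme not in ("OvO", "OvR"):
        raise InvalidArgumentError(f"scheme must be OvO or OvR, got {scheme!r}")

    banks: list[SpatialFilterBank] = []
    names: list[str] = []
    if scheme == "OvO":
        for a, b in combinations(range(len(covs)), 2):
            bank = fit_two_class_csp(covs[a], covs[b])
            banks.append(bank)
            j, k = bank.class_pair
            names += [f"csp_{j}v{k}_max{j}", f"csp_{j}v{k}_max{k}"]
    else:
        for a, cov in enumerate(covs):
            rest = np.mean([c.sigma for i, c in enumerate(covs) if i != a],
                           axis=0)
            rest_cov = ClassCovariance(
                motion=REST_LABEL, sigma=rest,
                n_windows=sum(c.n_windows for i, c in enumerate(covs) if i != a),
            )
            bank = fit_two_class_csp(cov, rest_cov)
            banks.append(bank)
            names += [f"csp_{cov.motion}vR_max{cov.motion}",
                      f"csp_{cov.motion}vR_maxrest"]
    return MulticlassCSPModel(
        scheme=scheme,
        banks=banks,
        n_classes=len(covs),
        class_labels=labels,
        feature_names=names,
    )


def _selected_filters(model: MulticlassCSPModel) -> np.ndarray:
    """Stack the selected filters of every bank into a (2M, c) matrix."""
    rows = []
    for bank in model.banks:
        rows.append(bank.W[bank.selected[0]])
        rows.append(bank.W[bank.selected[1]])
    return np.asarray(rows)


def csp_transform(model: MulticlassCSPModel, windows: WindowSet) -> FeatureMatrix:
    """Apply every bank's selected filters and take log-variance features.

    Per window the 2-per-bank components ``y = w' X`` are computed and their
    log-variances concatenated in canonical bank order, giving ``2M``
    features per window.  The window channel ordering must match the
    ordering the covariances were estimated on.
    """
    if windows.n_channels != model.dim:
        raise InvalidArgumentError(
            f"windows have {windows.n_channels} channels, model expects "
            f"{model.dim}"
        )
    filters = _selected_filters(model)  # (2M, c)
    n, _, l = windows.windows.shape
    flat = windows.windows.transpose(1, 0, 2).reshape(windows.n_channels, n * l)
    comps = (filters @ flat).reshape(-1, n, l).transpose(1, 0, 2)
    with np.errstate(divide="ignore"):
        values = log_variance(comps)
    return FeatureMatrix(
        values=values,
        labels=windows.labels.copy(),
        trial_ids=windows.trial_ids.copy(),
        feature_names=list(model.feature_names),
        feature_kind=model.feature_kind,
    )


def spatial_patterns(bank: SpatialFilterBank) -> np.ndarray:
    """Source patterns of the two selected filters, shape (c, 2).

    Columns of ``W^{-1}`` at the selected indices, each normalized to unit
    maximum absolute value for display.
    """
    cols = bank.patterns[:, list(bank.selected)]
    scale = np.abs(cols).max(axis=0)
    if np.any(scale == 0) or not np.all(np.isfinite(cols)):
        raise NumericalError("filter matrix is singular; patterns undefined")
    return cols / scale


# ---------------------------------------------------------------------------
# serialization


def save_model(path: "str | Path", model: MulticlassCSPModel,
               channels: "tuple[int, ...] | None" = None) -> Path:
    """Serialize a multiclass CSP model to HDF5 (+ embedded JSON manifest)."""
    import h5py  # local import keeps h5py optional at model-fit time
    import json

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["scheme"] = model.scheme
        f.attrs["n_classes"] = model.n_classes
        f.attrs["manifest"] = json.dumps({
            "scheme": model.scheme,
            "n_classes": model.n_classes,
            "class_labels": list(model.class_labels),
            "channels": list(channels) if channels is not None else None,
            "feature_names": model.feature_names,
        })
        for i, bank in enumerate(model.banks):
            g = f.create_group(f"bank_{i:03d}")
            g.create_dataset("W", data=bank.W)
            g.create_dataset("d_j", data=bank.d_j)
            g.create_dataset("d_k", data=bank.d_k)
            g.create_dataset("patterns", data=bank.patterns)
            g.attrs["selected"] = list(bank.selected)
            g.attrs["class_pair"] = list(bank.class_pair)
    return path


def load_model(path: "str | Path") -> MulticlassCSPModel:
    """Inverse of :func:`save_model`."""
    import h5py
    import json

    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        banks = []
        for key in sorted(k for k in f.keys() if k.startswith("bank_")):
            g = f[key]
            banks.append(SpatialFilterBank(
                class_pair=tuple(int(v) for v in g.attrs["class_pair"]),
                W=g["W"][()],
                d_j=g["d_j"][()],
                d_k=g["d_k"][()],
                selected=tuple(int(v) for v in g.attrs["selected"]),
                patterns=g["patterns"][()],
            ))
    return MulticlassCSPModel(
        scheme=manifest["scheme"],
        banks=banks,
        n_classes=int(manifest["n_classes"]),
        class_labels=tuple(manifest["class_labels"]),
        feature_names=list(manifest["feature_names"]),
    )
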