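"""Fit/transform feature pipelines shared by evaluation code.

Each pipeline turns a :class:`~emgshift.features.WindowSet` into a
:class:`~emgshift.features.FeatureMatrix` under a common contract:
``fit(windows)`` learns anything data-dependent (CSP filter banks, the
variogram lag set) from *training* windows only, and ``transform(windows)``
is then applicable to held-out or shifted windows.  TD/TDAR have no fitted
state beyond the channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import DEFAULT_RIDGE, MulticlassCSPModel, class_covariance, \
    csp_transform, fit_multiclass
from .exceptions import InvalidArgumentError
from .features import FeatureMatrix, WindowSet, _td_parts_batched, \
    ar_coefficients, td_feature_names, variogram_lags
from .grid import ElectrodeGrid

__all__ = ["FeatureSpec", "make_pipeline", "FEATURE_KINDS"]

FEATURE_KINDS = ("CSP-OvO", "CSP-OvR", "TD", "TDAR", "Variog")


@dataclass
class FeatureSpec:
    """Declarative description of one feature family and its parameters."""

    kind: str
    ar_order: int = 6
    zc_ssc_threshold: float = 0.0
    max_lag_mm: float = 80.0
    csp_ridge: float = DEFAULT_RIDGE

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise InvalidArgumentError(
                f"unknown feature kind {self.kind!r}; expected {FEATURE_KINDS}"
            )

    @property
    def default_classifier(self) -> str:
        """Variogram features pair with an SVM, everything else with LDA."""
        return "svm" if self.kind == "Variog" else "lda"


def make_pipeline(spec: FeatureSpec, grid: "ElectrodeGrid | None" = None):
    """Instantiate the pipeline for a feature spec (grid needed for Variog)."""
    if spec.kind in ("CSP-OvO", "CSP-OvR"):
        return CSPPipeline(scheme=spec.kind.split("-")[1], ridge=spec.csp_ridge)
    if spec.kind == "TD":
        return TDPipeline(threshold=spec.zc_ssc_threshold)
    if spec.kind == "TDAR":
        return TDARPipeline(order=spec.ar_order,
                            threshold=spec.zc_ssc_threshold)
    if grid is None:
        raise InvalidArgumentError("Variog pipeline needs the electrode grid")
    return VariogPipeline(grid=grid, max_lag_mm=spec.max_lag_mm)


@dataclass
class CSPPipeline:
    scheme: str = "OvO"
    ridge: float = DEFAULT_RIDGE
    model: "MulticlassCSPModel | None" = field(default=None, repr=False)

    def fit(self, windows: WindowSet) -> "CSPPipeline":
        covs = [class_covariance(windows, m, ridge=self.ridge)
                for m in np.unique(windows.labels)]
        self.model = fit_multiclass(covs, scheme=self.scheme)
        return self

    def transform(self, windows: WindowSet) -> FeatureMatrix:
        if self.model is None:
            raise InvalidArgumentError("pipeline not fitted")
        return csp_transform(self.model, windows)


@dataclass
class TDPipeline:
    threshold: float = 0.0

    def fit(self, windows: WindowSet) -> "TDPipeline":
        return self

    def transform(self, windows: WindowSet) -> FeatureMatrix:
        parts = _td_parts_batched(windows.windows, self.threshold)
        values = np.stack(parts, axis=-1).reshape(windows.n_windows, -1)
        return FeatureMatrix(
            values=values,
            labels=windows.labels.copy(),
            trial_ids=windows.trial_ids.copy(),
            feature_names=td_feature_names(windows.channels),
            feature_kind="TD",
        )


@dataclass
class TDARPipeline:
    order: int = 6
    threshold: float = 0.0

    def fit(self, windows: WindowSet) -> "TDARPipeline":
        return self

    def transform(self, windows: WindowSet) -> FeatureMatrix:
        parts = _td_parts_batched(windows.windows, self.threshold)
        td = np.stack(parts, axis=-1).reshape(windows.n_windows, -1)
        ar = ar_coefficients(windows.windows, self.order)
        values = np.concatenate([td, ar.reshape(windows.n_windows, -1)], axis=1)
        names = td_feature_names(windows.channels) + [
            f"ch{c}_ar{k + 1}" for c in windows.channels
            for k in range(self.order)
        ]
        return FeatureMatrix(
            values=values,
            labels=windows.labels.copy(),
            trial_ids=windows.trial_ids.copy(),
            feature_names=names,
            feature_kind="TDAR",
        )


@dataclass
class VariogPipeline:
    grid: ElectrodeGrid
    max_lag_mm: float = 80.0
    lags_: "np.ndarray | None" = field(default=None, repr=False)

    def fit(self, windows: WindowSet) -> "VariogPipeline":
        self.lags_, _ = variogram_lags(self.grid, windows.channels,
                                       self.max_lag_mm)
        return self

    def transform(self, windows: WindowSet) -> FeatureMatrix:
        lags, pairs = variogram_lags(self.grid, windows.channels,
                                     self.max_lag_mm)
        if self.lags_ is None:
            raise InvalidArgumentError("pipeline not fitted")
        if not np.array_equal(lags, self.lags_):
            raise InvalidArgumentError(
                "lag structure of these channels differs from the training "
                "partition; variogram features are not comparable"
            )
        x = windows.windows
        n, c, l = x.shape
        m = np.matmul(x, x.transpose(0, 2, 1)) / l
        values = np.empty((n, len(lags)))
        for idx, p in enumerate(pairs):
            i, j = p[:, 0], p[:, 1]
            values[:, idx] = np.mean(
                m[:, i, i] + m[:, j, j] - 2.0 * m[:, i, j], axis=1
            ) / 2.0
        return FeatureMatrix(
            values=values,
            labels=windows.labels.copy(),
            trial_ids=windows.trial_ids.copy(),
            feature_names=[f"variog_{lag:.1f}mm" for lag in lags],
            feature_kind="Variog",
        )
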