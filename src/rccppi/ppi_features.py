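"""Pair features for PPI classification.

Two per-protein RCC vectors are combined into one instance either by
elementwise addition (26 features) or by concatenation (52 features).  A
dataset of such instances can then be kept raw, min-max normalised to [0, 1]
or standardised to zero mean / unit variance — always fitting the scaler on
the training partition and applying the frozen statistics to test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .rcc_core import RCCVector

COMBINE_MODES = ("sum", "concat")
SCALINGS = ("raw", "normalize", "standardize")

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class PPIInstance:
    """One labelled protein pair in feature space."""

    features: tuple[float, ...]
    label: str
    pair_ids: tuple[str, str]
    mode: str
    scaling: str = "raw"

    def __post_init__(self) -> None:
        expected = {"sum": 26, "concat": 52}[self.mode]
        if len(self.features) != expected:
            raise ValueError(
                f"{self.mode} instance must have {expected} features, got {len(self.features)}"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


def combine(rcc_a: RCCVector, rcc_b: RCCVector, mode: str) -> np.ndarray:
    """Combine two RCC vectors that share cutoff and atom mode.

    ``sum`` adds elementwise (order-independent); ``concat`` appends b after
    a in the order given (order-sensitive by design — the input pair order is
    preserved, not canonicalised).
    """
    if mode not in COMBINE_MODES:
        raise ValueError(f"mode must be one of {COMBINE_MODES}, got {mode!r}")
    if (rcc_a.cutoff, rcc_a.atom_mode) != (rcc_b.cutoff, rcc_b.atom_mode):
        raise ValueError(
            "incompatible representations: cutoff/atom_mode differ "
            f"({rcc_a.cutoff}, {rcc_a.atom_mode}) vs ({rcc_b.cutoff}, {rcc_b.atom_mode})"
        )
    a, b = rcc_a.as_array(), rcc_b.as_array()
    return a + b if mode == "sum" else np.concatenate([a, b])


@dataclass
class ScalerState:
    """Frozen per-feature scaling statistics learned from a training table."""

    method: str
    _impl: object | None = None
    n_features: int | None = None


def fit_scaler(train_features: np.ndarray, method: str) -> ScalerState:
    """Learn scaling statistics on the training partition.

    normalize: per-feature min-max to [0, 1]; a zero-range feature maps to 0.
    standardize: per-feature (x - mean) / sd; a zero-variance feature maps
    to 0.  raw: identity.
    """
    if method not in SCALINGS:
        raise ValueError(f"method must be one of {SCALINGS}, got {method!r}")
    train_features = np.asarray(train_features, dtype=float)
    if train_features.ndim != 2 or train_features.shape[0] == 0:
        raise ValueError("training table must be a non-empty 2-D array")
    if method == "raw":
        return ScalerState(method="raw", n_features=train_features.shape[1])
    impl = MinMaxScaler() if method == "normalize" else StandardScaler()
    impl.fit(train_features)
    if method == "normalize":
        # zero-range features: force output 0 rather than sklearn's min_ shift
        zero = (impl.data_max_ - impl.data_min_) == 0
        impl.min_[zero] = 0.0
        impl.scale_[zero] = 0.0
    return ScalerState(method=method, _impl=impl, n_features=train_features.shape[1])


def apply_scaler(state: ScalerState, features: np.ndarray) -> np.ndarray:
    """Apply frozen statistics; never refits on the data it transforms."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if state.n_features is None:
        raise ValueError("scaler not fitted")
    if features.shape[1] != state.n_features:
        raise ValueError(
            f"feature count {features.shape[1]} does not match fitted {state.n_features}"
        )
    if state.method == "raw":
        return features.copy()
    if state.method == "normalize":
        impl = state._impl
        return features * impl.scale_ + impl.min_
    return state._impl.transform(features)
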