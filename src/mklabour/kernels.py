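"""Kernel construction for heterogeneous clinical features.

Continuous/ordinal features get Gaussian kernels with median-heuristic
bandwidths; categorical features get indicator-match kernels.  One kernel
per feature is the default, which is what lets the multiple-kernel learner
weigh features against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import NumericalError, ValidationError
from .pipeline import FeatureSchema

GAUSSIAN, INDICATOR = "gaussian", "indicator"


@dataclass(frozen=True)
class KernelSpec:
    """One kernel over a feature subset."""

    features: tuple
    family: str  # gaussian | indicator
    bandwidth: float | None = None  # resolved at build time if None (median heuristic)

    def __post_init__(self):
        if self.family not in (GAUSSIAN, INDICATOR):
            raise ValidationError(f"unknown kernel family {self.family!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValidationError(f"kernel over {self.features}: bandwidth must be > 0")


def default_specs(schema: FeatureSchema) -> list[KernelSpec]:
    """One kernel per schema feature, family chosen by feature kind."""
    specs = []
    for s in schema:
        family = INDICATOR if s.kind == "categorical" else GAUSSIAN
        specs.append(KernelSpec(features=(s.name,), family=family))
    return specs


def median_bandwidth(x: np.ndarray) -> float:
    """Median of the positive pairwise Euclidean distances (median heuristic)."""
    d = cdist(x, x)
    pos = d[np.triu_indices_from(d, k=1)]
    pos = pos[pos > 0]
    if pos.size == 0:
        return 1.0
    return float(np.median(pos))


def _columns(X: np.ndarray, feature_names: Sequence[str], spec: KernelSpec) -> np.ndarray:
    idx = []
    names = list(feature_names)
    for f in spec.features:
        if f not in names:
            raise ValidationError(f"kernel feature '{f}' not in feature matrix")
        idx.append(names.index(f))
    return np.asarray(X, dtype=float)[:, idx]


def evaluate_kernel(
    spec: KernelSpec, X: np.ndarray, feature_names: Sequence[str], Y: np.ndarray | None = None
) -> np.ndarray:
    """Kernel matrix K(X, Y) (Y defaults to X) for one spec.

    The same code path computes training Grams and out-of-sample columns, so
    a training sample projected out of sample reproduces its in-sample
    coordinates to machine precision.
    """
    a = _columns(X, feature_names, spec)
    b = a if Y is None else _columns(Y, feature_names, spec)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("kernel input contains missing entries; run propagation/imputation first")
    if spec.family == GAUSSIAN:
        if spec.bandwidth is None:
            raise ValidationError("gaussian kernel bandwidth unresolved; call build_kernels first")
        sq = cdist(a, b, metric="sqeuclidean")
        return np.exp(-sq / (2.0 * spec.bandwidth**2))
    # indicator-match: 1 iff all features in the subset agree
    eq = np.ones((a.shape[0], b.shape[0]), dtype=float)
    for j in range(a.shape[1]):
        eq *= (a[:, j][:, None] == b[:, j][None, :]).astype(float)
    return eq


def build_kernels(
    X: np.ndarray, feature_names: Sequence[str], specs: Sequence[KernelSpec],
    psd_tol: float = 1e-8, check_psd: bool = False,
) -> tuple[list[np.ndarray], list[KernelSpec]]:
    """Training Gram matrices, with median-heuristic bandwidths resolved.

    Returns ``(grams, resolved_specs)``.  Gaussian kernels have unit
    diagonal by construction; with ``check_psd`` the smallest eigenvalue of
    every Gram is verified to be ≥ -psd_tol.
    """
    X = np.asarray(X, dtype=float)
    covered = set()
    for s in specs:
        covered.update(s.features)
    missing = [f for f in feature_names if f not in covered]
    if missing:
        raise ValidationError(f"features not covered by any kernel spec: {missing}")

    grams, resolved = [], []
    for spec in specs:
        if spec.family == GAUSSIAN and spec.bandwidth is None:
            bw = median_bandwidth(_columns(X, feature_names, spec))
            spec = replace(spec, bandwidth=bw)
        K = evaluate_kernel(spec, X, feature_names)
        K = 0.5 * (K + K.T)
        if check_psd:
            w = np.linalg.eigvalsh(K)
            if w[0] < -psd_tol:
                raise NumericalError(
                    f"kernel over {spec.features} is not PSD (min eigenvalue {w[0]:.3e})"
                )
        grams.append(K)
        resolved.append(spec)
    return grams, resolved
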