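"""Second-order co-occurrence fusion of dual multi-layer embeddings.

The 2K = 10 layer vectors (K = 5 last layers from each of two frozen
backends, primary layers first, layers in ascending order within a backend)
are each compressed by its own affine map followed by ReLU, stacked into
X in R^{10 x 1024}, and combined through the Gram matrix C = X X^T, which
captures second-order interactions between layers and between models.  C is
flattened row-major to c_flat (100 entries), squashed by a trainable scaled
sigmoid p = 2*sigmoid(gamma*c_flat) - 1 so every entry is bounded in (-1, 1),
and concatenated with the primary backend's mean-pooled final-layer
embedding vQ.  With D = 4096 the fused feature has exactly 100 + 4096 = 4196
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .backends import LayerStack
from .errors import ShapeError

__all__ = [
    "FusionParams",
    "FusedVector",
    "N_FUSION_VECTORS",
    "PROJ_DIM",
    "init_fusion_params",
    "project",
    "cooccurrence",
    "scale_flatten",
    "fuse",
    "fused_dim",
]

N_FUSION_VECTORS = 10   # 2 backends x K=5 layers
PROJ_DIM = 1024         # per-vector compressed dimension


@dataclass
class FusionParams:
    """The 10 affine projections (one per layer vector) plus the scaling gamma.

    weights: (10, proj_dim, D); biases: (10, proj_dim); gamma: scalar,
    trainable and unconstrained in sign (initialized to 1).
    """

    weights: np.ndarray
    biases: np.ndarray
    gamma: float = 1.0

    def __post_init__(self):
        if self.weights.ndim != 3 or self.weights.shape[0] != N_FUSION_VECTORS:
            raise ShapeError(
                f"weights must be ({N_FUSION_VECTORS}, proj_dim, D), got {self.weights.shape}"
            )
        if self.biases.shape != self.weights.shape[:2]:
            raise ShapeError(
                f"biases shape {self.biases.shape} incompatible with weights {self.weights.shape}"
            )
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.biases))
                and np.isfinite(self.gamma)):
            raise ShapeError("fusion parameters must be finite")

    @property
    def proj_dim(self) -> int:
        return self.weights.shape[1]

    @property
    def d_model(self) -> int:
        return self.weights.shape[2]


def init_fusion_params(d_model: int, proj_dim: int = PROJ_DIM, seed: int = 0) -> FusionParams:
    """He-initialized projections, zero biases, gamma = 1."""
    rng = np.random.default_rng(seed)
    scale = np.sqrt(2.0 / d_model)
    w = rng.standard_normal((N_FUSION_VECTORS, proj_dim, d_model)) * scale
    b = np.zeros((N_FUSION_VECTORS, proj_dim))
    return FusionParams(weights=w, biases=b, gamma=1.0)


def project(v: np.ndarray, j: int, params: FusionParams) -> np.ndarray:
    """u_j = ReLU(W_j v + b_j) for vector index j in 1..10 (1-based)."""
    if not 1 <= j <= N_FUSION_VECTORS:
        raise ShapeError(f"projection index must be in 1..{N_FUSION_VECTORS}, got {j}")
    v = np.asarray(v, dtype=float)
    if v.shape != (params.d_model,):
        raise ShapeError(f"expected vector of length {params.d_model}, got shape {v.shape}")
    return np.maximum(params.weights[j - 1] @ v + params.biases[j - 1], 0.0)


def cooccurrence(U: np.ndarray) -> np.ndarray:
    """Cross-layer co-occurrence (Gram) matrix C = U U^T; symmetric PSD."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[0] != N_FUSION_VECTORS:
        raise ShapeError(f"expected ({N_FUSION_VECTORS}, proj_dim) matrix, got {U.shape}")
    return U @ U.T


def scale_flatten(C: np.ndarray, gamma: float) -> np.ndarray:
    """Row-major flatten and bounded squashing: p = 2*sigmoid(gamma*c_flat) - 1."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ShapeError(f"co-occurrence matrix must be 2-D, got shape {C.shape}")
    c_flat = C.ravel(order="C")
    # |arg| capped below the float64 saturation point of the sigmoid so the
    # output honors the strict (-1, 1) bound even for extreme co-occurrences
    arg = np.clip(gamma * c_flat, -36.0, 36.0)
    return 2.0 * expit(arg) - 1.0


def fused_dim(d_model: int) -> int:
    """Length of the fused feature: 10^2 co-occurrence entries + D."""
    return N_FUSION_VECTORS ** 2 + d_model


@dataclass(frozen=True)
class FusedVector:
    """The downstream feature f = Concat(p, vQ); first 100 entries in (-1, 1)."""

    values: np.ndarray

    def __post_init__(self):
        p = self.values[: N_FUSION_VECTORS ** 2]
        if np.any(np.abs(p) >= 1.0):
            raise ShapeError("co-occurrence head entries must lie strictly inside (-1, 1)")


def fuse(stacks: Sequence[LayerStack], vQ: np.ndarray, params: FusionParams) -> FusedVector:
    """Fuse the two K-layer stacks and the mean-pooled primary embedding.

    ``stacks`` is (primary, secondary); rows within each stack are layers in
    ascending order.  The 2K rows are projected individually, combined via
    the Gram matrix, squashed, and concatenated with ``vQ`` unchanged.
    """
    if len(stacks) != 2:
        raise ShapeError(f"expected stacks from exactly 2 backends, got {len(stacks)}")
    V = np.vstack([s.matrix for s in stacks])
    if V.shape != (N_FUSION_VECTORS, params.d_model):
        raise ShapeError(
            f"stacked layer vectors have shape {V.shape}, expected "
            f"({N_FUSION_VECTORS}, {params.d_model})"
        )
    vQ = np.asarray(vQ, dtype=float)
    if vQ.shape != (params.d_model,):
        raise ShapeError(f"vQ must have length {params.d_model}, got shape {vQ.shape}")
    U = np.stack([project(V[j], j + 1, params) for j in range(N_FUSION_VECTORS)])
    p = scale_flatten(cooccurrence(U), params.gamma)
    return FusedVector(values=np.concatenate([p, vQ]))
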