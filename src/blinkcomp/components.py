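"""Exact eigen-analysis objects of a blinking-emitter image stack.

For a stack ``I = G S`` of M independent, statistically identical
emitters (per-frame photon counts with mean mu and standard deviation
sigma, K frames) the Gram matrix ``J = I I^T`` converges to

    J = K G O G^T,      O = sigma^2 I_M + mu^2 L_M,

with L the all-ones matrix.  Expanding O separates temporal statistics
from emitter geometry:

    J = c1 C1 + c2 (C2 - C3)

    c1 = K M (sigma^2 + M mu^2)          c2 = K (M - 1) sigma^2
    C1 = (1/M^2) Gt Gt^T                 (Gt = sum of columns of G)
    C2 = (1/M)   sum_m  g_m g_m^T
    C3 = (1/(M(M-1))) sum_{m' != m} g_m' g_m^T

C1 is the rank-1 outer product of the mean image (contrast only); C2
carries cross-pixel auto-emitter terms (squared-PSF sharpening); C3
carries cross-pixel cross-emitter terms.  The three are linked by the
exact identity ``M C1 = C2 + (M-1) C3``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import SystemMatrix
from .stacks import ImageStack

__all__ = [
    "OMatrix",
    "ComponentSet",
    "o_matrix",
    "compute_components",
    "coefficients",
    "component_set",
    "reconstruct_J",
    "empirical_J",
    "eq_identity_residual",
    "magnitude",
    "numerical_rank",
    "component_report",
]

#: Relative eigenvalue threshold below which a mode counts as numerically zero.
RANK_RTOL = 1e-10


@dataclass(frozen=True)
class OMatrix:
    """Per-frame emitter-emitter second-moment matrix (M x M circulant)."""

    M: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return (self.sigma ** 2 * np.eye(self.M)
                + self.mu ** 2 * np.ones((self.M, self.M)))

    def eigenvalues(self) -> np.ndarray:
        """Closed form: sigma^2 + M mu^2 (once), sigma^2 (M-1 times)."""
        out = np.full(self.M, self.sigma ** 2)
        out[0] += self.M * self.mu ** 2
        return out

    def leading_eigenvector(self) -> np.ndarray:
        return np.full(self.M, 1.0 / np.sqrt(self.M))


def o_matrix(M: int, mu: float, sigma: float) -> OMatrix:
    return OMatrix(int(M), float(mu), float(sigma))


def _as_G(system) -> np.ndarray:
    return system.G if isinstance(system, SystemMatrix) else np.asarray(system, float)


def compute_components(system: SystemMatrix | np.ndarray):
    """Return (C1, C2, C3); C3 is None for a single emitter.

    C3's double sum runs over both index orders, so it is symmetric as a
    matrix.  All three are computed from closed forms: the cross-emitter
    sum equals ``Gt Gt^T - G G^T``.
    """
    G = _as_G(system)
    M = G.shape[1]
    Gt = G.sum(axis=1)
    C1 = np.outer(Gt, Gt) / M ** 2
    C2 = (G @ G.T) / M
    if M == 1:
        return C1, C2, None
    C3 = (np.outer(Gt, Gt) - G @ G.T) / (M * (M - 1))
    return C1, C2, C3


def coefficients(K: int, M: int, mu: float, sigma: float):
    """Blinking-statistics weights (c1, c2); c2/c1 < 1 always."""
    if K < 1 or M < 1:
        raise ValueError("K and M must be >= 1")
    c1 = K * M * (sigma ** 2 + M * mu ** 2)
    c2 = K * (M - 1) * sigma ** 2
    return float(c1), float(c2)


@dataclass(frozen=True)
class ComponentSet:
    """Component matrices with their blinking-statistics weights."""

    C1: np.ndarray
    C2: np.ndarray
    C3: np.ndarray | None
    c1: float
    c2: float
    M: int
    K: int
    mu: float
    sigma: float


def component_set(system: SystemMatrix | np.ndarray, K: int, mu: float,
                  sigma: float) -> ComponentSet:
    G = _as_G(system)
    M = G.shape[1]
    C1, C2, C3 = compute_components(G)
    c1, c2 = coefficients(K, M, mu, sigma)
    return ComponentSet(C1, C2, C3, c1, c2, M, int(K), float(mu), float(sigma))


def reconstruct_J(components: ComponentSet) -> np.ndarray:
    """J = c1 C1 + c2 (C2 - C3); equals K G O G^T exactly."""
    if components.C3 is None:
        if components.M == 1:
            # c2 = 0: the C3 term is absent for a single emitter
            return components.c1 * components.C1
        raise ValueError("C3 is missing for M >= 2")
    return (components.c1 * components.C1
            + components.c2 * (components.C2 - components.C3))


def empirical_J(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Gram matrix I I^T of a measured or simulated stack."""
    I = stack.I if isinstance(stack, ImageStack) else np.asarray(stack, float)
    return I @ I.T


def eq_identity_residual(C1: np.ndarray, C2: np.ndarray, C3: np.ndarray,
                         M: int) -> float:
    """Max-abs residual of the identity M C1 = C2 + (M-1) C3."""
    return float(np.abs(M * C1 - C2 - (M - 1) * C3).max())


def magnitude(C: np.ndarray) -> float:
    """Maximum entry of a component matrix (its 'magnitude')."""
    return float(np.asarray(C).max())


def numerical_rank(C: np.ndarray, rtol: float = RANK_RTOL) -> int:
    """Count of eigenvalues above ``rtol`` times the largest magnitude."""
    w = np.abs(np.linalg.eigvalsh(np.asarray(C, float)))
    return int(np.sum(w > rtol * w.max()))


def component_report(components: ComponentSet) -> dict:
    """JSON-serialisable summary: weights, magnitudes, ranks, identity residual."""
    cs = components
    rep = {
        "M": cs.M, "K": cs.K, "mu": cs.mu, "sigma": cs.sigma,
        "c1": cs.c1, "c2": cs.c2, "c2_over_c1": cs.c2 / cs.c1,
        "magnitude_C1": magnitude(cs.C1),
        "magnitude_C2": magnitude(cs.C2),
        "rank_C1": numerical_rank(cs.C1),
        "rank_C2": numerical_rank(cs.C2),
        "rank_rtol": RANK_RTOL,
    }
    if cs.C3 is not None:
        rep.update({
            "magnitude_C3": magnitude(cs.C3),
            "magnitude_C2_minus_C3": magnitude(cs.C2 - cs.C3),
            "identity_residual": eq_identity_residual(cs.C1, cs.C2, cs.C3, cs.M),
        })
    return rep
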