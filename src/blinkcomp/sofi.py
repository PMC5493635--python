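"""Second-order SOFI (temporal auto-cumulant) of an image stack.

The second-order SOFI image at time lag kappa is the per-pixel lagged
auto-covariance

    F(n, kappa) = (1/K) sum_k (I(n, k+kappa) - <I(n)>) (I(n, k) - <I(n)>)

with the temporal mean removed per pixel; at kappa = 0 this is the
per-pixel sample variance, whose effective PSF is the square of the
optical PSF.  For a stack I = G S of independent emitters the exact
per-pixel variance is ``sigma**2 * sum_m G(n, m)**2``; the component
check below reports this definitional expectation alongside the
weighted-component expression ``c2 * diag(C1 + C2 - C3) / K`` so the two
can be compared against the empirical image on equal terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .components import component_set, reconstruct_J
from .optics import SystemMatrix
from .stacks import ImageStack

__all__ = ["SOFIImage", "sofi2", "sofi_component_check"]


@dataclass(frozen=True)
class SOFIImage:
    """Per-pixel lagged auto-covariance image."""

    F: np.ndarray
    kappa: int
    normalization: str = "K"


def sofi2(stack: ImageStack | np.ndarray, kappa: int = 0,
          normalization: str = "K") -> SOFIImage:
    """Second-order SOFI image at frame lag ``kappa``.

    The sum runs over the K - kappa valid frame pairs and is divided by
    K (``normalization="K"``, as printed) or by the number of pairs
    (``normalization="pairs"``).
    """
    I = stack.I if isinstance(stack, ImageStack) else np.asarray(stack, float)
    K = I.shape[1]
    if not 0 <= kappa < K - 1:
        raise ValueError("require 0 <= kappa < K - 1")
    if normalization not in ("K", "pairs"):
        raise ValueError("normalization must be 'K' or 'pairs'")
    D = I - I.mean(axis=1, keepdims=True)
    prod = D[:, kappa:] * D[:, :K - kappa]
    denom = K if normalization == "K" else (K - kappa)
    return SOFIImage(prod.sum(axis=1) / denom, int(kappa), normalization)


def sofi_component_check(system: SystemMatrix | np.ndarray, mu: float,
                         sigma: float, stack: ImageStack | np.ndarray) -> dict:
    """Compare the empirical SOFI image against two model expressions.

    Returns a report with
      ``empirical``      diag of sofi2(stack, 0),
      ``weighted``       c2 * diag(C1 + C2 - C3) / K,
      ``definitional``   sigma**2 * sum_m G(n, m)**2,
    and the pairwise relative L2 distances.  No verdict is drawn; the
    caller can see which expression tracks the simulation.
    """
    G = system.G if isinstance(system, SystemMatrix) else np.asarray(system, float)
    I = stack.I if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if I.shape[0] != G.shape[0]:
        raise ValueError("stack and system matrix have different pixel counts")
    K = I.shape[1]
    cs = component_set(G, K, mu, sigma)
    empirical = sofi2(I, 0).F
    definitional = sigma ** 2 * (G ** 2).sum(axis=1)
    if cs.C3 is not None:
        weighted = cs.c2 * np.diag(cs.C1 + cs.C2 - cs.C3) / K
    else:
        weighted = np.zeros(G.shape[0])

    def rel_l2(a, b):
        denom = np.linalg.norm(b)
        return float(np.linalg.norm(a - b) / denom) if denom > 0 else float("nan")

    return {
        "empirical": empirical,
        "weighted": weighted,
        "definitional": definitional,
        "rel_l2_empirical_vs_definitional": rel_l2(empirical, definitional),
        "rel_l2_empirical_vs_weighted": rel_l2(empirical, weighted),
        "rel_l2_weighted_vs_definitional": rel_l2(weighted, definitional),
        "K": K, "M": cs.M, "mu": mu, "sigma": sigma,
    }
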