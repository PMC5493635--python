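"""Single-window MUSIC engine on stack Gram or component matrices.

The eigenvectors of the Gram matrix J (or of a single component matrix)
are "eigenimages"; sorting by singular value ``s_j = sqrt(|eigenvalue|)``
and thresholding at ``s0`` splits them into a signal subspace S (s_j >=
s0) and a null subspace N.  For a test position r' with hypothetical
emitter image ``g(r')``, the pseudo-spectrum

    f(r') = (d_PS(r') / d_PN(r'))**alpha

peaks where g(r') lies in S and is orthogonal to N.  d_PS and d_PN are
the norms of the orthogonal projections of g(r') onto S and N, so
``d_PS**2 + d_PN**2 = ||g(r')||**2`` holds identically.

For noiseless dense scenes the small eigenvalues of C2 = G G^T / M fall
below the floating-point floor (the conditioning of the Gram matrix is
the square of the factor's); :func:`subspaces_from_factor` builds the
same subspace split from the SVD of the emitter-image factor instead,
which resolves every direction of the column space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .optics import PixelGrid, PSFModel, SystemMatrix, emitter_image

__all__ = [
    "Subspaces",
    "Pseudospectrum",
    "eigenimages",
    "subspaces_from_factor",
    "split_subspaces",
    "pseudospectrum",
    "count_peaks",
]

#: Floor applied to d_PN to keep f finite at exact emitter positions.
DPN_FLOOR = 1e-12


@dataclass(frozen=True)
class Subspaces:
    """Orthonormal eigenimage basis with an optional signal/null split.

    ``singular_values`` are sorted descending; ``U`` holds the matching
    orthonormal eigenimages as columns (a complete basis of pixel
    space).  ``n_signal`` is None before thresholding.
    """

    singular_values: np.ndarray
    U: np.ndarray
    n_signal: int | None = None
    s0: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def signal(self) -> np.ndarray:
        if self.n_signal is None:
            raise ValueError("subspaces not split yet")
        return self.U[:, :self.n_signal]

    @property
    def null(self) -> np.ndarray:
        if self.n_signal is None:
            raise ValueError("subspaces not split yet")
        return self.U[:, self.n_signal:]


@dataclass(frozen=True)
class Pseudospectrum:
    """MUSIC map over a grid of test positions."""

    positions: np.ndarray
    f: np.ndarray
    dps: np.ndarray
    dpn: np.ndarray
    alpha: float
    floored: np.ndarray  # True where d_PN hit the numerical floor


def eigenimages(A: np.ndarray) -> Subspaces:
    """Eigen-decomposition of a symmetric matrix, sorted by |eigenvalue|.

    Singular values are the square roots of the eigenvalue magnitudes
    (component matrices such as C3 are symmetric but indefinite).  A
    non-symmetric input is symmetrised with a warning.
    """
    A = np.asarray(A, float)
    if not np.allclose(A, A.T, rtol=1e-8, atol=1e-12 * max(1.0, np.abs(A).max())):
        warnings.warn("input is not symmetric; using (A + A.T)/2", stacklevel=2)
    A = 0.5 * (A + A.T)
    w, U = np.linalg.eigh(A)
    order = np.argsort(-np.abs(w))
    w, U = w[order], U[:, order]
    return Subspaces(np.sqrt(np.abs(w)), U,
                     meta={"eigenvalues": w, "source": "eigh"})


def subspaces_from_factor(system: SystemMatrix | np.ndarray) -> Subspaces:
    """Eigenimage basis from the SVD of the emitter-image factor G.

    The left singular vectors of G are the eigenvectors of G G^T (hence
    of C2 up to scaling, and they span the column space shared by C2 and
    C3); working on the factor keeps directions whose Gram eigenvalues
    would underflow.  Reported singular values are those of the factor.
    """
    G = system.G if isinstance(system, SystemMatrix) else np.asarray(system, float)
    U, s, _ = np.linalg.svd(G, full_matrices=True)
    sv = np.zeros(U.shape[1])
    sv[:s.size] = s
    return Subspaces(sv, U, meta={"source": "factor_svd", "factor_rank": s.size})


def split_subspaces(sub: Subspaces, policy: str = "eigengap",
                    s0: float | None = None,
                    rank: int | None = None) -> Subspaces:
    """Assign eigenimages to the signal/null subspaces.

    policy="fixed"    : S = {j : s_j >= s0}; the leading eigenimage is
                        kept in S even if s0 exceeds s_1.
    policy="rank"     : |S| = rank.
    policy="eigengap" : split at the largest ratio s_j / s_{j+1} among
                        the positive singular values.
    """
    s = sub.singular_values
    if s.size < 2:
        raise ValueError("need at least two eigenpairs to split")
    if policy == "fixed":
        if s0 is None:
            raise ValueError("fixed policy requires s0")
        n_sig = int(np.sum(s >= s0))
        n_sig = max(n_sig, 1)  # leading eigenimage always in S
    elif policy == "rank":
        if rank is None:
            raise ValueError("rank policy requires rank")
        n_sig = int(np.clip(rank, 1, s.size - 1))
        s0 = float(0.5 * (s[n_sig - 1] + s[n_sig])) if n_sig < s.size else None
    elif policy == "eigengap":
        pos = s > 0
        last = int(np.sum(pos)) - 1
        if last < 1:
            n_sig = 1
        else:
            with np.errstate(divide="ignore"):
                ratios = s[:last] / s[1:last + 1]
            n_sig = int(np.argmax(ratios)) + 1
        s0 = float(0.5 * (s[n_sig - 1] + s[min(n_sig, s.size - 1)]))
    else:
        raise ValueError("policy must be 'fixed', 'rank' or 'eigengap'")
    if n_sig >= s.size:
        n_sig = s.size - 1  # keep the null space non-empty when possible
    return Subspaces(s, sub.U, n_sig, s0, dict(sub.meta, policy=policy))


def _test_images(positions: np.ndarray, grid: PixelGrid, psf: PSFModel,
                 subsamples: int) -> np.ndarray:
    """N x T matrix of hypothetical emitter images (same model as G)."""
    cols = [emitter_image(p, grid, psf, subsamples) for p in positions]
    return np.stack(cols, axis=1)


def pseudospectrum(sub: Subspaces, psf: PSFModel, grid: PixelGrid,
                   test_positions, alpha: float = 1.0, subsamples: int = 21,
                   use_null: bool = True) -> Pseudospectrum:
    """Evaluate f(r') = (d_PS/d_PN)**alpha over a grid of test points.

    Projections are taken against the explicit signal and null bases
    (computing d_PN by Pythagoras would cancel catastrophically near
    emitter positions).  ``use_null=False`` drops the denominator and
    returns the SCORE-like signal projection map d_PS**alpha.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    test_positions = np.asarray(test_positions, float)
    lo, hi = grid.span
    if test_positions.min() < lo or test_positions.max() > hi:
        raise ValueError("test grid extends beyond the imaged field")
    if use_null and (sub.n_signal is None or sub.null.shape[1] == 0):
        raise ValueError("null subspace is empty; pseudo-spectrum undefined")
    Gt = _test_images(test_positions, grid, psf, subsamples)
    dps = np.sqrt(((sub.signal.T @ Gt) ** 2).sum(axis=0))
    if use_null:
        dpn = np.sqrt(((sub.null.T @ Gt) ** 2).sum(axis=0))
    else:
        dpn = np.zeros_like(dps)
    floored = dpn < DPN_FLOOR
    if use_null:
        f = (dps / np.maximum(dpn, DPN_FLOOR)) ** alpha
    else:
        f = dps ** alpha
    return Pseudospectrum(test_positions, f, dps, dpn, float(alpha), floored)


def count_peaks(ps: Pseudospectrum, min_rel_height: float = 0.05,
                window: tuple | None = None):
    """Count strict local maxima of f above a relative height.

    ``window=(lo, hi)`` restricts the count to the emitter-containing
    region (noise can produce spurious peaks near the field boundary).
    Returns (count, peak positions).
    """
    if not np.all(np.isfinite(ps.f)):
        raise ValueError("pseudo-spectrum contains non-finite values")
    mask = np.ones(ps.positions.size, dtype=bool)
    if window is not None:
        mask = (ps.positions >= window[0]) & (ps.positions <= window[1])
    f = ps.f[mask]
    pos = ps.positions[mask]
    if f.size < 3:
        return 0, np.array([])
    idx, _ = find_peaks(f, height=min_rel_height * f.max())
    return int(idx.size), pos[idx]
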