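"""Spectral library construction and constrained linear unmixing.

Multispectral fluorescence microscopy records, at every pixel, an intensity
per spectral band. Each fluorophore (and the tissue autofluorescence)
contributes a characteristic emission signature, so the pixel spectrum is a
nonnegative linear combination of the library signatures. Unmixing inverts
this: given the library matrix ``S`` (bands x fluorophores) and a pixel
spectrum ``x``, find abundances ``a >= 0`` minimizing ``||S a - x||_2``.

Signatures are estimated from single-plex library stains (one fluorophore
per slide) plus an unstained slide for autofluorescence. By convention each
library column is normalized to unit sum, so abundances carry the intensity
scale of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

__all__ = [
    "SpectralLibrary",
    "estimate_signature",
    "unmix_pixels",
    "nnls_batched",
]


@dataclass(frozen=True)
class SpectralLibrary:
    """Per-fluorophore emission signatures over spectral bands.

    Parameters
    ----------
    names : list of str
        Fluorophore names, one per column. Should include an
        autofluorescence component (conventionally named ``"AF"``).
    signatures : ndarray, shape (n_bands, n_fluorophores)
        Nonnegative signature matrix; columns are normalized to unit sum.
    """

    names: tuple[str, ...]
    signatures: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.signatures, dtype=float)
        if S.ndim != 2 or S.shape[1] != len(self.names):
            raise ValueError(
                f"signature matrix shape {S.shape} does not match "
                f"{len(self.names)} fluorophore names"
            )
        if np.any(S < 0) or not np.all(np.isfinite(S)):
            raise ValueError("signatures must be finite and nonnegative")
        colsums = S.sum(axis=0)
        if np.any(colsums <= 0):
            bad = [n for n, c in zip(self.names, colsums) if c <= 0]
            raise ValueError(f"all-zero signature column(s): {bad}")
        object.__setattr__(self, "signatures", S / colsums)
        object.__setattr__(self, "names", tuple(self.names))
        if np.linalg.matrix_rank(self.signatures) < len(self.names):
            raise ValueError(
                "library is rank deficient; collinear fluorophores among "
                f"{list(self.names)}"
            )

    @property
    def n_bands(self) -> int:
        return self.signatures.shape[0]

    @property
    def n_fluorophores(self) -> int:
        return self.signatures.shape[1]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def permuted(self, order: list[int]) -> "SpectralLibrary":
        """Return a library with columns reordered by ``order``."""
        return SpectralLibrary(
            tuple(self.names[i] for i in order), self.signatures[:, order]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures,
            columns=list(self.names),
            index=[f"band_{i}" for i in range(self.n_bands)],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectralLibrary":
        return cls(tuple(df.columns), df.to_numpy(dtype=float))


def estimate_signature(
    pixels: np.ndarray,
    mask: np.ndarray,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate one fluorophore's emission signature from a single-plex image.

    The signature is the mean pixel spectrum over ``mask``, minus a
    background spectrum, floored at zero and normalized to unit sum.

    Parameters
    ----------
    pixels : ndarray, shape (n_bands, H, W)
        Single-plex multichannel image (one fluorophore plus background).
    mask : ndarray of bool, shape (H, W)
        Pixels dominated by the fluorophore.
    background : ndarray, shape (n_bands,), optional
        Background spectrum to subtract. If omitted, it is estimated as the
        mean spectrum over the complement of ``mask`` (zero if the mask
        covers the whole image).

    Returns
    -------
    ndarray, shape (n_bands,)
        Unit-sum, nonnegative signature.
    """
    pixels = np.asarray(pixels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.ndim != 3:
        raise ValueError("pixels must have shape (n_bands, H, W)")
    if mask.shape != pixels.shape[1:]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("empty mask: no pixels to estimate a signature from")
    flat = pixels.reshape(pixels.shape[0], -1)
    sig = flat[:, mask.ravel()].mean(axis=1)
    if background is None:
        outside = ~mask.ravel()
        background = (
            flat[:, outside].mean(axis=1) if outside.any() else np.zeros_like(sig)
        )
    sig = np.clip(sig - np.asarray(background, dtype=float), 0.0, None)
    total = sig.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum after background subtraction")
    return sig / total


# pseudoinverses of column subsets, keyed by library bytes then bitmask;
# bounded: one entry per distinct library in a process
_PINV_CACHE: dict[bytes, dict[int, np.ndarray]] = {}


def nnls_batched(
    S: np.ndarray, X: np.ndarray, kkt_tol: float = 1e-8
) -> np.ndarray:
    """Solve ``min ||S a - x||, a >= 0`` for many right-hand sides at once.

    Vectorized active-set scheme: start with all components active, solve the
    unconstrained least-squares problem for every pixel grouped by active-set
    bitmask, drop the most negative component per infeasible pixel, and
    repeat (at most one drop per component, so the loop is bounded by the
    number of fluorophores). Optimality is then verified through the KKT
    conditions ``S_inactive^T (x - S a) <= tol``; the rare pixels that fail
    are re-solved exactly with :func:`scipy.optimize.nnls`.

    Parameters
    ----------
    S : ndarray, shape (n_bands, k)
    X : ndarray, shape (n_bands, n_pixels)

    Returns
    -------
    ndarray, shape (k, n_pixels)
        Nonnegative abundances.
    """
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)
    n_bands, k = S.shape
    n_pix = X.shape[1]
    if k > 30:
        raise ValueError("too many components for bitmask active sets")

    full_mask = (1 << k) - 1
    active = np.full(n_pix, full_mask, dtype=np.int64)
    A = np.zeros((k, n_pix))
    pinv_cache = _PINV_CACHE.setdefault(S.tobytes(), {})

    def pinv_for(mask_bits: int) -> np.ndarray:
        P = pinv_cache.get(mask_bits)
        if P is None:
            cols = [i for i in range(k) if mask_bits >> i & 1]
            P = np.linalg.pinv(S[:, cols])
            pinv_cache[mask_bits] = P
        return P

    scale = max(float(np.abs(X).max()), 1.0)
    comp_bits = np.arange(k, dtype=np.int64)

    def solve_pending(pending: np.ndarray) -> np.ndarray:
        """Drop-negative loop on a subset of pixels; returns final subset."""
        touched = pending
        for _ in range(k + 1):
            if pending.size == 0:
                break
            masks = active[pending]
            A[:, pending] = 0.0
            for mask_bits in np.unique(masks):
                sel = pending[masks == mask_bits]
                if mask_bits == 0:
                    continue
                cols = [i for i in range(k) if mask_bits >> i & 1]
                A[np.ix_(cols, sel)] = pinv_for(int(mask_bits)) @ X[:, sel]
            sub = A[:, pending]
            neg = sub < -1e-12
            bad = neg.any(axis=0)
            if not bad.any():
                break
            bad_idx = pending[bad]
            # drop the most negative coefficient of each infeasible pixel
            worst = np.argmin(np.where(neg[:, bad], sub[:, bad], np.inf), axis=0)
            active[bad_idx] &= ~(1 << worst.astype(np.int64))
            A[worst, bad_idx] = 0.0
            pending = bad_idx
        return touched

    solve_pending(np.arange(n_pix))
    # KKT verification and repair: for inactive components the gradient of
    # the residual, S^T (x - S a), must be <= 0. Re-add the most violated
    # component and re-solve; loop is finite in practice, with an exact
    # per-pixel solve as the last resort.
    for _ in range(2 * k):
        np.clip(A, 0.0, None, out=A)
        grad = S.T @ (X - S @ A)
        inactive = (active[None, :] >> comp_bits[:, None] & 1) == 0
        viol = np.where(inactive, grad, -np.inf)
        bad = viol.max(axis=0) > kkt_tol * scale
        if not bad.any():
            return A
        bad_idx = np.flatnonzero(bad)
        best = np.argmax(viol[:, bad_idx], axis=0)
        active[bad_idx] |= 1 << best.astype(np.int64)
        solve_pending(bad_idx)
    np.clip(A, 0.0, None, out=A)
    grad = S.T @ (X - S @ A)
    inactive = (active[None, :] >> comp_bits[:, None] & 1) == 0
    for j in np.flatnonzero(((grad > kkt_tol * scale) & inactive).any(axis=0)):
        A[:, j] = _scipy_nnls(S, X[:, j])[0]
    return A


def unmix_pixels(
    pixels: np.ndarray,
    library: SpectralLibrary,
    nonnegative: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix a multichannel image into per-fluorophore abundance maps.

    Parameters
    ----------
    pixels : ndarray, shape (n_bands, H, W)
    library : SpectralLibrary
    nonnegative : bool
        If False, return the plain least-squares solution (diagnostic mode;
        abundances may be negative).

    Returns
    -------
    abundances : ndarray, shape (n_fluorophores, H, W)
    residual : ndarray, shape (H, W)
        Per-pixel residual 2-norm of the spectral fit.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3:
        raise ValueError("pixels must have shape (n_bands, H, W)")
    if pixels.shape[0] != library.n_bands:
        raise ValueError(
            f"image has {pixels.shape[0]} bands but library expects "
            f"{library.n_bands}"
        )
    h, w = pixels.shape[1:]
    X = pixels.reshape(library.n_bands, -1)
    S = library.signatures
    if nonnegative:
        A = nnls_batched(S, X)
    else:
        A = np.linalg.pinv(S) @ X
    resid = np.linalg.norm(X - S @ A, axis=0)
    return A.reshape(library.n_fluorophores, h, w), resid.reshape(h, w)
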