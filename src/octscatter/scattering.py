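"""Order-0/1/2 wavelet scattering coefficients and feature assembly.

The scattering transform iterates wavelet convolution and complex modulus,
then averages with the wide Gaussian ``phi_J``:

    S0 f = f * phi_J
    S1 f = |f * psi_{j1,g1}| * phi_J
    S2 f = ||f * psi_{j1,g1}| * psi_{j2,g2}| * phi_J,   j2 > j1

Each output is subsampled on the ``2^J`` grid, giving features that are
locally invariant to translations smaller than ``2^J`` pixels and stable to
small deformations.  Convolutions are circular (pointwise products in the
frequency domain); images whose sides are not multiples of ``2^J`` are
reflection-padded first so that wrap-around artifacts do not contaminate the
coarse scales, and outputs are cropped back to the original extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .filter_bank import FilterBank

__all__ = [
    "Image",
    "ScatteringPath",
    "ScatteringFeatures",
    "pad_shape",
    "scattering_paths",
    "feature_count",
    "convolve",
    "scatter",
    "energy_capture",
    "extract_features",
]


@dataclass
class Image:
    """A grayscale image with intensities in [0, 1] plus provenance."""

    pixels: np.ndarray
    source_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True, order=True)
class ScatteringPath:
    """One scattering path: the (scale, orientation) choices of a coefficient."""

    order: int
    j1: int = -1
    gamma1: int = -1
    j2: int = -1
    gamma2: int = -1

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"order must be 0, 1 or 2, got {self.order}")

    def __str__(self) -> str:
        if self.order == 0:
            return "S0"
        if self.order == 1:
            return f"S1[j1={self.j1},g1={self.gamma1}]"
        return f"S2[j1={self.j1},g1={self.gamma1},j2={self.j2},g2={self.gamma2}]"


@dataclass
class ScatteringFeatures:
    """Scattering coefficients of one image in canonical path order."""

    coefficients: dict[ScatteringPath, np.ndarray]
    vector: np.ndarray
    n_features: int
    paths: list[ScatteringPath] = field(default_factory=list)


def pad_shape(shape: tuple[int, int], J: int) -> tuple[int, int]:
    """Smallest shape >= `shape` with both sides multiples of ``2^J``."""
    m = 2**J
    return tuple(int(np.ceil(s / m)) * m for s in shape)


def scattering_paths(
    J: int, r: int, include_equal_scale: bool = False
) -> list[ScatteringPath]:
    """Canonical path order: order 0, then order 1 by (j1, g1), then order 2
    by (j1, g1, j2, g2).  Second-order scales are strictly increasing by
    default; ``include_equal_scale`` also admits ``j2 == j1``."""
    paths = [ScatteringPath(order=0)]
    for j1 in range(J):
        for g1 in range(r):
            paths.append(ScatteringPath(order=1, j1=j1, gamma1=g1))
    for j1 in range(J):
        for g1 in range(r):
            j2_start = j1 if include_equal_scale else j1 + 1
            for j2 in range(j2_start, J):
                for g2 in range(r):
                    paths.append(
                        ScatteringPath(order=2, j1=j1, gamma1=g1, j2=j2, gamma2=g2)
                    )
    return paths


def feature_count(
    shape: tuple[int, int], J: int, r: int, include_equal_scale: bool = False
) -> int:
    """Length N_J of the flattened feature vector.

    For sides divisible by ``2^J`` this equals the closed form
    ``(1 + r J + r^2 J(J-1)/2) * 2^{-2J} * N`` with ``N = H*W``; otherwise the
    subsampled grids are the ceiling sizes.
    """
    H, W = shape
    m = 2**J
    hs, ws = -(-H // m), -(-W // m)
    n_order2 = r * r * J * (J + 1) // 2 if include_equal_scale else r * r * J * (J - 1) // 2
    return (1 + r * J + n_order2) * hs * ws


def convolve(grid: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Filter a grid with a frequency-domain filter.

    The grid is reflection-padded up to the filter's shape (mitigating the
    wrap-around of circular convolution on non-periodic images), multiplied
    pointwise in the frequency domain, and cropped back to its original
    extent.  If the shapes already match the convolution is purely circular.
    """
    grid = np.asarray(grid)
    H, W = grid.shape
    fh, fw = filt.shape
    if fh < H or fw < W:
        raise ValueError(f"filter shape {filt.shape} smaller than input {grid.shape}")
    if (fh, fw) != (H, W):
        grid = np.pad(grid, ((0, fh - H), (0, fw - W)), mode="symmetric")
    out = np.fft.ifft2(np.fft.fft2(grid) * filt)
    return out[:H, :W]


def _check_image(image: Image, bank: FilterBank) -> np.ndarray:
    J = bank.params.J
    H, W = image.shape
    if min(H, W) < 2**J:
        raise ValueError(
            f"image {image.shape} smaller than the invariant scale 2^{J}"
        )
    target = bank.params.shape
    if pad_shape(image.shape, J) != target and image.shape != target:
        raise ValueError(
            f"bank built for grid {target} cannot filter image {image.shape}; "
            f"rebuild the bank on shape {pad_shape(image.shape, J)}"
        )
    return np.asarray(image.pixels, dtype=float)


def _first_order_moduli(
    fhat: np.ndarray, bank: FilterBank
) -> Iterator[tuple[int, int, np.ndarray]]:
    for (j1, g1) in sorted(bank.bandpass):
        u1 = np.abs(np.fft.ifft2(fhat * bank.bandpass[(j1, g1)]))
        yield j1, g1, u1


def scatter(
    image: Image, bank: FilterBank, include_equal_scale: bool = False
) -> ScatteringFeatures:
    """Compute all order-0..2 scattering coefficients of one image.

    Internal wavelet-modulus fields are kept at full resolution; each output
    is averaged with ``phi_J``, cropped to the image extent, and subsampled on
    the ``2^J`` grid starting at index 0.  The flattened vector concatenates
    the subsampled grids in canonical path order.
    """
    f = _check_image(image, bank)
    J, r = bank.params.J, bank.params.r
    H, W = image.shape
    m = 2**J
    fh, fw = bank.params.shape
    if (fh, fw) != (H, W):
        f = np.pad(f, ((0, fh - H), (0, fw - W)), mode="symmetric")

    fhat = np.fft.fft2(f)
    coeffs: dict[ScatteringPath, np.ndarray] = {}

    def smooth_subsample(grid_hat: np.ndarray) -> np.ndarray:
        s = np.real(np.fft.ifft2(grid_hat * bank.lowpass))
        return s[:H:m, :W:m].copy()

    coeffs[ScatteringPath(order=0)] = smooth_subsample(fhat)

    for j1, g1, u1 in _first_order_moduli(fhat, bank):
        u1_hat = np.fft.fft2(u1)
        coeffs[ScatteringPath(order=1, j1=j1, gamma1=g1)] = smooth_subsample(u1_hat)
        j2_start = j1 if include_equal_scale else j1 + 1
        for j2 in range(j2_start, J):
            for g2 in range(r):
                u2 = np.abs(np.fft.ifft2(u1_hat * bank.bandpass[(j2, g2)]))
                coeffs[
                    ScatteringPath(order=2, j1=j1, gamma1=g1, j2=j2, gamma2=g2)
                ] = smooth_subsample(np.fft.fft2(u2))

    paths = scattering_paths(J, r, include_equal_scale)
    vector = np.concatenate([coeffs[p].ravel() for p in paths])
    return ScatteringFeatures(
        coefficients=coeffs,
        vector=vector,
        n_features=vector.size,
        paths=paths,
    )


def energy_capture(
    image: Image, bank: FilterBank, include_equal_scale: bool = False
) -> float:
    """Fraction of signal energy retained by scattering orders 0-2.

    Returns ``E012 / (E012 + E3)`` where ``E012`` sums the squared L2 norms of
    every order-0, order-1 and order-2 scattering output at full resolution
    (before subsampling) and ``E3`` sums the squared norms of the order-3
    internal wavelet-modulus signals ``|||f*psi|*psi|*psi|`` over
    increasing-scale paths.  Requires a normalized bank (``lp_bound = 1``) so
    that the energies are comparable across orders.
    """
    f = _check_image(image, bank)
    if not np.isclose(bank.lp_bound, 1.0, atol=1e-6):
        raise ValueError("energy_capture requires a Littlewood-Paley-normalized bank")
    if np.all(f == 0):
        raise ValueError("energy fraction undefined for an all-zero image")
    J, r = bank.params.J, bank.params.r
    H, W = image.shape
    fh, fw = bank.params.shape
    if (fh, fw) != (H, W):
        f = np.pad(f, ((0, fh - H), (0, fw - W)), mode="symmetric")
    fhat = np.fft.fft2(f)

    def lowpass_energy(grid_hat: np.ndarray) -> float:
        s = np.real(np.fft.ifft2(grid_hat * bank.lowpass))[:H, :W]
        return float(np.sum(s**2))

    def sq(grid: np.ndarray) -> float:
        return float(np.sum(grid[:H, :W] ** 2))

    e_captured = lowpass_energy(fhat)
    e_third = 0.0
    for j1, g1, u1 in _first_order_moduli(fhat, bank):
        u1_hat = np.fft.fft2(u1)
        e_captured += lowpass_energy(u1_hat)
        j2_start = j1 if include_equal_scale else j1 + 1
        for j2 in range(j2_start, J):
            for g2 in range(r):
                u2 = np.abs(np.fft.ifft2(u1_hat * bank.bandpass[(j2, g2)]))
                u2_hat = np.fft.fft2(u2)
                e_captured += lowpass_energy(u2_hat)
                for j3 in range(j2 + 1, J):
                    for g3 in range(r):
                        u3 = np.abs(
                            np.fft.ifft2(u2_hat * bank.bandpass[(j3, g3)])
                        )
                        e_third += sq(u3)
    return e_captured / (e_captured + e_third)


def extract_features(
    images: Sequence[Image],
    bank: FilterBank,
    include_equal_scale: bool = False,
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Scatter a list of same-shape images into an (n_images, N_J) matrix.

    Returns the feature matrix plus a path index table mapping each canonical
    path to its column range ``(path_id, start, stop)``.
    """
    if not images:
        raise ValueError("no images given")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(
            f"images have heterogeneous shapes {sorted(shapes)}; load them "
            "with a resize policy to a common shape first"
        )
    rows = []
    table: list[tuple[str, int, int]] = []
    for i, im in enumerate(images):
        feats = scatter(im, bank, include_equal_scale)
        rows.append(feats.vector)
        if i == 0:
            start = 0
            for p in feats.paths:
                npix = feats.coefficients[p].size
                table.append((str(p), start, start + npix))
                start += npix
    return np.vstack(rows), table
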