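"""Morlet filter-bank construction for the 2D wavelet scattering transform.

The bank consists of one Gaussian low-pass filter ``phi_J`` at the invariant
scale ``2^J`` and ``J * r`` oriented Morlet band-pass wavelets
``psi_{j,gamma}``, sampled on the same (H, W) grid as the images they will be
applied to.  The Morlet wavelet is a plane wave localized by an isotropic
Gaussian window, corrected by a constant ``c2`` so that its integral (the DC
response) vanishes exactly on the sampled grid.  After construction the
band-pass family is rescaled by a single constant ``c1`` so that the
Littlewood-Paley sum

    A(w) = |phi_J^(w)|^2 + 1/2 * sum_{j,gamma} (|psi^(w)|^2 + |psi^(-w)|^2)

has supremum exactly 1 over the discrete frequency grid, which makes the
scattering transform non-expansive and energy accounting meaningful.

Filters are stored in the frequency domain with the standard discrete layout
(zero frequency at index (0, 0), negative frequencies wrapped), so filtering
an image is a pointwise product with its FFT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterParams",
    "FilterBank",
    "make_gaussian",
    "make_morlet",
    "build_filter_bank",
    "normalize_bank",
]

#: Central frequency of the unrotated, unscaled Morlet plane wave,
#: in radians per pixel: modulus 3*pi/4 along the first (row) axis.
XI_DEFAULT = (3.0 * np.pi / 4.0, 0.0)


@dataclass(frozen=True)
class FilterParams:
    """Parameters defining a scattering filter bank.

    Parameters
    ----------
    shape
        (height, width) of the grid the filters are sampled on.  Must be at
        least ``2^J`` in each dimension.
    J
        Number of dyadic scales; the invariant scale is ``2^J`` pixels.
    r
        Number of equidistant orientations in ``[0, pi)``.
    sigma
        Width of the Gaussian window in pixels.
    xi
        Central frequency vector of the mother wavelet before rotation,
        radians/pixel.
    """

    shape: tuple[int, int]
    J: int
    r: int = 12
    sigma: float = 0.85
    xi: tuple[float, float] = XI_DEFAULT

    def __post_init__(self) -> None:
        H, W = self.shape
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.J < 1:
            raise ValueError(f"J must be a positive integer, got {self.J}")
        if self.r < 1:
            raise ValueError(f"r must be a positive integer, got {self.r}")
        if min(H, W) < 2 ** self.J:
            raise ValueError(
                f"grid {self.shape} too small for J={self.J}: the low-pass "
                f"support 2^J={2 ** self.J} exceeds the grid; maximum "
                f"admissible J is {int(np.floor(np.log2(min(H, W))))}"
            )

    @property
    def angles(self) -> np.ndarray:
        """The rotation set Gamma = {k*pi/r : k = 0..r-1}, all in [0, pi)."""
        return np.arange(self.r) * np.pi / self.r


@dataclass
class FilterBank:
    """A built (and possibly normalized) scattering filter bank.

    Attributes
    ----------
    lowpass
        Frequency-domain grid of ``phi_J`` (real-valued response of a kernel
        whose spatial samples sum to 1, so ``lowpass[0, 0] == 1``).
    bandpass
        Mapping ``(j, gamma_index) -> complex frequency-domain grid`` of
        ``psi_{j,gamma}``, for ``j`` in ``0..J-1`` and ``gamma_index`` in
        ``0..r-1``.
    c1
        Per-filter amplitude constants; after :func:`normalize_bank` they all
        equal the common Littlewood-Paley rescaling factor.
    c2
        Per-filter zero-mean correction constants (ratio of the sampled
        windowed-plane-wave sum to the sampled Gaussian sum).
    lp_bound, lp_inf
        Supremum and infimum of the Littlewood-Paley sum over the frequency
        grid, recorded by :func:`normalize_bank`.
    """

    params: FilterParams
    lowpass: np.ndarray
    bandpass: dict[tuple[int, int], np.ndarray]
    c1: dict[tuple[int, int], float] = field(default_factory=dict)
    c2: dict[tuple[int, int], complex] = field(default_factory=dict)
    lp_bound: float = np.nan
    lp_inf: float = np.nan

    def littlewood_paley_sum(self) -> np.ndarray:
        """A(w) over the frequency grid (symmetrized over +/-w)."""
        A = np.abs(self.lowpass) ** 2
        for p in self.bandpass.values():
            m2 = np.abs(p) ** 2
            m2_neg = _negate_frequency(m2)
            A = A + 0.5 * (m2 + m2_neg)
        return A

    @property
    def n_bandpass(self) -> int:
        return len(self.bandpass)

    def save(self, path) -> None:
        """Serialize the bank (frequency grids + metadata) to an .npz archive."""
        keys = sorted(self.bandpass)
        meta = {
            "format_version": 1,
            "shape": list(self.params.shape),
            "J": self.params.J,
            "r": self.params.r,
            "sigma": self.params.sigma,
            "xi": list(self.params.xi),
            "lp_bound": float(self.lp_bound),
            "lp_inf": float(self.lp_inf),
            "keys": [list(k) for k in keys],
            "c1": [float(self.c1.get(k, 1.0)) for k in keys],
            "c2_re": [float(np.real(self.c2.get(k, 0.0))) for k in keys],
            "c2_im": [float(np.imag(self.c2.get(k, 0.0))) for k in keys],
        }
        np.savez(
            path,
            lowpass=self.lowpass,
            bandpass=np.stack([self.bandpass[k] for k in keys]),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "FilterBank":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            params = FilterParams(
                shape=tuple(meta["shape"]),
                J=meta["J"],
                r=meta["r"],
                sigma=meta["sigma"],
                xi=tuple(meta["xi"]),
            )
            keys = [tuple(k) for k in meta["keys"]]
            bp = dict(zip(keys, z["bandpass"]))
            c1 = dict(zip(keys, meta["c1"]))
            c2 = {
                k: complex(re, im)
                for k, re, im in zip(keys, meta["c2_re"], meta["c2_im"])
            }
            return cls(
                params=params,
                lowpass=z["lowpass"],
                bandpass=bp,
                c1=c1,
                c2=c2,
                lp_bound=meta["lp_bound"],
                lp_inf=meta["lp_inf"],
            )


def _centered_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate grids centered at index (H//2, W//2)."""
    H, W = shape
    x1 = np.arange(H) - H // 2
    x2 = np.arange(W) - W // 2
    return np.meshgrid(x1, x2, indexing="ij")


def _negate_frequency(grid: np.ndarray) -> np.ndarray:
    """Map grid(w) -> grid(-w) in the wrapped discrete-frequency layout."""
    return np.roll(np.flip(grid, axis=(0, 1)), shift=(1, 1), axis=(0, 1))


def make_gaussian(sigma: float, scale_J: int, shape: tuple[int, int]) -> np.ndarray:
    """Sample the dilated Gaussian window ``phi_J(x) = 2^{-2J} phi(2^{-J} x)``.

    ``phi(x) = exp(-|x|^2 / (2 sigma^2)) / (2 pi sigma^2)``.  The kernel is
    centered at the grid center and discretely renormalized so its sum is
    exactly 1 (so that filtering a constant image preserves the constant).

    Parameters
    ----------
    sigma
        Gaussian width in pixels (of the undilated window).
    scale_J
        Dyadic dilation exponent; the effective width is ``2^J sigma``.
    shape
        (height, width) of the sampling grid.

    Returns
    -------
    Real spatial grid, centered at ``(H//2, W//2)``, summing to 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if 2 ** scale_J > min(shape):
        raise ValueError(
            f"scale 2^{scale_J} exceeds grid {shape}; maximum admissible J "
            f"is {int(np.floor(np.log2(min(shape))))}"
        )
    X1, X2 = _centered_grid(shape)
    s = 2.0 ** (-scale_J)
    g = (
        2.0 ** (-2 * scale_J)
        / (2 * np.pi * sigma**2)
        * np.exp(-((s * X1) ** 2 + (s * X2) ** 2) / (2 * sigma**2))
    )
    return g / g.sum()


def make_morlet(
    sigma: float,
    xi: tuple[float, float],
    j: int,
    gamma: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, complex]:
    """Sample the scaled, rotated Morlet wavelet in the frequency domain.

    The mother wavelet is ``psi(u) = (exp(i xi . u) - c2) * phi(u)`` and the
    returned filter is ``psi_{j,gamma}(x) = 2^{-2j} psi(2^{-j} R_gamma x)``
    with the rotation acting on the spatial argument.  ``c2`` is computed from
    the sampled grids (windowed-plane-wave sum over Gaussian sum) so that the
    discrete filter is exactly zero-mean; the amplitude constant ``c1`` is set
    later at bank level by :func:`normalize_bank` and is left at 1 here.

    Returns
    -------
    (freq_grid, c2)
        ``freq_grid`` is the complex frequency-domain response in the wrapped
        layout; ``c2`` the zero-mean correction actually applied.
    """
    if not (0.0 <= gamma < np.pi):
        raise ValueError(f"gamma must lie in [0, pi), got {gamma}")
    if j < 0:
        raise ValueError(f"scale index must be nonnegative, got {j}")
    X1, X2 = _centered_grid(shape)
    s = 2.0 ** (-j)
    # rotated, dilated argument u = 2^{-j} R_gamma x
    u1 = s * (np.cos(gamma) * X1 + np.sin(gamma) * X2)
    u2 = s * (-np.sin(gamma) * X1 + np.cos(gamma) * X2)
    envelope = np.exp(-(u1**2 + u2**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    wave = np.exp(1j * (xi[0] * u1 + xi[1] * u2))
    c2 = complex(np.sum(wave * envelope) / np.sum(envelope))
    psi = 2.0 ** (-2 * j) * (wave - c2) * envelope
    # phase reference at index (0,0): shift the centered kernel before the FFT
    freq = np.fft.fft2(np.fft.ifftshift(psi))
    return freq, c2


def build_filter_bank(params: FilterParams) -> FilterBank:
    """Build and Littlewood-Paley-normalize the full filter bank.

    Contains ``phi_J`` and ``psi_{j,gamma}`` for ``j = 0..J-1`` and every
    angle in ``params.angles`` (``J * r`` band-pass filters in total).
    """
    phi = make_gaussian(params.sigma, params.J, params.shape)
    lowpass = np.fft.fft2(np.fft.ifftshift(phi))
    # phi is real and symmetric up to grid truncation; keep the tiny imaginary
    # residue out of the stored response
    lowpass = np.real(lowpass)
    bandpass: dict[tuple[int, int], np.ndarray] = {}
    c1: dict[tuple[int, int], float] = {}
    c2: dict[tuple[int, int], complex] = {}
    for j in range(params.J):
        for gi, gamma in enumerate(params.angles):
            freq, c2_jg = make_morlet(params.sigma, params.xi, j, gamma, params.shape)
            bandpass[(j, gi)] = freq
            c1[(j, gi)] = 1.0
            c2[(j, gi)] = c2_jg
    bank = FilterBank(params=params, lowpass=lowpass, bandpass=bandpass, c1=c1, c2=c2)
    return normalize_bank(bank)


def normalize_bank(bank: FilterBank) -> FilterBank:
    """Rescale all band-pass filters by one constant so that sup A(w) = 1.

    With the low-pass response fixed at ``phi_J^(0) = 1`` and every band-pass
    filter zero at DC, the Littlewood-Paley sum already equals 1 at the origin;
    the common factor ``c`` is the largest value keeping ``A(w) <= 1``
    everywhere on the grid, i.e.

        c^2 = min_{w : B(w) > 0} (1 - |phi_J^(w)|^2) / B(w)

    where ``B`` is the symmetrized band-pass sum.  The procedure is invariant
    to any prior positive rescaling of the band-pass family.
    """
    low2 = np.abs(bank.lowpass) ** 2
    B = np.zeros_like(low2)
    for p in bank.bandpass.values():
        m2 = np.abs(p) ** 2
        B += 0.5 * (m2 + _negate_frequency(m2))
    bmax = B.max()
    if bmax == 0.0:
        raise ValueError("cannot normalize a bank of all-zero band-pass filters")
    mask = B > 1e-12 * bmax
    c2_factor = np.min((1.0 - low2[mask]) / B[mask])
    c = float(np.sqrt(max(c2_factor, 0.0)))
    scaled = {k: c * v for k, v in bank.bandpass.items()}
    out = FilterBank(
        params=bank.params,
        lowpass=bank.lowpass,
        bandpass=scaled,
        c1={k: c * v for k, v in bank.c1.items()},
        c2=dict(bank.c2),
    )
    A = out.littlewood_paley_sum()
    out.lp_bound = float(A.max())
    out.lp_inf = float(A.min())
    return out
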