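"""Independent brute-force oracles used by the test suite.

Everything here is computed directly from the defining formulas in the
spatial domain — circular convolution by explicit kernel-shift summation,
frequency responses by an explicit DFT matrix product — so it shares no code
path with the package's FFT-based cascade.  It is intentionally slow and only
usable at tiny sizes.
"""

import numpy as np


def centered_coords(shape):
    H, W = shape
    return np.meshgrid(np.arange(H) - H // 2, np.arange(W) - W // 2, indexing="ij")


def gaussian_kernel(sigma, J, shape):
    X1, X2 = centered_coords(shape)
    s = 2.0**-J
    g = np.exp(-((s * X1) ** 2 + (s * X2) ** 2) / (2 * sigma**2))
    return g / g.sum()


def morlet_kernel(sigma, xi, j, gamma, shape):
    """Spatial Morlet 2^{-2j} (e^{i xi . u} - c2) phi(u), u = 2^{-j} R_gamma x,
    with c2 the sampled zero-mean correction; amplitude constant left at 1."""
    X1, X2 = centered_coords(shape)
    s = 2.0**-j
    u1 = s * (np.cos(gamma) * X1 + np.sin(gamma) * X2)
    u2 = s * (-np.sin(gamma) * X1 + np.cos(gamma) * X2)
    env = np.exp(-(u1**2 + u2**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    wave = np.exp(1j * (xi[0] * u1 + xi[1] * u2))
    c2 = np.sum(wave * env) / np.sum(env)
    return 2.0 ** (-2 * j) * (wave - c2) * env


def circular_conv(image, kernel_centered):
    """out[x] = sum_u k[u] image[x - u], kernel centered at (H//2, W//2)."""
    H, W = image.shape
    out = np.zeros_like(image, dtype=complex)
    for p in range(H):
        for q in range(W):
            k = kernel_centered[p, q]
            if k != 0:
                out += k * np.roll(image, (p - H // 2, q - W // 2), axis=(0, 1))
    return out


def dft_modulus(kernel_centered):
    """|DFT| of a kernel via an explicit DFT matrix product (no np.fft)."""
    H, W = kernel_centered.shape
    EH = np.exp(-2j * np.pi * np.outer(np.arange(H), np.arange(H)) / H)
    EW = np.exp(-2j * np.pi * np.outer(np.arange(W), np.arange(W)) / W)
    return np.abs(EH @ kernel_centered @ EW.T)


def lp_constant(sigma, xi, J, r, shape):
    """Common band-pass rescaling c with sup A(w) = 1, from first principles."""
    phi_mod = dft_modulus(gaussian_kernel(sigma, J, shape))
    B = np.zeros(shape)
    for j in range(J):
        for gi in range(r):
            m2 = dft_modulus(morlet_kernel(sigma, xi, j, gi * np.pi / r, shape)) ** 2
            m2_neg = np.roll(np.flip(m2, axis=(0, 1)), (1, 1), axis=(0, 1))
            B += 0.5 * (m2 + m2_neg)
    mask = B > 1e-12 * B.max()
    return np.sqrt(np.min((1.0 - phi_mod[mask] ** 2) / B[mask]))


def scatter_bruteforce(image, J, r, sigma=0.85, xi=(3 * np.pi / 4, 0.0)):
    """Full order-0..2 scattering vector by direct-space circular convolution.

    Assumes the image sides are multiples of 2^J (pure circular boundary).
    Path order matches the canonical ordering: S0, then (j1, g1), then
    (j1, g1, j2, g2) with j2 > j1.
    """
    shape = image.shape
    m = 2**J
    c = lp_constant(sigma, xi, J, r, shape)
    phi = gaussian_kernel(sigma, J, shape)
    psis = {
        (j, gi): c * morlet_kernel(sigma, xi, j, gi * np.pi / r, shape)
        for j in range(J)
        for gi in range(r)
    }

    def smooth_sub(u):
        return np.real(circular_conv(u, phi))[::m, ::m]

    parts = [smooth_sub(image).ravel()]
    u1_fields = {}
    for j1 in range(J):
        for g1 in range(r):
            u1 = np.abs(circular_conv(image, psis[(j1, g1)]))
            u1_fields[(j1, g1)] = u1
            parts.append(smooth_sub(u1).ravel())
    for j1 in range(J):
        for g1 in range(r):
            for j2 in range(j1 + 1, J):
                for g2 in range(r):
                    u2 = np.abs(circular_conv(u1_fields[(j1, g1)], psis[(j2, g2)]))
                    parts.append(smooth_sub(u2).ravel())
    return np.concatenate(parts)


def residual_lstsq(v, mean, basis):
    """Distance to an affine space by explicitly solving least squares."""
    w = np.asarray(v, dtype=float) - mean
    if basis.shape[1] == 0:
        return float(np.linalg.norm(w))
    coef, *_ = np.linalg.lstsq(basis, w, rcond=None)
    return float(np.linalg.norm(w - basis @ coef))
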