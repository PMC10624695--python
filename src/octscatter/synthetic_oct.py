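"""Seeded generator of OCT-like grayscale B-scan images.

Real retinal B-scans show a stack of alternating bright and dark horizontal
bands (the retinal layers), bent by the globe's curvature, degraded by strong
multiplicative speckle, and perturbed by pathology: fluid pockets (edema,
serous detachment) appear as dark dome-shaped regions, drusen elevate the
outer bands, macular holes cut a gap through the inner layers, and several
diseases thicken individual layers.  This module renders a cartoon of that
morphology — layered bands with jittered boundaries, one optional lesion, a
sinusoidal curvature warp and lognormal speckle — so that the scattering
pipeline can be exercised end to end with controllable class structure and no
external data.  It is test scaffolding, not a physical OCT simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scattering import Image

__all__ = [
    "LesionSpec",
    "SyntheticClassSpec",
    "default_class_specs",
    "generate_image",
    "generate_dataset",
    "write_dataset",
]

BACKGROUND = 0.05  # vitreous / choroid baseline reflectivity

LESION_KINDS = ("dome_fluid", "band_thickening", "gap", "sub_band_elevation")


@dataclass(frozen=True)
class LesionSpec:
    """One structural perturbation composited into the band stack.

    ``size`` is the (min, max) radius / half-width range in pixels,
    ``intensity_delta`` the reflectivity change inside the lesion, and
    ``depth`` the vertical placement as a fraction of the stack height
    (0 = inner retina, 1 = outer retina).
    """

    kind: str
    size: tuple[int, int]
    intensity_delta: float
    depth: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.size[0] < 1 or self.size[1] < self.size[0]:
            raise ValueError(f"bad lesion size range {self.size}")


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Generative parameters for one OCT-like image class."""

    name: str
    n_layers: int
    layer_intensities: tuple[float, ...]
    layer_thickness: tuple[tuple[float, float], ...]  # (mean, jitter) px per band
    lesion: Optional[LesionSpec] = None
    speckle_sigma: float = 0.3
    curvature: float = 5.0

    def __post_init__(self) -> None:
        if len(self.layer_intensities) != self.n_layers:
            raise ValueError("layer_intensities length must equal n_layers")
        if len(self.layer_thickness) != self.n_layers:
            raise ValueError("layer_thickness length must equal n_layers")
        if not all(0.0 <= v <= 1.0 for v in self.layer_intensities):
            raise ValueError("layer intensities must lie in [0, 1]")
        if not all(t[0] >= 1.0 for t in self.layer_thickness):
            raise ValueError("layer thickness must be >= 1 pixel")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def default_class_specs(scale: float = 1.0) -> list[SyntheticClassSpec]:
    """Five disease-like classes mimicking a 5-class OCT study.

    ``scale`` multiplies thicknesses and lesion sizes, for rendering at
    smaller or larger image heights (1.0 suits ~128-pixel-tall scans).
    """

    def th(pairs):
        return tuple((m * scale, j * scale) for m, j in pairs)

    def sz(lo, hi):
        return (max(1, round(lo * scale)), max(1, round(hi * scale)))

    base_int = (0.55, 0.8, 0.3, 0.65, 0.25, 0.75, 0.5)
    base_th = ((6, 1.5), (5, 1.0), (7, 1.5), (6, 1.0), (8, 2.0), (5, 1.0), (7, 1.5))
    common = dict(
        n_layers=7, layer_intensities=base_int, layer_thickness=th(base_th)
    )
    return [
        SyntheticClassSpec(name="normal", **common),
        SyntheticClassSpec(
            name="dme_like",
            lesion=LesionSpec("dome_fluid", sz(8, 14), 0.5, depth=0.45),
            **common,
        ),
        SyntheticClassSpec(
            name="amd_like",
            lesion=LesionSpec("sub_band_elevation", sz(10, 18), 0.2, depth=0.85),
            **common,
        ),
        SyntheticClassSpec(
            name="hole_like",
            lesion=LesionSpec("gap", sz(5, 9), 0.5, depth=0.3),
            **common,
        ),
        SyntheticClassSpec(
            name="csr_like",
            lesion=LesionSpec("dome_fluid", sz(14, 22), 0.45, depth=0.8),
            **common,
        ),
    ]


def _smooth_profile(rng: np.random.Generator, width: int, amplitude: float) -> np.ndarray:
    """Smooth zero-mean per-column jitter from a low-order cosine series."""
    x = np.arange(width) / width
    prof = np.zeros(width)
    for harmonic in range(1, 4):
        amp = rng.normal(0.0, 1.0) / harmonic
        phase = rng.uniform(0, 2 * np.pi)
        prof += amp * np.cos(2 * np.pi * harmonic * x + phase)
    peak = np.max(np.abs(prof))
    return amplitude * prof / peak if peak > 0 else prof


def _render_bands(
    boundaries: np.ndarray, intensities: Sequence[float], shape: tuple[int, int]
) -> np.ndarray:
    H, W = shape
    rows = np.arange(H)[:, None]
    img = np.full(shape, BACKGROUND)
    for i, val in enumerate(intensities):
        mask = (rows >= boundaries[i]) & (rows < boundaries[i + 1])
        img[mask] = val
    return img


def generate_image(
    spec: SyntheticClassSpec, shape: tuple[int, int], seed: int
) -> Image:
    """Render one labeled OCT-like image, deterministic in (spec, shape, seed)."""
    H, W = shape
    if H < 32 or W < 32:
        raise ValueError(f"shape must be at least 32x32, got {shape}")
    rng = np.random.default_rng(seed)

    total_th = sum(m for m, _ in spec.layer_thickness)
    if spec.lesion is not None and 2 * spec.lesion.size[1] > min(H, W):
        raise ValueError(
            f"lesion (max extent {2 * spec.lesion.size[1]} px) larger than image {shape}"
        )

    # curvature warp shared by all boundaries
    phase = rng.uniform(0, 2 * np.pi)
    curve = spec.curvature * np.sin(2 * np.pi * np.arange(W) / W + phase)
    top = (H - total_th) / 2 + curve

    # stacked boundaries with per-band smooth jitter
    boundaries = [top]
    for mean_th, jitter in spec.layer_thickness:
        th = mean_th + (_smooth_profile(rng, W, jitter) if jitter > 0 else 0.0)
        boundaries.append(boundaries[-1] + np.maximum(th, 1.0))
    boundaries = np.array(boundaries)  # (n_layers + 1, W)

    lesion = spec.lesion
    lesion_mask = None
    if lesion is not None:
        radius = int(rng.integers(lesion.size[0], lesion.size[1] + 1))
        cx = int(rng.integers(radius + 2, W - radius - 2))
        stack_top = boundaries[0]
        stack_bot = boundaries[-1]
        cy_col = stack_top + lesion.depth * (stack_bot - stack_top)
        cy = float(np.clip(cy_col[cx], radius + 1, H - radius - 1))
        if lesion.kind in ("band_thickening", "sub_band_elevation"):
            # local dome added to the thickness / elevation of the target band
            i_band = int(np.clip(round(lesion.depth * spec.n_layers), 1, spec.n_layers))
            xs = np.arange(W)
            bump = np.maximum(0.0, 1.0 - ((xs - cx) / radius) ** 2) * radius
            if lesion.kind == "band_thickening":
                boundaries[i_band:] += bump  # band i_band-1 grows downward
            else:
                boundaries[:i_band] -= bump  # bands above are pushed up (drusen)

    img = _render_bands(boundaries, spec.layer_intensities, shape)

    if lesion is not None and lesion.kind in ("dome_fluid", "gap"):
        rows = np.arange(H)[:, None]
        cols = np.arange(W)[None, :]
        if lesion.kind == "dome_fluid":
            lesion_mask = ((rows - cy) ** 2 + (cols - cx) ** 2) <= radius**2
        else:  # gap: full-thickness vertical notch (macular-hole-like)
            in_stack = (rows >= boundaries[0][None, :]) & (
                rows < boundaries[-1][None, :]
            )
            lesion_mask = in_stack & (np.abs(cols - cx) <= radius)
        img[lesion_mask] = np.maximum(
            img[lesion_mask] - lesion.intensity_delta, BACKGROUND / 2
        )

    if spec.speckle_sigma > 0:
        # multiplicative lognormal speckle with unit mean
        s = spec.speckle_sigma
        img = img * rng.lognormal(mean=-(s**2) / 2, sigma=s, size=shape)

    return Image(
        pixels=np.clip(img, 0.0, 1.0),
        source_id=f"{spec.name}-{seed}",
        label=spec.name,
    )


def derive_seed(master_seed: int, class_index: int, image_index: int) -> int:
    """Independent, reproducible per-image seed (counter-mixed sequence)."""
    ss = np.random.SeedSequence([int(master_seed), class_index, image_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    specs: Sequence[SyntheticClassSpec],
    n_per_class: int,
    shape: tuple[int, int],
    seed: int,
) -> tuple[list[Image], pd.DataFrame]:
    """Generate ``n_per_class`` images per spec with disjoint derived seeds.

    Returns the images plus a manifest DataFrame recording label, per-image
    seed and spec digest.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate class names in specs: {names}")
    images: list[Image] = []
    records = []
    for ci, spec in enumerate(specs):
        for i in range(n_per_class):
            s = derive_seed(seed, ci, i)
            img = generate_image(spec, shape, s)
            images.append(img)
            records.append(
                {
                    "source_id": img.source_id,
                    "label": spec.name,
                    "seed": s,
                    "spec_digest": spec.digest(),
                }
            )
    return images, pd.DataFrame.from_records(records)


def write_dataset(
    specs: Sequence[SyntheticClassSpec],
    n_per_class: int,
    shape: tuple[int, int],
    seed: int,
    outdir,
) -> pd.DataFrame:
    """Write PNGs into per-class directories plus a CSV manifest.

    The layout (``<outdir>/<label>/<name>.png`` + ``manifest.csv`` with
    columns path,label,case_id) is exactly what the dataset loader consumes.
    """
    from PIL import Image as PILImage

    outdir = Path(outdir)
    images, manifest = generate_dataset(specs, n_per_class, shape, seed)
    paths = []
    for img in images:
        d = outdir / img.label
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"{img.source_id}.png"
        arr = np.round(img.pixels * 255).astype(np.uint8)
        PILImage.fromarray(arr, mode="L").save(p)
        paths.append(str(p.relative_to(outdir)))
    manifest = manifest.assign(path=paths, case_id=manifest["source_id"])
    manifest[["path", "label", "case_id", "seed", "spec_digest"]].to_csv(
        outdir / "manifest.csv", index=False
    )
    return manifest
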