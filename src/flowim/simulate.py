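"""Seeded synthetic flow-imaging scenes with ground truth.

The generator emulates what the instrument sees, phenomenologically
rather than by wave-optics: polystyrene microspheres render as bright
annuli in darkfield (rings at their inner refractive diameter), algal
cells as filled soft-edged bright regions with mild internal texture,
bacterial flocs as irregular multi-lobed aggregates, and debris as
faint ragged spots.  Brightfield is the complementary view: dark
objects on a bright background.  Defocus widens the Gaussian point
spread and dims/thickens edges; sensor noise is additive Gaussian.

Ground-truth masks record the *ideal* particle geometry before blur
and noise, which is what the detection-scoring taxonomy needs.

Everything is driven by a single seed: identical seeds reproduce
identical scenes bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .classify import LabeledLibrary
from .detect import BBox, ROI
from .optics import OpticalConfig
from .preprocess import BRIGHTFIELD, DARKFIELD, Frame, MultimodalView
from .scoring import AnnotatedObject

#: Calibration microsphere diameters (um).  Four of the six are the
#: documented sizes (4.5, 6, 10, 15); 1 and 2 um complete the 1-15 um
#: range and are generator assumptions.
MICROSPHERE_DIAMETERS_UM = (1.0, 2.0, 4.5, 6.0, 10.0, 15.0)

MORPHOTYPES = ("sphere", "disk_cell", "ellipse_cell", "floc", "debris")

DENSITY_MEDIUM = 5e5  # cells/mL
DENSITY_HIGH = 5e6

# Darkfield rendering amplitudes per morphotype.
_AMPLITUDE = {
    "sphere": 0.9,
    "disk_cell": 0.85,
    "ellipse_cell": 0.85,
    "floc": 0.7,
    "debris": 0.35,
}
_DARK_BACKGROUND = 0.02
_BRIGHT_BACKGROUND = 0.85
_DEFOCUS_SIGMA_PER_UM = 0.12  # extra PSF sigma (um) per um of focus offset


@dataclass
class ParticleSpec:
    """One particle to render: geometry, morphotype, focus, label."""

    center: tuple  # (x_um, y_um) in the field of view
    diameter: float  # minor-axis diameter, um
    morphotype: str = "disk_cell"
    aspect_ratio: float = 1.0
    orientation: float = 0.0  # radians
    focus_offset: float = 0.0  # um; 0 = in focus
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {self.morphotype!r}")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect ratio must be >= 1")
        if self.morphotype in ("sphere", "disk_cell") and self.aspect_ratio != 1.0:
            raise ValueError(f"{self.morphotype} must have aspect ratio 1")


@dataclass
class SyntheticScene:
    """Rendered frames plus the ground truth that produced them."""

    particles: list
    frames: MultimodalView
    truth: list
    density: float  # particles/mL implied by count and frame volume
    seed: int


def scaled_config(
    frame_width_px: int,
    frame_height_px: int,
    base: Optional[OpticalConfig] = None,
) -> OpticalConfig:
    """Optics for a reduced frame with a geometrically consistent volume.

    Desk-scale simulations use smaller frames than the physical sensor;
    the per-frame volume is rescaled to FOV area x channel depth so
    that densities remain physically meaningful.
    """
    base = base or OpticalConfig()
    s = base.sample_pixel_size
    w_um = min(frame_width_px * s, base.channel_width)
    h_um = min(frame_height_px * s, base.channel_width)
    volume_ul = w_um * h_um * base.channel_depth / 1e9
    return replace(
        base,
        frame_width_px=frame_width_px,
        frame_height_px=frame_height_px,
        frame_volume=volume_ul,
    )


def sample_population(
    target_density: Optional[float] = None,
    n: Optional[int] = None,
    morphotype_mix: Optional[dict] = None,
    cfg: Optional[OpticalConfig] = None,
    size_medians_um: Optional[dict] = None,
    size_sigma_log: float = 0.12,
    microsphere_diameters: Optional[Sequence[float]] = None,
    focus_sd_um: float = 0.0,
    seed: int = 0,
) -> list[ParticleSpec]:
    """Draw a random particle population for one frame.

    The particle count is Poisson(target_density x frame volume) when a
    density is given, or exactly ``n``.  Positions are uniform inside
    the field of view (with an edge margin of one particle radius);
    diameters are lognormal around per-morphotype medians, except in
    microsphere mode where diameters are drawn uniformly from the given
    discrete set.
    """
    cfg = cfg or OpticalConfig()
    rng = np.random.default_rng(seed)
    if (target_density is None) == (n is None):
        raise ValueError("give exactly one of target_density or n")
    if target_density is not None:
        mean = target_density * cfg.frame_volume / 1000.0  # /mL * uL -> count
        n = int(rng.poisson(mean))
    mix = morphotype_mix or {"disk_cell": 1.0}
    names = list(mix)
    weights = np.array([mix[k] for k in names], dtype=float)
    if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("morphotype mix weights must be nonnegative and sum to 1")
    medians = {
        "sphere": 6.0,
        "disk_cell": 4.0,
        "ellipse_cell": 4.0,
        "floc": 10.0,
        "debris": 2.5,
        **(size_medians_um or {}),
    }
    aspects = {
        "sphere": (1.0, 1.0),
        "disk_cell": (1.0, 1.0),
        "ellipse_cell": (1.7, 2.5),
        "floc": (1.0, 1.6),
        "debris": (1.0, 2.0),
    }
    fw, fh = cfg.fov_width_um, cfg.fov_height_um
    particles = []
    for _ in range(n):
        morph = names[int(rng.choice(len(names), p=weights))]
        if microsphere_diameters is not None and morph == "sphere":
            d = float(rng.choice(np.asarray(microsphere_diameters, dtype=float)))
        else:
            d = float(medians[morph] * rng.lognormal(0.0, size_sigma_log))
        lo, hi = aspects[morph]
        aspect = 1.0 if hi == 1.0 else float(rng.uniform(lo, hi))
        margin = d * aspect / 2.0 + 1.0
        margin_x = min(margin, fw / 2.01)
        margin_y = min(margin, fh / 2.01)
        x = float(rng.uniform(margin_x, fw - margin_x))
        y = float(rng.uniform(margin_y, fh - margin_y))
        focus = float(rng.normal(0.0, focus_sd_um)) if focus_sd_um > 0 else 0.0
        particles.append(
            ParticleSpec(
                center=(x, y),
                diameter=d,
                morphotype=morph,
                aspect_ratio=aspect,
                orientation=float(rng.uniform(0, math.pi)),
                focus_offset=focus,
                class_label=morph,
            )
        )
    return particles


def _particle_stamp(p: ParticleSpec, cfg: OpticalConfig, psf_sigma_um: float,
                    rng: np.random.Generator):
    """Render one particle onto a local patch.

    Returns (darkfield stamp, ideal boolean mask, patch origin (row, col)).
    """
    s = cfg.sample_pixel_size
    b = p.diameter / 2.0 / s  # minor semi-axis, px
    a = b * p.aspect_ratio  # major semi-axis, px
    sigma_px = (psf_sigma_um + _DEFOCUS_SIGMA_PER_UM * abs(p.focus_offset)) / s
    half = int(math.ceil(a + 3.0 * sigma_px + 3))
    cx, cy = p.center[0] / s, p.center[1] / s
    row0, col0 = int(round(cy)) - half, int(round(cx)) - half
    side = 2 * half + 1
    yy, xx = np.mgrid[0:side, 0:side]
    dx = xx + col0 - cx
    dy = yy + row0 - cy
    ct, st = math.cos(p.orientation), math.sin(p.orientation)
    u = dx * ct + dy * st  # along major axis
    v = -dx * st + dy * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)

    amp = _AMPLITUDE[p.morphotype]
    if p.morphotype == "sphere":
        ring_w = max(0.10, 1.2 / b)
        stamp = amp * np.exp(-((rho - 0.8) ** 2) / (2 * ring_w**2))
        stamp += 0.3 * amp * np.clip(1.0 - rho / 0.5, 0.0, 1.0)
        mask = rho <= 1.0
    elif p.morphotype == "floc":
        n_sub = 4 + int(rng.poisson(5))
        mask = np.zeros((side, side), dtype=bool)
        for _ in range(n_sub):
            fr = rng.uniform(0.25, 0.5)
            theta = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.65)
            su = rad * math.cos(theta) * a
            sv = rad * math.sin(theta) * b
            rr = np.sqrt((u - su) ** 2 + (v - sv) ** 2)
            mask |= rr <= fr * min(a, b) * 1.6
        mask |= rho <= 0.45
        texture = ndimage.gaussian_filter(rng.normal(0, 1, (side, side)), 2.0)
        texture = 1.0 + 0.35 * texture / max(1e-9, np.abs(texture).max())
        stamp = amp * mask.astype(float) * texture
        stamp = ndimage.gaussian_filter(stamp, 1.0)
    else:  # disk_cell, ellipse_cell, debris: filled soft-edged ellipse
        edge = 0.08
        stamp = amp / (1.0 + np.exp((rho - 1.0) / edge))
        texture = ndimage.gaussian_filter(rng.normal(0, 1, (side, side)), 1.5)
        peak = max(1e-9, float(np.abs(texture).max()))
        depth = 0.5 if p.morphotype == "debris" else 0.15
        stamp *= 1.0 + depth * texture / peak
        mask = rho <= 1.0

    if sigma_px > 0.05:
        stamp = ndimage.gaussian_filter(stamp, sigma_px)
    return np.clip(stamp, 0.0, None), mask, (row0, col0)


def _paste(canvas: np.ndarray, stamp: np.ndarray, origin: tuple) -> None:
    h, w = canvas.shape
    r0, c0 = origin
    sr0, sc0 = max(0, -r0), max(0, -c0)
    r0, c0 = max(0, r0), max(0, c0)
    r1 = min(h, r0 + stamp.shape[0] - sr0)
    c1 = min(w, c0 + stamp.shape[1] - sc0)
    if r1 <= r0 or c1 <= c0:
        return
    canvas[r0:r1, c0:c1] += stamp[sr0 : sr0 + (r1 - r0), sc0 : sc0 + (c1 - c0)]


def render_scene(
    particles: Sequence[ParticleSpec],
    cfg: Optional[OpticalConfig] = None,
    psf_sigma_um: float = 0.3,
    noise_sd: float = 0.01,
    seed: int = 0,
    source: str = "synthetic",
) -> SyntheticScene:
    """Render a particle population into a paired bright/dark view.

    Truth masks are the ideal particle geometries recorded before blur
    and noise; the implied density is count / frame volume.
    """
    cfg = cfg or OpticalConfig()
    rng = np.random.default_rng(seed)
    h, w = cfg.frame_height_px, cfg.frame_width_px
    signal = np.zeros((h, w), dtype=float)
    truth = []
    s = cfg.sample_pixel_size
    for i, p in enumerate(sorted(particles, key=lambda q: (q.center[1], q.center[0]))):
        stamp, mask, origin = _particle_stamp(p, cfg, psf_sigma_um, rng)
        _paste(signal, stamp, origin)
        # clip the ideal mask to the frame
        r0, c0 = origin
        mr0, mc0 = max(0, -r0), max(0, -c0)
        fr0, fc0 = max(0, r0), max(0, c0)
        mr1 = mask.shape[0] - max(0, r0 + mask.shape[0] - h)
        mc1 = mask.shape[1] - max(0, c0 + mask.shape[1] - w)
        local = mask[mr0:mr1, mc0:mc1]
        if not local.any():
            continue
        truth.append(
            AnnotatedObject(
                id=i,
                center=(p.center[1] / s, p.center[0] / s),
                mask=local,
                origin=(fr0, fc0),
                label=p.class_label or p.morphotype,
            )
        )

    dark = np.clip(
        _DARK_BACKGROUND + signal + rng.normal(0, noise_sd, (h, w)), 0.0, 1.0
    )
    bright = np.clip(
        _BRIGHT_BACKGROUND - 0.6 * signal + rng.normal(0, noise_sd, (h, w)), 0.0, 1.0
    )
    view = MultimodalView(
        bright=Frame(bright, BRIGHTFIELD, cfg, source=source),
        dark=Frame(dark, DARKFIELD, cfg, source=source),
    )
    density = len(truth) / cfg.frame_volume * 1000.0 if cfg.frame_volume else 0.0
    return SyntheticScene(
        particles=list(particles), frames=view, truth=truth,
        density=density, seed=seed,
    )


# ---------------------------------------------------------------------------
# Classification libraries

#: Stylized analogs of the taxonomic/morphological classes the
#: instrument is used on: circular chlorella-like cells, ellipsoidal
#: scenedesmus-like cells, highly elongated monoraphidium-like cells,
#: irregular bacterial-floc aggregates, and a defocused/ambiguous
#: "unknown" null class.
CLASS_SPECS = {
    "disk_cell": dict(morphotype="disk_cell", diameter=4.0, aspect=(1.0, 1.0)),
    "ellipse_cell": dict(morphotype="ellipse_cell", diameter=4.0, aspect=(1.7, 2.5)),
    "elongated_cell": dict(morphotype="ellipse_cell", diameter=2.0, aspect=(4.0, 5.5)),
    "floc": dict(morphotype="floc", diameter=8.0, aspect=(1.0, 1.4)),
    "unknown": dict(morphotype="disk_cell", diameter=4.0, aspect=(1.0, 1.0),
                    focus=(8.0, 16.0)),
}


def render_particle_crop(
    p: ParticleSpec,
    cfg: OpticalConfig,
    crop_side: int = 48,
    psf_sigma_um: float = 0.3,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> ROI:
    """Render a single particle centered in a square crop."""
    crop_cfg = replace(
        cfg, frame_width_px=crop_side, frame_height_px=crop_side
    )
    scene = render_scene([p], crop_cfg, psf_sigma_um, noise_sd, seed=seed)
    return ROI(
        bbox=BBox(0, 0, crop_side, crop_side),
        crop=scene.frames.dark.pixels,
        crop_bright=scene.frames.bright.pixels,
        detector="synthetic",
        frame_source=f"synthetic-crop-{seed}",
    )


def make_classification_dataset(
    classes: Sequence[str],
    n_per_class: int = 1500,
    crop_side: int = 48,
    cfg: Optional[OpticalConfig] = None,
    size_sigma_log: float = 0.12,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> LabeledLibrary:
    """Build a labeled ROI library of stylized morphotype classes.

    Each item is a single rendered particle with random size (lognormal
    around the class median), aspect ratio, orientation, and sub-pixel
    center jitter.  Library sizes of 1500-2000 per class emulate a
    curated annotation effort; smaller sizes are fine for quick runs.
    """
    cfg = cfg or OpticalConfig()
    rng = np.random.default_rng(seed)
    s = cfg.sample_pixel_size
    center_um = crop_side / 2.0 * s
    items, labels = [], []
    for cls in classes:
        if cls not in CLASS_SPECS:
            raise ValueError(f"unknown class {cls!r}; known: {sorted(CLASS_SPECS)}")
        spec = CLASS_SPECS[cls]
        for _ in range(n_per_class):
            d = spec["diameter"] * rng.lognormal(0.0, size_sigma_log)
            lo, hi = spec["aspect"]
            aspect = 1.0 if hi == 1.0 else float(rng.uniform(lo, hi))
            focus = 0.0
            if "focus" in spec:
                flo, fhi = spec["focus"]
                focus = float(rng.uniform(flo, fhi)) * (1 if rng.random() < 0.5 else -1)
            jitter = rng.uniform(-s, s, size=2)
            p = ParticleSpec(
                center=(center_um + jitter[0], center_um + jitter[1]),
                diameter=float(d),
                morphotype=spec["morphotype"],
                aspect_ratio=aspect,
                orientation=float(rng.uniform(0, math.pi)),
                focus_offset=focus,
                class_label=cls,
            )
            items.append(
                render_particle_crop(
                    p, cfg, crop_side, noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            labels.append(cls)
    return LabeledLibrary(
        items=items, labels=labels, classes=tuple(classes), seed=seed
    )
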