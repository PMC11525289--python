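"""Seeded synthetic filter scenes with exact ground truth.

Emulates the optics of dark-field filter microscopy of tire wear particles
(TWP): a pale bluish filter background, opaque black particles whose outer
rim is replaced by saturated chromatic (blue / yellow / red) diffraction
colours, plus two kinds of distractors — coloured organic matter and black
angular charcoal. The chromatic rim is the mechanism that makes small
particles lose their black core and be under-sized or missed entirely by a
colour-based classifier; its width is a scene parameter, not a physical
light-scattering model.

Every particle's true minimum/maximum Feret diameter is computed from the
analytic boundary polygon *before* rasterisation, so the ground truth is
independent of any pixel-level measurement.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .geometry import feret_diameters
from .preprocess import FilterImage

__all__ = [
    "DARKNESS_CAP",
    "ParticleRequest",
    "SceneSpec",
    "TrueParticle",
    "GroundTruthTable",
    "PlacementError",
    "generate_scene",
    "render_halo",
]

#: 8-bit ceiling under which all three channels count as "black". A scene
#: convention chosen to leave a wide margin to the bluish background; the
#: rule-based classifier uses the same cap.
DARKNESS_CAP = 40

_CHROMA = np.array(
    [[40, 70, 210], [225, 205, 60], [205, 60, 50]], dtype=np.float32
)  # saturated blue, yellow, red rim colours

_ORGANIC_PALETTE = np.array(
    [[150, 110, 60], [110, 130, 60], [180, 160, 90], [90, 120, 80]],
    dtype=np.float32,
)  # browns / greens of organic residues


class PlacementError(RuntimeError):
    """Raised when a particle cannot be placed after bounded retries."""


@dataclass(frozen=True)
class ParticleRequest:
    """One particle to render: nominal size, elongation, shape and class."""

    mfd_um: float
    aspect: float = 1.0  # FD / mFD ratio of the generating shape
    shape: str = "ellipse"  # ellipse | superellipse | blob | angular
    cls: str = "twp"  # twp | charcoal | organic
    orientation_deg: float | None = None

    def __post_init__(self) -> None:
        if self.mfd_um <= 0:
            raise ValueError("mfd_um must be > 0")
        if self.aspect < 1:
            raise ValueError("aspect must be >= 1")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic filter scene.

    Identical spec + seed yields a bit-identical image and ground truth.
    ``halo_width_um`` is either one width or a ``(lo, hi)`` range sampled
    per particle; 3–5 µm reproduces the observed chromatic rim scale.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 1.5
    background_rgb: tuple[int, int, int] = (186, 202, 222)
    background_noise_sigma: float = 4.0
    halo_width_um: float | tuple[float, float] = 4.0
    particles: tuple[ParticleRequest, ...] = ()
    n_random: int = 0
    size_range_um: tuple[float, float] = (10.0, 200.0)
    aspect_range: tuple[float, float] = (1.0, 2.2)
    organic_per_mm2: float = 0.0
    charcoal_per_mm2: float = 0.0
    allow_overlap: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        lo, hi = self._halo_range()
        if lo < 0:
            raise ValueError("halo_width_um must be >= 0")
        if hi < lo:
            raise ValueError("halo range must be (lo, hi) with hi >= lo")

    def _halo_range(self) -> tuple[float, float]:
        if isinstance(self.halo_width_um, (tuple, list)):
            return float(self.halo_width_um[0]), float(self.halo_width_um[1])
        return float(self.halo_width_um), float(self.halo_width_um)

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.pixel_size_um * 1e-3) ** 2

    def to_json(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["particles"] = [dataclasses.asdict(p) for p in self.particles]
        path = Path(path)
        path.write_text(json.dumps(d, indent=1))
        return path


@dataclass
class TrueParticle:
    """Ground truth for one rendered particle (µm sizes, pixel centroid)."""

    id: int
    cls: str
    shape: str
    true_mfd_um: float
    true_fd_um: float
    orientation_deg: float
    centroid_row_px: float
    centroid_col_px: float
    area_px: int
    halo_width_um: float
    core_px: int  # rendered black-core pixels; 0 = undetectable by colour


@dataclass
class GroundTruthTable:
    """All true particles of a scene plus the spec that produced them.

    ``rasters`` carries in-memory truth maps (not serialised): ``label``
    (particle id per pixel over the full particle extent), ``core`` (black
    TWP-core pixels), ``halo`` (chromatic rim pixels of black particles).
    """

    particles: list[TrueParticle]
    spec: SceneSpec
    rasters: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.particles)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(p) for p in self.particles])

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def of_class(self, cls: str) -> pd.DataFrame:
        df = self.to_dataframe()
        if df.empty:
            return df
        return df[df["cls"] == cls].reset_index(drop=True)


# ---------------------------------------------------------------------------
# shape polygons (continuous pixel coordinates, centred at the origin)


def _unit_polygon(shape: str, aspect: float, rng: np.random.Generator) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, 256, endpoint=False)
    if shape == "ellipse":
        x, y = aspect * np.cos(t), np.sin(t)
    elif shape == "superellipse":
        n = rng.uniform(2.5, 5.0)
        c, s = np.cos(t), np.sin(t)
        x = aspect * np.sign(c) * np.abs(c) ** (2.0 / n)
        y = np.sign(s) * np.abs(s) ** (2.0 / n)
    elif shape == "blob":
        r = np.ones_like(t)
        for k in range(2, 6):
            r += rng.uniform(0.0, 0.08) * np.cos(k * t + rng.uniform(0, 2 * np.pi))
        x, y = aspect * r * np.cos(t), r * np.sin(t)
    elif shape == "angular":
        m = rng.integers(5, 10)
        ang = np.sort(rng.uniform(0, 2 * np.pi, m))
        rad = rng.uniform(0.55, 1.2, m)
        x, y = aspect * rad * np.cos(ang), rad * np.sin(ang)
    else:
        raise ValueError(f"unknown shape family: {shape!r}")
    return np.column_stack([y, x])  # (row, col) convention


def _particle_polygon(
    req: ParticleRequest, pixel_size_um: float, rng: np.random.Generator
) -> tuple[np.ndarray, float, float, float]:
    """Polygon (px, origin-centred), true (FD, mFD) in µm and orientation."""
    poly = _unit_polygon(req.shape, req.aspect, rng)
    theta = (
        np.deg2rad(req.orientation_deg)
        if req.orientation_deg is not None
        else rng.uniform(0, np.pi)
    )
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    poly = poly @ rot.T
    # rescale so the analytic minimal caliper equals the requested mFD
    fd0, mfd0 = feret_diameters(poly)
    scale = (req.mfd_um / pixel_size_um) / mfd0
    poly = poly * scale
    fd_um = fd0 * scale * pixel_size_um
    return poly, fd_um, req.mfd_um, float(np.rad2deg(theta) % 180.0)


def _rasterise(poly_abs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(poly_abs[:, 0], poly_abs[:, 1], shape=shape)
    mask[rr, cc] = True
    return mask


def _core_of(mask: np.ndarray, halo_width_um: float, pixel_size_um: float) -> np.ndarray:
    """Erode a particle mask inward by the halo width (sub-pixel, via EDT)."""
    if halo_width_um <= 0:
        return mask.copy()
    pad = np.pad(mask, 1)
    edt = ndi.distance_transform_edt(pad)[1:-1, 1:-1]
    return edt > halo_width_um / pixel_size_um


def _paint_black(rgb: np.ndarray, where: np.ndarray, rng: np.random.Generator) -> None:
    n = int(where.sum())
    base = rng.uniform(6.0, 30.0, n)
    vals = base[:, None] + rng.normal(0.0, 3.0, (n, 3))
    rgb[where] = np.clip(vals, 0, DARKNESS_CAP - 2).astype(np.uint8)


def _paint_chroma(rgb: np.ndarray, where: np.ndarray, rng: np.random.Generator) -> None:
    n = int(where.sum())
    pick = _CHROMA[rng.integers(0, len(_CHROMA), n)]
    vals = pick + rng.normal(0.0, 8.0, (n, 3))
    rgb[where] = np.clip(vals, 0, 255).astype(np.uint8)


def render_halo(
    core_mask: np.ndarray,
    halo_width_um: float,
    pixel_size_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one black particle with its chromatic diffraction rim.

    The outer band of ``halo_width_um`` of the particle footprint is painted
    with saturated blue / yellow / red pixels; the remaining interior stays
    strictly black (all channels below the darkness cap). A halo at least as
    wide as the particle's inradius leaves no black pixel at all — the
    rendered analogue of a particle too small to be detected by colour.
    Pixels outside the particle are returned white.
    """
    mask = np.asarray(core_mask, dtype=bool)
    if not mask.any():
        raise ValueError("core_mask must be nonempty")
    rgb = np.full(mask.shape + (3,), 255, dtype=np.uint8)
    inner = _core_of(mask, halo_width_um, pixel_size_um)
    _paint_chroma(rgb, mask & ~inner, rng)
    _paint_black(rgb, inner, rng)
    return rgb


# ---------------------------------------------------------------------------
# scene assembly


def _place(
    poly: np.ndarray,
    placed: list[tuple[float, float, float]],
    spec: SceneSpec,
    rng: np.random.Generator,
) -> tuple[float, float]:
    radius = float(np.hypot(poly[:, 0], poly[:, 1]).max())
    h, w = spec.height_px, spec.width_px
    if 2 * radius + 2 > min(h, w):
        raise PlacementError(
            f"particle of circumradius {radius:.0f} px does not fit a {h}x{w} image"
        )
    for _ in range(1000):
        r = rng.uniform(radius + 1, h - radius - 1)
        c = rng.uniform(radius + 1, w - radius - 1)
        if spec.allow_overlap or all(
            np.hypot(r - pr, c - pc) >= radius + prad + 2 for pr, pc, prad in placed
        ):
            placed.append((r, c, radius))
            return r, c
    raise PlacementError(
        f"could not place particle of circumradius {radius:.0f} px "
        f"after 1000 attempts (scene too crowded)"
    )


def _sample_requests(spec: SceneSpec, rng: np.random.Generator) -> list[ParticleRequest]:
    reqs = list(spec.particles)
    lo, hi = spec.size_range_um
    for _ in range(spec.n_random):
        reqs.append(
            ParticleRequest(
                mfd_um=float(rng.uniform(lo, hi)),
                aspect=float(rng.uniform(*spec.aspect_range)),
                shape=str(rng.choice(["ellipse", "superellipse", "blob"])),
                cls="twp",
            )
        )
    for cls, dens, sizes, shp in (
        ("charcoal", spec.charcoal_per_mm2, (20.0, 100.0), "angular"),
        ("organic", spec.organic_per_mm2, (30.0, 120.0), "blob"),
    ):
        n = int(round(dens * spec.area_mm2))
        for _ in range(n):
            reqs.append(
                ParticleRequest(
                    mfd_um=float(rng.uniform(*sizes)),
                    aspect=float(rng.uniform(1.0, 1.8)),
                    shape=shp,
                    cls=cls,
                )
            )
    return reqs


def generate_scene(spec: SceneSpec) -> tuple[FilterImage, GroundTruthTable]:
    """Render a scene and return the image with its exact ground truth.

    Particles are placed without overlap (unless ``allow_overlap``); large
    particles are placed first to keep crowded scenes feasible. Black
    particles (TWP and charcoal) get the chromatic rim treatment; organic
    distractors are rendered in non-black colours and get no rim.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height_px, spec.width_px
    bg = np.array(spec.background_rgb, dtype=np.float32)
    rgb = bg[None, None, :] + rng.normal(0.0, spec.background_noise_sigma, (h, w, 3))
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    label = np.zeros((h, w), dtype=np.int32)
    core_map = np.zeros((h, w), dtype=bool)
    halo_map = np.zeros((h, w), dtype=bool)
    lo_h, hi_h = spec._halo_range()

    reqs = _sample_requests(spec, rng)
    order = sorted(range(len(reqs)), key=lambda i: -reqs[i].mfd_um)
    placed: list[tuple[float, float, float]] = []
    records: list[TrueParticle] = []
    for pid, idx in enumerate(order, start=1):
        req = reqs[idx]
        poly, fd_um, mfd_um, orient = _particle_polygon(req, spec.pixel_size_um, rng)
        r0, c0 = _place(poly, placed, spec, rng)
        mask = _rasterise(poly + np.array([r0, c0]), (h, w))
        if not mask.any():
            continue
        halo_um = float(rng.uniform(lo_h, hi_h)) if hi_h > lo_h else lo_h
        if req.cls in ("twp", "charcoal"):
            core = _core_of(mask, halo_um, spec.pixel_size_um)
            _paint_chroma(rgb, mask & ~core, rng)
            _paint_black(rgb, core, rng)
            if req.cls == "charcoal" and core.any():
                # internal grey texture: the cue that separates charcoal by
                # texture (not colour) from rubber particles
                speck = core & (rng.random((h, w)) < 0.25)
                n = int(speck.sum())
                grey = rng.uniform(48.0, 95.0, n)
                rgb[speck] = np.clip(
                    grey[:, None] + rng.normal(0, 4, (n, 3)), 0, 255
                ).astype(np.uint8)
            halo_map |= mask & ~core
            if req.cls == "twp":
                core_map |= core
            n_core = int(core.sum())
        else:
            colour = _ORGANIC_PALETTE[rng.integers(0, len(_ORGANIC_PALETTE))]
            n = int(mask.sum())
            rgb[mask] = np.clip(
                colour[None, :] + rng.normal(0, 10, (n, 3)), 50, 255
            ).astype(np.uint8)
            n_core = 0
        label[mask] = pid
        records.append(
            TrueParticle(
                id=pid,
                cls=req.cls,
                shape=req.shape,
                true_mfd_um=float(mfd_um),
                true_fd_um=float(fd_um),
                orientation_deg=orient,
                centroid_row_px=float(r0),
                centroid_col_px=float(c0),
                area_px=int(mask.sum()),
                halo_width_um=halo_um,
                core_px=n_core,
            )
        )

    image = FilterImage(rgb, spec.pixel_size_um)
    truth = GroundTruthTable(
        particles=records,
        spec=spec,
        rasters={"label": label, "core": core_map, "halo": halo_map},
    )
    return image, truth
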