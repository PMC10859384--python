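"""Seeded synthetic data: class-structured spectra, DFIR particle scenes
and whole-filter subsampling experiments, all with ground truth.

No public spectral database exists for this problem, so the generators
emulate its structure: nylon MP spectra carry the amide I/II pair near
1635/1541 cm^-1 plus three minor bands (1464/1416/1370); "type I" non-MP
carries a sharp carbonyl band near 1740 cm^-1; "type II" non-MP a broad
band near 1077 cm^-1.  Spectra are a sum of Gaussian bands plus a weak
polynomial baseline, scaled by a multiplicative scatter factor, plus
additive Gaussian noise.  Band amplitudes are set so the four planted
band centers (1635, 1541, 1740, 1077) are the dominant class-contrast
features and remain recoverable by coefficient-based selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging import (CLASS_MP, CLASS_NONMP, DFIRStack, ParticleLabelMap,
                      ROIMask, DEFAULT_PIXEL_SIZE_UM, DEFAULT_REGION_SHAPE)
from .quantify import FilterLayout, RegionCounts
from .spectra import MP, NON_MP, SpectraMatrix, Spectrum, WavenumberGrid, default_grid

TEMPLATE_MP = "MP"
TEMPLATE_TYPE1 = "NONMP_TYPE1"
TEMPLATE_TYPE2 = "NONMP_TYPE2"

#: the four class-discriminative band centers planted by default (cm^-1)
PLANTED_CENTERS = (1077.0, 1541.0, 1635.0, 1740.0)


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band."""

    center: float      # cm^-1
    width: float       # Gaussian sigma, cm^-1
    amplitude: float   # a.u.

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((np.asarray(wavenumbers, dtype=float) - self.center)
                    / self.width) ** 2)


@dataclass
class ClassTemplate:
    """Band structure plus noise statistics for one particle class.

    ``band_jitter`` is the half-width of the uniform multiplicative factor
    applied independently to each band's amplitude per generated spectrum,
    emulating composition variation between particles.
    """

    name: str
    bands: tuple[BandModel, ...]
    noise_sd: float = 0.05
    scatter_range: tuple[float, float] = (0.7, 1.3)
    baseline: tuple[float, ...] = (0.05, 0.05)   # polynomial in t = (w-min)/(max-min)
    band_jitter: float = 0.2

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a class template needs at least one band")

    def clean(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Analytic band sum without baseline, scatter, jitter or noise."""
        w = np.asarray(wavenumbers, dtype=float)
        return np.sum([b.evaluate(w) for b in self.bands], axis=0)

    def jittered(self, wavenumbers: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
        """Band sum with per-band amplitude jitter."""
        w = np.asarray(wavenumbers, dtype=float)
        lo, hi = 1.0 - self.band_jitter, 1.0 + self.band_jitter
        return np.sum([rng.uniform(lo, hi) * b.evaluate(w)
                       for b in self.bands], axis=0)

    def baseline_values(self, wavenumbers: np.ndarray) -> np.ndarray:
        w = np.asarray(wavenumbers, dtype=float)
        t = (w - w.min()) / max(w.max() - w.min(), 1e-12)
        return np.polynomial.polynomial.polyval(t, np.asarray(self.baseline))


def default_templates() -> dict[str, ClassTemplate]:
    """The three default particle classes (amplitudes in a.u.)."""
    return {
        TEMPLATE_MP: ClassTemplate(
            name=TEMPLATE_MP,
            bands=(
                BandModel(1635.0, 8.0, 1.00),   # amide I
                BandModel(1541.0, 8.0, 0.85),   # amide II
                BandModel(1464.0, 7.0, 0.15),
                BandModel(1416.0, 7.0, 0.12),
                BandModel(1370.0, 7.0, 0.10),
            ),
        ),
        TEMPLATE_TYPE1: ClassTemplate(
            name=TEMPLATE_TYPE1,
            bands=(BandModel(1740.0, 12.0, 1.00),),   # sharp carbonyl
        ),
        TEMPLATE_TYPE2: ClassTemplate(
            name=TEMPLATE_TYPE2,
            bands=(BandModel(1077.0, 25.0, 0.90),),   # broad C-O region
        ),
    }


def gen_spectrum(template: ClassTemplate, grid: WavenumberGrid | None = None,
                 seed: int | np.random.Generator = 0) -> Spectrum:
    """One noisy spectrum: scatter * (bands + baseline) + Gaussian noise."""
    grid = grid or default_grid()
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    signal = (template.jittered(grid.values, rng)
              + template.baseline_values(grid.values))
    scatter = rng.uniform(*template.scatter_range)
    noise = rng.normal(0.0, template.noise_sd, size=len(grid))
    return Spectrum(grid, scatter * signal + noise,
                    meta={"template": template.name})


def gen_spectra_set(n_mp: int, n_nonmp: int, type1_fraction: float = 0.5,
                    grid: WavenumberGrid | None = None, seed: int = 0,
                    templates: dict[str, ClassTemplate] | None = None
                    ) -> SpectraMatrix:
    """Labeled spectra matrix with the non-MP rows split between the two
    non-MP types by ``type1_fraction``."""
    if n_mp < 1 or n_nonmp < 1:
        raise ValueError("need at least one spectrum per class")
    if not 0.0 <= type1_fraction <= 1.0:
        raise ValueError("type1_fraction must lie in [0, 1]")
    grid = grid or default_grid()
    templates = templates or default_templates()
    rng = np.random.default_rng(seed)
    n_type1 = int(round(type1_fraction * n_nonmp))
    rows, labels = [], []
    for _ in range(n_mp):
        rows.append(gen_spectrum(templates[TEMPLATE_MP], grid, rng).intensity)
        labels.append(MP)
    for i in range(n_nonmp):
        name = TEMPLATE_TYPE1 if i < n_type1 else TEMPLATE_TYPE2
        rows.append(gen_spectrum(templates[name], grid, rng).intensity)
        labels.append(NON_MP)
    return SpectraMatrix(grid, np.vstack(rows), labels)


# ---------------------------------------------------------------------------
# DFIR scenes

@dataclass
class SceneParticle:
    """One planted particle: a shape footprint plus its class template."""

    shape: str                       # disk | ellipse | rect
    center: tuple[int, int]          # (row, col), pixels
    size: tuple[float, float]        # disk: (r, r); ellipse: semi-axes; rect: (h, w)
    template_name: str = TEMPLATE_MP

    def footprint(self, shape_hw: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0:shape_hw[0], 0:shape_hw[1]]
        r0, c0 = self.center
        a, b = self.size
        if self.shape == "disk":
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= a ** 2
        if self.shape == "ellipse":
            return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
        if self.shape == "rect":
            return (np.abs(rr - r0) <= a / 2.0) & (np.abs(cc - c0) <= b / 2.0)
        raise ValueError(f"unknown particle shape {self.shape!r}")


@dataclass
class SceneSpec:
    """Layout of one synthetic imaging region."""

    particles: list[SceneParticle] = field(default_factory=list)
    shape: tuple[int, int] = DEFAULT_REGION_SHAPE
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel_wavenumbers: tuple[float, ...] = PLANTED_CENTERS
    background_level: float = 0.02
    noise_sd: float = 0.05


def gen_scene(spec: SceneSpec,
              templates: dict[str, ClassTemplate] | None = None,
              seed: int = 0
              ) -> tuple[DFIRStack, ROIMask, ParticleLabelMap, list[str]]:
    """Rasterize a particle scene into a DFIR stack with ground truth.

    Each particle's pixels carry its class template evaluated at the channel
    wavenumbers, jittered per pixel by a multiplicative scatter factor, plus
    Gaussian noise; the background carries a flat level plus noise.  Returns
    the stack, the true particle mask, the true label map (ids in raster
    order) and the true MP/NON_MP class per particle id.
    """
    templates = templates or default_templates()
    rng = np.random.default_rng(seed)
    wn = np.sort(np.asarray(spec.channel_wavenumbers, dtype=float))
    H, W = spec.shape
    n_ch = wn.size
    data = spec.background_level + rng.normal(0.0, spec.noise_sd,
                                              size=(n_ch, H, W))
    label_img = np.zeros((H, W), dtype=int)
    class_img = np.full((H, W), -1, dtype=np.int8)
    truth_classes: list[str] = []
    for p in spec.particles:
        r0, c0 = p.center
        if not (0 <= r0 < H and 0 <= c0 < W):
            raise ValueError(f"particle centered at {p.center} lies outside "
                             f"the {H}x{W} region")
        tmpl = templates[p.template_name]
        fp = p.footprint((H, W))
        n_px = int(fp.sum())
        if n_px == 0:
            raise ValueError(f"particle at {p.center} rasterizes to no pixels")
        signal = tmpl.jittered(wn, rng) + tmpl.baseline_values(wn)
        scatter = rng.uniform(*tmpl.scatter_range, size=n_px)
        data[:, fp] += signal[:, None] * scatter[None, :]
        pid = len(truth_classes) + 1
        label_img[fp] = pid
        is_mp = p.template_name == TEMPLATE_MP
        class_img[fp] = CLASS_MP if is_mp else CLASS_NONMP
        truth_classes.append(MP if is_mp else NON_MP)
    # renumber truth ids in raster-scan order of each particle's first
    # pixel, matching the id convention of segment_particles
    if truth_classes:
        flat = label_img.ravel()
        first = {}
        for pos, pid in enumerate(flat):
            if pid and pid not in first:
                first[pid] = pos
        order = sorted(first, key=first.get)
        remap = np.zeros(len(truth_classes) + 1, dtype=int)
        for new, old in enumerate(order, start=1):
            remap[old] = new
        label_img = remap[label_img]
        truth_classes = [truth_classes[old - 1] for old in order]
    stack = DFIRStack(data, wn, spec.pixel_size_um,
                      meta={"synthetic": True,
                            "seed": int(seed) if isinstance(seed, (int, np.integer)) else -1})
    mask = ROIMask(label_img > 0, provenance="MANUAL")
    truth = ParticleLabelMap(labels=label_img, classes=class_img)
    return stack, mask, truth, truth_classes


def random_scene_spec(n_particles: int, seed: int = 0,
                      mp_fraction: float = 0.5,
                      shape: tuple[int, int] = DEFAULT_REGION_SHAPE,
                      channel_wavenumbers: Sequence[float] = PLANTED_CENTERS,
                      radius_range: tuple[int, int] = (3, 10),
                      type1_fraction: float = 0.5,
                      max_tries: int = 10_000) -> SceneSpec:
    """Place ``n_particles`` non-overlapping random particles in a region.

    Classes are drawn per particle: MP with probability ``mp_fraction``,
    the non-MP remainder split between the two non-MP types.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    particles: list[SceneParticle] = []
    occupied = np.zeros(shape, dtype=bool)
    tries = 0
    while len(particles) < n_particles:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all particles without overlap")
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        r0 = int(rng.integers(r + 1, H - r - 1))
        c0 = int(rng.integers(r + 1, W - r - 1))
        kind = rng.choice(["disk", "ellipse", "rect"])
        if kind == "disk":
            size = (float(r), float(r))
        elif kind == "ellipse":
            size = (float(r), float(max(2, r // 2 + rng.integers(0, r))))
        else:
            size = (float(2 * r), float(max(3, rng.integers(r, 3 * r))))
        p = SceneParticle(shape=kind, center=(r0, c0), size=size)
        fp = p.footprint(shape)
        # dilated footprint keeps a 2 px gap so particles never touch
        grown = ndimage.binary_dilation(fp, iterations=2)
        if (grown & occupied).any() or not fp.any():
            continue
        if rng.random() < mp_fraction:
            p.template_name = TEMPLATE_MP
        else:
            p.template_name = (TEMPLATE_TYPE1 if rng.random() < type1_fraction
                               else TEMPLATE_TYPE2)
        particles.append(p)
        occupied |= grown
    return SceneSpec(particles=particles, shape=shape,
                     channel_wavenumbers=tuple(channel_wavenumbers))


# ---------------------------------------------------------------------------
# whole-filter experiments

def gen_filter_experiment(layout: FilterLayout, total_particles: int,
                          mp_fraction: float = 1.0, seed: int = 0
                          ) -> tuple[RegionCounts, dict]:
    """Scatter particles uniformly over the active filter area and count
    them inside the layout's subsampled regions.

    Returns the per-region counts plus a ground-truth dict with the planted
    totals.  Placement is uniform over the active disk via rejection
    sampling from the bounding square.
    """
    if total_particles < 0:
        raise ValueError("total_particles must be >= 0")
    if not 0.0 <= mp_fraction <= 1.0:
        raise ValueError("mp_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    r = layout.active_diameter_mm / 2.0
    pts = np.empty((0, 2))
    while pts.shape[0] < total_particles:
        cand = rng.uniform(-r, r, size=(max(16, 2 * total_particles), 2))
        cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= r]
        pts = np.vstack([pts, cand])
    pts = pts[:total_particles]
    is_mp = rng.random(total_particles) < mp_fraction
    hw = layout.region_width_um / 2000.0    # mm
    hh = layout.region_height_um / 2000.0
    mp_counts = np.zeros(layout.n_regions)
    tot_counts = np.zeros(layout.n_regions)
    for i, (cx, cy) in enumerate(layout.region_coordinates):
        inside = ((np.abs(pts[:, 0] - cx) <= hw)
                  & (np.abs(pts[:, 1] - cy) <= hh))
        tot_counts[i] = inside.sum()
        mp_counts[i] = (inside & is_mp).sum()
    truth = {"total_particles": total_particles,
             "total_mp": int(is_mp.sum()),
             "seed": seed}
    return RegionCounts(mp_counts, tot_counts, replicate_id=f"seed{seed}"), truth
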