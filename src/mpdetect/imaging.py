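"""Discrete-frequency IR (DFIR) image stacks: pixel-wise classification,
particle segmentation, majority voting and morphometry.

A stack holds one intensity image per selected wavenumber over a region
(default 240 x 320 px at 2 um/px = 480 um x 640 um).  Within a
region-of-interest mask each pixel's channel vector is normalized and
scored by the reduced discriminant model; a particle's class is the
majority vote of its pixels (ties go to NON_MP, the conservative call
against false positives).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.measure import regionprops

from .preprocess import snv_array
from .spectra import MP, NON_MP, DegenerateSpectrumError
from .svm import KIND_REDUCED, DiscriminantModel

log = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 2.0
DEFAULT_REGION_SHAPE = (240, 320)   # rows x cols = 480 um x 640 um

# per-pixel class codes in ParticleLabelMap.classes
CLASS_UNLABELED = -1
CLASS_NONMP = 0
CLASS_MP = 1


@dataclass
class DFIRStack:
    """Multi-channel single-frequency image stack, channels sorted by
    wavenumber.  ``data`` has shape (n_channels, height, width)."""

    data: np.ndarray
    channel_wavenumbers: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        wn = np.asarray(self.channel_wavenumbers, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != wn.size:
            raise ValueError("data must be (n_channels, H, W) with one "
                             "wavenumber per channel")
        if wn.size != np.unique(wn).size or np.any(np.diff(wn) <= 0):
            order = np.argsort(wn)
            wn = wn[order]
            if wn.size != np.unique(wn).size:
                raise ValueError("channel wavenumbers must be unique")
            self.data = self.data[order]
        self.channel_wavenumbers = wn

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class ROIMask:
    """Boolean region-of-interest image."""

    mask: np.ndarray
    provenance: str = "MANUAL"   # MANUAL | THRESHOLD

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D image")


@dataclass
class ParticleLabelMap:
    """Particle id image (0 background, 1..n) plus per-pixel class codes."""

    labels: np.ndarray
    classes: np.ndarray | None = None   # CLASS_* codes, same shape

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype=np.int8)
            if self.classes.shape != self.labels.shape:
                raise ValueError("class image shape must match label image")

    @property
    def n_particles(self) -> int:
        return int(self.labels.max())


@dataclass
class ParticleRecord:
    id: int
    particle_class: str
    mp_vote_fraction: float
    pixel_count: int
    area_um2: float
    length_um: float
    width_um: float
    circularity: float


# ---------------------------------------------------------------------------
# stack I/O: multi-page TIFF + JSON sidecar

def write_stack(stack: DFIRStack, tiff_path: str | Path) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.data.astype(np.float32),
                     photometric="minisblack")
    sidecar = {
        "channel_wavenumbers": stack.channel_wavenumbers.tolist(),
        "pixel_size_um": stack.pixel_size_um,
        **stack.meta,
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                         sort_keys=True))


def read_stack(tiff_path: str | Path) -> DFIRStack:
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    wn = np.array(sidecar.pop("channel_wavenumbers"), dtype=float)
    px = float(sidecar.pop("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
    return DFIRStack(data, wn, px, meta=sidecar)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def read_mask(path: str | Path, provenance: str = "MANUAL") -> ROIMask:
    img = tifffile.imread(Path(path))
    return ROIMask(img > 0, provenance=provenance)


def particle_table(records: list[ParticleRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "class": r.particle_class,
        "mp_vote_fraction": r.mp_vote_fraction, "pixel_count": r.pixel_count,
        "area_um2": r.area_um2, "length_um": r.length_um,
        "width_um": r.width_um, "circularity": r.circularity,
    } for r in records])


# ---------------------------------------------------------------------------
# operations

def normalize_channels(stack: DFIRStack) -> DFIRStack:
    """Min-max scale each channel independently to [0, 1] (the display
    convention for showing all chemical images on one intensity range)."""
    out = np.empty_like(stack.data)
    for c in range(stack.data.shape[0]):
        ch = stack.data[c]
        lo, hi = ch.min(), ch.max()
        if hi == lo:
            raise DegenerateSpectrumError(
                f"channel {stack.channel_wavenumbers[c]:g} cm^-1 is constant")
        out[c] = (ch - lo) / (hi - lo)
    return DFIRStack(out, stack.channel_wavenumbers.copy(),
                     stack.pixel_size_um, dict(stack.meta))


def threshold_mask(image: np.ndarray, threshold: float,
                   dark_particles: bool = False) -> ROIMask:
    """Foreground mask by global threshold (``>``, or ``<`` for dark
    particles on a bright background)."""
    image = np.asarray(image, dtype=float)
    if image.max() == image.min():
        raise DegenerateSpectrumError("constant image cannot be thresholded")
    m = image < threshold if dark_particles else image > threshold
    if not m.any():
        warnings.warn("threshold outside the image range: empty mask")
    return ROIMask(m, provenance="THRESHOLD")


def classify_pixels(stack: DFIRStack, mask: ROIMask, model: DiscriminantModel,
                    pixel_norm: str | None = None) -> ParticleLabelMap:
    """Score every masked pixel with the reduced model.

    Each pixel contributes a vector of channel intensities; with
    ``pixel_norm='snv'`` (the default for models trained in the matching
    ``vector_snv`` feature mode) that vector is SNV-normalized across the
    channels before scoring, so application features are built exactly like
    the training features; ``'raw'`` skips normalization.  Applying a model
    trained on full-spectrum-preprocessed features to bare pixel vectors is
    a train/apply mismatch and is warned about.
    """
    from .svm import FEAT_VECTOR_SNV

    if model.kind != KIND_REDUCED:
        raise ValueError("pixel classification requires the reduced model")
    if pixel_norm is None:
        pixel_norm = "snv"
    if model.feature_mode != FEAT_VECTOR_SNV:
        log.warning(
            "model was trained in feature mode %r but pixels only offer "
            "channel intensities; applying %s-normalized pixel vectors is a "
            "train/apply mismatch", model.feature_mode, pixel_norm)
    if stack.channel_wavenumbers.size != model.wavenumbers_used.size or \
            not np.allclose(stack.channel_wavenumbers, model.wavenumbers_used):
        raise ValueError(
            f"stack wavenumbers {stack.channel_wavenumbers.tolist()} do not "
            f"match model wavenumbers {model.wavenumbers_used.tolist()}")
    if mask.mask.shape != stack.shape:
        raise ValueError("mask shape does not match stack shape")
    classes = np.full(stack.shape, CLASS_UNLABELED, dtype=np.int8)
    idx = np.nonzero(mask.mask)
    vectors = stack.data[:, idx[0], idx[1]].T          # (n_pixels, n_channels)
    if pixel_norm == "snv":
        vectors = snv_array(vectors)
    elif pixel_norm != "raw":
        raise ValueError(f"unknown pixel_norm {pixel_norm!r}")
    scores = model.decision_scores(vectors)
    classes[idx] = np.where(scores > 0, CLASS_MP, CLASS_NONMP)
    return ParticleLabelMap(labels=np.zeros(stack.shape, dtype=int),
                            classes=classes)


def segment_particles(mask: ROIMask, connectivity: int = 8,
                      min_pixels: int = 2) -> ParticleLabelMap:
    """Connected components of the mask, ids in raster-scan order of each
    component's first pixel; components below ``min_pixels`` are dropped."""
    if not mask.mask.any():
        raise ValueError("empty mask: nothing to segment")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        raise ValueError("connectivity must be 4 or 8")
    raw, n = ndimage.label(mask.mask, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(raw), raw, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_pixels) + 1
    # scipy assigns labels in raster order already; re-number the survivors
    remap = np.zeros(n + 1, dtype=int)
    remap[keep] = np.arange(1, keep.size + 1)
    return ParticleLabelMap(labels=remap[raw])


def vote_particle_class(particles: ParticleLabelMap) -> list[tuple[int, str, float]]:
    """Majority vote per particle: MP iff MP pixels strictly outnumber
    non-MP pixels (tie -> NON_MP).  Returns (id, class, mp_vote_fraction)."""
    if particles.classes is None:
        raise ValueError("per-pixel classes are required for voting")
    out: list[tuple[int, str, float]] = []
    for pid in range(1, particles.n_particles + 1):
        sel = particles.labels == pid
        codes = particles.classes[sel]
        if np.any(codes == CLASS_UNLABELED):
            raise ValueError(f"particle {pid} contains unclassified pixels")
        n_mp = int(np.sum(codes == CLASS_MP))
        total = int(codes.size)
        cls = MP if n_mp > total - n_mp else NON_MP
        out.append((pid, cls, n_mp / total))
    return out


def morphometrics(particles: ParticleLabelMap,
                  pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                  votes: list[tuple[int, str, float]] | None = None
                  ) -> list[ParticleRecord]:
    """Area, fitted-ellipse axes and circularity per particle.

    Axis lengths come from the moment-equivalent ellipse (4 sqrt(eigenvalue)
    of the normalized second central moments); circularity is
    4*pi*area/perimeter^2 with the weighted contour-length perimeter
    estimator, capped at 1 since discretization can exceed it for small
    blobs.  Degenerate cases (single pixels, one-pixel-wide lines) floor the
    axes at one pixel size, since a pixel has physical extent.
    """
    if particles.n_particles == 0:
        raise ValueError("no particles to measure")
    vote_map = {pid: (cls, frac) for pid, cls, frac in votes} if votes else {}
    records: list[ParticleRecord] = []
    for prop in regionprops(particles.labels):
        pid = int(prop.label)
        n_px = int(prop.area)
        area = n_px * pixel_size_um ** 2
        if n_px == 1:
            length = width = pixel_size_um
            circ = 1.0
        else:
            length = max(prop.axis_major_length, 1.0) * pixel_size_um
            width = max(prop.axis_minor_length, 1.0) * pixel_size_um
            # computed in pixel units: dimensionless, exactly scale-free
            perim = prop.perimeter
            circ = min(1.0, 4.0 * np.pi * n_px / perim ** 2) if perim > 0 else 1.0
        cls, frac = vote_map.get(pid, ("", float("nan")))
        records.append(ParticleRecord(
            id=pid, particle_class=cls, mp_vote_fraction=frac,
            pixel_count=n_px, area_um2=area, length_um=length,
            width_um=width, circularity=circ,
        ))
    return records


def analyze_scene(stack: DFIRStack, mask: ROIMask, model: DiscriminantModel,
                  connectivity: int = 8, min_pixels: int = 2,
                  pixel_norm: str = "snv"
                  ) -> tuple[ParticleLabelMap, list[ParticleRecord]]:
    """Full application path: pixel classification, segmentation, votes,
    morphometry.  Returns the label map (with classes) and the records."""
    pixel_map = classify_pixels(stack, mask, model, pixel_norm=pixel_norm)
    seg = segment_particles(mask, connectivity=connectivity,
                            min_pixels=min_pixels)
    combined = ParticleLabelMap(labels=seg.labels, classes=pixel_map.classes)
    votes = vote_particle_class(combined)
    records = morphometrics(combined, stack.pixel_size_um, votes=votes)
    return combined, records
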