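"""Whole-filter quantification from subsampled regions.

Particles are counted in a handful of imaged regions (default: nine
480 um x 640 um rectangles evenly distributed over the active area of a
25 mm membrane filter whose outer 2.5 mm polypropylene ring is dead space),
and the counts are extrapolated to the whole filter by dividing by the
area-coverage fraction of the regions.  Replicate filters carry the
uncertainty: reported spreads are replicate standard deviations scaled by
the same factors as the means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .imaging import ParticleRecord
from .spectra import MP

log = logging.getLogger(__name__)


@dataclass
class FilterLayout:
    """Subsampling geometry on a circular filter (lengths in the stated units)."""

    filter_diameter_mm: float = 25.0
    active_diameter_mm: float = 20.0     # filter minus the 2.5 mm outer ring
    region_width_um: float = 640.0
    region_height_um: float = 480.0
    n_regions: int = 9
    region_coordinates: list[tuple[float, float]] = field(default_factory=list)
    coverage_override: float | None = None

    def __post_init__(self) -> None:
        if self.active_diameter_mm > self.filter_diameter_mm:
            raise ValueError("active diameter exceeds filter diameter")
        if not self.region_coordinates:
            self.region_coordinates = self._default_coordinates()
        if len(self.region_coordinates) != self.n_regions:
            raise ValueError("one coordinate per region required")
        r_active = self.active_diameter_mm / 2.0
        half_diag = math.hypot(self.region_width_um, self.region_height_um) / 2000.0
        for cx, cy in self.region_coordinates:
            if math.hypot(cx, cy) + half_diag > r_active + 1e-9:
                log.warning(
                    "region centered at (%g, %g) mm extends past the active "
                    "radius %g mm", cx, cy, r_active)

    def _default_coordinates(self) -> list[tuple[float, float]]:
        """Evenly distributed region centers: a 3x3 grid for 9 regions,
        otherwise a ring plus center, spaced inside the active area."""
        r = self.active_diameter_mm / 2.0
        if self.n_regions == 9:
            s = r / 2.0
            return [(x, y) for y in (s, 0.0, -s) for x in (-s, 0.0, s)]
        coords = [(0.0, 0.0)]
        for i in range(self.n_regions - 1):
            ang = 2 * math.pi * i / max(1, self.n_regions - 1)
            coords.append((0.6 * r * math.cos(ang), 0.6 * r * math.sin(ang)))
        return coords

    def region_area_mm2(self) -> float:
        return (self.region_width_um / 1000.0) * (self.region_height_um / 1000.0)

    def active_area_mm2(self) -> float:
        return math.pi * (self.active_diameter_mm / 2.0) ** 2

    def to_dict(self) -> dict:
        return {
            "filter_diameter_mm": self.filter_diameter_mm,
            "active_diameter_mm": self.active_diameter_mm,
            "region_um": [self.region_height_um, self.region_width_um],
            "n_regions": self.n_regions,
            "region_coordinates": [list(c) for c in self.region_coordinates],
            "coverage_override": self.coverage_override,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterLayout":
        region = d.get("region_um", [480.0, 640.0])
        return cls(
            filter_diameter_mm=d.get("filter_diameter_mm", 25.0),
            active_diameter_mm=d.get("active_diameter_mm", 20.0),
            region_height_um=region[0], region_width_um=region[1],
            n_regions=d.get("n_regions", 9),
            region_coordinates=[tuple(c) for c in d.get("region_coordinates", [])],
            coverage_override=d.get("coverage_override"),
        )


@dataclass
class RegionCounts:
    """Per-region MP and total particle counts for one replicate filter."""

    mp_counts: np.ndarray
    total_counts: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.mp_counts = np.asarray(self.mp_counts, dtype=float)
        self.total_counts = np.asarray(self.total_counts, dtype=float)
        if self.mp_counts.shape != self.total_counts.shape:
            raise ValueError("per-region count arrays differ in length")
        if np.any(self.mp_counts < 0) or np.any(self.mp_counts > self.total_counts):
            raise ValueError("need 0 <= MP count <= total count per region")

    @property
    def mp_total(self) -> float:
        return float(self.mp_counts.sum())


@dataclass
class QuantEstimate:
    mean_count: float
    sd_count: float
    coverage: float
    filter_total_mean: float
    filter_total_sd: float
    per_unit_mean: float | None = None
    per_unit_sd: float | None = None
    n_units: int | None = None

    def summary(self) -> dict:
        out = {
            "subsample_count": f"{self.mean_count:.1f} +/- {self.sd_count:.1f}",
            "coverage_fraction": self.coverage,
            "filter_total": f"{self.filter_total_mean:.1f} +/- {self.filter_total_sd:.1f}",
        }
        if self.n_units is not None:
            out["per_unit"] = f"{self.per_unit_mean:.1f} +/- {self.per_unit_sd:.1f}"
            out["n_units"] = self.n_units
        return out


@dataclass
class SphereSpec:
    """Reference microsphere stock used for the representativeness check."""

    density_g_cm3: float = 1.13
    diameter_low_um: float = 15.0
    diameter_high_um: float = 20.0
    nominal_mass_mg: float = 0.05

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.diameter_low_um >= self.diameter_high_um:
            raise ValueError("diameter range low must be below high")

    @property
    def mean_diameter_um(self) -> float:
        return 0.5 * (self.diameter_low_um + self.diameter_high_um)


# ---------------------------------------------------------------------------
# operations

def coverage_fraction(layout: FilterLayout) -> float:
    """Fraction of the active filter area covered by the subsampled regions.

    The default geometry (nine 480 x 640 um regions on a 20 mm active
    diameter) gives 0.880%; a ``coverage_override`` replaces the geometric
    value (and is logged) for matching an externally stated coverage.
    """
    if layout.coverage_override is not None:
        log.warning("using coverage_override=%g instead of geometric coverage",
                    layout.coverage_override)
        if not 0 < layout.coverage_override < 1:
            raise ValueError("coverage_override must lie in (0, 1)")
        return layout.coverage_override
    frac = layout.n_regions * layout.region_area_mm2() / layout.active_area_mm2()
    if not 0 < frac <= 1 + 1e-12:
        raise ValueError("regions exceed the active filter area")
    return min(frac, 1.0)


def extrapolate(counts: Sequence[float] | Sequence[RegionCounts],
                coverage: float) -> QuantEstimate:
    """Whole-filter estimate from replicate subsample counts.

    Each replicate's count (a number, or a RegionCounts whose MP counts are
    summed) is divided by the coverage fraction; mean and sd are taken over
    replicates, so the sd scales by the same 1/coverage factor.
    """
    if not 0 < coverage < 1 + 1e-12:
        raise ValueError("coverage must lie in (0, 1]")
    vals = np.array([c.mp_total if isinstance(c, RegionCounts) else float(c)
                     for c in counts])
    if vals.size == 0:
        raise ValueError("at least one replicate required")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return QuantEstimate(
        mean_count=mean, sd_count=sd, coverage=coverage,
        filter_total_mean=mean / coverage, filter_total_sd=sd / coverage,
    )


def per_unit(est: QuantEstimate, n_units: int) -> QuantEstimate:
    """Divide the whole-filter estimate evenly over ``n_units`` source items
    (e.g. three steeped teabags per filter)."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return QuantEstimate(
        mean_count=est.mean_count, sd_count=est.sd_count,
        coverage=est.coverage,
        filter_total_mean=est.filter_total_mean,
        filter_total_sd=est.filter_total_sd,
        per_unit_mean=est.filter_total_mean / n_units,
        per_unit_sd=est.filter_total_sd / n_units,
        n_units=n_units,
    )


def sphere_mass(count: float, spec: SphereSpec,
                diameter_um: float | None = None) -> float:
    """Mass in mg of ``count`` solid spheres of the given diameter.

    mass = count * density * pi d^3 / 6, with d in um converted to cm
    (1 um = 1e-4 cm) and g converted to mg.
    """
    d = spec.mean_diameter_um if diameter_um is None else diameter_um
    if d <= 0:
        raise ValueError("diameter must be positive")
    if not 1.0 <= d <= 100.0:
        raise ValueError(f"diameter {d} um outside the sanity range 1-100 um")
    if count < 0:
        raise ValueError("count must be non-negative")
    volume_cm3 = math.pi * (d * 1e-4) ** 3 / 6.0
    return count * spec.density_g_cm3 * volume_cm3 * 1000.0   # g -> mg


def representativeness_ratio(estimated_filter_mass_mg: float,
                             nominal_mass_mg: float) -> float:
    """Estimated-to-nominal mass ratio; > 1 flags overestimation."""
    if nominal_mass_mg <= 0:
        raise ValueError("nominal mass must be positive")
    ratio = estimated_filter_mass_mg / nominal_mass_mg
    if ratio > 1:
        log.info("representativeness ratio %.3f > 1: subsampling overestimates",
                 ratio)
    return ratio


def mp_all_ratio(records: Sequence[ParticleRecord]) -> float:
    """Fraction of detected particles classified as MP."""
    if len(records) == 0:
        raise ValueError("no particles: MP/All ratio undefined")
    n_mp = sum(1 for r in records if r.particle_class == MP)
    return n_mp / len(records)


@dataclass
class TreatmentComparison:
    statistic: float
    p_value: float
    significant: bool
    paired: bool
    alpha: float
    n_a: int
    n_b: int


def compare_treatments(a: Sequence[float], b: Sequence[float],
                       paired: bool = False,
                       alpha: float = 0.05) -> TreatmentComparison:
    """Two-sided t test of two groups of MP/All ratios.

    Paired comparisons (same filter regions before/after a treatment) use
    the paired t test; unpaired use Welch's unequal-variance t test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(stat):   # zero variance in the differences
        stat, p = 0.0, 1.0
    return TreatmentComparison(statistic=stat, p_value=p,
                               significant=p < alpha, paired=paired,
                               alpha=alpha, n_a=int(a.size), n_b=int(b.size))
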