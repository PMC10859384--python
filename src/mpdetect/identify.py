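"""Correlation-based particle identification.

For sparsely populated filter regions each particle is identified from up
to three point spectra taken at different spots, each compared against a
reference (parent-plastic) spectrum by Pearson correlation:

* any r > 0.7           -> MP
* max r in [0.6, 0.7]   -> MANUAL_REVIEW (human inspection of the peaks)
* max r < 0.6           -> NON_MP

Both boundaries are strict, so r exactly 0.6 or 0.7 falls in the manual
band.  The correlation may run over the full grid or be restricted to the
discriminative wavenumbers picked by the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import PreprocessSpec
from .spectra import DegenerateSpectrumError, Spectrum

log = logging.getLogger(__name__)

MP_THRESHOLD = 0.7
NONMP_THRESHOLD = 0.6

DECISION_MP = "MP"
DECISION_MANUAL = "MANUAL_REVIEW"
DECISION_NONMP = "NON_MP"


@dataclass
class CorrelationVerdict:
    particle_id: str
    r_values: tuple[float, ...]
    decision: str


def pearson_r(a: Spectrum, b: Spectrum,
              restrict: Sequence[float] | None = None) -> float:
    """Pearson correlation of two spectra on a shared grid.

    ``restrict`` optionally limits the comparison to the given wavenumbers
    (which must sit exactly on the grid).
    """
    if a.grid != b.grid:
        raise ValueError("spectra must share a wavenumber grid")
    x, y = a.intensity, b.intensity
    if restrict is not None:
        idx = a.grid.index_of(np.asarray(restrict, dtype=float))
        x, y = x[idx], y[idx]
    if x.size < 2:
        raise ValueError("need at least two points for correlation")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSpectrumError("zero-variance input to Pearson correlation")
    return float(np.corrcoef(x, y)[0, 1])


def decide_from_r(r_values: Sequence[float]) -> str:
    """Threshold rule on the spot correlations (pure function of r)."""
    r = np.asarray(r_values, dtype=float)
    if np.any(r > MP_THRESHOLD):
        return DECISION_MP
    if r.max() >= NONMP_THRESHOLD:
        return DECISION_MANUAL
    return DECISION_NONMP


def identify_particle(spot_spectra: Sequence[Spectrum], reference: Spectrum,
                      prep: PreprocessSpec | None = None,
                      restrict: Sequence[float] | None = None,
                      particle_id: str = "") -> CorrelationVerdict:
    """Apply the three-spot correlation rule to one particle.

    Each spot spectrum and the reference are run through ``prep`` before
    correlating.  Fewer than three spots are accepted with a warning (small
    particles may not offer three distinct spots); the rule is applied to
    the spots present.
    """
    if len(spot_spectra) == 0:
        raise ValueError("at least one spot spectrum is required")
    if len(spot_spectra) != 3:
        log.warning("particle %s: %d spot spectra instead of 3",
                    particle_id or "?", len(spot_spectra))
    prep = prep or PreprocessSpec()
    ref = prep.apply(reference)
    r_values = tuple(pearson_r(prep.apply(s), ref, restrict=restrict)
                     for s in spot_spectra)
    return CorrelationVerdict(particle_id, r_values, decide_from_r(r_values))
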