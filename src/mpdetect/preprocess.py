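"""Spectral preprocessing: SNV, Savitzky-Golay smoothing, asymmetric
least-squares baseline removal and min-max normalization.

The chain an instrument operator would run before library matching is
smoothing -> baseline removal -> normalization; model training uses SNV
alone.  ``PreprocessSpec`` serializes an ordered chain of these steps so a
trained model can carry its exact preprocessing with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .spectra import DegenerateSpectrumError, Spectrum


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum centering and scaling to unit
    sample (n-1) standard deviation, removing multiplicative scatter."""
    y = s.intensity
    if y.size < 2:
        raise ValueError("SNV requires at least two points")
    sd = y.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError(
            f"constant spectrum (sd=0), cannot SNV: meta={s.meta!r}"
        )
    return s.with_intensity((y - y.mean()) / sd)


def snv_array(Y: np.ndarray) -> np.ndarray:
    """Row-wise SNV on a 2-D intensity array."""
    Y = np.asarray(Y, dtype=float)
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("constant row encountered in SNV")
    return (Y - Y.mean(axis=1, keepdims=True)) / sd


def savgol_smooth(s: Spectrum, poly_order: int = 3, side_points: int = 7) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing.

    ``side_points`` is the half-window, so the window is 2*side_points + 1
    (15 points by default).  Edges are handled by mirror reflection so the
    output keeps the input length without extrapolating a trend.
    """
    window = 2 * side_points + 1
    if window > len(s.grid):
        raise ValueError(
            f"window {window} exceeds spectrum length {len(s.grid)}"
        )
    if poly_order >= window:
        raise ValueError("polynomial order must be below the window length")
    return s.with_intensity(
        savgol_filter(s.intensity, window_length=window, polyorder=poly_order,
                      mode="mirror")
    )


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                 n_iter: int = 10) -> np.ndarray:
    """Asymmetric least-squares baseline estimate (Eilers-Boelens style).

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((d2 z)^2) where the
    asymmetry weights w_i are p above the baseline and 1-p below, so the
    smooth curve z hugs the low envelope of the spectrum.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input to baseline estimation")
    n = y.size
    D = sp.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2), format="csc")
    penalty = lam * (D @ D.T)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        W = sp.diags(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(s: Spectrum, lam: float = 1e5, p: float = 0.01,
                     n_iter: int = 10) -> Spectrum:
    """Subtract the ALS-estimated smooth baseline from the spectrum."""
    return s.with_intensity(s.intensity - als_baseline(s.intensity, lam, p, n_iter))


def minmax_normalize(s: Spectrum) -> Spectrum:
    """Scale the spectrum linearly to the [0, 1] range."""
    y = s.intensity
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise DegenerateSpectrumError(
            f"constant spectrum, cannot min-max normalize: meta={s.meta!r}"
        )
    return s.with_intensity((y - lo) / (hi - lo))


@dataclass
class PreprocessSpec:
    """Ordered, serializable preprocessing chain.

    Each step is a mapping with a ``name`` key in {snv, savgol, baseline,
    minmax} plus that step's explicit parameters.  Applying the same spec
    twice to the same input yields identical output (all steps are
    deterministic).
    """

    steps: list[dict[str, Any]] = field(default_factory=list)

    _KNOWN = {"snv", "savgol", "baseline", "minmax"}

    def __post_init__(self) -> None:
        for st in self.steps:
            if st.get("name") not in self._KNOWN:
                raise ValueError(f"unknown preprocessing step: {st!r}")

    def apply(self, s: Spectrum) -> Spectrum:
        for st in self.steps:
            name = st["name"]
            if name == "snv":
                s = snv(s)
            elif name == "savgol":
                s = savgol_smooth(s, st.get("poly_order", 3), st.get("side_points", 7))
            elif name == "baseline":
                s = baseline_correct(s, st.get("lam", 1e5), st.get("p", 0.01),
                                     st.get("n_iter", 10))
            elif name == "minmax":
                s = minmax_normalize(s)
        return s

    def apply_array(self, grid, Y: np.ndarray) -> np.ndarray:
        """Row-wise application to a 2-D intensity array."""
        from .spectra import Spectrum as _S  # local to avoid cycle at import

        if self.steps == [{"name": "snv"}]:  # vectorized fast path
            return snv_array(Y)
        return np.stack([self.apply(_S(grid, row)).intensity for row in Y])

    def to_dict(self) -> dict:
        return {"steps": [dict(st) for st in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(steps=[dict(st) for st in d["steps"]])


def snv_spec() -> PreprocessSpec:
    """The model-training default: SNV only."""
    return PreprocessSpec(steps=[{"name": "snv"}])


def conventional_spec() -> PreprocessSpec:
    """The point-spectrum identification chain: smoothing (order 3, 7 side
    points), ALS baseline removal, then scaling to [0, 1]."""
    return PreprocessSpec(steps=[
        {"name": "savgol", "poly_order": 3, "side_points": 7},
        {"name": "baseline", "lam": 1e5, "p": 0.01, "n_iter": 10},
        {"name": "minmax"},
    ])
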