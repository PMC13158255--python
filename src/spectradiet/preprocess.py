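"""Spectral preprocessing for ATR-FTIR chemometrics.

The canonical order of operations, mirroring standard OPUS-style workflows, is

1. vector-normalize each replicate spectrum,
2. average replicates per sample,
3. excise the CO2 / ATR-crystal region (default 1800-2500 cm-1),
4. optionally compute Savitzky-Golay second derivatives for band resolution.

Order matters: normalizing before averaging weights each replicate equally
regardless of the absolute signal level it was recorded at; averaging first
would let high-throughput replicates dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import savgol_filter

from .errors import DataError, DegenerateInputError, ValidationError
from .io import Spectrum

NormMode = Literal["plain_unit_norm", "center_then_unit_norm"]


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    excise_lo / excise_hi
        Closed interval of wavenumbers (cm-1) removed before multivariate
        analysis; defaults bracket the atmospheric-CO2 / ATR-crystal region.
    sg_window, sg_polyorder
        Savitzky-Golay window (odd point count, default 9 points) and fitting
        polynomial order for second-derivative spectra.
    normalization_mode
        ``plain_unit_norm`` scales to unit Euclidean norm;
        ``center_then_unit_norm`` subtracts the mean first (the variant some
        vendor implementations of vector normalization use).
    peak_min_prominence
        Topographic prominence threshold for the automated peak search.
    """

    excise_lo: float = 1800.0
    excise_hi: float = 2500.0
    sg_window: int = 9
    sg_polyorder: int = 2
    normalization_mode: NormMode = "plain_unit_norm"
    peak_min_prominence: float = 0.001

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValidationError(
                f"sg_window must be odd and > sg_polyorder; got "
                f"{self.sg_window}/{self.sg_polyorder}"
            )
        if not self.excise_lo < self.excise_hi:
            raise ValidationError("excise_lo must be < excise_hi")
        if self.normalization_mode not in ("plain_unit_norm", "center_then_unit_norm"):
            raise ValidationError(f"unknown normalization mode {self.normalization_mode!r}")


def vector_normalize(s: Spectrum, mode: NormMode = "plain_unit_norm") -> Spectrum:
    """Scale a spectrum to unit Euclidean norm (optionally after mean centering)."""
    a = s.absorbance
    if mode == "center_then_unit_norm":
        a = a - a.mean()
    elif mode != "plain_unit_norm":
        raise ValidationError(f"unknown normalization mode {mode!r}")
    norm = float(np.linalg.norm(a))
    if norm == 0.0:
        what = "constant" if mode == "center_then_unit_norm" else "all-zero"
        raise DegenerateInputError(f"cannot normalize {what} spectrum {s.key()}")
    return s.with_values(absorbance=a / norm)


def average_replicates(replicates: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra; returns the averaged sample spectrum.

    All replicates must share the sample id and the exact wavenumber grid.
    """
    if not replicates:
        raise DegenerateInputError("no replicates to average")
    first = replicates[0]
    for r in replicates[1:]:
        if not np.array_equal(r.wavenumbers, first.wavenumbers):
            raise DataError(
                f"grid mismatch between replicates {first.key()} and {r.key()}"
            )
        if r.sample_id != first.sample_id:
            raise DataError(
                f"replicates from different samples: {first.sample_id!r} vs {r.sample_id!r}"
            )
    mean = np.mean([r.absorbance for r in replicates], axis=0)
    return Spectrum(
        wavenumbers=first.wavenumbers.copy(),
        absorbance=mean,
        sample_id=first.sample_id,
        replicate_id=None,
    )


def excise_region(s: Spectrum, lo: float = 1800.0, hi: float = 2500.0) -> Spectrum:
    """Remove all grid points with ``lo <= w <= hi`` (closed interval).

    Points outside the interval keep their values and order. Used to drop the
    atmospheric-CO2 / ATR-crystal region that carries no plant signal.
    """
    if not lo < hi:
        raise ValidationError(f"excision interval inverted: [{lo}, {hi}]")
    keep = (s.wavenumbers < lo) | (s.wavenumbers > hi)
    if not keep.any():
        raise DegenerateInputError(
            f"excising [{lo}, {hi}] would leave spectrum {s.key()} empty"
        )
    return s.with_values(
        wavenumbers=s.wavenumbers[keep], absorbance=s.absorbance[keep]
    )


def _uniform_spacing(wavenumbers: np.ndarray) -> float:
    diffs = np.diff(wavenumbers)
    if diffs.size == 0:
        raise DegenerateInputError("spectrum too short for derivative work")
    step = diffs[0]
    if not np.allclose(diffs, step, rtol=1e-8, atol=1e-10):
        raise DataError(
            "non-uniform wavenumber grid; resample with resample_uniform() first"
        )
    return float(step)


def resample_uniform(s: Spectrum, step: float | None = None) -> Spectrum:
    """Linearly interpolate a spectrum onto a uniform grid.

    ``step`` defaults to the modal absolute spacing of the input grid. The grid
    direction (ascending/descending) is preserved. Interpolation is explicit:
    derivative operations refuse non-uniform grids rather than resampling
    silently.
    """
    w = s.wavenumbers
    diffs = np.abs(np.diff(w))
    if diffs.size == 0:
        raise DegenerateInputError("cannot resample a single-point spectrum")
    if step is None:
        vals, counts = np.unique(np.round(diffs, 6), return_counts=True)
        step = float(vals[np.argmax(counts)])
    if step <= 0:
        raise ValidationError("resampling step must be positive")
    descending = w[0] > w[-1]
    lo, hi = (w[-1], w[0]) if descending else (w[0], w[-1])
    n = int(np.floor((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    asc_w = w[::-1] if descending else w
    asc_a = s.absorbance[::-1] if descending else s.absorbance
    interp = np.interp(grid, asc_w, asc_a)
    if descending:
        grid, interp = grid[::-1], interp[::-1]
    return s.with_values(wavenumbers=grid, absorbance=interp)


def second_derivative(s: Spectrum, window: int = 9, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay second derivative w.r.t. wavenumber (absorbance * cm^2).

    Requires a uniform grid. The output is shrunk to interior points — the
    half-window at each edge, where the filter would implicitly extrapolate,
    is dropped. Band minima of the second derivative sit at absorbance maxima,
    which is what makes this useful for resolving overlapping bands.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValidationError(f"window must be odd and > polyorder; got {window}/{polyorder}")
    if polyorder < 2:
        raise ValidationError("second derivative needs polyorder >= 2")
    if len(s) < window:
        raise DegenerateInputError(
            f"spectrum {s.key()} shorter ({len(s)}) than SG window ({window})"
        )
    step = _uniform_spacing(s.wavenumbers)
    deriv = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, deriv=2, delta=step
    )
    half = window // 2
    return s.with_values(
        wavenumbers=s.wavenumbers[half:-half], absorbance=deriv[half:-half]
    )


def find_peaks(s: Spectrum, min_prominence: float = 0.001) -> list[tuple[float, float]]:
    """Local absorbance maxima with topographic prominence >= ``min_prominence``.

    Returns ``(wavenumber, absorbance)`` pairs sorted by descending height, an
    automated surrogate for a vendor single-peak search.
    """
    idx, _ = _scipy_find_peaks(s.absorbance, prominence=min_prominence)
    peaks = [(float(s.wavenumbers[i]), float(s.absorbance[i])) for i in idx]
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return peaks


def preprocess_sample(
    replicates: list[Spectrum], config: PreprocessConfig | None = None
) -> Spectrum:
    """Normalize each replicate, average, and excise: one call per sample."""
    config = config or PreprocessConfig()
    normalized = [vector_normalize(r, config.normalization_mode) for r in replicates]
    averaged = average_replicates(normalized)
    return excise_region(averaged, config.excise_lo, config.excise_hi)
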