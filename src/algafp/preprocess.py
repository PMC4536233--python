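"""Profile-spectrum preprocessing: smoothing, baseline removal, noise
estimation, mass-axis calibration, and acquisition quality gating."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .io_formats import ProfileSpectrum

# Protein calibrant mixture: (name, reference mass in Da)
DEFAULT_CALIBRANTS: list[tuple[str, float]] = [
    ("ACTH 1-17", 2093.46),
    ("ACTH 18-39", 2464.19),
    ("Insulin Oxidized B", 3494.65),
    ("Insulin", 5730.61),
    ("Cytochrome C", 12362.00),
    ("Apomyoglobin", 16952.30),
]


@dataclass
class QualityParams:
    """Acceptance thresholds for a single-burst spectrum.

    All thresholds are inclusive. ``peak_width`` is interpreted as the
    maximum allowed FWHM of the base peak by default; set
    ``width_is_minimum=True`` for the opposite reading.
    """

    snr_min: float = 2.0
    peak_width: float = 10.0
    intensity_min: float = 100.0
    max_peaks: int = 500
    width_is_minimum: bool = False

    def __post_init__(self) -> None:
        for name in ("snr_min", "peak_width", "intensity_min", "max_peaks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class CalibrantSet:
    calibrants: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_CALIBRANTS)
    )

    def __post_init__(self) -> None:
        masses = self.reference_masses
        if len(masses) < 2:
            raise ValueError("need at least 2 calibrants for fitting")
        if np.any(np.diff(masses) <= 0):
            raise ValueError("reference masses must be strictly increasing")

    @property
    def reference_masses(self) -> np.ndarray:
        return np.array([m for _, m in self.calibrants], dtype=float)


def smooth_savitzky_golay(
    s: ProfileSpectrum, window_points: int = 9, poly_order: int = 3
) -> ProfileSpectrum:
    """Savitzky-Golay smoothing on the spectrum's own grid.

    Edge windows are handled by evaluating the terminal local polynomial
    fits (scipy's ``interp`` mode).
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points <= poly_order:
        raise ValueError("window_points must exceed poly_order")
    if len(s) < window_points:
        raise ValueError(
            f"spectrum has {len(s)} points, fewer than window_points={window_points}"
        )
    smoothed = scipy.signal.savgol_filter(
        s.intensity, window_length=window_points, polyorder=poly_order, mode="interp"
    )
    return s.replace_intensity(smoothed)


def _points_for_width(s: ProfileSpectrum, width_da: float) -> int:
    """Convert a width in Da to an odd number of grid points (median spacing)."""
    spacing = float(np.median(np.diff(s.mz))) if len(s) > 1 else 1.0
    n = max(3, int(round(width_da / spacing)))
    return n + 1 if n % 2 == 0 else n


def subtract_baseline_tophat(
    s: ProfileSpectrum, element_width: float = 150.0
) -> ProfileSpectrum:
    """Top-hat baseline removal: subtract the morphological opening
    (erosion then dilation with a flat element of ``element_width`` Da)."""
    if element_width <= 0:
        raise ValueError("element_width must be > 0")
    size = _points_for_width(s, element_width)
    opened = scipy.ndimage.grey_opening(s.intensity, size=size, mode="nearest")
    corrected = s.intensity - opened
    corrected[corrected < 0] = 0.0
    return s.replace_intensity(corrected)


# MAD of a standard normal is 0.6745 sigma
_MAD_TO_SD = 1.4826


def estimate_noise(s: ProfileSpectrum) -> float:
    """Robust noise scale: median absolute deviation of the intensity,
    scaled to be consistent with a normal standard deviation."""
    if len(s) == 0:
        raise ValueError("empty spectrum")
    x = s.intensity
    med = np.median(x)
    return float(_MAD_TO_SD * np.median(np.abs(x - med)))


def calibrate_mass_axis(
    s: ProfileSpectrum,
    observed: list[float] | np.ndarray,
    refs: CalibrantSet | None = None,
    model: str = "linear",
) -> tuple[ProfileSpectrum, float]:
    """Least-squares mass-axis recalibration against a calibrant set.

    ``observed`` are the measured m/z of the calibrants, paired in order
    with ``refs``. Returns the corrected spectrum and the maximum absolute
    fit residual (Da).
    """
    refs = refs if refs is not None else CalibrantSet()
    observed = np.asarray(observed, dtype=float)
    reference = refs.reference_masses
    if len(observed) != len(reference):
        raise ValueError(
            f"{len(observed)} observed masses but {len(reference)} calibrants"
        )
    degree = {"linear": 1, "quadratic": 2}.get(model)
    if degree is None:
        raise ValueError(f"unknown calibration model {model!r}")
    if len(observed) < degree + 1:
        raise ValueError(f"{model} model needs >= {degree + 1} calibrants")
    # fit on a scaled domain: raw powers of m/z are badly conditioned
    fit = np.polynomial.Polynomial.fit(observed, reference, degree)
    residuals = fit(observed) - reference
    corrected_mz = fit(s.mz)
    if np.any(np.diff(corrected_mz) <= 0):
        raise ValueError("calibration produced a non-monotone mass axis")
    lo, hi = s.mass_window
    eps = 1e-6  # tolerate float round-off at the window edges
    keep = (corrected_mz >= lo - eps) & (corrected_mz <= hi + eps)
    corrected_mz = np.clip(corrected_mz, lo, hi)
    out = ProfileSpectrum(
        mz=corrected_mz[keep],
        intensity=s.intensity[keep],
        sample_id=s.sample_id,
        replicate_index=s.replicate_index,
        burst_index=s.burst_index,
        mass_window=s.mass_window,
        metadata=dict(s.metadata),
    )
    return out, float(np.max(np.abs(residuals)))


def burst_quality_gate(
    peaks: pd.DataFrame, q: QualityParams | None = None
) -> tuple[bool, str | None]:
    """Accept or reject the peak list of one shot burst.

    Returns ``(accepted, reason)``; ``reason`` names the first failed
    criterion (``snr``, ``intensity``, ``width``, ``max_peaks``) or is
    None on acceptance. All thresholds are inclusive.
    """
    q = q if q is not None else QualityParams()
    if len(peaks) == 0:
        return False, "no peaks"
    base = peaks.loc[peaks["intensity"].idxmax()]
    if base["snr"] < q.snr_min:
        return False, "snr"
    if base["intensity"] < q.intensity_min:
        return False, "intensity"
    if q.width_is_minimum:
        if base["width"] < q.peak_width:
            return False, "width"
    elif base["width"] > q.peak_width:
        return False, "width"
    if len(peaks) > q.max_peaks:
        return False, "max_peaks"
    return True, None


def preprocess_spectrum(
    s: ProfileSpectrum,
    window_points: int = 9,
    poly_order: int = 3,
    element_width: float = 150.0,
) -> ProfileSpectrum:
    """Default preprocessing chain: Savitzky-Golay smoothing followed by
    top-hat baseline subtraction."""
    return subtract_baseline_tophat(
        smooth_savitzky_golay(s, window_points, poly_order), element_width
    )
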