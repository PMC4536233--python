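"""Synthetic spectra, replicates, mixtures, and sequence pairs with ground
truth attached, so every pipeline stage can be tested end to end.

All randomness flows through ``numpy.random.default_rng`` seeded by the
caller; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DEFAULT_MASS_WINDOW, ProfileSpectrum

MIN_PEAK_SEPARATION = 4.0
DEFAULT_PEAK_BOUNDS = (6, 56)


@dataclass
class StrainTemplate:
    strain_id: str
    positions: np.ndarray          # peak m/z, sorted
    intensities: np.ndarray        # mean apex intensities (a.u.)
    intensity_cv: float = 0.15     # replicate-to-replicate multiplicative CV
    peak_width: float = 10.0       # Gaussian FWHM in Da
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions/intensities length mismatch")
        if np.any(np.diff(self.positions) < MIN_PEAK_SEPARATION):
            raise ValueError(
                f"peak positions must be >= {MIN_PEAK_SEPARATION} Da apart"
            )

    @property
    def n_peaks(self) -> int:
        return len(self.positions)


@dataclass
class NoiseModel:
    additive_sd: float = 8.0
    baseline_amplitude: float = 60.0
    baseline_scale: float = 3000.0   # Da length-scale of the drift
    # chosen so replicate-to-replicate centroid differences (sd*sqrt(2))
    # stay within the +/-2 Da match tolerance with high probability
    mz_jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "baseline_amplitude", "baseline_scale", "mz_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MixtureDesign:
    constituents: list[StrainTemplate]
    proportions: list[float]
    suppression: list[float] | None = None
    injected_peaks: list[tuple[float, float]] = field(default_factory=list)
    mixture_id: str = "mixture"

    def __post_init__(self) -> None:
        if self.suppression is None:
            self.suppression = [1.0] * len(self.constituents)
        if not (
            len(self.constituents) == len(self.proportions) == len(self.suppression)
        ):
            raise ValueError("constituents/proportions/suppression length mismatch")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if any(not (0.0 <= s <= 1.0) for s in self.suppression):
            raise ValueError("suppression factors must be in [0, 1]")


def make_template(
    seed: int,
    n_peaks: int,
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
    strain_id: str | None = None,
    peak_bounds: tuple[int, int] = DEFAULT_PEAK_BOUNDS,
    base_intensity: float = 1500.0,
    min_separation: float = 25.0,
    avoid_positions: np.ndarray | list[float] | None = None,
) -> StrainTemplate:
    """Draw a strain template: peak positions uniform in the window with a
    minimum separation, intensities log-normal around ``base_intensity``.
    Deterministic for a fixed seed.

    ``min_separation`` defaults to 25 Da so that adjacent peaks stay
    resolvable at a ~10 Da FWHM and unambiguous at the +/-2 Da match
    tolerance; the hard floor of the template type itself is 4 Da.
    ``avoid_positions`` keeps the drawn peaks at least ``min_separation``
    away from another template's peaks (for controlled mixture designs
    where cross-strain peak overlap would confound attribution).
    """
    lo_n, hi_n = peak_bounds
    if not (lo_n <= n_peaks <= hi_n):
        raise ValueError(f"n_peaks must be within [{lo_n}, {hi_n}]")
    if min_separation < MIN_PEAK_SEPARATION:
        raise ValueError(f"min_separation must be >= {MIN_PEAK_SEPARATION}")
    lo, hi = mass_window
    margin = 50.0
    if (hi - lo - 2 * margin) / min_separation < n_peaks:
        raise ValueError("window too narrow for requested peak count")
    rng = np.random.default_rng(seed)
    avoid = np.asarray(avoid_positions, dtype=float) if avoid_positions is not None else np.array([])
    positions: list[float] = []
    attempts = 0
    while len(positions) < n_peaks:
        attempts += 1
        if attempts > 100000:
            raise ValueError("could not place peaks with required separation")
        cand = rng.uniform(lo + margin, hi - margin)
        if positions and min(abs(cand - p) for p in positions) < min_separation:
            continue
        if len(avoid) and np.min(np.abs(avoid - cand)) < min_separation:
            continue
        positions.append(cand)
    positions.sort()
    intensities = base_intensity * rng.lognormal(mean=0.0, sigma=0.7, size=n_peaks)
    return StrainTemplate(
        strain_id=strain_id if strain_id is not None else f"strain_{seed}",
        positions=np.array(positions),
        intensities=intensities,
        mass_window=mass_window,
    )


def _gaussian_trace(
    grid: np.ndarray, positions: np.ndarray, heights: np.ndarray, fwhm: float
) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    trace = np.zeros_like(grid)
    for pos, h in zip(positions, heights):
        window = np.abs(grid - pos) < 6 * sigma
        trace[window] += h * np.exp(-0.5 * ((grid[window] - pos) / sigma) ** 2)
    return trace


def _baseline(grid: np.ndarray, nm: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if nm.baseline_amplitude == 0:
        return np.zeros_like(grid)
    lo = grid[0]
    span = grid[-1] - grid[0]
    phase = rng.uniform(0, 2 * np.pi)
    decay = np.exp(-(grid - lo) / nm.baseline_scale)
    ripple = 0.3 * (1 + np.sin(2 * np.pi * (grid - lo) / (4 * nm.baseline_scale) + phase))
    return nm.baseline_amplitude * (decay + ripple)


def simulate_spectrum(
    t: StrainTemplate,
    nm: NoiseModel | None = None,
    replicate_index: int = 1,
    sample_id: str | None = None,
) -> ProfileSpectrum:
    """Sample one profile spectrum on a 1 Da grid: Gaussian peaks plus a
    smooth drifting baseline plus additive Gaussian noise.

    Ground truth (jittered positions and drawn heights) is attached under
    ``metadata['truth']``.
    """
    nm = nm if nm is not None else NoiseModel()
    rng = np.random.default_rng((nm.seed, zlib.crc32(t.strain_id.encode()), replicate_index))
    lo, hi = t.mass_window
    grid = np.arange(lo, hi + 1.0, 1.0)
    jitter = rng.normal(0.0, nm.mz_jitter_sd, size=t.n_peaks)
    positions = np.clip(t.positions + jitter, lo + 1, hi - 1)
    heights = t.intensities * rng.lognormal(
        mean=0.0, sigma=t.intensity_cv, size=t.n_peaks
    )
    trace = _gaussian_trace(grid, positions, heights, t.peak_width)
    trace += _baseline(grid, nm, rng)
    trace += rng.normal(0.0, nm.additive_sd, size=grid.shape)
    trace[trace < 0] = 0.0
    return ProfileSpectrum(
        mz=grid,
        intensity=trace,
        sample_id=sample_id if sample_id is not None else t.strain_id,
        replicate_index=replicate_index,
        mass_window=t.mass_window,
        metadata={
            "truth": {
                "positions": positions,
                "heights": heights,
                "template_positions": t.positions.copy(),
            }
        },
    )


def simulate_replicates(
    t: StrainTemplate, nm: NoiseModel | None = None, n: int = 3
) -> list[ProfileSpectrum]:
    """``n`` replicate spectra sharing the template, independent noise."""
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    return [simulate_spectrum(t, nm, replicate_index=i + 1) for i in range(n)]


def mixture_template(md: MixtureDesign) -> StrainTemplate:
    """Combine constituent templates into one template: each strain's
    intensities scaled by proportion x suppression; injected novel peaks
    appended verbatim. Peaks closer than the separation floor merge by
    intensity sum."""
    entries: list[tuple[float, float]] = []
    for tmpl, prop, sup in zip(md.constituents, md.proportions, md.suppression):
        scale = prop * sup
        if scale <= 0:
            continue
        for pos, inten in zip(tmpl.positions, tmpl.intensities):
            entries.append((float(pos), float(inten) * scale))
    for pos, inten in md.injected_peaks:
        entries.append((float(pos), float(inten)))
    entries.sort()
    merged: list[tuple[float, float]] = []
    for pos, inten in entries:
        if merged and pos - merged[-1][0] < MIN_PEAK_SEPARATION:
            prev_pos, prev_int = merged[-1]
            total = prev_int + inten
            merged[-1] = ((prev_pos * prev_int + pos * inten) / total, total)
        else:
            merged.append((pos, inten))
    positions = np.array([p for p, _ in merged])
    intensities = np.array([i for _, i in merged])
    window = md.constituents[0].mass_window
    return StrainTemplate(
        strain_id=md.mixture_id,
        positions=positions,
        intensities=intensities,
        peak_width=md.constituents[0].peak_width,
        mass_window=window,
    )


def expected_mixture_labels(md: MixtureDesign) -> dict[str, list[float]]:
    """Designed ground-truth labels: a constituent peak is expected
    suppressed (P) iff its strain's suppression factor is 0; injected
    peaks are expected mixture-specific (S)."""
    expected_m: list[float] = []
    expected_p: list[float] = []
    for tmpl, sup in zip(md.constituents, md.suppression):
        target = expected_p if sup == 0.0 else expected_m
        target.extend(float(p) for p in tmpl.positions)
    return {
        "M": sorted(expected_m),
        "P": sorted(expected_p),
        "S": sorted(float(p) for p, _ in md.injected_peaks),
    }


def simulate_mixture(
    md: MixtureDesign, nm: NoiseModel | None = None, n_replicates: int = 1
) -> list[ProfileSpectrum]:
    """Simulate mixture spectra (``n_replicates`` of them) with expected
    M/P/S ground truth attached under ``metadata['truth']['expected_labels']``."""
    tmpl = mixture_template(md)
    expected = expected_mixture_labels(md)
    if n_replicates == 1:
        spectra = [simulate_spectrum(tmpl, nm, replicate_index=1)]
    else:
        spectra = simulate_replicates(tmpl, nm, n=n_replicates)
    for s in spectra:
        s.metadata["truth"]["expected_labels"] = expected
    return spectra


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def mutate_sequence(
    seq: str,
    n_transitions: int,
    n_transversions: int,
    n_gaps: int = 0,
    seed: int = 0,
) -> tuple[str, str]:
    """Return an aligned (original, mutated) pair with exactly the
    requested numbers of transitions, transversions, and one-sided gap
    columns, all at distinct positions."""
    seq = seq.upper().replace("U", "T")
    usable = [i for i, ch in enumerate(seq) if ch in _BASES_STR]
    total = n_transitions + n_transversions + n_gaps
    if total > len(usable):
        raise ValueError("requested event count exceeds usable sequence length")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(usable), size=total, replace=False)
    sites = [usable[i] for i in chosen]
    mutated = list(seq)
    k = 0
    for _ in range(n_transitions):
        i = sites[k]; k += 1
        mutated[i] = _TRANSITION[mutated[i]]
    for _ in range(n_transversions):
        i = sites[k]; k += 1
        mutated[i] = _TRANSVERSIONS[mutated[i]][rng.integers(2)]
    for _ in range(n_gaps):
        i = sites[k]; k += 1
        mutated[i] = "-"
    return seq, "".join(mutated)


_BASES_STR = "ACGT"


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_BASES_STR), size=length))
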