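"""Centroided peak detection, tolerance-based peak matching, all-replicate
consensus lists, composite (summary) spectra, and per-spectrum statistics.

Two peaks are the same feature iff their m/z differ by at most the match
tolerance (default 2 Da, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from . import fingerprint_clustering as fpc
from .io_formats import ProfileSpectrum
from .preprocess import estimate_noise

DEFAULT_TOLERANCE = 2.0
DEFAULT_COMPOSITE_THRESHOLD = 0.65


@dataclass
class MatchTolerance:
    tol: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ConsensusPeak:
    mz: float
    intensity: float
    support: int


@dataclass
class ConsensusPeakList:
    sample_id: str
    peaks: list[ConsensusPeak]

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "mz": [p.mz for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
                "support": [p.support for p in self.peaks],
            }
        )


@dataclass
class CompositeSpectrum:
    sample_id: str
    included_replicates: list[int]
    excluded_replicates: list[tuple[int, float]]
    mz: np.ndarray
    intensity: np.ndarray
    similarity_threshold: float = DEFAULT_COMPOSITE_THRESHOLD
    replicate_scores: dict[int, float] = field(default_factory=dict)


def detect_peaks(s: ProfileSpectrum, snr_min: float = 2.0) -> pd.DataFrame:
    """Detect centroided peaks in a preprocessed (smoothed,
    baseline-subtracted) spectrum.

    A peak is a local maximum whose apex intensity is at least
    ``snr_min`` times the global robust noise. The centroid is the
    intensity-weighted mean m/z over the contiguous points above half
    maximum; the width is the FWHM estimated by linear interpolation.
    Returns a peak table sorted by m/z.
    """
    empty = pd.DataFrame(
        {"sample_id": pd.Series(dtype=str)}
        | {c: pd.Series(dtype=float) for c in ("mz", "intensity", "snr", "width")}
    )
    if len(s) < 3:
        return empty
    noise = estimate_noise(s)
    intensity = s.intensity
    if noise == 0:
        positive = intensity[intensity > 0]
        if len(positive) == 0:
            return empty
        # all-signal spectrum (no noise floor): keep every local maximum
        threshold = 0.0
    else:
        threshold = snr_min * noise
    apex_idx, _ = scipy.signal.find_peaks(intensity, height=max(threshold, 1e-12))
    rows = []
    for idx in apex_idx:
        apex = intensity[idx]
        half = apex / 2.0
        lo = idx
        while lo > 0 and intensity[lo - 1] >= half and intensity[lo - 1] <= intensity[lo]:
            lo -= 1
        hi = idx
        n = len(intensity)
        while hi < n - 1 and intensity[hi + 1] >= half and intensity[hi + 1] <= intensity[hi]:
            hi += 1
        seg = slice(lo, hi + 1)
        weights = intensity[seg]
        centroid = float(np.average(s.mz[seg], weights=weights))
        # FWHM: interpolate the half-maximum crossings on either flank
        left = s.mz[lo]
        if lo > 0 and intensity[lo - 1] < half:
            left = np.interp(half, [intensity[lo - 1], intensity[lo]], [s.mz[lo - 1], s.mz[lo]])
        right = s.mz[hi]
        if hi < n - 1 and intensity[hi + 1] < half:
            right = np.interp(
                half, [intensity[hi + 1], intensity[hi]], [s.mz[hi + 1], s.mz[hi]]
            )
        width = float(right - left)
        snr = float(apex / noise) if noise > 0 else float("inf")
        rows.append((s.sample_id, centroid, float(apex), snr, width))
    if not rows:
        return empty
    table = pd.DataFrame(rows, columns=["sample_id", "mz", "intensity", "snr", "width"])
    return table.sort_values("mz", ignore_index=True)


def match_peaks(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    t: MatchTolerance | float = DEFAULT_TOLERANCE,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-neighbor matching of two sorted peak m/z lists.

    Candidate pairs within tolerance are accepted in order of ascending
    |Δmz|; each peak is used at most once. Returns (matched index pairs,
    unmatched indices of a, unmatched indices of b).
    """
    tol = t.tol if isinstance(t, MatchTolerance) else float(t)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    candidates = [
        (abs(a[i] - b[j]), i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a[i] - b[j]) <= tol
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    unmatched_a = [i for i in range(len(a)) if i not in used_a]
    unmatched_b = [j for j in range(len(b)) if j not in used_b]
    return pairs, unmatched_a, unmatched_b


def consensus_peaks(
    replicates: list[pd.DataFrame],
    t: MatchTolerance | float = DEFAULT_TOLERANCE,
    sample_id: str | None = None,
) -> ConsensusPeakList:
    """Retain only peaks present in all replicates (within tolerance).

    The first replicate anchors the matching, with mean-position
    refinement: after each replicate is matched, the anchor position is
    updated to the running mean of the matched group. An anchor peak
    survives iff it has a match in every replicate. Consensus m/z and
    intensity are means over the matched group.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates for a consensus")
    sid = sample_id
    if sid is None:
        nonempty = [r for r in replicates if len(r)]
        sid = str(nonempty[0]["sample_id"].iloc[0]) if nonempty else ""
    anchor = replicates[0].reset_index(drop=True)
    groups: dict[int, list[tuple[float, float]]] = {
        i: [(anchor["mz"].iloc[i], anchor["intensity"].iloc[i])] for i in range(len(anchor))
    }
    alive = set(groups)
    anchor_pos = {i: float(anchor["mz"].iloc[i]) for i in groups}
    for other in replicates[1:]:
        other = other.reset_index(drop=True)
        idx = sorted(alive)
        pos = np.array([anchor_pos[i] for i in idx])
        pairs, _, _ = match_peaks(pos, other["mz"].to_numpy(), t)
        matched = {idx[k]: j for k, j in pairs}
        for i in list(alive):
            if i in matched:
                j = matched[i]
                groups[i].append((float(other["mz"].iloc[j]), float(other["intensity"].iloc[j])))
                anchor_pos[i] = float(np.mean([m for m, _ in groups[i]]))
            else:
                alive.discard(i)
    peaks = []
    n_rep = len(replicates)
    for i in sorted(alive):
        mzs, ints = zip(*groups[i])
        peaks.append(ConsensusPeak(float(np.mean(mzs)), float(np.mean(ints)), n_rep))
    peaks.sort(key=lambda p: p.mz)
    return ConsensusPeakList(sample_id=sid, peaks=peaks)


def composite_spectrum(
    replicates: list[ProfileSpectrum],
    threshold: float = DEFAULT_COMPOSITE_THRESHOLD,
    bin_width: float = 3.0,
) -> CompositeSpectrum:
    """Build a composite (summary) spectrum from replicates.

    A replicate is kept iff its mean Pearson similarity to the other kept
    replicates (on a common binned grid) is at least ``threshold``
    (inclusive). Exclusion is iterative: the replicate with the lowest
    mean similarity is dropped and the means are recomputed, so one
    outlier cannot drag every replicate below the threshold. The
    composite is the point-wise mean of the kept replicates; exclusions
    are reported with their scores.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates for a composite")
    vectors = [fpc.resample_to_grid(s, bin_width=bin_width) for s in replicates]
    n = len(replicates)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = fpc.pearson(vectors[i], vectors[j])

    def mean_scores(members: list[int]) -> dict[int, float]:
        return {
            i: float(np.mean([S[i, j] for j in members if j != i]))
            for i in members
        }

    members = list(range(n))
    excluded: list[tuple[int, float]] = []
    while len(members) >= 2:
        scores = mean_scores(members)
        worst = min(members, key=lambda i: (scores[i], -i))
        if scores[worst] >= threshold:
            break
        excluded.append((worst, scores[worst]))
        members.remove(worst)
    if len(members) < 2:
        raise ValueError("no replicate meets threshold")
    included = sorted(members)
    final_scores = mean_scores(members)
    scores = [
        final_scores.get(i, dict(excluded).get(i, float("nan"))) for i in range(n)
    ]
    excluded.sort()
    grids = [replicates[i].mz for i in included]
    same_grid = all(len(g) == len(grids[0]) and np.allclose(g, grids[0]) for g in grids)
    if same_grid:
        mz = grids[0].copy()
        intensity = np.mean([replicates[i].intensity for i in included], axis=0)
    else:
        lo, hi = replicates[0].mass_window
        mz = fpc.grid_centers(lo, hi, bin_width)
        intensity = np.mean([vectors[i] for i in included], axis=0)
    return CompositeSpectrum(
        sample_id=replicates[0].sample_id,
        included_replicates=included,
        excluded_replicates=excluded,
        mz=mz,
        intensity=intensity,
        similarity_threshold=threshold,
        replicate_scores={i: scores[i] for i in range(n)},
    )


def consensus_lists_from_table(table: pd.DataFrame) -> list[ConsensusPeakList]:
    """Interpret a peak table (one or more samples) as already-consensus
    peak lists, one per sample_id, in order of first appearance."""
    lists = []
    for sid in table["sample_id"].drop_duplicates():
        sub = table[table["sample_id"] == sid].sort_values("mz")
        peaks = [
            ConsensusPeak(float(r.mz), float(r.intensity), 1)
            for r in sub.itertuples()
        ]
        lists.append(ConsensusPeakList(sample_id=str(sid), peaks=peaks))
    return lists


def spectrum_stats(peaks: pd.DataFrame) -> tuple[tuple[float, float], int, float]:
    """Summary statistics of a peak list: (mass range, peak count, base
    peak m/z). Ties for the base peak break to the lowest m/z."""
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    mz = peaks["mz"].to_numpy()
    intensity = peaks["intensity"].to_numpy()
    max_int = intensity.max()
    base = float(mz[intensity == max_int].min())
    return (float(mz.min()), float(mz.max())), len(peaks), base
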