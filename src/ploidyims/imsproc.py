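"""Spectral preprocessing for linear-TOF imaging mass spectrometry.

The processing chain mirrors the standard profile-spectrum workflow for
protein-range (2–25 kDa) MALDI imaging data:

``restrict_mass_range`` -> ``recalibrate`` (single multiplicative ppm shift
per spectrum, capped) -> ``tic_normalize`` -> ``baseline_convex_hull`` ->
per-class ``class_average`` -> ``pick_peaks`` -> ``integrate_endpoint``
(peak area above the chord joining the window's endpoint intensities) ->
``build_peak_matrix``.

Spectra whose total ion count is ~0 ("null spectra") or whose estimated
calibration shift exceeds the ppm cap are excluded with a machine-readable
reason; retained + excluded always equals the input count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, peak_prominences, peak_widths

__all__ = [
    "Spectrum",
    "IMSDataset",
    "PeakWindow",
    "PeakMatrix",
    "PreprocessParams",
    "NullSpectrumError",
    "restrict_mass_range",
    "baseline_convex_hull",
    "tic_normalize",
    "recalibrate",
    "class_average",
    "pick_peaks",
    "integrate_endpoint",
    "build_peak_matrix",
    "preprocess",
]

EXCLUDE_NULL = "null spectrum"
EXCLUDE_SHIFT = "shift over limit"


class NullSpectrumError(ValueError):
    """Raised when an operation receives a spectrum with ~zero total ion count."""


@dataclass
class Spectrum:
    """One profile mass spectrum: ascending m/z axis plus intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    pixel: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def copy(self) -> "Spectrum":
        return Spectrum(self.mz.copy(), self.intensity.copy(), self.pixel)


@dataclass
class PeakWindow:
    """Integration window around one picked peak."""

    center_mz: float
    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.lo < self.center_mz < self.hi):
            raise ValueError("window must satisfy lo < center_mz < hi")
        if not self.label:
            self.label = f"mz_{self.center_mz:.0f}"


@dataclass
class IMSDataset:
    """Gridded imaging dataset: one spectrum per retained pixel."""

    pixels: dict[tuple[int, int], Spectrum]
    pixel_pitch: float = 90.0
    mass_range: tuple[float, float] = (2000.0, 25000.0)
    excluded: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        for xy in self.pixels:
            if len(xy) != 2 or xy[0] < 0 or xy[1] < 0:
                raise ValueError(f"invalid pixel coordinate {xy}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        coords = list(self.pixels) + list(self.excluded)
        if not coords:
            return (0, 0)
        xs = [c[0] for c in coords]
        ys = [c[1] for c in coords]
        return (max(xs) + 1, max(ys) + 1)


@dataclass
class PeakMatrix:
    """Integrated peak areas: one row per retained spectrum, one column per window."""

    values: pd.DataFrame                       # index: row ids, columns: window labels
    row_class: pd.Series | None = None         # optional class label per row

    def __post_init__(self) -> None:
        if self.row_class is not None:
            self.row_class = self.row_class.reindex(self.values.index)

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self.row_class is None:
            raise ValueError("matrix has no class labels")
        return self.values.to_numpy(), self.row_class.to_numpy()


# ---------------------------------------------------------------------------
# elementary operations


def restrict_mass_range(s: Spectrum, lo: float = 2000.0, hi: float = 25000.0) -> Spectrum:
    """Keep only points with lo <= m/z <= hi.  An empty result is a null spectrum."""
    if lo >= hi:
        raise ValueError("lo must be below hi")
    keep = (s.mz >= lo) & (s.mz <= hi)
    return Spectrum(s.mz[keep], s.intensity[keep], s.pixel)


def _lower_hull(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower convex hull of the point set (x strictly increasing), monotone chain."""
    hx: list[float] = []
    hy: list[float] = []
    for xi, yi in zip(x, y):
        while len(hx) >= 2:
            # pop while the last vertex is not a strict left turn
            cross = (hx[-1] - hx[-2]) * (yi - hy[-2]) - (hy[-1] - hy[-2]) * (xi - hx[-2])
            if cross <= 0:
                hx.pop()
                hy.pop()
            else:
                break
        hx.append(float(xi))
        hy.append(float(yi))
    return np.asarray(hx), np.asarray(hy)


def baseline_convex_hull(
    s: Spectrum, flatness: float = 0.8
) -> tuple[Spectrum, np.ndarray]:
    """Subtract the lower-convex-hull baseline from a spectrum.

    The baseline is the lower convex hull of the (m/z, intensity) points,
    linearly interpolated between hull vertices.  ``flatness`` in (0, 1]
    controls an optional median pre-filter applied before hull construction
    (window = (1 - flatness) x spectrum length); flatness 1.0 disables it.
    The baseline is clamped to the raw signal so the corrected intensity is
    non-negative everywhere, and re-application is a no-op on smooth spectra.

    Returns the corrected spectrum and the baseline curve.
    """
    if len(s) < 3:
        raise ValueError("need at least 3 points for baseline correction")
    if not (0 < flatness <= 1):
        raise ValueError("flatness must be in (0, 1]")
    y = s.intensity
    win = int(round((1.0 - flatness) * len(s)))
    if win >= 3:
        # edge replication: zero padding would collapse the baseline at the ends
        y_for_hull = median_filter(y, size=min(win, len(s)), mode="nearest")
    else:
        y_for_hull = y
    hx, hy = _lower_hull(s.mz, y_for_hull)
    baseline = np.interp(s.mz, hx, hy)
    baseline = np.minimum(baseline, y)
    corrected = y - baseline
    return Spectrum(s.mz, corrected, s.pixel), baseline


def tic_normalize(s: Spectrum, epsilon: float = 0.0) -> Spectrum:
    """Scale intensities so their sum (total ion count) equals 1.

    Raises :class:`NullSpectrumError` when the TIC is at or below ``epsilon``
    (such spectra are excluded upstream rather than rescaled).  Negative
    intensities are rejected: normalization runs on baseline-correctable,
    non-negative signal.
    """
    if s.intensity.size and s.intensity.min() < 0:
        raise ValueError("negative intensities; run baseline correction first")
    tic = s.tic
    if tic <= epsilon or s.intensity.size == 0:
        raise NullSpectrumError(EXCLUDE_NULL)
    return Spectrum(s.mz, s.intensity / tic, s.pixel)


def _top_peaks(s: Spectrum, k: int) -> np.ndarray:
    """m/z positions of the k most intense local maxima."""
    idx, _ = find_peaks(s.intensity)
    if idx.size == 0:
        return np.empty(0)
    order = np.argsort(s.intensity[idx])[::-1]
    return np.sort(s.mz[idx[order[:k]]])


def recalibrate(
    spectra: Sequence[Spectrum],
    reference: Spectrum,
    max_shift_ppm: float = 1000.0,
    top_k: int = 10,
    search_window_ppm: float = 5000.0,
) -> tuple[list[Spectrum], list[float], dict[int, str]]:
    """Align each spectrum to a reference by a single multiplicative m/z factor.

    The top-``top_k`` local maxima of each spectrum are matched to the nearest
    reference maxima within ``search_window_ppm``; the correction factor is the
    median of the matched reference/observed m/z ratios.  Spectra whose
    estimated |shift| exceeds ``max_shift_ppm``, or with no matchable peaks,
    are excluded (reason keyed by input position).

    Returns (aligned spectra, applied shift in ppm per retained input,
    excluded {index: reason}).  ``shifts`` carries NaN at excluded positions.
    """
    if len(reference) == 0:
        raise ValueError("reference spectrum is empty")
    ref_peaks = _top_peaks(reference, top_k)
    aligned: list[Spectrum] = []
    shifts: list[float] = []
    excluded: dict[int, str] = {}
    for i, s in enumerate(spectra):
        peaks = _top_peaks(s, top_k)
        ratios = []
        for p in peaks:
            if ref_peaks.size == 0:
                break
            j = int(np.argmin(np.abs(ref_peaks - p)))
            r = ref_peaks[j] / p
            if abs(r - 1.0) * 1e6 <= search_window_ppm:
                ratios.append(r)
        if not ratios:
            excluded[i] = EXCLUDE_NULL if len(s) == 0 or s.tic == 0 else "no matchable peaks"
            shifts.append(float("nan"))
            continue
        factor = float(np.median(ratios))
        shift_ppm = (factor - 1.0) * 1e6
        if abs(shift_ppm) > max_shift_ppm:
            excluded[i] = EXCLUDE_SHIFT
            shifts.append(float("nan"))
            continue
        aligned.append(Spectrum(s.mz * factor, s.intensity, s.pixel))
        shifts.append(shift_ppm)
    return aligned, shifts, excluded


def resample(s: Spectrum, axis: np.ndarray) -> Spectrum:
    """Linear interpolation of a spectrum onto a target m/z axis."""
    return Spectrum(axis, np.interp(axis, s.mz, s.intensity, left=0.0, right=0.0), s.pixel)


def class_average(spectra: Sequence[Spectrum], axis: np.ndarray | None = None) -> Spectrum:
    """Pointwise arithmetic mean spectrum of a class.

    Spectra not already on the common axis are resampled by linear
    interpolation.  The axis defaults to the first spectrum's.
    """
    if not spectra:
        raise ValueError("empty spectrum list")
    if axis is None:
        axis = spectra[0].mz
    acc = np.zeros_like(axis, dtype=float)
    for s in spectra:
        if s.mz.shape == axis.shape and np.array_equal(s.mz, axis):
            acc += s.intensity
        else:
            acc += np.interp(axis, s.mz, s.intensity, left=0.0, right=0.0)
    return Spectrum(axis, acc / len(spectra))


def _mad_noise(y: np.ndarray) -> float:
    """Robust noise scale: 1.4826 x median absolute deviation about the median."""
    med = np.median(y)
    return float(1.4826 * np.median(np.abs(y - med)))


def pick_peaks(avg: Spectrum, snr_threshold: float = 3.0) -> list[PeakWindow]:
    """Pick peaks on a baseline-corrected class-average spectrum.

    Local maxima become integration windows when their apex clears the
    median intensity by ``snr_threshold`` times the noise (1.4826 x median
    absolute deviation) *and* their prominence clears the same bar — the
    prominence requirement suppresses local maxima of pure noise, which pass
    an apex-only threshold in large numbers on long spectra.  Window bounds
    are the flanking local minima (prominence bases) tightened to the
    near-base width crossing, and truncated at the midpoint between adjacent
    accepted peaks so windows never overlap.
    """
    y = avg.intensity
    noise = _mad_noise(y)
    floor = max(snr_threshold * noise, 1e-12 * (y.max() if y.size else 1.0))
    idx, _ = find_peaks(y, height=float(np.median(y)) + floor, prominence=floor)
    if idx.size == 0:
        return []
    prominences, left_bases, right_bases = peak_prominences(y, idx)
    # near-base crossing keeps windows tight when the flanking minimum is remote
    _, _, left_ips, right_ips = peak_widths(
        y, idx, rel_height=0.95, prominence_data=(prominences, left_bases, right_bases)
    )
    windows: list[PeakWindow] = []
    for k, i in enumerate(idx):
        lo = float(np.interp(left_ips[k], np.arange(len(avg)), avg.mz))
        hi = float(np.interp(right_ips[k], np.arange(len(avg)), avg.mz))
        lo = max(lo, avg.mz[left_bases[k]])
        hi = min(hi, avg.mz[right_bases[k]])
        if k > 0:
            mid = 0.5 * (avg.mz[idx[k - 1]] + avg.mz[i])
            lo = max(lo, mid)
        if k + 1 < len(idx):
            mid = 0.5 * (avg.mz[i] + avg.mz[idx[k + 1]])
            hi = min(hi, mid)
        center = float(avg.mz[i])
        if not (lo < center < hi):  # guard against degenerate bases
            step = float(np.median(np.diff(avg.mz))) if len(avg) > 1 else 1.0
            lo, hi = center - step, center + step
        windows.append(PeakWindow(center, float(lo), float(hi)))
    return windows


def integrate_endpoint(s: Spectrum, w: PeakWindow) -> float:
    """End-point peak area: trapezoidal integral above the endpoint chord.

    The area under the linear chord joining the intensities at the window's
    first and last sample is subtracted from the trapezoidal integral of the
    signal over [lo, hi]; the result is clamped at 0.  Subtracting the chord
    makes the area invariant to any affine-in-m/z offset across the window.
    """
    if len(s) < 2 or w.lo < s.mz[0] or w.hi > s.mz[-1]:
        raise ValueError(f"window [{w.lo}, {w.hi}] outside spectrum range")
    sel = (s.mz > w.lo) & (s.mz < w.hi)
    # interpolated endpoint samples keep narrow windows well-defined
    x = np.concatenate([[w.lo], s.mz[sel], [w.hi]])
    y = np.concatenate(
        [
            [np.interp(w.lo, s.mz, s.intensity)],
            s.intensity[sel],
            [np.interp(w.hi, s.mz, s.intensity)],
        ]
    )
    total = np.trapezoid(y, x)
    chord = 0.5 * (y[0] + y[-1]) * (x[-1] - x[0])
    return float(max(total - chord, 0.0))


def build_peak_matrix(
    ds: IMSDataset | Sequence[Spectrum],
    windows: Sequence[PeakWindow],
) -> PeakMatrix:
    """Integrate every window in every retained spectrum.

    Rows are pixel coordinates (for a dataset) or list positions; excluded
    pixels never appear.
    """
    if not windows:
        raise ValueError("no peak windows")
    if isinstance(ds, IMSDataset):
        items: Iterable[tuple[object, Spectrum]] = sorted(ds.pixels.items())
    else:
        items = list(enumerate(ds))
    rows = {}
    for key, s in items:
        rows[key] = [integrate_endpoint(s, w) for w in windows]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[w.label for w in windows])
    return PeakMatrix(df)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PreprocessParams:
    """Knobs of the preprocessing chain, in application order."""

    mass_range: tuple[float, float] = (2000.0, 25000.0)
    max_shift_ppm: float = 1000.0
    flatness: float = 0.8
    snr_threshold: float = 3.0
    null_tic_rel_epsilon: float = 1e-6   # TIC below this x median slide TIC => null


def preprocess(
    ds: IMSDataset, params: PreprocessParams | None = None
) -> tuple[IMSDataset, list[str]]:
    """Run the fixed chain restrict -> recalibrate -> TIC-normalize -> baseline.

    Returns the processed dataset (with exclusions recorded) and a log with
    one line per operation and its parameters.
    """
    params = params or PreprocessParams()
    log: list[str] = []
    lo, hi = params.mass_range

    restricted: dict[tuple[int, int], Spectrum] = {}
    excluded = dict(ds.excluded)
    for xy, s in sorted(ds.pixels.items()):
        r = restrict_mass_range(s, lo, hi)
        if len(r) == 0:
            excluded[xy] = EXCLUDE_NULL
        else:
            restricted[xy] = r
    log.append(f"restrict_mass_range lo={lo} hi={hi} retained={len(restricted)}")

    tics = np.array([s.tic for s in restricted.values()])
    eps = params.null_tic_rel_epsilon * float(np.median(tics)) if tics.size else 0.0
    nonnull = {xy: s for xy, s in restricted.items() if s.tic > eps}
    for xy in restricted:
        if xy not in nonnull:
            excluded[xy] = EXCLUDE_NULL
    log.append(f"null_filter epsilon={eps:.3e} retained={len(nonnull)}")

    keys = sorted(nonnull)
    ref = class_average([nonnull[k] for k in keys]) if nonnull else None
    if ref is not None:
        aligned, shifts, shift_excl = recalibrate(
            [nonnull[k] for k in keys], ref, params.max_shift_ppm
        )
        for i, reason in shift_excl.items():
            excluded[keys[i]] = reason
        recal = {}
        kept = [k for i, k in enumerate(keys) if i not in shift_excl]
        for k, s in zip(kept, aligned):
            recal[k] = s
        log.append(
            f"recalibrate max_shift_ppm={params.max_shift_ppm} excluded={len(shift_excl)}"
        )
    else:
        recal = {}

    out: dict[tuple[int, int], Spectrum] = {}
    for xy, s in recal.items():
        try:
            t = tic_normalize(s)
        except NullSpectrumError:
            excluded[xy] = EXCLUDE_NULL
            continue
        c, _ = baseline_convex_hull(t, params.flatness)
        out[xy] = c
    log.append(f"tic_normalize+baseline flatness={params.flatness} retained={len(out)}")

    return (
        IMSDataset(out, ds.pixel_pitch, (lo, hi), excluded),
        log,
    )
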