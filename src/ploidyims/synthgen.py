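"""Synthetic inputs for every pipeline stage.

No raw imaging data accompany the study conditions this package targets, so
this module generates inputs with the statistical structure the analysis
assumes:

* **IMS slides** — linear-TOF-like profile spectra (2,000–25,000 m/z) on a
  pixel grid, with Gaussian marker peaks whose width scales with m/z
  (constant resolving power), a smooth positive baseline (decaying
  exponential plus a slow sinusoid), per-pixel multiplicative calibration
  jitter on the ppm scale, additive noise, and a configurable fraction of
  near-empty ("null") pixels.
* **DNA histograms** — per-nucleus c-values drawn from a stem-line mixture
  plus an optional scattered component above 4.5c, with the implied Auer
  type returned for recovery testing.
* **Cohorts** — records shaped like a tissue-microarray table: per-group
  immunopositivity on [0, 1] and exponential survival with a planted hazard
  ratio for marker-positive patients, censored administratively.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
identical spec + seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .clinstats import CohortRecord
from .imsproc import IMSDataset, Spectrum
from .ploidy import DNAHistogram

__all__ = [
    "PlantedPeak",
    "SlideSpec",
    "HistogramSpec",
    "CohortSpec",
    "DEFAULT_MARKER_MZ",
    "default_two_class_peaks",
    "two_region_slide_spec",
    "generate_ims_slide",
    "generate_dna_histogram",
    "generate_cohort",
    "write_slide_tsv",
    "write_slide_imzml",
    "write_masks_png",
    "write_cohort_csv",
]

#: Marker masses used as default planted peak centers (Da).
DEFAULT_MARKER_MZ = (2395.0, 3376.0, 4761.0, 4977.0, 6663.0, 8581.0)

#: Default resolving power m/dm for peak FWHM (broad linear-mode peaks).
DEFAULT_RESOLVING_POWER = 600.0


@dataclass
class PlantedPeak:
    """A Gaussian peak planted at a fixed m/z with class-specific mean apex."""

    center_mz: float
    class_means: dict[str, float]
    width: float | None = None          # FWHM in Da; default center/600
    cv: float = 0.0                     # relative apex noise

    def __post_init__(self) -> None:
        if self.width is None:
            self.width = self.center_mz / DEFAULT_RESOLVING_POWER
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if any(m < 0 for m in self.class_means.values()):
            raise ValueError("class means must be non-negative")


@dataclass
class SlideSpec:
    """Layout and noise model of one synthetic slide."""

    grid_shape: tuple[int, int] = (20, 10)           # (columns, rows)
    pixel_pitch: float = 90.0                        # micrometres
    regions: list[tuple[np.ndarray, str]] = field(default_factory=list)
    planted_peaks: list[PlantedPeak] = field(default_factory=list)
    baseline_amplitude: float = 20.0
    ppm_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    null_pixel_fraction: float = 0.0
    mass_range: tuple[float, float] = (2000.0, 25000.0)
    mz_step: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny = self.grid_shape
        if nx <= 0 or ny <= 0:
            raise ValueError("grid_shape must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if not (0 <= self.null_pixel_fraction < 1):
            raise ValueError("null_pixel_fraction must be in [0, 1)")
        lo, hi = self.mass_range
        occupancy = np.zeros((nx, ny), dtype=int)
        for mask, _label in self.regions:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (nx, ny):
                raise ValueError("region mask shape must match grid_shape")
            occupancy += mask
        if np.any(occupancy > 1):
            raise ValueError("region masks overlap")
        for p in self.planted_peaks:
            if not (lo <= p.center_mz <= hi):
                raise ValueError(
                    f"planted peak {p.center_mz} outside mass range {self.mass_range}"
                )


def default_two_class_peaks(
    labels: tuple[str, str] = ("diploid", "aneuploid"),
    effect: float = 2.0,
    cv: float = 0.2,
) -> list[PlantedPeak]:
    """Marker peaks with a two-class intensity contrast.

    The discriminating markers (m/z 2,395 and 4,977) carry an ``effect``-fold
    mean-intensity ratio favouring the second class; the remaining markers
    are shared at equal intensity.
    """
    a, b = labels
    peaks = []
    for mz in DEFAULT_MARKER_MZ:
        if mz in (2395.0, 4977.0):
            means = {a: 50.0, b: 50.0 * effect}
        else:
            means = {a: 50.0, b: 50.0}
        peaks.append(PlantedPeak(mz, means, cv=cv))
    return peaks


def two_region_slide_spec(
    labels: tuple[str, str] = ("diploid", "aneuploid"),
    grid_shape: tuple[int, int] = (20, 10),
    seed: int = 0,
    **kwargs,
) -> SlideSpec:
    """A slide split into left/right halves, one class per half."""
    nx, ny = grid_shape
    left = np.zeros((nx, ny), dtype=bool)
    left[: nx // 2, :] = True
    right = ~left
    peaks = kwargs.pop("planted_peaks", None) or default_two_class_peaks(labels)
    return SlideSpec(
        grid_shape=grid_shape,
        regions=[(left, labels[0]), (right, labels[1])],
        planted_peaks=peaks,
        seed=seed,
        **kwargs,
    )


def _baseline_curve(mz: np.ndarray, amplitude: float) -> np.ndarray:
    lo = mz[0]
    span = mz[-1] - mz[0]
    decay = np.exp(-(mz - lo) / (0.3 * span))
    slow = 0.15 * (1.0 + np.sin(2.0 * np.pi * (mz - lo) / span))
    return amplitude * (decay + slow)


def _gauss(mz: np.ndarray, center: float, fwhm: float, apex: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return apex * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


def generate_ims_slide(
    spec: SlideSpec,
) -> tuple[IMSDataset, dict[str, np.ndarray]]:
    """Generate one synthetic slide.

    Returns the dataset (one spectrum per grid pixel, shared m/z axis) and
    the ground-truth masks keyed by region label.  Pixels outside every
    region receive baseline-only background spectra and appear in no mask.
    Null pixels are drawn uniformly over the grid and emitted with ~zero
    intensity (they remain in the dataset; preprocessing excludes them).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.mass_range
    mz = np.arange(lo, hi + spec.mz_step, spec.mz_step)
    nx, ny = spec.grid_shape

    label_of: dict[tuple[int, int], str | None] = {}
    for x in range(nx):
        for y in range(ny):
            label_of[(x, y)] = None
    masks: dict[str, np.ndarray] = {}
    for mask, label in spec.regions:
        mask = np.asarray(mask, dtype=bool)
        masks[label] = mask
        for x, y in zip(*np.nonzero(mask)):
            label_of[(int(x), int(y))] = label

    n_pixels = nx * ny
    n_null = int(round(spec.null_pixel_fraction * n_pixels))
    null_flat = rng.choice(n_pixels, size=n_null, replace=False) if n_null else []
    null_set = {(int(i // ny), int(i % ny)) for i in null_flat}

    baseline = _baseline_curve(mz, spec.baseline_amplitude)
    pixels: dict[tuple[int, int], Spectrum] = {}
    for x in range(nx):
        for y in range(ny):
            label = label_of[(x, y)]
            jitter = (
                1.0 + rng.normal(0.0, spec.ppm_jitter_sd) * 1e-6
                if spec.ppm_jitter_sd > 0
                else 1.0
            )
            intensity = baseline.copy()
            for p in spec.planted_peaks:
                mean = p.class_means.get(label, 0.0) if label else 0.0
                if mean <= 0:
                    continue
                apex = mean * (1.0 + rng.normal(0.0, p.cv)) if p.cv > 0 else mean
                apex = max(apex, 0.0)
                intensity += _gauss(mz, p.center_mz * jitter, p.width, apex)
            if spec.noise_sd > 0:
                intensity = np.maximum(
                    intensity + rng.normal(0.0, spec.noise_sd, size=mz.size), 0.0
                )
            if (x, y) in null_set:
                intensity = intensity * 1e-9
            pixels[(x, y)] = Spectrum(mz, intensity, pixel=(x, y))

    ds = IMSDataset(pixels, spec.pixel_pitch, spec.mass_range)
    return ds, masks


# ---------------------------------------------------------------------------
# DNA histograms


@dataclass
class HistogramSpec:
    """Stem-line mixture defining one synthetic DNA histogram."""

    stem_lines: list[tuple[float, float]] = field(
        default_factory=lambda: [(2.0, 0.95)]
    )  # (c-position, weight fraction)
    within_line_sd: float = 0.1
    scatter_fraction_gt_4_5c: float = 0.0
    n_cells: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if any(c <= 0 for c, _ in self.stem_lines):
            raise ValueError("stem-line positions must be positive")
        total = sum(w for _, w in self.stem_lines) + self.scatter_fraction_gt_4_5c
        if total > 1.0 + 1e-12:
            raise ValueError("weights plus scatter fraction exceed 1")


def implied_auer_type(spec: HistogramSpec) -> str:
    """Auer type the spec's construction implies (ground truth for recovery)."""
    dip = sum(w for c, w in spec.stem_lines if 1.5 <= c <= 2.5)
    tet = sum(w for c, w in spec.stem_lines if 3.5 <= c <= 4.5)
    other = sum(w for c, w in spec.stem_lines) - dip - tet
    # residual weight spreads between the diploid and tetraploid regions
    resid = 1.0 - sum(w for _, w in spec.stem_lines) - spec.scatter_fraction_gt_4_5c
    if spec.scatter_fraction_gt_4_5c > 0.05:
        return "IV"
    if tet > 0 and dip + tet > 0.90:
        return "II"
    if dip > 0 and tet == 0 and other + resid + spec.scatter_fraction_gt_4_5c < 0.10:
        return "I"
    return "III"


def generate_dna_histogram(spec: HistogramSpec) -> tuple[DNAHistogram, str]:
    """Draw n_cells c-values from the stem-line mixture plus >4.5c scatter.

    Residual weight (1 - stem weights - scatter) spreads uniformly between
    the diploid and tetraploid regions, emulating proliferating S-phase
    nuclei.  Returns the histogram and the implied Auer type.
    """
    rng = np.random.default_rng(spec.seed)
    weights = [w for _, w in spec.stem_lines]
    resid = 1.0 - sum(weights) - spec.scatter_fraction_gt_4_5c
    probs = np.array(weights + [spec.scatter_fraction_gt_4_5c, max(resid, 0.0)])
    probs = probs / probs.sum()
    counts = rng.multinomial(spec.n_cells, probs)
    parts = []
    for (c, _), n in zip(spec.stem_lines, counts[: len(weights)]):
        if n:
            parts.append(rng.normal(c, spec.within_line_sd, size=n))
    n_scatter = counts[len(weights)]
    if n_scatter:
        parts.append(rng.uniform(4.6, 8.0, size=n_scatter))
    n_resid = counts[len(weights) + 1]
    if n_resid:
        parts.append(rng.uniform(2.5, 3.5, size=n_resid))
    values = np.concatenate(parts) if parts else np.empty(0)
    values = np.clip(values, 0.1, None)
    rng.shuffle(values)
    return DNAHistogram(values, source_id=f"synth-seed{spec.seed}"), implied_auer_type(spec)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Synthetic survival cohort shaped like the TMA table."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"normal": 10, "diploid": 9, "aneuploid": 9}
    )
    # immunopositivity Beta-like locations per group: (mean, sd) clipped to [0,1]
    ip_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "normal": (0.05, 0.05),
            "diploid": (0.30, 0.15),
            "aneuploid": (0.40, 0.20),
        }
    )
    hazard_ratio: float = 13.0
    baseline_hazard: float = 0.005      # events per month for marker-negatives
    censor_time: float = 174.0          # months of follow-up
    marker_cutoff: float = 0.4489       # ip above this doubles as marker-positive
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Draw one cohort: per-group IP values, exponential survival, censoring.

    Tumor-group patients whose IP exceeds ``marker_cutoff`` have their event
    hazard multiplied by ``hazard_ratio``; times beyond ``censor_time`` are
    administratively censored.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    idx = 0
    for group, n in spec.group_sizes.items():
        mean, sd = spec.ip_distributions.get(group, (0.3, 0.15))
        for _ in range(n):
            idx += 1
            ip = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
            rid = f"S{idx:03d}"
            sex = "m" if rng.random() < 0.5 else "w"
            age = int(rng.integers(45, 80))
            if group == "normal":
                records.append(
                    CohortRecord(rid, sex, age, "normal", None, ip=ip)
                )
                continue
            hazard = spec.baseline_hazard * (
                spec.hazard_ratio if ip > spec.marker_cutoff else 1.0
            )
            t = float(rng.exponential(1.0 / hazard))
            if t >= spec.censor_time:
                t, status = spec.censor_time, "alive"
            else:
                status = "dead"
            records.append(
                CohortRecord(
                    rid, sex, age, "tumor", group, survival_months=round(t, 1),
                    status=status, ip=ip,
                )
            )
    return records


# ---------------------------------------------------------------------------
# writers


def write_slide_tsv(ds: IMSDataset, path: str | Path) -> None:
    """Long-format TSV with columns x, y, mz, intensity."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["x", "y", "mz", "intensity"])
        for (x, y), s in sorted(ds.pixels.items()):
            for m, i in zip(s.mz, s.intensity):
                w.writerow([x, y, repr(float(m)), repr(float(i))])


def write_slide_imzml(ds: IMSDataset, path: str | Path) -> None:
    """Continuous-mode imzML (plus the paired .ibd binary)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous") as w:
        for (x, y), s in sorted(ds.pixels.items()):
            w.addSpectrum(s.mz, s.intensity, (x + 1, y + 1))


def write_masks_png(
    masks: dict[str, np.ndarray], png_path: str | Path, legend_path: str | Path
) -> None:
    """Region masks as an 8-bit label image plus a TSV legend (0 = background)."""
    from PIL import Image

    labels = sorted(masks)
    first = masks[labels[0]]
    lab = np.zeros(first.shape, dtype=np.uint8)
    for k, name in enumerate(labels, start=1):
        lab[masks[name]] = k
    Image.fromarray(lab.T, mode="L").save(png_path)
    with open(legend_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["value", "label"])
        w.writerow([0, "background"])
        for k, name in enumerate(labels, start=1):
            w.writerow([k, name])


def write_cohort_csv(records: Sequence[CohortRecord], path: str | Path) -> None:
    """Cohort CSV with the exact header set of the TMA-table fixture."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "sex", "age", "group", "ploidy", "T", "N", "M", "G", "UICC",
             "survival_months", "status", "ip"]
        )
        for r in records:
            w.writerow(
                [r.id, r.sex, r.age, r.group, r.ploidy or "", r.t or "", r.n or "",
                 r.m or "", r.g or "", r.uicc or "",
                 "" if r.survival_months is None else r.survival_months,
                 r.status or "", r.ip]
            )
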