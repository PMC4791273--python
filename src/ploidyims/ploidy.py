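"""DNA image-cytometry ploidy assessment: Auer histogram typing.

A Feulgen-stained imprint yields one integrated optical density (IOD) per
nucleus.  IODs are converted to DNA content in c-units by anchoring the mean
of an internal lymphocyte control at 2c (the normal diploid content).  The
resulting per-nucleus c-value histogram is classified into the four Auer
types:

* **Type I** — a single stem line in the diploid / near-diploid region
  (1.5–2.5c), with fewer than 10% of nuclei above 2.5c.
* **Type II** — a stem line in the tetraploid region (3.5–4.5c), alone or
  together with a diploid stem line, the two regions jointly holding more
  than 90% of nuclei.
* **Type III** — highly proliferating near-diploid populations with nuclei
  spread between the diploid and tetraploid regions; fewer than 5% exceed
  4.5c.
* **Type IV** — more than 5% of nuclei (or a distinctly scattered pattern)
  beyond 4.5c.

Types I–III are euploid; type IV is aneuploid.  Because the verbal rules
overlap, they are applied in the fixed precedence IV, II, I, III so that
every histogram receives exactly one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DNAHistogram",
    "AuerResult",
    "DIPLOID_REGION",
    "TETRAPLOID_REGION",
    "to_c_values",
    "detect_stem_lines",
    "exceeding_fraction",
    "classify_auer",
]

#: Closed c-value interval counted as diploid / near-diploid.
DIPLOID_REGION = (1.5, 2.5)
#: Closed c-value interval counted as tetraploid.
TETRAPLOID_REGION = (3.5, 4.5)

#: Acquisition guideline: histograms with fewer nuclei carry a quality flag.
MIN_CELLS = 500


@dataclass
class DNAHistogram:
    """Per-nucleus DNA content of one sample, in c-units (2c = diploid)."""

    c_values: np.ndarray
    source_id: str = ""
    min_cells: int = MIN_CELLS

    def __post_init__(self) -> None:
        self.c_values = np.asarray(self.c_values, dtype=float)
        if self.c_values.ndim != 1:
            raise ValueError("c_values must be one-dimensional")
        if self.c_values.size and not np.all(self.c_values > 0):
            raise ValueError("all c-values must be positive")

    @property
    def n_cells(self) -> int:
        return int(self.c_values.size)

    @property
    def low_cell_count(self) -> bool:
        """True when fewer nuclei than the acquisition guideline were measured."""
        return self.n_cells < self.min_cells


@dataclass
class AuerResult:
    """Auer type plus the summary fractions it was derived from."""

    auer_type: str                      # "I" | "II" | "III" | "IV"
    stem_lines: list[float]
    frac_gt_2_5c: float
    frac_diploid_region: float
    frac_tetraploid_region: float
    frac_between: float
    frac_gt_4_5c: float
    count_gt_4_5c: int
    count_gt_5c: int
    low_cell_count: bool = False
    source_id: str = ""

    @property
    def ploidy_label(self) -> str:
        return "aneuploid" if self.auer_type == "IV" else "euploid"

    def to_row(self) -> dict:
        return {
            "source_id": self.source_id,
            "auer_type": self.auer_type,
            "ploidy_label": self.ploidy_label,
            "stem_lines": " + ".join(f"{s:.2f}" for s in self.stem_lines),
            "frac_gt_2_5c": self.frac_gt_2_5c,
            "frac_diploid_region": self.frac_diploid_region,
            "frac_tetraploid_region": self.frac_tetraploid_region,
            "frac_between": self.frac_between,
            "frac_gt_4_5c": self.frac_gt_4_5c,
            "count_gt_4_5c": self.count_gt_4_5c,
            "count_gt_5c": self.count_gt_5c,
            "low_cell_count": self.low_cell_count,
        }


def load_reference_samples():
    """Published imaging-cohort ploidy measurements (fixture).

    One row per imprint: nucleus count, stem-line positions ("SL", two lines
    joined by ' + '), the count of 5c-exceeding events, and the reported
    euploid/aneuploid classification.  Used as worked examples for the
    typing rules.
    """
    import pandas as pd
    from importlib import resources

    ref = resources.files("ploidyims.fixtures") / "ims_ploidy_samples.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def to_c_values(raw_iod: Sequence[float], control_iod_mean: float) -> np.ndarray:
    """Standardize integrated optical densities against the lymphocyte control.

    The control population is assigned the diploid value 2c, so
    ``c = 2 * iod / control_iod_mean``.  Order is preserved.
    """
    if control_iod_mean <= 0:
        raise ValueError("control_iod_mean must be positive")
    raw = np.asarray(raw_iod, dtype=float)
    if raw.size and raw.min() < 0:
        raise ValueError("IOD values must be non-negative")
    return 2.0 * raw / control_iod_mean


def detect_stem_lines(
    hist: DNAHistogram,
    bin_width: float = 0.2,
    min_peak_fraction: float = 0.05,
) -> list[float]:
    """Locate stem lines (modal c-value positions) of a DNA histogram.

    The c-values are binned at ``bin_width``; local maxima of the binned
    counts holding at least ``min_peak_fraction`` of all nuclei become stem
    lines.  Each stem line is reported as the mean c-value of the nuclei in
    the modal bin and its two neighbours, ascending, rounded to 2 decimals.
    Runs of tied adjacent maxima are merged into one line.
    """
    if hist.n_cells == 0:
        raise ValueError("empty histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = hist.c_values
    lo = 0.0
    hi = float(v.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    n = hist.n_cells
    min_count = min_peak_fraction * n

    stem: list[float] = []
    padded = np.concatenate([[-1], counts, [-1]])
    i = 1
    while i <= len(counts):
        c = padded[i]
        if c >= min_count:
            # extent of the plateau of equal counts
            j = i
            while j + 1 <= len(counts) and padded[j + 1] == c:
                j += 1
            if padded[i - 1] < c and padded[j + 1] < c:
                b0, b1 = i - 1, j - 1      # bin indices of the plateau
                sel = (v >= edges[max(b0 - 1, 0)]) & (v < edges[min(b1 + 2, len(edges) - 1)])
                if sel.any():
                    stem.append(round(float(v[sel].mean()), 2))
            i = j + 1
        else:
            i += 1
    return sorted(stem)


def exceeding_fraction(c_values: Sequence[float], threshold: float) -> float:
    """Fraction of nuclei with DNA content strictly above ``threshold`` c."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(c_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return float(np.count_nonzero(v > threshold)) / v.size


def _region_fraction(v: np.ndarray, region: tuple[float, float]) -> float:
    lo, hi = region
    return float(np.count_nonzero((v >= lo) & (v <= hi))) / v.size


@dataclass
class ScatterRule:
    """Optional quantitative stand-in for the subjective 'distinctly
    scattered' aneuploidy trigger: at least ``min_nuclei`` nuclei above 5c
    whose coefficient of variation exceeds ``min_cv``.  Off by default."""

    enabled: bool = False
    min_nuclei: int = 20
    min_cv: float = 0.25

    def fires(self, v: np.ndarray) -> bool:
        if not self.enabled:
            return False
        above = v[v > 5.0]
        if above.size < self.min_nuclei:
            return False
        return float(above.std() / above.mean()) > self.min_cv


def classify_auer(
    hist: DNAHistogram,
    bin_width: float = 0.2,
    min_peak_fraction: float = 0.05,
    scatter_rule: ScatterRule | None = None,
) -> AuerResult:
    """Apply the Auer typing rules, precedence IV > II > I > III.

    A low nucleus count (< ``hist.min_cells``) sets a quality flag on the
    result but does not prevent classification.
    """
    if hist.n_cells == 0:
        raise ValueError("empty histogram")
    v = hist.c_values
    scatter_rule = scatter_rule or ScatterRule()

    stem = detect_stem_lines(hist, bin_width, min_peak_fraction)
    frac_gt_2_5 = exceeding_fraction(v, 2.5)
    frac_gt_4_5 = exceeding_fraction(v, 4.5)
    frac_dip = _region_fraction(v, DIPLOID_REGION)
    frac_tet = _region_fraction(v, TETRAPLOID_REGION)
    frac_between = float(np.count_nonzero((v > 2.5) & (v < 3.5))) / v.size

    dip_lo, dip_hi = DIPLOID_REGION
    tet_lo, tet_hi = TETRAPLOID_REGION
    has_dip_stem = any(dip_lo <= s <= dip_hi for s in stem)
    has_tet_stem = any(tet_lo <= s <= tet_hi for s in stem)

    if frac_gt_4_5 > 0.05 or scatter_rule.fires(v):
        auer = "IV"
    elif has_tet_stem and frac_dip + frac_tet > 0.90:
        auer = "II"
    elif has_dip_stem and not has_tet_stem and frac_gt_2_5 < 0.10:
        auer = "I"
    else:
        auer = "III"

    return AuerResult(
        auer_type=auer,
        stem_lines=stem,
        frac_gt_2_5c=frac_gt_2_5,
        frac_diploid_region=frac_dip,
        frac_tetraploid_region=frac_tet,
        frac_between=frac_between,
        frac_gt_4_5c=frac_gt_4_5,
        count_gt_4_5c=int(np.count_nonzero(v > 4.5)),
        count_gt_5c=int(np.count_nonzero(v > 5.0)),
        low_cell_count=hist.low_cell_count,
        source_id=hist.source_id,
    )
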