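"""FTIR preprocessing and band-integral feature extraction.

Spectra are treated as wavenumber-indexed absorbance traces over the
cell-wall fingerprint region (800-1800 cm^-1).  The processing chain is

1. linear baseline correction over the analysis window,
2. total-area normalization over the same window,
3. trapezoidal integration over a set of labelled wavenumber intervals,

which turns each spectrum into a short vector of compositional features
(relative band areas) suitable for classification.  Eleven canonical
intervals covering pectin, glucan, cellulose, phenol and protein bands
are provided; intervals can also be discovered from replicate spectra by
pointwise between-layer significance testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW = (800.0, 1800.0)


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance trace on a strictly increasing wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    layer: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        if w.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class SpectralInterval:
    """A labelled integration window [lower, upper] in cm^-1."""

    name: str
    lower: float
    upper: float
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"interval {self.name}: lower must be < upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


# The eleven cell-wall bands used throughout: bounds in cm^-1 with their
# standard vibrational assignments.
_CANONICAL = (
    ("Int1", 840.0, 880.0, "pectin ring"),
    ("Int2", 900.0, 940.0, "glucan"),
    ("Int3", 1090.0, 1120.0, "cellulose"),
    ("Int4", 1140.0, 1170.0, "cellulose"),
    ("Int5", 1300.0, 1360.0, "cellulose"),
    ("Int6", 1380.0, 1410.0, "pectin-like structures"),
    ("Int7", 1410.0, 1450.0, "phenols"),
    ("Int8", 1490.0, 1580.0, "protein amide II"),
    ("Int9", 1600.0, 1650.0, "protein beta-loops"),
    ("Int10", 1680.0, 1720.0, "aromatic compounds"),
    ("Int11", 1720.0, 1760.0, "esterified carboxylic groups of pectin"),
)


def canonical_intervals() -> list[SpectralInterval]:
    """Return the eleven canonical cell-wall integration intervals.

    The bands cover the pectin ring (840-880), glucan (900-940), three
    cellulose-associated regions, pectin-like structures, phenols, the
    protein amide II band, protein beta-loops, aromatic compounds and
    esterified pectin carboxyl groups, all within 800-1800 cm^-1.
    """
    return [SpectralInterval(n, lo, hi, ann) for n, lo, hi, ann in _CANONICAL]


def _check_window(spectrum: Spectrum, window: tuple[float, float]) -> None:
    lo, hi = window
    if not lo < hi:
        raise ValueError("window lower bound must be below upper bound")
    w = spectrum.wavenumbers
    if lo < w[0] or hi > w[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] outside spectrum range [{w[0]}, {w[-1]}]"
        )


def baseline_correct(
    spectrum: Spectrum, window: tuple[float, float] = DEFAULT_WINDOW
) -> Spectrum:
    """Subtract the straight line through the spectrum at the window ends.

    The absorbance at the two window endpoints (linearly interpolated if
    they fall between grid points) defines a line that is subtracted from
    the whole trace, so the corrected spectrum is zero at both endpoints.
    """
    _check_window(spectrum, window)
    lo, hi = window
    w, a = spectrum.wavenumbers, spectrum.absorbance
    a_lo = float(np.interp(lo, w, a))
    a_hi = float(np.interp(hi, w, a))
    line = a_lo + (a_hi - a_lo) * (w - lo) / (hi - lo)
    return replace(spectrum, absorbance=a - line)


def area_normalize(
    spectrum: Spectrum, window: tuple[float, float] = DEFAULT_WINDOW
) -> Spectrum:
    """Divide the trace by its trapezoidal integral over ``window``.

    After normalization the window integral equals 1, which removes
    sample-to-sample differences in overall signal intensity (film
    thickness, contact pressure).  A spectrum whose window area is zero
    or negative cannot be normalized and raises ``ValueError``.
    """
    _check_window(spectrum, window)
    area = _integrate_window(spectrum.wavenumbers, spectrum.absorbance, *window)
    if not area > 0:
        raise ValueError(f"degenerate spectrum: window area {area} is not positive")
    return replace(spectrum, absorbance=spectrum.absorbance / area)


def preprocess(
    spectrum: Spectrum, window: tuple[float, float] = DEFAULT_WINDOW
) -> Spectrum:
    """Baseline-correct then area-normalize over ``window``."""
    return area_normalize(baseline_correct(spectrum, window), window)


def _integrate_window(
    w: np.ndarray, a: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoidal integral of (w, a) over [lo, hi], interpolating at bounds."""
    inner = (w > lo) & (w < hi)
    ws = np.concatenate(([lo], w[inner], [hi]))
    vals = np.concatenate(
        ([np.interp(lo, w, a)], a[inner], [np.interp(hi, w, a)])
    )
    return float(np.trapezoid(vals, ws))


def integrate_intervals(
    spectrum: Spectrum, intervals: list[SpectralInterval] | None = None
) -> np.ndarray:
    """Band integrals of the spectrum over each interval, in interval order.

    Uses the trapezoidal rule with linear interpolation where interval
    bounds fall between grid points.  Intervals are closed
    ``[lower, upper]`` and must lie within the spectrum's range.
    """
    if intervals is None:
        intervals = canonical_intervals()
    w, a = spectrum.wavenumbers, spectrum.absorbance
    for iv in intervals:
        if iv.lower < w[0] or iv.upper > w[-1]:
            raise ValueError(
                f"interval {iv.name} [{iv.lower}, {iv.upper}] outside "
                f"spectrum range [{w[0]}, {w[-1]}]"
            )
    return np.array(
        [_integrate_window(w, a, iv.lower, iv.upper) for iv in intervals]
    )


def pointwise_significance(
    spectra_by_layer: dict[str, list[Spectrum]], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavenumber any-pair significance mask between layers.

    At every grid point an unpaired Welch t-test is run for each pair of
    layers; the point is flagged when any pair has p <= ``alpha``
    (exploratory any-pair rule, no multiplicity correction across
    wavenumbers).  Returns ``(grid, mask)``.

    All spectra must share one wavenumber grid; mismatched grids raise
    ``ValueError`` rather than being resampled silently.
    """
    layers = sorted(spectra_by_layer)
    if len(layers) < 2:
        raise ValueError("need spectra from at least two layers")
    for layer in layers:
        if len(spectra_by_layer[layer]) < 2:
            raise ValueError(f"layer {layer} needs at least two replicate spectra")
    grid = spectra_by_layer[layers[0]][0].wavenumbers
    stacks: dict[str, np.ndarray] = {}
    for layer in layers:
        rows = []
        for s in spectra_by_layer[layer]:
            if s.wavenumbers.shape != grid.shape or not np.array_equal(
                s.wavenumbers, grid
            ):
                raise ValueError(
                    f"spectrum {s.sample_id!r} is not on the common wavenumber grid"
                )
            rows.append(s.absorbance)
        stacks[layer] = np.vstack(rows)

    significant = np.zeros(grid.size, dtype=bool)
    if alpha <= 0:
        return grid, significant
    for la, lb in itertools.combinations(layers, 2):
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(stacks[la], stacks[lb], axis=0, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties are not evidence
        significant |= p <= alpha
    return grid, significant


def detect_significant_intervals(
    spectra_by_layer: dict[str, list[Spectrum]],
    alpha: float = 0.05,
    min_width: float = 16.0,
) -> list[SpectralInterval]:
    """Find wavenumber intervals where layers differ significantly.

    Maximal runs of points flagged by :func:`pointwise_significance`
    spanning strictly more than ``min_width`` cm^-1 become intervals;
    the default of 16 cm^-1 (two points at 8 cm^-1 resolution)
    suppresses isolated singletons.
    """
    grid, significant = pointwise_significance(spectra_by_layer, alpha)
    intervals: list[SpectralInterval] = []
    start = None
    for i, flag in enumerate(np.append(significant, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            lo, hi = grid[start], grid[i - 1]
            if hi - lo > min_width:
                intervals.append(
                    SpectralInterval(f"auto{len(intervals) + 1}", lo, hi, "detected")
                )
            start = None
    return intervals


def feature_table(
    spectra: list[Spectrum],
    intervals: list[SpectralInterval] | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    preprocessed: bool = False,
) -> pd.DataFrame:
    """Build a samples x band-integrals feature table from raw spectra.

    Each spectrum is baseline-corrected and area-normalized (unless
    ``preprocessed``), then integrated over ``intervals`` (canonical by
    default).  Returns a DataFrame with ``sample_id``, ``layer`` and one
    column per interval name.
    """
    if intervals is None:
        intervals = canonical_intervals()
    rows = []
    for s in spectra:
        proc = s if preprocessed else preprocess(s, window)
        feats = integrate_intervals(proc, intervals)
        row: dict[str, object] = {"sample_id": s.sample_id, "layer": s.layer}
        row.update({iv.name: v for iv, v in zip(intervals, feats)})
        rows.append(row)
    return pd.DataFrame(rows)
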