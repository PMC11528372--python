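"""Retinal isomer quantification from HPLC chromatograms.

Retinal extracted from a rhodopsin (as the oxime) separates on a normal
phase column into its isomeric forms (all-trans, 13-cis, 11-cis, 9-cis).
Because the isomers absorb with different extinction coefficients at the
detection wavelength, peak areas must be divided by the isomer-specific
coefficient before molar fractions are formed:

    fraction_i = (area_i / eps_i) / sum_j (area_j / eps_j)

Only relative (molar-fraction) quantification is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "Chromatogram",
    "IsomerTable",
    "Peak",
    "DEFAULT_ISOMER_TABLE",
    "detect_peaks",
    "assign_isomers",
    "isomer_composition",
]


@dataclass
class Chromatogram:
    """Detector trace of one HPLC run: retention time (min) vs signal (AU)."""

    time_min: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError("retention time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class IsomerTable:
    """Retention times (min) and relative extinction coefficients per isomer.

    The coefficients are relative values at the detection wavelength; only
    their ratios enter the molar-fraction formula. Defaults are
    literature-convention placeholders and should be replaced by the values
    calibrated for the actual column and detector.
    """

    entries: dict[str, tuple[float, float]]  # name -> (retention_time, epsilon)

    def __post_init__(self):
        rts = [rt for rt, _ in self.entries.values()]
        if len(set(rts)) != len(rts):
            raise ValueError("retention times must be distinct")
        if any(eps <= 0 for _, eps in self.entries.values()):
            raise ValueError("extinction coefficients must be positive")

    def retention_time(self, name: str) -> float:
        return self.entries[name][0]

    def epsilon(self, name: str) -> float:
        return self.entries[name][1]


DEFAULT_ISOMER_TABLE = IsomerTable(
    {
        "13-cis": (10.0, 0.72),
        "11-cis": (11.2, 0.55),
        "9-cis": (12.6, 0.80),
        "all-trans": (14.0, 1.00),
    }
)


@dataclass
class Peak:
    """One integrated chromatographic peak."""

    apex_time: float   # min
    area: float        # AU*min
    width: float       # min, full width at half maximum
    isomer: str | None = None


def detect_peaks(
    chromatogram: Chromatogram,
    min_prominence: float = 0.01,
    baseline_window: float = 2.0,
) -> list[Peak]:
    """Find and integrate peaks after rolling-baseline subtraction.

    The baseline is a rolling minimum over ``baseline_window`` minutes;
    local maxima of the corrected signal above ``min_prominence`` are
    integrated by the trapezoidal rule between their prominence bases.
    """
    if min_prominence <= 0:
        raise ValueError("prominence must be positive")
    t, y = chromatogram.time_min, chromatogram.signal
    dt = float(np.median(np.diff(t)))
    win = max(3, int(round(baseline_window / dt)) | 1)
    baseline = minimum_filter1d(y, size=win, mode="nearest")
    yc = y - baseline
    idx, props = find_peaks(yc, prominence=min_prominence)
    if idx.size == 0:
        return []
    widths_pts = peak_widths(yc, idx, rel_height=0.5)[0]
    # integration bounds: prominence bases, but adjacent peaks are split at
    # the valley between their apexes so no area is counted twice
    valleys = [int(idx[n] + np.argmin(yc[idx[n] : idx[n + 1] + 1]))
               for n in range(idx.size - 1)]
    peaks = []
    for n, i in enumerate(idx):
        lo = int(props["left_bases"][n])
        hi = int(props["right_bases"][n])
        if n > 0:
            lo = max(lo, valleys[n - 1])
        if n < idx.size - 1:
            hi = min(hi, valleys[n])
        area = float(np.trapezoid(yc[lo : hi + 1], t[lo : hi + 1]))
        peaks.append(Peak(apex_time=float(t[i]), area=area, width=float(widths_pts[n] * dt)))
    return peaks


def assign_isomers(
    peaks: list[Peak],
    table: IsomerTable = DEFAULT_ISOMER_TABLE,
    tolerance: float = 0.5,
) -> list[Peak]:
    """Label peaks by nearest reference retention time, one-to-one.

    Greedy assignment in order of increasing time difference; a tie is
    broken toward the earlier-eluting isomer. Peaks with no reference
    retention time within ``tolerance`` minutes stay labelled "unknown".
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    labelled = [Peak(p.apex_time, p.area, p.width, "unknown") for p in peaks]
    candidates = []
    for pi, p in enumerate(labelled):
        for name, (rt, _) in table.entries.items():
            d = abs(p.apex_time - rt)
            if d <= tolerance:
                candidates.append((d, rt, pi, name))
    used_peaks: set[int] = set()
    used_isomers: set[str] = set()
    for d, rt, pi, name in sorted(candidates, key=lambda c: (c[0], c[1])):
        if pi in used_peaks or name in used_isomers:
            continue
        labelled[pi].isomer = name
        used_peaks.add(pi)
        used_isomers.add(name)
    return labelled


def isomer_composition(
    peaks: list[Peak],
    table: IsomerTable = DEFAULT_ISOMER_TABLE,
) -> dict[str, float]:
    """Extinction-corrected molar fractions from labelled peak areas.

    Areas of same-isomer peaks are pooled, divided by the isomer's
    extinction coefficient, and normalized to sum to one. Raises if no
    peak carries a known isomer label.
    """
    if not peaks:
        raise ValueError("no peaks to quantify")
    moles: dict[str, float] = {}
    for p in peaks:
        if p.isomer in (None, "unknown"):
            continue
        moles[p.isomer] = moles.get(p.isomer, 0.0) + p.area / table.epsilon(p.isomer)
    if not moles:
        raise ValueError("no peak could be assigned to a known isomer")
    total = sum(moles.values())
    return {name: m / total for name, m in moles.items()}
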