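"""Light-induced pH assay analysis for ion-pumping rhodopsins.

A suspension of cells expressing a candidate pump is illuminated for a
fixed window while the medium pH is recorded. An outward proton pump
acidifies the medium during illumination; the protonophore CCCP collapses
the transmembrane proton gradient, so a pump signal that survives CCCP is
not electrogenic proton transport. Classification therefore combines the
initial light-on slope of the native trace with the slope ratio under
CCCP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PumpTrace",
    "PumpResult",
    "segment_trace",
    "initial_slope",
    "classify_pump",
]


@dataclass
class PumpTrace:
    """Time course of suspension pH with its illumination schedule."""

    time_s: np.ndarray
    ph: np.ndarray
    light_on: float | None     # s, start of illumination (None: never illuminated)
    light_off: float | None    # s, end of illumination
    condition: str = "native"   # 'native' | 'CCCP'
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.time_s.shape != self.ph.shape:
            raise ValueError("time and pH must have equal length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if self.light_on is not None:
            if not (self.time_s[0] <= self.light_on < self.light_off <= self.time_s[-1]):
                raise ValueError("light schedule must lie within the record")


@dataclass
class PumpResult:
    """Quantified pump-assay outcome."""

    slope_native: float          # pH/s, drift-corrected initial light-on slope
    slope_cccp: float | None     # pH/s, same for the CCCP trace
    delta_ph: float              # drift-corrected pH change over the light window
    cccp_ratio: float | None     # |slope_CCCP| / |slope_native|
    classification: str          # outward H+ pump | inward H+ transport | none | ambiguous


def segment_trace(trace: PumpTrace) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split a trace into pre-light, light, and post-light segments.

    The light segment is the closed interval [on, off]; pre and post are
    the open flanks. A segment absent from the record comes back empty
    rather than raising.
    """
    t, p = trace.time_s, trace.ph
    if trace.light_on is None:
        empty = (t[:0], p[:0])
        return {"pre": (t, p), "light": empty, "post": empty}
    pre = t < trace.light_on
    light = (t >= trace.light_on) & (t <= trace.light_off)
    post = t > trace.light_off
    return {
        "pre": (t[pre], p[pre]),
        "light": (t[light], p[light]),
        "post": (t[post], p[post]),
    }


def initial_slope(
    segment: tuple[np.ndarray, np.ndarray],
    fit_window: float = 30.0,
    drift: float = 0.0,
) -> float:
    """Drift-corrected least-squares slope over the first ``fit_window`` seconds.

    ``drift`` is the background slope (pH/s) estimated from the pre-light
    segment; it is subtracted from the fitted slope.
    """
    t, p = np.asarray(segment[0], float), np.asarray(segment[1], float)
    if t.size == 0:
        raise ValueError("empty segment")
    sel = t <= t[0] + fit_window
    if sel.sum() < 5:
        raise ValueError("fit window must contain at least 5 samples")
    slope = float(np.polyfit(t[sel], p[sel], 1)[0])
    return slope - drift


def estimate_drift(trace: PumpTrace) -> float:
    """Background pH drift (pH/s) from the pre-light segment; 0 if too short."""
    t, p = segment_trace(trace)["pre"]
    if t.size < 5:
        return 0.0
    return float(np.polyfit(t, p, 1)[0])


def classify_pump(
    native: PumpTrace,
    cccp: PumpTrace | None = None,
    slope_threshold: float = 1e-4,
    abolition_ratio: float = 0.2,
    fit_window: float = 30.0,
) -> PumpResult:
    """Classify pumping activity from a native trace and its CCCP control.

    Rules: a light-on slope below ``-slope_threshold`` (acidification)
    whose CCCP counterpart is reduced below ``abolition_ratio`` of the
    native magnitude is an outward H+ pump; the symmetric alkalization
    case is inward H+ transport; a sub-threshold native slope is "none";
    transport that CCCP fails to abolish is "ambiguous".
    """
    segs = segment_trace(native)
    if segs["light"][0].size == 0:
        return PumpResult(0.0, None, 0.0, None, "none")
    drift = estimate_drift(native)
    slope_n = initial_slope(segs["light"], fit_window=fit_window, drift=drift)
    t_l, p_l = segs["light"]
    delta_ph = float(p_l[-1] - p_l[0] - drift * (t_l[-1] - t_l[0]))

    slope_c = None
    ratio = None
    if cccp is not None:
        segs_c = segment_trace(cccp)
        slope_c = initial_slope(
            segs_c["light"], fit_window=fit_window, drift=estimate_drift(cccp)
        )
        ratio = abs(slope_c) / abs(slope_n) if slope_n != 0 else np.inf

    if abs(slope_n) <= slope_threshold:
        cls = "none"
    elif ratio is None:
        cls = "ambiguous"  # no control: direction known, mechanism unconfirmed
    elif ratio < abolition_ratio:
        cls = "outward H+ pump" if slope_n < 0 else "inward H+ transport"
    else:
        cls = "ambiguous"
    return PumpResult(slope_n, slope_c, delta_ph, ratio, cls)
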