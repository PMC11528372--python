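"""CSV/JSON/FASTA readers and writers for the measurement containers.

All tabular files are comma-separated with a header row and '.' decimal
point, independent of locale. Headers are matched case-insensitively.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chromaret import Chromatogram
from .photocycle import SpectralTimeSeries
from .pumpassay import PumpTrace
from .uvvis import Spectrum, TitrationSeries


class SchemaError(ValueError):
    """A table did not match the expected column schema."""


def read_table(path: str | Path, schema: list[str]) -> pd.DataFrame:
    """Read a CSV whose header must contain ``schema`` (case-insensitive).

    Returns the schema columns as floats, renamed to the canonical
    lower-case names. Malformed numeric cells raise with the offending
    line number.
    """
    df = pd.read_csv(path, dtype=str)
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in schema if c.lower() not in lower]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    out = {}
    for name in schema:
        col = df[lower[name.lower()]]
        try:
            out[name] = col.astype(float).to_numpy()
        except ValueError:
            for i, v in enumerate(col):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"{path}: malformed value {v!r} in column {name!r} at line {i + 2}"
                    ) from None
            raise
    return pd.DataFrame(out)


# -- Spectrum ---------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path, meta: dict | None = None) -> Spectrum:
    df = read_table(path, ["wavelength_nm", "absorbance"])
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy(),
                    meta=dict(meta or {}))


# -- TitrationSeries --------------------------------------------------------

def write_titration_series(series: TitrationSeries, directory: str | Path) -> None:
    """One spectrum CSV per pH plus a manifest mapping filename to pH."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for i, s in enumerate(series.spectra):
        name = f"spectrum_{i:03d}.csv"
        write_spectrum(s, directory / name)
        manifest[name] = s.ph
    with open(directory / "manifest.json", "w") as fh:
        json.dump({"reference_ph": series.reference_ph, "files": manifest}, fh, indent=1)


def read_titration_series(directory: str | Path) -> TitrationSeries:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    spectra = [
        read_spectrum(directory / name, meta={"pH": ph})
        for name, ph in manifest["files"].items()
    ]
    return TitrationSeries(spectra, reference_ph=manifest.get("reference_ph"))


# -- SpectralTimeSeries -----------------------------------------------------

def write_time_series(series: SpectralTimeSeries, path: str | Path) -> None:
    """First column ``time_ms``, remaining headers the wavelengths in nm."""
    df = pd.DataFrame(series.delta_a, columns=[f"{w:g}" for w in series.wavelengths])
    df.insert(0, "time_ms", series.times)
    df.to_csv(path, index=False)


def read_time_series(path: str | Path, meta: dict | None = None) -> SpectralTimeSeries:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if not cols or cols[0].lower() != "time_ms":
        raise SchemaError(f"{path}: first column must be time_ms")
    wl = np.array([float(c) for c in cols[1:]])
    return SpectralTimeSeries(
        df[cols[0]].to_numpy(float), wl, df[cols[1:]].to_numpy(float),
        meta=dict(meta or {}),
    )


# -- Chromatogram -----------------------------------------------------------

def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": chrom.time_min, "signal": chrom.signal}).to_csv(
        path, index=False
    )


def read_chromatogram(path: str | Path, meta: dict | None = None) -> Chromatogram:
    df = read_table(path, ["time_min", "signal"])
    return Chromatogram(df["time_min"].to_numpy(), df["signal"].to_numpy(),
                        meta=dict(meta or {}))


# -- PumpTrace --------------------------------------------------------------

def write_pump_trace(trace: PumpTrace, path: str | Path) -> None:
    """Trace CSV plus a JSON sidecar holding the illumination schedule."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "pH": trace.ph}).to_csv(path, index=False)
    sidecar = {
        "light_on_s": trace.light_on,
        "light_off_s": trace.light_off,
        "condition": trace.condition,
    }
    with open(path.with_suffix(".schedule.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_pump_trace(path: str | Path) -> PumpTrace:
    path = Path(path)
    df = read_table(path, ["time_s", "pH"])
    with open(path.with_suffix(".schedule.json")) as fh:
        sched = json.load(fh)
    return PumpTrace(
        df["time_s"].to_numpy(), df["pH"].to_numpy(),
        light_on=sched["light_on_s"], light_off=sched["light_off_s"],
        condition=sched.get("condition", "native"),
    )


# -- FASTA ------------------------------------------------------------------

def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_ground_truth(truth, path: str | Path) -> None:
    """Ground-truth JSON sidecar for a generated dataset."""
    with open(path, "w") as fh:
        json.dump(
            {"params": truth.params, "seed": truth.seed, "noise_sd": truth.noise_sd},
            fh, indent=1, default=float,
        )
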