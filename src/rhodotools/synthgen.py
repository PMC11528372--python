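"""Seeded synthetic-data generators for every measurement modality.

Each generator draws from an explicit ``numpy.random.Generator`` seeded by
the caller and returns its :class:`GroundTruth` alongside the data, so
downstream analyses can be scored by parameter recovery. At zero noise
every output is an exact evaluation of the corresponding forward model:
the recomposition residual against the analysis module's own model is
numerically zero, which the test-suite checks.

Modelling conventions (simplifications, configurable):

* absorption bands are Gaussian in wavelength with a default full width
  at half maximum of 100 nm, the broad shape typical of retinal proteins;
* titration spectra are population-weighted mixtures of protonation-state
  spectra with one independent Henderson–Hasselbalch sigmoid per
  transition;
* flash-photolysis matrices follow the sequential ground→K→M→ground
  chain solved in closed form by :func:`rhodotools.photocycle.solve_sequential`;
* noise is additive, i.i.d. Gaussian — no instrument artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromaret import Chromatogram, IsomerTable, DEFAULT_ISOMER_TABLE
from .photocycle import KineticScheme, SpectralTimeSeries, solve_sequential
from .pumpassay import PumpTrace
from .uvvis import Spectrum, TitrationSeries

__all__ = [
    "GroundTruth",
    "gaussian_band",
    "make_spectrum",
    "make_titration_series",
    "make_default_scheme",
    "make_photocycle_series",
    "make_chromatogram",
    "make_pump_trace",
    "make_opsin_sequence",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: reference positions never touched by random mutagenesis
PROTECTED_POSITIONS = (85, 89, 96, 194, 204, 212, 216)


@dataclass
class GroundTruth:
    """Parameters a generator used, for parameter-recovery scoring."""

    params: dict = field(default_factory=dict)
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self):
        fractions = self.params.get("molar_fractions")
        if fractions is not None:
            total = sum(fractions.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"molar fractions must sum to 1, got {total}")
        for key in ("k_km", "k_mp"):
            if key in self.params and self.params[key] <= 0:
                raise ValueError(f"rate constant {key} must be positive")


def gaussian_band(
    wavelengths: np.ndarray, center: float, fwhm: float, amplitude: float
) -> np.ndarray:
    """Gaussian absorption band parameterized by its full width at half maximum."""
    if fwhm <= 0:
        raise ValueError("band width must be positive")
    sigma = fwhm * FWHM_TO_SIGMA
    return amplitude * np.exp(-0.5 * ((np.asarray(wavelengths) - center) / sigma) ** 2)


def _grid(grid: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = grid
    if hi <= lo or step <= 0:
        raise ValueError("empty wavelength grid")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def make_spectrum(
    band_center: float = 570.0,
    band_width: float = 100.0,
    amplitude: float = 1.0,
    protein_band: bool = True,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    grid: tuple[float, float, float] = (250.0, 750.0, 0.5),
    seed: int = 0,
) -> tuple[Spectrum, GroundTruth]:
    """Synthetic UV–Vis spectrum of a purified retinal protein.

    One Gaussian visible band at ``band_center`` plus an optional 280-nm
    aromatic protein band, a flat baseline, and additive Gaussian noise.
    """
    wl = _grid(grid)
    rng = np.random.default_rng(seed)
    ab = gaussian_band(wl, band_center, band_width, amplitude) + baseline
    if protein_band:
        ab = ab + gaussian_band(wl, 280.0, 50.0, 1.5 * amplitude)
    if noise_sd > 0:
        ab = ab + rng.normal(0.0, noise_sd, wl.size)
    truth = GroundTruth(
        params={
            "band_center": band_center,
            "band_width": band_width,
            "amplitude": amplitude,
            "baseline": baseline,
            "protein_band": protein_band,
        },
        seed=seed,
        noise_sd=noise_sd,
    )
    return Spectrum(wl, ab, meta={"synthetic": True}), truth


def transition_weights(pka_list: list[float], ph: np.ndarray) -> np.ndarray:
    """State populations of a stepwise titration with independent transitions.

    For pKa values pKa_1 < ... < pKa_n the deprotonation of transition i
    follows θ_i(pH) = 1/(1 + 10^(pKa_i − pH)); state s (0-based, most
    protonated first) has weight w_0 = 1 − θ_1, w_s = θ_s − θ_{s+1},
    w_n = θ_n. Exact for well-separated pKa values, and by construction
    the single-wavelength observable is exactly the sum-of-sigmoids
    Henderson–Hasselbalch model fitted downstream.
    """
    ph = np.asarray(ph, dtype=float)
    pkas = sorted(pka_list)
    theta = [1.0 / (1.0 + 10.0 ** (p - ph)) for p in pkas]
    theta = [np.ones_like(ph)] + theta + [np.zeros_like(ph)]
    return np.array([theta[i] - theta[i + 1] for i in range(len(pkas) + 1)])


def make_titration_series(
    pka_list: list[float],
    state_band_centers: list[float],
    ph_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    band_width: float = 100.0,
    amplitude: float = 1.0,
    grid: tuple[float, float, float] = (250.0, 750.0, 1.0),
) -> tuple[TitrationSeries, GroundTruth]:
    """Titration series: each pH a population-weighted mixture of state spectra.

    ``state_band_centers`` gives the visible-band center of each protonation
    state, most protonated first; there must be one more state than pKa.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    if len(state_band_centers) != len(pka_list) + 1:
        raise ValueError("need exactly one more state than pKa values")
    if np.any(ph_grid < 0) or np.any(ph_grid > 14):
        raise ValueError("pH grid must lie within [0, 14]")
    wl = _grid(grid)
    rng = np.random.default_rng(seed)
    states = np.array(
        [gaussian_band(wl, c, band_width, amplitude) for c in state_band_centers]
    )
    weights = transition_weights(pka_list, ph_grid)  # (n_states, n_ph)
    spectra = []
    for j, ph in enumerate(ph_grid):
        ab = weights[:, j] @ states
        if noise_sd > 0:
            ab = ab + rng.normal(0.0, noise_sd, wl.size)
        spectra.append(Spectrum(wl, ab, meta={"pH": float(ph), "synthetic": True}))
    truth = GroundTruth(
        params={
            "pka": sorted(float(p) for p in pka_list),
            "state_band_centers": list(map(float, state_band_centers)),
            "band_width": band_width,
            "amplitude": amplitude,
        },
        seed=seed,
        noise_sd=noise_sd,
    )
    return TitrationSeries(spectra), truth


def default_time_grid(points_per_decade: int = 20) -> np.ndarray:
    """Log-spaced flash-photolysis time grid, 0.001–10000 ms."""
    return np.logspace(-3, 4, 7 * points_per_decade + 1)


def make_default_scheme(
    k_km: float = 0.5,
    k_mp: float = 0.0009,
    excited_fraction: float = 0.2,
    ground_center: float = 570.0,
    k_center: float = 675.0,
    m_center: float = 415.0,
    band_width: float = 100.0,
    amplitude: float = 1.0,
    wavelength_grid: np.ndarray | None = None,
) -> KineticScheme:
    """Sequential scheme with Gaussian-band species difference spectra.

    Δε of each intermediate is its own band minus the ground-state band,
    so the ground bleach emerges from the occupied intermediates.
    """
    if wavelength_grid is None:
        wavelength_grid = 370.0 + 5.0 * np.arange(71)  # 370–720 nm at 5 nm
    wl = np.asarray(wavelength_grid, dtype=float)
    ground = gaussian_band(wl, ground_center, band_width, amplitude)
    return KineticScheme(
        k_km=k_km,
        k_mp=k_mp,
        excited_fraction=excited_fraction,
        delta_eps={
            "K": gaussian_band(wl, k_center, band_width, amplitude) - ground,
            "M": gaussian_band(wl, m_center, band_width, amplitude) - ground,
        },
        wavelengths=wl,
    )


def make_photocycle_series(
    scheme: KineticScheme | None = None,
    time_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SpectralTimeSeries, GroundTruth]:
    """Flash-photolysis difference matrix ΔA(λ, t) for a sequential scheme.

    ΔA(t, λ) = Σ_s c_s(t) Δε_s(λ) + noise, with concentrations from the
    closed-form solution of the chain.
    """
    if scheme is None:
        scheme = make_default_scheme()
    if scheme.delta_eps is None or scheme.wavelengths is None:
        raise ValueError("scheme needs species difference spectra on a wavelength grid")
    if time_grid is None:
        time_grid = default_time_grid()
    t = np.asarray(time_grid, dtype=float)
    rng = np.random.default_rng(seed)
    conc = solve_sequential(scheme, t)
    da = np.zeros((t.size, scheme.wavelengths.size))
    for name, eps in scheme.delta_eps.items():
        da += np.outer(conc[name], eps)
    if noise_sd > 0:
        da = da + rng.normal(0.0, noise_sd, da.shape)
    truth = GroundTruth(
        params={
            "k_km": scheme.k_km,
            "k_mp": scheme.k_mp,
            "excited_fraction": scheme.excited_fraction,
        },
        seed=seed,
        noise_sd=noise_sd,
    )
    series = SpectralTimeSeries(t, scheme.wavelengths, da, meta={"synthetic": True})
    return series, truth


def make_chromatogram(
    molar_fractions: dict[str, float],
    epsilon_table: IsomerTable = DEFAULT_ISOMER_TABLE,
    peak_width: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
    time_grid: tuple[float, float, float] = (0.0, 20.0, 0.01),
    scale: float = 10.0,
) -> tuple[Chromatogram, GroundTruth]:
    """HPLC chromatogram whose peak areas encode a molar composition.

    Each isomer contributes a Gaussian peak at its table retention time
    with area = fraction × ε(isomer) × scale, i.e. the detector response
    is proportional to moles times the extinction coefficient, which is
    what extinction-corrected quantification inverts. ``peak_width`` is
    the Gaussian σ in minutes. Retention times closer than 2×σ set an
    ``overlap_warning`` flag in the metadata.
    """
    total = sum(molar_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"molar fractions must sum to 1, got {total}")
    if peak_width <= 0:
        raise ValueError("peak width must be positive")
    t = _grid(time_grid)
    rng = np.random.default_rng(seed)
    y = np.zeros_like(t)
    rts = []
    for name, frac in molar_fractions.items():
        rt = epsilon_table.retention_time(name)
        rts.append(rt)
        area = frac * epsilon_table.epsilon(name) * scale
        amp = area / (peak_width * np.sqrt(2.0 * np.pi))
        y += amp * np.exp(-0.5 * ((t - rt) / peak_width) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.size)
    rts = np.sort(rts)
    overlap = bool(rts.size > 1 and np.min(np.diff(rts)) < 2.0 * peak_width)
    truth = GroundTruth(
        params={
            "molar_fractions": dict(molar_fractions),
            "peak_width": peak_width,
            "scale": scale,
        },
        seed=seed,
        noise_sd=noise_sd,
    )
    chrom = Chromatogram(t, y, meta={"synthetic": True, "overlap_warning": overlap})
    return chrom, truth


def make_pump_trace(
    acidification_rate: float = 0.002,
    light_window: tuple[float, float] = (180.0, 300.0),
    drift: float = 0.0,
    cccp: bool = False,
    duration: float = 480.0,
    sampling_hz: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    start_ph: float = 7.0,
    saturation_tau: float = 240.0,
    recovery_tau: float = 600.0,
    cccp_leak: float = 0.02,
) -> tuple[PumpTrace, GroundTruth]:
    """Illumination-gated pH trace of a cell suspension.

    During the light window the pump acidifies the medium with initial
    rate ``acidification_rate`` (pH/s) saturating exponentially with time
    constant ``saturation_tau``; after light-off the pH relaxes back with
    ``recovery_tau``. A linear ``drift`` spans the whole record. With
    ``cccp`` the pump term is multiplied by ``cccp_leak`` (the
    protonophore short-circuits the proton gradient) while the drift is
    unchanged. A negative ``acidification_rate`` produces alkalization
    (inward transport).
    """
    on, off = light_window
    if not (0.0 <= on < off <= duration):
        raise ValueError("light window must lie within the record")
    n = int(round(duration * sampling_hz)) + 1
    t = np.arange(n) / sampling_hz
    rng = np.random.default_rng(seed)
    amp = acidification_rate * saturation_tau
    pump = np.zeros_like(t)
    in_light = (t >= on) & (t <= off)
    pump[in_light] = -amp * (1.0 - np.exp(-(t[in_light] - on) / saturation_tau))
    after = t > off
    level_off = -amp * (1.0 - np.exp(-(off - on) / saturation_tau))
    pump[after] = level_off * np.exp(-(t[after] - off) / recovery_tau)
    if cccp:
        pump = pump * cccp_leak
    ph = start_ph + drift * t + pump
    if noise_sd > 0:
        ph = ph + rng.normal(0.0, noise_sd, n)
    truth = GroundTruth(
        params={
            "acidification_rate": acidification_rate,
            "drift": drift,
            "cccp": cccp,
            "cccp_leak": cccp_leak,
            "saturation_tau": saturation_tau,
        },
        seed=seed,
        noise_sd=noise_sd,
    )
    trace = PumpTrace(
        t, ph, light_on=on, light_off=off,
        condition="CCCP" if cccp else "native",
        meta={"synthetic": True},
    )
    return trace, truth


def make_opsin_sequence(
    residue_spec: dict[int, str] | None = None,
    n_random_mutations: int = 0,
    seed: int = 0,
    template: str | None = None,
) -> tuple[str, GroundTruth]:
    """Opsin-like sequence with prescribed residues at reference positions.

    Starts from the bundled reference template (or ``template``), writes
    the residues of ``residue_spec`` (1-based reference positions) in
    place, then applies ``n_random_mutations`` random substitutions at
    positions outside the functional-residue set. Substitution-only
    mutagenesis keeps the reference mapping the identity, so extracted
    key residues equal the spec by construction.
    """
    from .opsinseq import load_reference  # deferred: avoids cycle at import time

    if template is None:
        _, template = load_reference()
    seq = list(template)
    residue_spec = residue_spec or {}
    for pos, aa in residue_spec.items():
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"position {pos} outside template length {len(seq)}")
        seq[pos - 1] = aa.upper()
    protected = set(PROTECTED_POSITIONS) | set(residue_spec)
    free = [i for i in range(1, len(seq) + 1) if i not in protected]
    if n_random_mutations > len(free):
        raise ValueError("more mutations requested than mutable positions")
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for pos in rng.choice(free, size=n_random_mutations, replace=False):
        current = seq[pos - 1]
        choices = [c for c in aas if c != current]
        seq[pos - 1] = choices[rng.integers(len(choices))]
    truth = GroundTruth(
        params={
            "residue_spec": {int(k): v.upper() for k, v in residue_spec.items()},
            "n_random_mutations": n_random_mutations,
        },
        seed=seed,
    )
    return "".join(seq), truth
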