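"""Synthetic SHG transport experiments and Langmuir isotherms.

Every downstream stage of the package is exercised on data produced here, so
the generators emulate the full measurement chain:

* a rapid adsorption rise (seconds) to the field maximum, followed by the
  bi-exponential decay whose slow constant obeys a planted Arrhenius law;
* conversion of the field to expected photon counts per bin, including the
  additive hyper-Rayleigh floor and the multiplicative extinction
  attenuation that the analysis must invert;
* independent Poisson draws per bin (photon counting);
* a single long-time "overnight" anchor bin that pins the decay plateau;
* liquid-expanded-phase pressure-area isotherms with a prescribed mean
  molecular area at 25 mN/m and additive Gaussian sensor noise.

Presets carry the planted ground truth in the trace metadata so recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics_model import (
    ArrheniusLaw,
    BiExpParams,
    KineticParams,
    biexp_field,
    field_from_trajectory,
    rate_at_temperature,
    solve_linear_chain,
)

__all__ = [
    "ExperimentPreset",
    "SHGTrace",
    "IsothermPreset",
    "Isotherm",
    "PRESETS",
    "ISOTHERM_PRESETS",
    "get_preset",
    "get_isotherm_preset",
    "generate_trace",
    "generate_experiment",
    "generate_isotherm",
]

#: Default temperature grid, kelvin (21-45 degC).
DEFAULT_TEMPERATURES = (294.15, 300.15, 306.15, 312.15, 318.15)

#: Reference temperature at which preset transport rates are pinned.
_T_REF = 306.15
#: Transport rate at the reference temperature, 1/s (tau2 = 600 s there).
_K_REF = 1.0 / 600.0


@dataclass(frozen=True)
class ExperimentPreset:
    """Everything needed to synthesize one multi-temperature experiment."""

    name: str
    law: ArrheniusLaw
    lipid: str
    vesicle_class: str  # "GUV" | "SUV"
    cholesterol_molfrac: float = 0.0
    tau1_ref: float = 30.0  # fast (flip) constant, s
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    # template for mechanistic mode; k_back = k_trans / w_flip makes the
    # equilibrium coherent field exactly zero, so the sum stays nonnegative
    # and the late decay is the pure slow eigenmode (rate k_trans + k_back)
    kinetic: KineticParams = field(
        default_factory=lambda: KineticParams(
            k_ads=1.0, k_flip=0.05, k_trans=0.002, k_back=0.005, w_flip=0.4
        )
    )
    counts_scale: float = 1e4  # expected counts per bin at the field peak
    hrs_level: float = 200.0  # additive hyper-Rayleigh floor, counts
    extinction_factor: float = 1.25
    bin_width: float = 1.0  # s
    duration: float = 3600.0  # s
    overnight_time: float = 43200.0  # s
    rise_time: float = 30.0  # time of the field maximum after addition, s
    plateau_frac: float = 0.15  # A0 / peak field
    fast_frac: float = 0.35  # B1 / peak field
    seed: int = 0

    def __post_init__(self) -> None:
        temps = tuple(self.temperatures)
        if len(set(temps)) < 3:
            raise ValueError("need >= 3 distinct temperatures")
        if max(temps) - min(temps) < 15.0:
            raise ValueError("temperature grid must span >= 15 K")
        if not self.counts_scale >= self.hrs_level >= 0:
            raise ValueError("require counts_scale >= hrs_level >= 0")
        if self.extinction_factor < 1.0:
            raise ValueError("extinction_factor must be >= 1")
        k_cold = rate_at_temperature(self.law, min(temps))
        if self.duration < 5.0 / k_cold and not self.overnight_time > self.duration:
            raise ValueError(
                "duration must cover 5 slow time constants at the coldest "
                "temperature or an overnight anchor must be supplied"
            )

    def truth_biexp(self, T: float) -> BiExpParams:
        """Planted bi-exponential parameters (field units) at temperature T."""
        tau2 = 1.0 / rate_at_temperature(self.law, T)
        e_peak = float(
            np.sqrt(max(self.counts_scale * self.extinction_factor - self.hrs_level, 0.0))
        )
        b2_frac = 1.0 - self.plateau_frac - self.fast_frac
        return BiExpParams(
            A0=self.plateau_frac * e_peak,
            B1=self.fast_frac * e_peak,
            tau1=self.tau1_ref,
            B2=b2_frac * e_peak,
            tau2=tau2,
            t0=self.rise_time,
        )


@dataclass(frozen=True)
class SHGTrace:
    """Raw photon-count time series at a single temperature.

    ``time`` is a constant-width bin grid in seconds, optionally followed by
    one long-time overnight anchor bin.  ``meta`` carries acquisition
    metadata and, for synthetic traces, the planted ground truth.
    """

    time: np.ndarray
    counts: np.ndarray
    temperature: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.counts)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if c.shape != t.shape:
            raise ValueError("counts must match the time grid")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        widths = np.diff(t)
        # constant bin width over the regular acquisition; a trailing
        # overnight anchor bin is allowed to break the spacing
        core = widths[:-1] if widths.size > 1 else widths
        if core.size and not np.allclose(core, core[0], rtol=1e-9):
            raise ValueError("bin width must be constant (apart from a final anchor)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive kelvin")


def _noiseless_field(preset: ExperimentPreset, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free field on the acquisition grid plus overnight anchor."""
    n_bins = int(round(preset.duration / preset.bin_width))
    t = np.arange(n_bins) * preset.bin_width
    if preset.overnight_time > preset.duration:
        t = np.append(t, preset.overnight_time)
    p = preset.truth_biexp(T)
    e = np.empty_like(t)
    rising = t < p.t0
    # saturating-exponential rise, continuous with the decay at its maximum
    tau_rise = p.t0 / 6.0
    e_peak = p.A0 + p.B1 + p.B2
    e[rising] = e_peak * (1.0 - np.exp(-t[rising] / tau_rise)) / (
        1.0 - np.exp(-p.t0 / tau_rise)
    )
    e[~rising] = biexp_field(p, t[~rising])
    return t, e


def mechanistic_field(
    preset: ExperimentPreset, T: float, times: np.ndarray
) -> np.ndarray:
    """Field from the four-state mechanistic chain with k_trans set by the law.

    Used for model-consistency checks; the phenomenological bi-exponential
    mode is the default generator because measured traces are fitted
    phenomenologically.
    """
    k = rate_at_temperature(preset.law, T)
    # preserve the k_back / k_trans ratio so the zero-equilibrium-field
    # construction of the template survives the temperature scaling
    ratio = preset.kinetic.k_back / preset.kinetic.k_trans
    params = replace(preset.kinetic, k_trans=k, k_back=ratio * k)
    traj = solve_linear_chain(params, times)
    weights = (params.w_up, params.w_flip, params.w_in)
    return field_from_trajectory(traj, weights=weights)


def generate_trace(
    preset: ExperimentPreset, T: float, seed: int, noise: bool = True
) -> SHGTrace:
    """Synthesize one photon-count trace at temperature ``T`` (kelvin).

    The expected counts per bin are ``lam(t) = (E(t)^2 + hrs_level) /
    extinction_factor``; with ``noise=True`` each bin is an independent
    Poisson draw with that mean, otherwise ``round(lam)``.
    """
    temps = np.asarray(preset.temperatures)
    if not np.any(np.isclose(temps, T)):
        raise ValueError(f"T={T} K is not in preset {preset.name!r} temperatures")
    t, e = _noiseless_field(preset, T)
    lam = (e**2 + preset.hrs_level) / preset.extinction_factor
    if np.any(lam > 2**62):
        raise OverflowError("expected counts overflow the integer representation")
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam)
    else:
        counts = np.round(lam).astype(np.int64)
    truth = preset.truth_biexp(T)
    meta = {
        "preset": preset.name,
        "lipid": preset.lipid,
        "vesicle_class": preset.vesicle_class,
        "cholesterol_molfrac": preset.cholesterol_molfrac,
        "seed": int(seed),
        "extinction_factor": preset.extinction_factor,
        "hrs_level": preset.hrs_level,
        "truth_tau1": truth.tau1,
        "truth_tau2": truth.tau2,
        "truth_A0": truth.A0,
        "truth_B1": truth.B1,
        "truth_B2": truth.B2,
        "truth_t0": truth.t0,
        "truth_Ea_kJ_mol": preset.law.Ea,
        "truth_lnA": preset.law.lnA,
    }
    return SHGTrace(time=t, counts=counts, temperature=float(T), meta=meta)


def generate_experiment(
    preset: ExperimentPreset, seed: int | None = None, noise: bool = True
) -> tuple[list[SHGTrace], dict]:
    """One trace per preset temperature plus the planted-truth record.

    Per-temperature seeds are derived deterministically from the experiment
    seed via a seed sequence, so the whole experiment is reproducible from a
    single integer.
    """
    base = preset.seed if seed is None else int(seed)
    child_seeds = np.random.SeedSequence(base).generate_state(len(preset.temperatures))
    traces = [
        generate_trace(preset, T, int(s % 2**31), noise=noise)
        for T, s in zip(preset.temperatures, child_seeds)
    ]
    truth = {
        "preset": preset.name,
        "seed": base,
        "Ea_kJ_mol": preset.law.Ea,
        "lnA": preset.law.lnA,
        "temperatures_K": list(preset.temperatures),
        "k_per_s": [rate_at_temperature(preset.law, T) for T in preset.temperatures],
        "tau2_s": [1.0 / rate_at_temperature(preset.law, T) for T in preset.temperatures],
    }
    return traces, truth


def _preset(name, Ea, lipid, vclass, chol=0.0) -> ExperimentPreset:
    return ExperimentPreset(
        name=name,
        law=ArrheniusLaw.from_rate_at(Ea, _T_REF, _K_REF),
        lipid=lipid,
        vesicle_class=vclass,
        cholesterol_molfrac=chol,
    )


# Activation energies: the DOPG GUV/SUV pair (68 -> 114 kJ/mol) is the
# quantitatively reported curvature contrast; the POPG and cardiolipin
# values are placeholders ordered by the qualitative findings (POPG well
# below DOPG and nearly curvature-independent; cardiolipin GUV slightly
# above DOPG GUV, its SUV slightly below its GUV; cholesterol raises every
# barrier).  Edit here to recalibrate.
PRESETS: dict[str, ExperimentPreset] = {
    p.name: p
    for p in [
        _preset("dopg_guv", 68.0, "DOPG", "GUV"),
        _preset("dopg_suv", 114.0, "DOPG", "SUV"),
        _preset("popg_guv", 45.0, "POPG", "GUV"),
        _preset("popg_suv", 47.0, "POPG", "SUV"),
        _preset("cardiolipin_guv", 72.0, "cardiolipin", "GUV"),
        _preset("cardiolipin_suv", 65.0, "cardiolipin", "SUV"),
        _preset("dopg_guv_chol", 90.0, "DOPG", "GUV", chol=0.5),
        _preset("popg_guv_chol", 70.0, "POPG", "GUV", chol=0.5),
        _preset("cardiolipin_guv_chol", 95.0, "cardiolipin", "GUV", chol=0.5),
    ]
}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# pressure-area isotherms


@dataclass(frozen=True)
class IsothermPreset:
    """Exponential liquid-expanded isotherm anchored at 25 mN/m.

    ``pi(A) = pi_max * exp(-(A - A_min) / lambda_decay)`` with ``A_min``
    chosen so that ``pi(area_at_25) = 25 mN/m`` exactly before noise.  The
    analytic compressional modulus is ``Cs^-1(A) = (A / lambda_decay) * pi(A)``.
    """

    name: str
    area_at_25: float  # mean molecular area at 25 mN/m, A^2
    lambda_decay: float  # exponential steepness, A^2
    pi_max: float = 45.0  # surface pressure at A_min, mN/m
    area_range: tuple[float, float] = (0.0, 0.0)  # sampled window, A^2
    n_points: int = 200
    noise_sd: float = 0.2  # additive pressure noise, mN/m

    def __post_init__(self) -> None:
        if self.pi_max <= 25.0:
            raise ValueError("pi_max must exceed the 25 mN/m anchor")
        lo, hi = self.area_range
        if not lo < self.area_at_25 < hi:
            raise ValueError("area_at_25 must lie inside area_range")
        if self.n_points < 20:
            raise ValueError("need at least 20 isotherm points")

    @property
    def area_min(self) -> float:
        """Area at which the pressure reaches pi_max."""
        return self.area_at_25 + self.lambda_decay * float(np.log(25.0 / self.pi_max))

    def pressure(self, area: np.ndarray) -> np.ndarray:
        """Noise-free pressure, mN/m."""
        a = np.asarray(area, dtype=float)
        return self.pi_max * np.exp(-(a - self.area_min) / self.lambda_decay)

    def modulus(self, area: np.ndarray) -> np.ndarray:
        """Analytic compressional modulus Cs^-1 = (A/lambda) * pi(A), mN/m."""
        a = np.asarray(area, dtype=float)
        return a / self.lambda_decay * self.pressure(a)


@dataclass(frozen=True)
class Isotherm:
    """Surface pressure-area isotherm (compression branch)."""

    area: np.ndarray  # A^2 / molecule
    pressure: np.ndarray  # mN/m
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.area, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if a.size < 20:
            raise ValueError("isotherm needs >= 20 points")
        if a.shape != p.shape or not np.all(np.isfinite(p)):
            raise ValueError("area and pressure must be finite, equal-length arrays")
        order = np.argsort(a)
        dup = np.diff(a[order]) == 0
        if np.any(dup):
            dupes = np.unique(a[order][:-1][dup])
            raise ValueError(f"duplicate molecular areas: {dupes.tolist()}")


# lambda ordering makes POPG the softest monolayer (largest lambda -> lowest
# Cs^-1 in the 20-30 mN/m liquid-expanded window), matching the monolayer
# rigidity ranking POPG < DOPG, cardiolipin.
ISOTHERM_PRESETS: dict[str, IsothermPreset] = {
    p.name: p
    for p in [
        IsothermPreset("cardiolipin", area_at_25=130.0, lambda_decay=25.0,
                       area_range=(116.0, 190.0)),
        IsothermPreset("popg", area_at_25=66.0, lambda_decay=28.0,
                       area_range=(51.0, 125.0)),
        IsothermPreset("dopg", area_at_25=69.0, lambda_decay=15.0,
                       area_range=(61.0, 110.0)),
    ]
}


def get_isotherm_preset(name: str) -> IsothermPreset:
    try:
        return ISOTHERM_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown isotherm preset {name!r}; available: {sorted(ISOTHERM_PRESETS)}"
        ) from None


def generate_isotherm(
    preset: IsothermPreset, seed: int = 0, noise_sd: float | None = None
) -> Isotherm:
    """Sample the preset isotherm on a uniform area grid with Gaussian noise."""
    lo, hi = preset.area_range
    area = np.linspace(lo, hi, preset.n_points)
    # include the 25 mN/m anchor area exactly on the grid
    area[np.argmin(np.abs(area - preset.area_at_25))] = preset.area_at_25
    pi = preset.pressure(area)
    sd = preset.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        rng = np.random.default_rng(seed)
        pi = pi + rng.normal(0.0, sd, size=pi.shape)
    meta = {
        "preset": preset.name,
        "seed": int(seed),
        "noise_sd": sd,
        "lambda_decay": preset.lambda_decay,
        "area_at_25": preset.area_at_25,
    }
    return Isotherm(area=area, pressure=pi, label=preset.name, meta=meta)
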