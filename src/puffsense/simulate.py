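"""Physics-based synthetic puff generator.

Maps puffing conditions (atomizer power, button duration, vaping-machine
pressurization time) to an emitted lognormal aerosol, a pressure-driven flow,
and time-resolved three-wavelength transmitted-intensity traces through the
simplified Beer-Lambert model

    A_j(t) = sum_i f[i][j] * c_i(t) * L,      I_j(t) = I0_j * 10^(-A_j(t)),

where ``c_i(t)`` are the instantaneous size-binned mass concentrations
(mg/L) crossing the beam, ``f`` the bin-by-band mass extinction matrix and
``L`` the optical path (mm).  Each simulated record carries its ground-truth
size-binned masses ``M_i = integral c_i(t) Q(t) dt`` so the generator can
stand in for the vaping-machine + SMPS reference measurement.

The emission map is a constrained stand-in: only its monotone trends
(higher power -> larger count median diameter and more mass; longer draw or
stronger inhalation -> more mass) are anchored to observed e-cigarette
behaviour; the absolute calibration is a package choice producing mg-scale
per-puff bin masses increasing from M1 to M3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import (
    SizeBinnedMass,
    SizeDistribution,
    bin_mass_fractions_from_mass_median,
    lognormal_number_distribution,
)
from .optics import DEFAULT_BIN_EDGES, ExtinctionMatrix

__all__ = [
    "PuffConditions",
    "EmissionModel",
    "FlowModel",
    "OpticalPathConfig",
    "NoiseSpec",
    "NOISELESS",
    "BinnedConcentrationTrace",
    "RawPuffSignals",
    "flow_rate",
    "inhalation_pressure",
    "emit_aerosol",
    "attenuation_from_concentrations",
    "simulate_puff",
    "default_condition_schedule",
    "test_condition_schedule",
    "generate_dataset",
    "write_raw_puff",
    "read_raw_puff",
]

OPTICAL_DT = 0.044  # s, photometric sampling interval
PRESSURE_DT = 0.338  # s, pressure sampling interval
AMBIENT_PRESSURE = 101_325.0  # Pa


@dataclass(frozen=True)
class PuffConditions:
    """Machine-settable puffing conditions."""

    atomizer_power: float = 20.0  # W, 15-25
    button_duration: float = 2.25  # s, 1.5-3
    pressurization_time: float = 60.0  # s, 7-150

    def __post_init__(self) -> None:
        if min(self.atomizer_power, self.button_duration, self.pressurization_time) <= 0:
            raise ValueError("puff conditions must be positive")


@dataclass(frozen=True)
class FlowModel:
    """Volumetric flow law Q = U[dP].

    Default orifice-like square-root law ``Q = k * dP^alpha`` (L/min, Pa)
    with ``k`` calibrated so nominal inhalation pressures (~1 kPa) draw
    1-2 L/min; a linear law (alpha = 1) is selectable.  ``resistance``
    scales the pressure required for a given flow, mimicking devices with
    tighter airflow.
    """

    coefficient: float = 0.062  # L/min per Pa^alpha at resistance 1
    alpha: float = 0.5
    resistance: float = 1.0

    def __post_init__(self) -> None:
        if self.coefficient <= 0 or self.alpha <= 0 or self.resistance <= 0:
            raise ValueError("flow-model parameters must be positive")


def flow_rate(pressure_pa, model: FlowModel | None = None):
    """Volumetric flow (L/min) for inhalation pressure(s) in Pa."""
    model = model or FlowModel()
    p = np.asarray(pressure_pa, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be >= 0")
    q = model.coefficient * (p / model.resistance) ** model.alpha
    return float(q) if np.isscalar(pressure_pa) else q


def inhalation_pressure(pressurization_time: float, p_scale: float = 2200.0,
                        tau: float = 100.0) -> float:
    """Plateau inhalation pressure (Pa) produced by the dilution-box pump.

    Longer pumping lowers the box pressure further; the approach saturates
    exponentially with time constant ``tau``.
    """
    if pressurization_time <= 0:
        raise ValueError("pressurization_time must be > 0")
    return p_scale * (1.0 - math.exp(-pressurization_time / tau))


@dataclass(frozen=True)
class EmissionModel:
    """Monotone map from puffing conditions to emitted aerosol.

    Produces a two-mode aerosol: a main accumulation mode whose count
    median diameter sits in the 100-300 nm range (so the number
    concentration peaks there) and a coalescence-grown coarse mode holding
    a puff-to-puff varying fraction of the emitted mass at larger
    diameters, as dense freshly generated vapour aerosols develop during
    transport.  The mass distribution consequently peaks at several hundred
    nm.  Monotone by construction: CMD and mass increase with power; mass
    increases with button duration and with inhalation pressure.
    """

    cmd_base: float = 230.0  # nm, main-mode count median at ref_power
    cmd_per_watt: float = 6.0  # nm/W
    ref_power: float = 20.0  # W
    gsd: float = 1.9  # main-mode geometric standard deviation
    mass_scale: float = 5.5  # mg at reference conditions
    power_exponent: float = 1.5
    ref_duration: float = 2.25  # s
    pressure_exponent: float = 0.5
    ref_pressure: float = 1000.0  # Pa
    cmd_noise: float = 20.0  # nm, 1 sigma puff-to-puff jitter
    gsd_noise: float = 0.2
    mass_rel_noise: float = 0.10  # lognormal sigma
    coarse_fraction_mean: float = 0.2  # mass fraction in the coarse mode
    coarse_fraction_noise: float = 0.15
    coarse_ratio: float = 1.6  # coarse over main mass-median diameter
    coarse_gsd: float = 1.4

    def draw(self, conditions: PuffConditions, delta_p: float, rng: np.random.Generator):
        """Sample (cmd_nm, gsd, total_mass_mg, coarse_fraction) for one puff."""
        cmd = self.cmd_base + self.cmd_per_watt * (conditions.atomizer_power - self.ref_power)
        cmd = max(cmd + self.cmd_noise * rng.standard_normal(), 60.0)
        gsd = max(self.gsd + self.gsd_noise * rng.standard_normal(), 1.2)
        mass = (
            self.mass_scale
            * (conditions.atomizer_power / self.ref_power) ** self.power_exponent
            * (conditions.button_duration / self.ref_duration)
            * (delta_p / self.ref_pressure) ** self.pressure_exponent
        )
        mass *= math.exp(self.mass_rel_noise * rng.standard_normal())
        phi = float(
            np.clip(
                self.coarse_fraction_mean
                + self.coarse_fraction_noise * rng.standard_normal(),
                0.0, 0.45,
            )
        )
        return cmd, gsd, mass, phi

    def bin_fractions(self, cmd: float, gsd: float, phi: float) -> np.ndarray:
        """Mass fraction of the emitted aerosol in each of the three bins."""
        main_mm = cmd * math.exp(3.0 * math.log(gsd) ** 2)
        frac_main = bin_mass_fractions_from_mass_median(main_mm, gsd, DEFAULT_BIN_EDGES)
        frac_coarse = bin_mass_fractions_from_mass_median(
            self.coarse_ratio * main_mm, self.coarse_gsd, DEFAULT_BIN_EDGES
        )
        return (1.0 - phi) * frac_main + phi * frac_coarse

    def number_distribution(self, cmd: float, gsd: float, phi: float) -> SizeDistribution:
        """Unit-total-number mixture distribution of the two modes."""
        main = lognormal_number_distribution(1.0, cmd, gsd)
        if phi <= 0:
            return main
        # coarse-mode count median giving mass median coarse_ratio * main's
        sig_m, sig_c = math.log(gsd), math.log(self.coarse_gsd)
        cmd_c = self.coarse_ratio * cmd * math.exp(3.0 * (sig_m**2 - sig_c**2))
        coarse = lognormal_number_distribution(1.0, cmd_c, self.coarse_gsd)
        # number weights reproducing the phi mass split (mass ~ N cmd^3 e^{4.5 sigma^2})
        m_main = cmd**3 * math.exp(4.5 * sig_m**2)
        m_coarse = cmd_c**3 * math.exp(4.5 * sig_c**2)
        w_c = phi / (1.0 - phi) * m_main / m_coarse
        dn = main.dN_dlogDp + w_c * coarse.dN_dlogDp
        total = float(np.sum(dn) / main.channels_per_decade)
        return SizeDistribution(main.channel_centers, dn / total, main.channels_per_decade)


@dataclass(frozen=True)
class OpticalPathConfig:
    """Beam geometry: path length = flow-channel diameter, 10 mm.

    The differential-path-length factor and geometry offset of the full
    modified Beer-Lambert law are fixed to 1 and 0 (the generic form
    ``A = eps * c * L``).
    """

    path_length: float = 10.0  # mm
    dpf: float = 1.0
    geometry_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.path_length > 0):
            raise ValueError("path_length must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise of the sensor and of the reference truth.

    ``intensity_rel`` and ``pressure_pa`` perturb the raw sensor traces.
    ``reference_rel_common`` and ``reference_rel_bin`` are lognormal sigmas
    of the reference (dilution box + SMPS) mass measurement: a common
    component shared by all three bins (dilution-volume error) and an
    independent per-bin component (scan and bin-reduction error).  The
    attached ground truth is the *measured* truth, as it would be in a real
    training campaign.
    """

    intensity_rel: float = 0.003
    pressure_pa: float = 2.0
    reference_rel_common: float = 0.08
    reference_rel_bin: float = 0.06

    def __post_init__(self) -> None:
        if min(self.intensity_rel, self.pressure_pa,
               self.reference_rel_common, self.reference_rel_bin) < 0:
            raise ValueError("noise levels must be >= 0")


NOISELESS = NoiseSpec(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class BinnedConcentrationTrace:
    """Instantaneous size-binned mass concentration (mg/L) crossing the beam."""

    time: np.ndarray
    concentrations: np.ndarray  # (3, n) for bins 1..3

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if c.shape != (3, t.size):
            raise ValueError("concentrations must have shape (3, len(time))")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class RawPuffSignals:
    """One puff's raw sensor record plus simulation ground truth."""

    optical_time: np.ndarray  # s, 44 ms grid
    intensity_uv: np.ndarray
    intensity_r: np.ndarray
    intensity_ir: np.ndarray
    pressure_time: np.ndarray  # s, 338 ms grid
    pressure_abs: np.ndarray  # Pa
    baseline_intensity: dict  # label -> I0 counts used by the simulator
    truth: SizeBinnedMass | None = None
    truth_mean_dp: float | None = None
    truth_attenuation: np.ndarray | None = None  # (3, n), noiseless A_j(t)
    truth_concentrations: BinnedConcentrationTrace | None = None


def _pulse_shape(t: np.ndarray, start: float, duration: float, ramp: float = 0.3) -> np.ndarray:
    """Smooth trapezoid: ramp up, plateau of length ``duration``, ramp down."""
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((start + ramp + duration + ramp - t) / ramp, 0.0, 1.0)
    return np.minimum(up, down)


def emit_aerosol(
    conditions: PuffConditions,
    emission: EmissionModel | None = None,
    flow: FlowModel | None = None,
    rng: np.random.Generator | None = None,
    puff_start: float = 3.0,
    total_time: float | None = None,
):
    """Generate one puff's emitted aerosol and concentration pulse.

    Returns ``(size_dist, trace, truth, delta_p)``: the per-puff lognormal
    number distribution (unit total number; shape only), the
    size-binned concentration trace on the optical grid, the ground-truth
    binned masses and the plateau inhalation pressure.
    """
    emission = emission or EmissionModel()
    flow = flow or FlowModel()
    rng = rng if rng is not None else np.random.default_rng()

    delta_p = inhalation_pressure(conditions.pressurization_time)
    cmd, gsd, total_mass, phi = emission.draw(conditions, delta_p, rng)
    bin_masses = emission.bin_fractions(cmd, gsd, phi) * total_mass  # mg

    if total_time is None:
        total_time = conditions.button_duration + 9.0
    t = np.arange(0.0, total_time, OPTICAL_DT)
    shape = _pulse_shape(t, puff_start, conditions.button_duration)
    area = conditions.button_duration + 0.3  # analytic trapezoid area, s
    q_lps = flow_rate(delta_p, flow) / 60.0  # L/s, constant during plateau
    # c_i(t) = M_i * s(t) / (area * Q) so that integral c_i Q dt == M_i
    conc = np.outer(bin_masses, shape / (area * q_lps))
    trace = BinnedConcentrationTrace(t, conc)
    dist = emission.number_distribution(cmd, gsd, phi)
    truth = SizeBinnedMass.from_array(bin_masses)
    return dist, trace, truth, delta_p


def attenuation_from_concentrations(
    trace: BinnedConcentrationTrace,
    ext: ExtinctionMatrix,
    path: OpticalPathConfig | None = None,
) -> np.ndarray:
    """Forward Beer-Lambert: A_j(t) = sum_i f[i][j] c_i(t) L, shape (3, n)."""
    path = path or OpticalPathConfig()
    return ext.coefficients.T @ trace.concentrations * path.path_length


def simulate_puff(
    conditions: PuffConditions,
    ext: ExtinctionMatrix,
    emission: EmissionModel | None = None,
    flow: FlowModel | None = None,
    path: OpticalPathConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator | None = None,
    baseline_counts: float = 30_000.0,
    max_attenuation: float = 6.0,
) -> RawPuffSignals:
    """Simulate one puff's raw three-wavelength and pressure record.

    The first and last 2 s of both traces are aerosol-free baseline.  The
    pressure trace ramps down to the plateau inhalation pressure before the
    aerosol pulse and recovers to ambient well before the end.
    """
    path = path or OpticalPathConfig()
    noise = noise if noise is not None else NoiseSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dist, trace, truth, delta_p = emit_aerosol(conditions, emission, flow, rng)
    if noise.reference_rel_common > 0 or noise.reference_rel_bin > 0:
        factors = np.exp(
            noise.reference_rel_common * rng.standard_normal()
            + noise.reference_rel_bin * rng.standard_normal(3)
        )
        truth = SizeBinnedMass.from_array(truth.as_array() * factors)
    atten = attenuation_from_concentrations(trace, ext, path)
    if np.max(atten) > max_attenuation:
        raise ValueError(
            f"peak attenuation {np.max(atten):.2f} exceeds {max_attenuation}; "
            "configuration is unphysical for this optical path"
        )

    t = trace.time
    i0 = {"UV": baseline_counts, "R": baseline_counts, "IR": baseline_counts}
    intensities = []
    for j, label in enumerate(("UV", "R", "IR")):
        sig = i0[label] * 10.0 ** (-atten[j])
        if noise.intensity_rel > 0:
            sig = sig + noise.intensity_rel * i0[label] * rng.standard_normal(t.size)
        intensities.append(sig)

    total_time = t[-1] + OPTICAL_DT
    tp = np.arange(0.0, total_time, PRESSURE_DT)
    pulse_end = 3.0 + conditions.button_duration + 0.6
    knots_t = [0.0, 2.0, 2.8, pulse_end + 0.3, pulse_end + 1.3, total_time]
    knots_dp = [0.0, 0.0, delta_p, delta_p, 0.0, 0.0]
    dp_profile = np.interp(tp, knots_t, knots_dp)
    p_abs = AMBIENT_PRESSURE - dp_profile
    if noise.pressure_pa > 0:
        p_abs = p_abs + noise.pressure_pa * rng.standard_normal(tp.size)

    return RawPuffSignals(
        optical_time=t,
        intensity_uv=intensities[0],
        intensity_r=intensities[1],
        intensity_ir=intensities[2],
        pressure_time=tp,
        pressure_abs=p_abs,
        baseline_intensity=i0,
        truth=truth,
        truth_mean_dp=delta_p,
        truth_attenuation=atten,
        truth_concentrations=trace,
    )


def _triangle(phase: float) -> float:
    """0 -> 0, 0.5 -> 1, 1 -> 0 periodic triangle."""
    return 1.0 - abs(2.0 * (phase % 1.0) - 1.0)


def _schedule(n: int, offset: float) -> list:
    conditions = []
    for i in range(n):
        power = 15.0 + 10.0 * _triangle((i + offset) / 8.0)
        duration = 1.5 + 1.5 * _triangle((i + offset) / 6.0)
        pressurization = 7.0 * (150.0 / 7.0) ** _triangle((i + offset) / 10.0)
        conditions.append(PuffConditions(power, duration, pressurization))
    return conditions


def default_condition_schedule(n_puffs: int = 100) -> list:
    """Training schedule: the three parameters cycle at periods 8, 6 and 10
    puffs (power, duration, pressurization), emulating the oscillating
    pattern of a diversified puffing protocol; each parameter sweeps its
    full range including both extremes."""
    if n_puffs < 1:
        raise ValueError("n_puffs must be >= 1")
    return _schedule(n_puffs, 0.0)


def test_condition_schedule(n_puffs: int = 10) -> list:
    """Held-out schedule: half-step phase shift, so every parameter stays
    strictly inside the training range while the specific combinations
    never occur in the training schedule."""
    if n_puffs < 1:
        raise ValueError("n_puffs must be >= 1")
    return _schedule(n_puffs, 0.5)


def generate_dataset(
    n_puffs: int,
    ext: ExtinctionMatrix,
    schedule=None,
    emission: EmissionModel | None = None,
    flow: FlowModel | None = None,
    path: OpticalPathConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> list:
    """Seeded, reproducible list of RawPuffSignals over a condition schedule."""
    if n_puffs < 1:
        raise ValueError("n_puffs must be >= 1")
    schedule = schedule if schedule is not None else default_condition_schedule(n_puffs)
    if len(schedule) < n_puffs:
        raise ValueError("schedule shorter than n_puffs")
    streams = np.random.SeedSequence(seed).spawn(n_puffs)
    return [
        simulate_puff(
            schedule[i], ext, emission, flow, path, noise,
            seed=np.random.default_rng(streams[i]),
        )
        for i in range(n_puffs)
    ]


# ---------------------------------------------------------------------------
# Raw-record CSV layout (one optical + one pressure file per puff)


def write_raw_puff(raw: RawPuffSignals, directory, puff_id: int) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "t_s": raw.optical_time,
            "i_uv": raw.intensity_uv,
            "i_r": raw.intensity_r,
            "i_ir": raw.intensity_ir,
        }
    ).to_csv(directory / f"puff_{puff_id:04d}_optical.csv", index=False, float_format="%.10g")
    pd.DataFrame({"t_s": raw.pressure_time, "p_pa": raw.pressure_abs}).to_csv(
        directory / f"puff_{puff_id:04d}_pressure.csv", index=False, float_format="%.10g"
    )


def read_raw_puff(directory, puff_id: int) -> RawPuffSignals:
    from pathlib import Path

    directory = Path(directory)
    opt = pd.read_csv(directory / f"puff_{puff_id:04d}_optical.csv")
    pre = pd.read_csv(directory / f"puff_{puff_id:04d}_pressure.csv")
    return RawPuffSignals(
        optical_time=opt["t_s"].to_numpy(),
        intensity_uv=opt["i_uv"].to_numpy(),
        intensity_r=opt["i_r"].to_numpy(),
        intensity_ir=opt["i_ir"].to_numpy(),
        pressure_time=pre["t_s"].to_numpy(),
        pressure_abs=pre["p_pa"].to_numpy(),
        baseline_intensity={},
    )
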