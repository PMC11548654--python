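"""Aerosol size distributions and SMPS-style data reduction.

A scanning mobility particle sizer reports the differential number
concentration ``dN/dlogDp`` (cm^-3 per log10-decade) on a geometric channel
grid, conventionally 64 channels per decade.  Assuming spherical droplets of
density ``rho_p`` the differential mass concentration follows channel-wise as

    dC/dlogDp = (pi/6) Dp^3 rho_p dN/dlogDp

and the total PM mass in a diameter bin inside a dilution box of volume
``V_box`` is the discrete integral of ``dC/dlogDp * V_box`` over the bin.

Units: diameters nm; dN/dlogDp cm^-3; dC/dlogDp g/cm^3; box volume L;
binned masses mg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import DEFAULT_BIN_EDGES, ParticleOpticalProperties

__all__ = [
    "SizeDistribution",
    "MassDistribution",
    "DilutionConfig",
    "SizeBinnedMass",
    "make_channel_grid",
    "lognormal_number_distribution",
    "lognormal_bin_mass_fractions",
    "number_to_mass",
    "size_binned_mass",
    "read_smps_table",
    "write_smps_table",
    "read_binned_masses",
    "write_binned_masses",
]

DEFAULT_CHANNELS_PER_DECADE = 64
#: SMPS scan range used for the reference measurements, nm.
DEFAULT_SCAN_RANGE = (60.0, 1170.0)


def _check_grid(centers: np.ndarray) -> None:
    if centers.ndim != 1 or centers.size < 2:
        raise ValueError("channel grid must be a 1-D array with >= 2 channels")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("channel centers must be strictly increasing")


@dataclass(frozen=True)
class SizeDistribution:
    """Number concentration per log10-diameter interval on an SMPS channel grid."""

    channel_centers: np.ndarray
    dN_dlogDp: np.ndarray
    channels_per_decade: int = DEFAULT_CHANNELS_PER_DECADE

    def __post_init__(self) -> None:
        c = np.asarray(self.channel_centers, dtype=float)
        n = np.asarray(self.dN_dlogDp, dtype=float)
        _check_grid(c)
        if n.shape != c.shape:
            raise ValueError("dN_dlogDp must match channel_centers in shape")
        if np.any(n < 0):
            raise ValueError("dN_dlogDp must be >= 0")
        object.__setattr__(self, "channel_centers", c)
        object.__setattr__(self, "dN_dlogDp", n)

    @property
    def dlog(self) -> float:
        return 1.0 / self.channels_per_decade

    def total_number(self) -> float:
        """Discrete integral of dN/dlogDp, cm^-3."""
        return float(np.sum(self.dN_dlogDp) * self.dlog)


@dataclass(frozen=True)
class MassDistribution:
    """Mass concentration (g/cm^3) per log10-diameter interval."""

    channel_centers: np.ndarray
    dC_dlogDp: np.ndarray
    channels_per_decade: int = DEFAULT_CHANNELS_PER_DECADE

    def __post_init__(self) -> None:
        c = np.asarray(self.channel_centers, dtype=float)
        m = np.asarray(self.dC_dlogDp, dtype=float)
        _check_grid(c)
        if m.shape != c.shape:
            raise ValueError("dC_dlogDp must match channel_centers in shape")
        if np.any(m < 0):
            raise ValueError("dC_dlogDp must be >= 0")
        object.__setattr__(self, "channel_centers", c)
        object.__setattr__(self, "dC_dlogDp", m)

    @property
    def dlog(self) -> float:
        return 1.0 / self.channels_per_decade


@dataclass(frozen=True)
class DilutionConfig:
    """Dilution-box geometry; the machine dilutes each puff by 300-1000x."""

    box_volume: float = 94.6  # L
    dilution_factor_range: tuple = (300.0, 1000.0)

    def __post_init__(self) -> None:
        if not (self.box_volume > 0):
            raise ValueError("box_volume must be > 0")


@dataclass(frozen=True)
class SizeBinnedMass:
    """Per-puff PM mass (mg) in the three diameter bins."""

    m1: float
    m2: float
    m3: float

    def __post_init__(self) -> None:
        if min(self.m1, self.m2, self.m3) < 0:
            raise ValueError("binned masses must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.m3])

    @classmethod
    def from_array(cls, arr) -> "SizeBinnedMass":
        a = np.asarray(arr, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


def make_channel_grid(
    d_min: float = DEFAULT_SCAN_RANGE[0],
    d_max: float = DEFAULT_SCAN_RANGE[1],
    channels_per_decade: int = DEFAULT_CHANNELS_PER_DECADE,
) -> np.ndarray:
    """Geometric channel-center grid at the SMPS export resolution."""
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    n = int(math.floor(channels_per_decade * math.log10(d_max / d_min))) + 1
    return d_min * 10.0 ** (np.arange(n) / channels_per_decade)


def lognormal_number_distribution(
    total_number: float,
    cmd: float,
    gsd: float,
    grid: np.ndarray | None = None,
    channels_per_decade: int = DEFAULT_CHANNELS_PER_DECADE,
) -> SizeDistribution:
    """Lognormal dN/dlogDp with count median ``cmd`` nm and geometric SD ``gsd``.

    The discrete channel sum times the log-spacing recovers ``total_number``
    (exactly, by construction on the returned grid).
    """
    if gsd <= 1.0:
        raise ValueError("gsd must be > 1")
    if total_number < 0 or cmd <= 0:
        raise ValueError("total_number must be >= 0 and cmd > 0")
    if grid is None:
        grid = make_channel_grid(channels_per_decade=channels_per_decade)
    grid = np.asarray(grid, dtype=float)
    sigma = math.log(gsd)
    density = (
        math.log(10.0)
        / (math.sqrt(2.0 * math.pi) * sigma)
        * np.exp(-0.5 * (np.log(grid / cmd) / sigma) ** 2)
    )
    dlog = 1.0 / channels_per_decade
    discrete_total = float(np.sum(density) * dlog)
    if discrete_total > 0:
        density = density * (1.0 / discrete_total)
    return SizeDistribution(grid, total_number * density, channels_per_decade)


def bin_mass_fractions_from_mass_median(
    mass_median: float, gsd: float, bin_edges=DEFAULT_BIN_EDGES
) -> np.ndarray:
    """Bin mass fractions of a lognormal *mass* distribution given its median."""
    if gsd <= 1.0:
        raise ValueError("gsd must be > 1")
    if mass_median <= 0:
        raise ValueError("mass_median must be > 0")
    from scipy.stats import norm

    sigma = math.log(gsd)
    z = (np.log(np.asarray(bin_edges, dtype=float) / mass_median)) / sigma
    return np.diff(norm.cdf(z))


def lognormal_bin_mass_fractions(
    cmd: float, gsd: float, bin_edges=DEFAULT_BIN_EDGES
) -> np.ndarray:
    """Fraction of total particle mass falling in each diameter bin.

    Uses the Hatch-Choate shift: the mass distribution of a lognormal number
    distribution is lognormal with the same GSD and median
    ``cmd * exp(3 ln^2 gsd)``.  Fractions are relative to the *total* mass
    over all diameters, so they need not sum to 1 (mass outside
    [100, 1000] nm is carried by no bin).
    """
    if gsd <= 1.0:
        raise ValueError("gsd must be > 1")
    sigma = math.log(gsd)
    return bin_mass_fractions_from_mass_median(
        cmd * math.exp(3.0 * sigma**2), gsd, bin_edges
    )


def number_to_mass(
    dist: SizeDistribution, optics: ParticleOpticalProperties
) -> MassDistribution:
    """Channel-wise conversion dC = (pi/6) Dp^3 rho_p dN (spherical droplets)."""
    d_cm = dist.channel_centers * 1e-7  # nm -> cm
    dc = (math.pi / 6.0) * d_cm**3 * optics.material_density * dist.dN_dlogDp
    return MassDistribution(dist.channel_centers, dc, dist.channels_per_decade)


def size_binned_mass(
    mass_dist: MassDistribution,
    dilution: DilutionConfig | None = None,
    bin_edges=DEFAULT_BIN_EDGES,
) -> SizeBinnedMass:
    """Discrete bin integrals of dC/dlogDp times the box volume, in mg.

    A channel belongs to bin ``[lo, hi)`` if its center falls in the
    half-open interval.  Bin edges outside the measured channel range
    trigger a truncation warning.
    """
    dilution = dilution or DilutionConfig()
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size != 4 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be four strictly increasing values")
    c = mass_dist.channel_centers
    if edges[0] < c[0] or edges[-1] > c[-1]:
        warnings.warn(
            "bin edges extend beyond the measured channel range; "
            "bin masses are truncated to measured channels",
            stacklevel=2,
        )
    vbox_cm3 = dilution.box_volume * 1000.0
    masses = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (c >= lo) & (c < hi)
        grams = float(np.sum(mass_dist.dC_dlogDp[mask]) * mass_dist.dlog * vbox_cm3)
        masses.append(grams * 1000.0)  # g -> mg
    return SizeBinnedMass(*masses)


# ---------------------------------------------------------------------------
# SMPS-export-style tables


def write_smps_table(dist: SizeDistribution, path) -> None:
    pd.DataFrame(
        {"diameter_nm": dist.channel_centers, "dN_dlogDp": dist.dN_dlogDp}
    ).to_csv(path, index=False, float_format="%.17g")


def read_smps_table(
    path, channels_per_decade: int = DEFAULT_CHANNELS_PER_DECADE
) -> SizeDistribution:
    """Read a (diameter_nm, dN_dlogDp) CSV; malformed rows are reported by line."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty SMPS table") from exc
    for col in ("diameter_nm", "dN_dlogDp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    parsed = df[["diameter_nm", "dN_dlogDp"]].apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna().any(axis=1)
    if bad.any():
        lines = [str(i + 2) for i in parsed.index[bad]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {', '.join(lines)}")
    d = parsed["diameter_nm"].to_numpy()
    if np.any(np.diff(d) <= 0):
        i = int(np.argmax(np.diff(d) <= 0))
        raise ValueError(f"{path}: non-monotone diameters near line {i + 2}")
    return SizeDistribution(d, parsed["dN_dlogDp"].to_numpy(), channels_per_decade)


def write_binned_masses(masses, path) -> None:
    """Write (puff_id, m1_mg, m2_mg, m3_mg) rows for a list of SizeBinnedMass."""
    rows = [
        {"puff_id": i, "m1_mg": m.m1, "m2_mg": m.m2, "m3_mg": m.m3}
        for i, m in enumerate(masses)
    ]
    pd.DataFrame(rows, columns=["puff_id", "m1_mg", "m2_mg", "m3_mg"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_binned_masses(path) -> list:
    df = pd.read_csv(path)
    return [
        SizeBinnedMass(row.m1_mg, row.m2_mg, row.m3_mg) for row in df.itertuples()
    ]
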