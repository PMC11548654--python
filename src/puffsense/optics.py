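"""Mie scattering optics for spherical liquid aerosol droplets.

The sensor's forward model rests on the extinction of light by sub-micron
liquid droplets.  For a homogeneous sphere of diameter ``Dp`` illuminated at
wavelength ``lam`` the size parameter is ``x = pi * Dp / lam`` and the Mie
partial-wave series yields the scattering and extinction efficiencies

    Q_sca = (2/x^2) * sum (2n+1) (|a_n|^2 + |b_n|^2)
    Q_ext = (2/x^2) * sum (2n+1) Re(a_n + b_n)

from which the mass-specific scattering cross-section (scattered power per
unit particle mass) follows as ``1.5 * Q / (Dp * rho)``.

Unit conventions used throughout the package:

* wavelengths and diameters in nm,
* material density in g/mL,
* mass-specific cross-sections in m^2/g,
* extinction-matrix entries in base-10 attenuation per (mg/L) mass
  concentration per mm of optical path, so that ``A = f * c * L`` is
  dimensionless with ``c`` in mg/L and ``L`` in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalWavelengthBand",
    "ParticleOpticalProperties",
    "MieResult",
    "ScatteringSpectrum",
    "ExtinctionMatrix",
    "UV_BAND",
    "RED_BAND",
    "IR_BAND",
    "DEFAULT_BANDS",
    "DEFAULT_BIN_EDGES",
    "wiscombe_cutoff",
    "mie_coefficients",
    "scattering_efficiency",
    "band_averaged_efficiency",
    "mass_specific_scattering",
    "mass_extinction_coefficient",
    "band_averaging_deviation",
    "scattering_spectrum",
    "build_extinction_matrix",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class OpticalWavelengthBand:
    """An LED emission band: peak wavelength and FWHM bandwidth, both nm."""

    center_wavelength: float
    fwhm_bandwidth: float
    label: str

    def __post_init__(self) -> None:
        if not (self.center_wavelength > 0):
            raise ValueError("center_wavelength must be > 0")
        if self.fwhm_bandwidth < 0:
            raise ValueError("fwhm_bandwidth must be >= 0")

    def quadrature_wavelengths(self, n_points: int = 21) -> np.ndarray:
        """Uniformly spaced wavelengths spanning the FWHM (rectangular weight)."""
        if self.fwhm_bandwidth == 0:
            return np.array([self.center_wavelength])
        if n_points < 2:
            raise ValueError("n_points must be >= 2 for a finite band")
        half = 0.5 * self.fwhm_bandwidth
        return np.linspace(self.center_wavelength - half, self.center_wavelength + half, n_points)


#: Default LED bands of the three-wavelength photometric module.
UV_BAND = OpticalWavelengthBand(370.0, 10.0, "UV")
RED_BAND = OpticalWavelengthBand(640.0, 17.0, "R")
IR_BAND = OpticalWavelengthBand(940.0, 50.0, "IR")
DEFAULT_BANDS = (UV_BAND, RED_BAND, IR_BAND)

#: Size-bin edges in nm: bin 1 = [100, 300), bin 2 = [300, 600), bin 3 = [600, 1000).
DEFAULT_BIN_EDGES = (100.0, 300.0, 600.0, 1000.0)


@dataclass(frozen=True)
class ParticleOpticalProperties:
    """Refractive index and density of the droplet material.

    The default index 1.45 + 0i is typical of a 70/30 VG/PG e-liquid; the
    default density 1.12 g/mL is the measured e-liquid density.
    """

    refractive_index_real: float = 1.45
    refractive_index_imag: float = 0.0
    material_density: float = 1.12

    def __post_init__(self) -> None:
        if self.refractive_index_real < 1.0:
            raise ValueError("refractive_index_real must be >= 1")
        if self.refractive_index_imag < 0.0:
            raise ValueError("refractive_index_imag must be >= 0 (absorbing convention)")
        if not (self.material_density > 0):
            raise ValueError("material_density must be > 0")

    @property
    def refractive_index(self) -> complex:
        return complex(self.refractive_index_real, self.refractive_index_imag)


@dataclass(frozen=True)
class MieResult:
    size_parameter: float
    q_scattering: float
    q_extinction: float
    n_terms_used: int


@dataclass(frozen=True)
class ScatteringSpectrum:
    """Mass-specific scattering spectra (m^2/g), one series per band."""

    diameters: np.ndarray
    efficiency_per_mass: dict  # label -> np.ndarray aligned with diameters

    def to_frame(self):
        import pandas as pd

        data = {"diameter_nm": self.diameters}
        for label, series in self.efficiency_per_mass.items():
            data[f"eff_per_mass_{label.lower()}"] = series
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ExtinctionMatrix:
    """Bin-by-wavelength mass-extinction coefficients f[i][j].

    ``coefficients[i, j]`` is base-10 attenuation per (mg/L) per mm for size
    bin ``i`` (100-300, 300-600, 600-1000 nm) and band ``j`` (UV, R, IR).
    """

    coefficients: np.ndarray
    bin_edges: tuple = DEFAULT_BIN_EDGES
    band_labels: tuple = ("UV", "R", "IR")

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (3, 3):
            raise ValueError("extinction matrix must be 3x3")
        if np.any(c < 0):
            raise ValueError("extinction coefficients must be >= 0")
        object.__setattr__(self, "coefficients", c)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.coefficients))


def wiscombe_cutoff(x: float) -> int:
    """Series truncation order: x + 4.05 x^(1/3) + 2."""
    return int(math.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(size_parameter: float, refractive_index: complex):
    """Mie partial-wave coefficients a_n, b_n for n = 1..n_max.

    Uses downward recurrence for the logarithmic derivative of the
    Riccati-Bessel function psi at the interior argument m*x (stable for
    large or absorbing spheres) and upward recurrence for psi, chi at x.
    """
    x = float(size_parameter)
    m = complex(refractive_index)
    if not math.isfinite(x) or not (math.isfinite(m.real) and math.isfinite(m.imag)):
        raise ValueError("non-finite size parameter or refractive index")
    if x <= 0:
        raise ValueError("size_parameter must be > 0")

    nmax = wiscombe_cutoff(x)
    mx = m * x
    nmx = max(nmax, int(math.ceil(abs(mx)))) + 16

    # Downward recurrence for D_n(mx) = psi_n'(mx) / psi_n(mx).
    d = np.zeros(nmx + 1, dtype=complex)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    n = np.arange(1, nmax + 1)
    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence.
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi[0] = math.cos(x), math.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi[0] = -math.sin(x), math.cos(x)
    for k in range(1, nmax + 1):
        psi[k] = (2 * k - 1) / x * psi[k - 1] - (psi[k - 2] if k >= 2 else psi_m1)
        chi[k] = (2 * k - 1) / x * chi[k - 1] - (chi[k - 2] if k >= 2 else chi_m1)
    xi = psi - 1j * chi  # xi_n(x) = psi_n - i chi_n = x * h_n^(1)(x)

    dn = d[1 : nmax + 1]
    ta = dn / m + n / x
    tb = dn * m + n / x
    a = (ta * psi[1:] - psi[:-1]) / (ta * xi[1:] - xi[:-1])
    b = (tb * psi[1:] - psi[:-1]) / (tb * xi[1:] - xi[:-1])
    return a, b


def _efficiencies(x: float, a: np.ndarray, b: np.ndarray):
    n = np.arange(1, a.size + 1)
    w = 2 * n + 1
    qsca = (2.0 / x**2) * float(np.sum(w * (np.abs(a) ** 2 + np.abs(b) ** 2)))
    qext = (2.0 / x**2) * float(np.sum(w * np.real(a + b)))
    return qsca, qext


def scattering_efficiency(
    diameter: float, wavelength: float, optics: ParticleOpticalProperties
) -> MieResult:
    """Mie efficiencies for a sphere of ``diameter`` nm at ``wavelength`` nm."""
    if not (diameter > 0):
        raise ValueError("diameter must be > 0")
    if not (wavelength > 0):
        raise ValueError("wavelength must be > 0")
    x = math.pi * diameter / wavelength
    a, b = mie_coefficients(x, optics.refractive_index)
    qsca, qext = _efficiencies(x, a, b)
    return MieResult(x, qsca, qext, a.size)


def band_averaged_efficiency(
    band: OpticalWavelengthBand,
    diameter: float,
    optics: ParticleOpticalProperties,
    n_points: int = 21,
    quantity: str = "scattering",
) -> float:
    """Scattering (or extinction) efficiency averaged uniformly over the FWHM.

    A zero-bandwidth band reduces to the monochromatic efficiency.
    """
    values = []
    for lam in band.quadrature_wavelengths(n_points):
        res = scattering_efficiency(diameter, lam, optics)
        values.append(res.q_scattering if quantity == "scattering" else res.q_extinction)
    return float(np.mean(values))


def _mass_specific(q: float, diameter_nm: float, density_g_ml: float) -> float:
    # 1.5 * Q / (D * rho): D in m, rho in g/m^3 (= 1e6 * g/mL) -> m^2/g
    return 1.5 * q / (diameter_nm * 1e-9 * density_g_ml * 1e6)


def mass_specific_scattering(
    diameter: float,
    band: OpticalWavelengthBand,
    optics: ParticleOpticalProperties,
    n_points: int = 21,
) -> float:
    """Band-averaged scattered power per unit particle mass, m^2/g.

    Geometric cross-section over particle mass gives
    ``Q * (pi D^2/4) / ((pi/6) D^3 rho) = 1.5 Q / (D rho)``.
    """
    if not (0 < diameter <= 10_000):
        raise ValueError("diameter must be in (0, 10 um]")
    q = band_averaged_efficiency(band, diameter, optics, n_points, "scattering")
    return _mass_specific(q, diameter, optics.material_density)


def mass_extinction_coefficient(
    diameter: float,
    band: OpticalWavelengthBand,
    optics: ParticleOpticalProperties,
    n_points: int = 21,
) -> float:
    """Band-averaged base-10 mass extinction: attenuation per (mg/L) per mm."""
    q = band_averaged_efficiency(band, diameter, optics, n_points, "extinction")
    sigma = _mass_specific(q, diameter, optics.material_density)  # m^2/g == (1/m)/(g/m^3)
    # 1 mg/L == 1 g/m^3; path in mm -> 1e-3 m; base-10 -> / ln 10
    return sigma * 1e-3 / LN10


def band_averaging_deviation(
    band: OpticalWavelengthBand,
    diameters: np.ndarray,
    optics: ParticleOpticalProperties,
    weights: np.ndarray | None = None,
    n_points: int = 21,
) -> float:
    """Weighted mean relative deviation of band-averaged from monochromatic Q_sca.

    Quantifies how much the finite LED bandwidth perturbs the scattering
    response relative to an ideal single-wavelength source.  ``weights``
    default to uniform; pass within-distribution mass weights to aggregate
    over an aerosol population.
    """
    diameters = np.asarray(diameters, dtype=float)
    mono = OpticalWavelengthBand(band.center_wavelength, 0.0, band.label)
    rel = np.empty(diameters.size)
    for i, dp in enumerate(diameters):
        q_band = band_averaged_efficiency(band, dp, optics, n_points)
        q_mono = band_averaged_efficiency(mono, dp, optics)
        rel[i] = abs(q_band - q_mono) / q_mono
    if weights is None:
        return float(np.mean(rel))
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(rel * weights) / np.sum(weights))


def scattering_spectrum(
    diameters: np.ndarray,
    bands=DEFAULT_BANDS,
    optics: ParticleOpticalProperties | None = None,
    n_points: int = 21,
) -> ScatteringSpectrum:
    """Mass-specific scattering spectra over a diameter grid, one per band."""
    optics = optics or ParticleOpticalProperties()
    diameters = np.asarray(diameters, dtype=float)
    if diameters.ndim != 1 or np.any(np.diff(diameters) <= 0):
        raise ValueError("diameter grid must be 1-D and strictly increasing")
    series = {}
    for band in bands:
        series[band.label] = np.array(
            [mass_specific_scattering(dp, band, optics, n_points) for dp in diameters]
        )
    return ScatteringSpectrum(diameters, series)


def _default_bin_weights(lo: float, hi: float, channels_per_decade: int = 64,
                         cmd: float = 250.0, gsd: float = 1.6):
    """Within-bin mass weights from a representative lognormal number distribution."""
    n_ch = max(int(round(channels_per_decade * math.log10(hi / lo))), 4)
    centers = lo * (hi / lo) ** ((np.arange(n_ch) + 0.5) / n_ch)
    sigma = math.log(gsd)
    dn = np.exp(-0.5 * ((np.log(centers / cmd)) / sigma) ** 2)
    return centers, dn * centers**3


def build_extinction_matrix(
    bins=None,
    bands=DEFAULT_BANDS,
    optics: ParticleOpticalProperties | None = None,
    representative_distribution=None,
    n_points: int = 21,
) -> ExtinctionMatrix:
    """Mass-weighted mean extinction per bin and band.

    ``f[i][j]`` is the mass-weighted mean of the per-mass extinction over
    diameters in bin ``i`` at band ``j``; weighting comes from
    ``representative_distribution`` (any object with ``channel_centers`` in nm
    and ``dN_dlogDp``), or from a default lognormal (CMD 250 nm, GSD 1.6).
    """
    optics = optics or ParticleOpticalProperties()
    if bins is None:
        e = DEFAULT_BIN_EDGES
        bins = [(e[0], e[1]), (e[1], e[2]), (e[2], e[3])]
    if len(bins) != 3 or len(bands) != 3:
        raise ValueError("three bins and three bands are required")

    f = np.zeros((3, 3))
    for i, (lo, hi) in enumerate(bins):
        if representative_distribution is None:
            centers, weights = _default_bin_weights(lo, hi)
        else:
            d = np.asarray(representative_distribution.channel_centers, dtype=float)
            dn = np.asarray(representative_distribution.dN_dlogDp, dtype=float)
            mask = (d >= lo) & (d < hi)
            centers, weights = d[mask], dn[mask] * d[mask] ** 3
        if centers.size == 0 or np.sum(weights) <= 0:
            raise ValueError(f"no mass in bin [{lo}, {hi}) nm of the representative distribution")
        for j, band in enumerate(bands):
            eps = np.array(
                [mass_extinction_coefficient(dp, band, optics, n_points) for dp in centers]
            )
            f[i, j] = float(np.sum(eps * weights) / np.sum(weights))
    return ExtinctionMatrix(f, tuple(np.unique([b for pair in bins for b in pair])),
                            tuple(b.label for b in bands))
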