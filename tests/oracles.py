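"""Independent brute-force Mie oracle for cross-checking the package.

Implements the partial-wave coefficients directly from spherical Bessel
functions (scipy) with a doubled truncation order and compensated (fsum)
summation.  Valid for real refractive indices; deliberately shares no code
with puffsense.optics.
"""

import math

import numpy as np
from scipy.special import spherical_jn, spherical_yn


def mie_efficiencies_oracle(x: float, m: float):
    """(q_sca, q_ext) for a non-absorbing sphere, brute-force summation."""
    nmax = 2 * int(math.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))
    n = np.arange(1, nmax + 1)
    mx = m * x

    def psi(rho, order):
        return rho * spherical_jn(order, rho)

    def psi_prime(rho, order):
        return spherical_jn(order, rho) + rho * spherical_jn(order, rho, derivative=True)

    def xi(rho, order):
        return rho * (spherical_jn(order, rho) + 1j * spherical_yn(order, rho))

    def xi_prime(rho, order):
        return (
            spherical_jn(order, rho)
            + rho * spherical_jn(order, rho, derivative=True)
            + 1j * (spherical_yn(order, rho) + rho * spherical_yn(order, rho, derivative=True))
        )

    pmx, dpmx = psi(mx, n), psi_prime(mx, n)
    px, dpx = psi(x, n), psi_prime(x, n)
    xx, dxx = xi(x, n), xi_prime(x, n)

    a = (m * pmx * dpx - px * dpmx) / (m * pmx * dxx - xx * dpmx)
    b = (pmx * dpx - m * px * dpmx) / (pmx * dxx - m * xx * dpmx)

    w = 2 * n + 1
    qsca = (2.0 / x**2) * math.fsum(w * (np.abs(a) ** 2 + np.abs(b) ** 2))
    qext = (2.0 / x**2) * math.fsum(w * np.real(a + b))
    return qsca, qext


def rayleigh_qsca(x: float, m: float) -> float:
    """Closed-form small-particle scattering efficiency."""
    return (8.0 / 3.0) * x**4 * abs((m**2 - 1.0) / (m**2 + 2.0)) ** 2
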