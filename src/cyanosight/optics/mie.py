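"""Analytic scattering of a plane wave by an infinite dielectric cylinder.

This is the exact 2-D counterpart of the FDTD simulation: a monochromatic
plane wave travelling along +x hits a homogeneous dielectric cylinder
(the model cell cross-section).  The total field — incident + scattered
outside, transmitted inside — is evaluated as a cylindrical-harmonic
series of Bessel/Hankel functions, and converted into the same intensity
the time-domain solver measures: the time average, over an optical
period, of the instantaneous Poynting-vector magnitude |S(t)|, normalized
to the incident wave.

Conventions: time factor exp(-i omega t); natural units c = eps0 = mu0 = 1;
lengths in µm.  'TM' means the electric field along the cylinder axis
(out-of-plane E), 'TE' the magnetic field along the axis.
"""

from __future__ import annotations

import numpy as np
from scipy.special import h1vp, hankel1, jv, jvp

__all__ = ["mie_cylinder_field", "mie_cylinder_intensity_map", "series_order"]


def series_order(size_parameter: float) -> int:
    """Truncation order for a cylindrical-harmonic series: x + 4 x^(1/3) + 10."""
    x = float(size_parameter)
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 10.0))


def _mode_coefficients(n: int, u: float, v: float, ratio: float):
    """Scattered (b_n) and interior (d_n) coefficients for harmonic n.

    Continuity of the axial field and of ``ratio``-weighted radial
    derivative at the cylinder surface; ``ratio`` is k1/k0 for TM and
    (k1/eps1)/(k0/eps0) for TE.  Solved as a 2x2 linear system.
    """
    # unknowns (b_n, d_n):
    #   b_n H_n(u) - d_n J_n(v) = -J_n(u)
    #   b_n H_n'(u) - ratio d_n J_n'(v) = -J_n'(u)
    A = np.array(
        [
            [hankel1(n, u), -jv(n, v)],
            [h1vp(n, u), -ratio * jvp(n, v)],
        ],
        dtype=complex,
    )
    rhs = np.array([-jv(n, u), -jvp(n, u)], dtype=complex)
    b, d = np.linalg.solve(A, rhs)
    return b, d


def mie_cylinder_field(
    wavelength_um: float,
    radius_um: float,
    n_cylinder: float,
    n_background: float,
    x_um: np.ndarray,
    y_um: np.ndarray,
    polarization: str = "TM",
    n_terms: int | None = None,
    check_convergence: bool = True,
    n_phase_samples: int = 32,
) -> dict:
    """Total electromagnetic field and intensity at Cartesian points.

    Points are relative to the cylinder centre; the incident wave travels
    along +x with unit axial-field amplitude.  Returns a dict with the
    axial field phasor ``axial`` and ``intensity`` (time-averaged |S(t)|,
    normalized to incident).
    """
    if polarization not in ("TM", "TE"):
        raise ValueError("polarization must be 'TM' or 'TE'")
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)

    omega = 2 * np.pi / wavelength_um
    k0 = n_background * omega
    k1 = n_cylinder * omega
    u = k0 * radius_um
    v = k1 * radius_um
    if polarization == "TM":
        ratio = k1 / k0
    else:
        ratio = (k1 / n_cylinder**2) / (k0 / n_background**2)

    N = n_terms if n_terms is not None else series_order(max(u, v))

    inside = r < radius_um
    k = np.where(inside, k1, k0)
    kr = k * r

    # The incident plane wave is evaluated in closed form outside the
    # cylinder (its own series would need orders up to k*r_max); only the
    # scattered (outside) / transmitted (inside) fields use the series,
    # whose coefficients decay beyond the size parameter.
    axial = np.zeros(r.shape, dtype=complex)  # Ez (TM) or Hz (TE)
    dr = np.zeros(r.shape, dtype=complex)  # d(axial)/dr
    dphi = np.zeros(r.shape, dtype=complex)  # d(axial)/dphi
    tail = 0.0
    for n in range(-N, N + 1):
        b, d = _mode_coefficients(n, u, v, ratio)
        radial = np.where(inside, d * jv(n, kr), b * hankel1(n, kr))
        radial_p = k * np.where(inside, d * jvp(n, kr), b * h1vp(n, kr))
        phase = (1j) ** n * np.exp(1j * n * phi)
        term = phase * radial
        axial += term
        dr += phase * radial_p
        dphi += 1j * n * term
        if abs(n) == N:
            tail = max(tail, float(np.max(np.abs(term))))
    if check_convergence and tail > 1e-8 * max(1.0, float(np.max(np.abs(axial)))):
        raise RuntimeError(
            f"cylindrical-harmonic series not converged at order {N} "
            f"(tail {tail:.2e}); increase n_terms"
        )
    plane = np.exp(1j * k0 * x)
    axial = axial + np.where(inside, 0.0, plane)
    # d/dr and d/dphi of exp(i k0 r cos phi)
    dr = dr + np.where(inside, 0.0, 1j * k0 * np.cos(phi) * plane)
    dphi = dphi + np.where(inside, 0.0, -1j * k0 * r * np.sin(phi) * plane)

    # transverse field phasors in the local polar basis
    r_safe = np.where(r > 0, r, 1.0)
    if polarization == "TM":
        # H = (1/(i omega)) curl(Ez zhat)
        Hr = dphi / (1j * omega * r_safe)
        Hphi = -dr / (1j * omega)
        # S = E x H*: A_r = -Re(Ez Hphi*)/2, A_phi = Re(Ez Hr*)/2
        Ar = -0.5 * np.real(axial * np.conj(Hphi))
        Aphi = 0.5 * np.real(axial * np.conj(Hr))
        Br = -0.5 * axial * Hphi
        Bphi = 0.5 * axial * Hr
        inc = 0.5 * n_background
    else:
        eps = np.where(inside, n_cylinder**2, n_background**2)
        # E = (i/(omega eps)) curl(Hz zhat)
        Er = 1j * dphi / (omega * eps * r_safe)
        Ephi = -1j * dr / (omega * eps)
        # S = E x H*: A_r = Re(Ephi Hz*)/2, A_phi = -Re(Er Hz*)/2
        Ar = 0.5 * np.real(Ephi * np.conj(axial))
        Aphi = -0.5 * np.real(Er * np.conj(axial))
        Br = 0.5 * Ephi * axial
        Bphi = -0.5 * Er * axial
        inc = 0.5 / n_background

    # <|S(t)|> with S(t) = A + Re(B e^{-i psi}), psi = 2 omega t
    psi = np.linspace(0.0, 2 * np.pi, n_phase_samples, endpoint=False)
    acc = np.zeros(r.shape)
    for p in psi:
        sr = Ar + np.real(Br * np.exp(-1j * p))
        sp = Aphi + np.real(Bphi * np.exp(-1j * p))
        acc += np.hypot(sr, sp)
    intensity = acc / n_phase_samples / inc

    return {
        "axial": axial,
        "intensity": intensity,
        "mean_sr": Ar / inc,
        "mean_sphi": Aphi / inc,
        "n_terms": N,
    }


def mie_cylinder_intensity_map(
    wavelength_um: float,
    radius_um: float,
    n_cylinder: float,
    n_background: float,
    x_grid_um: np.ndarray,
    y_grid_um: np.ndarray,
    polarization: str = "TM",
    **kw,
) -> np.ndarray:
    """Intensity on a Cartesian grid (meshgrid of the two coordinate vectors).

    Returned array is indexed [i, j] = (x, y), matching the FDTD FieldMap.
    """
    X, Y = np.meshgrid(np.asarray(x_grid_um), np.asarray(y_grid_um),
                       indexing="ij")
    out = mie_cylinder_field(
        wavelength_um, radius_um, n_cylinder, n_background, X, Y,
        polarization, **kw,
    )
    return out["intensity"]
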