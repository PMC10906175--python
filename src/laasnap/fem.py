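"""Explicit central-difference FEM for first-order tetrahedra with the Ogden
material.

Solver design notes
-------------------
* Units: mm–MPa–tonne–s internally (energies in mJ); the public interface
  takes pressures in mmHg and density in kg/m^3.
* Constant-strain tets lock volumetrically at nu = 0.495, so the volumetric
  response uses nodal-volume-averaged J (average nodal pressure): nodal
  volume ratios J_a = V_a / V0_a are formed from quarter-volume lumping and
  the volumetric energy sum runs over nodes.  Internal forces are the exact
  gradient of this discrete energy (deviatoric per element + volumetric per
  node), which the energy-audit and force-consistency tests rely on.
* Bulk viscosity: linear term b1*rho*c_d*Le*evdot always active, quadratic
  rho*(b2*Le*evdot)^2 only in volumetric compression; both enter as a
  hydrostatic stress with the sign of the volumetric strain rate, so their
  dissipation is non-negative.
* Cavity pressure is a follower load on the current inner facets; trabeculae
  are tension-only cables with the uniaxial Ogden closed form; self-contact
  is a frictionless node-to-triangle penalty with a KD-tree broad phase.
* Orifice-ring nodes have their translations pinned each step; with
  translational-only tet nodes this leaves rotation about the ring free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .geometry import VolumeMesh
from .ogden import OgdenMaterial, initial_moduli
from .protocol import PressureProtocol
from .units import mmhg_to_mpa

__all__ = [
    "ExplicitConfig", "EnergyTrace", "SolveResult", "ElementInversionError",
    "lumped_mass", "stable_time_increment", "advance", "run_protocol",
    "internal_forces", "follower_pressure_forces", "trabecula_forces",
    "strain_energy", "max_principal_stress_field", "cavity_volume",
    "bulk_viscosity_pressure",
]


@dataclass(frozen=True)
class ExplicitConfig:
    """Explicit-solver controls.

    ``b1``/``b2`` are the linear/quadratic bulk-viscosity coefficients (the
    common explicit-dynamics defaults); ``mass_scaling`` multiplies density
    (dt grows with its square root); ``mass_damping`` is a mass-proportional
    viscous coefficient (1/s) used for dynamic-relaxation settling;
    ``max_kinetic_fraction`` is the quasi-static QC threshold on
    kinetic/strain energy outside snap events."""

    b1: float = 0.06
    b2: float = 1.2
    dt_safety: float = 0.9
    mass_scaling: float = 1.0
    mass_damping: float = 0.0
    contact_penalty: float = 0.3      # MPa/mm, per tributary area
    contact_offset: float = 0.5       # mm clearance where repulsion begins
    contact_enabled: bool = False
    contact_rebuild: int = 25         # broad-phase refresh interval, steps
    output_interval: float = 1e-3     # s between trace samples
    max_kinetic_fraction: float = 0.10
    nodal_pressure: bool = True       # average-nodal-pressure volumetric term

    def __post_init__(self) -> None:
        if min(self.b1, self.b2) < 0 or not (0 < self.dt_safety <= 1):
            raise ValueError("b1, b2 must be >= 0 and dt_safety in (0, 1]")
        if self.mass_scaling < 1:
            raise ValueError("mass_scaling must be >= 1")


class ElementInversionError(RuntimeError):
    def __init__(self, element: int, time: float):
        self.element = int(element)
        self.time = float(time)
        super().__init__(f"element {element} inverted (J <= 0) at "
                         f"t = {time:.6g} s")


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _eig3_sym(a00, a11, a22, a01, a02, a12):
    """Ascending eigenvalues of a symmetric 3x3 matrix (analytic)."""
    p1 = a01 * a01 + a02 * a02 + a12 * a12
    if p1 < 1e-30 * (a00 * a00 + a11 * a11 + a22 * a22 + 1e-300):
        w0 = min(a00, min(a11, a22))
        w2 = max(a00, max(a11, a22))
        w1 = a00 + a11 + a22 - w0 - w2
        return w0, w1, w2
    q = (a00 + a11 + a22) / 3.0
    p2 = ((a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2 + 2.0 * p1)
    p = np.sqrt(p2 / 6.0)
    b00 = (a00 - q) / p
    b11 = (a11 - q) / p
    b22 = (a22 - q) / p
    b01 = a01 / p
    b02 = a02 / p
    b12 = a12 / p
    detb = (b00 * (b11 * b22 - b12 * b12)
            - b01 * (b01 * b22 - b12 * b02)
            + b02 * (b01 * b12 - b11 * b02))
    r = detb / 2.0
    if r <= -1.0:
        phi = np.pi / 3.0
    elif r >= 1.0:
        phi = 0.0
    else:
        phi = np.arccos(r) / 3.0
    w2 = q + 2.0 * p * np.cos(phi)
    w0 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    w1 = 3.0 * q - w2 - w0
    return w0, w1, w2


@njit(cache=True, inline="always")
def _ogden_dev_sigma6(b00, b11, b22, b01, b02, b12, J, mu, alpha):
    """Deviatoric Cauchy stress (6 symmetric components) and deviatoric
    energy density from the left Cauchy-Green tensor.

    The stress is the isotropic tensor function sigma = c0 I + c1 b + c2 b^2
    whose coefficients interpolate the principal values beta_i at the
    eigenvalues of b (reduced fits when eigenvalues coincide), which avoids
    forming eigenvectors."""
    w0, w1, w2 = _eig3_sym(b00, b11, b22, b01, b02, b12)
    if w0 < 1e-20:
        w0 = 1e-20
    Jm23 = J ** (-2.0 / 3.0)
    lb0 = np.sqrt(w0 * Jm23)
    lb1 = np.sqrt(w1 * Jm23)
    lb2 = np.sqrt(w2 * Jm23)
    t0 = 0.0
    t1 = 0.0
    t2 = 0.0
    wdev = 0.0
    for k in range(mu.shape[0]):
        c = 2.0 * mu[k] / alpha[k]
        p0 = lb0 ** alpha[k]
        p1_ = lb1 ** alpha[k]
        p2_ = lb2 ** alpha[k]
        t0 += c * p0
        t1 += c * p1_
        t2 += c * p2_
        wdev += (c / alpha[k]) * (p0 + p1_ + p2_ - 3.0)
    tm = (t0 + t1 + t2) / 3.0
    beta0 = (t0 - tm) / J
    beta1 = (t1 - tm) / J
    beta2 = (t2 - tm) / J

    tol = 1e-8 * (w2 if w2 > 1e-30 else 1e-30)
    d10 = w1 - w0
    d21 = w2 - w1
    if d10 <= tol and d21 <= tol:
        bm = (beta0 + beta1 + beta2) / 3.0
        return bm, bm, bm, 0.0, 0.0, 0.0, wdev
    if d10 <= tol:
        # linear fit through (w01, beta01) and (w2, beta2)
        c1 = (beta2 - 0.5 * (beta0 + beta1)) / (w2 - 0.5 * (w0 + w1))
        c0 = beta2 - c1 * w2
        c2 = 0.0
    elif d21 <= tol:
        c1 = (0.5 * (beta1 + beta2) - beta0) / (0.5 * (w1 + w2) - w0)
        c0 = beta0 - c1 * w0
        c2 = 0.0
    else:
        # quadratic Lagrange interpolation through the three principal pairs
        d01 = w0 - w1
        d02 = w0 - w2
        d12 = w1 - w2
        l0 = beta0 / (d01 * d02)
        l1 = beta1 / (-d01 * d12)
        l2 = beta2 / (d02 * d12)
        c2 = l0 + l1 + l2
        c1 = -(l0 * (w1 + w2) + l1 * (w0 + w2) + l2 * (w0 + w1))
        c0 = l0 * w1 * w2 + l1 * w0 * w2 + l2 * w0 * w1
    # b^2 (symmetric)
    q00 = b00 * b00 + b01 * b01 + b02 * b02
    q11 = b01 * b01 + b11 * b11 + b12 * b12
    q22 = b02 * b02 + b12 * b12 + b22 * b22
    q01 = b00 * b01 + b01 * b11 + b02 * b12
    q02 = b00 * b02 + b01 * b12 + b02 * b22
    q12 = b01 * b02 + b11 * b12 + b12 * b22
    s00 = c0 + c1 * b00 + c2 * q00
    s11 = c0 + c1 * b11 + c2 * q11
    s22 = c0 + c1 * b22 + c2 * q22
    s01 = c1 * b01 + c2 * q01
    s02 = c1 * b02 + c2 * q02
    s12 = c1 * b12 + c2 * q12
    return s00, s11, s22, s01, s02, s12, wdev


@njit(cache=True)
def _element_pass(x, tets, g0, V0, J_prev, mu, alpha, D1, rho, cd,
                  b1, b2, dt, nodal_V0, use_nodal_p, f):
    """Internal (deviatoric + volumetric + bulk-viscosity) nodal forces.

    Returns (E_dev, E_vol, visc_power, J_new, min_le, bad_element).
    """
    E = tets.shape[0]
    N = x.shape[0]
    J_new = np.empty(E)
    q_visc = np.empty(E)
    dVdx = np.empty((E, 4, 3))
    nodal_V = np.zeros(N)
    E_dev = 0.0
    visc_power = 0.0
    min_le = 1e30
    bad = -1

    for e in range(E):
        n0 = tets[e, 0]
        n1 = tets[e, 1]
        n2 = tets[e, 2]
        n3 = tets[e, 3]
        F00 = F01 = F02 = F10 = F11 = F12 = F20 = F21 = F22 = 0.0
        for a in range(4):
            na = tets[e, a]
            ga0 = g0[e, a, 0]
            ga1 = g0[e, a, 1]
            ga2 = g0[e, a, 2]
            F00 += x[na, 0] * ga0
            F01 += x[na, 0] * ga1
            F02 += x[na, 0] * ga2
            F10 += x[na, 1] * ga0
            F11 += x[na, 1] * ga1
            F12 += x[na, 1] * ga2
            F20 += x[na, 2] * ga0
            F21 += x[na, 2] * ga1
            F22 += x[na, 2] * ga2
        J = (F00 * (F11 * F22 - F12 * F21)
             - F01 * (F10 * F22 - F12 * F20)
             + F02 * (F10 * F21 - F11 * F20))
        if J <= 0.0:
            bad = e
            break
        J_new[e] = J
        Ve = J * V0[e]
        nodal_V[n0] += 0.25 * Ve
        nodal_V[n1] += 0.25 * Ve
        nodal_V[n2] += 0.25 * Ve
        nodal_V[n3] += 0.25 * Ve

        # inverse transpose of F (scaled by 1/J)
        iJ = 1.0 / J
        T00 = (F11 * F22 - F12 * F21) * iJ
        T01 = (F12 * F20 - F10 * F22) * iJ
        T02 = (F10 * F21 - F11 * F20) * iJ
        T10 = (F02 * F21 - F01 * F22) * iJ
        T11 = (F00 * F22 - F02 * F20) * iJ
        T12 = (F01 * F20 - F00 * F21) * iJ
        T20 = (F01 * F12 - F02 * F11) * iJ
        T21 = (F02 * F10 - F00 * F12) * iJ
        T22 = (F00 * F11 - F01 * F10) * iJ

        # left Cauchy-Green b = F F^T (symmetric)
        b00 = F00 * F00 + F01 * F01 + F02 * F02
        b11 = F10 * F10 + F11 * F11 + F12 * F12
        b22 = F20 * F20 + F21 * F21 + F22 * F22
        b01 = F00 * F10 + F01 * F11 + F02 * F12
        b02 = F00 * F20 + F01 * F21 + F02 * F22
        b12 = F10 * F20 + F11 * F21 + F12 * F22
        s00, s11, s22, s01, s02, s12, wdev = _ogden_dev_sigma6(
            b00, b11, b22, b01, b02, b12, J, mu, alpha)
        E_dev += wdev * V0[e]

        # spatial gradients, deviatoric force and volume gradient
        for a in range(4):
            na = tets[e, a]
            ga0 = g0[e, a, 0]
            ga1 = g0[e, a, 1]
            ga2 = g0[e, a, 2]
            gx0 = T00 * ga0 + T01 * ga1 + T02 * ga2
            gx1 = T10 * ga0 + T11 * ga1 + T12 * ga2
            gx2 = T20 * ga0 + T21 * ga1 + T22 * ga2
            dVdx[e, a, 0] = Ve * gx0
            dVdx[e, a, 1] = Ve * gx1
            dVdx[e, a, 2] = Ve * gx2
            f[na, 0] -= Ve * (s00 * gx0 + s01 * gx1 + s02 * gx2)
            f[na, 1] -= Ve * (s01 * gx0 + s11 * gx1 + s12 * gx2)
            f[na, 2] -= Ve * (s02 * gx0 + s12 * gx1 + s22 * gx2)

        # characteristic length: min altitude = 3 V / max face area
        amax = 0.0
        for a in range(4):
            i1 = tets[e, (a + 1) % 4]
            i2 = tets[e, (a + 2) % 4]
            i3 = tets[e, (a + 3) % 4]
            ux = x[i2, 0] - x[i1, 0]
            uy = x[i2, 1] - x[i1, 1]
            uz = x[i2, 2] - x[i1, 2]
            vx = x[i3, 0] - x[i1, 0]
            vy = x[i3, 1] - x[i1, 1]
            vz = x[i3, 2] - x[i1, 2]
            cxx = uy * vz - uz * vy
            cyy = uz * vx - ux * vz
            czz = ux * vy - uy * vx
            area = 0.5 * np.sqrt(cxx * cxx + cyy * cyy + czz * czz)
            if area > amax:
                amax = area
        le = 3.0 * Ve / amax if amax > 0 else 1e30
        if le < min_le:
            min_le = le

        # bulk viscosity
        if dt > 0.0:
            evdot = (J - J_prev[e]) / (dt * J)
            q = b1 * rho * cd * le * evdot
            if evdot < 0.0:
                q -= rho * (b2 * le * evdot) ** 2
            q_visc[e] = q
            visc_power += q * evdot * Ve
        else:
            q_visc[e] = 0.0

    if bad >= 0:
        return 0.0, 0.0, 0.0, J_new, 0.0, bad

    # volumetric term.  Smoothed formulation: E_vol = sum_e V0_e U(Jbar_e)
    # with Jbar_e the mean of the quarter-volume nodal volume ratios J_a;
    # the force is the exact gradient of this energy, which smooths the
    # pressure over a two-ring stencil and relieves the volumetric locking
    # of constant-strain tets at nu near 0.5.
    E_vol = 0.0
    if use_nodal_p:
        J_node = np.ones(N)
        for n in range(N):
            if nodal_V0[n] > 0.0:
                J_node[n] = nodal_V[n] / nodal_V0[n]
        w_num = np.zeros(N)
        for e in range(E):
            Jbar = 0.25 * (J_node[tets[e, 0]] + J_node[tets[e, 1]]
                           + J_node[tets[e, 2]] + J_node[tets[e, 3]])
            pe0 = 2.0 * (Jbar - 1.0) / D1
            E_vol += V0[e] * (Jbar - 1.0) ** 2 / D1
            for a in range(4):
                w_num[tets[e, a]] += 0.25 * V0[e] * pe0
        w_node = np.zeros(N)
        for n in range(N):
            if nodal_V0[n] > 0.0:
                w_node[n] = w_num[n] / nodal_V0[n]
        for e in range(E):
            pbar = 0.25 * (w_node[tets[e, 0]] + w_node[tets[e, 1]]
                           + w_node[tets[e, 2]] + w_node[tets[e, 3]])
            ptot = pbar + q_visc[e]
            for a in range(4):
                na = tets[e, a]
                f[na, 0] -= ptot * dVdx[e, a, 0]
                f[na, 1] -= ptot * dVdx[e, a, 1]
                f[na, 2] -= ptot * dVdx[e, a, 2]
    else:
        for e in range(E):
            pe = 2.0 * (J_new[e] - 1.0) / D1
            E_vol += V0[e] * (J_new[e] - 1.0) ** 2 / D1
            ptot = pe + q_visc[e]
            for a in range(4):
                na = tets[e, a]
                f[na, 0] -= ptot * dVdx[e, a, 0]
                f[na, 1] -= ptot * dVdx[e, a, 1]
                f[na, 2] -= ptot * dVdx[e, a, 2]

    return E_dev, E_vol, visc_power, J_new, min_le, -1


@njit(cache=True)
def _pressure_pass(x, facets, p, f):
    """Follower pressure p (MPa) on oriented facets; force p*A*n split evenly.
    Returns the flux volume (1/3) sum x_c . A n (cavity volume for closed
    surfaces with outward normals)."""
    vol = 0.0
    for k in range(facets.shape[0]):
        i0 = facets[k, 0]
        i1 = facets[k, 1]
        i2 = facets[k, 2]
        ux = x[i1, 0] - x[i0, 0]
        uy = x[i1, 1] - x[i0, 1]
        uz = x[i1, 2] - x[i0, 2]
        vx = x[i2, 0] - x[i0, 0]
        vy = x[i2, 1] - x[i0, 1]
        vz = x[i2, 2] - x[i0, 2]
        anx = 0.5 * (uy * vz - uz * vy)
        any_ = 0.5 * (uz * vx - ux * vz)
        anz = 0.5 * (ux * vy - uy * vx)
        cx = (x[i0, 0] + x[i1, 0] + x[i2, 0]) / 3.0
        cy = (x[i0, 1] + x[i1, 1] + x[i2, 1]) / 3.0
        cz = (x[i0, 2] + x[i1, 2] + x[i2, 2]) / 3.0
        vol += (cx * anx + cy * any_ + cz * anz) / 3.0
        fx = p * anx / 3.0
        fy = p * any_ / 3.0
        fz = p * anz / 3.0
        for a in range(3):
            na = facets[k, a]
            f[na, 0] += fx
            f[na, 1] += fy
            f[na, 2] += fz
    return vol


@njit(cache=True)
def _cable_pass(x, cab, A0, L0, mu, alpha, f):
    """Tension-only trabecula cable forces (uniaxial Ogden closed form).
    Returns (cable strain energy, max cable force)."""
    E_cab = 0.0
    fmax = 0.0
    for c in range(cab.shape[0]):
        na = cab[c, 0]
        nb = cab[c, 1]
        dx = x[nb, 0] - x[na, 0]
        dy = x[nb, 1] - x[na, 1]
        dz = x[nb, 2] - x[na, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        lam = L / L0[c]
        if lam <= 1.0 or L <= 0.0:
            continue
        P = 0.0
        W = 0.0
        for k in range(mu.shape[0]):
            ck = 2.0 * mu[k] / alpha[k]
            P += ck * (lam ** (alpha[k] - 1.0)
                       - lam ** (-alpha[k] / 2.0 - 1.0))
            W += (ck / alpha[k]) * (lam ** alpha[k]
                                    + 2.0 * lam ** (-alpha[k] / 2.0) - 3.0)
        force = P * A0[c]
        if force > fmax:
            fmax = force
        E_cab += W * A0[c] * L0[c]
        ux = dx / L
        uy = dy / L
        uz = dz / L
        f[na, 0] += force * ux
        f[na, 1] += force * uy
        f[na, 2] += force * uz
        f[nb, 0] -= force * ux
        f[nb, 1] -= force * uy
        f[nb, 2] -= force * uz
    return E_cab, fmax


@njit(cache=True)
def _contact_pass(x, pairs, facets, offset, k_pen, trib, f):
    """Frictionless node-triangle penalty repulsion inside ``offset``.
    Returns (contact potential energy, min clearance seen)."""
    E_c = 0.0
    min_clear = 1e30
    for p in range(pairs.shape[0]):
        n = pairs[p, 0]
        t = pairs[p, 1]
        i0 = facets[t, 0]
        i1 = facets[t, 1]
        i2 = facets[t, 2]
        # closest point on triangle (Ericson)
        ax = x[i0, 0]
        ay = x[i0, 1]
        az = x[i0, 2]
        abx = x[i1, 0] - ax
        aby = x[i1, 1] - ay
        abz = x[i1, 2] - az
        acx = x[i2, 0] - ax
        acy = x[i2, 1] - ay
        acz = x[i2, 2] - az
        px = x[n, 0] - ax
        py = x[n, 1] - ay
        pz = x[n, 2] - az
        d1 = abx * px + aby * py + abz * pz
        d2 = acx * px + acy * py + acz * pz
        u = 0.0
        v = 0.0
        if d1 <= 0.0 and d2 <= 0.0:
            u = 0.0
            v = 0.0
        else:
            bx = x[n, 0] - x[i1, 0]
            by = x[n, 1] - x[i1, 1]
            bz = x[n, 2] - x[i1, 2]
            d3 = abx * bx + aby * by + abz * bz
            d4 = acx * bx + acy * by + acz * bz
            cx_ = x[n, 0] - x[i2, 0]
            cy_ = x[n, 1] - x[i2, 1]
            cz_ = x[n, 2] - x[i2, 2]
            d5 = abx * cx_ + aby * cy_ + abz * cz_
            d6 = acx * cx_ + acy * cy_ + acz * cz_
            if d3 >= 0.0 and d4 <= d3:
                u = 1.0
                v = 0.0
            elif d6 >= 0.0 and d5 <= d6:
                u = 0.0
                v = 1.0
            else:
                vc = d1 * d4 - d3 * d2
                vb = d5 * d2 - d1 * d6
                va = d3 * d6 - d5 * d4
                if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                    u = d1 / (d1 - d3)
                    v = 0.0
                elif vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                    u = 0.0
                    v = d2 / (d2 - d6)
                elif va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                    u = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                    v = 1.0 - u
                else:
                    den = 1.0 / (va + vb + vc)
                    u = vb * den
                    v = vc * den
        qx = ax + u * abx + v * acx
        qy = ay + u * aby + v * acy
        qz = az + u * abz + v * acz
        gx = x[n, 0] - qx
        gy = x[n, 1] - qy
        gz = x[n, 2] - qz
        d = np.sqrt(gx * gx + gy * gy + gz * gz)
        if d < min_clear:
            min_clear = d
        if d >= offset or d <= 1e-12:
            continue
        pen = offset - d
        kA = k_pen * trib[n]
        fmag = kA * pen
        E_c += 0.5 * kA * pen * pen
        ux = gx / d
        uy = gy / d
        uz = gz / d
        f[n, 0] += fmag * ux
        f[n, 1] += fmag * uy
        f[n, 2] += fmag * uz
        w0 = 1.0 - u - v
        f[i0, 0] -= w0 * fmag * ux
        f[i0, 1] -= w0 * fmag * uy
        f[i0, 2] -= w0 * fmag * uz
        f[i1, 0] -= u * fmag * ux
        f[i1, 1] -= u * fmag * uy
        f[i1, 2] -= u * fmag * uz
        f[i2, 0] -= v * fmag * ux
        f[i2, 1] -= v * fmag * uy
        f[i2, 2] -= v * fmag * uz
    return E_c, min_clear


# ---------------------------------------------------------------------------
# public operations


def _reference_gradients(mesh: VolumeMesh):
    """Per-element reference shape-function gradients (E,4,3) and volumes."""
    x = mesh.nodes[mesh.tets]
    d = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))  # (E,3,3) columns=edges
    V0 = np.linalg.det(d) / 6.0
    if np.any(V0 <= 0):
        bad = np.where(V0 <= 0)[0]
        raise ValueError(f"non-positive reference volumes at elements "
                         f"{bad[:10]}")
    dinv = np.linalg.inv(d)                            # (E,3,3)
    g = np.empty((len(V0), 4, 3))
    g[:, 1:, :] = dinv                                 # rows are grad N_a
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, V0


def lumped_mass(mesh: VolumeMesh, density_kg_m3: float,
                mass_scaling: float = 1.0) -> np.ndarray:
    """Row-sum lumped nodal masses (tonne): each tet's mass split equally."""
    rho = density_kg_m3 * 1e-12 * mass_scaling
    V = mesh.tet_volumes()
    m = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(m, mesh.tets[:, a], 0.25 * rho * V)
    return m


def stable_time_increment(mesh: VolumeMesh, material: OgdenMaterial,
                          config: ExplicitConfig = ExplicitConfig()) -> float:
    """Element-by-element estimate: dt = safety * min(Le/c_d) * damping
    correction, with Le the minimum element altitude and c_d the dilatational
    wave speed at the (mass-scaled) density."""
    x = mesh.nodes[mesh.tets]
    V = np.abs(np.linalg.det(np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1)))) / 6.0
    amax = np.zeros(len(V))
    for a in range(4):
        idx = [b for b in range(4) if b != a]
        tri = x[:, idx, :]
        c = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        amax = np.maximum(amax, 0.5 * np.linalg.norm(c, axis=1))
    le = 3.0 * V / amax
    cd = initial_moduli(material)["c_d"] / np.sqrt(config.mass_scaling)
    xi = config.b1
    return float(config.dt_safety * le.min() / cd
                 * (np.sqrt(1.0 + xi * xi) - xi))


def bulk_viscosity_pressure(evdot: float, c_d: float, le: float, rho: float,
                            b1: float = 0.06, b2: float = 1.2) -> float:
    """Damping pressure for a volumetric strain rate (sign of evdot; the
    quadratic term only resists compression)."""
    q = b1 * rho * c_d * le * evdot
    if evdot < 0.0:
        q -= rho * (b2 * le * evdot) ** 2
    return q


def advance(u: np.ndarray, v: np.ndarray, forces: np.ndarray,
            masses: np.ndarray, dt: float,
            pinned: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One central-difference step; pinned node translations forced to zero."""
    a = forces / masses[:, None]
    v = v + a * dt
    if pinned is not None and len(pinned):
        v[pinned] = 0.0
    u = u + v * dt
    if pinned is not None and len(pinned):
        u[pinned] = 0.0
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("NaN/Inf in displacement update")
    return u, v


def internal_forces(mesh: VolumeMesh, material: OgdenMaterial,
                    u: np.ndarray, nodal_pressure: bool = True) -> np.ndarray:
    """Static internal nodal force vector at displacement u (no viscosity)."""
    g0, V0 = _reference_gradients(mesh)
    nodal_V0 = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(nodal_V0, mesh.tets[:, a], 0.25 * V0)
    f = np.zeros((mesh.n_nodes, 3))
    x = mesh.nodes + u
    out = _element_pass(x, mesh.tets, g0, V0, np.ones(mesh.n_elements),
                        np.asarray(material.mu), np.asarray(material.alpha),
                        material.D[0], 0.0, 0.0, 0.0, 0.0, 0.0,
                        nodal_V0, nodal_pressure, f)
    if out[5] >= 0:
        raise ElementInversionError(out[5], 0.0)
    return f


def strain_energy(mesh: VolumeMesh, material: OgdenMaterial,
                  u: np.ndarray, nodal_pressure: bool = True) -> float:
    """Total strain energy (mJ) at displacement u (elements + nodal
    volumetric + cables)."""
    g0, V0 = _reference_gradients(mesh)
    nodal_V0 = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(nodal_V0, mesh.tets[:, a], 0.25 * V0)
    f = np.zeros((mesh.n_nodes, 3))
    x = mesh.nodes + u
    E_dev, E_vol, _, _, _, bad = _element_pass(
        x, mesh.tets, g0, V0, np.ones(mesh.n_elements),
        np.asarray(material.mu), np.asarray(material.alpha),
        material.D[0], 0.0, 0.0, 0.0, 0.0, 0.0,
        nodal_V0, nodal_pressure, f)
    if bad >= 0:
        raise ElementInversionError(bad, 0.0)
    E_cab = 0.0
    if mesh.trabecula_cables:
        cab, A0, L0 = _cable_arrays(mesh)
        fc = np.zeros_like(f)
        E_cab, _ = _cable_pass(x, cab, A0, L0, np.asarray(material.mu),
                               np.asarray(material.alpha), fc)
    return float(E_dev + E_vol + E_cab)


def follower_pressure_forces(mesh: VolumeMesh, u: np.ndarray,
                             p_mmhg: float) -> np.ndarray:
    """Nodal forces from cavity pressure on the current inner facets."""
    f = np.zeros((mesh.n_nodes, 3))
    _pressure_pass(mesh.nodes + u, mesh.inner_facets, mmhg_to_mpa(p_mmhg), f)
    return f


def cavity_volume(mesh: VolumeMesh, u: np.ndarray | None = None) -> float:
    """Flux volume of the inner facets (exact cavity volume when closed)."""
    x = mesh.nodes if u is None else mesh.nodes + u
    f = np.zeros((mesh.n_nodes, 3))
    return float(_pressure_pass(x, mesh.inner_facets, 0.0, f))


def _cable_arrays(mesh: VolumeMesh):
    cab = np.asarray([[a, b] for a, b, _ in mesh.trabecula_cables],
                     dtype=np.int64).reshape(-1, 2)
    dia = np.asarray([d for _, _, d in mesh.trabecula_cables])
    A0 = 0.25 * np.pi * dia ** 2
    L0 = np.linalg.norm(mesh.nodes[cab[:, 0]] - mesh.nodes[cab[:, 1]], axis=1)
    if np.any(L0 <= 0):
        raise ValueError("zero reference length trabecula cable")
    return cab, A0, L0


def trabecula_forces(mesh: VolumeMesh, material: OgdenMaterial,
                     u: np.ndarray) -> tuple[np.ndarray, float]:
    """Cable nodal forces and the max cable axial force at displacement u."""
    f = np.zeros((mesh.n_nodes, 3))
    if not mesh.trabecula_cables:
        return f, 0.0
    cab, A0, L0 = _cable_arrays(mesh)
    _, fmax = _cable_pass(mesh.nodes + u, cab, A0, L0,
                          np.asarray(material.mu),
                          np.asarray(material.alpha), f)
    return f, float(fmax)


def contact_forces(mesh: VolumeMesh, u: np.ndarray,
                   penalty: float = 0.3, offset: float = 0.5
                   ) -> tuple[np.ndarray, float, float]:
    """Self-contact penalty forces among the inner facets at displacement u.

    One-shot convenience around the broad/narrow phases the time loop uses;
    returns (nodal forces, contact potential energy, min clearance seen).
    """
    x = mesh.nodes + u
    facets = mesh.inner_facets
    surf_nodes = mesh.node_sets.get("inner_surface", np.unique(facets))
    fc = np.cross(x[facets[:, 1]] - x[facets[:, 0]],
                  x[facets[:, 2]] - x[facets[:, 0]])
    fa = 0.5 * np.linalg.norm(fc, axis=1)
    trib = np.zeros(mesh.n_nodes)
    for a in range(3):
        np.add.at(trib, facets[:, a], fa / 3.0)
    from collections import defaultdict
    v2v = defaultdict(set)
    for tri in facets:
        for i in tri:
            v2v[int(i)].update(int(j) for j in tri)
    cent = x[facets].mean(axis=1)
    tree = cKDTree(cent)
    r = offset + 2.0 * float(np.sqrt(fa.max())) if len(fa) else offset
    pairs = []
    facet_sets = [set(int(i) for i in tri) for tri in facets]
    for nid, cands in zip(surf_nodes,
                          tree.query_ball_point(x[surf_nodes], r)):
        ring1 = v2v[int(nid)]
        excl = set(ring1)
        for j in ring1:
            excl |= v2v[j]
        for t in cands:
            if facet_sets[t] & excl:
                continue
            pairs.append((nid, t))
    f = np.zeros((mesh.n_nodes, 3))
    if not pairs:
        return f, 0.0, np.inf
    E, clear = _contact_pass(x, np.asarray(pairs, np.int64), facets, offset,
                             penalty, trib, f)
    return f, float(E), float(clear)


def max_principal_stress_field(mesh: VolumeMesh, material: OgdenMaterial,
                               u: np.ndarray,
                               nodal_pressure: bool = True) -> np.ndarray:
    """Largest principal Cauchy stress per element (MPa) at displacement u."""
    g0, V0 = _reference_gradients(mesh)
    x = mesh.nodes + u
    xe = x[mesh.tets]
    F = np.einsum("eai,eaj->eij", xe, g0)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ElementInversionError(int(np.argmax(J <= 0)), 0.0)
    b = np.einsum("eij,ekj->eik", F, F)
    lam2, n = np.linalg.eigh(b)
    lam = np.sqrt(np.maximum(lam2, 1e-30))
    lb = lam / J[:, None] ** (1.0 / 3.0)
    t = np.zeros_like(lb)
    for m_k, a_k in zip(material.mu, material.alpha):
        t += (2.0 * m_k / a_k) * lb ** a_k
    beta = (t - t.mean(axis=1, keepdims=True)) / J[:, None]
    if nodal_pressure:
        # mirror the solver's smoothed volumetric pressure
        nodal_V0 = np.zeros(mesh.n_nodes)
        nodal_V = np.zeros(mesh.n_nodes)
        Ve = J * V0
        for a in range(4):
            np.add.at(nodal_V0, mesh.tets[:, a], 0.25 * V0)
            np.add.at(nodal_V, mesh.tets[:, a], 0.25 * Ve)
        Jn = np.where(nodal_V0 > 0, nodal_V / np.maximum(nodal_V0, 1e-30), 1.0)
        Jbar = Jn[mesh.tets].mean(axis=1)
        p0 = 2.0 * (Jbar - 1.0) / material.D[0]
        w_num = np.zeros(mesh.n_nodes)
        for a in range(4):
            np.add.at(w_num, mesh.tets[:, a], 0.25 * V0 * p0)
        w_n = np.where(nodal_V0 > 0, w_num / np.maximum(nodal_V0, 1e-30), 0.0)
        p_e = w_n[mesh.tets].mean(axis=1)
    else:
        p_e = 2.0 * (J - 1.0) / material.D[0]
    return beta.max(axis=1) + p_e


# ---------------------------------------------------------------------------
# time loop


@dataclass
class EnergyTrace:
    """Sampled energy/pressure series from a run (energies in mJ)."""

    time: np.ndarray
    pressure: np.ndarray          # mmHg (protocol value)
    strain: np.ndarray
    kinetic: np.ndarray
    viscous: np.ndarray
    contact: np.ndarray
    external_work: np.ndarray
    cavity_volume: np.ndarray
    max_cable_force: np.ndarray   # N
    tip_centroid: np.ndarray      # (n, 3) mm, tracked node-set centroid
    kinetic_fraction_flags: np.ndarray

    def to_csv(self, path) -> None:
        hdr = ("time_s,pressure_mmHg,strain_mJ,kinetic_mJ,viscous_mJ,"
               "contact_mJ,external_work_mJ,cavity_volume_mm3,"
               "max_cable_force_N,tip_x_mm,tip_y_mm,tip_z_mm,ke_flag")
        data = np.column_stack([
            self.time, self.pressure, self.strain, self.kinetic, self.viscous,
            self.contact, self.external_work, self.cavity_volume,
            self.max_cable_force, self.tip_centroid,
            self.kinetic_fraction_flags.astype(float)])
        np.savetxt(path, data, delimiter=",", header=hdr, comments="",
                   fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "EnergyTrace":
        try:
            data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed trace CSV ({exc})") from exc
        if data.shape[1] != 13:
            raise ValueError(f"{path}: expected 13 columns, "
                             f"got {data.shape[1]}")
        return cls(time=data[:, 0], pressure=data[:, 1], strain=data[:, 2],
                   kinetic=data[:, 3], viscous=data[:, 4], contact=data[:, 5],
                   external_work=data[:, 6], cavity_volume=data[:, 7],
                   max_cable_force=data[:, 8], tip_centroid=data[:, 9:12],
                   kinetic_fraction_flags=data[:, 12].astype(bool))


@dataclass
class SolveResult:
    trace: EnergyTrace
    snapshots: list            # (time, displacement array) pairs
    snapshot_times: np.ndarray
    u: np.ndarray              # final displacement
    v: np.ndarray
    aborted: bool
    abort_reason: str
    dt_history: tuple[float, float]     # (min, max) dt used
    diagnostics: dict


def run_protocol(mesh: VolumeMesh, material: OgdenMaterial,
                 protocol: PressureProtocol,
                 config: ExplicitConfig = ExplicitConfig(),
                 track_nodes: np.ndarray | None = None,
                 snapshot_times: np.ndarray | None = None,
                 u0: np.ndarray | None = None,
                 progress: bool = False) -> SolveResult:
    """Integrate the mesh through the pressure protocol.

    ``track_nodes`` (e.g. the distal-tip node set) has its centroid recorded
    at every trace sample; full displacement snapshots are stored at stage
    boundaries plus any ``snapshot_times``.  Deterministic for fixed inputs.
    """
    g0, V0 = _reference_gradients(mesh)
    nodal_V0 = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(nodal_V0, mesh.tets[:, a], 0.25 * V0)
    m = lumped_mass(mesh, material.density, config.mass_scaling)
    rho = material.density * 1e-12 * config.mass_scaling
    mod = initial_moduli(material)
    cd = mod["c_d"] / np.sqrt(config.mass_scaling)
    mu = np.asarray(material.mu)
    alpha = np.asarray(material.alpha)
    D1 = material.D[0]
    pinned = mesh.orifice_ring

    has_cables = bool(mesh.trabecula_cables)
    if has_cables:
        cab, A0c, L0c = _cable_arrays(mesh)

    # contact precomputation
    contact_pairs = np.empty((0, 2), np.int64)
    if config.contact_enabled and len(mesh.inner_facets):
        surf_nodes = mesh.node_sets.get("inner_surface",
                                        np.unique(mesh.inner_facets))
        trib = np.zeros(mesh.n_nodes)
        fc = np.cross(
            mesh.nodes[mesh.inner_facets[:, 1]] - mesh.nodes[mesh.inner_facets[:, 0]],
            mesh.nodes[mesh.inner_facets[:, 2]] - mesh.nodes[mesh.inner_facets[:, 0]])
        fa = 0.5 * np.linalg.norm(fc, axis=1)
        for a in range(3):
            np.add.at(trib, mesh.inner_facets[:, a], fa / 3.0)
        # 2-ring topological exclusion around each surface node
        from collections import defaultdict
        v2v = defaultdict(set)
        for tri in mesh.inner_facets:
            for i in tri:
                v2v[int(i)].update(int(j) for j in tri)
        excl = {}
        for nid in surf_nodes:
            ring1 = v2v[int(nid)]
            ring2 = set(ring1)
            for j in ring1:
                ring2 |= v2v[j]
            excl[int(nid)] = ring2
        facet_sets = [set(int(i) for i in tri) for tri in mesh.inner_facets]

        def rebuild_pairs(x):
            cent = x[mesh.inner_facets].mean(axis=1)
            tree = cKDTree(cent)
            r = config.contact_offset + float(np.sqrt(fa.max()) * 2.0)
            prs = []
            groups = tree.query_ball_point(x[surf_nodes], r)
            for nid, cands in zip(surf_nodes, groups):
                ex = excl[int(nid)]
                for t in cands:
                    if facet_sets[t] & ex:
                        continue
                    prs.append((nid, t))
            if not prs:
                return np.empty((0, 2), np.int64)
            return np.asarray(prs, np.int64)
    else:
        trib = np.zeros(mesh.n_nodes)

    dt0 = stable_time_increment(mesh, material, config)
    if config.contact_enabled:
        # penalty-spring stability cap
        kmax = config.contact_penalty * max(trib.max(), 1e-30)
        dt_c = 0.5 * np.sqrt(m[m > 0].min() / max(kmax, 1e-30))
        dt0 = min(dt0, dt_c)

    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else u0.copy()
    v = np.zeros((mesh.n_nodes, 3))
    J_prev = np.ones(mesh.n_elements)
    t = protocol.t_start
    t_end = protocol.t_end

    samples: list[tuple] = []
    snaps: list[tuple[float, np.ndarray]] = []
    snap_req = sorted(set(list(protocol.stage_bounds)
                          + (list(np.atleast_1d(snapshot_times))
                             if snapshot_times is not None else [])))
    next_snap = 0
    E_visc = 0.0
    W_ext = 0.0
    f_ext_prev = np.zeros((mesh.n_nodes, 3))
    du_prev = np.zeros((mesh.n_nodes, 3))
    first = True
    next_sample = t
    dt_min_seen, dt_max_seen = np.inf, 0.0
    dt = dt0
    aborted = False
    abort_reason = ""
    step = 0

    while t < t_end - 1e-15:
        dt = min(dt, t_end - t)
        x = mesh.nodes + u
        f = np.zeros((mesh.n_nodes, 3))
        p_mmhg = float(protocol.pressure_at(min(t, t_end)))
        p_mpa = mmhg_to_mpa(p_mmhg)

        E_dev, E_vol, visc_pow, J_new, min_le, bad = _element_pass(
            x, mesh.tets, g0, V0, J_prev, mu, alpha, D1, rho, cd,
            config.b1, config.b2, dt if not first else 0.0,
            nodal_V0, config.nodal_pressure, f)
        if bad >= 0:
            aborted = True
            abort_reason = f"element {bad} inverted at t={t:.6g}"
            break
        f_int_neg = f.copy()      # internal contribution (already negative)

        f_ext = np.zeros((mesh.n_nodes, 3))
        vol_flux = _pressure_pass(x, mesh.inner_facets, p_mpa, f_ext)

        E_cab = 0.0
        fmax_cab = 0.0
        if has_cables:
            E_cab, fmax_cab = _cable_pass(x, cab, A0c, L0c, mu, alpha, f)

        E_con = 0.0
        if config.contact_enabled:
            if step % config.contact_rebuild == 0:
                contact_pairs = rebuild_pairs(x)
            if len(contact_pairs):
                E_con, _ = _contact_pass(x, contact_pairs, mesh.inner_facets,
                                         config.contact_offset,
                                         config.contact_penalty, trib, f)
        f += f_ext

        # external-work trapezoid (external = follower pressure only)
        if not first:
            W_ext += 0.5 * float(np.sum((f_ext + f_ext_prev) * du_prev))
        f_ext_prev = f_ext

        # mass damping
        if config.mass_damping > 0.0:
            f -= config.mass_damping * m[:, None] * v
            E_visc += config.mass_damping * float(np.sum(m * (v * v).sum(1))) * dt
        E_visc += visc_pow * dt if not first else 0.0

        # integrate
        a = f / m[:, None]
        v = v + a * dt
        if len(pinned):
            v[pinned] = 0.0
        du = v * dt
        u = u + du
        du_prev = du
        if not np.all(np.isfinite(u)):
            aborted = True
            abort_reason = f"NaN in displacements at t={t:.6g}"
            break
        J_prev = J_new
        t += dt
        step += 1
        first = False

        # adaptive dt from current geometry
        xi = config.b1
        dt_new = (config.dt_safety * min_le / cd
                  * (np.sqrt(1.0 + xi * xi) - xi))
        if config.contact_enabled:
            dt_new = min(dt_new, dt_c)
        dt = dt_new
        dt_min_seen = min(dt_min_seen, dt)
        dt_max_seen = max(dt_max_seen, dt)

        # sampling
        if t >= next_sample - 1e-15 or t >= t_end - 1e-15:
            KE = 0.5 * float(np.sum(m * (v * v).sum(1)))
            E_strain = E_dev + E_vol + E_cab
            ke_flag = KE > config.max_kinetic_fraction * max(E_strain, 1e-12)
            tipc = (x[track_nodes].mean(axis=0) if track_nodes is not None
                    and len(track_nodes) else np.full(3, np.nan))
            samples.append((t, p_mmhg, E_strain, KE, E_visc, E_con, W_ext,
                            vol_flux, fmax_cab, tipc, ke_flag))
            next_sample += config.output_interval
            if progress:  # pragma: no cover
                print(f"  t={t:.4g}s p={p_mmhg:.1f}mmHg E={E_strain:.4g}mJ "
                      f"KE={KE:.3g}mJ dt={dt:.3g}")
        while next_snap < len(snap_req) and t >= snap_req[next_snap] - 1e-12:
            snaps.append((snap_req[next_snap], u.copy()))
            next_snap += 1

    if not samples:
        raise RuntimeError("no samples recorded: protocol shorter than dt?")
    arr = samples
    trace = EnergyTrace(
        time=np.array([s[0] for s in arr]),
        pressure=np.array([s[1] for s in arr]),
        strain=np.array([s[2] for s in arr]),
        kinetic=np.array([s[3] for s in arr]),
        viscous=np.array([s[4] for s in arr]),
        contact=np.array([s[5] for s in arr]),
        external_work=np.array([s[6] for s in arr]),
        cavity_volume=np.array([s[7] for s in arr]),
        max_cable_force=np.array([s[8] for s in arr]),
        tip_centroid=np.vstack([s[9] for s in arr]),
        kinetic_fraction_flags=np.array([s[10] for s in arr], bool),
    )
    return SolveResult(
        trace=trace, snapshots=snaps,
        snapshot_times=np.array([s[0] for s in snaps]),
        u=u, v=v, aborted=aborted, abort_reason=abort_reason,
        dt_history=(float(dt_min_seen), float(dt_max_seen)),
        diagnostics={"steps": step, "dt0": dt0,
                     "qc_flagged_fraction":
                         float(trace.kinetic_fraction_flags.mean())},
    )
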