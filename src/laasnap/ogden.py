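"""Third-order nearly incompressible Ogden constitutive model.

Strain-energy density (deviatoric–volumetric split)::

    W = sum_i (2 mu_i / alpha_i^2) (lb1^a_i + lb2^a_i + lb3^a_i - 3)
      + sum_i (1 / D_i) (J - 1)^(2 i)          (terms with D_i != 0)

with J = l1 l2 l3 and isochoric stretches lb_k = J^(-1/3) l_k.  Under this
convention the initial shear modulus is mu0 = sum_i mu_i and the initial bulk
modulus K0 = 2 / D1; imposing a Poisson's ratio nu ties them through
K0 = 2 mu0 (1 + nu) / (3 (1 - 2 nu)).

Stresses are in MPa, density in kg/m^3 at this interface (the explicit solver
converts to its tonne/mm^3 internal unit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "OgdenMaterial",
    "BiaxialDataset",
    "FitDiagnostics",
    "table1",
    "bulk_coeffs_from_poisson",
    "strain_energy_density",
    "cauchy_stress",
    "uniaxial_nominal_stress",
    "equibiaxial_nominal_stress",
    "planar_nominal_stress",
    "initial_moduli",
    "fit_ogden",
]


@dataclass(frozen=True)
class OgdenMaterial:
    """Ogden coefficient set with volumetric terms and density.

    ``mu`` in MPa, ``alpha`` dimensionless, ``D`` in 1/MPa, ``density`` in
    kg/m^3.  ``mu`` and ``alpha`` must have equal length N (the model order);
    the effective initial shear modulus ``sum(mu)`` must be positive.
    """

    mu: tuple[float, ...]
    alpha: tuple[float, ...]
    D: tuple[float, ...]
    poisson: float = 0.495
    density: float = 1120.0
    name: str = "ogden"

    def __post_init__(self) -> None:
        if not (len(self.mu) == len(self.alpha) == len(self.D)):
            raise ValueError("mu, alpha, D must have equal length")
        if sum(self.mu) <= 0:
            raise ValueError("initial shear modulus sum(mu) must be positive")
        if not (0.0 < self.poisson < 0.5):
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if any(a == 0 for a in self.alpha):
            raise ValueError("alpha_i must be nonzero")

    @property
    def order(self) -> int:
        return len(self.mu)

    @property
    def mu0(self) -> float:
        """Initial (small-strain) shear modulus, MPa."""
        return float(sum(self.mu))

    @classmethod
    def from_json(cls, path_or_dict) -> "OgdenMaterial":
        if isinstance(path_or_dict, dict):
            d = path_or_dict
        else:
            with open(path_or_dict) as fh:
                d = json.load(fh)
        return cls(
            mu=tuple(d["mu"]), alpha=tuple(d["alpha"]), D=tuple(d["D"]),
            poisson=float(d.get("poisson", 0.495)),
            density=float(d.get("density", 1120.0)),
            name=str(d.get("name", "ogden")),
        )

    def to_json(self, path=None) -> dict:
        d = {
            "name": self.name,
            "units": {"mu": "MPa", "alpha": "-", "D": "1/MPa",
                      "density": "kg/m^3"},
            "order": self.order,
            "mu": list(self.mu), "alpha": list(self.alpha), "D": list(self.D),
            "poisson": self.poisson, "density": self.density,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def table1() -> OgdenMaterial:
    """The built-in appendage-tissue coefficient card (third order)."""
    ref = resources.files("laasnap.materials").joinpath("table1.json")
    return OgdenMaterial.from_json(json.loads(ref.read_text()))


def bulk_coeffs_from_poisson(mu, alpha, poisson: float) -> tuple[float, ...]:
    """Volumetric coefficients D_i from the shear set and Poisson's ratio.

    K0 = 2 mu0 (1 + nu) / (3 (1 - 2 nu)); D1 = 2 / K0; higher D_i are zero
    (only the leading volumetric term is used in near-incompressible practice).
    """
    if not (0.0 < poisson < 0.5):
        raise ValueError("Poisson's ratio must lie in (0, 0.5) — the "
                         "incompressible limit is not representable")
    mu0 = float(np.sum(mu))
    if mu0 <= 0:
        raise ValueError("sum(mu) must be positive")
    K0 = 2.0 * mu0 * (1.0 + poisson) / (3.0 * (1.0 - 2.0 * poisson))
    D = [2.0 / K0] + [0.0] * (len(mu) - 1)
    return tuple(D)


# ---------------------------------------------------------------------------
# closed-form responses


def _dev_energy(mat: OgdenMaterial, lb: np.ndarray) -> np.ndarray:
    """Deviatoric energy from isochoric stretches lb, shape (..., 3)."""
    w = np.zeros(lb.shape[:-1])
    for m, a in zip(mat.mu, mat.alpha):
        w = w + (2.0 * m / a**2) * (np.sum(lb**a, axis=-1) - 3.0)
    return w


def strain_energy_density(mat: OgdenMaterial, stretches) -> float:
    """W (MPa = mJ/mm^3) at the principal stretches (l1, l2, l3)."""
    lam = np.asarray(stretches, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected three principal stretches")
    if np.any(lam <= 0):
        raise ValueError("principal stretches must be positive")
    J = np.prod(lam, axis=-1)
    lb = lam * J[..., None] ** (-1.0 / 3.0)
    w = _dev_energy(mat, lb)
    for i, Di in enumerate(mat.D, start=1):
        if Di != 0.0:
            w = w + (1.0 / Di) * (J - 1.0) ** (2 * i)
    return float(w) if w.ndim == 0 else w


def volumetric_pressure(mat: OgdenMaterial, J) -> float:
    """dU/dJ, the volumetric (mean) stress contribution at volume ratio J."""
    J = np.asarray(J, dtype=float)
    p = np.zeros_like(J)
    for i, Di in enumerate(mat.D, start=1):
        if Di != 0.0:
            p = p + (2 * i / Di) * (J - 1.0) ** (2 * i - 1)
    return float(p) if p.ndim == 0 else p


def principal_cauchy(mat: OgdenMaterial, lam: np.ndarray) -> np.ndarray:
    """Principal Cauchy stresses at principal stretches, shape (..., 3)."""
    lam = np.asarray(lam, dtype=float)
    J = np.prod(lam, axis=-1, keepdims=True)
    lb = lam * J ** (-1.0 / 3.0)
    dev = np.zeros_like(lam)
    for m, a in zip(mat.mu, mat.alpha):
        t = (2.0 * m / a) * lb**a
        dev = dev + t - np.mean(t, axis=-1, keepdims=True)
    p = np.asarray(volumetric_pressure(mat, J[..., 0]))
    return dev / J + p[..., None]


def cauchy_stress(mat: OgdenMaterial, F: np.ndarray) -> np.ndarray:
    """Cauchy stress tensor (MPa) at deformation gradient F (3x3).

    Computed from the spectral decomposition of the left Cauchy–Green tensor
    b = F F^T; consistent with :func:`strain_energy_density` (verified against
    finite differences in the test suite).
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError("det F must be positive")
    b = F @ F.T
    lam2, n = np.linalg.eigh(b)
    lam = np.sqrt(np.maximum(lam2, 0.0))
    sig_p = principal_cauchy(mat, lam)
    return (n * sig_p) @ n.T


def uniaxial_nominal_stress(mat: OgdenMaterial, lam) -> float:
    """Nominal (first Piola) stress for incompressible uniaxial extension.

    P(l) = sum_i (2 mu_i / alpha_i) (l^(a_i - 1) - l^(-a_i/2 - 1)).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    P = np.zeros_like(lam)
    for m, a in zip(mat.mu, mat.alpha):
        P = P + (2.0 * m / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return float(P) if P.ndim == 0 else P


def equibiaxial_nominal_stress(mat: OgdenMaterial, lam) -> float:
    """Nominal stress per direction for incompressible equibiaxial extension.

    P(l) = sum_i (2 mu_i / alpha_i) (l^(a_i - 1) - l^(-2 a_i - 1)).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    P = np.zeros_like(lam)
    for m, a in zip(mat.mu, mat.alpha):
        P = P + (2.0 * m / a) * (lam ** (a - 1.0) - lam ** (-2.0 * a - 1.0))
    return float(P) if P.ndim == 0 else P


def planar_nominal_stress(mat: OgdenMaterial, lam) -> float:
    """Nominal stress for incompressible planar (pure-shear) extension."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    P = np.zeros_like(lam)
    for m, a in zip(mat.mu, mat.alpha):
        P = P + (2.0 * m / a) * (lam ** (a - 1.0) - lam ** (-a - 1.0))
    return float(P) if P.ndim == 0 else P


_MODES = {
    "uniaxial": uniaxial_nominal_stress,
    "equibiaxial": equibiaxial_nominal_stress,
    "planar": planar_nominal_stress,
}


def initial_moduli(mat: OgdenMaterial) -> dict:
    """Small-strain moduli and the dilatational wave speed.

    Returns mu0 (MPa), K0 = 2/D1 (MPa), E0 = 2 mu0 (1+nu) (MPa) and
    c_d = sqrt((K0 + 4 mu0 / 3) / rho) in mm/s at the card's density.
    """
    if mat.D[0] == 0.0:
        raise ValueError("D1 = 0: bulk modulus undefined")
    mu0 = mat.mu0
    K0 = 2.0 / mat.D[0]
    E0 = 2.0 * mu0 * (1.0 + mat.poisson)
    rho = mat.density * 1e-12  # tonne/mm^3
    c_d = float(np.sqrt((K0 + 4.0 * mu0 / 3.0) / rho))
    return {"mu0": mu0, "K0": K0, "E0": E0, "c_d": c_d}


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class BiaxialDataset:
    """Stretch–nominal-stress records from planar-biaxial style protocols."""

    mode: tuple[str, ...]
    stretch: np.ndarray
    stress: np.ndarray  # MPa

    def __post_init__(self) -> None:
        if len(self.mode) != len(self.stretch) or len(self.mode) != len(self.stress):
            raise ValueError("mode, stretch, stress must align")
        if len(self.mode) == 0:
            raise ValueError("empty dataset")
        if np.any(np.asarray(self.stretch) <= 0):
            raise ValueError("stretches must be positive")
        bad = set(self.mode) - set(_MODES)
        if bad:
            raise ValueError(f"unknown loading modes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.mode)

    @classmethod
    def from_csv(cls, path) -> "BiaxialDataset":
        """Read ``mode,stretch,nominal_stress_MPa`` CSV (header required)."""
        modes: list[str] = []
        lam: list[float] = []
        sig: list[float] = []
        with open(path) as fh:
            header = fh.readline().strip().lower().split(",")
            if header[:3] != ["mode", "stretch", "nominal_stress_mpa"]:
                raise ValueError(
                    f"{path}: expected header mode,stretch,nominal_stress_MPa")
            for ln, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                try:
                    modes.append(parts[0].strip())
                    lam.append(float(parts[1]))
                    sig.append(float(parts[2]))
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}:{ln}: malformed record") from exc
        if not modes:
            raise ValueError(f"{path}: no data records")
        return cls(tuple(modes), np.asarray(lam), np.asarray(sig))

    def predict(self, mat: OgdenMaterial) -> np.ndarray:
        out = np.empty(len(self))
        for m in set(self.mode):
            sel = np.fromiter((x == m for x in self.mode), bool, len(self))
            out[sel] = _MODES[m](mat, self.stretch[sel])
        return out


@dataclass(frozen=True)
class FitDiagnostics:
    residual_norm: float
    initial_residual_norm: float
    jacobian_condition: float
    converged: bool
    n_starts: int
    best_start: int


def _pack(mu, alpha):
    return np.concatenate([mu, alpha])


def _unpack(x, order):
    return x[:order], x[order:]


def fit_ogden(
    data: BiaxialDataset,
    order: int = 3,
    poisson: float = 0.495,
    density: float = 1120.0,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[OgdenMaterial, FitDiagnostics]:
    """Least-squares Ogden coefficient fit via Levenberg–Marquardt.

    Residuals are pooled over all loading modes with uniform weights; the
    incompressible closed forms are fitted (biaxial data carry no volumetric
    information) and the D_i are then derived from ``poisson``.  Because the
    residual surface is multimodal in the alphas, a seeded multi-start over
    alpha magnitudes and signs is used and the best converged solution
    returned.  Coefficient sets are generically non-unique; the fitted
    response curve, not the coefficients, is the meaningful output.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(data) < 2 * order:
        raise ValueError(f"need at least {2 * order} records for order {order}")

    scale = max(np.percentile(np.abs(data.stress), 90), 1e-12)

    def residual(x):
        mu, alpha = _unpack(x, order)
        alpha = np.where(np.abs(alpha) < 1e-6, 1e-6, alpha)
        P = np.zeros(len(data))
        lam = data.stretch
        with np.errstate(over="ignore", invalid="ignore"):
            for m_i, a_i in zip(mu, alpha):
                for mode in set(data.mode):
                    sel = np.fromiter((x_ == mode for x_ in data.mode), bool,
                                      len(data))
                    l_ = lam[sel]
                    if mode == "uniaxial":
                        term = l_ ** (a_i - 1.0) - l_ ** (-a_i / 2.0 - 1.0)
                    elif mode == "equibiaxial":
                        term = l_ ** (a_i - 1.0) - l_ ** (-2.0 * a_i - 1.0)
                    else:
                        term = l_ ** (a_i - 1.0) - l_ ** (-a_i - 1.0)
                    P[sel] += (2.0 * m_i / a_i) * term
        r = (P - data.stress) / scale
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    rng = np.random.default_rng(seed)
    mu0_guess = scale  # stresses ~ mu at moderate stretch
    best = None
    best_cost = np.inf
    best_start = -1
    init_norm = None
    for start in range(n_starts):
        if start == 0:
            alpha0 = np.array([2.0, 4.0, -2.0, 6.0, -4.0][:order], float)
            mu_init = np.full(order, mu0_guess / order)
        else:
            alpha0 = rng.uniform(1.0, 8.0, order) * rng.choice([-1.0, 1.0], order)
            mu_init = mu0_guess * rng.uniform(0.05, 2.0, order) / order
        x0 = _pack(mu_init, alpha0)
        r0 = residual(x0)
        if init_norm is None:
            init_norm = float(np.linalg.norm(r0))
        try:
            sol = least_squares(residual, x0, method="lm", xtol=1e-14,
                                ftol=1e-14, max_nfev=4000)
        except Exception:
            continue
        if sol.cost < best_cost and np.linalg.norm(sol.fun) <= np.linalg.norm(r0):
            best, best_cost, best_start = sol, sol.cost, start
    if best is None:
        raise RuntimeError("Ogden fit failed to converge from any start")

    mu, alpha = _unpack(best.x, order)
    if np.sum(mu) <= 0:
        # re-polish from the deterministic start if the best solution is
        # unphysical at small strain
        sol = least_squares(residual, _pack(np.full(order, mu0_guess / order),
                                            np.array([2.0, 4.0, -2.0, 6.0,
                                                      -4.0][:order])),
                            method="lm", xtol=1e-14, ftol=1e-14, max_nfev=4000)
        mu, alpha = _unpack(sol.x, order)
        best = sol
    D = bulk_coeffs_from_poisson(mu, alpha, poisson)
    mat = OgdenMaterial(mu=tuple(mu), alpha=tuple(alpha), D=D,
                        poisson=poisson, density=density, name="fitted-ogden")
    J = best.jac
    sv = np.linalg.svd(J, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    diag = FitDiagnostics(
        residual_norm=float(np.linalg.norm(best.fun)),
        initial_residual_norm=float(init_norm),
        jacobian_condition=cond,
        converged=bool(best.status > 0),
        n_starts=n_starts,
        best_start=best_start,
    )
    return mat, diag
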