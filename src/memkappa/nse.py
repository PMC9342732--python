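"""Neutron spin-echo relaxation analysis of membrane undulations.

The intermediate scattering function of a fluctuating membrane decays as a
stretched exponential with fixed exponent 2/3 (Zilman–Granek),

    I(q,t)/I(q,0) = exp[-(Γ t)^(2/3)],

optionally multiplied by a vesicle centre-of-mass diffusion factor
``exp(-D q² t)``. The decay rate scales as

    Γ(q) = 0.025 (kBT/κ̃)^(1/2) (kBT/η) q³,

where η is the solvent viscosity and κ̃ is the *effective* (dynamically
measured) bending modulus. κ̃ is related to the customary bending modulus κ
through the Watson–Brown monolayer-stretching correction κ̃ = κ + h²·K_A,
where h is the neutral-surface height of each monolayer. Eliminating the
area-compressibility K_A requires a model of the K_A–κ relation; three are
implemented:

===============  ==================  ======================
model            K_A relation        amplification κ̃/κ
===============  ==================  ======================
uncoupled        K_A = 48 κ/(2Dc)²   1 + 48 (h/2Dc)²
polymer_brush    K_A = 24 κ/(2Dc)²   1 + 24 (h/2Dc)²
cholesterol      K_A = 12 κ/δ²       1 + 12 (h/δ)²
===============  ==================  ======================

Here 2Dc is the hydrocarbon-core thickness and δ the stiff-layer length of
the high-cholesterol model. All rates are handled in ns⁻¹ with q in Å⁻¹;
conversion to SI happens only inside :func:`effective_kappa`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit

from .units import T_DEFAULT, T_DLS_DEFAULT, thermal_energy, kbt_per_ang2_to_mn_per_m

__all__ = [
    "ZG_PREFACTOR",
    "D2O_VISCOSITY",
    "NSECurve",
    "NSEDataset",
    "RelaxationFit",
    "MonolayerModel",
    "BendingResult",
    "FitError",
    "fit_stretched_exp",
    "fit_gamma_q3",
    "effective_kappa",
    "gamma_from_effective_kappa",
    "kappa_from_effective",
    "effective_from_kappa",
    "ka_from_kappa",
    "spectrin_ka_partition",
    "stokes_einstein",
    "radius_from_diffusion",
    "analyze_nse",
]

#: Zilman–Granek numerical prefactor in the Γ(q) relation.
ZG_PREFACTOR = 0.025

#: Dynamic viscosity of heavy water (Pa·s), interpolated from standard
#: tabulations (Hardy & Cottington-style data), keyed by temperature (K).
D2O_VISCOSITY = {310.15: 8.52e-4, 298.15: 1.095e-3}

# m²/s -> Å²/ns  (1 m² = 1e20 Å², 1 s = 1e9 ns)
_M2_PER_S_TO_ANG2_PER_NS = 1.0e11
# ns⁻¹·Å³ -> s⁻¹·m³
_NSANG3_TO_SM3 = 1.0e9 * 1.0e-30


class FitError(RuntimeError):
    """Raised when a relaxation fit fails to converge or is unphysical."""


@dataclass
class NSECurve:
    """One intermediate-scattering decay at fixed q.

    ``t`` in ns, ``i_rel`` = I(q,t)/I(q,0) dimensionless, ``sigma`` its
    one-standard-deviation uncertainty.
    """

    q: float
    t: np.ndarray
    i_rel: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i_rel = np.asarray(self.i_rel, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not self.q > 0:
            raise ValueError(f"q must be positive, got {self.q}")
        if np.any(self.t < 0):
            raise ValueError("Fourier times must be non-negative")
        if np.any(self.sigma <= 0):
            raise ValueError("uncertainties must be positive")

    def flag_unphysical(self) -> np.ndarray:
        """Boolean mask of points with I/I0 above 1 by more than 3σ."""
        return self.i_rel > 1.0 + 3.0 * self.sigma


@dataclass
class NSEDataset:
    """A set of per-q NSE decays plus the solvent/thermo context."""

    curves: list[NSECurve]
    T: float = T_DEFAULT
    viscosity: float | None = None
    vesicle_radius: float | None = None  # m
    diffusion_D: float | None = None  # m²/s
    meta: dict = field(default_factory=dict)

    @property
    def q_values(self) -> np.ndarray:
        return np.array([c.q for c in self.curves])


@dataclass
class RelaxationFit:
    """Fitted per-q decay rates and their q³ scaling prefactor."""

    q: np.ndarray  # Å⁻¹
    gamma: np.ndarray  # ns⁻¹
    gamma_err: np.ndarray
    diffusion_corrected: bool
    c: float | None = None  # ns⁻¹·Å³
    c_err: float | None = None


@dataclass(frozen=True)
class MonolayerModel:
    """Monolayer-coupling model for the κ̃ → κ conversion.

    ``h`` is the neutral-surface height (Å) above the bilayer midplane;
    ``two_Dc`` the hydrocarbon thickness 2Dc (Å) for the uncoupled and
    polymer-brush variants; ``delta`` the stiff-layer length δ (Å) for the
    cholesterol model.
    """

    name: str
    h: float
    two_Dc: float | None = None
    delta: float | None = None

    _COEFF = {"uncoupled": 48.0, "polymer_brush": 24.0, "cholesterol": 12.0}

    def __post_init__(self) -> None:
        if self.name not in self._COEFF:
            raise ValueError(
                f"unknown monolayer model {self.name!r}; "
                f"expected one of {sorted(self._COEFF)}"
            )
        if not self.h > 0:
            raise ValueError("neutral-surface height h must be positive")
        if self.length is None or not self.length > 0:
            needed = "delta" if self.name == "cholesterol" else "two_Dc"
            raise ValueError(f"model {self.name!r} requires a positive {needed}")

    @property
    def coefficient(self) -> float:
        """The numerical factor a in K_A = a·κ/ℓ²."""
        return self._COEFF[self.name]

    @property
    def length(self) -> float | None:
        """The model length scale ℓ: 2Dc or δ (Å)."""
        return self.delta if self.name == "cholesterol" else self.two_Dc

    @property
    def amplification(self) -> float:
        """κ̃/κ = 1 + a·(h/ℓ)²."""
        return 1.0 + self.coefficient * (self.h / self.length) ** 2


@dataclass
class BendingResult:
    """Bending modulus inferred from NSE with full model provenance."""

    kappa_eff: float  # kBT
    kappa: float  # kBT
    K_A: float  # mN/m
    model: MonolayerModel
    diffusion_corrected: bool
    kappa_eff_err: float | None = None
    kappa_err: float | None = None
    relaxation: RelaxationFit | None = None

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if self.kappa_eff < self.kappa:
            raise ValueError("effective kappa cannot be below kappa")


def _stretched_model(t, gamma, q, D):
    decay = np.exp(-np.power(np.clip(gamma * t, 0.0, None), 2.0 / 3.0))
    if D is not None:
        d_ang = D * _M2_PER_S_TO_ANG2_PER_NS
        decay = decay * np.exp(-d_ang * q * q * t)
    return decay


def fit_stretched_exp(
    curve: NSECurve, D: float | None = None
) -> tuple[float, float]:
    """Fit Γ of a single decay curve, exponent fixed at 2/3.

    ``D`` (m²/s), when given, divides out the vesicle-diffusion factor
    ``exp(-D q² t)``. Returns ``(gamma, stderr)`` in ns⁻¹.
    """
    if curve.t.size < 5:
        raise ValueError("need at least 5 time points to fit a decay rate")
    t, y, sig = curve.t, curve.i_rel, curve.sigma

    # moment-style initial guess from the most-decayed usable point
    pos = (y > 1e-6) & (t > 0)
    if not np.any(pos):
        raise FitError("curve has no usable positive points")
    ln_y = -np.log(y[pos])
    if D is not None:
        ln_y = ln_y - D * _M2_PER_S_TO_ANG2_PER_NS * curve.q**2 * t[pos]
    ln_y = np.clip(ln_y, 1e-12, None)
    gamma0 = float(np.median(np.power(ln_y, 1.5) / t[pos]))
    gamma0 = min(max(gamma0, 1e-8), 1e4)

    params = lmfit.Parameters()
    params.add("gamma", value=gamma0, min=1e-12, max=1e6)

    def residual(p):
        return (_stretched_model(t, p["gamma"].value, curve.q, D) - y) / sig

    out = lmfit.minimize(residual, params, method="least_squares")
    if not out.success:
        raise FitError(f"stretched-exponential fit failed: {out.message}")
    gamma = float(out.params["gamma"].value)
    if gamma <= 0:
        raise FitError(f"non-positive decay rate {gamma}")
    err = out.params["gamma"].stderr
    return gamma, float(err) if err is not None else float("nan")


def fit_gamma_q3(
    q: Sequence[float],
    gamma: Sequence[float],
    gamma_err: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Weighted least-squares fit of Γ = c·q³ through the origin.

    Returns ``(c, stderr)`` with c in ns⁻¹·Å³ for q in Å⁻¹ and Γ in ns⁻¹.
    """
    q = np.asarray(q, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 q points for the q^3 fit")
    if gamma_err is None:
        w = np.ones_like(q)
    else:
        w = 1.0 / np.square(np.asarray(gamma_err, dtype=float))
    x = q**3
    denom = float(np.sum(w * x * x))
    c = float(np.sum(w * x * gamma)) / denom
    # standard error of the single linear coefficient
    c_err = float(np.sqrt(1.0 / denom)) if gamma_err is not None else float("nan")
    return c, c_err


def effective_kappa(c: float, eta: float, T: float = T_DEFAULT) -> float:
    """Invert the Γ = 0.025 (kBT/κ̃)^½ (kBT/η) q³ relation for κ̃ (kBT).

    ``c`` is the Γ/q³ prefactor in ns⁻¹·Å³ and ``eta`` the solvent dynamic
    viscosity in Pa·s.
    """
    if not (c > 0 and eta > 0):
        raise ValueError("c and eta must be positive")
    kbt = thermal_energy(T)
    c_si = c * _NSANG3_TO_SM3  # s⁻¹·m³
    return (ZG_PREFACTOR * kbt / (eta * c_si)) ** 2


def gamma_from_effective_kappa(
    kappa_eff: float, q: float, eta: float, T: float = T_DEFAULT
) -> float:
    """Forward Zilman–Granek rate Γ(q) in s⁻¹ for κ̃ in kBT, q in Å⁻¹."""
    kbt = thermal_energy(T)
    q_si = q * 1.0e10
    return ZG_PREFACTOR * (1.0 / kappa_eff) ** 0.5 * (kbt / eta) * q_si**3


def kappa_from_effective(kappa_eff: float, model: MonolayerModel) -> float:
    """Convert κ̃ to κ under the chosen monolayer-coupling model (kBT)."""
    return kappa_eff / model.amplification


def effective_from_kappa(kappa: float, model: MonolayerModel) -> float:
    """Forward conversion κ → κ̃ (kBT)."""
    return kappa * model.amplification


def ka_from_kappa(kappa: float, model: MonolayerModel, T: float = T_DEFAULT) -> float:
    """Area-compressibility K_A = a·κ/ℓ² implied by the model, in mN/m.

    ``kappa`` in kBT; the result carries the kBT energy factor so it depends
    on temperature.
    """
    ka_kbt_per_ang2 = model.coefficient * kappa / model.length**2
    return kbt_per_ang2_to_mn_per_m(ka_kbt_per_ang2, T)


def spectrin_ka_partition(KA_total: float, KA_membrane: float) -> float:
    """K_A left for the spectrin network: composite minus membrane (mN/m).

    A composite shell's area-compressibility is the sum of its parallel
    components, so the spectrin share is the difference. A negative result
    signals a model inconsistency and raises.
    """
    if KA_membrane < 0:
        raise ValueError("membrane K_A must be non-negative")
    rest = KA_total - KA_membrane
    if rest < 0:
        raise ValueError(
            f"membrane K_A {KA_membrane} exceeds composite K_A {KA_total}: "
            "inconsistent partition"
        )
    return rest


def stokes_einstein(R: float, eta: float, T: float = T_DLS_DEFAULT) -> float:
    """Diffusion constant D = kBT/(6πηR) in m²/s for radius R in m."""
    if not (R > 0 and eta > 0):
        raise ValueError("radius and viscosity must be positive")
    return thermal_energy(T) / (6.0 * np.pi * eta * R)


def radius_from_diffusion(D: float, eta: float, T: float = T_DLS_DEFAULT) -> float:
    """Hydrodynamic radius (m) from a measured diffusion constant (m²/s)."""
    if not (D > 0 and eta > 0):
        raise ValueError("D and viscosity must be positive")
    return thermal_energy(T) / (6.0 * np.pi * eta * D)


def analyze_nse(
    dataset: NSEDataset,
    model: MonolayerModel,
    diffusion_correct: bool = False,
) -> BendingResult:
    """Full pipeline: per-q Γ fits → q³ scaling → κ̃ → κ and K_A.

    When ``diffusion_correct`` is true the vesicle diffusion constant is
    taken from ``dataset.diffusion_D`` or, failing that, computed from
    ``dataset.vesicle_radius`` by Stokes–Einstein at the dataset temperature
    and viscosity.
    """
    if dataset.viscosity is None:
        raise ValueError("dataset must declare a solvent viscosity (Pa·s)")
    D = None
    if diffusion_correct:
        D = dataset.diffusion_D
        if D is None:
            if dataset.vesicle_radius is None:
                raise ValueError(
                    "diffusion correction requested but neither diffusion_D "
                    "nor vesicle_radius is set"
                )
            D = stokes_einstein(dataset.vesicle_radius, dataset.viscosity, dataset.T)

    gams, errs = [], []
    for curve in dataset.curves:
        g, e = fit_stretched_exp(curve, D=D)
        gams.append(g)
        errs.append(e)
    q = dataset.q_values
    gamma = np.array(gams)
    gamma_err = np.array(errs)
    have_errs = np.all(np.isfinite(gamma_err))
    c, c_err = fit_gamma_q3(q, gamma, gamma_err if have_errs else None)
    relax = RelaxationFit(
        q=q, gamma=gamma, gamma_err=gamma_err,
        diffusion_corrected=diffusion_correct, c=c, c_err=c_err,
    )

    k_eff = effective_kappa(c, dataset.viscosity, dataset.T)
    kappa = kappa_from_effective(k_eff, model)
    ka = ka_from_kappa(kappa, model, dataset.T)
    # linear error propagation through κ̃ ∝ c⁻²
    k_eff_err = 2.0 * k_eff * c_err / c if (c_err and np.isfinite(c_err)) else None
    kappa_err = k_eff_err / model.amplification if k_eff_err is not None else None
    return BendingResult(
        kappa_eff=k_eff,
        kappa=kappa,
        K_A=ka,
        model=model,
        diffusion_corrected=diffusion_correct,
        kappa_eff_err=k_eff_err,
        kappa_err=kappa_err,
        relaxation=relax,
    )
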