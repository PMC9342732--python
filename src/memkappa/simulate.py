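"""Ground-truth generators for the three experimental tracks.

Every generator embeds its ground truth and seed in the output metadata and
is bit-reproducible under a fixed integer seed (NumPy ``default_rng``
streams). Defaults correspond to the study conditions of the red-blood-cell
cytoplasmic membrane measurements: a smectic stack with κ = 2 kBT,
B = 2·10⁻⁷ kBT/Å⁴ and d = 74.8 Å probed at q_z = 2q₁ and 2.5q₁ with
counting statistics peaking near 10⁵ counts; spin-echo decays at the four
experimental q values over Fourier times 0.01–100 ns; and 34 nm membrane
patches whose spectrum carries κ = 4.2 kBT and K_t = 3.63 mN/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .units import T_DEFAULT
from .nse import (
    MonolayerModel,
    NSECurve,
    NSEDataset,
    effective_from_kappa,
    gamma_from_effective_kappa,
)
from .undulation import HeightField, model_spectrum
from .xds import (
    CailleModel,
    DiffuseMap,
    DomainSizeModel,
    SmecticStackParams,
    TiltStackParams,
    XdsSettings,
)

__all__ = [
    "NoiseModel",
    "apply_noise",
    "simulate_diffuse_map",
    "simulate_nse",
    "sample_height_fields",
    "SimulatedHeightFields",
    "DEFAULT_NSE_Q",
]

#: The four spin-echo scattering vectors of the experiment (Å⁻¹).
DEFAULT_NSE_Q = (0.0523, 0.0664, 0.0794, 0.0959)


@dataclass(frozen=True)
class NoiseModel:
    """Declarative noise description shared by the generators.

    ``kind`` is one of ``none``, ``poisson`` or ``gaussian``. For Poisson
    noise, ``exposure`` converts model intensity to expected counts (when
    unset, it is chosen so the brightest pixel expects ``peak_counts``).
    For Gaussian noise the relative σ grows with a supplied fraction:
    ``sigma0 + sigma_slope·f`` where f ∈ [0, 1] spans the record (late
    spin-echo times are noisier).
    """

    kind: str = "none"
    exposure: float | None = None
    peak_counts: float = 1e5
    sigma0: float = 0.005
    sigma_slope: float = 0.015

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


def apply_noise(values: np.ndarray, noise: NoiseModel, rng: np.random.Generator):
    """Apply a noise model to non-negative model values; returns (values, sigma)."""
    values = np.asarray(values, dtype=float)
    if noise.kind == "none":
        return values.copy(), 0.01 * np.clip(values, 1e-12, None)
    if noise.kind == "poisson":
        exposure = noise.exposure
        if exposure is None:
            exposure = noise.peak_counts / float(values.max())
        counts = rng.poisson(np.clip(values, 0.0, None) * exposure).astype(float)
        sigma = np.sqrt(np.clip(counts, 1.0, None))
        return counts / exposure, sigma / exposure
    # gaussian, relative sigma growing along the record
    f = np.linspace(0.0, 1.0, values.size)
    sigma = (noise.sigma0 + noise.sigma_slope * f) * np.clip(values, 1e-12, None)
    return values + rng.normal(0.0, sigma), sigma


def simulate_diffuse_map(
    stack: SmecticStackParams,
    domains: DomainSizeModel,
    qz_grid: Sequence[float] | None = None,
    qpar_grid: Sequence[float] | None = None,
    scales: Sequence[float] | None = None,
    background: float = 0.0,
    noise: NoiseModel = NoiseModel(kind="poisson"),
    seed: int | None = None,
    tilt: TiltStackParams | None = None,
    settings: XdsSettings | None = None,
) -> DiffuseMap:
    """Simulate a gridded diffuse intensity map from the smectic model.

    Each q_z row is ``scale·S(q_z, q_∥) + background`` with the configured
    noise applied; the returned map's ``meta`` records the full ground
    truth. Default rows sit at q_z = 2q₁ and 2.5q₁, the slice positions of
    the diffuse-scattering analysis, over q_∥ ∈ [0.005, 0.105] Å⁻¹.
    """
    if qz_grid is None:
        qz_grid = [2.0 * stack.q1, 2.5 * stack.q1]
    if qpar_grid is None:
        qpar_grid = np.arange(0.005, 0.10501, 0.0025)
    qz_grid = np.asarray(qz_grid, dtype=float)
    qpar_grid = np.asarray(qpar_grid, dtype=float)
    if scales is None:
        scales = np.ones(qz_grid.size)
    scales = np.asarray(scales, dtype=float)

    model = CailleModel(stack.d, domains, T=stack.T, tilt=tilt, settings=settings)
    rng = np.random.default_rng(seed)
    clean = np.empty((qz_grid.size, qpar_grid.size))
    for i, qz in enumerate(qz_grid):
        clean[i] = scales[i] * model.structure_factor(stack, qz, qpar_grid) + background

    if noise.kind == "poisson" and noise.exposure is None:
        noise = NoiseModel(
            kind="poisson", exposure=noise.peak_counts / float(clean.max()),
            peak_counts=noise.peak_counts,
        )
    intensity = np.empty_like(clean)
    sigma = np.empty_like(clean)
    for i in range(qz_grid.size):
        intensity[i], sigma[i] = apply_noise(clean[i], noise, rng)

    meta = {
        "kappa": stack.kappa, "B": stack.B, "d": stack.d, "q1": stack.q1,
        "T": stack.T, "Lr": domains.Lr, "sigma_r": domains.sigma_r,
        "Lz": domains.Lz, "sigma_z": domains.sigma_z,
        "scales": list(map(float, scales)), "background": background,
        "noise": asdict(noise), "seed": seed,
        "Kt": tilt.Kt if tilt is not None else None,
    }
    return DiffuseMap(
        qz=qz_grid, qpar=qpar_grid, intensity=np.clip(intensity, 0.0, None),
        sigma=sigma, meta=meta,
    )


def simulate_nse(
    kappa_true: float,
    model: MonolayerModel,
    eta: float,
    T: float = T_DEFAULT,
    q_values: Sequence[float] = DEFAULT_NSE_Q,
    t_grid: Sequence[float] | None = None,
    D: float | None = None,
    noise: NoiseModel = NoiseModel(kind="gaussian"),
    seed: int | None = None,
) -> NSEDataset:
    """Simulate per-q intermediate-scattering decays for a known κ.

    The decay rate at each q follows the Zilman–Granek relation with the
    effective modulus κ̃ = κ·(model amplification); curves are
    ``exp(-D q² t)·exp(-(Γ t)^{2/3})`` with optional Gaussian noise whose
    relative σ grows towards late Fourier times.
    """
    if t_grid is None:
        t_grid = np.geomspace(0.01, 100.0, 40)
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)

    kappa_eff = effective_from_kappa(kappa_true, model)
    curves = []
    gamma_truth = {}
    for q in q_values:
        gamma_si = gamma_from_effective_kappa(kappa_eff, q, eta, T)
        gamma_ns = gamma_si * 1e-9
        gamma_truth[float(q)] = gamma_ns
        decay = np.exp(-np.power(gamma_ns * t_grid, 2.0 / 3.0))
        if D is not None:
            decay = decay * np.exp(-D * 1.0e11 * q * q * t_grid)  # m²/s → Å²/ns
        i_rel, sigma = apply_noise(decay, noise, rng)
        curves.append(NSECurve(q=float(q), t=t_grid.copy(), i_rel=i_rel, sigma=sigma))

    meta = {
        "kappa_true": kappa_true, "kappa_eff_true": kappa_eff,
        "model": model.name, "h": model.h, "two_Dc": model.two_Dc,
        "delta": model.delta, "eta": eta, "T": T, "D": D,
        "gamma_true_ns": gamma_truth, "noise": asdict(noise), "seed": seed,
    }
    return NSEDataset(curves=curves, T=T, viscosity=eta, diffusion_D=D, meta=meta)


@dataclass
class SimulatedHeightFields:
    """Sampled membrane height frames plus their generation metadata."""

    frames: list[HeightField]
    meta: dict


def sample_height_fields(
    L: float = 340.0,
    N: int = 64,
    kappa: float = 4.2,
    Kt: float = 3.63,
    T: float = T_DEFAULT,
    n_frames: int = 200,
    seed: int | None = None,
) -> SimulatedHeightFields:
    """Sample equilibrium height fields from the bending + tilt spectrum.

    Each Fourier mode receives an independent Gaussian amplitude with
    variance set by ⟨|h(Q)|²⟩ = kBT/(κQ⁴) + kBT/(K_tQ²) under the package's
    spectrum normalization; Hermitian symmetry is enforced by filtering a
    white real field, so the inverse transform is a real, zero-mean height
    field. ``kappa`` in kBT, ``Kt`` in mN/m, ``L`` in Å.
    """
    if not (kappa > 0 and Kt > 0 and L > 0 and N >= 8 and n_frames >= 1):
        raise ValueError("invalid height-field sampling parameters")
    rng = np.random.default_rng(seed)
    qx = 2.0 * np.pi * np.fft.fftfreq(N, d=L / N)
    QX, QY = np.meshgrid(qx, qx, indexing="ij")
    Qmag = np.hypot(QX, QY)
    amp = np.zeros_like(Qmag)
    nonzero = Qmag > 0
    spectrum = model_spectrum(Qmag[nonzero], kappa, Kt, T)  # Å⁴
    amp[nonzero] = (N / L) * np.sqrt(spectrum)

    frames = []
    meta = {
        "L": L, "N": N, "kappa": kappa, "Kt": Kt, "T": T,
        "n_frames": n_frames, "seed": seed,
    }
    for _ in range(n_frames):
        white = rng.standard_normal((N, N))
        h = np.fft.ifft2(amp * np.fft.fft2(white)).real
        h -= h.mean()
        frames.append(HeightField(L=L, heights=h, T=T, meta=dict(meta)))
    return SimulatedHeightFields(frames=frames, meta=meta)
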