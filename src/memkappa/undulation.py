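"""Membrane undulation spectra from height fields, and Helfrich–Canham + tilt fits.

A membrane patch on a periodic L×L box is described by a height field
h(x, y) sampled on an N×N grid. With the Fourier convention

    h(r) = Σ_Q ĥ_Q exp(iQ·r),      ĥ_Q = FFT2(h)/N²,

the quantity reported by :func:`compute_spectrum` is

    ⟨|h(Q)|²⟩ ≡ L² ⟨|ĥ_Q|²⟩   (Å⁴),

radially binned over shells of width ΔQ = 2π/L. This normalization makes
the real-space variance equal to the mode sum Σ ⟨|h(Q)|²⟩/L² (discrete
Parseval) and renders the spectrum box-size independent for a given
continuum model. Thermal equilibrium of an elastic sheet with bending
modulus κ and tilt modulus K_t predicts

    ⟨|h(Q)|²⟩ = kBT/(κ Q⁴) + kBT/(K_t Q²),

which :func:`fit_hc_tilt` fits on the low-Q regime (default Q < 0.2 Å⁻¹,
below which the continuum sheet picture holds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import T_DEFAULT, kbt_per_ang2_to_mn_per_m, mn_per_m_to_kbt_per_ang2

__all__ = [
    "HeightField",
    "UndulationSpectrum",
    "SpectrumFit",
    "q_min",
    "compute_spectrum",
    "fit_hc_tilt",
]


def q_min(L: float) -> float:
    """Smallest wave vector 2π/L (Å⁻¹) resolvable on a periodic box of edge L (Å)."""
    if not L > 0:
        raise ValueError(f"box edge must be positive, got {L}")
    return 2.0 * np.pi / L


@dataclass
class HeightField:
    """One snapshot of membrane heights on a periodic square grid.

    ``L`` box edge (Å), ``heights`` an N×N array (Å), ``T`` temperature (K).
    """

    L: float
    heights: np.ndarray
    T: float = T_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.shape[0] != self.heights.shape[1]:
            raise ValueError("heights must be a square 2-D array")
        if self.heights.shape[0] < 8:
            raise ValueError("need at least 8 samples per edge")
        if not self.L > 0:
            raise ValueError("box edge must be positive")

    @property
    def N(self) -> int:
        return self.heights.shape[0]


@dataclass
class UndulationSpectrum:
    """Radially binned fluctuation spectrum ⟨|h(Q)|²⟩ with standard errors.

    ``q4_inv_mean`` / ``q2_inv_mean`` hold the per-shell averages of Q⁻⁴ and
    Q⁻² over the discrete member modes. A shell of width ΔQ mixes modes of
    appreciably different |Q|, and Q⁻⁴ is convex enough that evaluating the
    model at the shell centre would bias a bending fit at low Q; averaging
    the regressors the same way the data are averaged removes that bias
    exactly. They are ``None`` for spectra tabulated without mode bookkeeping.
    """

    Q: np.ndarray  # shell centers, Å⁻¹
    values: np.ndarray  # Å⁴
    errors: np.ndarray  # standard error of the shell mean
    n_frames: int
    L: float
    T: float
    q4_inv_mean: np.ndarray | None = None
    q2_inv_mean: np.ndarray | None = None


@dataclass
class SpectrumFit:
    """Result of the bending + tilt spectrum fit."""

    kappa: float  # kBT
    kappa_err: float
    Kt: float  # mN/m (inf if the tilt term was dropped)
    Kt_err: float
    Qmax_fit: float
    chi2: float
    Kt_at_bound: bool = False


def compute_spectrum(frames: list[HeightField]) -> UndulationSpectrum:
    """Average the mode power of many frames into radial shells.

    Each frame is mean-subtracted (the Q = 0 mode carries no elastic
    information), Fourier transformed, and its mode powers |ĥ_Q|²·L² are
    averaged within shells |Q| ∈ [(m-½)ΔQ, (m+½)ΔQ), ΔQ = 2π/L. The shell
    value is the mean over frames; the error is the standard error over
    frames (or over shell members for a single frame).
    """
    if not frames:
        raise ValueError("need at least one frame")
    L, N, T = frames[0].L, frames[0].N, frames[0].T
    for f in frames:
        if f.L != L or f.N != N:
            raise ValueError("all frames must share the same box edge and grid size")

    dq = 2.0 * np.pi / L
    qx = 2.0 * np.pi * np.fft.fftfreq(N, d=L / N)
    QX, QY = np.meshgrid(qx, qx, indexing="ij")
    Qmag = np.hypot(QX, QY)
    shell = np.rint(Qmag / dq).astype(int)
    shell[0, 0] = -1  # exclude the zero mode
    n_shells = shell.max() + 1
    counts = np.bincount(shell[shell >= 0].ravel(), minlength=n_shells)

    per_frame = np.empty((len(frames), n_shells))
    for i, f in enumerate(frames):
        h = f.heights - f.heights.mean()
        hhat = np.fft.fft2(h) / N**2
        power = (np.abs(hhat) ** 2) * L**2
        sums = np.bincount(
            shell[shell >= 0].ravel(), weights=power[shell >= 0].ravel(),
            minlength=n_shells,
        )
        with np.errstate(invalid="ignore"):
            per_frame[i] = sums / counts

    valid = counts > 0
    values = per_frame[:, valid].mean(axis=0)
    if len(frames) > 1:
        errors = per_frame[:, valid].std(axis=0, ddof=1) / np.sqrt(len(frames))
    else:
        errors = values / np.sqrt(np.maximum(counts[valid], 1))
    Q = np.arange(n_shells)[valid] * dq

    flat = shell[shell >= 0].ravel()
    qmag = Qmag[shell >= 0].ravel()
    q4_inv = np.bincount(flat, weights=qmag**-4.0, minlength=n_shells) / counts.clip(1)
    q2_inv = np.bincount(flat, weights=qmag**-2.0, minlength=n_shells) / counts.clip(1)
    return UndulationSpectrum(
        Q=Q, values=values, errors=errors, n_frames=len(frames), L=L, T=T,
        q4_inv_mean=q4_inv[valid], q2_inv_mean=q2_inv[valid],
    )


def model_spectrum(Q, kappa: float, Kt_mn_per_m: float | None, T: float = T_DEFAULT):
    """⟨|h(Q)|²⟩ in Å⁴ for κ in kBT and K_t in mN/m (None drops the tilt term)."""
    Q = np.asarray(Q, dtype=float)
    s = 1.0 / (kappa * Q**4)
    if Kt_mn_per_m is not None and np.isfinite(Kt_mn_per_m):
        kt_int = mn_per_m_to_kbt_per_ang2(Kt_mn_per_m, T)
        s = s + 1.0 / (kt_int * Q**2)
    return s


def fit_hc_tilt(
    spec: UndulationSpectrum, Qmax_fit: float = 0.2, T: float | None = None
) -> SpectrumFit:
    """Weighted linear fit of kBT/(κQ⁴) + kBT/(K_tQ²) on bins below ``Qmax_fit``.

    The model is linear in (1/κ, 1/K_t), so the fit is a weighted linear
    least-squares solve with the parameter covariance from the normal
    equations. A non-positive tilt coefficient (spectrum steeper than the
    model allows) is flagged: K_t is reported at its rigid bound (infinite
    tilt stiffness) and the fit falls back to the pure bending term.
    """
    T = spec.T if T is None else T
    mask = (spec.Q < Qmax_fit) & (spec.Q > 0)
    if mask.sum() < 4:
        raise ValueError(
            f"need >= 4 spectrum bins below Qmax_fit={Qmax_fit}, got {mask.sum()}"
        )
    Q = spec.Q[mask]
    y = spec.values[mask]
    w = 1.0 / np.square(spec.errors[mask])

    if spec.q4_inv_mean is not None and spec.q2_inv_mean is not None:
        X = np.column_stack([spec.q4_inv_mean[mask], spec.q2_inv_mean[mask]])
    else:
        X = np.column_stack([Q**-4.0, Q**-2.0])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    coeff = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)

    kt_at_bound = coeff[1] <= 0
    if kt_at_bound:
        # pure Q^-4 refit
        x4 = X[:, 0]
        a_denom = float(np.sum(w * x4 * x4))
        a = float(np.sum(w * y * x4)) / a_denom
        a_err = float(np.sqrt(1.0 / a_denom))
        resid = (a * x4 - y) * np.sqrt(w)
        kappa = 1.0 / a
        return SpectrumFit(
            kappa=kappa,
            kappa_err=a_err / a**2,
            Kt=float("inf"),
            Kt_err=float("nan"),
            Qmax_fit=Qmax_fit,
            chi2=float(resid @ resid),
            Kt_at_bound=True,
        )

    a, bt = coeff
    a_err, bt_err = np.sqrt(np.diag(cov))
    resid = (X @ coeff - y) * np.sqrt(w)
    kappa = 1.0 / a
    kt_int = 1.0 / bt  # kBT/Å²
    return SpectrumFit(
        kappa=float(kappa),
        kappa_err=float(a_err / a**2),
        Kt=kbt_per_ang2_to_mn_per_m(kt_int, T),
        Kt_err=kbt_per_ang2_to_mn_per_m(bt_err / bt**2, T),
        Qmax_fit=Qmax_fit,
        chi2=float(resid @ resid),
    )
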