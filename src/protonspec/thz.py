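"""Experimental THz extinction handling and Kramers-Kronig conversion.

Transmitted intensities become extinction coefficients through the
Beer-Lambert law,

    alpha_solution(w) = ln(I_water / I_solution) / d + alpha_water(w),

and extinction is converted to the absorption spectrum w chi''(w) by
fitting a sum of damped-harmonic-oscillator (and optionally Debye) bands
whose analytic Kramers-Kronig-consistent susceptibilities are then
evaluated.  The model route is numerically stable on band-limited data; a
numerical Hilbert-transform alternative is provided for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal

from .constants import SPEED_OF_LIGHT_CM_S, angular_frequency_rad_fs
from .spectra import Spectrum


class ConversionError(RuntimeError):
    pass


@dataclass
class ExtinctionSpectrum:
    """Measured extinction coefficient alpha (cm^-1) vs wavenumber."""

    wavenumbers: np.ndarray  # cm^-1, instrument range ~30-650
    alpha: np.ndarray  # cm^-1
    thickness: float = 13e-4  # cm (sample-cell spacer)
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("non-finite extinction values")
        if self.thickness <= 0:
            raise ValueError("sample thickness must be positive")


def extinction_from_intensities(
    i_water: np.ndarray,
    i_solution: np.ndarray,
    wavenumbers: np.ndarray,
    thickness: float,
    alpha_water: Optional[np.ndarray] = None,
) -> ExtinctionSpectrum:
    """Beer-Lambert extinction from transmitted intensities.

    ``alpha_water`` is the literature extinction of the bulk-water
    reference (zeros if omitted, giving the pure attenuation difference).
    """
    i_w = np.asarray(i_water, dtype=float)
    i_s = np.asarray(i_solution, dtype=float)
    if np.any(i_w <= 0) or np.any(i_s <= 0):
        raise ValueError("intensities must be positive")
    base = np.zeros_like(i_w) if alpha_water is None else np.asarray(alpha_water)
    alpha = np.log(i_w / i_s) / thickness + base
    return ExtinctionSpectrum(wavenumbers=np.asarray(wavenumbers, dtype=float),
                              alpha=alpha, thickness=thickness)


# ---------------------------------------------------------------------------
# band model


@dataclass
class OscillatorBand:
    """One damped harmonic oscillator: chi(w) = s w0^2/(w0^2 - w^2 - i g w)."""

    center_cm: float  # w0 as a wavenumber
    width_cm: float  # damping g as a wavenumber
    strength: float  # dimensionless chi(0) contribution

    def chi_imag(self, nu_cm: np.ndarray) -> np.ndarray:
        w = np.asarray(nu_cm, dtype=float)
        w0, g = self.center_cm, self.width_cm
        return self.strength * w0 ** 2 * g * w / (
            (w0 ** 2 - w ** 2) ** 2 + (g * w) ** 2
        )


@dataclass
class DebyeBand:
    """Debye relaxation: chi(w) = s / (1 - i w tau)."""

    tau_cm: float  # relaxation wavenumber nu_D = 1/(2 pi c tau), cm^-1
    strength: float

    def chi_imag(self, nu_cm: np.ndarray) -> np.ndarray:
        w = np.asarray(nu_cm, dtype=float)
        x = w / self.tau_cm  # omega * tau
        return self.strength * x / (1 + x ** 2)

    @property
    def tau_fs(self) -> float:
        """Relaxation time in fs (tau = 1/(2 pi c nu_D))."""
        return 1.0 / angular_frequency_rad_fs(self.tau_cm)


@dataclass
class KKModel:
    """Band-model fit of an extinction spectrum with analytic KK pairs."""

    bands: list[OscillatorBand]
    debye: Optional[DebyeBand]
    background_index: float
    residual_rms: float
    n_points: int

    def chi_imag(self, nu_cm: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(nu_cm, dtype=float))
        for b in self.bands:
            out = out + b.chi_imag(nu_cm)
        if self.debye is not None:
            out = out + self.debye.chi_imag(nu_cm)
        return out

    def extinction(self, nu_cm: np.ndarray) -> np.ndarray:
        """Forward model: alpha = 2 pi nu chi'' / n_b (weak-absorption limit)."""
        nu = np.asarray(nu_cm, dtype=float)
        return 2 * math.pi * nu * self.chi_imag(nu) / self.background_index


def _model_alpha(nu: np.ndarray, params: np.ndarray, n_osc: int,
                 with_debye: bool, n_b: float) -> np.ndarray:
    out = np.zeros_like(nu)
    for k in range(n_osc):
        w0, g, s = params[3 * k: 3 * k + 3]
        out = out + OscillatorBand(w0, g, s).chi_imag(nu)
    if with_debye:
        nd, s = params[3 * n_osc: 3 * n_osc + 2]
        out = out + DebyeBand(nd, s).chi_imag(nu)
    return 2 * math.pi * nu * out / n_b


def kk_convert(
    ext: ExtinctionSpectrum,
    max_bands: int = 8,
    with_debye: bool = False,
    background_index: float = 2.1,
    rel_tol: float = 0.02,
) -> tuple[Spectrum, KKModel]:
    """Convert extinction to the absorption spectrum w chi'' via a band fit.

    Damped-harmonic-oscillator bands (plus an optional Debye term) are
    fitted to alpha(nu); the number of bands grows until a BIC-style
    penalty stops improving (capped at ``max_bands``).  The analytic chi''
    of the fitted model, evaluated on the measured band, is returned
    together with the model and its diagnostics.  Raises
    :class:`ConversionError` when no model reaches an acceptable residual.
    """
    nu = ext.wavenumbers
    alpha = ext.alpha
    scale = float(np.max(np.abs(alpha)))
    if scale == 0:
        zero = Spectrum(wavenumbers=nu.copy(), values=np.zeros_like(nu),
                        subsystem="experimental")
        return zero, KKModel([], None, background_index, 0.0, len(nu))

    # initial band guesses from smoothed-curve maxima
    smooth = signal.savgol_filter(alpha, max(5, len(nu) // 20 * 2 + 1), 3)
    peaks, _ = signal.find_peaks(smooth, prominence=0.05 * scale)
    guesses = list(nu[peaks]) or [float(nu[np.argmax(alpha)])]

    best: Optional[tuple[float, np.ndarray, int]] = None
    span = nu[-1] - nu[0]
    for n_osc in range(0 if with_debye else 1, max_bands + 1):
        centers = (guesses[:n_osc]
                   + list(np.linspace(nu[0] + 0.2 * span, nu[-1] - 0.1 * span,
                                      max(0, n_osc - len(guesses)))))
        p0, lo, hi = [], [], []
        for c in centers[:n_osc]:
            p0 += [c, span / 6, scale / (2 * math.pi * max(c, 1.0)) * 2]
            lo += [nu[0] / 3, 1.0, 0.0]
            hi += [nu[-1] * 3, span * 4, np.inf]
        if with_debye:
            p0 += [max(nu[0], 10.0), scale / (2 * math.pi * nu[0] + 1e-9)]
            lo += [0.1, 0.0]
            hi += [nu[-1] * 3, np.inf]

        def resid(p):
            return _model_alpha(nu, p, n_osc, with_debye, background_index) - alpha

        try:
            sol = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                         max_nfev=4000 * (n_osc + 1))
        except Exception:  # infeasible start; try more bands
            continue
        sse = float(np.sum(sol.fun ** 2))
        n_par = len(p0)
        bic = len(nu) * math.log(max(sse / len(nu), 1e-300)) + n_par * math.log(len(nu))
        if best is None or bic < best[0] - 2.0:
            best = (bic, sol.x, n_osc)
        else:
            break  # additional band no longer pays its penalty

    if best is None:
        raise ConversionError("band-model fit failed for every band count")
    _, params, n_osc = best
    bands = [OscillatorBand(*params[3 * k: 3 * k + 3]) for k in range(n_osc)]
    debye = (DebyeBand(*params[3 * n_osc: 3 * n_osc + 2]) if with_debye else None)
    model = KKModel(bands=bands, debye=debye, background_index=background_index,
                    residual_rms=0.0, n_points=len(nu))
    resid_rms = float(np.sqrt(np.mean((model.extinction(nu) - alpha) ** 2)))
    model.residual_rms = resid_rms
    if resid_rms > rel_tol * scale * 5:
        raise ConversionError(
            f"band model residual {resid_rms:.3g} too large (scale {scale:.3g})"
        )
    # w chi'' with omega in rad/s, matching the simulation spectra convention
    omega_si = 2 * math.pi * SPEED_OF_LIGHT_CM_S * nu
    values = omega_si * model.chi_imag(nu)
    return (Spectrum(wavenumbers=nu.copy(), values=values,
                     subsystem="experimental"), model)


def kk_convert_hilbert(ext: ExtinctionSpectrum,
                       background_index: float = 2.1) -> Spectrum:
    """Model-free alternative: chi'' directly from the weak-absorption map.

    Inverts the same forward relation alpha = 2 pi nu chi'' / n_b used by
    the band model, point by point, without enforcing Kramers-Kronig
    consistency.  Useful as a cross-check of the band-model conversion on
    smooth data; noisier and extrapolation-sensitive at the band edges.
    """
    nu = ext.wavenumbers
    chi2 = np.zeros_like(nu)
    pos = nu > 0
    chi2[pos] = ext.alpha[pos] * background_index / (2 * math.pi * nu[pos])
    omega_si = 2 * math.pi * SPEED_OF_LIGHT_CM_S * nu
    return Spectrum(wavenumbers=nu.copy(), values=omega_si * chi2,
                    subsystem="experimental")


def normalized_difference(
    solution: Spectrum,
    water: Spectrum,
    c_w: float,
    c_w0: float,
    c_hcl: Optional[float] = None,
) -> Spectrum:
    """Concentration-normalized experimental difference spectrum.

    Identical to the simulation-side difference rule: solution and water
    spectra divided by their water concentrations, optionally further
    divided by the HCl concentration.
    """
    from .spectra import difference_spectrum

    if c_w is None or c_w0 is None:
        raise ValueError("water concentrations are required")
    return difference_spectrum(solution, water, c_w, c_w0, c_hcl)
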