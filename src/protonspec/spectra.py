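"""Linear-response IR/THz spectra from dipole and coordinate trajectories.

The absorptive part of the dielectric susceptibility follows from the
equilibrium dipole autocorrelation C(t) = sum_D <p(t) p(0)>,

    chi(w) = (C(0) - i (w/2) C+(w)) / (V kB T eps0 D),

with C+(w) the one-sided Fourier transform of C.  The energy absorption
rate is proportional to w chi''(w), which for a sampled series reduces to
the (manifestly nonnegative) periodogram route

    w chi''(w)  proportional to  w^2 |p(w)|^2 / L_t.

Correlation functions are estimated with the finite-length bias correction
1/(L_t - t); for charged subsystems the current route (the |j(w)|^2 / w^2
form) avoids the origin-dependence of the polarization.

Internal units: dipoles in e*A, time in fs, wavenumbers in cm^-1.
chi'' is dimensionless (SI conversion happens in the prefactor); reported
values are w*chi'' with w in rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .constants import (
    BOLTZMANN_J_K,
    ELEMENTARY_CHARGE_C,
    SPEED_OF_LIGHT_CM_FS,
    VACUUM_PERMITTIVITY,
    DEFAULT_CHARGE_MAP,
)
from .traj_io import Trajectory, TrajectoryMeta, unwrap_series


@dataclass
class DipoleSeries:
    """Uniformly sampled dipole (or scalar-coordinate) series in e*A."""

    dt: float  # fs
    vectors: np.ndarray  # (T,) or (T, D)
    subsystem: str = "total"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim == 1:
            self.vectors = self.vectors[:, None]
        if self.vectors.shape[1] not in (1, 3):
            raise ValueError("dipole must have 1 or 3 components")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite dipole values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def length_fs(self) -> float:
        return len(self.vectors) * self.dt

    def __len__(self) -> int:
        return len(self.vectors)

    def __sub__(self, other: "DipoleSeries") -> "DipoleSeries":
        if len(other) != len(self) or other.n_dim != self.n_dim:
            raise ValueError("dipole series shapes differ")
        return DipoleSeries(self.dt, self.vectors - other.vectors,
                            subsystem=f"{self.subsystem}-{other.subsystem}")


@dataclass
class CorrelationFunction:
    """Autocorrelation C(t) with optional link back to its periodogram."""

    dt: float
    values: np.ndarray  # C(t_k), k = 0..K-1
    periodogram: Optional[np.ndarray] = None  # |p(w_j)|^2 * dt / N, nonneg
    n_samples: Optional[int] = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


@dataclass
class Spectrum:
    """Spectral values on a strictly increasing wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray
    values: np.ndarray
    normalization: str = "none"  # none | per_cw | per_chcl | per_cw_per_chcl
    sigma_cm: float = 0.0
    subsystem: str = "total"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite spectral values")

    def interp(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavenumbers, self.values)

    def peak_wavenumber(self, lo: float = 0.0, hi: float = math.inf) -> float:
        """Peak position with local parabolic interpolation over 5 points."""
        sel = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        nu, v = self.wavenumbers[sel], self.values[sel]
        if len(nu) < 3:
            raise ValueError("too few grid points in the peak window")
        k = int(np.argmax(v))
        lo_i, hi_i = max(0, k - 2), min(len(nu), k + 3)
        coef = np.polyfit(nu[lo_i:hi_i], v[lo_i:hi_i], 2)
        if coef[0] >= 0:  # degenerate window, fall back to grid maximum
            return float(nu[k])
        return float(-coef[1] / (2 * coef[0]))

    def __add__(self, other: "Spectrum") -> "Spectrum":
        self._check_grid(other)
        return replace(self, values=self.values + other.values)

    def __sub__(self, other: "Spectrum") -> "Spectrum":
        self._check_grid(other)
        return replace(self, values=self.values - other.values)

    def _check_grid(self, other: "Spectrum") -> None:
        if len(other.wavenumbers) != len(self.wavenumbers) or not np.allclose(
            other.wavenumbers, self.wavenumbers
        ):
            raise ValueError("spectra live on different grids")


# ---------------------------------------------------------------------------
# dipole assembly


def dipole_from_frames(
    traj: Trajectory,
    charge_map: Optional[dict[str, float]] = None,
    subsystem: Optional[np.ndarray] = None,
    subsystem_label: str = "total",
    require_neutral: bool = False,
) -> DipoleSeries:
    """Assemble p(t) = sum_i q_i r_i over a subsystem of a trajectory.

    Wannier centers carry charge -2e and nuclei their pseudopotential core
    charges (H +1, O +6, Cl +7) by default; ``charge_map`` overrides.  A
    full-system dipole requires Wannier data on every frame.  Positions are
    unwrapped in time so molecular dipoles stay continuous across the
    periodic boundary.
    """
    charges = dict(DEFAULT_CHARGE_MAP)
    if charge_map:
        charges.update(charge_map)
    elems = np.asarray(traj.elements)
    if subsystem is None:
        subsystem = np.arange(len(elems))
        if any(fr.wannier_positions is None for fr in traj.frames):
            raise ValueError(
                "full-system dipole needs Wannier centers on every frame"
            )
    subsystem = np.asarray(subsystem)
    q_nuc = np.array([charges[e] for e in elems[subsystem]])

    cell = traj.frames[0].cell_edge
    pos = unwrap_series(
        np.stack([fr.positions[subsystem] for fr in traj.frames]), cell
    )
    p = np.einsum("i,tij->tj", q_nuc, pos)
    has_wc = traj.frames[0].wannier_positions is not None
    if has_wc:
        wpos = unwrap_series(
            np.stack([fr.wannier_positions for fr in traj.frames]), cell
        )
        q_total = q_nuc.sum() + charges["X"] * wpos.shape[1]
        if require_neutral and abs(q_total) > 1e-9:
            raise ValueError(f"system is not neutral: total charge {q_total} e")
        p = p + charges["X"] * wpos.sum(axis=1)
    return DipoleSeries(dt=traj.dt, vectors=p, subsystem=subsystem_label)


# ---------------------------------------------------------------------------
# correlation and susceptibility estimators


def autocorrelation_wk(
    series: DipoleSeries,
    max_lag_fraction: float = 0.5,
    subtract_mean: bool = True,
) -> CorrelationFunction:
    """Bias-corrected autocorrelation via the Wiener-Khinchin FFT route.

    C(t_k) = (1/(N-k)) sum_m p(t_m) . p(t_m+k), computed with zero-padded
    FFTs and the 1/(L_t - t) finite-length correction.  The correlation is
    truncated at ``max_lag_fraction`` of the series length to control the
    variance blow-up of the correction factor.
    """
    x = series.vectors
    n = len(x)
    if n < 2:
        raise ValueError("series must have at least 2 samples")
    if subtract_mean:
        x = x - x.mean(axis=0)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    xf = np.fft.rfft(x, n=nfft, axis=0)
    raw = np.fft.irfft((xf * np.conj(xf)).sum(axis=1), n=nfft)[:n]
    k_max = max(2, int(n * max_lag_fraction))
    corr = raw[:k_max] / (n - np.arange(k_max))
    # nonnegative periodogram of the same (mean-free) series, for the
    # positivity-exact spectral route: |p~(w)|^2 / L_t = dt |X_j|^2 / N
    pgram = (np.abs(np.fft.rfft(x, axis=0)) ** 2).sum(axis=1) * series.dt / n
    return CorrelationFunction(
        dt=series.dt, values=corr, periodogram=pgram, n_samples=n
    )


def autocorrelation_direct(series: DipoleSeries, max_lag: int) -> np.ndarray:
    """O(N^2) lag-sum reference estimator (small inputs only)."""
    x = series.vectors - series.vectors.mean(axis=0)
    n = len(x)
    return np.array(
        [(x[: n - k] * x[k:]).sum() / (n - k) for k in range(max_lag)]
    )


def _si_prefactor(meta: TrajectoryMeta, n_dim: int) -> float:
    """1/(V kB T eps0 D) with dipoles in e*A, volume in A^3, time in fs.

    Returns the factor converting (e*A)^2 * fs  ->  dimensionless chi,
    i.e. includes the fs->s conversion of the time integral.
    """
    if meta.volume is None:
        raise ValueError("susceptibility needs the system volume in meta")
    p2_si = (ELEMENTARY_CHARGE_C * 1e-10) ** 2  # (e*A)^2 -> (C m)^2
    v_si = meta.volume * 1e-30
    kt = BOLTZMANN_J_K * meta.temperature
    return p2_si * 1e-15 / (v_si * kt * VACUUM_PERMITTIVITY * n_dim)


def susceptibility(
    corr: CorrelationFunction,
    meta: TrajectoryMeta,
    n_dim: int = 3,
    subsystem: str = "total",
) -> Spectrum:
    """Absorption spectrum w*chi''(w) from a dipole autocorrelation.

    chi''(w) = (w/2) Re C+(w) / (V kB T eps0 D).  When the correlation
    object carries the periodogram of its source series, Re C+ is taken as
    half the periodogram (the exact discrete Wiener-Khinchin identity),
    which makes w*chi'' nonnegative at every grid point.  For analytic
    C(t) inputs a one-sided cosine transform of C is used instead.
    """
    pref = _si_prefactor(meta, n_dim)
    dt = corr.dt
    if corr.periodogram is not None and corr.n_samples is not None:
        re_cplus = 0.5 * corr.periodogram  # fs * (e A)^2
        n_grid = corr.n_samples
    else:
        c = corr.values
        # one-sided cosine transform on the FFT grid of length 2K.  The DTFT
        # of the sampled C aliases the spectral tails back into the band;
        # treating C(t) as piecewise linear between samples (a sinc^2 factor
        # on the DTFT) removes that bias to high accuracy.
        nfft = 2 * len(c)
        spec = np.fft.rfft(c, n=nfft).real - 0.5 * c[0]
        half = np.pi * np.arange(len(spec)) / nfft  # = omega*dt/2
        sinc2 = np.ones_like(half)
        nz = half > 0
        sinc2[nz] = (np.sin(half[nz]) / half[nz]) ** 2
        re_cplus = spec * dt * sinc2
        n_grid = nfft
    freqs = np.fft.rfftfreq(n_grid, d=dt)  # 1/fs
    wavenumbers = freqs / SPEED_OF_LIGHT_CM_FS
    omega_si = 2 * np.pi * freqs * 1e15  # rad/s
    chi2 = pref * (omega_si / 2.0) * re_cplus[: len(freqs)]
    values = omega_si * chi2
    keep = wavenumbers > 0
    return Spectrum(wavenumbers=wavenumbers[keep], values=values[keep],
                    subsystem=subsystem)


def current_from_dipole(series: DipoleSeries) -> DipoleSeries:
    """Current j = dp/dt by centered differences (endpoints dropped), e*A/fs."""
    p = series.vectors
    j = (p[2:] - p[:-2]) / (2 * series.dt)
    out = DipoleSeries(series.dt, j, subsystem=series.subsystem)
    out._centered_difference = True  # type: ignore[attr-defined]
    return out


def current_spectrum(
    j: DipoleSeries, meta: TrajectoryMeta, subsystem: str = "total"
) -> Spectrum:
    """Absorption spectrum from a current series via the w^-2 weighted route.

    The polarization periodogram is recovered as |j(w)|^2 / w^2; for
    currents built by :func:`current_from_dipole` the exact discrete
    derivative gain sin(w dt)/dt replaces w, so the two routes agree to
    machine precision for band-limited signals.  The w = 0 bin is excluded.
    """
    x = j.vectors - j.vectors.mean(axis=0)
    n = len(x)
    pgram_j = (np.abs(np.fft.rfft(x, axis=0)) ** 2).sum(axis=1) * j.dt / n
    freqs = np.fft.rfftfreq(n, d=j.dt)
    omega = 2 * np.pi * freqs  # rad/fs
    if getattr(j, "_centered_difference", False):
        gain = np.sin(omega * j.dt) / j.dt  # centered-difference response
    else:
        gain = omega
    keep = (freqs > 0) & (gain != 0)
    pgram_p = np.zeros_like(pgram_j)
    pgram_p[keep] = pgram_j[keep] / gain[keep] ** 2

    pref = _si_prefactor(meta, j.n_dim)
    omega_si = omega * 1e15
    chi2 = pref * (omega_si / 2.0) * 0.5 * pgram_p
    values = omega_si * chi2
    wavenumbers = freqs / SPEED_OF_LIGHT_CM_FS
    return Spectrum(wavenumbers=wavenumbers[keep], values=values[keep],
                    subsystem=subsystem)


def scalar_power_spectrum(
    x: np.ndarray,
    dt: float,
    meta: TrajectoryMeta,
    charge: float = 1.0,
    subsystem: str = "d",
) -> Spectrum:
    """Spectrum of a scalar coordinate carrying a bare charge (default 1 e).

    Treats p(t) = charge * x(t) as a one-component dipole (D = 1) and
    applies the polarization route.
    """
    series = DipoleSeries(dt=dt, vectors=charge * np.asarray(x, dtype=float),
                          subsystem=subsystem)
    corr = autocorrelation_wk(series)
    return susceptibility(corr, meta, n_dim=1, subsystem=subsystem)


# ---------------------------------------------------------------------------
# post-processing


def smooth_gaussian(spectrum: Spectrum, sigma_cm: float) -> Spectrum:
    """Gaussian smoothing on the wavenumber grid with edge renormalization."""
    if sigma_cm < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma_cm == 0:
        return replace(spectrum, sigma_cm=0.0)
    nu = spectrum.wavenumbers
    # kernel matrix would be O(N^2); use a truncated convolution instead
    step = np.diff(nu)
    if not np.allclose(step, step[0], rtol=1e-6):
        raise ValueError("smoothing requires a uniform wavenumber grid")
    h = step[0]
    half = int(np.ceil(8.5 * sigma_cm / h))
    kern = np.exp(-0.5 * ((np.arange(-half, half + 1) * h) / sigma_cm) ** 2)
    num = np.convolve(spectrum.values, kern, mode="same")
    den = np.convolve(np.ones_like(spectrum.values), kern, mode="same")
    return replace(spectrum, values=num / den, sigma_cm=sigma_cm)


def difference_spectrum(
    solution: Spectrum,
    water: Spectrum,
    c_w: float,
    c_w0: float,
    c_hcl: Optional[float] = None,
) -> Spectrum:
    """Concentration-normalized difference spectrum.

    w Dchi'' = w chi''_solution / c_w - w chi''_water / c_w0, optionally
    divided further by the HCl concentration.  The water spectrum is
    interpolated onto the solution grid if necessary.
    """
    if c_w <= 0 or c_w0 <= 0:
        raise ValueError("water concentrations must be positive")
    w_vals = water.interp(solution.wavenumbers)
    values = solution.values / c_w - w_vals / c_w0
    norm = "per_cw"
    if c_hcl is not None:
        if c_hcl <= 0:
            raise ValueError("c_hcl must be positive")
        values = values / c_hcl
        norm = "per_cw_per_chcl"
    return Spectrum(wavenumbers=solution.wavenumbers.copy(), values=values,
                    normalization=norm, subsystem=f"{solution.subsystem}-diff")


def subsystem_decomposition(
    total: DipoleSeries, part: DipoleSeries, meta: TrajectoryMeta
) -> tuple[Spectrum, Spectrum]:
    """Split a total spectrum into a part (with all cross terms) + remainder.

    The remainder spectrum is computed from the remainder autocorrelation
    alone; the part spectrum is total minus remainder, so every
    cross-correlation lands in the part -- the convention used for the
    chloride contribution.
    """
    if len(part) != len(total) or part.n_dim != total.n_dim:
        raise ValueError("part and total series must have matching shapes")
    remainder = total - part
    s_total = susceptibility(autocorrelation_wk(total), meta, total.n_dim,
                             subsystem=total.subsystem)
    s_rem = susceptibility(autocorrelation_wk(remainder), meta, total.n_dim,
                           subsystem="remainder")
    s_part = replace(s_total, values=s_total.values - s_rem.values,
                     subsystem=f"{part.subsystem}+cross")
    return s_part, s_rem
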