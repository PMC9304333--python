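"""2D free-energy landscape, quartic cuts, d*(R_OO) branch and transfer paths.

The landscape F(d, R_OO) = -ln P(d, R_OO) (in kB T, gauge min F = 0) is
built from excess-proton samples and symmetrized in d, reflecting the
physical midplane symmetry.  Fixed-R_OO cuts are fitted to the quartic

    F(d) = F_{d=0} (1 + g2 d^2 + g4 d^4),

whose double-well minima d* = sqrt(-g2 / (2 g4)) define the most likely
proton asymmetry.  d*^2 grows linearly with R_OO above the barrier onset
R0, so the branch d*(R_OO) is a parabola in the (d, R_OO) plane.

Transfer paths are the segments that actually cross the midplane: a
complete path runs from the last crossing of d* on one side to the first
crossing of -d* on the other, an incomplete path crosses d = 0 but returns
to the starting side's d*; both are extended to the nearest velocity
turning points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .tracking import ExcessProtonTrack


class FitError(RuntimeError):
    pass


class StatisticsError(RuntimeError):
    pass


@dataclass
class FreeEnergy2D:
    """Binned -ln P surface over (d, R_OO), symmetric in d, min F = 0."""

    d_edges: np.ndarray
    roo_edges: np.ndarray
    F: np.ndarray  # (n_d, n_roo), NaN where counts == 0, kB T
    counts: np.ndarray

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def roo_centers(self) -> np.ndarray:
        return 0.5 * (self.roo_edges[:-1] + self.roo_edges[1:])

    def cut(self, roo: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(d_centers, F, counts) of the cut nearest to the requested R_OO."""
        j = int(np.argmin(np.abs(self.roo_centers - roo)))
        return self.d_centers, self.F[:, j], self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        dd, rr = np.meshgrid(self.d_centers, self.roo_centers, indexing="ij")
        return pd.DataFrame(
            {"d_A": dd.ravel(), "Roo_A": rr.ravel(),
             "F_kBT": self.F.ravel(), "counts": self.counts.ravel()}
        )


@dataclass
class QuarticFit:
    """Quartic fit of one fixed-R_OO free-energy cut (absolute gauge)."""

    roo: float
    f_d0: float  # kB T at d = 0
    gamma2: float  # A^-2
    gamma4: float  # A^-4
    residual: float  # rms residual over the fitted bins, kB T

    @property
    def dstar(self) -> float:
        """Well position sqrt(-g2/(2 g4)); 0 for single-well cuts."""
        if self.gamma2 >= 0:
            return 0.0
        return math.sqrt(-self.gamma2 / (2 * self.gamma4))

    @property
    def relative_barrier(self) -> float:
        """F(0) - F(d*) = F_{d=0} g2^2 / (4 g4); 0 for single wells."""
        if self.gamma2 >= 0:
            return 0.0
        return self.f_d0 * self.gamma2 ** 2 / (4 * self.gamma4)

    def evaluate(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.f_d0 * (1 + self.gamma2 * d ** 2 + self.gamma4 * d ** 4)


@dataclass
class DstarBranch:
    """Parabolic most-likely-position branch: d*^2 = slope * (R_OO - R0)."""

    slope: float  # A (d*^2 per A of R_OO)
    onset: float  # R0, A
    roo_range: tuple[float, float]

    def dstar(self, roo: np.ndarray) -> np.ndarray:
        roo = np.asarray(roo, dtype=float)
        return np.sqrt(np.clip(self.slope * (roo - self.onset), 0.0, None))


@dataclass
class TransferPath:
    start: int  # frame index within the track (turning-point extended)
    end: int  # inclusive
    complete: bool
    duration: float  # fs
    crossing_roo: float  # R_OO at the (last) d = 0 crossing, A

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("path duration must be positive")


@dataclass
class ErlangFit:
    """Integer-shape Erlang fit of the transfer-path-time histogram.

    p(t) = t^(b-1)/(b-1)! * (b/tau)^b * exp(-b t / tau); the distribution
    mean equals tau for every shape b.
    """

    beta: int
    tau_tp: float  # fs
    amplitude: float
    fit_range: tuple[float, float]
    sse: float
    n_samples: int

    @property
    def tau_stderr(self) -> float:
        # variance of the Erlang is tau^2/beta; standard error of the mean
        return self.tau_tp / math.sqrt(self.beta * self.n_samples)


def erlang_pdf(t: np.ndarray, beta: int, tau: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    rate = beta / tau
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = ((beta - 1) * np.log(np.where(t > 0, t, 1.0))
                 + beta * np.log(rate) - rate * t - math.lgamma(beta))
    out = np.exp(log_p)
    out[t < 0] = 0.0
    out[t == 0] = 0.0 if beta > 1 else rate
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# landscape construction and fits


def free_energy_2d(
    tracks: Iterable[ExcessProtonTrack] | tuple[np.ndarray, np.ndarray],
    d_bin: float = 0.02,
    roo_bin: float = 0.02,
    d_max: float = 0.8,
    roo_range: Optional[tuple[float, float]] = None,
) -> FreeEnergy2D:
    """Histogram excess-proton samples into F = -ln(P/P_max).

    Accepts either a collection of tracks (chloride-flagged frames are
    excluded) or a raw ``(d, roo)`` pair of sample arrays.  Counts are
    symmetrized by averaging (d, R) with (-d, R) before taking the log;
    the bin grid is symmetric about d = 0 so the symmetry is exact.
    """
    if isinstance(tracks, tuple):
        d, roo = (np.asarray(a, dtype=float) for a in tracks)
    else:
        tr = list(tracks)
        if not tr:
            raise StatisticsError("no tracks supplied")
        d = np.concatenate([t.d[~t.chloride_flag] for t in tr])
        roo = np.concatenate([t.roo[~t.chloride_flag] for t in tr])
    if len(d) == 0:
        raise StatisticsError("no unflagged samples")

    n_half = int(np.ceil(d_max / d_bin))
    d_edges = np.arange(-n_half, n_half + 1) * d_bin
    if roo_range is None:
        roo_range = (roo.min() - roo_bin, roo.max() + roo_bin)
    lo = math.floor(roo_range[0] / roo_bin) * roo_bin
    roo_edges = np.arange(lo, roo_range[1] + roo_bin, roo_bin)

    counts, _, _ = np.histogram2d(d, roo, bins=(d_edges, roo_edges))
    counts = 0.5 * (counts + counts[::-1])  # midplane symmetrization
    with np.errstate(divide="ignore"):
        F = -np.log(counts / counts.max())
    F[counts == 0] = np.nan
    return FreeEnergy2D(d_edges=d_edges, roo_edges=roo_edges, F=F, counts=counts)


def fit_quartic_cut(
    d_centers: np.ndarray,
    f_row: np.ndarray,
    counts_row: Optional[np.ndarray] = None,
    roo: float = float("nan"),
    d_fit_max: float = 0.45,
    min_counts: float = 0.0,
) -> QuarticFit:
    """Weighted least-squares quartic fit of one free-energy cut.

    The model F(d) = a + b d^2 + c d^4 is linear in (a, b, c); the quartic
    parameters follow as F_{d=0} = a, g2 = b/a, g4 = c/a.  Bins are
    weighted by their counts (Poisson errors of -ln P scale as
    1/sqrt(counts)).
    """
    d = np.asarray(d_centers, dtype=float)
    f = np.asarray(f_row, dtype=float)
    w = np.ones_like(f) if counts_row is None else np.asarray(counts_row, float)
    sel = np.isfinite(f) & (np.abs(d) <= d_fit_max) & (w > min_counts)
    if sel.sum() < 5 or d[sel].min() >= 0 or d[sel].max() <= 0:
        raise FitError("cut needs >= 5 populated bins spanning d = 0")
    basis = np.stack([np.ones(sel.sum()), d[sel] ** 2, d[sel] ** 4], axis=1)
    sw = np.sqrt(w[sel])
    coef, *_ = np.linalg.lstsq(basis * sw[:, None], f[sel] * sw, rcond=None)
    a, b, c = coef
    if c <= 0:
        raise FitError(f"non-confining quartic coefficient g4 = {c / a:.3g}")
    if a <= 0:
        raise FitError("nonpositive free energy at d = 0 in absolute gauge")
    resid = float(np.sqrt(np.mean((basis @ coef - f[sel]) ** 2)))
    return QuarticFit(roo=float(roo), f_d0=float(a), gamma2=float(b / a),
                      gamma4=float(c / a), residual=resid)


def fit_all_cuts(
    surface: FreeEnergy2D,
    min_counts: float = 200.0,
    d_fit_max: float = 0.45,
) -> list[QuarticFit]:
    """Quartic fits of every sufficiently populated R_OO cut."""
    fits = []
    for j, roo in enumerate(surface.roo_centers):
        if surface.counts[:, j].sum() < min_counts:
            continue
        try:
            fits.append(
                fit_quartic_cut(
                    surface.d_centers, surface.F[:, j], surface.counts[:, j],
                    roo=roo, d_fit_max=d_fit_max,
                )
            )
        except FitError:
            continue
    return fits


def dstar_branch(fits: Sequence[QuarticFit]) -> DstarBranch:
    """Fit the parabola d*^2 = slope (R_OO - R0) through double-well cuts."""
    pts = [(f.roo, f.dstar ** 2) for f in fits if f.gamma2 < 0]
    if len(pts) < 3:
        raise FitError("need at least 3 double-well cuts for the d* branch")
    r = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(r, y, 1)
    if slope <= 0:
        raise FitError("d* branch slope is not positive")
    return DstarBranch(slope=float(slope), onset=float(-intercept / slope),
                       roo_range=(float(r.min()), float(r.max())))


@dataclass
class BarrierProfiles:
    """Absolute d = 0 free energy and relative barrier height vs R_OO."""

    roo: np.ndarray
    absolute_f_d0: np.ndarray  # kB T
    relative_barrier: np.ndarray  # kB T
    transition_state_roo: float  # argmin of the absolute profile, A
    transition_state_f: float  # kB T


def barrier_profiles(fits: Sequence[QuarticFit]) -> BarrierProfiles:
    """Barrier curves and the transition state from the quartic fits.

    The transition state is the R_OO minimizing the absolute free energy at
    d = 0; its location is refined by a local parabola through the three
    cuts around the discrete minimum.
    """
    if not fits:
        raise StatisticsError("no quartic fits available")
    roo = np.array([f.roo for f in fits])
    order = np.argsort(roo)
    roo = roo[order]
    f_abs = np.array([f.f_d0 for f in fits])[order]
    f_rel = np.array([f.relative_barrier for f in fits])[order]
    k = int(np.argmin(f_abs))
    if 0 < k < len(roo) - 1:
        coef = np.polyfit(roo[k - 1:k + 2], f_abs[k - 1:k + 2], 2)
        ts_roo = float(-coef[1] / (2 * coef[0])) if coef[0] > 0 else float(roo[k])
        ts_f = float(np.polyval(coef, ts_roo)) if coef[0] > 0 else float(f_abs[k])
    else:
        ts_roo, ts_f = float(roo[k]), float(f_abs[k])
    return BarrierProfiles(roo=roo, absolute_f_d0=f_abs, relative_barrier=f_rel,
                           transition_state_roo=ts_roo, transition_state_f=ts_f)


# ---------------------------------------------------------------------------
# transfer-path segmentation


def _filled_signs(y: np.ndarray) -> np.ndarray:
    """Sign of y with exact zeros inheriting the previous frame's sign."""
    s = np.sign(y)
    for k in np.flatnonzero(s == 0):
        s[k] = s[k - 1] if k > 0 else 0
    return s


def segment_paths(
    track: ExcessProtonTrack, branch: DstarBranch | float
) -> list[TransferPath]:
    """Segment a track into complete and incomplete transfer paths.

    Implemented as a single forward scan over midplane crossings; each
    emitted path consumes its frames, so paths are disjoint in time.
    ``branch`` may be a fitted :class:`DstarBranch` or a constant d* level.
    ``crossing_roo`` is recorded at the decisive (last) d = 0 crossing of
    the path with linear interpolation between frames; durations are
    integer multiples of dt, as warranted by histogram resolution.
    """
    d = track.d
    roo = track.roo
    n = len(d)
    if n < 3:
        return []
    if isinstance(branch, DstarBranch):
        dstar = branch.dstar(roo)
    else:
        dstar = np.full(n, float(branch))
    v = np.diff(d)  # discrete velocity (length n-1)
    s = _filled_signs(d)

    paths: list[TransferPath] = []
    ptr = 0
    while ptr < n - 1:
        # next midplane crossing at or after ptr (between k0 and k0+1)
        flips = np.flatnonzero(s[ptr:-1] * s[ptr + 1:] < 0)
        if len(flips) == 0:
            break
        k0 = ptr + int(flips[0])
        side = s[k0]
        if side == 0:
            ptr = k0 + 1
            continue
        # start: last frame at or beyond the origin-side d* before the crossing
        beyond = np.flatnonzero(d[ptr:k0 + 1] * side >= dstar[ptr:k0 + 1])
        if len(beyond) == 0:
            ptr = k0 + 1  # crossing without a preceding d* excursion
            continue
        start = ptr + int(beyond[-1])
        # forward: first frame at or beyond either d* branch after the crossing
        end: Optional[int] = None
        complete = False
        last_cross = k0
        for j in range(k0 + 1, n):
            if d[j] * side <= -dstar[j]:
                end, complete = j, True
                break
            if d[j] * side >= dstar[j]:
                end, complete = j, False
                break
            if j < n - 1 and s[j] * s[j + 1] < 0:
                last_cross = j
        if end is None:
            break  # track ends mid-attempt; discard the unfinished path

        # turning-point extension: walk outward until the discrete velocity
        # changes sign (boundary placed at the turning frame)
        s0 = start
        v_in = v[start] if start < n - 1 else v[start - 1]
        while s0 > ptr and v[s0 - 1] * v_in > 0:
            s0 -= 1
        e0 = end
        v_out = v[end - 1]
        while e0 < n - 1 and v[e0] * v_out > 0:
            e0 += 1

        # R_OO at the decisive midplane crossing, linearly interpolated
        k = last_cross
        denom = d[k + 1] - d[k]
        frac = 0.0 if denom == 0 else -d[k] / denom
        cross_roo = float(roo[k] + frac * (roo[k + 1] - roo[k]))

        duration = (e0 - s0) * track.dt
        if duration > 0:
            paths.append(TransferPath(start=s0, end=e0, complete=complete,
                                      duration=duration, crossing_roo=cross_roo))
        ptr = max(e0 + 1, k0 + 1)  # paths stay disjoint in time
    return paths


def path_mask(track: ExcessProtonTrack, paths: Sequence[TransferPath]) -> np.ndarray:
    """Boolean mask of frames lying inside any transfer path."""
    mask = np.zeros(len(track), dtype=bool)
    for p in paths:
        mask[p.start:p.end + 1] = True
    return mask


def erlang_fit(
    durations: Sequence[float],
    beta_max: int = 10,
    n_bins: int = 60,
    fit_range: Optional[tuple[float, float]] = None,
    min_samples: int = 50,
) -> ErlangFit:
    """Fit the main peak of a duration histogram to the Erlang distribution.

    The integer shape is scanned exhaustively; for each shape the mean time
    and amplitude are least-squares fitted to the histogram density over
    ``fit_range`` (default [0, 3 * median], excluding the long tail).
    """
    t = np.asarray(durations, dtype=float)
    if len(t) < min_samples:
        raise StatisticsError(f"need >= {min_samples} durations, got {len(t)}")
    if fit_range is None:
        fit_range = (0.0, 3.0 * float(np.median(t)))
    hist, edges = np.histogram(t, bins=n_bins, range=fit_range, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    best: Optional[ErlangFit] = None
    tau0 = float(np.mean(t[(t >= fit_range[0]) & (t <= fit_range[1])]))
    for beta in range(1, beta_max + 1):
        def model(tt, tau, amp, _b=beta):
            return amp * erlang_pdf(tt, _b, tau)
        try:
            popt, _ = optimize.curve_fit(
                model, centers, hist, p0=[tau0, 1.0],
                bounds=([1e-6, 1e-6], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(centers, *popt) - hist) ** 2))
        cand = ErlangFit(beta=beta, tau_tp=float(popt[0]), amplitude=float(popt[1]),
                         fit_range=fit_range, sse=sse, n_samples=len(t))
        if best is None or sse < best.sse:
            best = cand
    if best is None:
        raise FitError("Erlang fit failed for every shape")
    return best


def transition_state_distribution(
    paths: Sequence[TransferPath],
    threshold: float = 2.39,
    bins: int = 40,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of crossing R_OO of complete paths + fraction above onset.

    Returns ``(edges, counts, fraction_above_threshold)``.
    """
    complete = [p.crossing_roo for p in paths if p.complete]
    if not complete:
        raise StatisticsError("no complete transfer paths")
    r = np.asarray(complete)
    counts, edges = np.histogram(r, bins=bins)
    return edges, counts, float(np.mean(r > threshold))
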