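"""High-level modelling interface: fit the transfer-kinetics analysis chain.

``ProtonTransferModel`` wraps one or more excess-proton coordinate tracks
(from ab initio MD via the tracker, or from the Langevin surrogate) and
``fit()`` runs the full chain -- free-energy landscape, quartic cuts,
d*(R_OO) branch, barrier profiles, transfer-path segmentation, Erlang
fits, first-passage waiting times, trajectory/spectral decomposition and
time-scale extraction -- returning a ``ProtonTransferResults`` object that
carries the estimates with their uncertainties and renders a summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import transfer_path_wavenumber, wavenumber_from_time
from .decomposition import (
    DecomposedTrack,
    TimescaleSummary,
    WaitingTimeAnalysis,
    decompose_track,
    extract_timescales,
    spectral_decomposition,
    waiting_time_analysis,
)
from .free_energy import (
    BarrierProfiles,
    DstarBranch,
    ErlangFit,
    FreeEnergy2D,
    QuarticFit,
    StatisticsError,
    TransferPath,
    barrier_profiles,
    dstar_branch,
    erlang_fit,
    fit_all_cuts,
    free_energy_2d,
    segment_paths,
    transition_state_distribution,
)
from .spectra import Spectrum, scalar_power_spectrum, smooth_gaussian
from .tracking import ExcessProtonTrack
from .traj_io import Trajectory, TrajectoryMeta


@dataclass
class ModelConfig:
    """Analysis knobs with the package defaults."""

    d_bin: float = 0.02  # A
    roo_bin: float = 0.02  # A
    d_fit_max: float = 0.45  # A, quartic fit range
    min_cut_counts: float = 200.0
    nm_band_cm: tuple[float, float] = (2000.0, 3000.0)
    onset_threshold: float = 2.39  # A, crossing-distribution threshold
    smoothing_sigma_cm: float = 50.0  # excess-proton spectra
    proton_charge: float = 1.0  # e


class ProtonTransferModel:
    """Proton-transfer kinetics model over (d, R_OO) coordinate tracks.

    Parameters
    ----------
    tracks:
        One or more :class:`ExcessProtonTrack` (surrogate tracks are
        adapted automatically by :meth:`from_surrogate`).
    meta:
        Thermodynamic metadata (temperature, volume) for the spectral
        normalization.
    config:
        Analysis configuration; defaults follow the package conventions.
    """

    def __init__(
        self,
        tracks: Sequence[ExcessProtonTrack],
        meta: Optional[TrajectoryMeta] = None,
        config: Optional[ModelConfig] = None,
    ) -> None:
        if not tracks:
            raise StatisticsError("model needs at least one track")
        self.tracks = list(tracks)
        self.meta = meta or TrajectoryMeta(volume=20.0 ** 3)
        self.config = config or ModelConfig()

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_trajectory(
        cls, traj: Trajectory, config: Optional[ModelConfig] = None
    ) -> "ProtonTransferModel":
        """Run the excess-proton tracker on an atomistic trajectory."""
        from .tracking import extract_excess_tracks, flag_chloride_coordination

        tracks = extract_excess_tracks(traj)
        tracks = [flag_chloride_coordination(t, traj) for t in tracks]
        if not tracks:
            raise StatisticsError("no transferring excess protons found")
        meta = traj.meta
        if meta.volume is None:
            meta.volume = traj.frames[0].cell_edge ** 3
        return cls(tracks, meta=meta, config=config)

    @classmethod
    def from_surrogate(
        cls, synthetic, config: Optional[ModelConfig] = None
    ) -> "ProtonTransferModel":
        """Wrap a Langevin surrogate run as a single coordinate track."""
        track = ExcessProtonTrack(
            proton_index=0, first_frame=0, dt=synthetic.dt,
            d=synthetic.d, roo=synthetic.roo,
            flanking_oxygens=np.zeros((len(synthetic.d), 2), dtype=int),
        )
        meta = TrajectoryMeta(temperature=synthetic.config.temperature,
                              volume=20.0 ** 3)
        return cls([track], meta=meta, config=config)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        dt: Optional[float] = None,
        meta: Optional[TrajectoryMeta] = None,
        config: Optional[ModelConfig] = None,
    ) -> "ProtonTransferModel":
        """Build from a track table (columns d_A, Roo_A, proton_idx, ...)."""
        tracks = []
        if dt is None:
            t = table["time_fs"].to_numpy()
            f = table["frame"].to_numpy()
            sel = f[1:] != f[:-1]
            dt = float(np.min(np.abs(np.diff(t)[sel]))) if sel.any() else 0.5
        for proton, grp in table.groupby("proton_idx", sort=True):
            grp = grp.sort_values("frame")
            tracks.append(
                ExcessProtonTrack(
                    proton_index=int(proton),
                    first_frame=int(grp["frame"].iloc[0]),
                    dt=dt,
                    d=grp["d_A"].to_numpy(),
                    roo=grp["Roo_A"].to_numpy(),
                    flanking_oxygens=np.stack(
                        [grp["O1_idx"].to_numpy(), grp["O2_idx"].to_numpy()], axis=1
                    ) if "O1_idx" in grp else np.zeros((len(grp), 2), dtype=int),
                    chloride_flag=grp["cl_flag"].to_numpy().astype(bool)
                    if "cl_flag" in grp else None,
                )
            )
        return cls(tracks, meta=meta, config=config)

    # -- estimation ------------------------------------------------------
    def fit(self) -> "ProtonTransferResults":
        """Run the full analysis chain and collect the results."""
        cfg = self.config
        surface = free_energy_2d(self.tracks, d_bin=cfg.d_bin, roo_bin=cfg.roo_bin)
        fits = fit_all_cuts(surface, min_counts=cfg.min_cut_counts,
                            d_fit_max=cfg.d_fit_max)
        if not fits:
            raise StatisticsError("free-energy stage: no fittable R_OO cuts")
        branch = dstar_branch(fits)
        barriers = barrier_profiles(fits)

        all_paths: list[list[TransferPath]] = []
        complete_durations: list[float] = []
        incomplete_durations: list[float] = []
        for tr in self.tracks:
            paths = segment_paths(tr, branch)
            all_paths.append(paths)
            complete_durations += [p.duration for p in paths if p.complete]
            incomplete_durations += [p.duration for p in paths if not p.complete]
        if not complete_durations:
            raise StatisticsError("path stage: no complete transfer paths")

        def _try_erlang(durs: list[float]) -> Optional[ErlangFit]:
            try:
                return erlang_fit(durs)
            except StatisticsError:
                return None

        erl_c = _try_erlang(complete_durations)
        erl_i = _try_erlang(incomplete_durations)

        flat_paths = [p for ps in all_paths for p in ps]
        edges, counts, frac_above = transition_state_distribution(
            flat_paths, threshold=cfg.onset_threshold
        )

        # waiting times pooled over tracks
        intervals = []
        for tr in self.tracks:
            try:
                intervals.append(waiting_time_analysis(tr, branch).intervals)
            except StatisticsError:
                continue
        if not intervals:
            raise StatisticsError("waiting stage: no completed passages")
        pooled = np.concatenate(intervals)
        from .decomposition import exponentiality_pvalue

        tau = float(pooled.mean())
        waiting = WaitingTimeAnalysis(
            intervals=pooled, tau_tw=tau,
            stderr=float(pooled.std(ddof=1) / np.sqrt(len(pooled))),
            cv=float(pooled.std(ddof=1) / tau),
            ks_pvalue=exponentiality_pvalue(pooled),
        )

        # spectra: longest track carries the spectral estimates
        main_idx = int(np.argmax([len(t) for t in self.tracks]))
        main = self.tracks[main_idx]
        decomposed = decompose_track(main, branch, all_paths[main_idx])
        comp_spectra = spectral_decomposition(main, decomposed, self.meta,
                                              charge=cfg.proton_charge)
        roo_spec = scalar_power_spectrum(main.roo - main.roo.mean(), main.dt,
                                         self.meta, charge=1.0, subsystem="Roo")
        timescales = extract_timescales(
            roo_spectrum=smooth_gaussian(roo_spec, cfg.smoothing_sigma_cm),
            erlang_complete=erl_c,
            erlang_incomplete=erl_i,
            waiting=waiting,
            nm_band_cm=cfg.nm_band_cm,
        )
        return ProtonTransferResults(
            model=self, surface=surface, quartic_fits=fits, branch=branch,
            barriers=barriers, paths=all_paths, erlang_complete=erl_c,
            erlang_incomplete=erl_i, crossing_edges=edges,
            crossing_counts=counts, fraction_above_onset=frac_above,
            waiting=waiting, decomposed=decomposed, spectra=comp_spectra,
            roo_spectrum=roo_spec, timescales=timescales,
        )


@dataclass
class ProtonTransferResults:
    """Fitted landscape, kinetics and spectra of a proton-transfer model."""

    model: ProtonTransferModel
    surface: FreeEnergy2D
    quartic_fits: list[QuarticFit]
    branch: DstarBranch
    barriers: BarrierProfiles
    paths: list[list[TransferPath]]
    erlang_complete: Optional[ErlangFit]
    erlang_incomplete: Optional[ErlangFit]
    crossing_edges: np.ndarray
    crossing_counts: np.ndarray
    fraction_above_onset: float
    waiting: WaitingTimeAnalysis
    decomposed: DecomposedTrack
    spectra: dict[str, Spectrum]
    roo_spectrum: Spectrum
    timescales: TimescaleSummary
    _cache: dict = field(default_factory=dict, repr=False)

    # -- headline numbers ------------------------------------------------
    @property
    def barrier_onset(self) -> float:
        """R_OO where the d barrier vanishes (A)."""
        return self.branch.onset

    @property
    def transition_state_roo(self) -> float:
        return self.barriers.transition_state_roo

    @property
    def min_absolute_barrier(self) -> float:
        return self.barriers.transition_state_f

    def dstar_at(self, roo: float) -> float:
        return float(self.branch.dstar(np.array([roo]))[0])

    @property
    def global_minimum(self) -> tuple[float, float]:
        """(|d|, R_OO) of the lowest free-energy bin."""
        fe = self.surface
        i, j = np.unravel_index(np.nanargmin(fe.F), fe.F.shape)
        return abs(float(fe.d_centers[i])), float(fe.roo_centers[j])

    def absolute_barrier_at(self, roo: float) -> float:
        """Absolute d = 0 free energy of the cut nearest to roo (kB T)."""
        k = int(np.argmin(np.abs(self.barriers.roo - roo)))
        return float(self.barriers.absolute_f_d0[k])

    def n_paths(self, complete: Optional[bool] = None) -> int:
        flat = [p for ps in self.paths for p in ps]
        if complete is None:
            return len(flat)
        return sum(1 for p in flat if p.complete == complete)

    def predicted_tp_wavenumbers(self) -> dict[str, float]:
        """Transfer-path band positions 1/(2 c tau_TP) from the Erlang fits."""
        out = {}
        if self.erlang_complete is not None:
            out["complete"] = transfer_path_wavenumber(self.erlang_complete.tau_tp)
        if self.erlang_incomplete is not None:
            out["incomplete"] = transfer_path_wavenumber(self.erlang_incomplete.tau_tp)
        return out

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary table of the fitted quantities."""
        ts = self.timescales
        lines = [
            "Proton-transfer kinetics summary",
            "=" * 48,
            f"tracks analyzed        : {len(self.model.tracks)}",
            f"frames (total)         : {sum(len(t) for t in self.model.tracks)}",
            f"transfer paths         : {self.n_paths(True)} complete / "
            f"{self.n_paths(False)} incomplete",
            "-" * 48,
            "free-energy landscape (kB T, A)",
            f"  barrier onset R0     : {self.barrier_onset:8.3f}",
            f"  transition state Roo : {self.transition_state_roo:8.3f}",
            f"  min absolute barrier : {self.min_absolute_barrier:8.3f}",
            f"  lowest-F bin (d, R)  : ({self.global_minimum[0]:.2f}, "
            f"{self.global_minimum[1]:.2f})",
            f"  d* at Roo = 2.51 A   : {self.dstar_at(2.51):8.3f}",
            "-" * 48,
            "time scales (fs)",
        ]
        if ts.tau_tw is not None:
            lines.append(f"  tau_TW               : {ts.tau_tw:8.1f}"
                         f" +- {ts.tau_tw_stderr:.1f}")
        if ts.tau_roo is not None:
            lines.append(f"  tau_Roo              : {ts.tau_roo:8.1f}")
        if ts.tau_tp_complete is not None:
            lines.append(f"  tau_TP (complete)    : {ts.tau_tp_complete:8.1f}"
                         f" +- {ts.tau_tp_complete_stderr:.1f}")
        if ts.tau_tp_incomplete is not None:
            lines.append(f"  tau_TP (incomplete)  : {ts.tau_tp_incomplete:8.1f}"
                         f" +- {ts.tau_tp_incomplete_stderr:.1f}")
        if ts.tau_nm_range is not None:
            lines.append(f"  tau_NM range         : {ts.tau_nm_range[0]:.0f}"
                         f" - {ts.tau_nm_range[1]:.0f}")
        preds = self.predicted_tp_wavenumbers()
        if preds:
            lines.append("-" * 48)
            for key, nu in preds.items():
                lines.append(f"  f_TP ({key:<10})    : {nu:8.0f} cm^-1")
        lines.append(f"  crossings above R0   : {100 * self.fraction_above_onset:.0f}%")
        return "\n".join(lines)

    def plot_landscape(self, ax=None):
        """Free-energy surface with the fitted d*(R_OO) branch overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fe = self.surface
        mesh = ax.pcolormesh(fe.d_centers, fe.roo_centers, fe.F.T,
                             shading="auto", cmap="viridis")
        rr = np.linspace(self.branch.onset, fe.roo_edges[-1], 100)
        ds = self.branch.dstar(rr)
        ax.plot(ds, rr, "k--", lw=1)
        ax.plot(-ds, rr, "k--", lw=1)
        ax.set_xlabel("d (A)")
        ax.set_ylabel("R_OO (A)")
        plt.colorbar(mesh, ax=ax, label="F (kB T)")
        return ax

    def plot_spectra(self, sigma_cm: float = 50.0, ax=None):
        """Total and component spectra on a log-frequency axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for key, color in [("total", "k"), ("TW", "tab:blue"),
                           ("TP", "tab:red"), ("NM", "tab:green")]:
            s = smooth_gaussian(self.spectra[key], sigma_cm)
            ax.plot(s.wavenumbers, s.values, color=color, label=key)
        ax.set_xscale("log")
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel(r"$\omega\chi''$")
        ax.legend()
        return ax

    def timescale_table(self) -> pd.DataFrame:
        d = self.timescales.as_dict()
        d.pop("missing", None)
        return pd.DataFrame({"quantity": list(d.keys()), "value": list(d.values())})
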