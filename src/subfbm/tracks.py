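"""Trajectory-table I/O, observation-time windowing, and synthetic
single-particle-tracking fixtures.

File dialect: header-bearing CSV with columns ``track_id, frame, t, x[, y]``;
frames are 0-based consecutive integers, times in seconds (``t = frame*dt``),
positions in micrometers.  Each spatial coordinate is analyzed as an
independent 1-D realization of the subordinated process.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import Ensemble, FbmParams, WaitingTimeModel, simulate_ensemble

logger = logging.getLogger(__name__)

__all__ = ["TrackTable", "read_tracks", "write_tracks", "window_tracks",
           "make_fixture"]

_REQUIRED = ("track_id", "frame", "t", "x")


@dataclass
class TrackTable:
    """Validated table of uniformly sampled tracks.

    ``df`` holds rows (track_id, frame, t, x[, y]); ``dt`` is the shared
    sampling interval; ``diagnostics`` records per-track rejections.
    """

    df: pd.DataFrame
    dt: float
    diagnostics: list[str] = field(default_factory=list)

    @property
    def has_y(self) -> bool:
        return "y" in self.df.columns

    @property
    def track_ids(self) -> list:
        return list(self.df["track_id"].unique())

    @property
    def n_tracks(self) -> int:
        return int(self.df["track_id"].nunique())

    def track_lengths(self) -> pd.Series:
        return self.df.groupby("track_id", sort=False).size()


def read_tracks(path, dialect: dict | None = None,
                delimiter: str = ",") -> TrackTable:
    """Read and validate a track table from delimited text.

    ``dialect`` optionally maps the standard column names to the file's own
    headers, e.g. ``{"track_id": "traj", "x": "x_um"}``.  Tracks with skipped
    frames or non-uniform sampling are rejected individually, with a
    diagnostic per rejected track; mixed sampling intervals across tracks are
    an error.
    """
    raw = pd.read_csv(path, sep=delimiter)
    rename = {}
    if dialect:
        rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    cols = list(_REQUIRED) + (["y"] if "y" in raw.columns else [])
    raw = raw[cols]
    kept = []
    diagnostics: list[str] = []
    dts: list[float] = []
    for tid, grp in raw.groupby("track_id", sort=False):
        frames = grp["frame"].to_numpy()
        times = grp["t"].to_numpy(dtype=float)
        if frames.size < 2:
            diagnostics.append(f"track {tid!r}: fewer than 2 localizations")
            continue
        steps = np.diff(frames)
        if np.any(steps != 1):
            diagnostics.append(f"track {tid!r}: skipped or repeated frames")
            continue
        dt_track = float(np.median(np.diff(times)))
        if dt_track <= 0 or not np.allclose(np.diff(times), dt_track,
                                            rtol=1e-6, atol=1e-9):
            diagnostics.append(f"track {tid!r}: non-uniform sampling")
            continue
        kept.append(grp)
        dts.append(dt_track)
    if not kept:
        raise ValueError("no valid tracks in file; "
                         + "; ".join(diagnostics[:5]))
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-6):
        raise ValueError("mixed sampling intervals across tracks")
    for msg in diagnostics:
        logger.warning("rejected %s", msg)
    df = pd.concat(kept, ignore_index=True)
    return TrackTable(df=df, dt=dt, diagnostics=diagnostics)


def write_tracks(table: TrackTable, path) -> None:
    """Write a track table as CSV in the package dialect."""
    table.df.to_csv(path, index=False)


def window_tracks(table: TrackTable, tm_list) -> dict[float, Ensemble]:
    """Window every track to each observation time in ``tm_list``.

    Windows are prefixes (the first ``t_m/dt + 1`` localizations), because
    aging statistics are anchored to the time the process started; each
    spatial coordinate becomes an independent 1-D trajectory, referenced to
    its initial position.
    """
    dt = table.dt
    lengths = table.track_lengths()
    out: dict[float, Ensemble] = {}
    coords = ["x", "y"] if table.has_y else ["x"]
    for t_m in np.atleast_1d(np.asarray(tm_list, dtype=float)):
        n_pts = int(round(t_m / dt)) + 1
        if abs((n_pts - 1) * dt - t_m) > 1e-9:
            raise ValueError(f"t_m={t_m} is not a multiple of dt={dt}")
        if n_pts < 3:
            raise ValueError(f"t_m={t_m} gives a window of {n_pts} points")
        if n_pts > int(lengths.min()):
            raise ValueError(
                f"t_m={t_m} needs {n_pts} points but the shortest track has "
                f"{int(lengths.min())}")
        rows = []
        for _, grp in table.df.groupby("track_id", sort=False):
            for coord in coords:
                vals = grp[coord].to_numpy(dtype=float)[:n_pts]
                rows.append(vals - vals[0])
        out[float(t_m)] = Ensemble(
            positions=np.stack(rows), dt=dt, t_m=(n_pts - 1) * dt,
            meta={"coords": coords, "n_tracks": table.n_tracks,
                  "windowing": "prefix"})
    return out


def make_fixture(alpha: float, hurst: float, n_tracks: int = 87,
                 n_points: int = 256, dt: float = 0.05,
                 dx: float = 0.1, t0: float | None = None,
                 loc_noise_sd: float = 0.02, seed=None,
                 two_d: bool = True) -> TrackTable:
    """Generate a synthetic SPT table with subordinated-fBM statistics.

    Emulates membrane-protein tracking data: ``n_tracks`` subordinated-fBM
    tracks of ``n_points`` localizations at spacing ``dt`` (seconds), step
    amplitude ``dx`` (micrometers), waiting-time cutoff ``t0`` (default: one
    frame), plus i.i.d. zero-mean Gaussian localization noise of standard
    deviation ``loc_noise_sd`` (micrometers) on every localization — the
    noise produces the white high-frequency floor seen in experimental
    spectra.  Fully reproducible by ``seed``.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    if loc_noise_sd < 0:
        raise ValueError("loc_noise_sd must be >= 0")
    if t0 is None:
        t0 = dt
    wt = WaitingTimeModel(alpha=alpha, t0=t0)
    fp = FbmParams(hurst=hurst, dx=dx)
    t_m = (n_points - 1) * dt
    ss = np.random.SeedSequence(seed)
    coord_seeds = ss.spawn(3)  # x-ensemble, y-ensemble, noise
    coords = ["x", "y"] if two_d else ["x"]
    ensembles = {
        coord: simulate_ensemble(wt, fp, t_m=t_m, dt=dt, n_real=n_tracks,
                                 seed=coord_seeds[i])
        for i, coord in enumerate(coords)
    }
    noise_rng = np.random.default_rng(coord_seeds[2])
    frames = np.tile(np.arange(n_points), n_tracks)
    data = {
        "track_id": np.repeat(np.arange(n_tracks), n_points),
        "frame": frames,
        "t": frames * dt,
    }
    for coord in coords:
        pos = ensembles[coord].positions.copy()
        if loc_noise_sd > 0:
            pos += noise_rng.normal(0.0, loc_noise_sd, size=pos.shape)
        data[coord] = pos.reshape(-1)
    df = pd.DataFrame(data)
    return TrackTable(df=df, dt=float(dt))
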