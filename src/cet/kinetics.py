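"""In-vivo convergence kinetics from nuclear tracks.

Convergence is quantified as signed mediolateral (ML) displacement: per
track step, ``s = |x_t - midline| - |x_{t+1} - midline|``, so movement
toward the dorsal midline is positive regardless of side.  The per-frame
mean over cells is smoothed with a sliding window (default four frames) and
the onset of convergence is called as the breakpoint of a two-segment
continuous piecewise-linear (hinge) fit, accepted only when the hinge beats
a single line by an F test and the post-break slope exceeds the pre-break
slope.

Filtering follows the imaging analysis: observations within 100 um of the
midline are removed (convergence is reduced there), and only tracks with at
least three consecutive frames (15 min at 5-min framing) contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

TRACK_COLUMNS = ("track_id", "frame", "t_hpf", "x", "y")


@dataclass
class TrackTable:
    """Per-cell positions over frames, with acquisition metadata.

    ``data`` columns: track_id, frame (int), t_hpf, x (um), y (um).
    """

    data: pd.DataFrame
    frame_interval_min: float = 5.0
    midline_x: float = 0.0

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        d = self.data
        if len(d):
            if not np.isfinite(d[["x", "y", "t_hpf"]].to_numpy()).all():
                raise ValueError("non-finite coordinates in track table")
            dup = d.duplicated(["track_id", "frame"])
            if dup.any():
                tid = d.loc[dup.idxmax(), "track_id"]
                raise ValueError(f"duplicated (track, frame) row in track {tid!r}")
            self.data = d.sort_values(["track_id", "frame"]).reset_index(drop=True)

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def tracks(self):
        """Iterate (track_id, per-track DataFrame) in frame order."""
        yield from self.data.groupby("track_id", sort=True)


@dataclass
class FilterReport:
    n_obs_in: int
    n_obs_midline_removed: int
    n_tracks_in: int
    n_tracks_too_short: int
    n_tracks_out: int


@dataclass
class OnsetResult:
    onset_hpf: Optional[float]
    f_stat: float
    p_value: float
    pre_slope: float
    post_slope: float
    sse_line: float
    sse_hinge: float

    @property
    def detected(self) -> bool:
        return self.onset_hpf is not None


@dataclass
class KineticsSummary:
    curve: pd.DataFrame              # frame, t_hpf, mean, se, n per frame
    smoothed: np.ndarray             # sliding-window mean of `mean`
    cumulative: np.ndarray           # running sum of per-frame means (um)
    onset: OnsetResult
    per_track: pd.DataFrame          # track_id, persistence, straight-line speed, mean step speed
    filter_report: FilterReport


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _consecutive_runs(frames: np.ndarray) -> list[np.ndarray]:
    """Split sorted frame indices into maximal consecutive runs (as index arrays)."""
    if frames.size == 0:
        return []
    breaks = np.where(np.diff(frames) != 1)[0] + 1
    return np.split(np.arange(frames.size), breaks)


def filter_tracks(
    table: TrackTable,
    min_frames: int = 3,
    exclusion_radius_um: float = 100.0,
    midline_mode: str = "per_observation",
) -> tuple[TrackTable, FilterReport]:
    """Apply midline-exclusion and minimum-duration rules.

    ``per_observation`` (default) removes individual observations with
    ``|x - midline| <= exclusion_radius_um`` and then keeps only maximal
    runs of >= ``min_frames`` consecutive frames; ``per_track`` drops whole
    tracks that ever enter the exclusion band.
    """
    d = table.data
    n_obs_in = len(d)
    n_tracks_in = table.n_tracks
    near = np.abs(d["x"].to_numpy() - table.midline_x) <= exclusion_radius_um

    if midline_mode == "per_observation":
        kept = d[~near]
        removed_mid = int(near.sum())
    elif midline_mode == "per_track":
        bad_tracks = set(d.loc[near, "track_id"].unique())
        kept = d[~d["track_id"].isin(bad_tracks)]
        removed_mid = n_obs_in - len(kept)
    else:
        raise ValueError(f"unknown midline_mode {midline_mode!r}")

    parts = []
    n_short = 0
    for tid, g in kept.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        runs = _consecutive_runs(g["frame"].to_numpy())
        long_runs = [r for r in runs if r.size >= min_frames]
        if not long_runs:
            n_short += 1
            continue
        for k, r in enumerate(long_runs):
            seg = g.iloc[r].copy()
            if len(long_runs) > 1:
                seg["track_id"] = f"{tid}/{k}"
            parts.append(seg)

    out = pd.concat(parts, ignore_index=True) if parts else d.iloc[0:0].copy()
    report = FilterReport(
        n_obs_in=n_obs_in,
        n_obs_midline_removed=removed_mid,
        n_tracks_in=n_tracks_in,
        n_tracks_too_short=n_short,
        n_tracks_out=pd.unique(out["track_id"]).size if len(out) else 0,
    )
    if len(out) == 0:
        import warnings

        warnings.warn("no tracks survive filtering", stacklevel=2)
    return TrackTable(out, table.frame_interval_min, table.midline_x), report


# ---------------------------------------------------------------------------
# ML displacement curve
# ---------------------------------------------------------------------------


def ml_displacement_curve(table: TrackTable) -> pd.DataFrame:
    """Per-frame mean signed ML displacement (um/frame), with SE and n.

    Each within-track step between consecutive frames contributes
    ``|x_t - midline| - |x_{t+1} - midline|`` (positive toward the midline)
    at the step's later frame.  Frames with no cells are absent from the
    output (missing).
    """
    recs = []
    m = table.midline_x
    for _, g in table.tracks():
        fr = g["frame"].to_numpy()
        x = g["x"].to_numpy()
        t = g["t_hpf"].to_numpy()
        consec = np.diff(fr) == 1
        dist = np.abs(x - m)
        s = dist[:-1] - dist[1:]
        recs.append(pd.DataFrame({
            "frame": fr[1:][consec], "t_hpf": t[1:][consec], "s": s[consec]}))
    if not recs:
        return pd.DataFrame(columns=["frame", "t_hpf", "mean", "se", "n"])
    steps = pd.concat(recs, ignore_index=True)
    out = steps.groupby("frame").agg(
        t_hpf=("t_hpf", "first"),
        mean=("s", "mean"),
        se=("s", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
        n=("s", "size"),
    ).reset_index()
    return out


def smooth_curve(values: np.ndarray, window: int = 4, align: str = "trailing") -> np.ndarray:
    """Sliding-window mean, NaN-aware, with shrinking edge windows.

    ``trailing`` (default): out[i] = mean(values[i-window+1 : i+1]);
    ``centered``: symmetric window of the same width.  Window 1 is the
    identity; missing values are omitted per-window (all-missing -> NaN).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for i in range(len(v)):
        if align == "trailing":
            lo, hi = max(0, i - window + 1), i + 1
        elif align == "centered":
            half = (window - 1) / 2.0
            lo, hi = max(0, int(np.ceil(i - half))), min(len(v), int(np.floor(i + half)) + 1)
        else:
            raise ValueError(f"unknown align {align!r}")
        w = v[lo:hi]
        w = w[np.isfinite(w)]
        out[i] = w.mean() if w.size else np.nan
    return out


# ---------------------------------------------------------------------------
# Onset changepoint
# ---------------------------------------------------------------------------


def convergence_onset(
    curve: np.ndarray, t_grid: np.ndarray, alpha: float = 0.05, min_segment: int = 3
) -> OnsetResult:
    """Hinge-changepoint onset of a rising curve.

    Fits a continuous two-segment piecewise-linear model over a breakpoint
    grid at frame resolution and compares the best hinge with a single
    straight line by an F test (2 extra parameters: second slope and
    breakpoint).  The onset is the SSE-minimizing breakpoint, reported only
    when p < alpha and the post-break slope exceeds the pre-break slope.
    """
    y = np.asarray(curve, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    if not ok.any():
        raise ValueError("curve is all-missing")
    y, t = y[ok], t[ok]
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 finite frames for onset calling, got {n}")

    # single line
    X1 = np.column_stack([np.ones(n), t])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse_line = float(np.sum((X1 @ beta1 - y) ** 2))
    scale = float(np.sum((y - y.mean()) ** 2))
    if sse_line <= 1e-12 * max(scale, np.finfo(float).tiny):
        # a single line already fits to numerical precision: no breakpoint
        return OnsetResult(None, 0.0, 1.0, float(beta1[1]), float(beta1[1]),
                           sse_line, sse_line)

    best = None
    for b in t[min_segment: n - min_segment]:
        X = np.column_stack([np.ones(n), np.minimum(t - b, 0.0), np.maximum(t - b, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ beta - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(b), float(beta[1]), float(beta[2]))
    sse_hinge, bp, pre, post = best
    sse_hinge = min(sse_hinge, sse_line)

    df_den = n - 4
    if sse_hinge <= 0:
        f = np.inf if sse_line > sse_hinge else 0.0
    else:
        f = ((sse_line - sse_hinge) / 2.0) / (sse_hinge / df_den)
    p = float(stats.f.sf(f, 2, df_den)) if np.isfinite(f) else 0.0
    onset = bp if (p < alpha and post > pre) else None
    return OnsetResult(onset, float(f), p, pre, post, sse_line, sse_hinge)


# ---------------------------------------------------------------------------
# Per-track statistics
# ---------------------------------------------------------------------------


def track_persistence(track: pd.DataFrame) -> float:
    """Straightness of a track: net displacement / total path length, in [0, 1].

    A stationary track (zero path length) is defined as 0.
    """
    xy = track[["x", "y"]].to_numpy(dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("persistence needs >= 2 observations")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = steps.sum()
    if path == 0:
        return 0.0
    return float(np.linalg.norm(xy[-1] - xy[0]) / path)


def track_speeds(track: pd.DataFrame, frame_interval_min: float = 5.0) -> tuple[float, np.ndarray]:
    """Straight-line speed and per-step instantaneous velocities (um/min).

    Straight-line speed: net displacement over total tracking time.
    Instantaneous velocity: step length / frame interval, per step.
    """
    xy = track[["x", "y"]].to_numpy(dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("speed needs >= 2 observations")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    total_min = (xy.shape[0] - 1) * frame_interval_min
    straight = float(np.linalg.norm(xy[-1] - xy[0]) / total_min)
    inst = steps / frame_interval_min
    return straight, inst


# ---------------------------------------------------------------------------
# Pipeline summary
# ---------------------------------------------------------------------------


def summarize_kinetics(
    table: TrackTable,
    min_frames: int = 3,
    exclusion_radius_um: float = 100.0,
    window: int = 4,
    alpha: float = 0.05,
) -> KineticsSummary:
    """Filter tracks and compute the full convergence-kinetics summary.

    The hinge onset is called on the cumulative mean ML displacement (the
    running sum of the per-frame means): convergence turns that curve from
    flat to rising, which is exactly the hinge alternative the changepoint
    model tests.
    """
    filtered, report = filter_tracks(table, min_frames, exclusion_radius_um)
    curve = ml_displacement_curve(filtered)
    if curve.empty:
        raise ValueError("no displacement steps after filtering")
    smoothed = smooth_curve(curve["mean"].to_numpy(), window=window)
    means = np.nan_to_num(curve["mean"].to_numpy(), nan=0.0)
    cumulative = np.cumsum(means)
    onset = convergence_onset(cumulative, curve["t_hpf"].to_numpy(), alpha=alpha)

    rows = []
    for tid, g in filtered.tracks():
        if len(g) < 2:
            continue
        straight, inst = track_speeds(g, filtered.frame_interval_min)
        rows.append({
            "track_id": tid,
            "persistence": track_persistence(g),
            "straight_line_speed_um_min": straight,
            "mean_instantaneous_velocity_um_min": float(inst.mean()),
        })
    per_track = pd.DataFrame(rows, columns=[
        "track_id", "persistence", "straight_line_speed_um_min",
        "mean_instantaneous_velocity_um_min"])
    return KineticsSummary(curve, smoothed, cumulative, onset, per_track, report)
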