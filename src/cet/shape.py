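"""Explant shape dynamics: roundness, Boltzmann fits, F tests, onset calling.

Roundness is the moments-based shape descriptor ``4*Area / (pi * Major^2)``,
where Major is the major-axis length of the ellipse with the same second
central moments as the region: 1 for a circle, decreasing as the explant
elongates.  Roundness-over-time curves are fitted with the decreasing
Boltzmann sigmoid

    r(t) = Bottom + (Top - Bottom) / (1 + exp((t - V50) / slope))

(slope > 0 means roundness decreases over time; V50 is the time of half the
total roundness change).  Groups of curves are compared by the extra
sum-of-squares F test between a fit with parameters shared across groups and
one in which they vary per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from skimage import measure

PARAM_NAMES = ("bottom", "top", "v50", "slope")


@dataclass
class ShapeSeries:
    """Roundness over time for a single explant."""

    explant_id: str
    group: str
    t_hpf: np.ndarray
    roundness: np.ndarray
    source: str = "direct"

    def __post_init__(self) -> None:
        self.t_hpf = np.asarray(self.t_hpf, dtype=float)
        self.roundness = np.asarray(self.roundness, dtype=float)
        if self.t_hpf.shape != self.roundness.shape:
            raise ValueError("t_hpf and roundness must have equal length")
        if np.any(np.diff(self.t_hpf) <= 0):
            raise ValueError("t_hpf must be strictly increasing")
        finite = np.isfinite(self.roundness)
        if np.any((self.roundness[finite] <= 0) | (self.roundness[finite] > 1)):
            raise ValueError("roundness must lie in (0, 1] (or be NaN for missing)")

    def interpolate_gaps(self, max_gap: int = 2) -> "ShapeSeries":
        """Linearly fill runs of <= max_gap missing frames; longer runs stay NaN."""
        r = self.roundness.copy()
        isnan = ~np.isfinite(r)
        if not isnan.any():
            return self
        i = 0
        n = len(r)
        while i < n:
            if isnan[i]:
                j = i
                while j < n and isnan[j]:
                    j += 1
                if 0 < i and j < n and (j - i) <= max_gap:
                    r[i:j] = np.interp(self.t_hpf[i:j], [self.t_hpf[i - 1], self.t_hpf[j]], [r[i - 1], r[j]])
                i = j
            else:
                i += 1
        return ShapeSeries(self.explant_id, self.group, self.t_hpf, r, self.source)


@dataclass
class SigmoidFit:
    bottom: float
    top: float
    v50: float
    slope: float
    sse: float
    df: int
    converged: bool
    n_points: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.bottom, self.top, self.v50, self.slope])

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _boltzmann(np.asarray(t, float), *self.params)


@dataclass
class FTestResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    sse_pooled: float
    sse_separate: float
    pooled_fit: dict
    separate_fits: dict


@dataclass
class MorphometryResult:
    midline_length: float
    width: float

    @property
    def ratio(self) -> float:
        return self.midline_length / self.width


# ---------------------------------------------------------------------------
# Roundness from masks
# ---------------------------------------------------------------------------


def roundness_from_mask(mask: np.ndarray, label: int | None = None, min_area: int = 50) -> float:
    """Roundness 4A/(pi*Major^2) of a labeled region in a mask image.

    ``mask`` may be binary or a label image; with multiple labels present a
    ``label`` id must be given.  Regions smaller than ``min_area`` pixels are
    rejected as segmentation noise.
    """
    mask = np.asarray(mask)
    labels = np.unique(mask[mask > 0])
    if labels.size == 0:
        raise ValueError("mask contains no foreground region")
    if label is None:
        if labels.size > 1:
            raise ValueError(f"mask has {labels.size} labels; specify which (ids {labels.tolist()})")
        label = int(labels[0])
    region = (mask == label)
    area = int(region.sum())
    if area == 0:
        raise ValueError(f"label {label} not present in mask")
    if area < min_area:
        raise ValueError(f"region of label {label} has area {area} < min_area {min_area}")
    props = measure.regionprops(region.astype(np.uint8))[0]
    major = props.axis_major_length
    if major <= 0:
        raise ValueError("degenerate region: zero major axis")
    r = 4.0 * area / (np.pi * major**2)
    return float(min(r, 1.0))


def roundness_from_polygon(xy: np.ndarray) -> float:
    """Roundness of a polygon via its exact area and second central moments."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 3:
        raise ValueError("polygon needs >= 3 vertices")
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("degenerate polygon: zero area")
    sgn = np.sign(area)
    area = abs(area)
    cx = ((x + x1) * cross).sum() / (6 * sgn * area)
    cy = ((y + y1) * cross).sum() / (6 * sgn * area)
    xs, ys = x - cx, y - cy
    xs1, ys1 = np.roll(xs, -1), np.roll(ys, -1)
    c = xs * ys1 - xs1 * ys
    ixx = (c * (ys**2 + ys * ys1 + ys1**2)).sum() / (12 * sgn * area)
    iyy = (c * (xs**2 + xs * xs1 + xs1**2)).sum() / (12 * sgn * area)
    ixy = (c * (xs * ys1 + 2 * xs * ys + 2 * xs1 * ys1 + xs1 * ys)).sum() / (24 * sgn * area)
    cov = np.array([[iyy, ixy], [ixy, ixx]])
    lam = np.linalg.eigvalsh(cov)
    major = 4.0 * np.sqrt(max(lam[-1], 0.0))
    if major <= 0:
        raise ValueError("degenerate polygon: zero major axis")
    return float(min(4.0 * area / (np.pi * major**2), 1.0))


# ---------------------------------------------------------------------------
# Inclusion rule
# ---------------------------------------------------------------------------


@dataclass
class InclusionDecision:
    include: bool
    reason: str
    min_roundness: float | None = None


def include_explant(
    series: ShapeSeries, cutoff_roundness: float = 0.5, cutoff_time_hpf: float = 12.0
) -> InclusionDecision:
    """Keep only explants whose roundness drops below the cutoff in time.

    An explant is included iff its minimum roundness over frames at or
    before ``cutoff_time_hpf`` is below ``cutoff_roundness``; explants that
    never elongate (e.g. uninjected controls near roundness 1) are excluded
    so that timing comparisons are not confounded by failed morphogenesis.
    """
    in_window = series.t_hpf <= cutoff_time_hpf
    vals = series.roundness[in_window]
    vals = vals[np.isfinite(vals)]
    if series.t_hpf[-1] < cutoff_time_hpf:
        warnings.warn(
            f"series {series.explant_id} ends at {series.t_hpf[-1]:.2f} hpf, "
            f"before the {cutoff_time_hpf} hpf cutoff", stacklevel=2,
        )
        if vals.size == 0 or vals.min() >= cutoff_roundness:
            return InclusionDecision(False, "indeterminate: series ends before cutoff time",
                                     float(vals.min()) if vals.size else None)
    if vals.size == 0:
        return InclusionDecision(False, "no finite roundness values in window", None)
    mn = float(vals.min())
    if mn < cutoff_roundness:
        return InclusionDecision(True, "reached cutoff roundness in time", mn)
    return InclusionDecision(False, f"min roundness {mn:.3f} >= cutoff {cutoff_roundness}", mn)


# ---------------------------------------------------------------------------
# Boltzmann fitting
# ---------------------------------------------------------------------------


def _boltzmann(t, bottom, top, v50, slope):
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + np.exp((t - v50) / slope))


def _collect_points(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, ShapeSeries):
        series = [series]
    ts, rs = [], []
    for s in series:
        s = s.interpolate_gaps()
        ok = np.isfinite(s.roundness)
        ts.append(s.t_hpf[ok])
        rs.append(s.roundness[ok])
    return np.concatenate(ts), np.concatenate(rs)


def _initial_params(t: np.ndarray, r: np.ndarray) -> np.ndarray:
    top, bottom = float(r.max()), float(r.min())
    mid = (top + bottom) / 2.0
    v50 = float(t[np.argmin(np.abs(r - mid))])
    slope = max((t.max() - t.min()) / 10.0, 1e-3)
    return np.array([bottom, top, v50, slope])


def fit_boltzmann(
    series, min_range: float = 0.05, n_restarts: int = 5, seed: int = 0
) -> SigmoidFit:
    """Least-squares Boltzmann fit to one series or a pooled group of series.

    Initialization: Top = max r, Bottom = min r, V50 = time of the value
    closest to midrange, slope = time range / 10, plus ``n_restarts``
    multiplicatively jittered restarts; the best SSE wins.
    """
    t, r = _collect_points(series)
    if t.size < 6:
        raise ValueError(f"need >= 6 points to fit, got {t.size}")
    if r.max() - r.min() < min_range:
        raise ValueError(
            f"flat series: dynamic range {r.max() - r.min():.4f} < {min_range}")
    p0 = _initial_params(t, r)
    rng = np.random.default_rng(seed)
    starts = [p0]
    for _ in range(n_restarts):
        jit = p0 * rng.uniform(0.8, 1.2, size=4)
        jit[3] = max(jit[3], 1e-3)
        starts.append(jit)

    def resid(p):
        return _boltzmann(t, *p) - r

    best = None
    for s0 in starts:
        try:
            sol = optimize.least_squares(
                resid, s0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=5000,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0] - 1e-10 * max(best[0], 1.0):
            best = (sse, sol)
    if best is None:
        raise RuntimeError("Boltzmann fit failed from every start")
    sse, sol = best
    b, tp, v, sl = sol.x
    if sl < 0:  # equivalent curve with slope > 0 and asymptotes swapped
        b, tp, sl = tp, b, -sl
    converged = bool(sol.success) and tp > b
    return SigmoidFit(float(b), float(tp), float(v), float(sl), sse,
                      df=t.size - 4, converged=converged, n_points=t.size)


# ---------------------------------------------------------------------------
# Extra sum-of-squares F test
# ---------------------------------------------------------------------------


def _fit_shared(groups: dict, share: set[str], seed: int = 0, singles: dict | None = None) -> tuple[float, dict]:
    """Fit all groups jointly with the `share` parameters common.

    Returns total SSE and per-group parameter dicts.  Parameter vector is
    [shared...] + per-group [free...] in group order.
    """
    names = list(PARAM_NAMES)
    shared_idx = [i for i, nm in enumerate(names) if nm in share]
    free_idx = [i for i, nm in enumerate(names) if nm not in share]
    labels = list(groups)
    pts = {g: _collect_points(groups[g]) for g in labels}

    # starts from per-group single fits
    if singles is None:
        singles = {g: fit_boltzmann(groups[g], seed=seed) for g in labels}
    p0 = np.empty(len(shared_idx) + len(free_idx) * len(labels))
    for k, i in enumerate(shared_idx):
        p0[k] = np.mean([singles[g].params[i] for g in labels])
    off = len(shared_idx)
    for gi, g in enumerate(labels):
        for k, i in enumerate(free_idx):
            p0[off + gi * len(free_idx) + k] = singles[g].params[i]

    def unpack(p):
        out = {}
        for gi, g in enumerate(labels):
            q = np.empty(4)
            for k, i in enumerate(shared_idx):
                q[i] = p[k]
            for k, i in enumerate(free_idx):
                q[i] = p[off + gi * len(free_idx) + k]
            out[g] = q
        return out

    def resid(p):
        qs = unpack(p)
        return np.concatenate([
            _boltzmann(pts[g][0], *qs[g]) - pts[g][1] for g in labels
        ])

    sol = optimize.least_squares(resid, p0, method="lm", xtol=1e-15, ftol=1e-15,
                                 gtol=1e-15, max_nfev=20000)
    sse = float(np.sum(sol.fun**2))
    qs = unpack(sol.x)
    return sse, {g: dict(zip(names, map(float, qs[g]))) for g in labels}


def compare_fits_f_test(
    groups: dict, parameters_to_share=frozenset(PARAM_NAMES), seed: int = 0
) -> FTestResult:
    """Extra sum-of-squares F test between shared- and free-parameter fits.

    ``groups`` maps label -> ShapeSeries or list of ShapeSeries (residuals
    pooled across a group's explants).  The pooled (null) model shares
    ``parameters_to_share`` across groups; the separate (alternative) model
    fits every parameter per group.  F = ((SSE0-SSE1)/(df0-df1)) /
    (SSE1/df1) with p from the F(df0-df1, df1) distribution.
    """
    share = set(parameters_to_share)
    bad = share - set(PARAM_NAMES)
    if bad:
        raise ValueError(f"unknown parameters to share: {sorted(bad)}")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if not share:
        raise ValueError("parameters_to_share must be non-empty")

    sep_fits = {}
    for g, series in groups.items():
        try:
            sep_fits[g] = fit_boltzmann(series, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"separate fit failed for group {g!r}: {exc}") from exc
    sse_sep = sum(f.sse for f in sep_fits.values())
    n_total = sum(f.n_points for f in sep_fits.values())
    df_sep = n_total - 4 * len(groups)

    sse_pool, pool_params = _fit_shared(groups, share, seed=seed, singles=sep_fits)
    df_pool = n_total - (len(share) + (4 - len(share)) * len(groups))
    # the nested (shared) model can never beat the free model; clip numeric jitter
    sse_pool = max(sse_pool, sse_sep)

    df_num = df_pool - df_sep
    f_stat = ((sse_pool - sse_sep) / df_num) / (sse_sep / df_sep)
    p = float(stats.f.sf(f_stat, df_num, df_sep))
    return FTestResult(float(f_stat), df_num, df_sep, p, sse_pool, sse_sep,
                       pooled_fit=pool_params,
                       separate_fits={g: dict(zip(PARAM_NAMES, map(float, f.params)))
                                      for g, f in sep_fits.items()})


# ---------------------------------------------------------------------------
# Extension onset & morphometry
# ---------------------------------------------------------------------------


def extension_onset_from_series(
    series: ShapeSeries, drop_fraction: float = 0.05, sustain_frames: int = 3,
    plateau_frames: int = 6,
) -> float | None:
    """Automated extension-onset call by sustained drop below the plateau.

    Onset is the first time roundness falls below (1 - drop_fraction) times
    the mean of the first ``plateau_frames`` frames and stays below for
    ``sustain_frames`` consecutive frames; None if that never happens.
    """
    r = series.roundness
    if len(r) < plateau_frames:
        raise ValueError(f"series shorter than plateau window ({plateau_frames} frames)")
    plateau = np.nanmean(r[:plateau_frames])
    thresh = plateau * (1.0 - drop_fraction)
    below = r < thresh
    for i in range(len(r) - sustain_frames + 1):
        if below[i: i + sustain_frames].all():
            return float(series.t_hpf[i])
    return None


def length_width_ratio(midline: np.ndarray, width_segment: np.ndarray) -> MorphometryResult:
    """Curvature-aware length/width ratio of an explant.

    ``midline`` is a polyline of >= 2 points traced along the explant's long
    axis; ``width_segment`` is the point pair spanning the maximal width
    perpendicular to it.  The ratio is polyline arc length / segment length.
    """
    midline = np.asarray(midline, dtype=float)
    width_segment = np.asarray(width_segment, dtype=float)
    if midline.ndim != 2 or midline.shape[0] < 2:
        raise ValueError("midline must be a polyline of >= 2 points")
    if width_segment.shape != (2, 2):
        raise ValueError("width_segment must be a pair of 2D points")
    length = float(np.sum(np.linalg.norm(np.diff(midline, axis=0), axis=1)))
    width = float(np.linalg.norm(width_segment[1] - width_segment[0]))
    if width == 0:
        raise ValueError("zero-length width segment")
    return MorphometryResult(length, width)
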