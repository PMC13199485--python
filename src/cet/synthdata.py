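"""Synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the pipeline's real inputs with known ground truth:

- :func:`gen_expression_panel` — seven-stage TPM trajectories with planted
  trigger genes (flat before gastrulation onset, sharply elevated from the
  trigger stage onward) among a mixture of confounder patterns, with
  lognormal multiplicative replicate noise.
- :func:`gen_tracks` — nuclear tracks performing an unbiased random walk
  before a planted convergence onset and gaining a constant mediolateral
  bias toward the dorsal midline afterwards.
- :func:`gen_shape_series` — explant roundness decaying along a Boltzmann
  sigmoid, optionally with matching elliptical label masks whose analytic
  roundness equals the series value frame by frame.

Randomness: one master seed per spec; every entity (gene, cell, explant)
draws from its own substream ``default_rng(SeedSequence(seed, spawn_key=(k,)))``
with a documented counter ``k``, so outputs are bit-identical for a fixed
seed regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DEFAULT_STAGE_GRID, ExpressionPanel
from .kinetics import TrackTable
from .shape import ShapeSeries


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Substream `stream` of master `seed` (counter-keyed SeedSequence)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Expression panels
# ---------------------------------------------------------------------------

#: Mixture over non-trigger temporal patterns: flat, monotone-decreasing,
#: late-rising (after the trigger stage).  The decreasing and late classes
#: exercise the screen's pre-window and trigger-stage criteria respectively.
DEFAULT_PATTERN_MIX = {"flat": 0.7, "decreasing": 0.15, "late": 0.15}


@dataclass
class SimExpressionSpec:
    """Design of a synthetic stage-resolved expression experiment.

    ``trigger_effect`` is the fold elevation planted from ``trigger_stage``
    onward (dimensionless, > 1).  ``baseline_log_mean``/``baseline_log_sd``
    parameterize the lognormal distribution of per-gene baseline TPM.
    ``noise_cv`` is the per-replicate coefficient of variation of the
    mean-preserving lognormal noise.
    """

    n_genes: int = 100
    stage_grid: tuple[tuple[str, float], ...] = DEFAULT_STAGE_GRID
    conditions: tuple[str, ...] = ("uninjected", "acvr1b", "ndr2", "embryo")
    planted_triggers: frozenset[int] = frozenset()
    trigger_stage: str = "shield"
    trigger_effect: float = 3.0
    baseline_log_mean: float = 3.5
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.2
    n_replicates: int = 3
    pattern_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    decay_per_stage: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        hpf = [h for _, h in self.stage_grid]
        if any(b <= a for a, b in zip(hpf, hpf[1:])):
            raise ValueError("stage_grid must be strictly increasing in hpf")
        names = [s for s, _ in self.stage_grid]
        if self.trigger_stage not in names:
            raise ValueError(f"trigger_stage {self.trigger_stage!r} not in stage_grid")
        if not all(0 <= i < self.n_genes for i in self.planted_triggers):
            raise ValueError("planted_triggers must be valid gene indices")
        if self.trigger_effect <= 1:
            raise ValueError("trigger_effect must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def gen_expression_panel(spec: SimExpressionSpec) -> ExpressionPanel:
    """Generate a replicate-aware TPM panel with planted trigger genes.

    Planted genes are flat (within noise) at all stages before the trigger
    stage and elevated by ``trigger_effect`` from it onward, in every
    condition.  Non-planted genes follow the ``pattern_mix`` mixture of
    flat, monotone-decreasing (factor ``decay_per_stage`` per stage), and
    late-rising (elevation starting one stage after the trigger) shapes.
    """
    stages = [s for s, _ in spec.stage_grid]
    stage_hpf = dict(spec.stage_grid)
    trig_idx = stages.index(spec.trigger_stage)
    n_stage = len(stages)

    mix_names = list(spec.pattern_mix)
    mix_p = np.array([spec.pattern_mix[k] for k in mix_names], dtype=float)
    mix_p = mix_p / mix_p.sum()

    rows: list[pd.DataFrame] = []
    for g in range(spec.n_genes):
        rng = _rng(spec.seed, g)
        base = float(rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd))
        if g in spec.planted_triggers:
            shape = np.ones(n_stage)
            shape[trig_idx:] = spec.trigger_effect
        else:
            pattern = rng.choice(mix_names, p=mix_p)
            shape = np.ones(n_stage)
            if pattern == "decreasing":
                shape = spec.decay_per_stage ** np.arange(n_stage)
            elif pattern == "late" and trig_idx + 1 < n_stage:
                shape[trig_idx + 1:] = spec.trigger_effect
        mean = base * shape
        noise = _noise_factors(
            rng, spec.noise_cv, (len(spec.conditions), n_stage, spec.n_replicates)
        )
        tpm = mean[None, :, None] * noise
        idx = pd.MultiIndex.from_product(
            [spec.conditions, stages, range(spec.n_replicates)],
            names=["condition", "stage", "replicate"],
        )
        df = pd.DataFrame({"tpm": tpm.ravel()}, index=idx).reset_index()
        df.insert(0, "gene", f"gene{g:05d}")
        rows.append(df)

    if rows:
        data = pd.concat(rows, ignore_index=True)
    else:
        data = pd.DataFrame(
            {"gene": pd.Series(dtype=str), "stage": pd.Series(dtype=str),
             "condition": pd.Series(dtype=str), "replicate": pd.Series(dtype=int),
             "tpm": pd.Series(dtype=float)}
        )
    return ExpressionPanel(data, stage_hpf, list(spec.conditions))


def planted_gene_ids(spec: SimExpressionSpec) -> set[str]:
    """Gene identifiers of the planted trigger genes."""
    return {f"gene{g:05d}" for g in spec.planted_triggers}


# ---------------------------------------------------------------------------
# Nuclear tracks
# ---------------------------------------------------------------------------


@dataclass
class SimTrackSpec:
    """Design of a synthetic nuclear-tracking movie.

    Cells random-walk isotropically (``diffusion_sd`` um per frame) and,
    from ``onset_hpf`` on, gain a constant bias of ``convergence_speed`` um
    per frame toward ``midline_x``.  Initial x positions are uniform over
    the field excluding a ``dead_zone_um`` band around the midline; walks
    reflect at the field edges.
    """

    n_cells: int = 200
    frame_interval_min: float = 5.0
    t_start_hpf: float = 6.5
    t_end_hpf: float = 10.5
    onset_hpf: float = 8.0
    convergence_speed: float = 1.0
    diffusion_sd: float = 1.0
    midline_x: float = 0.0
    field_half_width: float = 400.0
    dead_zone_um: float = 120.0
    field_height: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_start_hpf < self.onset_hpf < self.t_end_hpf):
            raise ValueError("onset_hpf must lie strictly inside [t_start_hpf, t_end_hpf]")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.diffusion_sd < 0:
            raise ValueError("diffusion_sd must be >= 0")
        if not (0 <= self.dead_zone_um < self.field_half_width):
            raise ValueError("dead_zone_um must be in [0, field_half_width)")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def gen_tracks(spec: SimTrackSpec) -> TrackTable:
    """Simulate biased-random-walk nuclear tracks with a planted onset."""
    n_frames = int(round((spec.t_end_hpf - spec.t_start_hpf) * 60 / spec.frame_interval_min)) + 1
    t_hpf = spec.t_start_hpf + np.arange(n_frames) * spec.frame_interval_min / 60.0
    lo = spec.midline_x - spec.field_half_width
    hi = spec.midline_x + spec.field_half_width

    frames = np.arange(n_frames)
    recs = []
    for c in range(spec.n_cells):
        rng = _rng(spec.seed, c)
        # uniform over the field minus the midline dead zone, symmetric sides
        side = 1 if rng.random() < 0.5 else -1
        off = rng.uniform(spec.dead_zone_um, spec.field_half_width)
        x = np.empty(n_frames)
        y = np.empty(n_frames)
        x[0] = spec.midline_x + side * off
        y[0] = rng.uniform(0.0, spec.field_height)
        steps = rng.normal(0.0, spec.diffusion_sd, size=(n_frames - 1, 2)) if spec.diffusion_sd > 0 else np.zeros((n_frames - 1, 2))
        for i in range(n_frames - 1):
            dx, dy = steps[i]
            if t_hpf[i] >= spec.onset_hpf:
                dx += spec.convergence_speed * np.sign(spec.midline_x - x[i])
            nx, ny = x[i] + dx, y[i] + dy
            # reflect only out-of-bounds moves so in-bounds steps stay exact
            if nx < lo or nx > hi:
                nx = _reflect(np.array([nx]), lo, hi)[0]
            if ny < 0.0 or ny > spec.field_height:
                ny = _reflect(np.array([ny]), 0.0, spec.field_height)[0]
            x[i + 1], y[i + 1] = nx, ny
        recs.append(pd.DataFrame({"track_id": c, "frame": frames, "t_hpf": t_hpf, "x": x, "y": y}))

    data = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame(
        columns=["track_id", "frame", "t_hpf", "x", "y"]
    )
    return TrackTable(data, frame_interval_min=spec.frame_interval_min, midline_x=spec.midline_x)


# ---------------------------------------------------------------------------
# Explant shape series
# ---------------------------------------------------------------------------


@dataclass
class SimShapeSpec:
    """Design of synthetic explant roundness decay series.

    The noiseless series follows the decreasing Boltzmann sigmoid
    ``r(t) = bottom + (top - bottom) / (1 + exp((t - v50_hpf) / slope))``
    with ``slope > 0``; additive Gaussian noise of SD ``noise_sd`` is
    clipped back into (0, 1].
    """

    n_explants: int = 10
    bottom: float = 0.3
    top: float = 0.95
    v50_hpf: float = 9.0
    slope: float = 0.5
    noise_sd: float = 0.02
    t_start_hpf: float = 6.0
    t_end_hpf: float = 12.0
    frame_interval_min: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.bottom < self.top <= 1):
            raise ValueError("need 0 < bottom < top <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")


def boltzmann(t: np.ndarray, bottom: float, top: float, v50: float, slope: float) -> np.ndarray:
    """Decreasing Boltzmann sigmoid; at ``t = v50`` equals ``(top+bottom)/2``."""
    return bottom + (top - bottom) / (1.0 + np.exp((np.asarray(t, float) - v50) / slope))


def gen_shape_series(spec: SimShapeSpec, group: str = "sim") -> list[ShapeSeries]:
    """Generate per-explant roundness time series along a Boltzmann decay."""
    n_frames = int(round((spec.t_end_hpf - spec.t_start_hpf) * 60 / spec.frame_interval_min)) + 1
    t = spec.t_start_hpf + np.arange(n_frames) * spec.frame_interval_min / 60.0
    clean = boltzmann(t, spec.bottom, spec.top, spec.v50_hpf, spec.slope)
    out = []
    for e in range(spec.n_explants):
        rng = _rng(spec.seed, e)
        noise = rng.normal(0.0, spec.noise_sd, size=n_frames) if spec.noise_sd > 0 else 0.0
        r = np.clip(clean + noise, np.finfo(float).tiny, 1.0)
        out.append(ShapeSeries(explant_id=f"explant{e:03d}", group=group, t_hpf=t.copy(), roundness=r))
    return out


def ellipse_mask_for_roundness(
    roundness: float, area_px: float = 20000.0, pad: int = 8
) -> np.ndarray:
    """Binary ellipse mask whose analytic roundness equals ``roundness``.

    For an ellipse with semi-axes a >= b, roundness 4*Area/(pi*Major^2)
    = 4(pi a b)/(pi (2a)^2) = b/a, so axes are chosen with b/a = roundness
    at the requested area.  A roundness of 0.5 therefore yields a major
    axis exactly twice the minor axis.
    """
    if not (0 < roundness <= 1):
        raise ValueError("roundness must be in (0, 1]")
    # area = pi*a*b with b = roundness*a  ->  a = sqrt(area/(pi*roundness))
    a = float(np.sqrt(area_px / (np.pi * roundness)))
    b = roundness * a
    h = int(np.ceil(2 * b)) + 2 * pad
    w = int(np.ceil(2 * a)) + 2 * pad
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((xx - cx) ** 2 / a**2 + (yy - cy) ** 2 / b**2) <= 1.0


def gen_shape_masks(spec: SimShapeSpec, explant: int = 0, area_px: float = 20000.0) -> list[np.ndarray]:
    """Per-frame elliptical masks matching one generated roundness series."""
    series = gen_shape_series(spec)[explant]
    return [ellipse_mask_for_roundness(float(r), area_px=area_px) for r in series.roundness]
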