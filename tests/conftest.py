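import numpy as np
import pandas as pd
import pytest

from cet.panel import DEFAULT_STAGE_GRID, ExpressionPanel
from cet.shape import ShapeSeries

STAGES = [s for s, _ in DEFAULT_STAGE_GRID]


def make_single_gene_series(tpm_by_stage, n_replicates=1):
    """Replicate-level gene series DataFrame for classify_trigger_pattern."""
    rows = []
    for s, v in zip(STAGES, tpm_by_stage):
        for r in range(n_replicates):
            rows.append({"gene": "g", "stage": s, "condition": "c",
                         "replicate": r, "tpm": float(v)})
    return pd.DataFrame(rows)


def panel_from_matrix(values, conditions=("c",), genes=None):
    """Panel from a genes x stages matrix (one replicate, each condition)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    rows = []
    for cond in conditions:
        for gi, g in enumerate(genes):
            for si, s in enumerate(STAGES):
                rows.append({"gene": g, "stage": s, "condition": cond,
                             "replicate": 0, "tpm": values[gi, si]})
    return ExpressionPanel(pd.DataFrame(rows), dict(DEFAULT_STAGE_GRID))


@pytest.fixture
def track_df():
    def make(points, track_id=0, t0=7.0, interval_min=5.0):
        points = np.asarray(points, dtype=float)
        n = len(points)
        return pd.DataFrame({
            "track_id": track_id, "frame": np.arange(n),
            "t_hpf": t0 + np.arange(n) * interval_min / 60.0,
            "x": points[:, 0], "y": points[:, 1]})
    return make


@pytest.fixture
def boltzmann_series():
    from cet.synthdata import boltzmann

    def make(bottom=0.3, top=0.95, v50=9.0, slope=0.5, noise_sd=0.0, seed=0,
             t0=6.0, t1=12.0, interval_min=10.0, explant_id="e0", group="g"):
        t = np.arange(t0, t1 + 1e-9, interval_min / 60.0)
        r = boltzmann(t, bottom, top, v50, slope)
        if noise_sd:
            r = r + np.random.default_rng(seed).normal(0, noise_sd, t.size)
        return ShapeSeries(explant_id, group, t, np.clip(r, 1e-9, 1.0))
    return make
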