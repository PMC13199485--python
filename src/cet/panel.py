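"""Stage-resolved expression panels (genes x stages x conditions, TPM)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default seven-stage grid spanning zebrafish gastrulation, as
#: (stage label, hours post fertilization).  Sphere through bud stage covers
#: the pre-gastrula plateau, gastrulation onset (shield, ~6 hpf) and the
#: post-onset stages at which sustained expression is checked.
DEFAULT_STAGE_GRID: tuple[tuple[str, float], ...] = (
    ("sphere", 4.0),
    ("dome", 4.3),
    ("50pct", 5.3),
    ("shield", 6.0),
    ("75pct", 8.0),
    ("90pct", 9.0),
    ("bud", 10.0),
)


@dataclass
class ExpressionPanel:
    """TPM values per (gene, stage, condition, replicate).

    The canonical in-memory form is a tidy DataFrame ``data`` with columns
    ``gene``, ``stage``, ``condition``, ``replicate`` (int, 0-based) and
    ``tpm`` (float, >= 0).  ``stage_hpf`` orders the stages on the
    developmental time axis; iteration order of the dict is the stage order.
    """

    data: pd.DataFrame
    stage_hpf: dict[str, float]
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"gene", "stage", "condition", "replicate", "tpm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"panel data missing columns: {sorted(missing)}")
        hpf = list(self.stage_hpf.values())
        if any(b <= a for a, b in zip(hpf, hpf[1:])):
            raise ValueError("stage_hpf must be strictly increasing in hpf")
        unknown = set(self.data["stage"]) - set(self.stage_hpf)
        if unknown:
            raise ValueError(f"stages without hpf mapping: {sorted(unknown)}")
        if len(self.data) and (self.data["tpm"] < 0).any():
            bad = self.data.index[self.data["tpm"] < 0][0]
            raise ValueError(f"negative TPM at row {bad}")
        if not self.conditions:
            self.conditions = sorted(self.data["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def stages(self) -> list[str]:
        return list(self.stage_hpf)

    def subset(self, condition: str) -> "ExpressionPanel":
        """Panel restricted to one condition."""
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        sub = self.data[self.data["condition"] == condition].reset_index(drop=True)
        return ExpressionPanel(sub, dict(self.stage_hpf), [condition])

    def replicate_means(self, condition: str | None = None) -> pd.DataFrame:
        """Mean TPM over replicates as a genes x stages DataFrame."""
        d = self.data
        if condition is not None:
            d = d[d["condition"] == condition]
        wide = d.groupby(["gene", "stage"], sort=False)["tpm"].mean().unstack("stage")
        return wide.reindex(columns=self.stages)

    def gene_series(self, gene: str, condition: str) -> pd.DataFrame:
        """Replicate-level TPM for one gene/condition, stage-ordered."""
        d = self.data
        d = d[(d["gene"] == gene) & (d["condition"] == condition)]
        if d.empty:
            raise KeyError(f"no data for gene {gene!r} in condition {condition!r}")
        order = {s: i for i, s in enumerate(self.stages)}
        return d.sort_values(["stage", "replicate"], key=lambda c: c.map(order) if c.name == "stage" else c).reset_index(drop=True)

    @property
    def hpf(self) -> np.ndarray:
        return np.array(list(self.stage_hpf.values()), dtype=float)
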