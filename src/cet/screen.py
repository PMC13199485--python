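"""Temporal trigger-gene screen and paired-gene ratio trajectories.

A "trigger" gene is one whose expression is flat across a pre-gastrulation
window (sphere to 50% epiboly by default), rises sharply at the trigger
stage (shield, gastrulation onset), and stays elevated at later stages.
The screen applies these criteria per explant condition, intersects the
calls across conditions, confirms the survivors against an intact-embryo
series, and finally applies a sharp-increase (Delta) and expression-level
(TPM) filter — yielding nested candidate tiers.

Fold-change criteria operate on replicate-mean TPM with a pseudocount
(default 0.1 TPM) added before any log or ratio; an optional replicate-level
Welch test on log2(TPM + pseudocount) tightens the "increased" call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ExpressionPanel


@dataclass
class ScreenCriteria:
    """Operational definition of the trigger pattern.

    - ``pre_window``: (first, last) stage labels across which expression must
      be unchanged (|log FC| <= log ``unchanged_max_fc``).
    - ``trigger_stage``: stage at which the rise must begin; the fold change
      vs the pre-window end must be >= ``increase_min_fc``.
    - ``sustained``: require the mean at every later stage to remain at or
      above ``retention_fraction`` of the trigger-stage level.
    - ``delta_min`` / ``tpm_min``: the sharp-increase filter on the
      confirmation (embryo) series — fractional increase Delta from the
      pre-window end to the trigger stage above ``delta_min`` and
      trigger-stage expression above ``tpm_min`` TPM.
    - ``significance_mode``: "fold_only" (default) or "replicate_test"
      (additionally Welch's t on log2(TPM + pseudocount) at alpha).
    """

    pre_window: tuple[str, str] = ("sphere", "50pct")
    trigger_stage: str = "shield"
    unchanged_max_fc: float = 1.25
    increase_min_fc: float = 1.5
    sustained: bool = True
    retention_fraction: float = 0.8
    delta_min: float = 0.5
    tpm_min: float = 5.0
    significance_mode: str = "fold_only"
    alpha: float = 0.05
    pseudocount: float = 0.1
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.unchanged_max_fc < 1:
            raise ValueError("unchanged_max_fc must be >= 1")
        if self.increase_min_fc <= 1:
            raise ValueError("increase_min_fc must be > 1")
        if self.delta_min <= 0:
            raise ValueError("delta_min must be > 0")
        if self.tpm_min < 0:
            raise ValueError("tpm_min must be >= 0")
        if self.significance_mode not in ("fold_only", "replicate_test"):
            raise ValueError("significance_mode must be fold_only or replicate_test")


@dataclass
class TriggerCall:
    gene: str
    condition: str
    is_trigger: bool
    failing_criterion: str | None
    pre_window_fc: float
    trigger_fc: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.is_trigger and self.failing_criterion:
            raise ValueError("trigger verdict cannot carry a failing criterion")
        if not self.is_trigger and not self.failing_criterion:
            raise ValueError("non-trigger verdict must record the failing criterion")


@dataclass
class CandidateSet:
    """Nested candidate tiers with per-gene provenance.

    tier1: trigger pattern in every explant condition; tier2: tier1 genes
    also increased in the embryo series over the trigger transition;
    tier3: tier2 genes passing the Delta / TPM sharp-increase filter.
    """

    tier1: list[str]
    tier2: list[str]
    tier3: list[str]
    audit: pd.DataFrame
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.tier1), len(self.tier2), len(self.tier3)


@dataclass
class RatioTrajectory:
    stages: list[str]
    hpf: np.ndarray
    fold_numerator: np.ndarray
    fold_denominator: np.ndarray
    ratio: np.ndarray
    peak_stage: str
    inversion_hpf: Optional[float]


# ---------------------------------------------------------------------------
# Per-gene classification
# ---------------------------------------------------------------------------


def _stage_stats(gene_series: pd.DataFrame, stages: list[str]):
    """Replicate mean TPM and raw replicate arrays per stage."""
    means, reps = {}, {}
    for s in stages:
        v = gene_series.loc[gene_series["stage"] == s, "tpm"].to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"missing stage {s!r} in gene series")
        means[s] = float(v.mean())
        reps[s] = v
    return means, reps


def classify_trigger_pattern(
    gene_series: pd.DataFrame, stages: list[str], criteria: ScreenCriteria,
    gene: str = "", condition: str = "",
) -> TriggerCall:
    """Classify one gene's stage series (single condition) as trigger or not.

    ``gene_series`` is replicate-level: columns stage, tpm (replicate rows).
    ``stages`` gives the hpf ordering of stage labels.
    """
    for s in (*criteria.pre_window, criteria.trigger_stage):
        if s not in stages:
            raise ValueError(f"criteria stage {s!r} not in panel stages {stages}")
    means, reps = _stage_stats(gene_series, stages)
    pc = criteria.pseudocount
    pre_a, pre_b = criteria.pre_window
    trig = criteria.trigger_stage

    if all(means[s] == 0 for s in stages) and pc == 0:
        return TriggerCall(gene, condition, False, "below detection",
                          pre_window_fc=np.nan, trigger_fc=np.nan)

    pre_fc = (means[pre_b] + pc) / (means[pre_a] + pc)
    trig_fc = (means[trig] + pc) / (means[pre_b] + pc)

    if abs(np.log(pre_fc)) > np.log(criteria.unchanged_max_fc):
        return TriggerCall(gene, condition, False, "pre-window unchanged", pre_fc, trig_fc)
    if trig_fc < criteria.increase_min_fc:
        return TriggerCall(gene, condition, False, "trigger-stage increase", pre_fc, trig_fc)

    p_val = None
    if criteria.significance_mode == "replicate_test":
        a = np.log2(reps[pre_b] + pc)
        b = np.log2(reps[trig] + pc)
        if len(a) < 2 or len(b) < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            p_val = 0.0 if trig_fc >= criteria.increase_min_fc else 1.0
        else:
            p_val = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        if p_val >= criteria.alpha:
            return TriggerCall(gene, condition, False, "replicate test", pre_fc, trig_fc, p_val)

    if criteria.sustained:
        later = stages[stages.index(trig) + 1:]
        floor = means[trig] * criteria.retention_fraction
        for s in later:
            if means[s] < floor:
                return TriggerCall(gene, condition, False, f"not sustained at {s}",
                                  pre_fc, trig_fc, p_val)
    return TriggerCall(gene, condition, True, None, pre_fc, trig_fc, p_val)


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _embryo_confirmation(
    panel: ExpressionPanel, genes: list[str], criteria: ScreenCriteria
) -> pd.DataFrame:
    """Per-gene increase/Delta/TPM metrics over the trigger transition in embryos."""
    cond = panel.conditions[0]
    means = panel.replicate_means(cond)
    pc = criteria.pseudocount
    pre_b = criteria.pre_window[1]
    trig = criteria.trigger_stage
    rows = []
    for g in genes:
        m_pre = float(means.loc[g, pre_b])
        m_trig = float(means.loc[g, trig])
        fc = (m_trig + pc) / (m_pre + pc)
        delta = (m_trig - m_pre) / (m_pre + pc)
        increased = fc >= criteria.increase_min_fc
        if criteria.significance_mode == "replicate_test":
            d = panel.data
            a = d[(d["gene"] == g) & (d["stage"] == pre_b)]["tpm"].to_numpy()
            b = d[(d["gene"] == g) & (d["stage"] == trig)]["tpm"].to_numpy()
            if len(a) >= 2 and len(b) >= 2 and not (np.ptp(np.log2(a + pc)) == 0 and np.ptp(np.log2(b + pc)) == 0):
                p = float(stats.ttest_ind(np.log2(b + pc), np.log2(a + pc), equal_var=False).pvalue)
                increased = increased and p < criteria.alpha
        rows.append({"gene": g, "embryo_fc": fc, "embryo_delta": delta,
                     "embryo_trigger_tpm": m_trig, "embryo_increased": increased})
    return pd.DataFrame(rows).set_index("gene")


def run_screen(
    explant_panels: dict[str, ExpressionPanel],
    embryo_panel: ExpressionPanel,
    criteria: ScreenCriteria | None = None,
) -> CandidateSet:
    """Run the full tiered trigger screen.

    ``explant_panels`` maps condition label -> single-condition panel.  The
    gene universe is the inner join across all panels (dropped ids are
    recorded).  Tier 1 requires the trigger pattern in every explant
    condition; tier 2 additionally requires an increase over the trigger
    transition in the embryo panel; tier 3 applies the Delta / TPM filter
    on the embryo series.
    """
    if criteria is None:
        criteria = ScreenCriteria()
    panels = list(explant_panels.values()) + [embryo_panel]
    stage_sets = [tuple(p.stages) for p in panels]
    if len(set(stage_sets)) > 1:
        labels = sorted({s for ss in stage_sets for s in ss} - set.intersection(*map(set, stage_sets)))
        raise ValueError(f"stage label mismatch across panels: {labels}")

    universes = [set(p.genes) for p in panels]
    universe = set.intersection(*universes)
    if not universe:
        raise ValueError("gene universes are disjoint across panels")
    dropped = sorted(set.union(*universes) - universe)
    genes = sorted(universe)
    stages = panels[0].stages

    calls = []
    for cond, panel in explant_panels.items():
        by_gene = dict(iter(panel.data.groupby("gene", sort=False)))
        for g in genes:
            calls.append(classify_trigger_pattern(by_gene[g], stages, criteria, gene=g, condition=cond))
    call_df = pd.DataFrame([{
        "gene": c.gene, "condition": c.condition, "is_trigger": c.is_trigger,
        "failing_criterion": c.failing_criterion, "pre_window_fc": c.pre_window_fc,
        "trigger_fc": c.trigger_fc, "p_value": c.p_value} for c in calls])

    if criteria.significance_mode == "replicate_test" and criteria.bh_correct:
        # optional BH across genes, within each condition, on the replicate-test
        # p-values; calls whose adjusted p fails alpha are demoted
        for cond in explant_panels:
            sel = (call_df["condition"] == cond) & call_df["p_value"].notna()
            if not sel.any():
                continue
            p = call_df.loc[sel, "p_value"].to_numpy()
            adj = _bh_adjust(p)
            fail = sel.copy()
            fail.loc[sel] = (adj >= criteria.alpha)
            demote = fail & call_df["is_trigger"]
            call_df.loc[demote, "is_trigger"] = False
            call_df.loc[demote, "failing_criterion"] = "replicate test (BH)"

    per_gene = call_df.groupby("gene")["is_trigger"].all()
    tier1 = sorted(per_gene.index[per_gene])

    emb = _embryo_confirmation(embryo_panel, genes, criteria)
    tier2 = [g for g in tier1 if bool(emb.loc[g, "embryo_increased"])]
    tier3 = [g for g in tier2
             if emb.loc[g, "embryo_delta"] > criteria.delta_min
             and emb.loc[g, "embryo_trigger_tpm"] > criteria.tpm_min]

    audit = call_df.pivot(index="gene", columns="condition", values="is_trigger")
    audit.columns = [f"trigger_{c}" for c in audit.columns]
    audit = audit.join(emb)
    audit["tier1"] = audit.index.isin(tier1)
    audit["tier2"] = audit.index.isin(tier2)
    audit["tier3"] = audit.index.isin(tier3)
    return CandidateSet(tier1, tier2, tier3, audit.reset_index(), dropped)


# ---------------------------------------------------------------------------
# Paired-gene ratio trajectory
# ---------------------------------------------------------------------------


def ratio_trajectory(
    panel: ExpressionPanel,
    gene_numerator: str,
    gene_denominator: str,
    condition: str | None = None,
    pseudocount: float = 0.1,
) -> RatioTrajectory:
    """Fold changes vs the first stage and the per-stage numerator/denominator
    ratio, with its peak stage (earliest argmax) and first up-crossing of 1
    (linearly interpolated in hpf; None if the ratio never crosses upward).
    """
    cond = condition or panel.conditions[0]
    means = panel.replicate_means(cond)
    for g in (gene_numerator, gene_denominator):
        if g not in means.index:
            raise KeyError(f"gene {g!r} not in panel")
    num = means.loc[gene_numerator].to_numpy(dtype=float)
    den = means.loc[gene_denominator].to_numpy(dtype=float)
    if np.all(den == 0) and pseudocount == 0:
        raise ValueError("ratio undefined: denominator gene is zero at all stages")
    hpf = panel.hpf
    fold_num = (num + pseudocount) / (num[0] + pseudocount)
    fold_den = (den + pseudocount) / (den[0] + pseudocount)
    ratio = (num + pseudocount) / (den + pseudocount)

    peak_idx = int(np.argmax(ratio))  # argmax returns the earliest maximum
    inversion = None
    for i in range(1, len(ratio)):
        if ratio[i - 1] < 1.0 <= ratio[i]:
            frac = (1.0 - ratio[i - 1]) / (ratio[i] - ratio[i - 1])
            inversion = float(hpf[i - 1] + frac * (hpf[i] - hpf[i - 1]))
            break
    return RatioTrajectory(panel.stages, hpf, fold_num, fold_den, ratio,
                           panel.stages[peak_idx], inversion)
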