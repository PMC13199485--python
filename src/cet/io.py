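"""File formats, configuration and the pipeline driver.

Formats (all plain text except TIFF masks):

- Expression TSV: first column ``gene_id``; remaining columns named
  ``<stage>|<condition>|<replicate>``; a sidecar YAML (``<path>.stages.yaml``)
  maps stage labels to hpf.
- Track CSV: common tracker-export convention
  (TRACK_ID/FRAME/POSITION_X/POSITION_Y[/POSITION_T]) or generic
  track_id/frame/x/y[/t]; a custom column map may be supplied.
- Masks: multi-frame TIFF label images, or per-frame polygon CSV with
  columns frame, vertex, x, y.
- Shape series: tidy CSV explant_id, group, hpf, roundness.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import ExpressionPanel
from .kinetics import TrackTable
from .shape import ShapeSeries

DEFAULT_TRACK_MAP = {
    "track_id": ("TRACK_ID", "track_id"),
    "frame": ("FRAME", "frame"),
    "x": ("POSITION_X", "x"),
    "y": ("POSITION_Y", "y"),
    "t": ("POSITION_T", "t", "t_hpf"),
}


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def write_expression_tsv(panel: ExpressionPanel, path: str | Path) -> None:
    path = Path(path)
    d = panel.data
    wide = d.pivot_table(index="gene", columns=["stage", "condition", "replicate"],
                         values="tpm", sort=False)
    wide.columns = [f"{s}|{c}|{r}" for s, c, r in wide.columns]
    wide.index.name = "gene_id"
    wide.to_csv(path, sep="\t")
    with open(str(path) + ".stages.yaml", "w") as fh:
        yaml.safe_dump({"stages": {k: float(v) for k, v in panel.stage_hpf.items()}},
                       fh, sort_keys=False)


def read_expression_tsv(path: str | Path, stage_hpf: dict[str, float] | None = None) -> ExpressionPanel:
    """Read an expression panel; stage->hpf comes from the sidecar YAML
    unless given explicitly."""
    path = Path(path)
    if stage_hpf is None:
        sidecar = Path(str(path) + ".stages.yaml")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing stage map sidecar {sidecar}")
        with open(sidecar) as fh:
            raw = {k: float(v) for k, v in yaml.safe_load(fh)["stages"].items()}
        stage_hpf = dict(sorted(raw.items(), key=lambda kv: kv[1]))
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("no data rows in expression TSV")
    if df.columns[0] != "gene_id":
        raise ValueError(f"first column must be gene_id, got {df.columns[0]!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicated gene id {df.loc[dup.idxmax(), 'gene_id']!r}")
    bad = [c for c in df.columns[1:] if len(c.split("|")) != 3]
    if bad:
        raise ValueError(f"malformed expression columns (need stage|condition|replicate): {bad}")
    long = df.melt(id_vars="gene_id", var_name="key", value_name="tpm")
    parts = long["key"].str.split("|", expand=True)
    long["stage"], long["condition"], long["replicate"] = parts[0], parts[1], parts[2].astype(int)
    neg = long["tpm"] < 0
    if neg.any():
        raise ValueError(f"negative TPM for gene {long.loc[neg.idxmax(), 'gene_id']!r}")
    data = long.rename(columns={"gene_id": "gene"})[
        ["gene", "stage", "condition", "replicate", "tpm"]]
    return ExpressionPanel(data, stage_hpf)


# ---------------------------------------------------------------------------
# Track CSV
# ---------------------------------------------------------------------------


def write_tracks_csv(table: TrackTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_tracks_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    frame_interval_min: float = 5.0,
    midline_x: float = 0.0,
    scale_um_per_px: float = 1.0,
    t0_hpf: float | None = None,
) -> TrackTable:
    """Read a tracker-export CSV into a TrackTable.

    ``scale_um_per_px`` converts pixel coordinates to um (midline_x is in
    the same output units).  Times come from a mapped ``t`` column (hpf) or
    are reconstructed as ``t0_hpf + frame * interval``.
    """
    df = pd.read_csv(path)
    cols = {}
    for key, aliases in DEFAULT_TRACK_MAP.items():
        if column_map and key in column_map:
            aliases = (column_map[key],)
        found = [a for a in aliases if a in df.columns]
        if found:
            cols[key] = found[0]
        elif key != "t":
            raise ValueError(f"missing mapped column for {key!r} (tried {aliases})")
    out = pd.DataFrame({
        "track_id": df[cols["track_id"]],
        "frame": df[cols["frame"]].astype(int),
        "x": df[cols["x"]].astype(float) * scale_um_per_px,
        "y": df[cols["y"]].astype(float) * scale_um_per_px,
    })
    if "t" in cols:
        out["t_hpf"] = df[cols["t"]].astype(float)
    else:
        if t0_hpf is None:
            raise ValueError("t0_hpf required when the file has no time column")
        out["t_hpf"] = t0_hpf + out["frame"] * frame_interval_min / 60.0
    return TrackTable(out[["track_id", "frame", "t_hpf", "x", "y"]],
                      frame_interval_min=frame_interval_min, midline_x=midline_x)


# ---------------------------------------------------------------------------
# Shape series CSV / masks
# ---------------------------------------------------------------------------


def write_shape_series_csv(series: list[ShapeSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, r in zip(s.t_hpf, s.roundness):
            rows.append({"explant_id": s.explant_id, "group": s.group,
                         "hpf": t, "roundness": r})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_shape_series_csv(path: str | Path) -> list[ShapeSeries]:
    df = pd.read_csv(path)
    required = {"explant_id", "group", "hpf", "roundness"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shape series CSV missing columns: {sorted(missing)}")
    out = []
    for (eid, grp), g in df.groupby(["explant_id", "group"], sort=True):
        g = g.sort_values("hpf")
        out.append(ShapeSeries(str(eid), str(grp), g["hpf"].to_numpy(),
                               g["roundness"].to_numpy(), source="direct"))
    return out


def read_mask_tiff(path: str | Path) -> np.ndarray:
    """Multi-frame label TIFF as (frames, y, x); single frames gain an axis."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D TIFF, got shape {arr.shape}")
    return arr


def read_polygons_csv(path: str | Path) -> dict[int, np.ndarray]:
    """Per-frame boundary polygons: columns frame, vertex, x, y."""
    df = pd.read_csv(path)
    required = {"frame", "vertex", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"polygon CSV missing columns: {sorted(missing)}")
    out = {}
    for f, g in df.groupby("frame", sort=True):
        g = g.sort_values("vertex")
        out[int(f)] = g[["x", "y"]].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration and manifest
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    shape: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for block in (self.screen, self.kinetics, self.shape, self.quant):
            for key, val in block.items():
                if key.endswith(("_path", "_paths")):
                    paths = val if isinstance(val, list) else [val]
                    for p in paths:
                        if not Path(p).exists():
                            raise FileNotFoundError(f"configured input does not exist: {p}")


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages (simulate -> screen -> shape -> kinetics
    -> quant), writing tidy outputs plus a manifest under ``config.outdir``.

    Any stage failure is recorded in the manifest and re-raised with the
    stage name prefixed.
    """
    from . import synthdata, screen as screen_mod, shape as shape_mod
    from . import kinetics as kin_mod, quant as quant_mod

    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    stage = None
    caught: list = []
    try:
      with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if config.simulate:
            stage = "simulate"
            sim = config.simulate
            if "expression" in sim:
                spec = synthdata.SimExpressionSpec(seed=config.seed, **sim["expression"])
                panel = synthdata.gen_expression_panel(spec)
                write_expression_tsv(panel, outdir / "expression.tsv")
                manifest.stage_counts["simulate.expression"] = {
                    "genes": len(panel.genes), "rows": len(panel.data)}
            if "tracks" in sim:
                spec = synthdata.SimTrackSpec(seed=config.seed, **sim["tracks"])
                tracks = synthdata.gen_tracks(spec)
                write_tracks_csv(tracks, outdir / "tracks.csv")
                manifest.stage_counts["simulate.tracks"] = {
                    "tracks": tracks.n_tracks, "rows": len(tracks.data)}
            if "shape" in sim:
                spec = synthdata.SimShapeSpec(seed=config.seed, **sim["shape"])
                series = synthdata.gen_shape_series(spec)
                write_shape_series_csv(series, outdir / "shape_series.csv")
                manifest.stage_counts["simulate.shape"] = {"explants": len(series)}

        if config.screen:
            stage = "screen"
            blk = dict(config.screen)
            explant_paths = blk.pop("explant_paths")
            embryo_path = blk.pop("embryo_path")
            crit = screen_mod.ScreenCriteria(**blk.get("criteria", {}))
            for p in explant_paths + [embryo_path]:
                manifest.input_checksums[str(p)] = _checksum(p)
            panels = {}
            for p in explant_paths:
                panel = read_expression_tsv(p)
                for cond in panel.conditions:
                    panels[cond] = panel.subset(cond)
            embryo = read_expression_tsv(embryo_path)
            if len(embryo.conditions) > 1:
                embryo = embryo.subset(blk.get("embryo_condition", embryo.conditions[0]))
            explant_conds = blk.get("explant_conditions")
            if explant_conds:
                panels = {c: panels[c] for c in explant_conds}
            result = screen_mod.run_screen(panels, embryo, crit)
            result.audit.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            manifest.stage_counts["screen"] = {
                "tier1": len(result.tier1), "tier2": len(result.tier2),
                "tier3": len(result.tier3)}

        if config.shape:
            stage = "shape"
            blk = config.shape
            series = read_shape_series_csv(blk["series_path"])
            manifest.input_checksums[str(blk["series_path"])] = _checksum(blk["series_path"])
            included = [s for s in series if shape_mod.include_explant(
                s, blk.get("cutoff_roundness", 0.5), blk.get("cutoff_time_hpf", 12.0)).include]
            groups: dict[str, list] = {}
            for s in included:
                groups.setdefault(s.group, []).append(s)
            fit_rows = []
            for grp, ss in groups.items():
                fit = shape_mod.fit_boltzmann(ss, seed=config.seed)
                fit_rows.append({"group": grp, "n_explants": len(ss),
                                 "bottom": fit.bottom, "top": fit.top,
                                 "v50_hpf": fit.v50, "slope_hpf": fit.slope,
                                 "sse": fit.sse, "df": fit.df})
            pd.DataFrame(fit_rows).to_csv(outdir / "shape_fits.csv", index=False)
            if len(groups) >= 2:
                ft = shape_mod.compare_fits_f_test(groups, seed=config.seed)
                with open(outdir / "shape_f_test.json", "w") as fh:
                    json.dump({"f": ft.f_stat, "df_num": ft.df_num,
                               "df_den": ft.df_den, "p": ft.p_value}, fh, indent=2)
            onsets = [{"explant_id": s.explant_id, "group": s.group,
                       "onset_hpf": shape_mod.extension_onset_from_series(s)}
                      for s in included]
            pd.DataFrame(onsets).to_csv(outdir / "shape_onsets.csv", index=False)
            manifest.stage_counts["shape"] = {
                "series_in": len(series), "included": len(included)}

        if config.kinetics:
            stage = "kinetics"
            blk = config.kinetics
            tracks = read_tracks_csv(
                blk["tracks_path"],
                frame_interval_min=blk.get("frame_interval_min", 5.0),
                midline_x=blk.get("midline_x", 0.0),
                scale_um_per_px=blk.get("scale_um_per_px", 1.0),
                t0_hpf=blk.get("t0_hpf"),
            )
            manifest.input_checksums[str(blk["tracks_path"])] = _checksum(blk["tracks_path"])
            summary = kin_mod.summarize_kinetics(
                tracks,
                min_frames=blk.get("min_frames", 3),
                exclusion_radius_um=blk.get("exclusion_radius_um", 100.0),
                window=blk.get("window", 4),
            )
            curve = summary.curve.copy()
            curve["smoothed"] = summary.smoothed
            curve["cumulative_um"] = summary.cumulative
            curve.to_csv(outdir / "ml_displacement.csv", index=False)
            summary.per_track.to_csv(outdir / "track_stats.csv", index=False)
            with open(outdir / "onset.json", "w") as fh:
                json.dump({"onset_hpf": summary.onset.onset_hpf,
                           "f": summary.onset.f_stat, "p": summary.onset.p_value},
                          fh, indent=2)
            manifest.stage_counts["kinetics"] = {
                "tracks_in": summary.filter_report.n_tracks_in,
                "tracks_out": summary.filter_report.n_tracks_out,
                "onset_hpf": summary.onset.onset_hpf}

        if config.quant:
            stage = "quant"
            blk = config.quant
            if "ct_path" in blk:
                ct = pd.read_csv(blk["ct_path"])
                manifest.input_checksums[str(blk["ct_path"])] = _checksum(blk["ct_path"])
                res = quant_mod.ddct(ct, blk["target"], blk["reference"], blk["calibrator"])
                res.to_csv(outdir / "ddct.csv", index=False)
                manifest.stage_counts["quant.ddct"] = {"samples": len(res)}
            if "peaks_path" in blk:
                peaks = pd.read_csv(blk["peaks_path"])
                manifest.input_checksums[str(blk["peaks_path"])] = _checksum(blk["peaks_path"])
                res = quant_mod.quantify_disaccharides(
                    peaks, blk.get("standard_pmol", 20.0), blk.get("protein_ug"))
                res.to_csv(outdir / "disaccharides.csv", index=False)
                manifest.stage_counts["quant.gag"] = {"codes": len(res)}
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.warnings.extend(str(w.message) for w in caught)
        manifest.write(outdir / "manifest.json")
        raise RuntimeError(f"[{stage}] {exc}") from exc

    manifest.warnings.extend(str(w.message) for w in caught)
    manifest.write(outdir / "manifest.json")
    return manifest
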