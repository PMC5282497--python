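"""End-to-end orchestration: simulate -> segment -> topology -> clusters -> stats.

The pipeline streams cells (each cell is simulated or loaded, analysed, and
released) so full cohorts run in bounded memory.  Every output carries the
configuration hash and master seed; per-cell failures are logged and skipped,
and the run aborts only if more than half of the cells fail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _version
from .clusters import (
    MERGE_RADIUS,
    PROXIMITY,
    colocalize_pair,
    count_clusters,
)
from .segmentation import (
    DETECT_THRESHOLD,
    MIN_VOXELS,
    PRESENCE_THRESHOLD,
    SMOOTH_SIGMA,
    detect_signals,
    measure_axes,
    segment_nucleus,
)
from .stats import (
    chisq_gof,
    monte_carlo_region_null,
    paired_method_comparison,
    subject_homogeneity,
)
from .synthetic import (
    FISH_CHANNELS,
    CellSim,
    SyntheticSpec,
    iter_cohort_cells,
    make_nucleus,
    simulate_cohort,
)
from .topology import (
    LONGITUDINAL_REGIONS,
    RADIAL_REGIONS,
    assign_longitudinal,
    assign_radial,
    distance_map,
    distance_to_edge,
)
from .types import FishSignal, NucleusModel, VoxelImage


@dataclass
class RunConfig:
    """Configuration of a pipeline run (all thresholds in physical units)."""

    mode: str = "simulate+analyze"  # simulate | analyze | simulate+analyze
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    channels: Tuple[str, ...] = FISH_CHANNELS
    gaussian_sigma: float = SMOOTH_SIGMA
    detect_threshold: float = DETECT_THRESHOLD
    presence_threshold: float = PRESENCE_THRESHOLD
    min_voxels: int = MIN_VOXELS
    smooth_sigma: float = SMOOTH_SIGMA
    merge_radius: float = MERGE_RADIUS
    proximity: float = PROXIMITY
    null_kind: str = "both"  # equal_thirds | monte_carlo_volume | both
    mc_null_points: int = 50_000
    seed: int = 0
    save_images: bool = False
    overwrite: bool = False
    make_figures: bool = False
    compare_2d: bool = True

    def __post_init__(self) -> None:
        for name in (
            "gaussian_sigma",
            "detect_threshold",
            "presence_threshold",
            "merge_radius",
            "proximity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mode not in ("simulate", "analyze", "simulate+analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze" and self.input_dir is None:
            raise ValueError("analyze mode needs input_dir")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"]["telomere_cluster_sizes"] = {
            str(k): v for k, v in d["spec"]["telomere_cluster_sizes"].items()
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "spec" in raw and isinstance(raw["spec"], dict):
            spec_raw = dict(raw["spec"])
            if "telomere_cluster_sizes" in spec_raw:
                spec_raw["telomere_cluster_sizes"] = {
                    int(k): float(v)
                    for k, v in spec_raw["telomere_cluster_sizes"].items()
                }
            raw["spec"] = SyntheticSpec(**spec_raw)
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        return cls(**raw)


@dataclass
class CellAnalysis:
    cell_id: str
    subject: int
    nucleus: NucleusModel
    signals: Dict[str, List[FishSignal]]
    n_nonrendered: Dict[str, int]
    signal_rows: List[dict]
    record: dict


def _measured_nucleus(
    dapi: VoxelImage, tail_point: np.ndarray, cfg: RunConfig
) -> NucleusModel:
    nucleus = segment_nucleus(dapi, gaussian_sigma=cfg.gaussian_sigma)
    head, L, D = measure_axes(nucleus, tail_point)
    nucleus.tail_point = np.asarray(tail_point, dtype=float)
    nucleus.head_point = head
    nucleus.length_L = L
    nucleus.widest_diameter_D = D
    return nucleus


def analyze_cell(
    cell: CellSim, cfg: RunConfig, subject: Optional[int] = None
) -> CellAnalysis:
    """Run the measurement chain on one simulated (or loaded) cell.

    Segmentation and axis measurement are recomputed from the DAPI image;
    only the tail attachment point is taken from the cell's metadata
    (tail identification was manual in the source protocol).
    """
    subject = cell.subject if subject is None else subject
    nucleus = _measured_nucleus(cell.dapi, cell.nucleus.tail_point, cfg)
    edt = distance_map(nucleus.mask, nucleus.voxel_size)

    signals: Dict[str, List[FishSignal]] = {}
    n_nonrendered: Dict[str, int] = {}
    signal_rows: List[dict] = []
    for ch, img in cell.images.items():
        sigs, n_nr = detect_signals(
            img,
            nucleus,
            detect_threshold=cfg.detect_threshold,
            presence_threshold=cfg.presence_threshold,
            min_voxels=cfg.min_voxels,
            smooth_sigma=cfg.smooth_sigma,
        )
        signals[ch] = sigs
        n_nonrendered[ch] = n_nr
        for s in sigs:
            row = {
                "cell_id": cell.cell_id,
                "subject": subject,
                "channel": ch,
                "x": s.centroid[0],
                "y": s.centroid[1],
                "z": s.centroid[2],
                "voxels": s.voxel_count,
                "peak": s.peak_intensity,
                "rendered": s.rendered,
                "d_edge": np.nan,
                "radial_region": "",
            }
            if s.rendered:
                try:
                    d = distance_to_edge(
                        nucleus.mask, nucleus.voxel_size, s.centroid, edt=edt
                    )
                    ra = assign_radial(d, nucleus.widest_diameter_D)
                    row["d_edge"] = d
                    row["radial_region"] = ra.region
                except ValueError:
                    row["rendered"] = False  # centroid fell outside the mask
            la = assign_longitudinal(
                s.centroid, nucleus.tail_point, nucleus.head_point
            )
            row["s_axial"] = la.axial_s
            row["longitudinal_region"] = la.region
            signal_rows.append(row)

    record = {
        "cell_id": cell.cell_id,
        "subject": subject,
        "nucleus_volume": nucleus.volume,
        "length_L": nucleus.length_L,
        "widest_D": nucleus.widest_diameter_D,
    }
    tel = signals.get("pantelomere", [])
    if "pantelomere" in cell.images:
        record["tel_total"] = len(tel)
        record["tel_rendered"] = sum(s.rendered for s in tel)
        record["tel_nonrendered"] = n_nonrendered["pantelomere"]
        record["tel_clusters"] = len(count_clusters(tel, cfg.merge_radius))
    if "pancentromere" in cell.images:
        cen = [s for s in signals["pancentromere"] if s.rendered]
        chromo = count_clusters(
            cen, cfg.merge_radius, cell_id=cell.cell_id, channel="pancentromere"
        )
        record["chromocenters"] = len(chromo)
        if "NOR" in cell.images or "cen_1_5_19" in cell.images:
            nor = [s for s in signals.get("NOR", []) if s.rendered]
            c159 = [s for s in signals.get("cen_1_5_19", []) if s.rendered]
            rec_nor, rec_c = colocalize_pair(
                nor, c159, chromo, cfg.proximity, cell_id=cell.cell_id
            )
            record.update(
                nor_signals=rec_nor.n_discrete_signals,
                nor_distinct=rec_nor.n_distinct_chromocenters_associated,
                nor_all_in_one=rec_nor.all_in_one,
                cen159_signals=rec_c.n_discrete_signals,
                cen159_distinct=rec_c.n_distinct_chromocenters_associated,
                cen159_all_in_one=rec_c.all_in_one,
                shares_chromocenter=rec_nor.shares_chromocenter_with_other_probe_set,
            )

    # 2D arm: maximum projection of the telomere channel, longitudinal only
    if cfg.compare_2d and "pantelomere" in cell.images:
        img3 = cell.images["pantelomere"]
        proj = VoxelImage(
            img3.data.max(axis=0), img3.voxel_size[1:], channel="pantelomere"
        )
        mask2d = nucleus.mask.any(axis=0)
        nuc2d = NucleusModel(
            mask=mask2d,
            voxel_size=nucleus.voxel_size[1:],
            tail_point=nucleus.tail_point[:2],
            head_point=nucleus.head_point[:2],
        )
        sigs2d, _ = detect_signals(
            proj,
            nuc2d,
            detect_threshold=cfg.detect_threshold,
            presence_threshold=cfg.presence_threshold,
            min_voxels=cfg.min_voxels,
            smooth_sigma=cfg.smooth_sigma,
        )
        counts2d = np.zeros(3, dtype=int)
        for s in sigs2d:
            la = assign_longitudinal(
                s.centroid, nuc2d.tail_point, nuc2d.head_point
            )
            counts2d[LONGITUDINAL_REGIONS.index(la.region)] += 1
        record["tel_2d_total"] = len(sigs2d)
        for reg, cnt in zip(LONGITUDINAL_REGIONS, counts2d):
            record[f"tel_2d_long_{reg}"] = int(cnt)

    # per-channel region counts for aggregation
    for ch in cell.images:
        rows = [r for r in signal_rows if r["channel"] == ch]
        for reg in RADIAL_REGIONS:
            record[f"{ch}_radial_{reg}"] = sum(
                1 for r in rows if r["rendered"] and r["radial_region"] == reg
            )
        for reg in LONGITUDINAL_REGIONS:
            record[f"{ch}_long_{reg}"] = sum(
                1 for r in rows if r["longitudinal_region"] == reg
            )

    return CellAnalysis(
        cell_id=cell.cell_id,
        subject=subject,
        nucleus=nucleus,
        signals=signals,
        n_nonrendered=n_nonrendered,
        signal_rows=signal_rows,
        record=record,
    )


@dataclass
class CohortResult:
    cell_records: pd.DataFrame
    signal_table: pd.DataFrame
    stats_table: pd.DataFrame
    summary: dict
    failures: List[Tuple[str, str]]
    config_hash: str


def _subject_region_table(
    records: pd.DataFrame, channel: str, kind: str, regions
) -> np.ndarray:
    cols = [f"{channel}_{kind}_{r}" for r in regions]
    grouped = records.groupby("subject")[cols].sum()
    return grouped.to_numpy(), grouped.index.to_numpy()


def analyze_cohort(cfg: RunConfig) -> CohortResult:
    """Simulate (streaming) and analyse the whole synthetic cohort."""
    spec = cfg.spec
    records: List[dict] = []
    signal_rows: List[dict] = []
    failures: List[Tuple[str, str]] = []
    n_cells = 0
    for cell in iter_cohort_cells(spec, channels=cfg.channels):
        n_cells += 1
        try:
            ana = analyze_cell(cell, cfg)
            records.append(ana.record)
            signal_rows.extend(ana.signal_rows)
        except Exception as exc:  # noqa: BLE001 - logged and surfaced
            failures.append((cell.cell_id, str(exc)))
    if n_cells == 0:
        raise ValueError("no cells found")
    if len(failures) > 0.5 * n_cells:
        raise RuntimeError(
            f"{len(failures)}/{n_cells} cells failed; first: {failures[0]}"
        )

    cell_records = pd.DataFrame(records)
    signal_table = pd.DataFrame(signal_rows)

    # Monte-Carlo volume-weighted null from the analytic cohort nucleus
    mc = None
    if cfg.null_kind in ("monte_carlo_volume", "both"):
        _, nuc = make_nucleus(spec, treated=True, seed=spec.seed)
        mc = monte_carlo_region_null(
            nuc, n_points=cfg.mc_null_points, seed=spec.seed + 1
        )

    stats_rows: List[dict] = []
    summary: dict = {"n_cells": int(n_cells - len(failures))}
    for ch in cfg.channels:
        for kind, regions in (
            ("radial", RADIAL_REGIONS),
            ("long", LONGITUDINAL_REGIONS),
        ):
            table, subjects = _subject_region_table(
                cell_records, ch, kind, regions
            )
            pooled = table.sum(axis=0)
            if pooled.sum() == 0:
                continue
            kind_name = "radial" if kind == "radial" else "longitudinal"
            nulls = {"equal_thirds": None}
            if kind == "radial" and mc is not None:
                nulls["monte_carlo_volume"] = mc.fractions
            if cfg.null_kind == "monte_carlo_volume" and kind == "radial":
                nulls.pop("equal_thirds")
            for null_name, frac in nulls.items():
                res = chisq_gof(pooled, frac, null_kind=null_name)
                stats_rows.append(
                    {
                        "target": ch,
                        "axis": kind_name,
                        "scope": "pooled",
                        "null_kind": null_name,
                        "chi2": res.chi2,
                        "df": res.degrees_of_freedom,
                        "p": res.p_value,
                    }
                )
                for subj, row in zip(subjects, table):
                    if row.sum() == 0:
                        continue
                    r = chisq_gof(row, frac, null_kind=null_name)
                    stats_rows.append(
                        {
                            "target": ch,
                            "axis": kind_name,
                            "scope": f"subject_{subj}",
                            "null_kind": null_name,
                            "chi2": r.chi2,
                            "df": r.degrees_of_freedom,
                            "p": r.p_value,
                        }
                    )
            if table.shape[0] >= 2 and (table.sum(axis=1) > 0).sum() >= 2:
                hom = subject_homogeneity(table[table.sum(axis=1) > 0])
                stats_rows.append(
                    {
                        "target": ch,
                        "axis": kind_name,
                        "scope": "between_subjects",
                        "null_kind": "homogeneity",
                        "chi2": hom.chi2,
                        "df": hom.df,
                        "p": hom.p_value,
                    }
                )
            summary[f"{ch}_{kind_name}_fractions"] = (
                pooled / pooled.sum()
            ).tolist()

    # headline per-cell means
    for col, name in (
        ("tel_total", "mean_telomere_signals_per_cell"),
        ("tel_rendered", "mean_rendered_telomeres_per_cell"),
        ("tel_clusters", "mean_telomere_clusters_per_cell"),
        ("chromocenters", "mean_chromocenters_per_cell"),
        ("nor_signals", "mean_nor_signals_per_cell"),
        ("cen159_signals", "mean_cen159_signals_per_cell"),
    ):
        if col in cell_records:
            summary[name] = float(cell_records[col].mean())
    if {"tel_total", "tel_nonrendered"} <= set(cell_records.columns):
        tot = cell_records["tel_total"].sum()
        summary["telomere_nonrendered_fraction"] = (
            float(cell_records["tel_nonrendered"].sum() / tot) if tot else np.nan
        )
    if "nor_distinct" in cell_records:
        summary["nor_distinct_distribution"] = (
            cell_records["nor_distinct"].value_counts(normalize=True).sort_index().to_dict()
        )
        summary["cen159_distinct_distribution"] = (
            cell_records["cen159_distinct"].value_counts(normalize=True).sort_index().to_dict()
        )
        summary["shared_chromocenter_fraction"] = float(
            cell_records["shares_chromocenter"].mean()
        )
    if mc is not None:
        summary["mc_null_fractions"] = mc.fractions.tolist()

    # 3D vs 2D method comparison (telomere longitudinal fractions and counts)
    if cfg.compare_2d and "tel_2d_total" in cell_records:
        per_subj = cell_records.groupby("subject")
        comp = {}
        for reg in LONGITUDINAL_REGIONS:
            c3 = per_subj[f"pantelomere_long_{reg}"].sum()
            t3 = sum(
                per_subj[f"pantelomere_long_{r}"].sum()
                for r in LONGITUDINAL_REGIONS
            )
            c2 = per_subj[f"tel_2d_long_{reg}"].sum()
            t2 = sum(
                per_subj[f"tel_2d_long_{r}"].sum() for r in LONGITUDINAL_REGIONS
            )
            if len(c3) >= 2:
                res = paired_method_comparison(
                    (c3 / t3).to_numpy(), (c2 / t2).to_numpy()
                )
                comp[f"fraction_{reg}_p"] = res.p_value
        if len(per_subj) >= 2:
            res = paired_method_comparison(
                per_subj["tel_total"].mean().to_numpy(),
                per_subj["tel_2d_total"].mean().to_numpy(),
            )
            comp["count_p"] = res.p_value
            comp["count_mean_3d"] = float(cell_records["tel_total"].mean())
            comp["count_mean_2d"] = float(cell_records["tel_2d_total"].mean())
        summary["method_comparison"] = comp

    stats_table = pd.DataFrame(stats_rows)
    result = CohortResult(
        cell_records=cell_records,
        signal_table=signal_table,
        stats_table=stats_table,
        summary=summary,
        failures=failures,
        config_hash=cfg.config_hash(),
    )
    if cfg.output_dir is not None:
        _write_outputs(result, cfg)
    return result


def _write_outputs(result: CohortResult, cfg: RunConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cell_records.to_csv(out / "cell_records.csv", index=False)
    result.signal_table.to_csv(out / "signals.csv", index=False)
    result.stats_table.to_csv(out / "stats.csv", index=False)
    meta = {
        "config_hash": result.config_hash,
        "seed": cfg.seed,
        "spec_seed": cfg.spec.seed,
        "version": _version,
        "failures": result.failures,
        "summary": {
            k: v for k, v in result.summary.items() if not isinstance(v, dict)
        },
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    (out / "report.txt").write_text(render_report(result))
    if cfg.make_figures:
        _write_figures(result, out)


def render_report(result: CohortResult) -> str:
    """Human-readable cohort report."""
    s = result.summary
    lines = [
        "Sperm nucleus topology cohort report",
        f"config hash: {result.config_hash}",
        f"cells analysed: {s.get('n_cells')}",
        "",
    ]
    for ch in FISH_CHANNELS:
        key = f"{ch}_radial_fractions"
        if key in s:
            fr = s[key]
            lines.append(
                f"{ch} radial (periphery/intermediate/interior): "
                + "/".join(f"{100 * f:.1f}%" for f in fr)
            )
        key = f"{ch}_longitudinal_fractions"
        if key in s:
            fr = s[key]
            lines.append(
                f"{ch} longitudinal (tail/mid/head): "
                + "/".join(f"{100 * f:.1f}%" for f in fr)
            )
    for key, label in (
        ("mean_telomere_signals_per_cell", "mean telomere signals per cell"),
        ("mean_rendered_telomeres_per_cell", "mean rendered telomeres per cell"),
        ("mean_telomere_clusters_per_cell", "mean telomere clusters per cell"),
        ("telomere_nonrendered_fraction", "non-rendered telomere fraction"),
        ("mean_chromocenters_per_cell", "mean chromocenters per cell"),
        ("shared_chromocenter_fraction", "NOR/cen-1-5-19 shared-chromocenter fraction"),
    ):
        if key in s:
            val = s[key]
            lines.append(
                f"{label}: {100 * val:.1f}%"
                if "fraction" in key
                else f"{label}: {val:.2f}"
            )
    if "mc_null_fractions" in s:
        lines.append(
            "volume-weighted (Monte-Carlo) radial null: "
            + "/".join(f"{100 * f:.1f}%" for f in s["mc_null_fractions"])
        )
    if "method_comparison" in s:
        mc = s["method_comparison"]
        lines.append("")
        lines.append("3D vs 2D (telomere):")
        for k, v in mc.items():
            lines.append(f"  {k}: {v:.4g}")
    if result.failures:
        lines.append("")
        lines.append(f"skipped cells ({len(result.failures)}):")
        for cid, reason in result.failures:
            lines.append(f"  {cid}: {reason}")
    return "\n".join(lines) + "\n"


def _write_figures(result: CohortResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = result.cell_records
    # region histograms per subject, one panel per channel/axis
    for kind, regions in (
        ("radial", RADIAL_REGIONS),
        ("long", LONGITUDINAL_REGIONS),
    ):
        chans = [
            ch
            for ch in FISH_CHANNELS
            if f"{ch}_{kind}_{regions[0]}" in rec.columns
        ]
        if not chans:
            continue
        fig, axes = plt.subplots(
            1, len(chans), figsize=(4 * len(chans), 3), squeeze=False
        )
        for ax, ch in zip(axes[0], chans):
            table = (
                rec.groupby("subject")[[f"{ch}_{kind}_{r}" for r in regions]]
                .sum()
                .pipe(lambda t: t.div(t.sum(axis=1), axis=0))
            )
            table.plot.bar(stacked=True, ax=ax, legend=False)
            ax.set_title(ch)
            ax.set_ylabel("fraction")
        axes[0][-1].legend(regions, fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"fig_{kind}.png", dpi=120)
        plt.close(fig)
    if "tel_clusters" in rec.columns:
        fig, ax = plt.subplots(figsize=(5, 3))
        for col, lab in (("tel_clusters", "telomere clusters"), ("chromocenters", "chromocenters")):
            if col in rec.columns:
                ax.hist(rec[col], bins=range(0, 40), alpha=0.6, label=lab)
        ax.set_xlabel("clusters per cell")
        ax.set_ylabel("cells")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "fig_clusters.png", dpi=120)
        plt.close(fig)


def run_pipeline(cfg: RunConfig) -> Optional[CohortResult]:
    """Dispatch on ``cfg.mode``; returns the cohort result for analysis modes."""
    if cfg.mode == "simulate":
        if cfg.output_dir is None:
            raise ValueError("simulate mode needs output_dir")
        simulate_cohort(
            cfg.spec,
            out_dir=cfg.output_dir,
            channels=cfg.channels,
            write_images=cfg.save_images,
            overwrite=cfg.overwrite,
        )
        return None
    if cfg.mode == "analyze":
        return analyze_image_dir(cfg)
    return analyze_cohort(cfg)


def analyze_image_dir(cfg: RunConfig) -> CohortResult:
    """Analyse a directory written by ``simulate_cohort(write_images=True)``."""
    from .io import load_stack

    in_dir = Path(cfg.input_dir)
    manifest_path = in_dir / "manifest.csv"
    if not manifest_path.exists():
        raise ValueError(f"no cells found: missing {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    if len(manifest) == 0:
        raise ValueError("no cells found: empty manifest")

    records, signal_rows, failures = [], [], []
    for _, row in manifest.iterrows():
        cell_id = row["cell_id"]
        try:
            dapi = load_stack(in_dir / row["path_dapi"])
            images = {}
            for ch in cfg.channels:
                key = f"path_{ch}"
                if key in row and isinstance(row[key], str):
                    images[ch] = load_stack(in_dir / row[key])
            tail = np.array([row["tail_x"], row["tail_y"], row["tail_z"]])
            head = np.array([row["head_x"], row["head_y"], row["head_z"]])
            pseudo = CellSim(
                cell_id=cell_id,
                subject=int(row["subject"]),
                seed_entropy=(),
                nucleus=NucleusModel(
                    mask=np.ones((1, 1, 1), bool),
                    voxel_size=dapi.voxel_size,
                    tail_point=tail,
                    head_point=head,
                ),
                dapi=dapi,
                images=images,
                spots=[],
            )
            ana = analyze_cell(pseudo, cfg)
            records.append(ana.record)
            signal_rows.extend(ana.signal_rows)
        except Exception as exc:  # noqa: BLE001
            failures.append((cell_id, str(exc)))
    if len(failures) > 0.5 * len(manifest):
        raise RuntimeError(
            f"{len(failures)}/{len(manifest)} cells failed; first: {failures[0]}"
        )
    cell_records = pd.DataFrame(records)
    signal_table = pd.DataFrame(signal_rows)
    result = CohortResult(
        cell_records=cell_records,
        signal_table=signal_table,
        stats_table=pd.DataFrame(),
        summary={"n_cells": len(records)},
        failures=failures,
        config_hash=cfg.config_hash(),
    )
    if cfg.output_dir is not None:
        _write_outputs(result, cfg)
    return result
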