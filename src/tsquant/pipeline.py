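"""End-to-end experiment orchestration.

``run_experiment`` composes the whole analysis — simulate, detect spots in
both channels, select free peptides, calibrate the single-peptide unit,
quantify every mRNA's translation site, aggregate per cell and per
condition, and run the pairwise condition comparisons — as a pure function
of (config, master seed).  Per-cell seeds are derived by hashing the master
seed with the condition name and cell index, so adding cells or conditions
never perturbs existing ones.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .detect import Spot, SpotFilter, detect_spots, spots_to_frame
from .geometry import CellGeometry, ImageStack, default_geometry
from .quantify import (
    CalibrationError,
    SiteFitParams,
    SinglePeptideCalibration,
    calibrate_single_peptide,
    quantify_translation_site,
    select_free_peptides,
    sites_to_frame,
)
from .simulate import ConditionPreset, NoiseModel, PSFModel, PRESETS, cell_seed
from .stats import CellStats, cell_summary, condition_summary, two_sample_ttest

logger = logging.getLogger("tsquant")


@dataclass
class DetectionParams:
    k_mad: float = 6.0
    window: tuple[int, int, int] = (5, 11, 11)
    min_separation_px: float = 2.0
    bounds: SpotFilter = field(default_factory=SpotFilter)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one synthetic experiment."""

    conditions: list[str] = field(default_factory=lambda: list(PRESETS))
    n_cells: int = 24
    master_seed: int = 0
    stack_shape: tuple[int, int, int] = (11, 256, 256)
    dx_nm: float = 107.5
    dz_nm: float = 300.0
    psf: PSFModel = field(default_factory=PSFModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    i_single_true: float = 1200.0
    mrna_intensity_mean: float = 2000.0
    mrna_intensity_cv: float = 0.2
    n_mrna_range: tuple[int, int] = (8, 30)
    min_spacing_px: float = 5.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    site: SiteFitParams = field(default_factory=SiteFitParams)
    exclusion_radius_nm: float = 300.0
    min_calibration_spots: int = 5

    def geometry(self) -> CellGeometry:
        return default_geometry(self.stack_shape, dx_nm=self.dx_nm, dz_nm=self.dz_nm)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, typ in (("psf", PSFModel), ("noise", NoiseModel)):
            if isinstance(raw.get(key), dict):
                raw[key] = typ(**raw[key])
        if isinstance(raw.get("detection"), dict):
            det = dict(raw["detection"])
            if isinstance(det.get("bounds"), dict):
                det["bounds"] = SpotFilter(**det["bounds"])
            if isinstance(det.get("window"), list):
                det["window"] = tuple(det["window"])
            raw["detection"] = DetectionParams(**det)
        if isinstance(raw.get("site"), dict):
            site = dict(raw["site"])
            if isinstance(site.get("fit_window"), list):
                site["fit_window"] = tuple(site["fit_window"])
            raw["site"] = SiteFitParams(**site)
        for key in ("stack_shape", "n_mrna_range"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CellResult:
    """Everything the pipeline measured in one cell."""

    cell_id: str
    condition: str
    stats: CellStats | None
    calibration: SinglePeptideCalibration | None
    mrna_spots: list[Spot]
    sites: list
    error: str | None = None


@dataclass
class ExperimentReport:
    per_cell: pd.DataFrame
    summaries: dict[str, dict]
    pairwise: pd.DataFrame
    config: ExperimentConfig

    def to_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_cell.to_csv(out_dir / "per_cell.csv", index=False)
        self.pairwise.to_csv(out_dir / "pairwise_tests.csv", index=False)
        (out_dir / "condition_summaries.json").write_text(
            json.dumps(self.summaries, indent=2)
        )
        self.config.to_yaml(out_dir / "config.yaml")


def analyze_cell(
    mrna_stack: ImageStack,
    protein_stack: ImageStack,
    cyto_mask: np.ndarray,
    config: ExperimentConfig,
    cell_id: str = "cell",
    condition: str = "",
) -> CellResult:
    """Run detection, calibration and site quantification on one cell."""
    sxy = config.psf.sigma_xy_nm / mrna_stack.dx_nm
    sz = config.psf.sigma_z_nm / mrna_stack.dz_nm
    det = config.detection
    kw = dict(
        sigma_xy=sxy,
        sigma_z=sz,
        k_mad=det.k_mad,
        window=det.window,
        bounds=det.bounds,
        min_separation_px=det.min_separation_px,
    )
    mrna_spots = detect_spots(mrna_stack, **kw)
    # keep only cytoplasmic mRNAs
    n_y, n_x = cyto_mask.shape
    mrna_spots = [
        s
        for s in mrna_spots
        if 0 <= int(round(s.y0)) < n_y
        and 0 <= int(round(s.x0)) < n_x
        and cyto_mask[int(round(s.y0)), int(round(s.x0))]
    ]
    protein_spots = detect_spots(protein_stack, **kw)
    free = select_free_peptides(
        protein_spots,
        mrna_spots,
        cyto_mask,
        exclusion_radius_px=config.exclusion_radius_nm / mrna_stack.dx_nm,
    )
    try:
        cal = calibrate_single_peptide(free, min_spots=config.min_calibration_spots)
    except CalibrationError as exc:
        return CellResult(cell_id, condition, None, None, mrna_spots, [], error=str(exc))

    sites = [
        quantify_translation_site(protein_stack, s, cal, config.site, mrna_id=i)
        for i, s in enumerate(mrna_spots)
    ]
    stats = cell_summary(sites, cell_id, condition)
    return CellResult(cell_id, condition, stats, cal, mrna_spots, sites)


def simulate_cell(
    config: ExperimentConfig, condition: str, cell_index: int
) -> tuple[ImageStack, ImageStack, simulate.GroundTruth, int]:
    """Render one synthetic cell deterministically from the master seed."""
    preset = PRESETS[condition] if condition in PRESETS else ConditionPreset(condition, 0.5)
    geometry = config.geometry()
    cseed = cell_seed(config.master_seed, condition, cell_index)
    rng = np.random.default_rng(cseed)
    n_mrna = int(rng.integers(config.n_mrna_range[0], config.n_mrna_range[1] + 1))
    gt = simulate.sample_ground_truth(
        preset,
        geometry,
        n_mrna,
        seed=cseed,
        min_spacing_px=config.min_spacing_px,
        mrna_intensity_mean=config.mrna_intensity_mean,
        mrna_intensity_cv=config.mrna_intensity_cv,
    )
    mrna_stack, prot_stack = render = simulate.render_stack(
        gt, geometry, config.psf, config.noise, config.i_single_true, seed=cseed + 1
    )
    return mrna_stack, prot_stack, gt, cseed


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    write_stacks: bool = False,
) -> ExperimentReport:
    """Simulate and analyze a full multi-condition experiment.

    A failing cell (e.g. calibration failure) is recorded with its stage and
    id and the remaining cells still run.  With ``out_dir`` set, per-cell
    spot/site tables and the report are written; ``write_stacks`` addition-
    ally persists every rendered TIFF pair.
    """
    from .io import write_stack

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    geometry = config.geometry()
    rows = []
    by_condition: dict[str, list[CellStats]] = {c: [] for c in config.conditions}
    for condition in config.conditions:
        for i in range(config.n_cells):
            cell_id = f"{condition}_cell{i:03d}"
            try:
                mrna_stack, prot_stack, gt, cseed = simulate_cell(config, condition, i)
                result = analyze_cell(
                    mrna_stack, prot_stack, geometry.cyto_mask, config, cell_id, condition
                )
            except Exception as exc:  # keep processing remaining cells
                logger.warning("cell %s failed: %s", cell_id, exc)
                rows.append({"cell_id": cell_id, "condition": condition, "error": str(exc)})
                continue
            if out_path is not None:
                spots_to_frame(result.mrna_spots, mrna_stack.dx_nm, mrna_stack.dz_nm).to_csv(
                    out_path / f"{cell_id}_mrna_spots.csv", index=False
                )
                sites_to_frame(result.sites).to_csv(
                    out_path / f"{cell_id}_sites.csv", index=False
                )
                if write_stacks:
                    write_stack(mrna_stack, out_path / f"{cell_id}_mrna.tif")
                    write_stack(prot_stack, out_path / f"{cell_id}_protein.tif")
            if result.error is not None:
                logger.warning("cell %s: %s", cell_id, result.error)
                rows.append(
                    {"cell_id": cell_id, "condition": condition, "error": result.error}
                )
                continue
            st = result.stats
            rows.append(
                {
                    "cell_id": cell_id,
                    "condition": condition,
                    "seed": cseed,
                    "n_mrna_true": len(gt.mrna),
                    "true_fraction": float(gt.mrna["translating"].mean())
                    if len(gt.mrna)
                    else float("nan"),
                    "n_mrna": st.n_mrna,
                    "n_associated": st.n_associated,
                    "fraction": st.fraction,
                    "included": st.included,
                    "i_single": result.calibration.i_single,
                    "n_calibration_spots": result.calibration.n_spots_used,
                    "error": "",
                }
            )
            by_condition[condition].append(st)
            logger.info(
                "%s: %d mRNAs, %d associated (fraction %.2f)",
                cell_id,
                st.n_mrna,
                st.n_associated,
                st.fraction,
            )

    per_cell = pd.DataFrame(rows)
    summaries = {}
    for condition, cells in by_condition.items():
        try:
            s = condition_summary(cells)
            summaries[condition] = {
                "n_cells": s.n_cells,
                "mean_fraction": s.mean_fraction,
                "sem_fraction": s.sem_fraction,
            }
        except ValueError as exc:
            summaries[condition] = {"error": str(exc)}

    pair_rows = []
    for a, b in itertools.combinations(config.conditions, 2):
        fa = [c.fraction for c in by_condition[a] if c.included]
        fb = [c.fraction for c in by_condition[b] if c.included]
        try:
            t, p = two_sample_ttest(fa, fb)
            pair_rows.append({"condition_a": a, "condition_b": b, "t": t, "p": p})
        except ValueError as exc:
            pair_rows.append(
                {"condition_a": a, "condition_b": b, "t": float("nan"), "p": float("nan")}
            )
    pairwise = pd.DataFrame(pair_rows, columns=["condition_a", "condition_b", "t", "p"])

    report = ExperimentReport(per_cell=per_cell, summaries=summaries, pairwise=pairwise, config=config)
    if out_path is not None:
        report.to_dir(out_path)
    return report


def plot_fractions(report: ExperimentReport, out_path: str | Path | None = None):
    """Dot plot of per-cell colocalized fractions with mean +/- SEM bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.4 * len(report.config.conditions) + 1, 4))
    rng = np.random.default_rng(0)
    for i, cond in enumerate(report.config.conditions):
        sub = report.per_cell.query("condition == @cond and included == True")
        x = i + rng.uniform(-0.12, 0.12, size=len(sub))
        ax.plot(x, sub["fraction"], "o", ms=5, alpha=0.7)
        summ = report.summaries.get(cond, {})
        if "mean_fraction" in summ:
            m, s = summ["mean_fraction"], summ["sem_fraction"]
            ax.errorbar([i], [m], yerr=[s], fmt="_", color="k", ms=24, capsize=6, lw=1.5)
    ax.set_xticks(range(len(report.config.conditions)))
    ax.set_xticklabels(report.config.conditions, rotation=30, ha="right")
    ax.set_ylabel("fraction of mRNAs with SunTag signal")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
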