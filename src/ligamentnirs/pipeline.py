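"""End-to-end orchestration: simulate -> fit -> report.

Produces one ModelReport per requested reference property, a summary table
(property, wavelength ratio, LV count, and median r/R²/RMSE/explained
variance with bootstrap CIs) and serialized report files (JSON + CSV +
Markdown).  Every stochastic stage is driven by explicit seeds so a run is
reproducible byte-for-byte from (seeds, config).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import preprocess as prep
from .io import ReferenceTable, read_dataset
from .synthetic import generate_dataset

log = logging.getLogger("ligamentnirs")

__all__ = ["RunConfig", "run_pipeline", "make_report", "DEFAULT_PROPERTIES"]

#: The nine properties modelled by default (the assayed compositions on both
#: weight bases plus the two crimp parameters).
DEFAULT_PROPERTIES = (
    "water_content",
    "hydroxyproline_ww",
    "hydroxyproline_dw",
    "uronic_acid_ww",
    "uronic_acid_dw",
    "elastin_ww",
    "elastin_dw",
    "crimp_angle",
    "crimp_length",
)

SUMMARY_COLUMNS = [
    "property",
    "wavelengths_selected",
    "wavelengths_initial",
    "n_lv",
    "ev_median",
    "ev_lo",
    "ev_hi",
    "r_median",
    "r_lo",
    "r_hi",
    "r2_median",
    "r2_lo",
    "r2_hi",
    "rmse_median",
    "rmse_lo",
    "rmse_hi",
]


@dataclass
class RunConfig:
    """One pipeline run: data source, properties, grid and seeds."""

    out_dir: Path
    spectra_path: Path | None = None  # None -> simulate
    refs_path: Path | None = None
    properties: tuple = DEFAULT_PROPERTIES
    grid: str = "default"  # "default" | "reduced"
    config_path: Path | None = None  # single PreprocessConfig file overrides grid
    sim_seed: int = 7
    cv_seed: int = 0
    n_joints: int = 10
    max_lv: int = chem.DEFAULT_MAX_LV

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.grid not in ("default", "reduced"):
            raise ValueError(f"unknown grid {self.grid!r}")

    def make_grid(self) -> list:
        if self.config_path is not None:
            return [prep.load_config(self.config_path)]
        if self.grid == "reduced":
            return prep.reduced_grid()
        return prep.enumerate_preprocess_grid()


def _load_or_simulate(cfg: RunConfig) -> tuple:
    if cfg.spectra_path is None:
        log.info("simulating dataset: n_joints=%d seed=%d", cfg.n_joints, cfg.sim_seed)
        return generate_dataset(n_joints=cfg.n_joints, seed=cfg.sim_seed)
    data_dir = Path(cfg.spectra_path).parent
    log.info("reading dataset from %s", data_dir)
    return read_dataset(data_dir)


def run_pipeline(cfg: RunConfig) -> tuple:
    """Run the full analysis; returns (reports, summary DataFrame)."""
    records, refs = _load_or_simulate(cfg)
    unknown = [p for p in cfg.properties if p not in refs.data.columns]
    if unknown:
        raise KeyError(
            f"unknown properties {unknown}; reference table has "
            f"{list(refs.data.columns)}"
        )
    grid = cfg.make_grid()
    log.info(
        "fitting %d properties over %d preprocessing configs",
        len(cfg.properties),
        len(grid),
    )
    reports = []
    for name in cfg.properties:
        log.info("property %s", name)
        report = chem.run_model_search(
            records,
            refs,
            name,
            grid,
            seed=cfg.cv_seed,
            max_lv=cfg.max_lv,
            log=lambda msg: log.info("  %s", msg),
        )
        log.info(
            "  best: median EV %.3f  n_lv=%d  %d/%d wavelengths",
            report.cv.medians["explained_variance"],
            report.n_lv,
            report.mask.n_kept,
            report.n_features_initial,
        )
        reports.append(report)
    summary = summarize(reports)
    return reports, summary


def summarize(reports: list) -> pd.DataFrame:
    rows = []
    for rep in reports:
        med, ci = rep.cv.medians, rep.cv.ci
        rows.append(
            {
                "property": rep.property_name,
                "wavelengths_selected": rep.mask.n_kept,
                "wavelengths_initial": rep.n_features_initial,
                "n_lv": rep.n_lv,
                "ev_median": med["explained_variance"],
                "ev_lo": ci["explained_variance"][0],
                "ev_hi": ci["explained_variance"][1],
                "r_median": med["r"],
                "r_lo": ci["r"][0],
                "r_hi": ci["r"][1],
                "r2_median": med["R2"],
                "r2_lo": ci["R2"][0],
                "r2_hi": ci["R2"][1],
                "rmse_median": med["RMSE"],
                "rmse_lo": ci["RMSE"][0],
                "rmse_hi": ci["RMSE"][1],
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def report_to_dict(rep: chem.ModelReport) -> dict:
    top5 = chem.top_influential_wavelengths(
        rep.model, rep.feature_wavelengths, k=min(5, rep.feature_wavelengths.size)
    )
    cfg = rep.config
    return {
        "property": rep.property_name,
        "config": {
            "d1": {
                "sg_window_nm": cfg.d1.sg_window_nm,
                "deriv": cfg.d1.deriv,
                "snv": cfg.d1.snv,
                "crop": cfg.d1.crop,
            },
            "d2": {
                "sg_window_nm": cfg.d2.sg_window_nm,
                "deriv": cfg.d2.deriv,
                "snv": cfg.d2.snv,
                "crop": cfg.d2.crop,
            },
            "resample_step": cfg.resample_step,
        },
        "n_lv": rep.n_lv,
        "wavelengths_selected": int(rep.mask.n_kept),
        "wavelengths_initial": int(rep.n_features_initial),
        "selected_wavelengths": [
            [det, float(wl)]
            for det, wl in zip(rep.feature_detectors, rep.feature_wavelengths)
        ],
        "medians": rep.cv.medians,
        "ci": {k: list(v) for k, v in rep.cv.ci.items()},
        "top_influential_wavelengths": [
            {"wavelength_nm": wl, "coefficient": c} for wl, c in top5
        ],
        "y_mean": rep.y_mean,
        "y_sd": rep.y_sd,
    }


def summary_from_dicts(report_dicts: list) -> pd.DataFrame:
    """Rebuild the summary table from serialized report entries."""
    rows = []
    for d in report_dicts:
        med, ci = d["medians"], d["ci"]
        rows.append(
            {
                "property": d["property"],
                "wavelengths_selected": d["wavelengths_selected"],
                "wavelengths_initial": d["wavelengths_initial"],
                "n_lv": d["n_lv"],
                "ev_median": med["explained_variance"],
                "ev_lo": ci["explained_variance"][0],
                "ev_hi": ci["explained_variance"][1],
                "r_median": med["r"],
                "r_lo": ci["r"][0],
                "r_hi": ci["r"][1],
                "r2_median": med["R2"],
                "r2_lo": ci["R2"][0],
                "r2_hi": ci["R2"][1],
                "rmse_median": med["RMSE"],
                "rmse_lo": ci["RMSE"][0],
                "rmse_hi": ci["RMSE"][1],
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _write_summary_files(summary: pd.DataFrame, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "summary.csv"
    summary.to_csv(csv_path, index=False, float_format="%.12g")

    md_path = out_dir / "summary.md"
    lines = [
        "| Property | Wavelengths | LVs | EV | r | R2 | RMSE |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, row in summary.iterrows():

        def cell(prefix: str) -> str:
            return (
                f"{row[prefix + '_median']:.2f} "
                f"({row[prefix + '_lo']:.2f}-{row[prefix + '_hi']:.2f})"
            )

        ratio = f"{row['wavelengths_selected']} / {row['wavelengths_initial']}"
        lines.append(
            f"| {row['property']} | {ratio} | {row['n_lv']} | "
            f"{cell('ev')} | {cell('r')} | {cell('r2')} | {cell('rmse')} |"
        )
    md_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    fig_path = out_dir / "explained_variance.png"
    _plot_ev_bars(summary, fig_path)
    return {"csv": csv_path, "markdown": md_path, "figure": fig_path}


def remake_report(report_json, out_dir) -> dict:
    """Re-emit summary files (CSV/Markdown/figure) from a saved report.json."""
    with open(report_json, encoding="utf-8") as fh:
        report_dicts = json.load(fh)
    if not report_dicts:
        raise ValueError("no reports to write")
    return _write_summary_files(summary_from_dicts(report_dicts), Path(out_dir))


def make_report(reports: list, out_dir) -> dict:
    """Write report.json, summary.csv/.md and the EV bar chart; returns paths."""
    if not reports:
        raise ValueError("no reports to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    json_path = out_dir / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump([report_to_dict(r) for r in reports], fh, indent=2)

    paths = _write_summary_files(summarize(reports), out_dir)
    return {"json": json_path, **paths}


def _plot_ev_bars(summary: pd.DataFrame, path: Path) -> None:
    """Bar chart of median cross-validated explained variance per property."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(summary))
    err = np.vstack(
        [
            summary["ev_median"] - summary["ev_lo"],
            summary["ev_hi"] - summary["ev_median"],
        ]
    ).clip(min=0)
    ax.bar(x, summary["ev_median"], yerr=err, capsize=3, color="#4878a8")
    ax.set_xticks(x)
    ax.set_xticklabels(summary["property"], rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("explained variance (median CV)")
    ax.axhline(0.0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
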