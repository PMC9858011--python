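"""End-to-end orchestration: simulate/load -> preprocess -> difference spectra
-> PCA -> PCA-LDA -> PLS -> consensus WAMACs -> aquagrams.

Stages run per leaf zone in the order of the study's analysis protocol.
``run_pipeline`` is deterministic given (config, seed): every random draw
derives from the config seed, so a rerun reproduces the report
byte-for-byte (timestamps excluded by construction — none are recorded).
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import (
    diffspec,
    lda_classify,
    pca_explore,
    pls_regress,
    synthetic_data,
    wamac_aquagram,
)
from .spectra_io import SpectraSet, read_spectra_csv, trim_range, write_spectra_csv

__all__ = ["default_pipeline_config", "load_pipeline_config", "run_pipeline"]

log = logging.getLogger(__name__)


def default_pipeline_config() -> dict:
    with resources.files("waspmon").joinpath("data/defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_pipeline_config(path=None) -> dict:
    """Load a YAML pipeline config, filling gaps from the shipped defaults."""
    cfg = default_pipeline_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, other: dict) -> dict:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _load_input(cfg: dict, seed: int | None) -> SpectraSet:
    if "input" in cfg and cfg["input"]:
        inp = cfg["input"]
        return read_spectra_csv(inp["path"], inp.get("dialect", "wide"))
    sim = cfg.get("simulate", {}) or {}
    synth = synthetic_data.default_config(
        seed=int(seed if seed is not None else sim.get("seed", 0))
    )
    return synthetic_data.generate(synth)


def run_pipeline(config: dict | None = None, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full workflow; returns a JSON-serialisable run report.

    Writes intermediate artifacts (spectra CSV, peak tables, confusion
    matrices, regression report, WAMAC list, aquagram CSVs) under
    ``out_dir`` when given.  Raises on the first failing stage, naming it;
    artifacts written before the failure are kept.
    """
    cfg = config if config is not None else default_pipeline_config()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"stages": {}, "zones": {}}
    stage = "simulate/load"
    try:
        data = _load_input(cfg, seed)
        report["stages"]["input"] = {"n_spectra": data.n, "n_channels": data.p}
        if out is not None:
            write_spectra_csv(data, out / "spectra.csv", "wide")

        stage = "trim"
        lo, hi = cfg.get("range", [1300, 1600])
        trimmed = trim_range(data, lo, hi)

        evidence = {}
        for zone in cfg.get("zones", ["inner", "outer"]):
            zrep: dict = {}
            zdata = trimmed.zone(zone)
            y = zdata.meta["day"].to_numpy()

            stage = f"diffspec[{zone}]"
            dcfg = cfg["diffspec"]
            diffs = diffspec.difference_spectra(
                trimmed, zone, cfg.get("reference_day", 1), dcfg["pretreat"]
            )
            diff_peaks = [
                diffspec.pick_peaks(
                    d.values,
                    d.grid,
                    dcfg.get("min_rel_magnitude", 0.10),
                    "diff",
                    f"Day {d.day}-Day {d.reference_day}",
                )
                for d in diffs
            ]
            zrep["n_difference_spectra"] = len(diffs)

            stage = f"pca[{zone}]"
            pcfg = cfg["pca"]
            pca = pca_explore.fit_pca(zdata, pcfg.get("k", 10))
            comp = pcfg.get("inspect_component", {}).get(zone, 1)
            comp = min(comp, pca.k)
            pca_peaks = pca_explore.loading_peaks(
                pca, zdata, comp, dcfg.get("min_rel_magnitude", 0.10)
            )
            outlier_mask = pca_explore.flag_outliers(
                pca, zdata, alpha=pcfg.get("outlier_alpha", 0.01)
            )
            zrep["pca"] = {
                "explained_variance_ratio": pca.explained_variance_ratio.round(6).tolist(),
                "inspected_component": int(comp),
                "n_outliers_flagged": int(outlier_mask.sum()),
            }

            stage = f"lda[{zone}]"
            lcfg = cfg["lda"]
            from .preprocess import apply_recipe

            ldata = apply_recipe(zdata, lcfg.get("pretreat", {}).get(zone, []))
            nr_pcs = lcfg.get("nr_pcs")
            if nr_pcs is None:
                nr_pcs = lda_classify.select_nr_pcs(
                    ldata,
                    y,
                    max_pcs=lcfg.get("max_pcs", 30),
                    folds=lcfg.get("folds", 3),
                    seed=int(seed or 0),
                )
            cal, val = lda_classify.lolo_validate(ldata, nr_pcs=nr_pcs)
            model = lda_classify.fit_lda(ldata.absorbance, y, nr_pcs)
            contrib = lda_classify.wavelength_contributions(model)
            lda_peaks = diffspec.pick_peaks(
                contrib, ldata.grid, dcfg.get("min_rel_magnitude", 0.10),
                "lda_contrib", "overall",
            )
            zrep["lda"] = {
                "nr_pcs": int(nr_pcs),
                "calibration_average_accuracy": round(cal.average_accuracy, 2),
                "validation_average_accuracy": round(val.average_accuracy, 2),
            }
            if out is not None:
                cal.to_frame().to_csv(out / f"confusion_cal_{zone}.csv")
                val.to_frame().to_csv(out / f"confusion_val_{zone}.csv")

            stage = f"pls[{zone}]"
            rcfg = cfg["pls"]
            pdata = apply_recipe(zdata, rcfg.get("pretreat", []))
            nr_lv = rcfg.get("nr_lv")
            if nr_lv is None:
                nr_lv = pls_regress.select_nr_lv(pdata, y, max_lv=rcfg.get("max_lv", 12))
            reg = pls_regress.lolo_regress(pdata, y, nr_lv=nr_lv)
            pls_model = pls_regress.fit_pls(pdata.absorbance, y, nr_lv)
            pls_peaks = pls_regress.regression_vector_peaks(
                pls_model, pdata, dcfg.get("min_rel_magnitude", 0.10)
            )
            zrep["pls"] = {
                "nr_lv": int(nr_lv),
                "r2_cal": round(reg.r2_cal, 4),
                "rmse_cal": round(reg.rmse_cal, 4),
                "r2_cv": round(reg.r2_cv, 4),
                "rmse_cv": round(reg.rmse_cv, 4),
                "n_used": reg.n_used,
            }

            stage = f"evidence[{zone}]"
            evidence[zone] = wamac_aquagram.build_evidence(
                diff_peaks + [pca_peaks, lda_peaks, pls_peaks], zone, trimmed.grid
            )
            if out is not None:
                evidence[zone].to_csv(out / f"evidence_{zone}.csv", index=False)
            report["zones"][zone] = zrep

        stage = "wamac"
        wcfg = cfg["wamac"]
        wamacs = wamac_aquagram.select_wamacs(
            evidence.get("inner"),
            evidence.get("outer"),
            min_sources=wcfg.get("min_sources", 2),
            require_both_zones=wcfg.get("require_both_zones", True),
        )
        report["wamacs"] = [round(w, 2) for w in wamacs.wavelengths]
        if out is not None:
            (out / "wamacs.txt").write_text(
                "\n".join(f"{w:.2f}" for w in wamacs.wavelengths) + "\n"
            )

        stage = "aquagram"
        acfg = cfg["aquagram"]
        aquagrams = {}
        for zone in cfg.get("zones", ["inner", "outer"]):
            aq = wamac_aquagram.compute_aquagram(
                trimmed.zone(zone),
                wamacs,
                group_by="day",
                reference_group=cfg.get("reference_day", 1),
                pretreat=acfg.get("pretreat", wamac_aquagram.DEFAULT_AQUAGRAM_PRETREAT),
            )
            aquagrams[zone] = aq
            report["zones"][zone]["aquagram"] = {
                str(g): [round(v, 4) for v in aq.values.loc[g].tolist()]
                for g in aq.groups
            }
            if out is not None:
                aq.values.to_csv(out / f"aquagram_{zone}.csv")
                wamac_aquagram.plot_aquagram(
                    aq, out / f"aquagram_{zone}.png", f"Aquagram ({zone} leaves)"
                )
        if out is not None:
            (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
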