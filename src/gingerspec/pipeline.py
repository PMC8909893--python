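"""End-to-end orchestration of the model grid.

The canonical study design fits, on one shared 80/20 split of the averaged
ROI spectra:

* 8 pre-treatments x {PLSR, LASSO}  -> 16 models without wavelength
  selection, each with its hyperparameter (latent-variable count or
  penalty) chosen by leave-one-out cross-validation on the training split;
* 8 pre-treatments x {β-coefficient, VIP} -> 16 more PLSR models refitted
  on the retained wavelengths only.

That is 32 evaluation rows in canonical mode — the shape of the appendix
model-grid table.  A failing cell is recorded and the grid continues; the
CLI exits non-zero if any cell failed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import ROI, CalibrationFrames, calibrate, crop_roi, mean_spectrum
from .dataset import SpectralDataset
from .evaluation import EvaluationReport, evaluate
from .preprocessing import CANONICAL_TREATMENTS, make_treatment
from .regression import (
    SplitSpec, fit_lasso, fit_plsr, predict, select_alpha_cv, select_lvs_loocv,
    split_dataset,
)
from .selection import beta_select, refit_on_selection, vip_select

__all__ = [
    "GridConfig",
    "GridResult",
    "extract_dataset",
    "run_grid",
    "best_models",
    "export_scatter",
]


def extract_dataset(samples, roi: ROI | None = None) -> SpectralDataset:
    """Calibrate each sample's raw cube, crop the ROI, average the pixel
    spectra, and assemble the sample x band dataset with the ratio response."""
    if not samples:
        raise ValueError("no samples")
    spectra, y, ids = [], [], []
    for s in samples:
        frames = CalibrationFrames(s.white_frame, s.dark_frame)
        cube = calibrate(s.raw_cube, frames)
        if roi is not None:
            cube = crop_roi(cube, roi)
        spec = mean_spectrum(cube)
        spectra.append(spec.values)
        y.append(s.ratio)
        ids.append(s.sample_id)
    return SpectralDataset(np.vstack(spectra), samples[0].raw_cube.wavelengths.copy(),
                           np.array(y), ids)


@dataclass
class GridConfig:
    """Configuration of the model grid."""

    treatments: tuple = CANONICAL_TREATMENTS
    models: tuple = ("plsr", "lasso")
    selection_methods: tuple = ("beta_coefficient", "vip")
    split: SplitSpec = field(default_factory=SplitSpec)
    max_lvs: int = 20
    n_alphas: int = 50
    alpha_min_ratio: float = 1e-4
    sg_window: int = 11
    sg_polyorder_first: int = 2
    sg_polyorder_second: int = 3

    def expected_rows(self) -> int:
        n_t = len(self.treatments)
        return n_t * (len(self.models) + len(self.selection_methods))

    def to_yaml_str(self) -> str:
        d = asdict(self)
        d["treatments"] = list(d["treatments"])
        d["models"] = list(d["models"])
        d["selection_methods"] = list(d["selection_methods"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "split" in d and isinstance(d["split"], dict):
            d["split"] = SplitSpec(**d["split"])
        for key in ("treatments", "models", "selection_methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GridResult:
    """All evaluation rows plus per-family winners and the run manifest."""

    rows: list
    failures: list
    best_by_rpd: dict
    manifest: dict
    models: dict = field(default_factory=dict)   # (treatment, model, selection) -> fitted model

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows])


def _family(row: EvaluationReport) -> str:
    if row.selection_method == "beta_coefficient":
        return "plsr_beta"
    if row.selection_method == "vip":
        return "plsr_vip"
    return row.model_type


def best_models(result: GridResult, criterion: str = "rpd_test") -> dict:
    """Per-family argmax row (``plsr``, ``lasso``, ``plsr_beta``,
    ``plsr_vip``); ties resolve to the earlier row in canonical order."""
    if not result.rows:
        raise ValueError("empty grid")
    best: dict[str, EvaluationReport] = {}
    for row in result.rows:
        fam = _family(row)
        value = getattr(row, criterion)
        if fam not in best or value > getattr(best[fam], criterion):
            best[fam] = row
    return best


def run_grid(dataset: SpectralDataset, config: GridConfig = GridConfig(),
             outdir: str | Path | None = None) -> GridResult:
    """Run the full treatment x model grid on one shared train/test split.

    Returns the 32-row (canonical mode) :class:`GridResult`; when ``outdir``
    is given, writes ``grid_results.csv``, ``best_models.json``,
    ``manifest.json`` and scatter CSVs for the per-family winners.
    """
    if dataset.n_samples < 10:
        raise ValueError(f"need at least 10 samples, got {dataset.n_samples}")
    train, test = split_dataset(dataset, config.split)

    rows: list[EvaluationReport] = []
    failures: list[dict] = []
    fitted: dict = {}
    plsr_by_treatment: dict[str, object] = {}
    treated: dict[str, tuple] = {}

    sg_kw = dict(sg_window=config.sg_window,
                 sg_polyorder_first=config.sg_polyorder_first,
                 sg_polyorder_second=config.sg_polyorder_second)

    for tag in config.treatments:
        try:
            t = make_treatment(tag, **sg_kw)
            Xtr = t.fit_transform(train.spectra).X
            Xte = t.transform(test.spectra).X
            treated[tag] = (Xtr, Xte)
        except Exception as exc:  # record-and-continue: one bad cell must not kill the grid
            failures.append({"treatment": tag, "stage": "preprocess", "error": str(exc)})
            continue

        for model_name in config.models:
            try:
                if model_name == "plsr":
                    j_star, curve = select_lvs_loocv(Xtr, train.y, max_lvs=config.max_lvs)
                    model = fit_plsr(Xtr, train.y, j_star)
                    model.rmsecv_curve = curve
                    hyper = j_star
                    plsr_by_treatment[tag] = model
                elif model_name == "lasso":
                    search = select_alpha_cv(Xtr, train.y, n_alphas=config.n_alphas,
                                             min_ratio=config.alpha_min_ratio)
                    model = fit_lasso(Xtr, train.y, search.alpha)
                    model.alpha_grid, model.cv_rmse = search.alpha_grid, search.cv_rmse
                    hyper = search.alpha
                else:
                    raise ValueError(f"unknown model {model_name!r}")
                report = evaluate(model, Xtr, train.y, Xte, test.y,
                                  treatment=tag, model_type=model_name,
                                  hyperparameter=hyper, n_bands=dataset.n_bands)
                rows.append(report)
                fitted[(tag, model_name, None)] = model
            except Exception as exc:
                failures.append({"treatment": tag, "stage": model_name, "error": str(exc)})

    for tag in config.treatments:
        parent = plsr_by_treatment.get(tag)
        if parent is None or tag not in treated:
            if config.selection_methods:
                failures.append({"treatment": tag, "stage": "selection",
                                 "error": "no parent PLSR fit available"})
            continue
        Xtr, Xte = treated[tag]
        for method in config.selection_methods:
            try:
                if method == "beta_coefficient":
                    sel = beta_select(parent, wavelengths=dataset.wavelengths)
                elif method == "vip":
                    sel = vip_select(parent, wavelengths=dataset.wavelengths)
                else:
                    raise ValueError(f"unknown selection method {method!r}")
                model, report = refit_on_selection(Xtr, train.y, Xte, test.y, sel,
                                                   max_lvs=config.max_lvs, treatment=tag)
                rows.append(report)
                fitted[(tag, "plsr", method)] = (model, sel)
            except Exception as exc:
                failures.append({"treatment": tag, "stage": method, "error": str(exc)})

    best = best_models_safe(rows)
    manifest = {
        "config_hash": hashlib.sha256(config.to_yaml_str().encode()).hexdigest(),
        "split_seed": config.split.seed,
        "n_samples": dataset.n_samples,
        "n_bands": dataset.n_bands,
        "n_rows": len(rows),
        "n_failures": len(failures),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    result = GridResult(rows, failures, {k: v.to_dict() for k, v in best.items()},
                        manifest, fitted)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(outdir / "grid_results.csv", index=False, float_format="%.10g")
        (outdir / "best_models.json").write_text(json.dumps(result.best_by_rpd, indent=2))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for fam, row in best.items():
            key = (row.treatment, "plsr" if row.model_type == "plsr" else row.model_type,
                   row.selection_method)
            entry = fitted.get(key)
            if entry is None:
                continue
            model = entry[0] if isinstance(entry, tuple) else entry
            Xtr, Xte = treated[row.treatment]
            if isinstance(entry, tuple):  # selection model: subset the bands
                cols = entry[1].retained_indices
                Xtr, Xte = Xtr[:, cols], Xte[:, cols]
            export_scatter(model, Xtr, train.y, Xte, test.y,
                           outdir / f"scatter_{fam}.csv")
    return result


def best_models_safe(rows: list) -> dict:
    """best_models over a possibly empty row list (empty grid -> empty dict)."""
    if not rows:
        return {}
    return best_models(GridResult(rows, [], {}, {}))


def export_scatter(model, X_train, y_train, X_test, y_test,
                   path: str | Path | None = None) -> pd.DataFrame:
    """Measured-vs-predicted table for both splits (one row per sample)."""
    frames = []
    for X, y, split in ((X_train, y_train, "train"), (X_test, y_test, "test")):
        frames.append(pd.DataFrame({
            "measured": np.asarray(y, dtype=float),
            "predicted": predict(model, X),
            "split": split,
        }))
    df = pd.concat(frames, ignore_index=True)
    if path is not None:
        df.to_csv(path, index=False, float_format="%.10g")
    return df
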