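"""Wavelength selection for PLSR: β-coefficient thresholding and VIP scores.

Full Vis-NIR spectra are heavily collinear; most bands contribute little.
Two standard reduction rules operate on a fitted PLSR model:

* **β-coefficient rule** — bands whose absolute regression coefficient falls
  below the standard deviation of all coefficients are discarded (large
  positive or negative coefficients carry the information).  The SD is the
  population (1/K) value by default; equality retains the band.
* **VIP rule** — the variable importance in projection accumulates each
  band's share of explained response variance across components,

      VIP_j = sqrt( K · Σ_a SSY_a (w_ja / ||w_a||)² / Σ_a SSY_a ),

  with ``SSY_a = q_a² t_a' t_a``.  The scores are mean-square normalised,
  ``(1/K) Σ_j VIP_j² = 1``, which makes 1 the natural retention threshold.

Selection is always computed from the training fit; the retained bands are
then applied to both splits and the PLSR refitted (latent-variable count
re-selected by leave-one-out on the reduced matrix).  LASSO needs neither
rule — its penalty already zeroes coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import EvaluationReport, evaluate
from .regression import PLSRModel, fit_plsr, select_lvs_loocv

__all__ = ["SelectionResult", "beta_select", "vip_scores", "vip_select", "refit_on_selection"]


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection rule."""

    method: str                       # "beta_coefficient" or "vip"
    scores: np.ndarray                # per-band |beta| or VIP
    threshold: float
    retained_indices: np.ndarray
    retained_wavelengths: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return self.retained_indices.size


def beta_select(model: PLSRModel, wavelengths=None, ddof: int = 0) -> SelectionResult:
    """Retain bands with ``|beta_j|`` at least the SD of all coefficients.

    ``ddof=0`` (population SD) is the default; the retained set is invariant
    under a global sign flip or rescaling of the coefficient vector.
    """
    beta = np.asarray(model.coef, dtype=float)
    scores = np.abs(beta)
    threshold = float(beta.std(ddof=ddof))
    retained = np.flatnonzero(scores >= threshold)
    if retained.size == 0:
        raise ValueError(
            "beta-coefficient rule discarded every band; the coefficient "
            "vector is degenerate — review the threshold or the fit"
        )
    wl = None if wavelengths is None else np.asarray(wavelengths, dtype=float)[retained]
    return SelectionResult("beta_coefficient", scores, threshold, retained, wl)


def vip_scores(model: PLSRModel) -> np.ndarray:
    """Variable importance in projection for a single-response PLSR fit."""
    W = model.weights          # K x J, unit-norm columns from NIPALS
    T = model.x_scores
    q = model.y_loadings
    k = W.shape[0]
    ssy = q**2 * np.einsum("ij,ij->j", T, T)      # explained response variance per LV
    total = float(ssy.sum())
    if total == 0:
        raise ValueError("model explains no response variance; VIP undefined")
    wnorm2 = np.sum(W**2, axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (W**2 / wnorm2) @ ssy
    return np.sqrt(k * contrib / total)


def vip_select(model: PLSRModel, threshold: float = 1.0, wavelengths=None) -> SelectionResult:
    """Retain bands with VIP ≥ ``threshold`` (default 1).

    Because ``(1/K) Σ VIP² = 1``, at threshold 1 at least one band always
    survives; an empty retention can only arise from a larger threshold and
    raises.
    """
    scores = vip_scores(model)
    retained = np.flatnonzero(scores >= threshold)
    if retained.size == 0:
        raise ValueError(f"VIP threshold {threshold} retained no bands")
    wl = None if wavelengths is None else np.asarray(wavelengths, dtype=float)[retained]
    return SelectionResult("vip", scores, float(threshold), retained, wl)


def refit_on_selection(X_train, y_train, X_test, y_test, result: SelectionResult,
                       max_lvs: int = 20, treatment: str = "") -> tuple[PLSRModel, EvaluationReport]:
    """Refit PLSR on the retained bands and evaluate both splits.

    The latent-variable count is re-selected by leave-one-out on the reduced
    training matrix; the test split never influences retention or the refit.
    """
    from .preprocessing import SpectraMatrix

    if isinstance(X_train, SpectraMatrix):
        X_train = X_train.X
    if isinstance(X_test, SpectraMatrix):
        X_test = X_test.X
    cols = result.retained_indices
    Xtr = np.asarray(X_train, dtype=float)[:, cols]
    Xte = np.asarray(X_test, dtype=float)[:, cols]
    j_star, curve = select_lvs_loocv(Xtr, y_train, max_lvs=max_lvs)
    model = fit_plsr(Xtr, y_train, j_star)
    model.rmsecv_curve = curve
    report = evaluate(
        model, Xtr, y_train, Xte, y_test,
        treatment=treatment, model_type="plsr", hyperparameter=j_star,
        selection_method=result.method, n_bands=int(cols.size),
    )
    return model, report
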