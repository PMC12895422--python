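"""Evaluation, perturbation-sensitivity and calibration machinery.

* ``l1_deviation`` — the pooled mean absolute deviation over the six
  excited-state energies,
  L1 = (1/(6·N)) Σ_n Σ_i |ΔE_Sn(i)| + |ΔE_Tn(i)|, n = 1..3.
* ``per_state_metrics`` — MAE, Pearson r, signed-error mean/std,
  directional exceedance probabilities P(error > t) / P(error < −t) and
  Q–Q points against a fitted normal, for each state and each of the
  three key gaps.
* ``apply_perturbation`` / ``percent_delta_l1`` — channel-wise or
  element-wise descriptor perturbations and the resulting percentage
  change of the L1 deviation,
  %ΔL1 = 100 · (L1_perturbed − L1) / L1.
* ``two_point_calibration`` — an affine map fitted exactly through two
  (predicted, experimental) anchor pairs, applied to the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .image import ImageDataset
from .model import GAP_MATRIX, OUTPUT_ORDER

__all__ = ["MetricsReport", "PerturbationSpec", "l1_deviation",
           "per_state_metrics", "apply_perturbation", "percent_delta_l1",
           "two_point_calibration", "CalibrationResult"]

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3)  # eV
GAP_NAMES = ("dE_S1-T1", "dE_S2-S1", "dE_T2-T1")
_CHANNEL_INDEX = {"epsilon": 0, "v_hole": 1, "v_particle": 2}


def l1_deviation(pred: np.ndarray, ref: np.ndarray) -> float:
    """Pooled mean |error| over six states and all molecules, in eV."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 2 or pred.shape[1] != 6:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(ref))):
        raise ValueError("non-finite energies")
    return float(np.mean(np.abs(pred - ref)))


@dataclass
class MetricsReport:
    """Per-state diagnostics plus the pooled L1 deviation (all in eV)."""

    l1_deviation: float
    per_state: dict  # name -> {mae, r, mean, std, exceedance{t: (P>, P<)}, qq}
    thresholds: tuple = DEFAULT_THRESHOLDS
    n_samples: int = 0

    def to_dict(self) -> dict:
        out = {"l1_deviation_eV": self.l1_deviation,
               "n_samples": self.n_samples, "per_state": {}}
        for name, st in self.per_state.items():
            out["per_state"][name] = {
                "mae_eV": st["mae"], "pearson_r": st["r"],
                "error_mean_eV": st["mean"], "error_std_eV": st["std"],
                "exceedance": {f"{t:g}": {"P(err>t)": p[0], "P(err<-t)": p[1]}
                               for t, p in st["exceedance"].items()},
            }
        return out


def _one_state(pred: np.ndarray, ref: np.ndarray,
               thresholds: Sequence[float]) -> dict:
    err = pred - ref
    n = len(err)
    mae = float(np.mean(np.abs(err)))
    if n >= 2 and np.std(pred) > 0 and np.std(ref) > 0:
        r = float(stats.pearsonr(pred, ref)[0])
    else:
        r = float("nan")
    mean = float(np.mean(err))
    std = float(np.std(err, ddof=1)) if n >= 2 else 0.0
    exceed = {float(t): (float(np.mean(err > t)), float(np.mean(err < -t)))
              for t in thresholds}
    # Q-Q points against the normal fitted by sample mean/std
    q = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(q, loc=mean, scale=std if std > 0 else 1.0)
    qq = np.column_stack([theo, np.sort(err)])
    return {"mae": mae, "r": r, "mean": mean, "std": std,
            "exceedance": exceed, "qq": qq}


def per_state_metrics(pred: np.ndarray, ref: np.ndarray,
                      thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                      ) -> MetricsReport:
    """Diagnostics for each of the six states and the three key gaps."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 2 or pred.shape[1] != 6:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    report: dict = {}
    for j, name in enumerate(OUTPUT_ORDER):
        report[name] = _one_state(pred[:, j], ref[:, j], thresholds)
    gaps_pred = pred @ GAP_MATRIX.T
    gaps_ref = ref @ GAP_MATRIX.T
    for j, name in enumerate(GAP_NAMES):
        report[name] = _one_state(gaps_pred[:, j], gaps_ref[:, j], thresholds)
    return MetricsReport(l1_deviation=l1_deviation(pred, ref),
                         per_state=report, thresholds=tuple(thresholds),
                         n_samples=len(pred))


@dataclass(frozen=True)
class PerturbationSpec:
    """A descriptor perturbation.

    ``channel_scale`` multiplies every pixel of one channel by (1 + δ),
    leaving the other channels untouched. ``element_scale`` multiplies the
    single diagonal ε pixel at ``element_index`` by (1 + δ) — the V
    channels are untouched, matching the δ·ε_p notation; the fixed
    HOMO/LUMO image alignment makes a shared pixel index meaningful across
    a dataset.
    """

    mode: str
    channel: str = "epsilon"
    delta: float = 0.05
    element_index: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("channel_scale", "element_scale"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.mode == "channel_scale" and self.channel not in _CHANNEL_INDEX:
            raise ValueError(f"unknown channel {self.channel!r}")


def apply_perturbation(dataset: ImageDataset,
                       spec: PerturbationSpec) -> ImageDataset:
    """Return a perturbed copy of the dataset (δ = 0 is a bitwise identity)."""
    out = dataset.copy()
    factor = 1.0 + spec.delta
    if spec.mode == "channel_scale":
        ci = _CHANNEL_INDEX[spec.channel]
        for im in out.images:
            im.pixels[ci] *= factor
    else:
        p = spec.element_index
        if not 0 <= p < dataset.n_mo:
            raise ValueError(f"element_index {p} outside image of edge "
                             f"{dataset.n_mo}")
        for im in out.images:
            im.pixels[0, p, p] *= factor
    return out


def percent_delta_l1(results, dataset: ImageDataset,
                     spec: PerturbationSpec) -> float:
    """%ΔL1 of the model's predictions under a descriptor perturbation.

    ``results`` is anything with a ``predict(pixels) -> (n, 6)`` method.
    """
    if dataset.targets is None:
        raise ValueError("dataset has no reference targets")
    base = l1_deviation(results.predict(dataset), dataset.targets)
    if base == 0:
        raise ZeroDivisionError("unperturbed L1 deviation is zero")
    pert = l1_deviation(results.predict(apply_perturbation(dataset, spec)),
                        dataset.targets)
    return 100.0 * (pert - base) / base


@dataclass
class CalibrationResult:
    """E_cal = slope · E_pred + intercept, anchored on two compounds."""

    slope: float
    intercept: float
    calibrated: np.ndarray
    anchor_indices: Optional[tuple] = None
    mae: Optional[float] = None  # vs experiment, anchors excluded

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def two_point_calibration(pred_es1: Sequence[float],
                          anchors: Sequence[tuple[float, float]],
                          experimental: Optional[Sequence[float]] = None,
                          anchor_indices: Optional[tuple[int, int]] = None
                          ) -> CalibrationResult:
    """Affine calibration through two (predicted, experimental) anchors.

    The line passes exactly through both anchor pairs; when a full
    experimental vector is supplied, the MAE excludes the anchor entries.
    """
    (x1, y1), (x2, y2) = anchors
    if x1 == x2:
        raise ValueError("anchor predictions are identical; no unique line")
    slope = (y2 - y1) / (x2 - x1)
    intercept = y1 - slope * x1
    pred = np.asarray(pred_es1, dtype=float)
    calibrated = slope * pred + intercept
    mae = None
    if experimental is not None:
        exp = np.asarray(experimental, dtype=float)
        mask = np.ones(len(exp), dtype=bool)
        if anchor_indices is not None:
            mask[list(anchor_indices)] = False
        if mask.any():
            mae = float(np.mean(np.abs(calibrated[mask] - exp[mask])))
    return CalibrationResult(slope=slope, intercept=intercept,
                             calibrated=calibrated,
                             anchor_indices=anchor_indices, mae=mae)
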