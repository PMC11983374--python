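"""Deviation metrics and evaluation reports.

Accuracy is scored as the relative difference between predicted and
certified values for concentrations and density, and as the absolute
deviation (um) for the surface position.  Trace elements certified below
0.1% are scored separately by order-of-magnitude agreement, since the
relative deviation is unstable at trace level; elements certified at
exactly 0.1% fall in the "over 0.1%" stratum.  Concentrations predicted
for elements that are certified absent are accumulated into a
nonpresent-element sum per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import QuantPrediction
from .samples import Composition

__all__ = [
    "CONCENTRATION_STRATUM_BOUNDARY",
    "relative_deviation",
    "nonpresent_sum",
    "EvalReport",
    "build_report",
]

#: mass-fraction boundary between "trace" and "quantifiable" strata (0.1%)
CONCENTRATION_STRATUM_BOUNDARY = 1e-3


def relative_deviation(predicted, certified) -> np.ndarray | float:
    """|predicted - certified| / certified; requires certified > 0.

    Vectorized over arrays; the certified = 0 case is handled by the
    nonpresent-element accounting instead.
    """
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(certified, dtype=float)
    if np.any(c <= 0):
        raise ValueError("relative deviation requires certified > 0")
    out = np.abs(p - c) / c
    return float(out) if out.ndim == 0 else out


def nonpresent_sum(pred: QuantPrediction, truth: Composition) -> float:
    """Summed predicted mass fraction over elements certified absent."""
    total = 0.0
    for z, w_pred in zip(pred.elements, pred.concentrations):
        if truth.fraction(z) == 0.0:
            total += float(w_pred)
    return total


@dataclass
class EvalReport:
    """Per-(sample, element) metric table plus summary statistics."""

    per_element: pd.DataFrame  # sample, Z, certified, predicted, rel_dev, log10_ratio, stratum
    per_sample: pd.DataFrame  # sample, density dev, x0 dev, nonpresent sum
    summary: dict

    def to_json(self) -> str:
        return json.dumps(self.summary, indent=2)

    def save(self, prefix) -> None:
        self.per_element.to_csv(f"{prefix}_elements.csv", index=False)
        self.per_sample.to_csv(f"{prefix}_samples.csv", index=False)
        with open(f"{prefix}_summary.json", "w") as fh:
            fh.write(self.to_json())


def build_report(
    preds: list[QuantPrediction],
    truths: list[Composition],
    x0_true: list[float] | None = None,
    density_tolerance: float = 0.30,
    x0_tolerance_um: float = 10.0,
) -> EvalReport:
    """Score aggregated predictions against ground truth.

    ``x0_true`` may be omitted when surface positions are not part of
    the ground truth (x0 deviations are then NaN).
    """
    if len(preds) != len(truths):
        raise ValueError("one truth is required per prediction")
    el_rows, s_rows = [], []
    for i, (p, t) in enumerate(zip(preds, truths)):
        for z, w_pred in zip(p.elements, p.concentrations):
            w_true = t.fraction(z)
            if w_true <= 0:
                continue
            stratum = (
                "over_0.1%"
                if w_true >= CONCENTRATION_STRATUM_BOUNDARY
                else "under_0.1%"
            )
            el_rows.append(
                {
                    "sample": i,
                    "Z": z,
                    "certified": w_true,
                    "predicted": float(w_pred),
                    "rel_dev": relative_deviation(max(float(w_pred), 0.0), w_true),
                    "log10_ratio": float(
                        np.log10(max(w_pred, 1e-12) / w_true)
                    ),
                    "stratum": stratum,
                }
            )
        row = {
            "sample": i,
            "density_certified": t.density,
            "density_predicted": p.density,
            "density_rel_dev": relative_deviation(p.density, t.density),
            "nonpresent_sum": nonpresent_sum(p, t),
        }
        if x0_true is not None:
            row["x0_certified"] = x0_true[i]
            row["x0_predicted"] = p.x0
            row["x0_abs_dev_um"] = abs(p.x0 - x0_true[i])
        s_rows.append(row)

    per_element = pd.DataFrame(el_rows)
    per_sample = pd.DataFrame(s_rows)

    over = per_element[per_element["stratum"] == "over_0.1%"] if len(el_rows) else per_element
    under = per_element[per_element["stratum"] == "under_0.1%"] if len(el_rows) else per_element
    summary = {
        "n_samples": len(preds),
        "n_element_pairs": len(per_element),
        "median_conc_rel_dev_over_0.1%": _safe_median(over.get("rel_dev")),
        "median_conc_rel_dev_under_0.1%": _safe_median(under.get("rel_dev")),
        "frac_under_0.1%_within_order_of_magnitude": (
            float((under["log10_ratio"].abs() <= 1.0).mean()) if len(under) else None
        ),
        "median_density_rel_dev": _safe_median(per_sample.get("density_rel_dev")),
        "frac_density_dev_below_tolerance": float(
            (per_sample["density_rel_dev"] < density_tolerance).mean()
        ),
        "median_nonpresent_sum": _safe_median(per_sample.get("nonpresent_sum")),
    }
    if x0_true is not None:
        summary["median_x0_abs_dev_um"] = _safe_median(per_sample.get("x0_abs_dev_um"))
        summary["frac_x0_within_tolerance"] = float(
            (per_sample["x0_abs_dev_um"] <= x0_tolerance_um).mean()
        )
    return EvalReport(per_element, per_sample, summary)


def _safe_median(col) -> float | None:
    if col is None or len(col) == 0:
        return None
    return float(np.median(col))
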