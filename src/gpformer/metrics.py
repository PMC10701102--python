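"""Evaluation metrics for phenotype prediction: MAE, PCC and the
consistent index (CI).

CI combines trend accuracy (Pearson correlation) and numerical accuracy
(mean absolute error) into one scalar:

    CI = rho_c / (MAE / mean(|y|) + 1)

where rho_c is the Pearson correlation between observed and predicted
phenotypes and mean(|y|) is the mean absolute observed value of the test
set.  CI equals PCC at zero error, decreases as MAE grows, and satisfies
|CI| <= |PCC| since the denominator is at least 1.  Larger is better.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D vectors of equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("metrics require finite inputs")
    return y_true, y_pred


def mae(y_true, y_pred) -> float:
    """Mean absolute error (1/m) sum |f(x_i) - y_i| over the test set."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(y_pred - y_true)))


def pcc(y_true, y_pred) -> float:
    """Pearson product-moment correlation; raises on zero-variance input."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if np.std(y_true) == 0.0 or np.std(y_pred) == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def ci(y_true, y_pred) -> float:
    """Consistent index: PCC discounted by normalized MAE (see module doc)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    scale = float(np.mean(np.abs(y_true)))
    if scale == 0.0:
        raise ValueError("CI undefined when mean(|y|) is zero")
    return pcc(y_true, y_pred) / (mae(y_true, y_pred) / scale + 1.0)


@dataclass
class MetricsReport:
    """Per-fold and fold-averaged (MAE, PCC, CI) for one trait."""

    trait_name: str
    per_fold: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    @property
    def mean(self) -> tuple[float, float, float]:
        arr = np.asarray(self.per_fold, dtype=np.float64)
        return tuple(arr.mean(axis=0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_fold, columns=["MAE", "PCC", "CI"])
        df.insert(0, "fold", np.arange(self.n_folds))
        mean_row = pd.DataFrame(
            [["mean", *self.mean]], columns=["fold", "MAE", "PCC", "CI"]
        )
        return pd.concat([df, mean_row], ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_json(self, path: str | Path) -> None:
        m = self.mean
        payload = {
            "trait": self.trait_name,
            "n_folds": self.n_folds,
            "per_fold": [dict(zip(("MAE", "PCC", "CI"), f)) for f in self.per_fold],
            "mean": {"MAE": m[0], "PCC": m[1], "CI": m[2]},
        }
        Path(path).write_text(json.dumps(payload, indent=2))
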