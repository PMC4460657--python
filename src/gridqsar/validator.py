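"""Model-robustness validation: Y-randomization Z-scores with normal-curve
areas and empirical p-values, plus observed-vs-predicted fitness data."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chem_io import ActivityRecord
from .splitter import SplitResult
from .sw_mlr import QsarModel, fit_qsar, loo_q2, pred_r2

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 100


@dataclass
class RandomizationReport:
    """Null distributions from Y-shuffled refits and the real model's
    Z-scores / normal-curve areas / empirical p-values against them."""

    n_permutations: int
    actual: dict[str, float]
    permuted: dict[str, list[float]]
    z_scores: dict[str, float] = field(default_factory=dict)
    areas_percent: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "actual": self.actual,
            "z_scores": self.z_scores,
            "areas_percent": self.areas_percent,
            "p_values": self.p_values,
            "permuted": self.permuted,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def normal_area(z: float) -> float:
    """Percent area under the standard normal curve to the left of z."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(100.0 * norm.cdf(z))


def _score_statistics(
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    x_test: pd.DataFrame | None,
    y_test: np.ndarray | None,
    f_enter: float,
    max_terms: int | None,
) -> dict[str, float]:
    model = fit_qsar(x_train, y_train, f_enter=f_enter, max_terms=max_terms)
    stats = {"r2": model.r2 if model.selected else 0.0}
    if model.selected:
        stats["q2"] = model.q2
    else:
        # intercept-only model: PRESS with mean of remaining rows
        n = len(y_train)
        loo_means = (y_train.sum() - y_train) / (n - 1)
        press = float(np.sum((y_train - loo_means) ** 2))
        sst = float(np.sum((y_train - y_train.mean()) ** 2))
        stats["q2"] = 1.0 - press / sst if sst > 0 else 0.0
    if x_test is not None and y_test is not None and len(y_test):
        try:
            pr2, _ = pred_r2(model, x_test, y_test)
        except (KeyError, ValueError):
            pr2 = float("nan")
        stats["pred_r2"] = pr2
    return stats


def y_randomization(
    data: pd.DataFrame,
    activities: Sequence[ActivityRecord],
    split: SplitResult,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    f_enter: float = 6.0,
    max_terms: int | None = None,
) -> RandomizationReport:
    """Shuffle training activities (test labels untouched), re-run the FULL
    stepwise pipeline per permutation, and locate the real statistics in the
    null: Z_s = (s_actual − mean(s_perm))/sd(s_perm), empirical
    p = (1 + #{s_perm ≥ s_actual})/(1 + n_permutations)."""
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    if seed is None:
        raise ValueError("y_randomization requires an explicit seed")
    rng = np.random.default_rng(seed)
    act = {r.compound_id: r.pIC50 for r in activities}
    x_train = data.loc[split.training_ids]
    y_train = np.array([act[c] for c in split.training_ids])
    have_test = bool(split.test_ids)
    x_test = data.loc[split.test_ids] if have_test else None
    y_test = np.array([act[c] for c in split.test_ids]) if have_test else None

    actual = _score_statistics(x_train, y_train, x_test, y_test, f_enter, max_terms)
    permuted: dict[str, list[float]] = {k: [] for k in actual}
    for _ in range(n_permutations):
        y_perm = rng.permutation(y_train)
        stats = _score_statistics(x_train, y_perm, x_test, y_test, f_enter, max_terms)
        for k in permuted:
            permuted[k].append(stats.get(k, float("nan")))

    report = RandomizationReport(
        n_permutations=n_permutations, actual=actual, permuted=permuted, seed=seed
    )
    for name, values in permuted.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            raise ValueError(f"too few finite permuted values for {name}")
        sd = float(arr.std(ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate null distribution for {name}")
        z = (actual[name] - float(arr.mean())) / sd
        report.z_scores[name] = z
        report.areas_percent[name] = normal_area(z)
        report.p_values[name] = float(
            (1 + np.sum(arr >= actual[name])) / (1 + len(arr))
        )
    return report


def fitness_data(
    model: QsarModel,
    data: pd.DataFrame,
    activities: Sequence[ActivityRecord],
    split: SplitResult,
) -> pd.DataFrame:
    """Observed vs predicted activity per compound, tagged with set
    membership — the data behind fitness scatter / radar plots."""
    act = {r.compound_id: r.pIC50 for r in activities}
    rows = []
    for cid in list(split.training_ids) + list(split.test_ids):
        label = "train" if cid in set(split.training_ids) else "test"
        rows.append(
            {
                "compound_id": cid,
                "set": label,
                "observed": act[cid],
                "predicted": model.predict(data.loc[cid]),
            }
        )
    return pd.DataFrame(rows)


def recompute_external_stats(
    model: QsarModel,
    data: pd.DataFrame,
    activities: Sequence[ActivityRecord],
    split: SplitResult,
) -> QsarModel:
    """Fill in pred_r² / pred_r²_se of a fitted model from the test set."""
    if not split.test_ids:
        return model
    act = {r.compound_id: r.pIC50 for r in activities}
    y_test = np.array([act[c] for c in split.test_ids])
    model.pred_r2, model.pred_r2_se = pred_r2(model, data.loc[split.test_ids], y_test)
    return model
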