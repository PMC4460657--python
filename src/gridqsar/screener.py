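"""Library screening: predicted activity for each external compound plus a
signed applicability-domain (extrapolation) score.

The extrapolation score of a compound is the range-normalized excursion of
its worst-offending selected descriptor: for training range [m, M] of width
w, a value above M scores (x − M)/w, below m scores (x − m)/w (negative),
inside scores 0; the signed score of maximum magnitude over the selected
descriptors is reported.  0 therefore means "inside the training domain on
every selected descriptor"."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .descriptor_table import FieldDescriptorMatrix
from .sw_mlr import QsarModel


@dataclass
class ScreenResult:
    compound_id: str
    predicted_pIC50: float
    extrapolation: float
    out_of_range: dict[str, float] = field(default_factory=dict)


def extrapolation_score(
    model: QsarModel, x: Mapping[str, float]
) -> tuple[float, dict[str, float]]:
    """Signed worst-descriptor excursion from the training ranges (see
    module doc).  Also returns the per-descriptor nonzero excursions."""
    if not model.selected:
        return 0.0, {}
    if not model.training_ranges:
        raise ValueError("model carries no training ranges")
    excursions: dict[str, float] = {}
    worst = 0.0
    for name in model.selected:
        lo, hi = model.training_ranges[name]
        width = hi - lo
        if width <= 0:
            raise ValueError(f"zero-width training range for descriptor {name!r}")
        try:
            v = float(x[name])
        except (KeyError, IndexError, TypeError):
            raise KeyError(f"missing descriptor {name!r} in input vector") from None
        if v > hi:
            d = (v - hi) / width
        elif v < lo:
            d = (v - lo) / width
        else:
            d = 0.0
        if d != 0.0:
            excursions[name] = d
        if abs(d) > abs(worst):
            worst = d
    return worst, excursions


def screen_library(
    model: QsarModel, library_matrix: FieldDescriptorMatrix
) -> list[ScreenResult]:
    """Predict every library compound and rank by descending predicted
    activity (ties by compound id).  The library must carry the same grid
    provenance hash as the model."""
    if model.grid_hash and library_matrix.grid_hash and model.grid_hash != library_matrix.grid_hash:
        raise ValueError(
            f"grid provenance mismatch: model {model.grid_hash} vs library "
            f"{library_matrix.grid_hash}; descriptors are not comparable"
        )
    missing = [n for n in model.selected if n not in library_matrix.descriptor_names]
    if missing:
        raise KeyError(f"library matrix lacks selected descriptor {missing[0]!r}")
    predictions = model.predict_matrix(library_matrix.data)
    results = []
    for cid in library_matrix.compound_ids:
        score, detail = extrapolation_score(model, library_matrix.data.loc[cid])
        results.append(
            ScreenResult(
                compound_id=cid,
                predicted_pIC50=float(predictions.loc[cid]),
                extrapolation=score,
                out_of_range=detail,
            )
        )
    results.sort(key=lambda r: (-r.predicted_pIC50, r.compound_id))
    return results


def filter_hits(
    results: Sequence[ScreenResult],
    min_activity: float = 8.0,
    extrapolation_bounds: tuple[float, float] = (-1.0, 1.0),
) -> list[ScreenResult]:
    """Keep results with prediction > min_activity and extrapolation strictly
    inside the bounds, preserving order."""
    lo, hi = extrapolation_bounds
    if lo > hi:
        raise ValueError("extrapolation bounds out of order")
    return [
        r for r in results
        if r.predicted_pIC50 > min_activity and lo < r.extrapolation < hi
    ]


def write_hits(results: Iterable[ScreenResult], path: str | Path) -> None:
    """Ranked hits CSV: rank, compound_id, predicted_pIC50, extrapolation."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "compound_id", "predicted_pIC50", "extrapolation"])
        for rank, r in enumerate(results, start=1):
            writer.writerow([rank, r.compound_id, f"{r.predicted_pIC50:.4f}", f"{r.extrapolation:.4f}"])
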