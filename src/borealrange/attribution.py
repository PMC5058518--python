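"""Counterfactual attribution of between-decade probability change.

For a pair of decades, two "no-change" landscapes are formed: one keeps the
previous decade's climate with the current decade's land use/cover, the
other keeps the previous land use/cover with the current climate.  The
difference between the actual current-decade probability and each
counterfactual probability isolates the contribution of the factor that was
allowed to change; the driver label per cell is the factor with the larger
absolute contribution.  Because the model is nonlinear on the probability
scale, the two contributions need not sum to the actual change — all three
deltas are reported so the discrepancy stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import DecadalLandscape
from .sdm import PredictionGrid, SDMCoefficients, classify, predict_probability

__all__ = [
    "CLIMATE_COLUMNS",
    "LANDUSE_COLUMNS",
    "AttributionGrid",
    "counterfactual_landscape",
    "attribute",
    "summarize_attribution",
]

CLIMATE_COLUMNS = ["wsi_mean", "gs_mean"]
LANDUSE_COLUMNS = ["prop_deciduous", "prop_wetland", "prop_footprint"]


def _check_same_grid(prev: DecadalLandscape, curr: DecadalLandscape) -> None:
    if not np.array_equal(prev.cell_ids, curr.cell_ids):
        raise ValueError("landscapes are on different grids")


def counterfactual_landscape(
    prev: DecadalLandscape, curr: DecadalLandscape, hold: str
) -> DecadalLandscape:
    """Landscape with one factor frozen at the previous decade.

    ``hold='climate'`` keeps the previous decade's climate means with the
    current land use/cover (the no-climate-change scenario);
    ``hold='land_use'`` keeps the previous land use/cover with the current
    climate.
    """
    _check_same_grid(prev, curr)
    if hold == "climate":
        frozen = CLIMATE_COLUMNS
    elif hold == "land_use":
        frozen = LANDUSE_COLUMNS
    else:
        raise ValueError(f"hold must be 'climate' or 'land_use', got {hold!r}")
    frame = curr.frame.copy()
    frame[frozen] = prev.frame[frozen]
    return DecadalLandscape(curr.decade, frame)


@dataclass
class AttributionGrid:
    """Per-cell change decomposition for a pair of decades.

    ``frame`` columns: p_prev, p_curr, delta_actual, delta_climate,
    delta_landuse, driver ('climate' | 'land_use' | 'none'), tie,
    crossed_threshold, crossing_direction ('gain' | 'loss' | ''),
    crossing_driver.
    """

    decade_pair: tuple[int, int]
    threshold: float
    frame: pd.DataFrame


def attribute(
    prev: DecadalLandscape,
    curr: DecadalLandscape,
    coef: SDMCoefficients | None = None,
    threshold: float = 0.73,
) -> AttributionGrid:
    """Label each cell's dominant driver of probability change.

    delta_climate = p(curr) − p(climate held at prev);
    delta_landuse = p(curr) − p(land use held at prev).
    The driver is the factor with the larger |delta| (ties, which have
    measure zero on continuous inputs, go to climate deterministically and
    are flagged); 'none' when both deltas are exactly zero.  Cells whose
    presence classification changes between the decades carry the crossing
    direction and driver.
    """
    _check_same_grid(prev, curr)
    coef = coef or SDMCoefficients()
    p_prev = predict_probability(prev, coef).probability
    p_curr = predict_probability(curr, coef).probability
    p_hold_climate = predict_probability(
        counterfactual_landscape(prev, curr, "climate"), coef
    ).probability
    p_hold_landuse = predict_probability(
        counterfactual_landscape(prev, curr, "land_use"), coef
    ).probability

    d_climate = p_curr - p_hold_climate
    d_landuse = p_curr - p_hold_landuse
    abs_c, abs_l = d_climate.abs(), d_landuse.abs()

    driver = np.where(
        (abs_c == 0) & (abs_l == 0), "none", np.where(abs_c >= abs_l, "climate", "land_use")
    )
    tie = (abs_c == abs_l) & (abs_c > 0)

    pres_prev = classify(PredictionGrid(prev.decade, pd.DataFrame({"probability": p_prev})), threshold)
    pres_curr = classify(PredictionGrid(curr.decade, pd.DataFrame({"probability": p_curr})), threshold)
    crossed = pres_prev != pres_curr
    direction = np.where(crossed & pres_curr, "gain", np.where(crossed, "loss", ""))
    crossing_driver = np.where(crossed, driver, "none")

    frame = pd.DataFrame(
        {
            "p_prev": p_prev,
            "p_curr": p_curr,
            "delta_actual": p_curr - p_prev,
            "delta_climate": d_climate,
            "delta_landuse": d_landuse,
            "driver": driver,
            "tie": tie,
            "crossed_threshold": crossed,
            "crossing_direction": direction,
            "crossing_driver": crossing_driver,
        },
        index=p_curr.index,
    )
    return AttributionGrid((prev.decade, curr.decade), threshold, frame)


def summarize_attribution(attr: AttributionGrid) -> dict:
    """Tally drivers over cells with increased probability and over crossings.

    Percentages are over cells whose actual probability increased (the
    area-of-increase convention); zero denominators are flagged rather than
    silently divided through.
    """
    f = attr.frame
    increased = f[f["delta_actual"] > 0]
    gains = f[(f["crossing_direction"] == "gain")]
    losses = f[(f["crossing_direction"] == "loss")]

    def tally(sub: pd.DataFrame) -> dict:
        counts = sub["driver"].value_counts().to_dict()
        n = len(sub)
        return {
            "n": n,
            "climate": int(counts.get("climate", 0)),
            "land_use": int(counts.get("land_use", 0)),
            "pct_climate": (100.0 * counts.get("climate", 0) / n) if n else float("nan"),
            "pct_land_use": (100.0 * counts.get("land_use", 0) / n) if n else float("nan"),
        }

    return {
        "decade_pair": attr.decade_pair,
        "threshold": attr.threshold,
        "n_cells": int(len(f)),
        "increase": tally(increased),
        "crossings_gain": tally(gains),
        "crossings_loss": tally(losses),
        "n_ties": int(f["tie"].sum()),
        "empty_denominator": bool(len(increased) == 0),
    }
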