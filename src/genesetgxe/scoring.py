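"""Harsh-parenting scoring, parent pooling and outcome imputation.

Harsh-parenting items are parent-reported discipline frequencies on a 0-5
scale ("never" .. "five times or more").  Because the upper categories
are rare they are collapsed (0 -> 0, 1 -> 1, >= 2 -> 2); the
high-prevalence "shouted or screamed" item is dropped; the remaining five
collapsed items are summed (range 0-10) and the exposure dichotomy is
harsh iff the sum is >= 1.  Pooling across parents marks a child exposed
if either parent reports harsh discipline.

Missing externalizing scores at the main assessment are completed by
regression imputation from the scores collected at the two earlier waves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SHOUTED_INDEX

_N_ITEMS = 6


def collapse_item(raw: np.ndarray) -> np.ndarray:
    """Collapse the 0-5 frequency scale to {0, 1, 2} (>= 2 -> 2)."""
    out = np.minimum(raw, 2.0)
    out[np.isnan(raw)] = np.nan
    return out


def score_harsh_parenting(
    items, parent: str = "father", shouted_index: int = SHOUTED_INDEX
) -> pd.DataFrame:
    """Score six raw discipline items into the harsh-parenting assignment.

    ``items`` is (n, 6) with raw frequencies 0-5 (NaN allowed).  Returns a
    DataFrame with the five collapsed retained items, ``sum_score`` (0-10)
    and ``group`` ('harsh' iff sum >= 1); any missing retained item leaves
    the assignment undefined (NaN group) and the sample is excluded from
    that parent's analysis downstream.  The dropped item never contributes.
    """
    if isinstance(items, pd.DataFrame):
        index = items.index
        items = items.to_numpy(dtype=float)
    else:
        items = np.asarray(items, dtype=float)
        index = pd.RangeIndex(items.shape[0])
    if items.ndim != 2 or items.shape[1] != _N_ITEMS:
        raise ValueError(f"expected (n, {_N_ITEMS}) item matrix")
    valid = np.isnan(items) | ((items >= 0) & (items <= 5))
    if not valid.all():
        raise ValueError("raw item scores must lie on the 0-5 scale")

    retained = [j for j in range(_N_ITEMS) if j != shouted_index]
    collapsed = collapse_item(items[:, retained])
    sum_score = collapsed.sum(axis=1)  # NaN if any retained item missing
    group = np.where(sum_score >= 1, "harsh", "no_harsh").astype(object)
    group[np.isnan(sum_score)] = np.nan

    frame = pd.DataFrame(
        collapsed, columns=[f"item{j + 1}" for j in retained], index=index
    )
    frame["parent"] = parent
    frame["sum_score"] = sum_score
    frame["group"] = group
    return frame


def harsh_group_from_exposures(
    exposures: pd.DataFrame, parent: str, shouted_index: int = SHOUTED_INDEX
) -> pd.Series:
    """Exposure dichotomy (0/1, NaN undefined) from an item table.

    Accepts the simulator's ``{parent}_item1..6`` columns (already on the
    collapsed {0,1,2} scale, a fixed point of the collapse rule).
    """
    if parent == "pooled":
        father = harsh_group_from_exposures(exposures, "father", shouted_index)
        mother = harsh_group_from_exposures(exposures, "mother", shouted_index)
        return pool_parents(father, mother)
    cols = [f"{parent}_item{j + 1}" for j in range(_N_ITEMS)]
    scored = score_harsh_parenting(exposures[cols], parent, shouted_index)
    out = pd.Series(np.nan, index=exposures.index, name=f"{parent}_harsh")
    defined = scored["group"].notna()
    out[defined] = (scored.loc[defined, "group"] == "harsh").astype(float)
    return out


def pool_parents(father: pd.Series, mother: pd.Series) -> pd.Series:
    """Pooled dichotomy: harsh iff either parent reports harsh discipline.

    Undefined (NaN) if either parent's assignment is undefined; symmetric
    in the two parents.
    """
    pooled = np.maximum(father.to_numpy(dtype=float), mother.to_numpy(dtype=float))
    undefined = father.isna().to_numpy() | mother.isna().to_numpy()
    pooled = pooled.astype(float)
    pooled[undefined] = np.nan
    return pd.Series(pooled, index=father.index, name="pooled_harsh")


def impute_externalizing(age5, wave18m, wave36m) -> tuple[np.ndarray, np.ndarray]:
    """Regression-impute missing main-wave scores from earlier waves.

    Fits OLS of the observed main-wave score on the earlier-wave scores —
    both predictors when present for a sample, a single-predictor model
    otherwise — and replaces missing entries with fitted values.  Returns
    (completed scores, imputed flags); samples with no observed predictor
    wave stay missing (and are dropped by the pipeline).
    """
    y = np.asarray(age5, dtype=float).copy()
    w18 = np.asarray(wave18m, dtype=float)
    w36 = np.asarray(wave36m, dtype=float)
    observed = ~np.isnan(y)
    if not observed.any():
        raise ValueError("all main-wave scores missing; nothing to fit on")
    imputed = np.zeros(y.shape[0], dtype=bool)

    patterns = {
        "both": (~np.isnan(w18)) & (~np.isnan(w36)),
        "w18": (~np.isnan(w18)) & np.isnan(w36),
        "w36": np.isnan(w18) & (~np.isnan(w36)),
    }
    predictors = {"both": (w18, w36), "w18": (w18,), "w36": (w36,)}
    for name, available in patterns.items():
        holes = np.isnan(y) & available
        if not holes.any():
            continue
        # train on every observed sample where these predictors exist
        train = observed & available if name != "both" else observed & patterns["both"]
        if name == "w18":
            train = observed & ~np.isnan(w18)
        elif name == "w36":
            train = observed & ~np.isnan(w36)
        if train.sum() < len(predictors[name]) + 2:
            continue
        design = np.column_stack(
            [np.ones(int(train.sum()))] + [p[train] for p in predictors[name]]
        )
        beta, *_ = np.linalg.lstsq(design, y[train], rcond=None)
        fill_design = np.column_stack(
            [np.ones(int(holes.sum()))] + [p[holes] for p in predictors[name]]
        )
        y[holes] = fill_design @ beta
        imputed |= holes
    return y, imputed
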