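"""Column orientation and best-performer-100 scaling.

Every indicator column is first oriented so that larger is better, then
scaled so the best-performing unit scores exactly 100; remaining units are
expressed as their gap to that optimum. Cost indicators (mortality,
pollutant emissions, altitude, ...) are reflected rather than inverted:
``max + min - x`` after shifting any negative minimum to zero, which avoids
the blow-ups a reciprocal transform produces near zero. The reciprocal
variant remains available via ``cost_transform="reciprocal"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .scheme import IndicatorScheme, UnitDataMatrix

__all__ = ["NormalizedMatrix", "orient_column", "normalize_best_100", "normalize_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Oriented, best-performer-100 scaled values; column max is 100 (or the
    column was constant and normalizes to all-100)."""

    unit_ids: list[str]
    indicator_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def internal(self) -> np.ndarray:
        """Values on the [0, 1] scale used inside the optimizers."""
        return self.values / 100.0


def orient_column(values: np.ndarray, polarity: int, *, transform: str = "reflect") -> np.ndarray:
    """Map a raw column so that larger oriented values are better.

    Benefit columns (+1) pass through unchanged. Cost columns (-1) are
    shifted so the minimum is 0 if any value is negative, then reflected
    through ``max + min - x``; with ``transform="reciprocal"`` they become
    ``min / x`` instead (requires strictly positive values).
    """
    x = np.asarray(values, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size == 0:
        raise ValueError("all-missing column cannot be oriented")
    if polarity == 1:
        return x.copy()
    if polarity != -1:
        raise ValueError(f"polarity must be +1 or -1, got {polarity}")
    if transform == "reflect":
        if obs.min() < 0:
            x = x - obs.min()
            obs = obs - obs.min()
        return obs.max() + obs.min() - x
    if transform == "reciprocal":
        if obs.min() <= 0:
            raise ValueError("reciprocal cost transform requires strictly positive values")
        return obs.min() / x
    raise ValueError(f"unknown cost transform: {transform}")


def normalize_best_100(oriented: np.ndarray) -> np.ndarray:
    """Scale a nonnegative oriented column so its maximum is exactly 100.

    A degenerate column (max 0, i.e. constant after orientation) normalizes
    to all-100: with no disparity there is nothing to penalise. A warning is
    logged since such a column carries no information.
    """
    x = np.asarray(oriented, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size == 0:
        raise ValueError("all-missing column cannot be scaled")
    if np.any(obs < 0):
        raise ValueError("oriented values must be nonnegative")
    m = obs.max()
    if m == 0.0:
        logger.warning("constant column normalizes to all-100 (no disparity)")
        out = np.full_like(x, 100.0)
        out[~np.isfinite(x)] = np.nan
        return out
    return x * (100.0 / m)


def normalize_matrix(
    raw: UnitDataMatrix,
    scheme: IndicatorScheme,
    *,
    cost_transform: str = "reflect",
    missing_policy: str = "median",
) -> NormalizedMatrix:
    """Orient and scale every column of a raw matrix.

    Missing cells are handled before scaling according to ``missing_policy``:
    ``median`` imputes the column median of observed units (logged),
    ``drop_unit`` removes any unit with a missing cell, ``error`` refuses.
    """
    if missing_policy not in ("median", "drop_unit", "error"):
        raise ValueError(f"unknown missing policy: {missing_policy}")
    unit_ids = list(raw.unit_ids)
    values = raw.values.astype(float).copy()
    values[raw.missing_mask] = np.nan

    if raw.missing_mask.any():
        if missing_policy == "error":
            bad = [raw.indicator_ids[j] for j in np.where(raw.missing_mask.any(axis=0))[0]]
            raise ValueError(f"missing values in columns {bad} with missing_policy='error'")
        if missing_policy == "drop_unit":
            keep = ~raw.missing_mask.any(axis=1)
            if not keep.any():
                raise ValueError("drop_unit removed every unit")
            unit_ids = [u for u, k in zip(unit_ids, keep) if k]
            values = values[keep]
        else:
            for j in range(values.shape[1]):
                col = values[:, j]
                miss = ~np.isfinite(col)
                if miss.any():
                    if miss.all():
                        raise ValueError(f"indicator {raw.indicator_ids[j]} has no observed values")
                    med = float(np.nanmedian(col))
                    col[miss] = med
                    logger.info(
                        "imputed %d missing cell(s) in %s with column median %.6g",
                        miss.sum(), raw.indicator_ids[j], med,
                    )

    polarity = {}
    for ind in raw.indicator_ids:
        pol = scheme.polarity_of(ind)
        if pol not in (1, -1):
            raise ValueError(f"indicator {ind} has no polarity in the scheme")
        polarity[ind] = pol

    out = np.empty_like(values)
    for j, ind in enumerate(raw.indicator_ids):
        oriented = orient_column(values[:, j], polarity[ind], transform=cost_transform)
        out[:, j] = normalize_best_100(oriented)
    return NormalizedMatrix(unit_ids=unit_ids, indicator_ids=list(raw.indicator_ids), values=out)
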