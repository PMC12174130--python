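"""Hierarchical aggregation, zoning and ranking.

Each grade-1 component index is produced by running the DEA-CP engine on
that component's grade-3 indicator block and rescaling so the best unit
scores 100.00. The composite LDI is the grade-1-weighted sum of the six
component indices, again rescaled to best = 100 (default on) and reported
at two decimals. Units are ranked by descending LDI and partitioned into
five security zones at the cut points 84 / 75 / 70 / 65.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import DeaConfig, common_scores, cp_common_weights, dea_ideal_scores
from .normalization import normalize_matrix
from .scheme import IndicatorScheme, ScoreFixture, UnitDataMatrix

__all__ = [
    "ZoneScheme",
    "DEFAULT_ZONES",
    "BlockIndexTable",
    "LdiResult",
    "ConsistencyReport",
    "round_half_up",
    "classify_zone",
    "compute_block_index",
    "compute_ldi",
    "rank_units",
    "assemble_result",
    "run_pipeline",
    "verify_against_fixture",
    "export_radar_data",
]


def round_half_up(x, decimals: int = 2):
    """Round with halves going up (reporting convention for printed scores)."""
    factor = 10.0 ** decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


@dataclass(frozen=True)
class ZoneScheme:
    """Five ordered score bands over four descending cut points.

    Intervals are half-open [lo, hi) with the top band closed below at its
    cut ("greater than or equal to 84" for the high band), so a score equal
    to a cut point falls in the band above it.
    """

    thresholds: tuple = (84.0, 75.0, 70.0, 65.0)
    labels: tuple = ("high", "medium-to-high", "medium", "low-to-medium", "low")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need exactly one more label than thresholds")
        if any(a <= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly descending")


DEFAULT_ZONES = ZoneScheme()


def classify_zone(ldi: float, zones: ZoneScheme = DEFAULT_ZONES) -> str:
    if not math.isfinite(ldi):
        raise ValueError("score must be finite")
    for cut, label in zip(zones.thresholds, zones.labels):
        if ldi >= cut:
            return label
    return zones.labels[-1]


@dataclass
class BlockIndexTable:
    """One grade-1 component index per unit, best unit = 100.00.

    ``index`` is the reported value (2 decimals); ``index_exact`` keeps full
    precision for downstream aggregation — rounding happens at report time
    only.
    """

    unit_ids: list[str]
    block_id: str
    index: np.ndarray
    index_exact: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None
    cp_objective: Optional[float] = None

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        if self.index_exact is None:
            self.index_exact = self.index.copy()
        else:
            self.index_exact = np.asarray(self.index_exact, dtype=float)


@dataclass
class LdiResult:
    """Per-unit component indices, composite LDI, rank and security zone."""

    unit_ids: list[str]
    grade1_ids: list[str]
    grade1_indices: np.ndarray
    ldi: np.ndarray
    rank: np.ndarray
    zone: list[str]
    ldi_exact: Optional[np.ndarray] = None  # pre-rounding composite

    def __post_init__(self) -> None:
        if self.ldi_exact is None:
            self.ldi_exact = np.asarray(self.ldi, dtype=float).copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grade1_indices, index=self.unit_ids, columns=self.grade1_ids)
        df.insert(0, "ldi", self.ldi)
        df["rank"] = self.rank
        df["zone"] = self.zone
        df.index.name = "unit"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path: str | Path) -> None:
        records = self.to_frame().reset_index().to_dict(orient="records")
        Path(path).write_text(json.dumps(records, indent=1))


@dataclass
class ConsistencyReport:
    """Recomputed-vs-printed comparison for a published score table."""

    unit_ids: list[str]
    recomputed: np.ndarray
    printed: np.ndarray
    max_abs_dev: float
    tol: float
    failing_units: list[str]

    @property
    def passed(self) -> bool:
        return not self.failing_units


def compute_block_index(
    raw: UnitDataMatrix,
    scheme: IndicatorScheme,
    grade1_id: str,
    cfg: DeaConfig | None = None,
    *,
    cost_transform: str = "reflect",
    missing_policy: str = "median",
) -> BlockIndexTable:
    """Run the full DEA-CP pipeline on one grade-1 block.

    normalize -> Stage-1 ideal scores -> Stage-2 common weights -> common
    scores -> rescale so the best unit is exactly 100 -> report 2 decimals.
    """
    cfg = cfg or DeaConfig()
    leaves = [n.node_id for n in scheme.leaves_of(grade1_id)]
    leaves = [l for l in leaves if l in raw.indicator_ids]
    if not leaves:
        raise ValueError(f"grade-1 block {grade1_id!r} has no indicators with data")
    block_raw = raw.subset(leaves)
    block = normalize_matrix(block_raw, scheme, cost_transform=cost_transform, missing_policy=missing_policy)
    ideal = dea_ideal_scores(block, cfg)
    weights = cp_common_weights(block, ideal, cfg)
    scores = common_scores(block, weights)
    top = scores.max()
    if top <= 0:
        raise ValueError(f"grade-1 block {grade1_id!r} produced all-zero scores")
    exact = scores * (100.0 / top)
    return BlockIndexTable(
        unit_ids=list(block.unit_ids),
        block_id=grade1_id,
        index=round_half_up(exact),
        index_exact=exact,
        weights=weights.w,
        cp_objective=weights.objective_value,
    )


def compute_ldi(
    grade1_indices: np.ndarray,
    grade1_weights: Sequence[float],
    *,
    rescale: bool = True,
    decimals: int | None = 2,
) -> np.ndarray:
    """Composite LDI: grade-1-weighted sum of component indices.

    With ``rescale`` (default) the weighted sums are scaled so the best unit
    is exactly 100. ``decimals=None`` skips the report rounding.
    """
    G = np.asarray(grade1_indices, dtype=float)
    w = np.asarray(grade1_weights, dtype=float)
    if G.ndim != 2 or G.shape[1] != w.size:
        raise ValueError(f"index table has {G.shape[1] if G.ndim == 2 else '?'} columns, {w.size} weights given")
    raw = G @ w
    if rescale:
        top = raw.max()
        if top <= 0:
            raise ValueError("cannot rescale: no positive composite score")
        raw = raw * (100.0 / top)
    return raw if decimals is None else round_half_up(raw, decimals)


def rank_units(ldi: np.ndarray, method: str = "ordinal") -> np.ndarray:
    """Ranks by descending score, 1 = best.

    ``ordinal`` (default) breaks ties by row order, matching published
    practice of assigning consecutive ranks to tied scores; ``dense`` gives
    tied scores the same rank.
    """
    ldi = np.asarray(ldi, dtype=float)
    order = np.argsort(-ldi, kind="stable")
    ranks = np.empty(ldi.size, dtype=int)
    if method == "ordinal":
        ranks[order] = np.arange(1, ldi.size + 1)
    elif method == "dense":
        r = 0
        prev = None
        for pos in order:
            if prev is None or ldi[pos] != prev:
                r += 1
                prev = ldi[pos]
            ranks[pos] = r
    else:
        raise ValueError(f"unknown ranking method: {method}")
    return ranks


def assemble_result(
    unit_ids: Sequence[str],
    grade1_ids: Sequence[str],
    grade1_indices: np.ndarray,
    grade1_weights: Sequence[float],
    *,
    rescale: bool = True,
    zones: ZoneScheme = DEFAULT_ZONES,
    rank_method: str = "ordinal",
    grade1_indices_exact: Optional[np.ndarray] = None,
) -> LdiResult:
    """Composite + rank + zone from component indices.

    Ranking uses the pre-rounding composite (ties in the printed value are
    broken by true order, then row order); zones use the printed value, the
    convention of published tables.
    """
    exact_in = grade1_indices if grade1_indices_exact is None else grade1_indices_exact
    exact = compute_ldi(exact_in, grade1_weights, rescale=rescale, decimals=None)
    ldi = round_half_up(exact)
    return LdiResult(
        unit_ids=list(unit_ids),
        grade1_ids=list(grade1_ids),
        grade1_indices=np.asarray(grade1_indices, dtype=float),
        ldi=ldi,
        rank=rank_units(exact, rank_method),
        zone=[classify_zone(v, zones) for v in ldi],
        ldi_exact=exact,
    )


def run_pipeline(
    raw: UnitDataMatrix,
    scheme: IndicatorScheme,
    cfg: DeaConfig | None = None,
    *,
    rescale: bool = True,
    zones: ZoneScheme = DEFAULT_ZONES,
    cost_transform: str = "reflect",
    missing_policy: str = "median",
    rank_method: str = "ordinal",
) -> tuple[LdiResult, list[BlockIndexTable]]:
    """End-to-end: per-block DEA-CP indices, then the weighted composite."""
    cfg = cfg or DeaConfig()
    grade1 = scheme.grade_nodes(1)
    blocks = [
        compute_block_index(
            raw, scheme, g.node_id, cfg,
            cost_transform=cost_transform, missing_policy=missing_policy,
        )
        for g in grade1
    ]
    result = assemble_result(
        blocks[0].unit_ids,
        [g.node_id for g in grade1],
        np.column_stack([b.index for b in blocks]),
        scheme.grade1_weights(),
        rescale=rescale,
        zones=zones,
        rank_method=rank_method,
        grade1_indices_exact=np.column_stack([b.index_exact for b in blocks]),
    )
    return result, blocks


def verify_against_fixture(
    fixture: ScoreFixture,
    grade1_weights: Sequence[float],
    tol: float = 0.01,
    *,
    rescale: bool = True,
) -> ConsistencyReport:
    """Recompute the composite from the printed component indices and compare.

    The printed composite should be reproduced to within ``tol`` (default
    0.01, i.e. the 2-decimal printing precision) for every unit.
    """
    recomputed = compute_ldi(fixture.grade1_indices, grade1_weights, rescale=rescale)
    dev = np.abs(recomputed - fixture.ldi)
    failing = [u for u, d in zip(fixture.unit_ids, dev) if d > tol + 1e-12]
    return ConsistencyReport(
        unit_ids=list(fixture.unit_ids),
        recomputed=recomputed,
        printed=fixture.ldi.copy(),
        max_abs_dev=float(dev.max()),
        tol=tol,
        failing_units=failing,
    )


def export_radar_data(result: LdiResult, path: str | Path) -> None:
    """Write the six component indices + zone per unit, for radar-chart plotting."""
    df = pd.DataFrame(result.grade1_indices, index=result.unit_ids, columns=result.grade1_ids)
    df["zone"] = result.zone
    df.index.name = "unit"
    df.to_csv(path)
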