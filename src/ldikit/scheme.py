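"""Hierarchical indicator scheme: data model, readers/writers, validation.

The life-safety disparity index (LDI) is organised as a three-level
indicator tree: 6 grade-1 components (health level, medical capabilities,
disease prevention and control, ecological environment, health expenditure,
health industry), 21 grade-2 groups, and 65 grade-3 leaf indicators. Only
leaf indicators carry data; grade-2 nodes are structural grouping and carry
no weights; grade-1 and grade-3 nodes carry nonnegative weights.

Polarity (benefit vs. cost direction) is defined on leaf indicators only.
The packaged scheme assigns polarity from indicator semantics and flags
every such row as an assumption in its ``note`` column; callers can
override it through the input file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorNode",
    "IndicatorScheme",
    "UnitDataMatrix",
    "ScoreFixture",
    "ValidationReport",
    "SchemeValidationError",
    "load_scheme",
    "write_scheme",
    "validate_scheme",
    "load_score_fixture",
    "load_matrix",
    "write_matrix",
    "scheme_to_json",
    "scheme_from_json",
    "packaged_scheme_path",
    "packaged_scores_path",
    "load_packaged_scheme",
    "load_packaged_scores",
]


class SchemeValidationError(ValueError):
    """A structural problem in an indicator scheme, naming the offending node."""


@dataclass(frozen=True)
class IndicatorNode:
    """One node of the 3-level indicator tree.

    ``polarity`` is +1 (benefit: larger raw value is better) or -1 (cost:
    smaller is better) and is meaningful only for grade-3 nodes. ``weight``
    is a nonnegative unitless multiplier or ``None`` when the scheme does
    not fix one (grade-2 nodes never carry weights).
    """

    node_id: str
    name: str
    grade: int
    parent_id: Optional[str] = None
    polarity: Optional[int] = None
    weight: Optional[float] = None
    data_year: Optional[int] = None
    note: str = ""


@dataclass
class IndicatorScheme:
    """Ordered collection of :class:`IndicatorNode` forming a forest of 3-level trees."""

    nodes: list[IndicatorNode]
    metadata: dict = field(default_factory=dict)

    def grade_nodes(self, grade: int) -> list[IndicatorNode]:
        return [n for n in self.nodes if n.grade == grade]

    def node(self, node_id: str) -> IndicatorNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def children(self, node_id: str) -> list[IndicatorNode]:
        return [n for n in self.nodes if n.parent_id == node_id]

    def leaves_of(self, grade1_id: str) -> list[IndicatorNode]:
        """Grade-3 descendants of a grade-1 node, in scheme order."""
        g2 = {n.node_id for n in self.children(grade1_id)}
        return [n for n in self.nodes if n.grade == 3 and n.parent_id in g2]

    def polarity_of(self, leaf_id: str) -> Optional[int]:
        return self.node(leaf_id).polarity

    def grade1_weights(self) -> np.ndarray:
        ws = [n.weight for n in self.grade_nodes(1)]
        if any(w is None for w in ws):
            raise SchemeValidationError("grade-1 node without a weight")
        return np.asarray(ws, dtype=float)


@dataclass
class ValidationReport:
    """Outcome of structural validation; failures are carried, not raised."""

    counts: dict[int, int]
    duplicate_ids: list[str]
    missing_polarity: list[str]
    weight_summary: dict[str, dict]
    failures: list[str]

    @property
    def passed(self) -> bool:
        return not self.failures


@dataclass
class UnitDataMatrix:
    """Raw unit x indicator values with a missing mask.

    Stands in for the provincial yearbook data feeding the index: rows are
    evaluation units (provinces), columns are grade-3 indicator ids.
    """

    unit_ids: list[str]
    indicator_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.unit_ids), len(self.indicator_ids)):
            raise ValueError("values shape does not match unit/indicator labels")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite value outside the missing mask")

    def column(self, indicator_id: str) -> np.ndarray:
        j = self.indicator_ids.index(indicator_id)
        col = self.values[:, j].copy()
        col[self.missing_mask[:, j]] = np.nan
        return col

    def subset(self, indicator_ids: Sequence[str]) -> "UnitDataMatrix":
        idx = [self.indicator_ids.index(i) for i in indicator_ids]
        return UnitDataMatrix(
            unit_ids=list(self.unit_ids),
            indicator_ids=list(indicator_ids),
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )


@dataclass
class ScoreFixture:
    """Published per-province scores: composite LDI plus the six component indices.

    All values are on the best-unit-100 scale, printed at 2 decimals; every
    component column contains at least one 100.00 (its best performer).
    """

    unit_ids: list[str]
    ldi: np.ndarray
    grade1_indices: np.ndarray
    grade1_names: list[str]
    zones: list[str]

    def __post_init__(self) -> None:
        self.ldi = np.asarray(self.ldi, dtype=float)
        self.grade1_indices = np.asarray(self.grade1_indices, dtype=float)
        allv = np.concatenate([self.ldi, self.grade1_indices.ravel()])
        if np.any(allv < 0) or np.any(allv > 100):
            bad = allv[(allv < 0) | (allv > 100)][0]
            raise ValueError(f"score outside [0, 100]: {bad}")


# ---------------------------------------------------------------------------
# readers / writers

_SCHEME_COLUMNS = ["grade", "node_id", "parent_id", "name", "polarity", "weight", "data_year", "note"]


def _nodes_from_frame(df: pd.DataFrame) -> list[IndicatorNode]:
    missing = [c for c in ("grade", "node_id", "name") if c not in df.columns]
    if missing:
        raise SchemeValidationError(f"scheme table missing columns: {missing}")
    nodes = []
    for _, row in df.iterrows():
        def opt(key, cast):
            v = row.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return cast(v)

        nodes.append(
            IndicatorNode(
                node_id=str(row["node_id"]),
                name=str(row["name"]),
                grade=int(row["grade"]),
                parent_id=opt("parent_id", str),
                polarity=opt("polarity", lambda v: int(float(v))),
                weight=opt("weight", float),
                data_year=opt("data_year", lambda v: int(float(v))),
                note="" if opt("note", str) is None else str(row["note"]),
            )
        )
    return nodes


def _check_structure(nodes: Sequence[IndicatorNode]) -> list[str]:
    """Return a list of structural failure messages (empty = valid)."""
    failures: list[str] = []
    ids = [n.node_id for n in nodes]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            failures.append(f"duplicate node_id: {i}")
        seen.add(i)
    by_id = {n.node_id: n for n in nodes}
    for n in nodes:
        if n.grade not in (1, 2, 3):
            failures.append(f"node {n.node_id}: grade {n.grade} not in {{1,2,3}}")
            continue
        if n.grade == 1:
            if n.parent_id is not None:
                failures.append(f"node {n.node_id}: grade-1 node must have no parent")
        else:
            if n.parent_id is None:
                failures.append(f"node {n.node_id}: orphan grade-{n.grade} node (no parent)")
            elif n.parent_id not in by_id:
                failures.append(f"node {n.node_id}: unknown parent {n.parent_id}")
            elif by_id[n.parent_id].grade != n.grade - 1:
                failures.append(
                    f"node {n.node_id}: grade skip (grade-{n.grade} under grade-{by_id[n.parent_id].grade})"
                )
        if n.weight is not None and (not np.isfinite(n.weight) or n.weight < 0):
            failures.append(f"node {n.node_id}: weight must be finite and >= 0")
    g1 = [n for n in nodes if n.grade == 1]
    if not g1:
        failures.append("no grade-1 nodes")
    g2_by_parent: dict[str, set[str]] = {}
    for n in nodes:
        if n.grade == 2 and n.parent_id:
            g2_by_parent.setdefault(n.parent_id, set()).add(n.node_id)
    leaf_parents = {n.parent_id for n in nodes if n.grade == 3}
    for top in g1:
        g2 = g2_by_parent.get(top.node_id, set())
        if not (g2 & leaf_parents):
            failures.append(f"node {top.node_id}: grade-1 node without grade-3 descendants")
    return failures


def load_scheme(path: str | Path) -> IndicatorScheme:
    """Read an indicator scheme from a CSV table and validate its structure.

    Raises :class:`SchemeValidationError` naming the offending node on a
    malformed hierarchy (orphan, grade skip, duplicate id).
    """
    df = pd.read_csv(path, dtype={"node_id": str, "parent_id": str})
    nodes = _nodes_from_frame(df)
    failures = _check_structure(nodes)
    if failures:
        raise SchemeValidationError("; ".join(failures))
    return IndicatorScheme(nodes=nodes)


def write_scheme(scheme: IndicatorScheme, path: str | Path) -> None:
    rows = []
    for n in scheme.nodes:
        rows.append(
            {
                "grade": n.grade,
                "node_id": n.node_id,
                "parent_id": n.parent_id,
                "name": n.name,
                "polarity": n.polarity,
                "weight": n.weight,
                "data_year": n.data_year,
                "note": n.note,
            }
        )
    pd.DataFrame(rows, columns=_SCHEME_COLUMNS).to_csv(path, index=False)


def validate_scheme(scheme: IndicatorScheme) -> ValidationReport:
    """Structural report: per-grade counts, duplicates, polarity gaps, weight summary."""
    nodes = scheme.nodes
    counts = {g: sum(1 for n in nodes if n.grade == g) for g in (1, 2, 3)}
    ids = [n.node_id for n in nodes]
    duplicate_ids = sorted({i for i in ids if ids.count(i) > 1})
    missing_polarity = [n.node_id for n in nodes if n.grade == 3 and n.polarity not in (1, -1)]
    failures = _check_structure(nodes)
    if missing_polarity:
        failures.append(f"grade-3 nodes without polarity: {missing_polarity}")
    weight_summary: dict[str, dict] = {}
    for top in scheme.grade_nodes(1):
        leaf_w = [n.weight for n in scheme.leaves_of(top.node_id) if n.weight is not None]
        weight_summary[top.node_id] = {
            "grade1_weight": top.weight,
            "n_leaves": len(scheme.leaves_of(top.node_id)),
            "leaf_weight_sum": float(np.sum(leaf_w)) if leaf_w else None,
        }
    return ValidationReport(
        counts=counts,
        duplicate_ids=duplicate_ids,
        missing_polarity=missing_polarity,
        weight_summary=weight_summary,
        failures=failures,
    )


def load_score_fixture(path: str | Path) -> ScoreFixture:
    """Read the published province score table (composite + 6 component indices)."""
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c not in ("zone", "province")]
    if "ldi" not in value_cols:
        raise ValueError("score table must have an 'ldi' column")
    g1_cols = [c for c in value_cols if c != "ldi"]
    return ScoreFixture(
        unit_ids=df["province"].astype(str).tolist(),
        ldi=df["ldi"].to_numpy(float),
        grade1_indices=df[g1_cols].to_numpy(float),
        grade1_names=g1_cols,
        zones=df["zone"].astype(str).tolist() if "zone" in df.columns else [""] * len(df),
    )


def load_matrix(path: str | Path) -> UnitDataMatrix:
    """Read a unit x indicator CSV (first column = unit labels); blanks are missing."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(float)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return UnitDataMatrix(
        unit_ids=[str(u) for u in df.index],
        indicator_ids=[str(c) for c in df.columns],
        values=values,
        missing_mask=mask,
    )


def write_matrix(matrix: UnitDataMatrix, path: str | Path) -> None:
    values = matrix.values.astype(float).copy()
    values[matrix.missing_mask] = np.nan
    pd.DataFrame(values, index=matrix.unit_ids, columns=matrix.indicator_ids).to_csv(path)


def scheme_to_json(scheme: IndicatorScheme) -> str:
    """Serialize a scheme as JSON nested by grade (grade-1 -> grade-2 -> leaves)."""

    def node_dict(n: IndicatorNode) -> dict:
        d: dict = {"node_id": n.node_id, "name": n.name}
        for k in ("polarity", "weight", "data_year"):
            v = getattr(n, k)
            if v is not None:
                d[k] = v
        if n.note:
            d["note"] = n.note
        return d

    tree = []
    for top in scheme.grade_nodes(1):
        top_d = node_dict(top)
        top_d["children"] = []
        for mid in scheme.children(top.node_id):
            mid_d = node_dict(mid)
            mid_d["children"] = [node_dict(leaf) for leaf in scheme.children(mid.node_id)]
            top_d["children"].append(mid_d)
        tree.append(top_d)
    return json.dumps({"scheme": tree, "metadata": scheme.metadata}, indent=1)


def scheme_from_json(text: str) -> IndicatorScheme:
    payload = json.loads(text)
    nodes: list[IndicatorNode] = []

    def mk(d: dict, grade: int, parent: Optional[str]) -> IndicatorNode:
        return IndicatorNode(
            node_id=d["node_id"],
            name=d["name"],
            grade=grade,
            parent_id=parent,
            polarity=d.get("polarity"),
            weight=d.get("weight"),
            data_year=d.get("data_year"),
            note=d.get("note", ""),
        )

    for top in payload["scheme"]:
        nodes.append(mk(top, 1, None))
        for mid in top.get("children", []):
            nodes.append(mk(mid, 2, top["node_id"]))
            for leaf in mid.get("children", []):
                nodes.append(mk(leaf, 3, mid["node_id"]))
    # keep original row order: grade-1 block order with descendants grouped is
    # acceptable for JSON round-trips; CSV remains the canonical dialect
    failures = _check_structure(nodes)
    if failures:
        raise SchemeValidationError("; ".join(failures))
    return IndicatorScheme(nodes=nodes, metadata=payload.get("metadata", {}))


# ---------------------------------------------------------------------------
# packaged fixtures


def packaged_scheme_path() -> Path:
    return Path(str(resources.files("ldikit") / "fixtures" / "table1_scheme.csv"))


def packaged_scores_path() -> Path:
    return Path(str(resources.files("ldikit") / "fixtures" / "table2_scores.csv"))


def load_packaged_scheme() -> IndicatorScheme:
    """The packaged 6/21/65 indicator-and-weight scheme."""
    scheme = load_scheme(packaged_scheme_path())
    scheme.metadata["provenance"] = (
        "Published indicator-and-weight scheme; 73 initial indicators reduced "
        "to 65 after 8 deletions for data availability. Polarity column is an "
        "implementer assumption (see note column)."
    )
    return scheme


def load_packaged_scores() -> ScoreFixture:
    """The packaged 31-province score table (composite LDI + 6 component indices)."""
    return load_score_fixture(packaged_scores_path())
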