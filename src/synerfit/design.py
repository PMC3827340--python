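"""Uniform-design and synergistic-design dose tables.

A uniform design U_n(q^s) assigns each of s factors (drug components) one of q
dose levels per run such that every level of every factor occurs exactly once
across the n runs.  This module builds dose tables from a level matrix plus
per-component level->dose grids, composes ratio/mono/pair designs at fixed
total doses, and validates level uniformity.  The nine-run three-component
table used throughout ships as a packaged fixture (:func:`load_uniform_design`), as do
its dose grids and the fourteen-run synergistic design (:func:`load_synergy_design`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseGrid",
    "DesignTable",
    "build_design_table",
    "compose_ratio_design",
    "check_design_uniformity",
    "validate_totals",
    "load_uniform_design",
    "load_dose_grids",
    "load_synergy_design",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention, not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DoseGrid:
    """Level -> dose (mg/kg) map for one drug component.

    Levels must be consecutive integers starting at 1 and doses must be
    non-decreasing in level.  Level 1 may map to dose 0 (a component absent
    from that run).
    """

    component: str
    level_doses: Mapping[int, float]

    def __post_init__(self) -> None:
        levels = sorted(self.level_doses)
        if levels != list(range(1, len(levels) + 1)):
            raise ValueError(
                f"grid for {self.component!r}: levels must be consecutive "
                f"integers starting at 1, got {levels}"
            )
        doses = [self.level_doses[lv] for lv in levels]
        if any(d < 0 for d in doses):
            raise ValueError(f"grid for {self.component!r}: negative dose")
        if any(b < a for a, b in zip(doses, doses[1:])):
            raise ValueError(
                f"grid for {self.component!r}: doses must be non-decreasing in level"
            )

    @property
    def n_levels(self) -> int:
        return len(self.level_doses)

    def dose(self, level: int) -> float:
        try:
            return float(self.level_doses[level])
        except KeyError:
            raise KeyError(
                f"level {level} not in grid for component {self.component!r}"
            ) from None


@dataclass
class DesignTable:
    """Runs x components dose table with per-run totals.

    ``table`` columns: ``run``, optional ``label``, optional ``level_<c>``
    per component, one dose column per component (mg/kg), and ``total``.
    """

    components: list[str]
    table: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    @property
    def doses(self) -> np.ndarray:
        return self.table[self.components].to_numpy(dtype=float)

    @property
    def n_runs(self) -> int:
        return len(self.table)

    def dose_ranges(self) -> dict[str, tuple[float, float]]:
        d = self.doses
        return {
            c: (float(d[:, i].min()), float(d[:, i].max()))
            for i, c in enumerate(self.components)
        }


def build_design_table(levels: np.ndarray, grids: Sequence[DoseGrid]) -> DesignTable:
    """Construct a :class:`DesignTable` from a run x component level matrix.

    Doses are looked up in the per-component grids; the total dose is the sum
    of component doses rounded to 3 decimals (printed totals are never
    trusted, see :func:`validate_totals`).  Unknown levels raise; duplicate
    levels within a column emit a warning because they violate the
    each-level-once-only uniformity rule.
    """
    levels = np.asarray(levels, dtype=int)
    if levels.ndim != 2:
        raise ValueError("levels must be a 2-D run x component matrix")
    n_runs, n_comp = levels.shape
    if n_comp != len(grids):
        raise ValueError(f"levels has {n_comp} columns but {len(grids)} grids given")

    rows = []
    for r in range(n_runs):
        doses = []
        for j, grid in enumerate(grids):
            lv = int(levels[r, j])
            if lv not in grid.level_doses:
                raise KeyError(
                    f"run {r + 1}, component {grid.component!r}: unknown level {lv}"
                )
            doses.append(grid.dose(lv))
        rows.append(doses)

    report = check_design_uniformity(levels)
    for j, grid in enumerate(grids):
        if not report["pass"][j]:
            warnings.warn(
                f"column {grid.component!r} is not uniform: "
                f"duplicate or missing levels {report['counts'][j]}",
                stacklevel=2,
            )

    components = [g.component for g in grids]
    table = pd.DataFrame(rows, columns=components)
    for j, c in enumerate(components):
        table.insert(j, f"level_{c}", levels[:, j])
    table.insert(0, "run", np.arange(1, n_runs + 1))
    table["total"] = [round_half_up(s, 3) for s in table[components].sum(axis=1)]
    return DesignTable(components=components, table=table)


def compose_ratio_design(
    ratio: Mapping[str, float],
    totals: Iterable[float],
    patterns: Iterable[frozenset[str] | set[str]] | None = None,
) -> DesignTable:
    """Ratio / mono / pair design at fixed total doses.

    For the full-combination pattern each component receives
    ``total * w_i / sum(w)`` (rounded to 2 decimals); a single-component
    pattern receives the whole total; any intermediate pattern splits the
    total equally among its members.  One row is produced per (total,
    pattern) pair, totals varying slowest.
    """
    components = list(ratio)
    weights = np.array([ratio[c] for c in components], dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("ratio weights must be non-negative and not all zero")
    totals = [float(t) for t in totals]
    if any(t <= 0 for t in totals):
        raise ValueError("totals must be positive")
    if patterns is None:
        patterns = default_patterns(components)
    patterns = [frozenset(p) for p in patterns]
    for p in patterns:
        if not p:
            raise ValueError("empty component pattern")
        unknown = p - set(components)
        if unknown:
            raise ValueError(f"pattern names unknown components: {sorted(unknown)}")

    rows = []
    for total in totals:
        for pat in patterns:
            if len(pat) == len(components):
                doses = total * weights / weights.sum()
            elif len(pat) == 1:
                doses = np.array(
                    [total if c in pat else 0.0 for c in components]
                )
            else:
                doses = np.array(
                    [total / len(pat) if c in pat else 0.0 for c in components]
                )
            doses = [round_half_up(d, 2) for d in doses]
            label = "".join(c[0].upper() for c in components if c in pat)
            rows.append([label, *doses, total])

    table = pd.DataFrame(rows, columns=["label", *components, "total"])
    table.insert(0, "run", np.arange(1, len(table) + 1))
    return DesignTable(components=components, table=table)


def default_patterns(components: Sequence[str]) -> list[frozenset[str]]:
    """Full combination, then each mono, then pairs in the printed order
    (for G,B,J: GB, BJ, GJ)."""
    full = frozenset(components)
    monos = [frozenset({c}) for c in components]
    n = len(components)
    pairs = [
        frozenset({components[i], components[(i + 1) % n]}) for i in range(n)
    ]
    # drop the wrap-around duplicate when only two components exist
    seen: list[frozenset[str]] = []
    for p in pairs:
        if p not in seen and len(p) == 2:
            seen.append(p)
    return [full, *monos, *seen]


def check_design_uniformity(levels: np.ndarray) -> dict:
    """Per-column uniformity report: a column passes iff each level 1..n
    appears exactly once.  Reports, never raises."""
    levels = np.asarray(levels, dtype=int)
    if levels.ndim != 2:
        raise ValueError("levels must be a 2-D matrix")
    n = levels.shape[0]
    passes, counts = [], []
    for j in range(levels.shape[1]):
        col = levels[:, j]
        cnt = {lv: int((col == lv).sum()) for lv in range(1, n + 1)}
        passes.append(all(v == 1 for v in cnt.values()))
        counts.append(cnt)
    return {"pass": passes, "counts": counts, "all_pass": all(passes)}


def validate_totals(
    design: DesignTable, printed_totals: Sequence[float], tol: float = 0.01
) -> list[str]:
    """Flag runs whose printed total disagrees with the component sum by more
    than ``tol`` mg/kg.  Returns the flag messages (also stored on the
    design)."""
    flags = []
    for run, computed, printed in zip(
        design.table["run"], design.table["total"], printed_totals
    ):
        if abs(computed - printed) > tol:
            flags.append(
                f"run {run}: printed total {printed:.3f} != component sum "
                f"{computed:.3f} (discrepancy {abs(computed - printed):.3f})"
            )
    design.flags.extend(flags)
    return flags


def _data_path(name: str):
    return resources.files("synerfit.data").joinpath(name)


def load_dose_grids() -> list[DoseGrid]:
    """The packaged nine-level dose grids for ginsenosides, berberine and
    jasminoidin (mg/kg)."""
    df = pd.read_csv(_data_path("dose_grids.csv"))
    grids = []
    for comp, sub in df.groupby("component", sort=False):
        grids.append(
            DoseGrid(comp, dict(zip(sub["level"].astype(int), sub["dose"])))
        )
    return grids


def load_uniform_design(validate: bool = True) -> DesignTable:
    """The packaged 9-run uniform design (levels + printed doses/totals).

    The table is rebuilt from the level matrix and grids; printed totals are
    cross-checked and discrepancies flagged (run 6's printed total is known
    to disagree with its component sum by 0.182 mg/kg).
    """
    df = pd.read_csv(_data_path("uniform_design.csv"))
    grids = load_dose_grids()
    levels = df[[f"level_{g.component}" for g in grids]].to_numpy(dtype=int)
    design = build_design_table(levels, grids)
    if validate:
        validate_totals(design, df["total"].tolist())
    return design


def load_synergy_design() -> DesignTable:
    """The packaged 14-run synergistic design (full / mono / pair groups at
    total doses 25 and 5 mg/kg)."""
    df = pd.read_csv(_data_path("synergy_design.csv"))
    components = ["ginsenosides", "berberine", "jasminoidin"]
    return DesignTable(components=components, table=df.copy())
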