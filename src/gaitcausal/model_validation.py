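"""Plausibility testing of a causal model against cohort data.

Every conditional independence the DAG implies is checked with a partial
correlation on the data: residualize both variables on the conditioning set
by least squares and correlate the residuals.  The model is judged plausible
when every coefficient is inside the conventional +/-0.3 cutoff.  No
multiple-testing correction is applied: the criterion is a fixed cutoff on
the coefficients themselves, not on p-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causal_graph import CausalDAG, IndependenceStatement, implied_independencies

__all__ = [
    "ValidationConfig",
    "ImplicationResult",
    "PlausibilityReport",
    "partial_correlation",
    "test_model_plausibility",
]


@dataclass(frozen=True)
class ValidationConfig:
    """Settings for the independence checks.

    cutoff
        Absolute partial correlation below which an implication counts as
        satisfied; 0.3 is the conventional value.
    min_n
        Minimum complete cases beyond ``len(given) + 2`` needed to evaluate
        an implication.
    """

    cutoff: float = 0.3
    min_n: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.cutoff < 1):
            raise ValueError("cutoff must be in [0, 1)")


@dataclass
class ImplicationResult:
    statement: IndependenceStatement
    n: int
    partial_r: float | None
    passed: bool | None  # None when the implication could not be evaluated
    note: str = ""


@dataclass
class PlausibilityReport:
    results: list[ImplicationResult]
    cutoff: float
    max_abs_r: float = field(init=False)
    plausible: bool = field(init=False)

    def __post_init__(self) -> None:
        rs = [abs(r.partial_r) for r in self.results if r.partial_r is not None]
        self.max_abs_r = max(rs) if rs else float("nan")
        self.plausible = bool(rs) and self.max_abs_r < self.cutoff

    def to_json(self) -> str:
        payload = {
            "cutoff": self.cutoff,
            "max_abs_partial_r": self.max_abs_r,
            "plausible": self.plausible,
            "implications": [
                {
                    "x": r.statement.x,
                    "y": r.statement.y,
                    "given": sorted(r.statement.given),
                    "n": r.n,
                    "partial_r": r.partial_r,
                    "passed": r.passed,
                    "note": r.note,
                }
                for r in self.results
            ],
        }
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        lines = [f"{'implication':<50} {'n':>6} {'partial r':>10}  verdict"]
        for r in self.results:
            rr = "   --  " if r.partial_r is None else f"{r.partial_r:+.3f}"
            verdict = {True: "pass", False: "FAIL", None: f"n/a ({r.note})"}[r.passed]
            lines.append(f"{str(r.statement):<50} {r.n:>6} {rr:>10}  {verdict}")
        lines.append(
            f"max |partial r| = {self.max_abs_r:.3f} "
            f"(cutoff {self.cutoff}) -> "
            + ("model plausible" if self.plausible else "model NOT plausible")
        )
        return "\n".join(lines)


def partial_correlation(
    data: pd.DataFrame, x: str, y: str, given=()
) -> tuple[float, int]:
    """Partial correlation of ``x`` and ``y`` given a conditioning set.

    Complete cases over ``{x, y} | given``; both variables are residualized
    on the conditioning set (with intercept) by least squares and the
    Pearson correlation of the residuals returned, together with the number
    of cases used.  With an empty conditioning set this is the Pearson
    correlation.
    """
    given = sorted(set(given))
    cols = [x, y, *given]
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"column {c!r} not in data")
    sub = data[cols].apply(pd.to_numeric).dropna()
    n = len(sub)
    if n < len(given) + 3:
        raise ValueError(
            f"insufficient complete cases for ({x}, {y} | {given}): n={n}"
        )
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if given:
        z = np.column_stack([np.ones(n), sub[given].to_numpy(dtype=float)])
        rank = np.linalg.matrix_rank(z)
        if rank < z.shape[1]:
            raise ValueError(f"collinear conditioning set {given} for ({x}, {y})")
        xv = xv - z @ np.linalg.lstsq(z, xv, rcond=None)[0]
        yv = yv - z @ np.linalg.lstsq(z, yv, rcond=None)[0]
    else:
        xv = xv - xv.mean()
        yv = yv - yv.mean()
    denom = np.sqrt((xv @ xv) * (yv @ yv))
    if denom == 0:
        raise ValueError(f"zero residual variance for ({x}, {y} | {given})")
    return float(np.clip(xv @ yv / denom, -1.0, 1.0)), n


def test_model_plausibility(
    dag: CausalDAG,
    data: pd.DataFrame,
    config: ValidationConfig | None = None,
) -> PlausibilityReport:
    """Evaluate every implied conditional independency on the data.

    Implications that cannot be evaluated (insufficient complete cases,
    degenerate columns) are flagged in the report, not fatal.  Results are
    sorted by \\|partial r\\| descending, unevaluable ones last.
    """
    config = config or ValidationConfig()
    missing = sorted(dag.observed - set(data.columns))
    if missing:
        raise KeyError(f"data lacks column(s) for observed variables: {missing}")
    results: list[ImplicationResult] = []
    for stmt in implied_independencies(dag):
        try:
            r, n = partial_correlation(data, stmt.x, stmt.y, stmt.given)
        except (ValueError, KeyError) as exc:
            results.append(ImplicationResult(stmt, 0, None, None, note=str(exc)))
            continue
        results.append(ImplicationResult(stmt, n, r, abs(r) < config.cutoff))
    results.sort(
        key=lambda r: (r.partial_r is None, -(abs(r.partial_r) if r.partial_r is not None else 0))
    )
    return PlausibilityReport(results=results, cutoff=config.cutoff)
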