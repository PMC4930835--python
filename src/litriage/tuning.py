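"""Coefficient tuning: exhaustive grid search over the ranking weights.

The linear ranking function has three coefficients (search score, matching
index size, term frequency).  They are tuned by evaluating every triple of a
Cartesian grid against a QREL benchmark and keeping the argmax of the chosen
metric.  The default grid spans a in 0..1.5, b in 0..1.0 and c in 0..0.5 at
step 0.1 with the all-zero triple removed; the default tuning metric is P@1,
since triage optimizes precision at the top of the list.

Ties are broken by the earlier grid position, so results are invariant to
re-runs.  By default the search tunes and reports on the same benchmark
(no held-out split); the report flags this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .evaluation import Qrel, Run, compute_metrics
from .ranking import AxisWeights

#: pipeline handle: weights -> run over the benchmark queries.
Pipeline = Callable[[AxisWeights], Run]

TUNING_METRICS = {"p_at_1": "p_at_1", "map": "ap", "mrr": "rr", "interp_p0": "interp_p0"}


def _frange(stop: float, step: float = 0.1) -> list[float]:
    out, i = [], 0
    while True:
        v = round(i * step, 10)
        if v > stop + 1e-9:
            return out
        out.append(round(v, 2))
        i += 1


@dataclass(frozen=True)
class Grid:
    """Candidate values per coefficient; points() excludes the all-zero triple."""

    a_values: tuple[float, ...]
    b_values: tuple[float, ...]
    c_values: tuple[float, ...]

    def points(self) -> list[AxisWeights]:
        pts = [
            AxisWeights(a, b, c)
            for a in self.a_values
            for b in self.b_values
            for c in self.c_values
            if not (a == 0 and b == 0 and c == 0)
        ]
        return pts

    def __len__(self) -> int:
        total = len(self.a_values) * len(self.b_values) * len(self.c_values)
        if 0.0 in self.a_values and 0.0 in self.b_values and 0.0 in self.c_values:
            total -= 1
        return total


@dataclass
class TuneResult:
    best_weights: AxisWeights
    best_metric_value: float
    metric: str
    table: list[tuple[AxisWeights, float]] = field(default_factory=list)
    held_out: bool = False


def generate_grid(
    a_values: Sequence[float], b_values: Sequence[float], c_values: Sequence[float]
) -> Grid:
    """Build a grid from per-coefficient value lists (deterministic order)."""
    if not (a_values and b_values and c_values):
        raise ValueError("every coefficient needs at least one candidate value")
    grid = Grid(tuple(a_values), tuple(b_values), tuple(c_values))
    if len(grid) == 0:
        raise ValueError("grid contains only the all-zero triple")
    return grid


def default_grid() -> Grid:
    """a in 0..1.5, b in 0..1.0, c in 0..0.5, step 0.1, all-zero removed."""
    return generate_grid(_frange(1.5), _frange(1.0), _frange(0.5))


def grid_search(
    grid: Grid,
    queries: Sequence[str],
    qrel: Qrel,
    pipeline: Pipeline,
    metric: str = "p_at_1",
) -> TuneResult:
    """Evaluate every grid point and return the argmax.

    ``pipeline`` maps a weight triple to a run over the benchmark queries;
    each run is scored with :func:`compute_metrics` against ``qrel`` and the
    mean of ``metric`` is maximized.  Ties keep the earlier grid point.
    """
    if not queries:
        raise ValueError("benchmark has zero queries")
    if metric not in TUNING_METRICS:
        raise ValueError(f"unknown tuning metric {metric!r}; expected one of {sorted(TUNING_METRICS)}")
    metric_attr = TUNING_METRICS[metric]

    best: tuple[AxisWeights, float] | None = None
    table: list[tuple[AxisWeights, float]] = []
    for weights in grid.points():
        run = pipeline(weights)
        report = compute_metrics(run, qrel)
        value = report.mean(metric_attr)
        table.append((weights, value))
        if best is None or value > best[1]:
            best = (weights, value)
    assert best is not None
    return TuneResult(best_weights=best[0], best_metric_value=best[1], metric=metric, table=table)


def write_tuning_report(path: str | Path, result: TuneResult) -> Path:
    """TSV report: one row per combination, best row marked."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# tuning metric: {result.metric}\n")
        if not result.held_out:
            fh.write("# note: tuned and evaluated on the same benchmark (no held-out split)\n")
        fh.write("a_search\tb_index\tc_tf\tmetric_value\tbest\n")
        for weights, value in result.table:
            best = "*" if weights == result.best_weights else ""
            fh.write(f"{weights.a_search}\t{weights.b_index}\t{weights.c_tf}\t{value:.6f}\t{best}\n")
    return path
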