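"""Prediction-rate definitions and cross-participant summaries.

Rates are percentages of correctly predicted minutes:

* overall — all minutes;
* overall transport — minutes whose TRUE label is a transport mode,
  still requiring the exact mode to be predicted;
* per-class recall — minutes of each true class predicted as that class;
* trip vs place (supplementary) — binary accuracy of "on a trip" vs
  "at an activity place", ignoring which mode.

Across leave-one-participant-out iterations, each cell is summarized by
its median and 2.5th / 97.5th percentiles; iterations whose denominator
for a cell is zero are excluded from that cell only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MODES, TRANSPORT_MODES

#: Row order of the report tables.
REPORT_CELLS: tuple[str, ...] = ("overall", "overall_transport") + MODES


class EvaluationError(ValueError):
    pass


@dataclass
class RatesReport:
    """Prediction rates (%) for one prediction series; None = no data."""

    overall: float | None
    overall_transport: float | None
    per_class: dict[str, float | None]
    denominators: dict[str, int]
    trip_vs_place: float | None = None

    def cell(self, name: str) -> float | None:
        if name == "overall":
            return self.overall
        if name == "overall_transport":
            return self.overall_transport
        if name == "trip_vs_place":
            return self.trip_vs_place
        return self.per_class.get(name)

    def as_dict(self) -> dict[str, float | None]:
        out = {"overall": self.overall,
               "overall_transport": self.overall_transport}
        out.update(self.per_class)
        out["trip_vs_place"] = self.trip_vs_place
        return out


def _rate(correct: np.ndarray, mask: np.ndarray) -> tuple[float | None, int]:
    n = int(mask.sum())
    if n == 0:
        return None, 0
    return float(100.0 * correct[mask].mean()), n


def prediction_rates(truth, pred) -> RatesReport:
    """Compute the rate report from aligned truth/prediction arrays."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise EvaluationError(
            f"length mismatch: truth {truth.shape} vs pred {pred.shape}")
    correct = truth == pred
    denominators: dict[str, int] = {}
    overall, denominators["overall"] = _rate(correct,
                                             np.ones(truth.size, dtype=bool))
    is_transport = np.isin(truth, TRANSPORT_MODES)
    overall_transport, denominators["overall_transport"] = _rate(
        correct, is_transport)
    per_class: dict[str, float | None] = {}
    for mode in MODES:
        per_class[mode], denominators[mode] = _rate(correct, truth == mode)
    pred_transport = np.isin(pred, TRANSPORT_MODES)
    binary = is_transport == pred_transport
    trip_vs_place, denominators["trip_vs_place"] = _rate(
        binary, np.ones(truth.size, dtype=bool))
    return RatesReport(overall=overall, overall_transport=overall_transport,
                       per_class=per_class, denominators=denominators,
                       trip_vs_place=trip_vs_place)


@dataclass
class SummaryReport:
    """Cross-iteration cell summaries: median and 2.5/97.5 percentiles."""

    table: pd.DataFrame          # index cells, columns median/p2_5/p97_5/n
    n_iterations: int = 0

    def cell(self, name: str) -> dict[str, float]:
        return self.table.loc[name].to_dict()


def summarize_across_participants(reports: list[RatesReport],
                                  cells: tuple[str, ...] = REPORT_CELLS,
                                  ) -> SummaryReport:
    """Cell-wise median and percentile summary over iterations.

    A cell missing in an iteration (zero denominator) drops that
    iteration from that cell only; ``n`` records how many contributed.
    """
    rows = []
    for cell in cells:
        vals = np.array([r.cell(cell) for r in reports
                         if r.cell(cell) is not None], dtype=float)
        if vals.size:
            rows.append({
                "cell": cell,
                "median": float(np.median(vals)),
                "p2_5": float(np.percentile(vals, 2.5)),
                "p97_5": float(np.percentile(vals, 97.5)),
                "n": int(vals.size),
            })
        else:
            rows.append({"cell": cell, "median": np.nan, "p2_5": np.nan,
                         "p97_5": np.nan, "n": 0})
    table = pd.DataFrame(rows).set_index("cell")
    return SummaryReport(table=table, n_iterations=len(reports))


def format_cell(median: float, p2_5: float, p97_5: float) -> str:
    """Human-readable "median (p2.5-p97.5)" cell, rounded to integers."""
    if np.isnan(median):
        return "-"
    return (f"{median:.0f} ({p2_5:.0f}"
            f"\N{EN DASH}{p97_5:.0f})")


def _format_summary_column(summary: SummaryReport) -> pd.Series:
    t = summary.table
    return pd.Series(
        [format_cell(t.loc[c, "median"], t.loc[c, "p2_5"], t.loc[c, "p97_5"])
         for c in t.index], index=t.index)


def build_report_tables(
    split_reports: dict[str, list[RatesReport]],
    hr_reports: dict[str, list[RatesReport]],
    bandwidth_reports: dict[int, list[RatesReport]],
) -> dict[str, dict[str, pd.DataFrame]]:
    """Assemble the three headline tables.

    * split comparison — naive OOB vs held-out-participant test rates,
      before and after the prevalence cut-off correction (columns of
      ``split_reports``: e.g. ``oob_unweighted``, ``test_weighted``);
    * HR contribution — test rates without vs with heart-rate features;
    * bandwidth sweep — test rates after moving-majority smoothing at
      each bandwidth (0 = before homogenization).

    Returns, per table, a machine-readable numeric frame (cells x
    column x statistic) and a human-readable frame of formatted cells.
    """
    def assemble(columns: dict[str, list[RatesReport]]):
        numeric = {}
        human = {}
        for name, reports in columns.items():
            s = summarize_across_participants(reports)
            for stat in ("median", "p2_5", "p97_5", "n"):
                numeric[(name, stat)] = s.table[stat]
            human[name] = _format_summary_column(s)
        return (pd.DataFrame(numeric), pd.DataFrame(human))

    out: dict[str, dict[str, pd.DataFrame]] = {}
    for key, cols in (("split_comparison", split_reports),
                      ("hr_contribution", hr_reports),
                      ("bandwidth_sweep",
                       {f"bandwidth_{b}": r
                        for b, r in sorted(bandwidth_reports.items())})):
        numeric, human = assemble(cols)
        out[key] = {"numeric": numeric, "human": human}
    return out
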