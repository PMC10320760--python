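"""Threshold classification and the 48-motif prediction benchmark.

A panel of 48 experimentally characterized motifs (gel-shift observed
prenylation status in the Ydj1 reporter context) is packaged together with
the scores of four predictors: PrePS (positive above -2), a published SVM
(calls treated as scores, positive above 0), the Ras-reporter screen EF
(positive above 3), and the Ydj1 HM score (positive above 3).  All four
flow through the same classify/confusion path so their summary statistics
are directly comparable.

Percentage conventions follow the benchmark's printed summary block:
%correct is over all rows, %false positive is over predicted positives,
and %false negative is over predicted negatives.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

#: sha256 of the packaged benchmark fixture (48 rows).
TABLE3_SHA256 = "3a693a7b931f12b47dea860778304301acad19a85b7452128de7a36f780fb7a9"

REQUIRED_COLUMNS = ("protein", "motif", "observed", "percent_shift",
                    "preps_score", "svm_call", "rrs_ef", "ydj1_hm")

#: Predictor -> (score column, positive cutoff); all strict 'greater'.
PREDICTORS: dict[str, tuple[str, float]] = {
    "PrePS": ("preps_score", -2.0),
    "SVM": ("svm_call", 0.0),
    "RRS": ("rrs_ef", 3.0),
    "YDJ1_HM": ("ydj1_hm", 3.0),
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention used for reported percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionSummary:
    """Counts and percentages for one predictor against observed status."""

    n_total: int
    n_correct: int
    n_false_positive: int
    n_false_negative: int
    n_predicted_positive: int
    n_predicted_negative: int

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_total

    @property
    def pct_false_positive(self) -> float:
        if self.n_predicted_positive == 0:
            return 0.0
        return 100.0 * self.n_false_positive / self.n_predicted_positive

    @property
    def pct_false_negative(self) -> float:
        if self.n_predicted_negative == 0:
            return 0.0
        return 100.0 * self.n_false_negative / self.n_predicted_negative

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "n_false_positive": self.n_false_positive,
            "n_false_negative": self.n_false_negative,
            "n_predicted_positive": self.n_predicted_positive,
            "n_predicted_negative": self.n_predicted_negative,
            "pct_correct": self.pct_correct,
            "pct_false_positive": self.pct_false_positive,
            "pct_false_negative": self.pct_false_negative,
            "pct_correct_rounded": round_half_up(self.pct_correct),
            "pct_false_positive_rounded": round_half_up(self.pct_false_positive),
            "pct_false_negative_rounded": round_half_up(self.pct_false_negative),
        }


def classify(
    scores: Mapping[object, float],
    cutoff: float,
    direction: str = "greater",
) -> dict[object, str]:
    """Call each key positive iff its score exceeds the cutoff.

    ``direction`` is ``greater`` (strict, default) or ``greater_equal``;
    a score exactly at the cutoff is negative under the strict convention.
    """
    if direction not in ("greater", "greater_equal"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "greater":
        return {k: ("positive" if v > cutoff else "negative")
                for k, v in scores.items()}
    return {k: ("positive" if v >= cutoff else "negative")
            for k, v in scores.items()}


def confusion(
    predictions: Mapping[object, str],
    observed: Mapping[object, str],
) -> ConfusionSummary:
    """Confusion statistics of predicted vs observed positive/negative."""
    if set(predictions) != set(observed):
        raise ValueError("prediction and observation key sets differ")
    n_total = len(observed)
    fp = fn = correct = pred_pos = 0
    for key, pred in predictions.items():
        obs = observed[key]
        if pred == "positive":
            pred_pos += 1
        if pred == obs:
            correct += 1
        elif pred == "positive":
            fp += 1
        else:
            fn += 1
    return ConfusionSummary(
        n_total=n_total,
        n_correct=correct,
        n_false_positive=fp,
        n_false_negative=fn,
        n_predicted_positive=pred_pos,
        n_predicted_negative=n_total - pred_pos,
    )


def load_table3(path: str | Path | None = None,
                verify_checksum: bool = True) -> pd.DataFrame:
    """Load and validate the packaged 48-row benchmark fixture.

    A user-supplied file with the same columns may be passed instead (the
    checksum is then not enforced).  Duplicate motifs are legitimate: the
    panel lists CKQH twice, and the printed totals require both rows.
    """
    if path is None:
        ref = resources.files("caaxscreen.data").joinpath("table3.tsv")
        raw = ref.read_bytes()
        if verify_checksum:
            digest = hashlib.sha256(raw).hexdigest()
            if digest != TABLE3_SHA256:
                raise ValueError(
                    f"packaged benchmark fixture checksum mismatch: {digest}")
        from io import BytesIO
        # keep_default_na: the panel uses the literal label "NA" for
        # motifs without a named protein
        df = pd.read_csv(BytesIO(raw), sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"benchmark table missing columns: {missing}")
    if df[list(REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError("benchmark table has unpopulated fields")
    bad = df.loc[~df["observed"].isin(["+", "-"]), "observed"]
    if len(bad):
        raise ValueError(f"invalid observed status values: {bad.tolist()}")
    if path is None and len(df) != 48:
        raise ValueError(f"packaged fixture must have 48 rows, got {len(df)}")
    return df


def benchmark_table3(df: pd.DataFrame | None = None
                     ) -> dict[str, ConfusionSummary]:
    """Run all four predictors through classify/confusion on the panel.

    Rows are keyed by index (not motif) so duplicated motifs stay distinct.
    """
    if df is None:
        df = load_table3()
    observed = {i: ("positive" if v == "+" else "negative")
                for i, v in df["observed"].items()}
    report: dict[str, ConfusionSummary] = {}
    for name, (column, cutoff) in PREDICTORS.items():
        scores = dict(df[column].astype(float).items())
        preds = classify(scores, cutoff, "greater")
        report[name] = confusion(preds, observed)
    return report


def format_benchmark(report: Mapping[str, ConfusionSummary]) -> str:
    """Human-readable benchmark summary block."""
    names = list(report)
    lines = [
        "predictor            " + "".join(f"{n:>10}" for n in names),
        "# predicted correctly" + "".join(
            f"{report[n].n_correct:>10}" for n in names),
        "# false positive     " + "".join(
            f"{report[n].n_false_positive:>10}" for n in names),
        "# false negative     " + "".join(
            f"{report[n].n_false_negative:>10}" for n in names),
        "% predicted correctly" + "".join(
            f"{round_half_up(report[n].pct_correct):>9}%" for n in names),
        "% false positive     " + "".join(
            f"{round_half_up(report[n].pct_false_positive):>9}%" for n in names),
        "% false negative     " + "".join(
            f"{round_half_up(report[n].pct_false_negative):>9}%" for n in names),
    ]
    return "\n".join(lines)


def write_benchmark(report: Mapping[str, ConfusionSummary],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({name: summ.to_dict() for name, summ in report.items()},
                  fh, indent=2)
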