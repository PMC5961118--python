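"""Accuracy, confusion matrices, region-count tuning and metadata audits.

Accuracy follows a strict denominator rule: only samples whose reported
value is present, meaningful, and one of the model's levels enter the
denominator; everything excluded is tallied by reason. Unassigned
predictions are in the denominator and count as incorrect — abstention is
penalized, not forgiven. Sensitivity and specificity are one-vs-rest per
level, with undefined ratios reported as NaN (never 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categorical import UNASSIGNED, build_predictor, test_predictor
from .matrix import ExpressionMatrix
from .phenotypes import PhenotypeTable, ValueStatus
from .selection import select_regions

logger = logging.getLogger(__name__)

#: Minimum training accuracy (percent) for a predictor to be releasable.
RELEASE_ACCURACY_THRESHOLD = 85.0


# ---------------------------------------------------------------------------
# accuracy and confusion
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Accuracy summary over the usable denominator."""

    accuracy: float                      # percent
    n_denominator: int
    n_correct: int
    excluded: dict[str, int]             # reason -> count
    confusion: pd.DataFrame | None = None
    rates: pd.DataFrame | None = None    # per-level sensitivity/specificity (%)

    @property
    def releasable(self) -> bool:
        return self.accuracy >= RELEASE_ACCURACY_THRESHOLD


def _usable_denominator(
    predicted: np.ndarray,
    pheno: PhenotypeTable,
    column: str,
    model_levels: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, int]]:
    predicted = np.asarray(predicted, dtype=object)
    if predicted.shape[0] != len(pheno.samples):
        raise ValueError("predictions do not cover all samples")
    status = pheno.status[column].to_numpy()
    reported = pheno.values(column)
    level_set = set(model_levels)
    in_model = np.array([v in level_set for v in reported], dtype=bool)
    mask = (status == ValueStatus.OK.value) & in_model
    excluded = {
        "missing": int(np.sum(status == ValueStatus.MISSING.value)),
        "non_meaningful": int(np.sum(status == ValueStatus.NON_MEANINGFUL.value)),
        "level_not_in_model": int(
            np.sum((status == ValueStatus.OK.value) & ~in_model)
        ),
    }
    return predicted, reported, mask, excluded


def compute_accuracy(
    predicted: np.ndarray,
    pheno: PhenotypeTable,
    column: str,
    model_levels: list[str],
) -> EvaluationReport:
    """Accuracy = 100 x correct / predicted over the usable denominator."""
    predicted, reported, mask, excluded = _usable_denominator(
        predicted, pheno, column, model_levels
    )
    n_denom = int(mask.sum())
    if n_denom == 0:
        raise ValueError("denominator is empty: accuracy undefined")
    n_correct = int(np.sum(predicted[mask] == reported[mask]))
    confusion, rates = confusion_and_rates(
        predicted[mask], reported[mask], model_levels
    )
    return EvaluationReport(
        accuracy=100.0 * n_correct / n_denom,
        n_denominator=n_denom,
        n_correct=n_correct,
        excluded=excluded,
        confusion=confusion,
        rates=rates,
    )


def confusion_and_rates(
    predicted: np.ndarray,
    reported: np.ndarray,
    levels: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix (rows reported, columns predicted + unassigned) and
    one-vs-rest sensitivity/specificity per level, in percent.

    Unassigned counts as a negative prediction for every level: it adds to
    the false negatives of the true level and the true negatives of the
    others.
    """
    predicted = np.asarray(predicted, dtype=object)
    reported = np.asarray(reported, dtype=object)
    cols = list(levels) + [UNASSIGNED]
    conf = pd.DataFrame(0, index=list(levels), columns=cols, dtype=int)
    for rep, pred in zip(reported, predicted):
        if rep not in conf.index:
            continue
        col = pred if pred in cols else UNASSIGNED
        conf.loc[rep, col] += 1
    total = int(conf.to_numpy().sum())
    rows = []
    for lev in levels:
        tp = int(conf.loc[lev, lev])
        fn = int(conf.loc[lev].sum() - tp)
        fp = int(conf[lev].sum() - tp)
        tn = total - tp - fn - fp
        sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else np.nan
        spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else np.nan
        rows.append(
            {"level": lev, "TP": tp, "FN": fn, "FP": fp, "TN": tn,
             "sensitivity": sens, "specificity": spec}
        )
    return conf, pd.DataFrame(rows).set_index("level")


# ---------------------------------------------------------------------------
# region-count tuning
# ---------------------------------------------------------------------------

#: Eight candidate values spanning 10-200 regions per level.
DEFAULT_NUM_REGIONS_GRID = (10, 20, 40, 60, 80, 100, 150, 200)


@dataclass
class TuningCurve:
    """Training accuracy per candidate region count and the chosen value.

    ``chosen`` is the smallest candidate attaining the maximum accuracy —
    the cost of building and applying the predictor grows with the region
    count, so ties break toward fewer regions.
    """

    candidates: list[int]
    accuracy: list[float]           # percent; NaN where a candidate failed
    chosen: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"num_regions": self.candidates, "accuracy": self.accuracy})


def optimize_num_regions(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    column: str,
    candidates=DEFAULT_NUM_REGIONS_GRID,
    seed: int | None = None,
) -> TuningCurve:
    """Tune the per-level region count by resubstitution accuracy.

    For each candidate n: select regions, build the predictor, and score it
    on the data it was built from. Degenerate failures record NaN and are
    excluded from the argmax. ``seed`` is recorded for provenance; the
    procedure itself is deterministic.
    """
    candidates = [int(c) for c in candidates]
    if not candidates or any(c < 1 for c in candidates):
        raise ValueError("candidates must be a non-empty list of integers >= 1")
    accuracies: dict[int, float] = {}
    for n in sorted(set(candidates)):
        try:
            selection = select_regions(m, pheno, column, n)
            model = build_predictor(
                m, pheno, column, selection, provenance={"seed": seed, "num_regions": n}
            )
            report = test_predictor(m, pheno, model)
            accuracies[n] = report.accuracy
        except ValueError as exc:
            logger.warning("candidate n = %d failed: %s", n, exc)
            accuracies[n] = float("nan")
    curve = [accuracies[int(c)] for c in candidates]
    finite = {n: a for n, a in accuracies.items() if np.isfinite(a)}
    if not finite:
        raise ValueError("every candidate failed; no tuning possible")
    best = max(finite.values())
    chosen = min(n for n, a in finite.items() if a == best)
    return TuningCurve(candidates=candidates, accuracy=curve, chosen=chosen)


# ---------------------------------------------------------------------------
# sequencing-strategy audit
# ---------------------------------------------------------------------------

def audit_sequencing_strategy(
    reported,
    reads_counted,
    spots,
    rule: str = "printed",
) -> pd.DataFrame:
    """Cross-check reported single/paired library layout against read counts.

    ``printed`` rule: a sample reported single-end whose counted reads
    exceed its reported spots is flagged misreported-should-be-paired; a
    sample reported paired-end with exactly twice as many spots as counted
    reads is flagged misreported-should-be-single. The ``inverted`` rule
    replaces the paired-end condition with reads_counted == spots (one read
    per spot indicating a single-end run).
    """
    reported = np.asarray(reported, dtype=object)
    reads = np.asarray(reads_counted, dtype=np.int64)
    spots_arr = np.asarray(spots, dtype=np.int64)
    if np.any(reads < 0) or np.any(spots_arr < 0):
        raise ValueError("read and spot counts must be non-negative")
    if rule not in {"printed", "inverted"}:
        raise ValueError(f"unknown audit rule {rule!r}")
    verdicts = []
    for rep, r, s in zip(reported, reads, spots_arr):
        rep_norm = str(rep).strip().lower()
        if rep_norm in {"single", "single end", "single-end"}:
            verdict = "misreported-should-be-paired" if r > s else "consistent"
        elif rep_norm in {"paired", "paired end", "paired-end"}:
            if rule == "printed":
                flag = s == 2 * r
            else:
                flag = r == s
            verdict = "misreported-should-be-single" if flag else "consistent"
        else:
            verdict = "unrecognized-strategy"
        verdicts.append(verdict)
    return pd.DataFrame(
        {"reported": reported, "reads_counted": reads, "spots": spots_arr,
         "verdict": verdicts}
    )


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def summarize_cohort(labels, groups) -> tuple[pd.DataFrame, pd.Series]:
    """Classify each group by its predicted-label composition.

    A group is "<level> only" when all its samples share one predicted
    level, "unassigned only" when all are unassigned, and "mixed"
    otherwise. Also returns overall per-label percentages.
    """
    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(groups, dtype=object)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must align")
    df = pd.DataFrame({"label": labels, "group": groups})
    rows = []
    for group, sub in df.groupby("group", sort=True):
        uniq = set(sub["label"])
        if uniq == {UNASSIGNED}:
            composition = "unassigned only"
        elif len(uniq) == 1:
            composition = f"{next(iter(uniq))} only"
        else:
            composition = "mixed"
        rows.append({"group": group, "n_samples": len(sub), "composition": composition})
    overall = 100.0 * df["label"].value_counts(normalize=True)
    return pd.DataFrame(rows).set_index("group"), overall
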