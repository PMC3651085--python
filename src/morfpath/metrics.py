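"""Scoring engine start-codon calls against a trusted reference annotation.

Per mORF, an engine's call is classified as

* ``correct`` — the engine has a member in a reference-bearing mORF and its
  start coordinate equals the reference start exactly (no tolerance);
* ``incorrect`` — member present in a reference-bearing mORF, start differs;
* ``false_positive`` — member present in a mORF with no reference member;
* ``false_negative`` — no member in a reference-bearing mORF;
* ``absent`` — no member in a reference-free mORF (another engine's FP);
  bookkeeping only, never scored.

From the per-engine counts,

* error-rate  = (incorrect + FP) / (correct + incorrect + FP)
* specificity = 1 - error-rate = correct / (correct + incorrect + FP)
* sensitivity = (correct + incorrect) / n_reference

``fp_mode="exclude"`` drops false positives from the error-rate/specificity
ratio (incorrect / (correct + incorrect)); the default includes them so that
specificity is exactly the fraction of made predictions that are correct.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, UndefinedMetricError
from .io import Orf, REFERENCE_SOURCE
from .morf import MOrf

logger = logging.getLogger(__name__)

LENGTH_BIAS_THRESHOLD_NT = 750


class CallLabel(str, enum.Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    FALSE_POSITIVE = "false_positive"
    FALSE_NEGATIVE = "false_negative"
    ABSENT = "absent"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScoreCounts:
    """Per-engine (or per-combination) classification tallies."""

    n_correct: int = 0
    n_incorrect: int = 0
    n_fp: int = 0
    n_fn: int = 0
    n_reference: int = 0

    @property
    def predictions(self) -> int:
        return self.n_correct + self.n_incorrect + self.n_fp

    def __add__(self, other: "ScoreCounts") -> "ScoreCounts":
        return ScoreCounts(self.n_correct + other.n_correct,
                           self.n_incorrect + other.n_incorrect,
                           self.n_fp + other.n_fp,
                           self.n_fn + other.n_fn,
                           self.n_reference + other.n_reference)


def classify(morfs: Sequence[MOrf], engine: str) -> dict[str, CallLabel]:
    """Classify one engine's start call in every mORF.

    Multi-call mORFs are resolved before scoring: the engine member whose
    start lies closest to the reference start is the one compared.
    """
    labels: dict[str, CallLabel] = {}
    seen_any = False
    for morf in morfs:
        member = morf.member(engine)
        ref = morf.reference_member
        if member is not None:
            seen_any = True
            if ref is None:
                labels[morf.morf_id] = CallLabel.FALSE_POSITIVE
            elif member.start_coord == ref.start_coord:
                labels[morf.morf_id] = CallLabel.CORRECT
            else:
                labels[morf.morf_id] = CallLabel.INCORRECT
        else:
            if ref is None:
                labels[morf.morf_id] = CallLabel.ABSENT
            else:
                labels[morf.morf_id] = CallLabel.FALSE_NEGATIVE
    if not seen_any:
        logger.warning("engine %s has no member in any mORF; all calls are "
                       "false_negative/absent", engine)
    return labels


def count_labels(labels: Iterable[CallLabel]) -> ScoreCounts:
    tally = {label: 0 for label in CallLabel}
    for label in labels:
        tally[label] += 1
    n_reference = (tally[CallLabel.CORRECT] + tally[CallLabel.INCORRECT]
                   + tally[CallLabel.FALSE_NEGATIVE])
    return ScoreCounts(n_correct=tally[CallLabel.CORRECT],
                       n_incorrect=tally[CallLabel.INCORRECT],
                       n_fp=tally[CallLabel.FALSE_POSITIVE],
                       n_fn=tally[CallLabel.FALSE_NEGATIVE],
                       n_reference=n_reference)


def score_engine(morfs: Sequence[MOrf], engine: str) -> ScoreCounts:
    return count_labels(classify(morfs, engine).values())


def error_rate(counts: ScoreCounts, fp_mode: str = "include") -> float:
    """Fraction of made predictions that are wrong (formula-level inverse of
    :func:`specificity`)."""
    if fp_mode == "include":
        denom = counts.predictions
        num = counts.n_incorrect + counts.n_fp
    elif fp_mode == "exclude":
        denom = counts.n_correct + counts.n_incorrect
        num = counts.n_incorrect
    else:
        raise ValueError(f"unknown fp_mode {fp_mode!r}")
    if denom == 0:
        raise UndefinedMetricError("error-rate undefined with zero "
                                   "predictions")
    return num / denom


def specificity(counts: ScoreCounts, fp_mode: str = "include") -> float:
    """Fraction of made predictions whose start coordinate is correct."""
    return 1.0 - error_rate(counts, fp_mode=fp_mode)


def sensitivity(counts: ScoreCounts) -> float:
    """Coverage of the reference: fraction of reference ORFs recovered by
    any call, with either a correct or an incorrect start."""
    if counts.n_reference == 0:
        raise UndefinedMetricError("sensitivity undefined with zero "
                                   "reference ORFs")
    return (counts.n_correct + counts.n_incorrect) / counts.n_reference


def length_bias_test(flagged: Iterable[Orf], all_ref: Iterable[Orf],
                     threshold_nt: int = LENGTH_BIAS_THRESHOLD_NT
                     ) -> tuple[float, float, np.ndarray]:
    """Chi-square test for enrichment of short ORFs among flagged ones.

    Builds the 2x2 table (flagged vs not) x (length < threshold vs >=) over
    the reference ORFs and applies Pearson's chi-square without continuity
    correction.  Returns ``(statistic, p_value, table)`` with table rows
    (flagged, not flagged) and columns (short, long).
    """
    all_ref = list(all_ref)
    flagged_keys = {o.coords_key for o in flagged}
    unknown = flagged_keys - {o.coords_key for o in all_ref}
    if unknown:
        raise ValueError(f"{len(unknown)} flagged ORFs are not part of the "
                         "reference set")
    table = np.zeros((2, 2), dtype=int)
    for orf in all_ref:
        row = 0 if orf.coords_key in flagged_keys else 1
        col = 0 if orf.length < threshold_nt else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"degenerate 2x2 table {table.tolist()}")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), table


def summarize_engines(morfs: Sequence[MOrf], panel: Sequence[str],
                      fp_mode: str = "include") -> pd.DataFrame:
    """Per-engine score summary: counts plus error-rate, specificity and
    sensitivity, one row per engine."""
    rows = []
    for engine in panel:
        counts = score_engine(morfs, engine)
        row = {"engine": engine,
               "n_correct": counts.n_correct,
               "n_incorrect": counts.n_incorrect,
               "n_fp": counts.n_fp,
               "n_fn": counts.n_fn,
               "n_reference": counts.n_reference}
        try:
            row["error_rate"] = error_rate(counts, fp_mode=fp_mode)
            row["specificity"] = specificity(counts, fp_mode=fp_mode)
        except UndefinedMetricError:
            row["error_rate"] = np.nan
            row["specificity"] = np.nan
        try:
            row["sensitivity"] = sensitivity(counts)
        except UndefinedMetricError:
            row["sensitivity"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
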