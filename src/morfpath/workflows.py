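"""End-to-end orchestration: evaluate, vote, train and apply, as plain
Python functions.

These functions are the package's operational surface — the equivalents of
what a shell tool would expose as subcommands.  Each takes in-memory
prediction sets (or file paths via :class:`RunConfig`), runs the mORF
assignment -> classification -> combination pipeline, and returns pandas
DataFrames ready for :func:`morfpath.io.write_report`.  Given identical
inputs, configuration and seed, every report is byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .combine import Combination, majority_vote
from .errors import ConfigurationError
from .io import (PredictionSet, REFERENCE_SOURCE, read_annotation,
                 write_report)
from .metrics import (CallLabel, classify, count_labels, summarize_engines)
from .morf import MOrf, assign_morfs, morf_dump_table
from .path import (DEFAULT_IMPACT_FORM, DEFAULT_MAX_ROUNDS, PathSpec,
                   RoundResult, apply_path, run_path, train_general_path)
from .simulate import (CorrelationSpec, EngineProfile, default_panel_profiles,
                       generate_reference, simulate_panel)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Shared knobs for the workflow functions.

    ``panel`` maps engine names to annotation file paths; ``reference_path``
    optionally points at the trusted annotation.  Defaults follow the
    published protocol: 10% grouping margin, five path rounds, false
    positives included in the error-rate denominator.
    """

    panel: dict[str, str] = field(default_factory=dict)
    reference_path: Optional[str] = None
    margin_fraction: float = 0.10
    max_rounds: int = DEFAULT_MAX_ROUNDS
    fp_mode: str = "include"
    impact_form: str = DEFAULT_IMPACT_FORM
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.margin_fraction <= 0.5:
            raise ConfigurationError("margin_fraction must be in (0, 0.5]")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds must be >= 1")

    def load_sets(self) -> tuple[list[PredictionSet],
                                 Optional[PredictionSet]]:
        sets = []
        for engine, path in self.panel.items():
            if not Path(path).exists():
                raise ConfigurationError(
                    f"annotation file for engine {engine!r} not found: "
                    f"{path}")
            sets.append(read_annotation(path, source_label=engine))
        reference = None
        if self.reference_path is not None:
            reference = read_annotation(self.reference_path,
                                        source_label=REFERENCE_SOURCE)
        return sets, reference


def build_morf_table(morfs: Sequence[MOrf], panel: Sequence[str],
                     labels: Optional[Mapping[str, Mapping[str, CallLabel]]]
                     = None,
                     path_calls: Optional[Mapping] = None) -> pd.DataFrame:
    """One row per mORF: coordinates, each engine's start call and label,
    and (when a path was applied) the calling round and its projected
    confidence."""
    rows = []
    for morf in morfs:
        ref = morf.reference_member
        row: dict = {
            "morf_id": morf.morf_id,
            "contig": morf.contig,
            "strand": morf.strand,
            "ref_start": ref.start_coord if ref else pd.NA,
            "ref_stop": ref.stop_coord if ref else pd.NA,
        }
        for engine in panel:
            start = morf.start_of(engine)
            row[f"{engine}_start"] = pd.NA if start is None else start
            if labels is not None:
                label = labels.get(engine, {}).get(morf.morf_id)
                row[f"{engine}_label"] = (pd.NA if label is None
                                          else label.value)
        if path_calls is not None:
            call = path_calls.get(morf.morf_id)
            if call is None or call.start is None:
                row["path_start"] = pd.NA
                row["path_round"] = pd.NA
                row["projected_confidence"] = pd.NA
            else:
                row["path_start"] = call.start
                row["path_round"] = call.round_index
                row["projected_confidence"] = call.projected_confidence
        rows.append(row)
    columns = ["morf_id", "contig", "strand", "ref_start", "ref_stop"]
    for engine in panel:
        columns.append(f"{engine}_start")
        if labels is not None:
            columns.append(f"{engine}_label")
    if path_calls is not None:
        columns += ["path_start", "path_round", "projected_confidence"]
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values("morf_id", kind="mergesort",
                             ignore_index=True)


def evaluate(sets: Sequence[PredictionSet], reference: PredictionSet,
             *, margin_fraction: float = 0.10, fp_mode: str = "include",
             containment: bool = False, anchor: Optional[str] = None
             ) -> tuple[list[MOrf], pd.DataFrame, pd.DataFrame]:
    """Score every engine against the reference on one genome.

    Returns ``(morfs, summary, morf_table)`` — the mORF partition, the
    per-engine count/metric summary and the per-mORF call table.
    """
    panel = [s.source for s in sets]
    morfs = assign_morfs(sets, reference, margin_fraction=margin_fraction,
                         containment=containment, anchor=anchor)
    labels = {engine: classify(morfs, engine) for engine in panel}
    summary = summarize_engines(morfs, panel, fp_mode=fp_mode)
    table = build_morf_table(morfs, panel, labels=labels)
    return morfs, summary, table


def vote(sets: Sequence[PredictionSet], reference: PredictionSet,
         *, margin_fraction: float = 0.10, fp_mode: str = "include",
         denominator: str = "panel") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Majority-voting baseline on one genome.

    Returns ``(summary, calls)``: a one-row summary with the vote's counts
    and metrics, and the per-mORF voted coordinate with its label.
    """
    panel = [s.source for s in sets]
    morfs = assign_morfs(sets, reference, margin_fraction=margin_fraction)
    rows = []
    for morf in morfs:
        coord = majority_vote(morf, panel, denominator=denominator)
        ref = morf.reference_member
        if coord is not None:
            if ref is None:
                label = CallLabel.FALSE_POSITIVE
            elif coord == ref.start_coord:
                label = CallLabel.CORRECT
            else:
                label = CallLabel.INCORRECT
        else:
            label = (CallLabel.FALSE_NEGATIVE if ref is not None
                     else CallLabel.ABSENT)
        rows.append({"morf_id": morf.morf_id,
                     "voted_start": coord if coord is not None else pd.NA,
                     "label": label.value})
    calls = pd.DataFrame(rows, columns=["morf_id", "voted_start", "label"])
    counts = count_labels(CallLabel(v) for v in calls["label"])
    from .metrics import error_rate, sensitivity, specificity
    summary = pd.DataFrame([{
        "method": "majority_vote",
        "n_correct": counts.n_correct,
        "n_incorrect": counts.n_incorrect,
        "n_fp": counts.n_fp,
        "n_fn": counts.n_fn,
        "n_reference": counts.n_reference,
        "error_rate": (error_rate(counts, fp_mode=fp_mode)
                       if counts.predictions else np.nan),
        "specificity": (specificity(counts, fp_mode=fp_mode)
                        if counts.predictions else np.nan),
        "sensitivity": (sensitivity(counts)
                        if counts.n_reference else np.nan),
    }])
    return summary, calls


def train_path_workflow(genomes: Mapping[str, tuple[Sequence[PredictionSet],
                                                    PredictionSet]],
                        *, margin_fraction: float = 0.10,
                        max_rounds: int = DEFAULT_MAX_ROUNDS,
                        fp_mode: str = "include",
                        impact_form: str = DEFAULT_IMPACT_FORM) -> PathSpec:
    """Train a general consensus path on several reference genomes.

    ``genomes`` maps genome name -> (engine prediction sets, reference set);
    every genome must use the same engine panel.
    """
    panels = {name: tuple(sorted(s.source for s in sets))
              for name, (sets, _) in genomes.items()}
    if len(set(panels.values())) > 1:
        raise ConfigurationError(
            f"genomes use different engine panels: {panels}")
    genome_morfs = {}
    for name, (sets, reference) in genomes.items():
        genome_morfs[name] = assign_morfs(sets, reference,
                                          margin_fraction=margin_fraction)
    panel = sorted(next(iter(panels.values())))
    return train_general_path(genome_morfs, panel, max_rounds=max_rounds,
                              fp_mode=fp_mode, impact_form=impact_form)


def apply_path_workflow(sets: Sequence[PredictionSet], path: PathSpec,
                        *, margin_fraction: float = 0.10,
                        reference: Optional[PredictionSet] = None
                        ) -> pd.DataFrame:
    """Apply a trained path to a (typically reference-free) genome and
    return the per-mORF report table."""
    panel = [s.source for s in sets]
    morfs = assign_morfs(sets, reference, margin_fraction=margin_fraction)
    calls = apply_path(morfs, path)
    labels = None
    if reference is not None:
        labels = {engine: classify(morfs, engine) for engine in panel}
    return build_morf_table(morfs, panel, labels=labels, path_calls=calls)


def simulate_workflow(n_orfs: int = 2000, seed: int = 0,
                      profiles: Optional[Sequence[EngineProfile]] = None,
                      corr: Optional[CorrelationSpec] = None,
                      outdir: Optional[str] = None
                      ) -> tuple[PredictionSet, list[PredictionSet]]:
    """Generate a synthetic genome and panel; optionally write GFF3/TSV."""
    profiles = list(profiles) if profiles else default_panel_profiles()
    reference = generate_reference(n_orfs=n_orfs, seed=seed)
    sets = simulate_panel(reference, profiles, corr, seed=seed)
    if outdir is not None:
        from .io import write_gff3, write_tsv
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gff3(reference, out / "reference.gff3")
        write_tsv(reference, out / "reference.tsv")
        for pset in sets:
            write_gff3(pset, out / f"{pset.source}.gff3")
            write_tsv(pset, out / f"{pset.source}.tsv")
    return reference, sets
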