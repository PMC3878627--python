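"""Scoring alignments against held-out identifications or ground truth.

*Recall* is the fraction of cross-run feature pairs sharing an
identification (at or above a score threshold, seed groups excluded)
that the alignment matched.  The *mismatch rate* is the number of
matched pairs carrying conflicting identifications divided by all
matched pairs — including pairs where neither member is identified
("unidentifiable"), so it is not a false-discovery rate.  Sequence
conflict is exact case-normalized string inequality: an
isoleucine/leucine swap or permuted residue order counts as a conflict.

Decoy scoring counts, per match-probability threshold, matched pairs
whose members come from the same vs. different species; cross-species
matches estimate false matching with no identification bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import AlignmentResult

__all__ = [
    "EvaluationError",
    "EvaluationReport",
    "recall_rate",
    "mismatch_rate",
    "decoy_species_counts",
    "identifications_frame",
    "ground_truth_identifications",
    "evaluation_report",
]

Key = tuple[str, int]  # (dataset_label, feature_id)


class EvaluationError(ValueError):
    """Undefined rate (empty denominator) or missing labels."""


@dataclass
class EvaluationReport:
    recall: float
    mismatch: float
    n_correct: int
    n_mismatched: int
    n_unidentifiable: int
    n_matches: int
    threshold_curve: pd.DataFrame  # columns: prob_threshold, recall, mismatch

    def summary(self) -> str:
        lines = [
            f"matched pairs:        {self.n_matches}",
            f"  correct:            {self.n_correct}",
            f"  mismatched:         {self.n_mismatched}",
            f"  unidentifiable:     {self.n_unidentifiable}",
            f"recall rate:          {self.recall:.4f}",
            f"mismatch rate:        {self.mismatch:.4f}",
        ]
        return "\n".join(lines)


def identifications_frame(datasets) -> pd.DataFrame:
    """Collect (dataset_label, feature_id, sequence, score) for identified features."""
    rows = [
        {
            "dataset_label": fs.dataset_label,
            "feature_id": f.feature_index,
            "sequence": f.sequence.upper(),
            "score": f.id_score if f.id_score is not None else 0.0,
        }
        for fs in datasets
        for f in fs.features
        if f.sequence is not None
    ]
    return pd.DataFrame(
        rows, columns=["dataset_label", "feature_id", "sequence", "score"]
    )


def ground_truth_identifications(truth, datasets) -> pd.DataFrame:
    """Treat every feature's true latent peptide as a perfect identification."""
    label_of = {d: fs.dataset_label for d, fs in enumerate(datasets)}
    rows = [
        {
            "dataset_label": label_of[d],
            "feature_id": fid,
            "sequence": truth.sequences[j],
            "score": 100.0,
        }
        for (d, fid), j in truth.assignment.items()
    ]
    return pd.DataFrame(
        rows, columns=["dataset_label", "feature_id", "sequence", "score"]
    )


def _matched_pairs(alignment: AlignmentResult, prob_threshold: float = 0.0):
    return list(alignment.pairwise_matches(threshold=prob_threshold))


def _sequence_of(identifications: pd.DataFrame, score_threshold: float):
    df = identifications[identifications["score"] >= score_threshold]
    return {
        (row.dataset_label, int(row.feature_id)): str(row.sequence).upper()
        for row in df.itertuples()
    }


def recall_rate(
    alignment: AlignmentResult,
    identifications: pd.DataFrame,
    score_threshold: float = 0.0,
    prob_threshold: float = 0.0,
    exclude: Optional[Sequence[frozenset]] = None,
) -> float:
    """Fraction of shared identifications the alignment recovered.

    Denominator: cross-dataset feature pairs sharing a sequence at score
    >= *score_threshold* (pairs listed in *exclude* — typically the seed
    groups — are left out).  Numerator: those pairs matched at pairwise
    probability >= *prob_threshold*.
    """
    seq_of = _sequence_of(identifications, score_threshold)
    excluded = set(exclude or [])
    by_seq: dict[str, list[Key]] = {}
    for key, seq in seq_of.items():
        by_seq.setdefault(seq, []).append(key)
    expected = set()
    for keys in by_seq.values():
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                if keys[x][0] != keys[y][0]:
                    pair = frozenset((keys[x], keys[y]))
                    if pair not in excluded:
                        expected.add(pair)
    if not expected:
        raise EvaluationError(
            "no shared identifications at this score threshold; recall undefined"
        )
    matched = {
        frozenset((a, b)) for a, b, _p in _matched_pairs(alignment, prob_threshold)
    }
    return len(expected & matched) / len(expected)


def mismatch_rate(
    alignment: AlignmentResult,
    identifications: pd.DataFrame,
    score_threshold: float = 0.0,
    prob_threshold: float = 0.0,
    exclude: Optional[Sequence[frozenset]] = None,
) -> float:
    """Conflicting-identification pairs over all matched pairs.

    The denominator includes unidentifiable matches (neither member
    identified), per the reporting convention for this statistic.
    """
    seq_of = _sequence_of(identifications, score_threshold)
    excluded = set(exclude or [])
    pairs = [
        (a, b)
        for a, b, _p in _matched_pairs(alignment, prob_threshold)
        if frozenset((a, b)) not in excluded
    ]
    if not pairs:
        raise EvaluationError("alignment produced no matches; rate undefined")
    n_mis = sum(
        1
        for a, b in pairs
        if a in seq_of and b in seq_of and seq_of[a] != seq_of[b]
    )
    return n_mis / len(pairs)


def evaluation_report(
    alignment: AlignmentResult,
    identifications: pd.DataFrame,
    score_threshold: float = 0.0,
    prob_thresholds: Sequence[float] = (0.0,),
    exclude: Optional[Sequence[frozenset]] = None,
) -> EvaluationReport:
    seq_of = _sequence_of(identifications, score_threshold)
    excluded = set(exclude or [])
    pairs = [
        (a, b)
        for a, b, _p in _matched_pairs(alignment)
        if frozenset((a, b)) not in excluded
    ]
    n_correct = sum(
        1 for a, b in pairs if a in seq_of and b in seq_of and seq_of[a] == seq_of[b]
    )
    n_mis = sum(
        1 for a, b in pairs if a in seq_of and b in seq_of and seq_of[a] != seq_of[b]
    )
    n_unid = sum(1 for a, b in pairs if a not in seq_of and b not in seq_of)
    curve = []
    for tau in prob_thresholds:
        try:
            rec = recall_rate(alignment, identifications, score_threshold, tau, exclude)
        except EvaluationError:
            rec = np.nan
        try:
            mis = mismatch_rate(alignment, identifications, score_threshold, tau, exclude)
        except EvaluationError:
            mis = np.nan
        curve.append({"prob_threshold": tau, "recall": rec, "mismatch": mis})
    return EvaluationReport(
        recall=recall_rate(alignment, identifications, score_threshold, 0.0, exclude),
        mismatch=(n_mis / len(pairs)) if pairs else np.nan,
        n_correct=n_correct,
        n_mismatched=n_mis,
        n_unidentifiable=n_unid,
        n_matches=len(pairs),
        threshold_curve=pd.DataFrame(curve),
    )


def decoy_species_counts(
    alignment: AlignmentResult,
    species_labels: Mapping[Key, str],
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10)),
) -> pd.DataFrame:
    """Per-threshold counts of same-species and cross-species matches.

    Every matched feature must carry a species label; the default sweep
    runs match-probability cutoffs 0.1 ... 1.0 in 0.1 steps.
    """
    pairs = _matched_pairs(alignment)
    for a, b, _p in pairs:
        if a not in species_labels or b not in species_labels:
            raise EvaluationError(f"feature {a if a not in species_labels else b} has no species label")
    rows = []
    for tau in thresholds:
        correct = sum(
            1 for a, b, p in pairs if p >= tau and species_labels[a] == species_labels[b]
        )
        incorrect = sum(
            1 for a, b, p in pairs if p >= tau and species_labels[a] != species_labels[b]
        )
        rows.append({"threshold": tau, "correct": correct, "incorrect": incorrect})
    return pd.DataFrame(rows)
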