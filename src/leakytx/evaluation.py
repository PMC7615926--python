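"""Confusion-matrix evaluation of classifiers against curated marker lists.

The unit of evaluation is the gene–dataset combination: one marker gene's
classification in one dataset.  Four classification methods are scored:

* ``gt0_tpm`` — predicted positive iff TPM > 0 (detection alone);
* ``gt1_tpm`` — predicted positive iff TPM > 1 (the common heuristic);
* ``gmm``     — predicted positive iff the posterior label is ``active``;
  ``undetermined`` combinations are excluded from the matrix;
* ``ztpm``    — predicted positive iff the z-score exceeds the threshold.

Under every method a gene with TPM = 0 is a predicted negative (absence of
transcripts and zero counts are indistinguishable downstream, so a marker
gene missing from a dataset's table counts as TPM = 0).  Each method draws
only on the datasets eligible for it, so denominators differ between
methods; excluded undetermined combinations are counted for transparency.

Sensitivity = TP / (TP + FN) over actual-positive combinations;
specificity = TN / (TN + FP) over actual-negative combinations.  Empty
denominators yield ``None`` (undefined, distinct from zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import DatasetCalls

__all__ = [
    "METHODS",
    "MarkerSet",
    "EvaluationResult",
    "predict_for_method",
    "confusion_matrix",
    "evaluate_all",
    "results_to_frame",
]

METHODS = ("gt0_tpm", "gt1_tpm", "gmm", "ztpm")


@dataclass(frozen=True)
class MarkerSet:
    """Curated actual-positive and actual-negative marker genes."""

    positives: frozenset[str]
    negatives: frozenset[str]
    label: str = "markers"

    def __post_init__(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("marker set needs both positives and negatives")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"markers in both classes: {sorted(overlap)}")


@dataclass
class EvaluationResult:
    """Confusion-matrix tallies and metrics for one method on one group."""

    marker_label: str
    method: str
    group: str  # a group label or "ALL"
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded_undetermined: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d > 0 else None


def predict_for_method(method: str, gene_id: str, calls: "DatasetCalls") -> str:
    """Predicted class of one gene–dataset combination: positive/negative/excluded.

    The caller is responsible for only passing datasets eligible for
    ``method``; this function looks at a single combination.
    """
    tpm = calls.tpm_of(gene_id)
    if method == "gt0_tpm":
        return "positive" if tpm > 0 else "negative"
    if method == "gt1_tpm":
        return "positive" if tpm > 1 else "negative"
    if method == "gmm":
        if tpm == 0:
            return "negative"
        call = calls.gmm.call_map.get(gene_id)
        if call is None:  # detected but outside the coding universe
            return "negative"
        if call.label == "active":
            return "positive"
        if call.label == "undetermined":
            return "excluded"
        return "negative"
    if method == "ztpm":
        if tpm == 0:
            return "negative"
        call = calls.ztpm.call_map.get(gene_id)
        if call is None:
            return "negative"
        return "positive" if call.above_threshold else "negative"
    raise ValueError(f"unknown method {method!r}")


def confusion_matrix(
    markers: MarkerSet,
    method: str,
    calls: Mapping[str, "DatasetCalls"],
    group: str | None = None,
) -> EvaluationResult:
    """Tally TP/FP/TN/FN over all eligible gene–dataset combinations.

    ``group`` restricts the tally to datasets of that group; ``None`` pools
    every group (the "ALL" row).
    """
    tp = fp = tn = fn = excluded = 0
    for ds_id in sorted(calls):
        dc = calls[ds_id]
        if group is not None and dc.dataset.group != group:
            continue
        if not dc.eligible(method):
            continue
        for gene in sorted(markers.positives):
            pred = predict_for_method(method, gene, dc)
            if pred == "positive":
                tp += 1
            elif pred == "negative":
                fn += 1
            else:
                excluded += 1
        for gene in sorted(markers.negatives):
            pred = predict_for_method(method, gene, dc)
            if pred == "negative":
                tn += 1
            elif pred == "positive":
                fp += 1
            else:
                excluded += 1
    return EvaluationResult(
        marker_label=markers.label,
        method=method,
        group=group or "ALL",
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_excluded_undetermined=excluded,
    )


def evaluate_all(
    marker_sets: Sequence[MarkerSet],
    calls: Mapping[str, "DatasetCalls"],
    methods: Sequence[str] = METHODS,
    groups: Iterable[str] | None = None,
) -> list[EvaluationResult]:
    """Cross-product of marker sets x methods x (ALL + each group)."""
    if groups is None:
        groups = sorted({dc.dataset.group for dc in calls.values()})
    else:
        groups = sorted(groups)
    results = []
    for markers in marker_sets:
        for method in methods:
            results.append(confusion_matrix(markers, method, calls, group=None))
            for group in groups:
                results.append(confusion_matrix(markers, method, calls, group=group))
    return results


def results_to_frame(results: Sequence[EvaluationResult]):
    """Tidy DataFrame of evaluation results (full precision)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "marker_set": r.marker_label,
                "group": r.group,
                "method": r.method,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
                "n_excluded_undetermined": r.n_excluded_undetermined,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for r in results
        ]
    )
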