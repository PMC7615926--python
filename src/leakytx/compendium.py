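"""Compendium aggregation: per-gene summaries across many datasets.

For each gene, per group and pooled over all groups: how many datasets
detect it (TPM > 0), how many exceed a user-adjustable TPM threshold
(default 1, the common heuristic line), its expression range over detected
datasets (median and interquartile range), and the tallies of GMM labels
(active / leaky / undetermined) and zTPM threshold calls over the datasets
eligible for each method.  Pooled percentages are count ratios over the
pooled denominators, not means of group percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gmm import GmmDatasetResult
from .io import ExpressionDataset
from .ztpm import ZtpmDatasetResult

__all__ = [
    "GroupSummary",
    "CompendiumSummary",
    "summarize_gene",
    "summarize_table",
    "summaries_to_frame",
    "write_summary_tsv",
]


@dataclass
class GroupSummary:
    """Aggregated counts for one gene within one group (or pooled "ALL")."""

    group: str
    n_datasets: int
    n_detected: int
    n_above_user_threshold: int
    user_threshold: float
    tpm_values: list[tuple[str, float]]  # detected datasets only
    median_tpm: float | None
    iqr_tpm: tuple[float, float] | None
    gmm_active: int
    gmm_leaky: int
    gmm_undetermined: int
    ztpm_above: int
    ztpm_below: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_detected <= self.n_datasets:
            raise ValueError("n_detected must lie in [0, n_datasets]")
        if self.n_above_user_threshold > self.n_detected:
            raise ValueError("n_above_user_threshold cannot exceed n_detected")

    @property
    def gmm_eligible_detected(self) -> int:
        return self.gmm_active + self.gmm_leaky + self.gmm_undetermined

    @property
    def percent_active(self) -> float | None:
        d = self.gmm_eligible_detected
        return 100.0 * self.gmm_active / d if d > 0 else None

    @property
    def ztpm_eligible_detected(self) -> int:
        return self.ztpm_above + self.ztpm_below

    @property
    def percent_above(self) -> float | None:
        d = self.ztpm_eligible_detected
        return 100.0 * self.ztpm_above / d if d > 0 else None

    @property
    def percent_detected(self) -> float | None:
        return 100.0 * self.n_detected / self.n_datasets if self.n_datasets else None


@dataclass
class CompendiumSummary:
    """Per-gene summary: one record per group plus the pooled record."""

    gene_id: str
    per_group: dict[str, GroupSummary]
    overall: GroupSummary


def _summarize_subset(
    gene_id: str,
    label: str,
    datasets: Sequence[ExpressionDataset],
    gmm_results: Mapping[str, GmmDatasetResult],
    ztpm_results: Mapping[str, ZtpmDatasetResult],
    user_threshold: float,
) -> GroupSummary:
    detected: list[tuple[str, float]] = []
    n_above = 0
    gmm_counts = {"active": 0, "leaky": 0, "undetermined": 0}
    z_above = z_below = 0
    for ds in datasets:
        tpm = float(ds.tpm.get(gene_id, 0.0))
        if tpm > 0:
            detected.append((ds.dataset_id, tpm))
            if tpm > user_threshold:
                n_above += 1
            gr = gmm_results.get(ds.dataset_id)
            if gr is not None and gr.eligible:
                call = gr.call_map.get(gene_id)
                if call is not None:
                    gmm_counts[call.label] += 1
            zr = ztpm_results.get(ds.dataset_id)
            if zr is not None and zr.eligible:
                zcall = zr.call_map.get(gene_id)
                if zcall is not None:
                    if zcall.above_threshold:
                        z_above += 1
                    else:
                        z_below += 1
    values = np.array([t for _, t in detected])
    median = float(np.median(values)) if values.size else None
    iqr = (
        (float(np.percentile(values, 25)), float(np.percentile(values, 75)))
        if values.size
        else None
    )
    return GroupSummary(
        group=label,
        n_datasets=len(datasets),
        n_detected=len(detected),
        n_above_user_threshold=n_above,
        user_threshold=float(user_threshold),
        tpm_values=detected,
        median_tpm=median,
        iqr_tpm=iqr,
        gmm_active=gmm_counts["active"],
        gmm_leaky=gmm_counts["leaky"],
        gmm_undetermined=gmm_counts["undetermined"],
        ztpm_above=z_above,
        ztpm_below=z_below,
    )


def summarize_gene(
    gene_id: str,
    datasets: Sequence[ExpressionDataset],
    gmm_results: Mapping[str, GmmDatasetResult],
    ztpm_results: Mapping[str, ZtpmDatasetResult],
    user_threshold: float = 1.0,
) -> CompendiumSummary:
    """Aggregate one gene's detection, expression range and labels.

    Detection is strict TPM > 0; the user threshold is strict
    TPM > ``user_threshold``.  GMM and zTPM tallies cover only the datasets
    eligible for the respective method in which the gene is detected.  A
    gene absent from every dataset yields all-zero counts, not an error.
    """
    by_group: dict[str, list[ExpressionDataset]] = {}
    for ds in datasets:
        by_group.setdefault(ds.group, []).append(ds)
    per_group = {
        group: _summarize_subset(
            gene_id, group, members, gmm_results, ztpm_results, user_threshold
        )
        for group, members in sorted(by_group.items())
    }
    overall = _summarize_subset(
        gene_id, "ALL", list(datasets), gmm_results, ztpm_results, user_threshold
    )
    return CompendiumSummary(gene_id=gene_id, per_group=per_group, overall=overall)


def summarize_table(
    gene_ids: Sequence[str],
    datasets: Sequence[ExpressionDataset],
    gmm_results: Mapping[str, GmmDatasetResult],
    ztpm_results: Mapping[str, ZtpmDatasetResult],
    user_threshold: float = 1.0,
) -> list[CompendiumSummary]:
    """Batch of :func:`summarize_gene`, ordered lexicographically by gene."""
    return [
        summarize_gene(g, datasets, gmm_results, ztpm_results, user_threshold)
        for g in sorted(set(gene_ids))
    ]


def summaries_to_frame(summaries: Sequence[CompendiumSummary]) -> pd.DataFrame:
    """Tidy frame: one row per gene per group plus the pooled ALL row."""
    rows = []
    for s in summaries:
        records = list(s.per_group.values()) + [s.overall]
        for rec in records:
            rows.append(
                {
                    "gene_id": s.gene_id,
                    "group": rec.group,
                    "n_datasets": rec.n_datasets,
                    "n_detected": rec.n_detected,
                    "n_above_user_threshold": rec.n_above_user_threshold,
                    "user_threshold": rec.user_threshold,
                    "percent_detected": rec.percent_detected,
                    "median_tpm": rec.median_tpm,
                    "q1_tpm": rec.iqr_tpm[0] if rec.iqr_tpm else None,
                    "q3_tpm": rec.iqr_tpm[1] if rec.iqr_tpm else None,
                    "gmm_active": rec.gmm_active,
                    "gmm_leaky": rec.gmm_leaky,
                    "gmm_undetermined": rec.gmm_undetermined,
                    "percent_active": rec.percent_active,
                    "ztpm_above": rec.ztpm_above,
                    "ztpm_below": rec.ztpm_below,
                    "percent_above": rec.percent_above,
                }
            )
    return pd.DataFrame(rows)


def write_summary_tsv(summaries: Sequence[CompendiumSummary], path) -> None:
    """Text output: percentages to one decimal place, counts exact."""
    df = summaries_to_frame(summaries)
    for col in ("percent_detected", "percent_active", "percent_above"):
        df[col] = df[col].round(1)
    df.to_csv(path, sep="\t", index=False)
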