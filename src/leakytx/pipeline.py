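"""End-to-end orchestration: QC gate, shared eligibility, both classifiers.

:func:`classify_compendium` runs, for each QC-passing dataset: one shape
assessment (shared by both classifiers, so the GMM and zTPM analyses agree
on which datasets are unimodal), the two-component GMM posterior
classification, and the zTPM standardization.  Results are bundled per
dataset in :class:`DatasetCalls`, the container the aggregation and
evaluation layers consume.  Per-dataset seeds are derived deterministically
from the run seed and the sorted dataset order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gmm import (
    GmmDatasetResult,
    GmmFit,
    P_ACTIVE_LOWER,
    P_ACTIVE_UPPER,
    PosteriorCall,
    assess_eligibility,
    classify_by_posterior,
    gmm_classify_dataset,
)
from .io import ExpressionDataset, GeneUniverse, QcReport, coding_log2_values, qc_gate
from .ztpm import (
    ZTPM_THRESHOLD,
    ZtpmCall,
    ZtpmDatasetResult,
    ZtpmFit,
    ztpm_classify_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["DatasetCalls", "classify_compendium", "write_calls", "read_calls"]


@dataclass
class DatasetCalls:
    """All per-dataset classification output for downstream consumers."""

    dataset: ExpressionDataset
    gmm: GmmDatasetResult
    ztpm: ZtpmDatasetResult

    def tpm_of(self, gene_id: str) -> float:
        return float(self.dataset.tpm.get(gene_id, 0.0))

    def eligible(self, method: str) -> bool:
        """Per-method eligibility: thresholds always, GMM/zTPM per verdict."""
        if method in ("gt0_tpm", "gt1_tpm"):
            return True
        if method == "gmm":
            return self.gmm.eligible
        if method == "ztpm":
            return self.ztpm.eligible
        raise ValueError(f"unknown method {method!r}")


def _dataset_seed(root_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def classify_compendium(
    datasets: Sequence[ExpressionDataset],
    universe: GeneUniverse,
    seed: int,
    qc_markers: Sequence[str] | None = None,
    qc_min_tpm: float = 1.0,
    p_lower: float = P_ACTIVE_LOWER,
    p_upper: float = P_ACTIVE_UPPER,
    ztpm_threshold: float = ZTPM_THRESHOLD,
    eligibility_overrides: Mapping[str, str] | None = None,
) -> tuple[dict[str, DatasetCalls], list[QcReport]]:
    """Run QC, eligibility and both classifiers over a compendium.

    Returns ``(calls, qc_reports)``.  Datasets failing the marker QC gate
    (when ``qc_markers`` is given) are excluded from ``calls`` entirely and
    reported in ``qc_reports``.  ``eligibility_overrides`` maps dataset_id
    to a forced shape verdict (``two_component`` / ``three_component`` /
    ``unimodal``), replicating manual curation.
    """
    overrides = dict(eligibility_overrides or {})
    calls: dict[str, DatasetCalls] = {}
    reports: list[QcReport] = []
    ordered = sorted(datasets, key=lambda d: d.dataset_id)
    for index, ds in enumerate(ordered):
        if qc_markers:
            report = qc_gate(ds, qc_markers, min_tpm=qc_min_tpm)
            reports.append(report)
            if not report.passed:
                logger.info(
                    "dataset %s failed marker QC (%s); excluded",
                    ds.dataset_id,
                    ", ".join(f"{g}={t:g}" for g, t in report.failed_markers),
                )
                continue
        ds_seed = _dataset_seed(seed, index)
        pairs = coding_log2_values(ds, universe)
        values = np.array([v for _, v in pairs])
        verdict = overrides.get(ds.dataset_id) or assess_eligibility(values, ds_seed)
        gmm_res = gmm_classify_dataset(
            ds, universe, ds_seed, lower=p_lower, upper=p_upper, eligibility=verdict
        )
        ztpm_res = ztpm_classify_dataset(
            ds, universe, threshold=ztpm_threshold, eligibility=verdict
        )
        logger.info(
            "dataset %s: shape=%s gmm_calls=%d ztpm_calls=%d",
            ds.dataset_id, verdict, len(gmm_res.calls), len(ztpm_res.calls),
        )
        calls[ds.dataset_id] = DatasetCalls(dataset=ds, gmm=gmm_res, ztpm=ztpm_res)
    return calls, reports


def write_calls(calls: Mapping[str, DatasetCalls], outdir: str | Path) -> None:
    """Persist calls as two TSVs plus a per-dataset fit/eligibility JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gmm_rows = []
    ztpm_rows = []
    fits: dict[str, dict] = {}
    for ds_id in sorted(calls):
        dc = calls[ds_id]
        for c in dc.gmm.calls:
            gmm_rows.append(
                (ds_id, c.gene_id, dc.tpm_of(c.gene_id), c.log2_tpm,
                 c.p_active, c.label)
            )
        for c in dc.ztpm.calls:
            ztpm_rows.append(
                (ds_id, c.gene_id, dc.tpm_of(c.gene_id), c.ztpm,
                 c.above_threshold, c.threshold)
            )
        fit = dc.gmm.fit
        zfit = dc.ztpm.fit
        fits[ds_id] = {
            "group": dc.dataset.group,
            "species": dc.dataset.species,
            "gmm_eligibility": dc.gmm.eligibility,
            "ztpm_eligibility": dc.ztpm.eligibility,
            "gmm_fit": None
            if fit is None
            else {
                "mu_leaky": fit.mu_leaky,
                "mu_active": fit.mu_active,
                "sigma_leaky": fit.sigma_leaky,
                "sigma_active": fit.sigma_active,
                "w_leaky": fit.w_leaky,
                "w_active": fit.w_active,
                "converged": fit.converged,
                "n_points": fit.n_points,
                "final_loglik": fit.loglik_trace[-1],
                "n_iterations": len(fit.loglik_trace),
            },
            "ztpm_fit": None
            if zfit is None
            else {
                "mu_peak": zfit.mu_peak,
                "sigma_half": zfit.sigma_half,
                "bandwidth": zfit.bandwidth,
                "grid": list(zfit.grid),
            },
        }

    pd.DataFrame(
        gmm_rows,
        columns=["dataset_id", "gene_id", "tpm", "log2_tpm", "p_active", "gmm_label"],
    ).to_csv(outdir / "gmm_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        ztpm_rows,
        columns=["dataset_id", "gene_id", "tpm", "ztpm", "above_threshold",
                 "threshold"],
    ).to_csv(outdir / "ztpm_calls.tsv", sep="\t", index=False)
    with open(outdir / "fits.json", "w", encoding="utf-8") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True)


def read_calls(
    outdir: str | Path,
    datasets: Sequence[ExpressionDataset],
) -> dict[str, DatasetCalls]:
    """Reload a calls directory written by :func:`write_calls`.

    ``datasets`` supplies the raw TPM tables (calls files carry only the
    classified genes).  Log-likelihood traces are not persisted; reloaded
    fits carry the final log-likelihood only.
    """
    outdir = Path(outdir)
    with open(outdir / "fits.json", encoding="utf-8") as fh:
        fits = json.load(fh)
    by_id = {ds.dataset_id: ds for ds in datasets}

    gmm_df = pd.read_csv(outdir / "gmm_calls.tsv", sep="\t")
    ztpm_df = pd.read_csv(outdir / "ztpm_calls.tsv", sep="\t")
    gmm_groups = dict(tuple(gmm_df.groupby("dataset_id", sort=True)))
    ztpm_groups = dict(tuple(ztpm_df.groupby("dataset_id", sort=True)))

    calls: dict[str, DatasetCalls] = {}
    for ds_id, meta in fits.items():
        if ds_id not in by_id:
            raise ValueError(f"calls reference unknown dataset {ds_id!r}")
        fit = None
        if meta["gmm_fit"] is not None:
            f = meta["gmm_fit"]
            fit = GmmFit(
                mu_leaky=f["mu_leaky"],
                mu_active=f["mu_active"],
                sigma_leaky=f["sigma_leaky"],
                sigma_active=f["sigma_active"],
                w_leaky=f["w_leaky"],
                w_active=f["w_active"],
                loglik_trace=[f["final_loglik"]],
                converged=f["converged"],
                n_points=f["n_points"],
                eligibility=meta["gmm_eligibility"],
            )
        gmm_calls = []
        if ds_id in gmm_groups:
            for row in gmm_groups[ds_id].itertuples(index=False):
                pa = float(row.p_active)
                gmm_calls.append(
                    PosteriorCall(
                        gene_id=str(row.gene_id),
                        log2_tpm=float(row.log2_tpm),
                        p_active=pa,
                        p_leaky=1.0 - pa,
                        label=str(row.gmm_label),
                    )
                )
        ztpm_calls = []
        if ds_id in ztpm_groups:
            for row in ztpm_groups[ds_id].itertuples(index=False):
                ztpm_calls.append(
                    ZtpmCall(
                        gene_id=str(row.gene_id),
                        ztpm=float(row.ztpm),
                        above_threshold=bool(row.above_threshold),
                        threshold=float(row.threshold),
                    )
                )
        zfit = None
        if meta["ztpm_fit"] is not None:
            zf = meta["ztpm_fit"]
            zfit = ZtpmFit(
                mu_peak=zf["mu_peak"],
                sigma_half=zf["sigma_half"],
                bandwidth=zf["bandwidth"],
                grid=tuple(zf["grid"]),
            )
        calls[ds_id] = DatasetCalls(
            dataset=by_id[ds_id],
            gmm=GmmDatasetResult(ds_id, meta["gmm_eligibility"], fit, gmm_calls),
            ztpm=ZtpmDatasetResult(ds_id, meta["ztpm_eligibility"], zfit, ztpm_calls),
        )
    return calls
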