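"""Shared fixtures: hand-built toy call tables and a simulated compendium."""

from __future__ import annotations

import numpy as np
import pytest

from leakytx.gmm import GmmDatasetResult, GmmFit, PosteriorCall
from leakytx.io import ExpressionDataset, GeneUniverse
from leakytx.pipeline import DatasetCalls
from leakytx.ztpm import ZtpmCall, ZtpmDatasetResult, ZtpmFit


def make_gmm_fit(
    mu_leaky=-3.0, mu_active=3.5, sigma_leaky=1.5, sigma_active=2.0,
    w_leaky=0.25, w_active=0.75,
) -> GmmFit:
    return GmmFit(
        mu_leaky=mu_leaky, mu_active=mu_active,
        sigma_leaky=sigma_leaky, sigma_active=sigma_active,
        w_leaky=w_leaky, w_active=w_active,
        loglik_trace=[-1.0], converged=True, n_points=100,
    )


def make_dataset_calls(
    dataset_id: str,
    group: str,
    gene_states: dict[str, tuple[float, str | None, bool | None]],
    gmm_eligibility: str = "two_component",
    ztpm_eligibility: str = "eligible",
) -> DatasetCalls:
    """Build a DatasetCalls by hand.

    ``gene_states`` maps gene -> (tpm, gmm_label_or_None, ztpm_above_or_None);
    ``None`` entries mean the gene gets no call of that kind (for example a
    TPM = 0 gene, which is never classified).
    """
    tpm = {g: s[0] for g, s in gene_states.items()}
    ds = ExpressionDataset(dataset_id=dataset_id, group=group, species="Hs", tpm=tpm)
    label_p = {"active": 0.9, "leaky": 0.1, "undetermined": 0.5}
    gmm_calls = [
        PosteriorCall(
            gene_id=g,
            log2_tpm=float(np.log2(s[0])) if s[0] > 0 else 0.0,
            p_active=label_p[s[1]],
            p_leaky=1.0 - label_p[s[1]],
            label=s[1],
        )
        for g, s in gene_states.items()
        if s[1] is not None
    ]
    ztpm_calls = [
        ZtpmCall(
            gene_id=g,
            ztpm=0.5 if s[2] else -5.0,
            above_threshold=bool(s[2]),
            threshold=-2.38,
        )
        for g, s in gene_states.items()
        if s[2] is not None
    ]
    eligible = gmm_eligibility == "two_component"
    gmm_res = GmmDatasetResult(
        dataset_id, gmm_eligibility, make_gmm_fit() if eligible else None,
        gmm_calls if eligible else [],
    )
    z_eligible = ztpm_eligibility == "eligible"
    ztpm_res = ZtpmDatasetResult(
        dataset_id, ztpm_eligibility,
        ZtpmFit(3.5, 2.0, 0.3, (-8.0, 10.0, 512)) if z_eligible else None,
        ztpm_calls if z_eligible else [],
    )
    return DatasetCalls(dataset=ds, gmm=gmm_res, ztpm=ztpm_res)


@pytest.fixture(scope="session")
def spec_mixture_sample():
    """10,000 draws from 0.25 N(-3.5, 1.2^2) + 0.75 N(3.0, 1.8^2)."""
    rng = np.random.default_rng(20240917)
    n_leaky = rng.binomial(10_000, 0.25)
    return np.concatenate(
        [
            rng.normal(-3.5, 1.2, n_leaky),
            rng.normal(3.0, 1.8, 10_000 - n_leaky),
        ]
    )


@pytest.fixture(scope="session")
def default_compendium():
    """20 bimodal datasets x 2,000 genes with the default planted panel.

    Includes an extra 'ordering' panel of negatives planted in the leaky
    component with dropout 0 (low but nonzero TPM in every dataset).
    Classified once and shared across tests (read-only).
    """
    from leakytx.pipeline import classify_compendium
    from leakytx.simulate import (
        GroupSpec,
        PlantedMarker,
        SimConfig,
        default_marker_panel,
        simulate_compendium,
    )

    ordering_negatives = tuple(
        PlantedMarker(f"ORDN{i:03d}", "negative", "leaky", dropout=0.0)
        for i in range(20)
    )
    cfg = SimConfig(
        n_genes=2000,
        groups=(GroupSpec("HUVEC", 20, "bimodal"),),
        planted_markers=default_marker_panel() + ordering_negatives,
        seed=0,
    )
    datasets, truth = simulate_compendium(cfg)
    universe = GeneUniverse(frozenset(datasets[0].tpm))
    calls, _ = classify_compendium(datasets, universe, seed=0)
    return {
        "config": cfg,
        "datasets": datasets,
        "truth": truth,
        "universe": universe,
        "calls": calls,
    }
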