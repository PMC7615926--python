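"""Synthetic bulk RNA-seq compendia with known active/leaky ground truth.

The generator realizes the two-class model the classifiers assume: each
gene is either actively or leakily transcribed, and its log2(TPM) in a
dataset is drawn from the corresponding Gaussian component.  Defaults put
the active class at N(3.5, 2.0^2) with weight 0.75 and the leaky class at
N(-3.0, 1.5^2) — a dominant right peak with a low left shoulder.  Zero
inflation is modeled by per-class dropout: a dropped gene has TPM = 0 in
that dataset (leaky transcripts are only sporadically detected, so their
dropout is high by default).

A gene's class is fixed across datasets (a cell type's stable high/low
expression partition); between-dataset variation comes from the component
draw and dropout alone.  Shape variants emulate failure modes seen in real
compendia: ``unimodal`` draws every gene from the active component (for
example, a sample dominated by a contaminating cell type), and
``trimodal`` re-draws a fraction of genes from a middle component
(partial contamination).  Both are ineligible for classification and
exercise the eligibility gate.

QC marker genes (default KDR and CDH5, the core endothelial markers) are
planted high in every dataset so the marker QC gate passes by
construction; marker panels with known truth can be planted for
evaluating any classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .evaluation import MarkerSet
from .io import ExpressionDataset

__all__ = [
    "GroupSpec",
    "PlantedMarker",
    "SimConfig",
    "TruthTable",
    "simulate_compendium",
    "plant_marker_panel",
    "default_marker_panel",
]


@dataclass(frozen=True)
class GroupSpec:
    """One compendium group: label, dataset count, distribution shape."""

    label: str
    n_datasets: int
    shape: str = "bimodal"  # bimodal | unimodal | trimodal
    species: str = "Hs"

    def __post_init__(self) -> None:
        if self.shape not in ("bimodal", "unimodal", "trimodal"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be positive")


@dataclass(frozen=True)
class PlantedMarker:
    """A marker gene planted with a fixed class and drawing component.

    ``component``: ``active`` (drawn from the active Gaussian), ``leaky``
    (drawn from the leaky Gaussian) or ``absent`` (TPM = 0 everywhere).
    ``dropout`` overrides the class default dropout; planted active markers
    default to dropout 0 (present in every dataset).
    """

    gene_id: str
    cls: str  # positive | negative
    component: str  # active | leaky | absent
    dropout: float | None = None

    def __post_init__(self) -> None:
        if self.cls not in ("positive", "negative"):
            raise ValueError(f"unknown marker class {self.cls!r}")
        if self.component not in ("active", "leaky", "absent"):
            raise ValueError(f"unknown component {self.component!r}")
        if self.dropout is not None and not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic compendium.

    Component parameters are in log2(TPM) units.  ``frac_active`` is the
    probability that a gene belongs to the active class; dropout fields are
    the per-dataset probability that a gene of that class yields TPM = 0.
    """

    n_genes: int = 2000
    frac_active: float = 0.75
    mu_active: float = 3.5
    sigma_active: float = 2.0
    mu_leaky: float = -3.0
    sigma_leaky: float = 1.5
    dropout_active: float = 0.02
    dropout_leaky: float = 0.5
    groups: tuple[GroupSpec, ...] = (GroupSpec("HUVEC", 10),)
    mu_middle: float | None = None  # default: midpoint of the two class means
    sigma_middle: float = 1.0
    frac_middle: float = 0.25
    qc_markers: tuple[str, ...] = ("KDR", "CDH5")
    qc_marker_mu: float = 7.0
    qc_marker_sigma: float = 0.5
    planted_markers: tuple[PlantedMarker, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_active", "dropout_active", "dropout_leaky", "frac_middle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.mu_active > self.mu_leaky:
            raise ValueError("mu_active must exceed mu_leaky")
        if min(self.sigma_active, self.sigma_leaky, self.sigma_middle) <= 0:
            raise ValueError("component s.d.s must be positive")
        planted_ids = [m.gene_id for m in self.planted_markers]
        if len(planted_ids) != len(set(planted_ids)):
            raise ValueError("planted marker gene ids must be unique")
        if set(planted_ids) & set(self.qc_markers):
            raise ValueError("planted markers must not collide with QC markers")
        if self.n_genes < len(planted_ids) + len(self.qc_markers):
            raise ValueError("n_genes too small for planted and QC markers")

    @property
    def n_datasets(self) -> int:
        return sum(g.n_datasets for g in self.groups)

    @property
    def middle_mean(self) -> float:
        if self.mu_middle is not None:
            return self.mu_middle
        return 0.5 * (self.mu_leaky + self.mu_active)


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated compendium.

    ``gene_class`` maps each gene to its fixed class; ``values`` maps
    (gene_id, dataset_id) to the drawn log2(TPM), or ``None`` when the gene
    was dropped out (TPM = 0) in that dataset.
    """

    gene_class: dict[str, str]
    values: dict[tuple[str, str], float | None]

    def to_json_obj(self) -> dict:
        return {
            "gene_class": self.gene_class,
            "values": {
                f"{g}\t{d}": v for (g, d), v in self.values.items()
            },
        }


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Fixed per-gene class labels; planted and QC genes override the draw."""
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    planted = {m.gene_id for m in cfg.planted_markers}
    reserved = planted | set(cfg.qc_markers)
    # replace the tail of the id space with reserved names
    free = [g for g in gene_ids][: cfg.n_genes - len(reserved)]
    active = rng.random(len(free)) < cfg.frac_active
    classes = {g: ("active" if a else "leaky") for g, a in zip(free, active)}
    for marker in cfg.qc_markers:
        classes[marker] = "active"
    for m in cfg.planted_markers:
        classes[m.gene_id] = "active" if m.component == "active" else "leaky"
    return classes


def _draw_dataset(
    cfg: SimConfig,
    spec: GroupSpec,
    classes: dict[str, str],
    rng: np.random.Generator,
) -> dict[str, float | None]:
    """Per-gene log2(TPM) draws for one dataset (None means dropped out)."""
    planted = {m.gene_id: m for m in cfg.planted_markers}
    genes = list(classes)
    n = len(genes)

    mu = np.empty(n)
    sd = np.empty(n)
    drop_p = np.empty(n)
    absent = np.zeros(n, dtype=bool)
    for i, g in enumerate(genes):
        if g in cfg.qc_markers:
            mu[i], sd[i], drop_p[i] = cfg.qc_marker_mu, cfg.qc_marker_sigma, 0.0
        elif g in planted:
            m = planted[g]
            if m.component == "absent":
                absent[i] = True
                mu[i], sd[i], drop_p[i] = 0.0, 1.0, 1.0
            elif m.component == "active":
                mu[i], sd[i] = cfg.mu_active, cfg.sigma_active
                drop_p[i] = 0.0 if m.dropout is None else m.dropout
            else:
                mu[i], sd[i] = cfg.mu_leaky, cfg.sigma_leaky
                drop_p[i] = cfg.dropout_leaky if m.dropout is None else m.dropout
        elif classes[g] == "active" or spec.shape == "unimodal":
            mu[i], sd[i], drop_p[i] = cfg.mu_active, cfg.sigma_active, cfg.dropout_active
        else:
            mu[i], sd[i], drop_p[i] = cfg.mu_leaky, cfg.sigma_leaky, cfg.dropout_leaky

    if spec.shape == "trimodal":
        eligible = np.array(
            [g not in planted and g not in cfg.qc_markers for g in genes]
        )
        candidates = np.flatnonzero(eligible)
        n_mid = int(round(cfg.frac_middle * n))
        chosen = rng.choice(candidates, size=min(n_mid, candidates.size), replace=False)
        mu[chosen] = cfg.middle_mean
        sd[chosen] = cfg.sigma_middle
        drop_p[chosen] = 0.0

    values = rng.normal(mu, sd)
    dropped = (rng.random(n) < drop_p) | absent
    return {
        g: (None if dropped[i] else float(values[i])) for i, g in enumerate(genes)
    }


def simulate_compendium(cfg: SimConfig) -> tuple[list[ExpressionDataset], TruthTable]:
    """Generate the compendium: one ExpressionDataset per group dataset.

    Fully reproducible: the same config (including seed) yields bit-identical
    output.  TPM = 2**log2_value for drawn genes, 0 for dropped genes.
    """
    root = np.random.SeedSequence(cfg.seed)
    class_rng = np.random.default_rng(root.spawn(1)[0])
    classes = _assign_classes(cfg, class_rng)

    datasets: list[ExpressionDataset] = []
    truth_values: dict[tuple[str, str], float | None] = {}
    ds_seeds = root.spawn(1 + cfg.n_datasets)[1:]
    k = 0
    for spec in cfg.groups:
        for i in range(spec.n_datasets):
            rng = np.random.default_rng(ds_seeds[k])
            k += 1
            ds_id = f"{spec.label}_{i:03d}"
            draws = _draw_dataset(cfg, spec, classes, rng)
            tpm = {
                g: (0.0 if v is None else float(2.0 ** v)) for g, v in draws.items()
            }
            datasets.append(
                ExpressionDataset(
                    dataset_id=ds_id,
                    group=spec.label,
                    species=spec.species,
                    tpm=tpm,
                )
            )
            for g, v in draws.items():
                truth_values[(g, ds_id)] = v
    return datasets, TruthTable(gene_class=classes, values=truth_values)


def plant_marker_panel(cfg: SimConfig) -> MarkerSet:
    """MarkerSet of the planted panel: positives active, negatives leaky/absent."""
    if not cfg.planted_markers:
        raise ValueError("config has no planted markers")
    positives = frozenset(
        m.gene_id for m in cfg.planted_markers if m.cls == "positive"
    )
    negatives = frozenset(
        m.gene_id for m in cfg.planted_markers if m.cls == "negative"
    )
    return MarkerSet(positives=positives, negatives=negatives, label="planted")


def default_marker_panel(
    n_positive: int = 10,
    n_leaky_negative: int = 10,
    n_absent_negative: int = 10,
    leaky_dropout: float | None = None,
) -> tuple[PlantedMarker, ...]:
    """Standard planted panel: active positives plus leaky and absent negatives.

    Mirrors a curated marker list for a cell type: positive markers are
    robustly expressed everywhere, while negative markers split into genes
    never detected and genes sporadically detected at leaky levels.
    """
    markers = [
        PlantedMarker(f"POS{i:03d}", "positive", "active")
        for i in range(n_positive)
    ]
    markers += [
        PlantedMarker(f"NEGL{i:03d}", "negative", "leaky", dropout=leaky_dropout)
        for i in range(n_leaky_negative)
    ]
    markers += [
        PlantedMarker(f"NEGA{i:03d}", "negative", "absent")
        for i in range(n_absent_negative)
    ]
    return tuple(markers)
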