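"""Reading and writing of expression tables, gene lists, marker lists and manifests.

File conventions
----------------
* Long expression table: delimited text with header columns
  ``dataset_id``, ``gene_id``, ``tpm`` (one row per gene per dataset).
* Wide expression table: genes as rows, datasets as columns; the first
  column holds the gene identifier.  Group/species metadata comes from a
  manifest sidecar.
* Manifest: delimited text with columns ``dataset_id``, ``group``,
  ``species``.
* Gene universe: plain text, one identifier per line.
* Marker list: delimited text with columns ``gene_id``, ``class`` where
  class is ``positive`` or ``negative``.

All files are UTF-8; lines starting with ``#`` are ignored.  Tab- and
comma-separated files are both accepted (the delimiter is sniffed from the
header line).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneUniverse",
    "QcReport",
    "load_expression",
    "write_expression",
    "load_manifest",
    "load_gene_universe",
    "load_marker_table",
    "qc_gate",
    "coding_log2_values",
]


@dataclass
class ExpressionDataset:
    """One bulk RNA-seq sample: gene -> TPM plus minimal metadata.

    TPM values must be finite and non-negative; gene identifiers are opaque
    strings, unique within a dataset (enforced by the dict container).
    """

    dataset_id: str
    group: str
    species: str
    tpm: dict[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.tpm.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"dataset {self.dataset_id!r}: invalid TPM {value!r} "
                    f"for gene {gene!r} (must be finite and >= 0)"
                )

    @property
    def genes(self) -> set[str]:
        return set(self.tpm)


@dataclass(frozen=True)
class GeneUniverse:
    """The protein-coding gene universe used for model fitting."""

    coding_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.coding_genes:
            raise ValueError("gene universe is empty")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.coding_genes

    def __len__(self) -> int:
        return len(self.coding_genes)


@dataclass(frozen=True)
class QcReport:
    """Outcome of the marker-based dataset QC gate."""

    dataset_id: str
    passed: bool
    failed_markers: tuple[tuple[str, float], ...]
    min_tpm: float

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_markers) == 0):
            raise ValueError("passed flag inconsistent with failed_markers")


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: file contains no data lines")


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    try:
        return pd.read_csv(path, sep=sep, comment="#", dtype=str,
                           skip_blank_lines=True, **kwargs)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"{path}: parse error: {exc}") from exc


def _to_tpm(raw: pd.Series, path: Path) -> np.ndarray:
    # Python's float() is correctly rounded, so written values round-trip
    # bit-identically; pandas' numeric parser is not guaranteed to.
    arr = np.empty(len(raw), dtype=float)
    for i, token in enumerate(raw.to_numpy()):
        try:
            arr[i] = float(token)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric TPM value {token!r} at data row {i + 1}"
            ) from None
    neg = arr < 0
    if neg.any():
        idx = int(np.flatnonzero(neg)[0])
        raise ValueError(f"{path}: negative TPM {arr[idx]} at data row {idx + 1}")
    return arr


def load_manifest(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a dataset manifest; returns dataset_id -> (group, species)."""
    df = _read_table(path)
    required = {"dataset_id", "group", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    if df["dataset_id"].duplicated().any():
        dup = df.loc[df["dataset_id"].duplicated(), "dataset_id"].iloc[0]
        raise ValueError(f"{path}: duplicate dataset_id {dup!r} in manifest")
    return {
        row.dataset_id: (row.group, row.species)
        for row in df.itertuples(index=False)
    }


def load_expression(
    path: str | Path,
    format: str = "long",
    manifest: Mapping[str, tuple[str, str]] | str | Path | None = None,
) -> list[ExpressionDataset]:
    """Read an expression table into one :class:`ExpressionDataset` per dataset.

    Parameters
    ----------
    path
        Delimited text file (see module docstring for the two layouts).
    format
        ``"long"`` or ``"wide"``.
    manifest
        Either an already-loaded manifest mapping or a path to one.  Datasets
        absent from the manifest get group/species ``"NA"``.

    Missing cells in the wide layout are treated as TPM = 0 (sparse
    quantifier output) and logged as a warning.
    """
    path = Path(path)
    if isinstance(manifest, (str, Path)):
        manifest = load_manifest(manifest)
    meta = dict(manifest) if manifest else {}

    if format == "long":
        df = _read_table(path)
        required = {"dataset_id", "gene_id", "tpm"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: long format needs columns {sorted(required)}")
        dup = df.duplicated(subset=["dataset_id", "gene_id"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValueError(
                f"{path}: duplicate entry for dataset {row.dataset_id!r}, "
                f"gene {row.gene_id!r}"
            )
        tpm = _to_tpm(df["tpm"], path)
        datasets = []
        for ds_id, idx in df.groupby("dataset_id", sort=True).groups.items():
            sub = df.loc[idx]
            group, species = meta.get(str(ds_id), ("NA", "NA"))
            datasets.append(
                ExpressionDataset(
                    dataset_id=str(ds_id),
                    group=group,
                    species=species,
                    tpm=dict(zip(sub["gene_id"], tpm[sub.index])),
                )
            )
        return datasets

    if format == "wide":
        df = _read_table(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: wide format needs a gene column plus datasets")
        gene_col = df.columns[0]
        if df[gene_col].duplicated().any():
            dup = df.loc[df[gene_col].duplicated(), gene_col].iloc[0]
            raise ValueError(f"{path}: duplicate gene_id {dup!r}")
        genes = df[gene_col].tolist()
        datasets = []
        for col in df.columns[1:]:
            raw = df[col]
            n_missing = int(raw.isna().sum())
            if n_missing:
                logger.warning(
                    "%s: dataset %r has %d missing cells; treated as TPM = 0",
                    path, col, n_missing,
                )
            values = _to_tpm(raw.fillna("0"), path)
            group, species = meta.get(str(col), ("NA", "NA"))
            datasets.append(
                ExpressionDataset(
                    dataset_id=str(col),
                    group=group,
                    species=species,
                    tpm=dict(zip(genes, values)),
                )
            )
        return datasets

    raise ValueError(f"unknown expression format {format!r}")


def write_expression(
    datasets: Sequence[ExpressionDataset],
    path: str | Path,
    format: str = "long",
) -> None:
    """Write datasets back to disk in the long or wide layout (TSV)."""
    path = Path(path)
    if format == "long":
        rows = [
            (ds.dataset_id, gene, repr(float(tpm)))
            for ds in datasets
            for gene, tpm in sorted(ds.tpm.items())
        ]
        df = pd.DataFrame(rows, columns=["dataset_id", "gene_id", "tpm"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "wide":
        genes = sorted({g for ds in datasets for g in ds.tpm})
        table = {"gene_id": genes}
        for ds in datasets:
            table[ds.dataset_id] = [repr(float(ds.tpm.get(g, 0.0))) for g in genes]
        pd.DataFrame(table).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown expression format {format!r}")


def write_manifest(datasets: Sequence[ExpressionDataset], path: str | Path) -> None:
    df = pd.DataFrame(
        [(ds.dataset_id, ds.group, ds.species) for ds in datasets],
        columns=["dataset_id", "group", "species"],
    )
    df.to_csv(path, sep="\t", index=False)


def load_gene_universe(path: str | Path) -> GeneUniverse:
    """Read a plain-text gene list (one identifier per line) into a universe."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.append(token)
    return GeneUniverse(frozenset(genes))


def write_gene_universe(universe: GeneUniverse | Iterable[str], path: str | Path) -> None:
    genes = universe.coding_genes if isinstance(universe, GeneUniverse) else universe
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(genes):
            fh.write(f"{gene}\n")


def load_marker_table(path: str | Path, label: str | None = None):
    """Read a ``gene_id<TAB>class`` marker list into a MarkerSet.

    Class values must be ``positive`` or ``negative``.
    """
    from .evaluation import MarkerSet  # local import to keep modules acyclic

    df = _read_table(path)
    required = {"gene_id", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: marker list needs columns {sorted(required)}")
    classes = set(df["class"])
    bad = classes - {"positive", "negative"}
    if bad:
        raise ValueError(f"{path}: unknown marker class values {sorted(bad)}")
    positives = frozenset(df.loc[df["class"] == "positive", "gene_id"])
    negatives = frozenset(df.loc[df["class"] == "negative", "gene_id"])
    return MarkerSet(positives=positives, negatives=negatives,
                     label=label or Path(path).stem)


def qc_gate(
    ds: ExpressionDataset,
    required_markers: Sequence[str],
    min_tpm: float = 1.0,
) -> QcReport:
    """Marker-based dataset QC: every required marker must exceed ``min_tpm``.

    A dataset passes only if each required marker gene has TPM strictly
    greater than ``min_tpm`` (default 1.0, the core-marker gate applied
    during compendium construction).  A marker absent from the table counts
    as TPM = 0 and therefore fails the gate.
    """
    if not required_markers:
        raise ValueError("required_markers must be non-empty")
    failed = tuple(
        (marker, float(ds.tpm.get(marker, 0.0)))
        for marker in required_markers
        if not ds.tpm.get(marker, 0.0) > min_tpm
    )
    return QcReport(
        dataset_id=ds.dataset_id,
        passed=not failed,
        failed_markers=failed,
        min_tpm=float(min_tpm),
    )


def coding_log2_values(
    ds: ExpressionDataset,
    universe: GeneUniverse,
) -> list[tuple[str, float]]:
    """log2(TPM) for detected protein-coding genes, lexicographic by gene.

    Genes with TPM = 0 are excluded (they are "not detected" downstream and
    are never imputed with a pseudocount).  Raises if the dataset shares no
    genes with the universe or if every shared gene has zero TPM — there is
    nothing to fit in either case.
    """
    shared = sorted(set(ds.tpm) & universe.coding_genes)
    if not shared:
        raise ValueError(
            f"dataset {ds.dataset_id!r} shares no genes with the coding universe"
        )
    out = [
        (gene, math.log2(ds.tpm[gene]))
        for gene in shared
        if ds.tpm[gene] > 0
    ]
    if not out:
        raise ValueError(
            f"dataset {ds.dataset_id!r}: all coding genes have TPM = 0; "
            "nothing to fit"
        )
    return out
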