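"""Reading, writing and validation of case-control genotype datasets.

The on-disk interchange format is a delimited text table: one header row
naming every SNP column followed by a final ``Class`` column, then one row
per sample.  Genotypes are minor-allele counts (0 = homozygous common,
1 = heterozygous, 2 = homozygous minor); the phenotype is 0 (control) or
1 (case).  Missing values, multi-allelic sites and covariates are not
supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PHENOTYPE_COLUMN = "Class"

__all__ = [
    "GenotypeDataset",
    "TruthManifest",
    "read_dataset",
    "write_dataset",
    "read_manifest",
    "write_manifest",
    "PHENOTYPE_COLUMN",
]


class DatasetFormatError(ValueError):
    """Raised when a genotype file violates the interchange format."""


@dataclass(frozen=True)
class GenotypeDataset:
    """An in-memory case-control genotype matrix.

    Attributes
    ----------
    genotypes : ndarray of shape (n_samples, n_snps)
        Minor-allele counts, entries in {0, 1, 2}.
    phenotype : ndarray of shape (n_samples,)
        0 for controls, 1 for cases; both classes must be present.
    snp_ids : tuple of str
        Unique identifiers aligned with genotype columns.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        y = np.asarray(self.phenotype)
        if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
            raise DatasetFormatError("genotype matrix must be 2-D and non-empty")
        if not np.issubdtype(g.dtype, np.integer):
            raise DatasetFormatError("genotypes must be integers")
        if g.min() < 0 or g.max() > 2:
            bad = np.argwhere((g < 0) | (g > 2))[0]
            raise DatasetFormatError(
                f"genotype out of range at sample {bad[0]}, SNP column {bad[1]}: "
                f"{g[bad[0], bad[1]]} (allowed values are 0, 1, 2)"
            )
        if y.shape != (g.shape[0],):
            raise DatasetFormatError("phenotype length must match sample count")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise DatasetFormatError(
                "phenotype must contain both 0 (control) and 1 (case) and nothing else"
            )
        ids = tuple(str(s) for s in self.snp_ids)
        if len(ids) != g.shape[1]:
            raise DatasetFormatError("snp_ids must align with genotype columns")
        if len(set(ids)) != len(ids):
            raise DatasetFormatError("snp_ids must be unique")
        object.__setattr__(self, "genotypes", np.ascontiguousarray(g, dtype=np.int8))
        object.__setattr__(self, "phenotype", np.ascontiguousarray(y, dtype=np.int8))
        object.__setattr__(self, "snp_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
        )


@dataclass(frozen=True)
class TruthManifest:
    """Ground truth for a simulated dataset: which SNP pair is causal."""

    dataset_id: str
    causal_pair: tuple[str, str]
    model_name: str = field(default="")

    def __post_init__(self) -> None:
        a, b = self.causal_pair
        if a == b:
            raise ValueError("causal pair must name two distinct SNPs")
        object.__setattr__(self, "causal_pair", tuple(sorted((str(a), str(b)))))


def read_dataset(path: str | Path, delimiter: str = ",") -> GenotypeDataset:
    """Read a delimited genotype table into a validated :class:`GenotypeDataset`.

    The header must name every SNP column plus one phenotype column called
    ``Class``.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    if PHENOTYPE_COLUMN not in df.columns:
        raise DatasetFormatError(f"{path}: missing required '{PHENOTYPE_COLUMN}' column")
    snp_cols = [c for c in df.columns if c != PHENOTYPE_COLUMN]
    if not snp_cols:
        raise DatasetFormatError(f"{path}: no SNP columns found")
    try:
        geno = df[snp_cols].to_numpy(dtype=np.int64)
    except (ValueError, TypeError):
        # locate the offending cell for a useful message
        for j, col in enumerate(snp_cols):
            for i, cell in enumerate(df[col]):
                try:
                    int(cell)
                except (ValueError, TypeError):
                    raise DatasetFormatError(
                        f"{path}: non-integer genotype {cell!r} at row {i}, column {col!r}"
                    ) from None
        raise
    bad = np.argwhere((geno < 0) | (geno > 2))
    if bad.size:
        i, j = bad[0]
        raise DatasetFormatError(
            f"{path}: invalid genotype {geno[i, j]} at row {i}, column {snp_cols[j]!r} "
            "(allowed values are 0, 1, 2)"
        )
    try:
        pheno = df[PHENOTYPE_COLUMN].to_numpy(dtype=np.int64)
    except (ValueError, TypeError):
        raise DatasetFormatError(f"{path}: non-integer phenotype value") from None
    if not np.isin(pheno, [0, 1]).all():
        raise DatasetFormatError(f"{path}: phenotype column must be binary 0/1")
    if np.unique(pheno).size < 2:
        raise DatasetFormatError(f"{path}: phenotype must contain both cases and controls")
    return GenotypeDataset(genotypes=geno, phenotype=pheno, snp_ids=tuple(snp_cols))


def write_dataset(
    dataset: GenotypeDataset, path: str | Path, delimiter: str = ","
) -> None:
    """Write a dataset in the format accepted by :func:`read_dataset` (lossless)."""
    path = Path(path)
    df = pd.DataFrame(dataset.genotypes, columns=list(dataset.snp_ids))
    df[PHENOTYPE_COLUMN] = dataset.phenotype
    df.to_csv(path, sep=delimiter, index=False)


def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    """Write a ground-truth manifest as a small key-value text file."""
    lines = [
        f"dataset_id: {manifest.dataset_id}",
        f"model: {manifest.model_name}",
        f"snp1: {manifest.causal_pair[0]}",
        f"snp2: {manifest.causal_pair[1]}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> TruthManifest:
    """Read a ground-truth manifest written by :func:`write_manifest`."""
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    for required in ("dataset_id", "snp1", "snp2"):
        if required not in fields:
            raise ValueError(f"{path}: manifest missing field {required!r}")
    return TruthManifest(
        dataset_id=fields["dataset_id"],
        causal_pair=(fields["snp1"], fields["snp2"]),
        model_name=fields.get("model", ""),
    )
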