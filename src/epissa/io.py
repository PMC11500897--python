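"""Reading and writing case-control genotype tables in the GAMETES dialect.

A dataset is a plain text table: one header row of SNP identifiers plus a
``Class`` column, then one row per sample.  Genotypes are coded 0/1/2 as
minor-allele counts; the class column is 0 for controls and 1 for cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Dataset",
    "GroundTruth",
    "read_dataset",
    "write_dataset",
    "read_ground_truth",
    "write_ground_truth",
    "DatasetFormatError",
    "MalformedGenotypeError",
    "MalformedClassError",
    "DuplicateHeaderError",
    "EmptyInputError",
]


class DatasetFormatError(ValueError):
    """Base class for malformed genotype-table input."""


class MalformedGenotypeError(DatasetFormatError):
    pass


class MalformedClassError(DatasetFormatError):
    pass


class DuplicateHeaderError(DatasetFormatError):
    pass


class EmptyInputError(DatasetFormatError):
    pass


@dataclass
class Dataset:
    """A case-control genotype matrix.

    Attributes
    ----------
    genotypes
        Integer matrix, rows = samples, columns = SNPs, entries in {0, 1, 2}
        (minor-allele counts).
    phenotype
        Integer vector aligned to rows; 0 = control, 1 = case.
    snp_names
        One unique identifier per column.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DatasetFormatError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[0] != self.phenotype.shape[0]:
            raise DatasetFormatError("phenotype length must match sample count")
        if len(self.snp_names) != self.genotypes.shape[1]:
            raise DatasetFormatError("snp_names length must match SNP count")
        if len(set(self.snp_names)) != len(self.snp_names):
            raise DuplicateHeaderError("duplicate SNP names")
        bad = (self.genotypes < 0) | (self.genotypes > 2)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MalformedGenotypeError(
                f"genotype outside {{0,1,2}} at row {r}, column {self.snp_names[c]!r}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            r = int(np.flatnonzero(~np.isin(self.phenotype, (0, 1)))[0])
            raise MalformedClassError(f"phenotype outside {{0,1}} at row {r}")

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_snps(self) -> int:
        """Number of SNP columns (N)."""
        return int(self.genotypes.shape[1])

    @property
    def m0(self) -> int:
        """Number of control samples."""
        return int(np.count_nonzero(self.phenotype == 0))

    @property
    def m1(self) -> int:
        """Number of case samples."""
        return int(np.count_nonzero(self.phenotype == 1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.snp_names == other.snp_names
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
        )


@dataclass
class GroundTruth:
    """The pathogenic interactions planted in a simulated dataset."""

    functional_sets: list[frozenset[str]]
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.functional_sets = [frozenset(s) for s in self.functional_sets]
        for s in self.functional_sets:
            if len(s) < 2:
                raise ValueError("each functional set must have size >= 2")


_CLASS_LABEL = "class"


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_dataset(path: str | Path, delimiter: str | None = None) -> Dataset:
    """Read a GAMETES-dialect genotype table.

    The class column is recognised by its header (``Class``, case-insensitive)
    and may appear at any position; SNP column order is preserved.
    ``delimiter=None`` auto-detects tab first, then comma.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty input")
    delim = delimiter or _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(delim)]
    class_cols = [i for i, h in enumerate(header) if h.lower() == _CLASS_LABEL]
    if not class_cols:
        raise DatasetFormatError(f"{path}: no 'Class' column in header")
    class_col = class_cols[0]
    snp_names = [h for i, h in enumerate(header) if i != class_col]
    if len(set(snp_names)) != len(snp_names):
        raise DuplicateHeaderError(f"{path}: duplicate SNP name in header")
    if len(lines) == 1:
        raise EmptyInputError(f"{path}: header only, no samples")

    n_rows = len(lines) - 1
    geno = np.empty((n_rows, len(snp_names)), dtype=np.int8)
    phen = np.empty(n_rows, dtype=np.int8)
    for r, line in enumerate(lines[1:]):
        fields = line.split(delim)
        if len(fields) != len(header):
            raise DatasetFormatError(
                f"{path}: row {r} has {len(fields)} fields, expected {len(header)}"
            )
        for c, tok in enumerate(fields):
            tok = tok.strip()
            try:
                v = int(tok)
            except ValueError:
                v = -1
            if c == class_col:
                if v not in (0, 1):
                    raise MalformedClassError(f"{path}: bad class {tok!r} at row {r}")
                phen[r] = v
            else:
                if v not in (0, 1, 2):
                    name = header[c]
                    raise MalformedGenotypeError(
                        f"{path}: bad genotype {tok!r} at row {r}, column {name!r}"
                    )
                geno[r, c - (1 if c > class_col else 0)] = v
    return Dataset(genotypes=geno, phenotype=phen, snp_names=snp_names)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write ``dataset`` as a tab-delimited table; inverse of :func:`read_dataset`."""
    path = Path(path)
    out = ["\t".join([*dataset.snp_names, "Class"])]
    for row, y in zip(dataset.genotypes, dataset.phenotype):
        out.append("\t".join([*map(str, row.tolist()), str(int(y))]))
    path.write_text("\n".join(out) + "\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the planted-interaction manifest: one comma-joined SNP set per row."""
    path = Path(path)
    out = ["model_id\tsnps"]
    for s in truth.functional_sets:
        out.append(f"{truth.model_id}\t{','.join(sorted(s))}")
    path.write_text("\n".join(out) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty manifest")
    sets: list[frozenset[str]] = []
    model_id = "model"
    for ln in lines[1:]:
        model_id, snps = ln.split("\t")
        sets.append(frozenset(snps.split(",")))
    return GroundTruth(functional_sets=sets, model_id=model_id)
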