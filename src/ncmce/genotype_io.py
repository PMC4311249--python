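"""Genotype matrix container and readers/writers.

The central in-memory object is :class:`GenotypeMatrix`: an
individuals x SNPs numeric matrix using the 4-level coding

    0  homozygous wild-type
    1  heterozygous
    2  homozygous variant
    3  missing

with sample ids on the rows, SNP ids on the columns and an optional
``sample_id -> population`` label map.  The primary on-disk format is a
delimited table whose first column holds the sample id, with an optional
header row of SNP ids.  A VCF reader (GT subfield only, biallelic sites)
and a two-column label-table reader are provided as well.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    EmptyOutputError,
    GenotypeParseError,
    GenotypeStructureError,
    IdentityError,
    LabelError,
    VcfFormatError,
)

logger = logging.getLogger(__name__)

MISSING = 3
_VALID_INT_CODES = frozenset({0.0, 1.0, 2.0, 3.0})


def _is_integer_coded(values: np.ndarray) -> bool:
    return bool(np.isin(values, (0.0, 1.0, 2.0, 3.0)).all())


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype matrix.

    Parameters
    ----------
    values
        ``(n_individuals, n_snps)`` float array.
    sample_ids, snp_ids
        Unique row / column identifiers.
    labels
        Optional ``sample_id -> population`` map covering every sample.
    """

    values: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    labels: dict[str, str] | None = None
    integer_coded: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GenotypeStructureError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise GenotypeStructureError(
                f"{n} rows but {len(self.sample_ids)} sample ids"
            )
        if m != len(self.snp_ids):
            raise GenotypeStructureError(
                f"{m} columns but {len(self.snp_ids)} SNP ids"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise IdentityError(f"duplicate sample ids: {dupes}")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise IdentityError("duplicate SNP ids")
        if self.labels is not None:
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise LabelError(f"samples without a population label: {missing}")
        self.integer_coded = _is_integer_coded(self.values)

    # -- conveniences -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> list[str]:
        """Per-row population labels, in sample order."""
        if self.labels is None:
            raise LabelError("genotype matrix has no population labels")
        return [self.labels[s] for s in self.sample_ids]

    def with_values(self, values: np.ndarray) -> "GenotypeMatrix":
        """Copy with replaced values (ids and labels preserved)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        unknown = [s for s in ids if s not in pos]
        if unknown:
            raise IdentityError(f"unknown sample ids: {sorted(unknown)}")
        return np.asarray([pos[s] for s in ids], dtype=int)


# -- delimited tables ----------------------------------------------------


def read_genotype_table(
    path: str | Path,
    delimiter: str = ",",
    has_header: bool = True,
) -> GenotypeMatrix:
    """Read a delimited genotype table (rows = individuals).

    The first column holds the sample id; when ``has_header`` the first row
    holds SNP ids (its leading cell is ignored).  All data cells must parse
    as numbers; ``integer_coded`` is set iff every value lies in {0,1,2,3}.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r]  # drop blank lines
    if not rows:
        raise GenotypeStructureError(f"{path}: empty file")

    if has_header:
        snp_ids = [c.strip() for c in rows[0][1:]]
        data_rows = rows[1:]
    else:
        snp_ids = None
        data_rows = rows
    if not data_rows:
        raise GenotypeStructureError(f"{path}: no data rows")

    width = len(data_rows[0])
    sample_ids: list[str] = []
    values = np.empty((len(data_rows), width - 1), dtype=float)
    for i, row in enumerate(data_rows):
        if len(row) != width:
            raise GenotypeStructureError(
                f"{path}: ragged row {i + 1} ({len(row)} fields, expected {width})"
            )
        sample_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: non-numeric cell {cell!r} at (row {i + 1}, col {j + 1})"
                ) from None
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(width - 1)]
    if len(snp_ids) != width - 1:
        raise GenotypeStructureError(
            f"{path}: header has {len(snp_ids)} SNP ids for {width - 1} data columns"
        )
    return GenotypeMatrix(values, sample_ids, snp_ids)


def write_genotype_table(
    g: GenotypeMatrix, path: str | Path, delimiter: str = ","
) -> None:
    """Write ``g`` in the format read by :func:`read_genotype_table`.

    Integer-valued cells are written without a decimal point so that an
    integer-coded matrix round-trips exactly.
    """

    def fmt(x: float) -> str:
        x = float(x)
        return str(int(x)) if x.is_integer() else repr(x)

    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["sample_id", *g.snp_ids])
        for sid, row in zip(g.sample_ids, g.values):
            w.writerow([sid, *(fmt(x) for x in row)])


# -- PLINK .traw (optional extension) ------------------------------------


def read_traw(path: str | Path) -> GenotypeMatrix:
    """Read a PLINK ``.traw`` additive-dosage table (SNPs in rows).

    The source is transposed to individuals x SNPs; ``NA`` cells become the
    missing code 3.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or rows[0][:6] != ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]:
        raise GenotypeStructureError(f"{path}: not a PLINK .traw table")
    sample_ids = [c.split("_", 1)[-1] for c in rows[0][6:]]
    snp_ids = [r[1] for r in rows[1:]]
    values = np.empty((len(sample_ids), len(snp_ids)), dtype=float)
    for j, row in enumerate(rows[1:]):
        for i, cell in enumerate(row[6:]):
            values[i, j] = MISSING if cell in ("NA", "") else float(cell)
    return GenotypeMatrix(values, sample_ids, snp_ids)


# -- VCF -----------------------------------------------------------------


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT subfield, biallelic sites only).

    Coding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, any missing allele -> 3;
    phase is ignored.  Multiallelic records are skipped (count logged).
    SNP ids are ``CHROM:POS:REF:ALT``.
    """
    from cyvcf2 import VCF  # deferred: htslib import is relatively heavy

    path = str(path)
    vcf = VCF(path, gts012=False)
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    snp_ids: list[str] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        if variant.FORMAT and "GT" not in variant.FORMAT:
            raise VcfFormatError(f"{path}: record without GT at {variant.POS}")
        gts = variant.genotypes  # [allele_a, allele_b, phased] per sample
        if gts is None:
            raise VcfFormatError(f"{path}: missing GT format key")
        col = np.empty(len(sample_ids), dtype=float)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            col[i] = MISSING if (a < 0 or b < 0) else float(a + b)
        columns.append(col)
        snp_ids.append(f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}")
    if skipped:
        logger.info("read_vcf_genotypes: skipped %d non-biallelic record(s)", skipped)
    if not columns:
        raise EmptyOutputError(f"{path}: no biallelic sites with GT found")
    values = np.column_stack(columns)
    return GenotypeMatrix(values, sample_ids, snp_ids)


# -- population labels ---------------------------------------------------


def read_labels(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column ``sample_id <tab> population`` table."""
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open(newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter=delimiter)):
            if not row:
                continue
            if len(row) < 2:
                raise GenotypeStructureError(
                    f"{path}: row {i + 1} has fewer than two columns"
                )
            labels[row[0].strip()] = row[1].strip()
    return labels


def attach_labels(
    g: GenotypeMatrix, table: str | Path | Mapping[str, str], delimiter: str = "\t"
) -> GenotypeMatrix:
    """Return a copy of ``g`` with population labels attached.

    Samples of ``g`` absent from the table raise :class:`LabelError`;
    table entries for unknown samples are ignored with a logged warning.
    """
    if isinstance(table, (str, Path)):
        table = read_labels(table, delimiter=delimiter)
    known = set(g.sample_ids)
    extra = sorted(set(table) - known)
    if extra:
        logger.warning("attach_labels: ignoring %d unknown sample id(s): %s",
                       len(extra), extra[:10])
    unlabelled = [s for s in g.sample_ids if s not in table]
    if unlabelled:
        raise LabelError(f"samples without a population label: {unlabelled}")
    labels = {s: table[s] for s in g.sample_ids}
    return replace(g, labels=labels)
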