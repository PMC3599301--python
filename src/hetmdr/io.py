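"""Reading and writing the tab-delimited MDR flat-file format.

Plain text, UTF-8, Unix newlines.  Header row: locus names then the literal
column name ``Class``; one row per individual; genotype columns coded 0/1/2
(minor-allele counts); final column 1 = case, 0 = control.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulate import Dataset

CLASS_COLUMN = "Class"


class MdrFormatError(ValueError):
    """Malformed MDR flat file; the message carries the 1-based line number."""


def write_mdr_file(dataset: Dataset, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([*dataset.locus_names, CLASS_COLUMN]) + "\n")
        for row, status in zip(dataset.genotypes, dataset.status):
            fh.write("\t".join(map(str, row.tolist())) + f"\t{int(status)}\n")


def read_mdr_file(path) -> Dataset:
    """Parse an MDR flat file into a truth-free :class:`Dataset`."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise MdrFormatError(f"{path}: line 1: empty file")
        columns = header.rstrip("\n").split("\t")
        if len(columns) < 2 or columns[-1] != CLASS_COLUMN:
            raise MdrFormatError(
                f"{path}: line 1: header must list locus names followed by {CLASS_COLUMN!r}"
            )
        locus_names = columns[:-1]
        n_loci = len(locus_names)

        genotypes, status = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_loci + 1:
                raise MdrFormatError(
                    f"{path}: line {lineno}: expected {n_loci + 1} columns, got {len(fields)}"
                )
            try:
                values = [int(v) for v in fields]
            except ValueError:
                raise MdrFormatError(f"{path}: line {lineno}: non-integer field") from None
            if any(g not in (0, 1, 2) for g in values[:-1]):
                raise MdrFormatError(
                    f"{path}: line {lineno}: genotype codes must be 0, 1 or 2"
                )
            if values[-1] not in (0, 1):
                raise MdrFormatError(
                    f"{path}: line {lineno}: status must be 0 (control) or 1 (case)"
                )
            genotypes.append(values[:-1])
            status.append(values[-1])

    if not genotypes:
        raise MdrFormatError(f"{path}: line 2: no individuals")
    return Dataset(
        genotypes=np.array(genotypes, dtype=np.int8),
        status=np.array(status, dtype=np.int8),
        locus_names=locus_names,
    )
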