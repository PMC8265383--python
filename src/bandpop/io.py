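"""Readers and writers for band-matrix files.

Two plain-text dialects are supported:

* the GenAlEx binary CSV layout — row 1: ``n_loci, n_samples, n_pops,
  size_1, ..., size_k``; row 2: title cell, two blanks, then population
  labels; row 3: ``Accession, Pop, locus_1, ...``; data rows:
  ``accession, population, 0/1 cells``;
* a plain TSV with header ``accession<TAB>population[<TAB>taxon]<TAB>loci...``.

The loader is strict by default: a missing or non-binary cell raises
:class:`~bandpop.exceptions.ParseError` naming the row and column.  Loci
containing missing cells can instead be dropped with
``on_missing="drop-locus"`` — silent imputation is never performed, since
it would bias downstream allele-frequency estimates.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .exceptions import ParseError, ValidationError
from .matrix import BandMatrix

__all__ = [
    "read_genalex_binary",
    "write_genalex_binary",
    "read_tsv",
    "write_tsv",
]

_MISSING_TOKENS = {"", "?", "NA", "-9"}


def _parse_cell(token: str, row: int, col: int):
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    if token in ("0", "1"):
        return int(token)
    raise ParseError(f"non-binary band score {token!r}", row=row, column=col)


def _apply_missing(accessions, locus_ids, cells, on_missing):
    values = np.empty((len(accessions), len(locus_ids)), dtype=float)
    for i, row in enumerate(cells):
        for j, v in enumerate(row):
            values[i, j] = np.nan if v is None else v
    missing_cols = np.isnan(values).any(axis=0)
    if missing_cols.any():
        if on_missing == "strict":
            i, j = np.argwhere(np.isnan(values))[0]
            raise ParseError(
                f"missing band score for accession {accessions[i]!r} at locus "
                f"{locus_ids[j]!r}; rerun with on_missing='drop-locus' to drop "
                f"affected loci")
        if on_missing != "drop-locus":
            raise ValueError(f"unknown on_missing policy {on_missing!r}")
        keep = ~missing_cols
        values = values[:, keep]
        locus_ids = [l for l, k in zip(locus_ids, keep) if k]
        if not locus_ids:
            raise ParseError("all loci contain missing data")
    return locus_ids, values.astype(np.int8)


def read_genalex_binary(path, on_missing: str = "strict") -> BandMatrix:
    """Read a GenAlEx-dialect binary CSV file into a :class:`BandMatrix`."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ParseError(f"{path.name}: expected header rows plus data, "
                         f"got {len(rows)} rows")
    header = rows[0]
    try:
        n_loci, n_samples, n_pops = (int(header[i]) for i in range(3))
    except (ValueError, IndexError):
        raise ParseError(
            "malformed header: first row must start with n_loci, n_samples, "
            "n_pops", row=1) from None
    if n_loci < 1 or n_samples < 1 or n_pops < 1:
        raise ParseError("header counts must be positive", row=1)
    try:
        sizes = [int(header[3 + i]) for i in range(n_pops)]
    except (ValueError, IndexError):
        raise ParseError(
            f"header must carry {n_pops} population sizes after the counts",
            row=1) from None
    if sum(sizes) != n_samples:
        raise ParseError(
            f"declared population sizes sum to {sum(sizes)}, not "
            f"n_samples={n_samples}", row=1)
    pop_labels = [c.strip() for c in rows[1][3:3 + n_pops]]
    if len(pop_labels) != n_pops or any(not p for p in pop_labels):
        raise ParseError(
            f"row 2 must carry {n_pops} population labels from column 4",
            row=2)
    locus_row = rows[2]
    locus_ids = [c.strip() for c in locus_row[2:2 + n_loci]]
    if len(locus_ids) != n_loci or any(not l for l in locus_ids):
        raise ParseError(
            f"row 3 must carry {n_loci} locus ids from column 3", row=3)

    data = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data) != n_samples:
        raise ParseError(
            f"header declares {n_samples} samples but file has {len(data)} "
            f"data rows")
    accessions, pops, cells = [], [], []
    for k, r in enumerate(data):
        rowno = k + 4
        if len(r) < 2 + n_loci:
            raise ParseError(
                f"data row has {len(r)} columns, expected {2 + n_loci}",
                row=rowno)
        acc, pop = r[0].strip(), r[1].strip()
        if not acc:
            raise ParseError("empty accession id", row=rowno, column=1)
        if acc in accessions:
            raise ParseError(f"duplicate accession id {acc!r}", row=rowno,
                             column=1)
        if pop not in pop_labels:
            raise ParseError(
                f"population {pop!r} not declared in header", row=rowno,
                column=2)
        accessions.append(acc)
        pops.append(pop)
        cells.append([_parse_cell(c, rowno, 3 + j)
                      for j, c in enumerate(r[2:2 + n_loci])])
    counts = {p: pops.count(p) for p in pop_labels}
    declared = dict(zip(pop_labels, sizes))
    if counts != declared:
        bad = [p for p in pop_labels if counts[p] != declared[p]]
        raise ParseError(
            f"population size mismatch between header and body for {bad}: "
            f"declared {[declared[p] for p in bad]}, "
            f"found {[counts[p] for p in bad]}")
    locus_ids, values = _apply_missing(accessions, locus_ids, cells, on_missing)
    return BandMatrix(accessions, locus_ids, values,
                      dict(zip(accessions, pops)))


def write_genalex_binary(matrix: BandMatrix, path, title: str = "bandpop") -> None:
    """Write *matrix* in the GenAlEx binary CSV dialect."""
    if matrix.n_loci == 0:
        raise ValidationError("refusing to write a matrix with 0 loci")
    layout = matrix.layout()
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([matrix.n_loci, matrix.n_individuals,
                    layout.n_populations, *layout.sizes])
        w.writerow([title, "", "", *layout.populations])
        w.writerow(["Accession", "Pop", *matrix.locus_ids])
        for i, acc in enumerate(matrix.accession_ids):
            w.writerow([acc, matrix.pop_of[acc], *matrix.values[i].tolist()])


def read_tsv(path, on_missing: str = "strict") -> BandMatrix:
    """Read the plain TSV dialect (``accession\\tpopulation[\\ttaxon]\\tloci...``)."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise ParseError(f"{path.name}: empty file")
    header = [c.strip() for c in rows[0]]
    if len(header) < 3 or header[0].lower() != "accession" \
            or header[1].lower() != "population":
        raise ParseError(
            "TSV header must start with 'accession', 'population'", row=1)
    has_taxon = len(header) > 2 and header[2].lower() == "taxon"
    first_locus = 3 if has_taxon else 2
    locus_ids = header[first_locus:]
    if not locus_ids:
        raise ParseError("no locus columns in header", row=1)
    accessions, pops, taxa, cells = [], [], {}, []
    for k, r in enumerate(rows[1:]):
        rowno = k + 2
        if len(r) != len(header):
            raise ParseError(
                f"row has {len(r)} columns, expected {len(header)}", row=rowno)
        acc, pop = r[0].strip(), r[1].strip()
        if acc in accessions:
            raise ParseError(f"duplicate accession id {acc!r}", row=rowno,
                             column=1)
        accessions.append(acc)
        pops.append(pop)
        if has_taxon:
            taxa[pop] = r[2].strip()
        cells.append([_parse_cell(c, rowno, first_locus + 1 + j)
                      for j, c in enumerate(r[first_locus:])])
    locus_ids, values = _apply_missing(accessions, locus_ids, cells, on_missing)
    return BandMatrix(accessions, locus_ids, values,
                      dict(zip(accessions, pops)),
                      taxon_of=taxa if has_taxon else None)


def write_tsv(matrix: BandMatrix, path) -> None:
    """Write *matrix* in the plain TSV dialect (taxon column if present)."""
    if matrix.n_loci == 0:
        raise ValidationError("refusing to write a matrix with 0 loci")
    has_taxon = matrix.taxon_of is not None
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        header = ["accession", "population"]
        if has_taxon:
            header.append("taxon")
        w.writerow(header + matrix.locus_ids)
        for i, acc in enumerate(matrix.accession_ids):
            pop = matrix.pop_of[acc]
            row = [acc, pop]
            if has_taxon:
                row.append(matrix.taxon_of.get(pop, ""))
            w.writerow(row + matrix.values[i].tolist())
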