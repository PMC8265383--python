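"""Domain types and operations for binary dominant-marker band data.

A dominant marker system (iPBS, ISSR, RAPD ...) scores each locus in each
individual as band present (1) or absent (0); heterozygotes are
indistinguishable from band-allele homozygotes, and absence implies the
null homozygote.  :class:`BandMatrix` is the single in-memory container
every analysis stage consumes: an individuals x loci 0/1 matrix plus a
population assignment per individual, an optional locus -> primer map
(gel-band provenance) and an optional population -> taxon map for
hierarchical analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "BandMatrix",
    "PopulationLayout",
    "PrivateBands",
    "band_frequency",
    "band_frequencies",
    "find_duplicates",
    "private_bands",
]


@dataclass(frozen=True)
class PopulationLayout:
    """Ordered populations, their sizes, and an optional taxon partition.

    Parameters
    ----------
    populations
        Population labels in presentation order.
    sizes
        Individuals per population (same order).
    taxa
        Optional mapping population -> higher-level group (taxon/series).
    """

    populations: tuple[str, ...]
    sizes: tuple[int, ...]
    taxa: Mapping[str, str] | None = None

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if len(self.populations) != len(self.sizes):
            raise ValidationError("populations and sizes differ in length")
        if len(set(self.populations)) != len(self.populations):
            raise ValidationError("duplicate population labels")
        if any(s < 1 for s in self.sizes):
            raise ValidationError("every population size must be >= 1")
        if self.taxa is not None:
            missing = [p for p in self.populations if p not in self.taxa]
            if missing:
                raise ValidationError(
                    f"populations missing from taxon map: {missing}")

    @property
    def n_individuals(self) -> int:
        return sum(self.sizes)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def size_of(self, population: str) -> int:
        try:
            return self.sizes[self.populations.index(population)]
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None


class BandMatrix:
    """Binary band scores for a set of accessions at a set of loci.

    Invariants enforced at construction: entries are 0/1 only, accession
    and locus ids are unique, and every accession carries exactly one
    population label.  Duplicate *rows* are legal — they are biological
    duplicates to be reported by :func:`find_duplicates`, not rejected.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        locus_ids: Sequence[str],
        values,
        pop_of: Mapping[str, str],
        locus_primer: Mapping[str, str] | None = None,
        taxon_of: Mapping[str, str] | None = None,
    ):
        self.accession_ids = [str(a) for a in accession_ids]
        self.locus_ids = [str(l) for l in locus_ids]
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if values.shape != (len(self.accession_ids), len(self.locus_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.accession_ids)} accessions x "
                f"{len(self.locus_ids)} loci")
        if values.size == 0:
            raise ValidationError("empty band matrix (no accessions or loci)")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValidationError(
                f"non-binary entry {values[tuple(bad)]!r} at accession "
                f"{self.accession_ids[bad[0]]!r}, locus {self.locus_ids[bad[1]]!r}")
        self.values = values.astype(np.int8)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            seen: set[str] = set()
            dups = []
            for a in self.accession_ids:
                if a in seen:
                    dups.append(a)
                seen.add(a)
            raise ValidationError(f"duplicate accession ids: {sorted(set(dups))}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus ids")
        missing = [a for a in self.accession_ids if a not in pop_of]
        if missing:
            raise ValidationError(f"accessions without a population: {missing}")
        self.pop_of = {a: str(pop_of[a]) for a in self.accession_ids}
        self.locus_primer = dict(locus_primer) if locus_primer else None
        if self.locus_primer is not None:
            unknown = set(self.locus_primer) - set(self.locus_ids)
            if unknown:
                raise ValidationError(
                    f"primer map references unknown loci: {sorted(unknown)}")
        self.taxon_of = dict(taxon_of) if taxon_of else None

    # ---- basic structure -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.accession_ids:
            seen.setdefault(self.pop_of[a], None)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(self.accession_ids)
                        if self.pop_of[a] == population], dtype=int)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def layout(self) -> PopulationLayout:
        pops = self.populations
        sizes = [len(self.population_indices(p)) for p in pops]
        taxa = None
        if self.taxon_of is not None:
            taxa = {p: self.taxon_of[p] for p in pops if p in self.taxon_of}
            if len(taxa) != len(pops):
                taxa = None
        return PopulationLayout(tuple(pops), tuple(sizes), taxa)

    def subset(self, populations: Iterable[str]) -> "BandMatrix":
        """Restrict to the given populations (order preserved from self)."""
        keep = list(populations)
        for p in keep:
            self.population_indices(p)  # raises on unknown
        keep_set = set(keep)
        rows = [i for i, a in enumerate(self.accession_ids)
                if self.pop_of[a] in keep_set]
        acc = [self.accession_ids[i] for i in rows]
        return BandMatrix(
            acc, self.locus_ids, self.values[rows],
            {a: self.pop_of[a] for a in acc},
            self.locus_primer,
            {p: self.taxon_of[p] for p in keep if self.taxon_of and p in self.taxon_of}
            or None if self.taxon_of else None,
        )

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BandMatrix)
            and self.accession_ids == other.accession_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.values, other.values)
            and self.pop_of == other.pop_of
        )

    def __repr__(self) -> str:
        return (f"<BandMatrix {self.n_individuals} accessions x "
                f"{self.n_loci} loci, {len(self.populations)} populations>")


# ---- operations ----------------------------------------------------------


def band_frequency(matrix: BandMatrix, population: str, locus: str) -> float:
    """Fraction of individuals in *population* showing the band at *locus*."""
    idx = matrix.population_indices(population)
    j = matrix.locus_index(locus)
    return float(matrix.values[idx, j].mean())


def band_frequencies(matrix: BandMatrix, population: str) -> np.ndarray:
    """Per-locus band frequencies within one population (vector of length n_loci)."""
    idx = matrix.population_indices(population)
    return matrix.values[idx].mean(axis=0)


def find_duplicates(matrix: BandMatrix) -> list[list[str]]:
    """Maximal groups (size >= 2) of accessions identical at all loci.

    Multi-locus matching: accessions with bitwise-identical band rows are
    reported together; singletons are omitted.  Groups are ordered by the
    position of their first member, members in row order.
    """
    groups: dict[bytes, list[str]] = {}
    for acc, row in zip(matrix.accession_ids, matrix.values):
        groups.setdefault(row.tobytes(), []).append(acc)
    return [g for g in groups.values() if len(g) >= 2]


@dataclass
class PrivateBands:
    """Loci private to a single population within a scoped set.

    ``by_population[p]`` lists loci whose band occurs in ``p`` and in no
    other population of the scope; ``per_primer`` tallies those loci by
    primer when the matrix carries a primer map.  ``definition`` is
    ``"any"`` (band frequency > 0 in the owner) or ``"fixed"`` (band
    present in every individual of the owner).
    """

    scope: list[str]
    definition: str
    by_population: dict[str, list[str]]
    per_primer: dict[str, int] | None = None

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_population.values())


def private_bands(matrix: BandMatrix, scope: Sequence[str] | None = None,
                  definition: str = "any") -> PrivateBands:
    """Find population-specific bands within *scope*.

    A locus is private to population ``p`` iff its band frequency is > 0 in
    ``p`` and 0 in every other scoped population.  With
    ``definition="fixed"`` the owner must additionally show the band in all
    of its individuals (frequency 1).
    """
    if definition not in ("any", "fixed"):
        raise ValueError(f"unknown private-band definition {definition!r}")
    scope = list(scope) if scope is not None else matrix.populations
    if not scope:
        raise ValueError("scope must contain at least one population")
    freqs = {p: band_frequencies(matrix, p) for p in scope}  # raises on unknown
    by_pop: dict[str, list[str]] = {p: [] for p in scope}
    for j, locus in enumerate(matrix.locus_ids):
        present = [p for p in scope if freqs[p][j] > 0]
        if len(present) == 1:
            owner = present[0]
            if definition == "fixed" and freqs[owner][j] < 1.0:
                continue
            by_pop[owner].append(locus)
    per_primer = None
    if matrix.locus_primer is not None:
        per_primer = {}
        for loci in by_pop.values():
            for locus in loci:
                primer = matrix.locus_primer.get(locus, "unassigned")
                per_primer[primer] = per_primer.get(primer, 0) + 1
    return PrivateBands(scope, definition, by_pop, per_primer)
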