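"""Dominant-marker allele-frequency estimation and diversity statistics.

For a dominant biallelic locus under Hardy-Weinberg equilibrium the band
is absent only in null homozygotes, so the null-allele frequency is
estimated from the band frequency f as ``q = sqrt(1 - f)`` and the band
allele as ``p = 1 - q``.  From (p, q) the standard per-locus indices
follow:

======  ==========================================
Na      band-presence indicator, 1{f > 0}
Ne      effective allele number, 1 / (p^2 + q^2)
I       Shannon's information index, -(p ln p + q ln q)  [nats]
He      expected heterozygosity, 2 p q
uHe     unbiased He, (2N / (2N - 1)) * He
PIC     polymorphic information content, 1 - [f^2 + (1 - f)^2]
======  ==========================================

Per-population summaries are means +/- SE over *all* loci, monomorphic
loci included (their zeros belong in the mean), with SE = sd(ddof=1) /
sqrt(n_loci) — the presentation convention of dominant-marker packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BandMatrix, band_frequencies

__all__ = [
    "LocusStats",
    "PopDiversity",
    "PicSummary",
    "estimate_allele_freqs",
    "locus_stats",
    "population_summary",
    "diversity_table",
    "pic",
    "pic_summary",
]

_STATS = ("na", "ne", "shannon_i", "he", "uhe")


def estimate_allele_freqs(band_freq: float) -> tuple[float, float]:
    """Estimate (p_hat, q_hat) from a band frequency under HWE + dominance.

    q_hat = sqrt(1 - band_freq) is the null-allele frequency; p_hat = 1 - q_hat.
    """
    if not 0.0 <= band_freq <= 1.0:
        raise ValueError(f"band frequency {band_freq} outside [0, 1]")
    q = float(np.sqrt(1.0 - band_freq))
    return 1.0 - q, q


@dataclass(frozen=True)
class LocusStats:
    """Per-locus allele-frequency estimates and diversity indices."""

    locus: str
    band_freq: float
    p_hat: float
    q_hat: float
    na: int
    ne: float
    shannon_i: float
    he: float
    uhe: float
    polymorphic: bool


def _shannon(p: float, q: float) -> float:
    s = 0.0
    for x in (p, q):
        if x > 0.0:
            s -= x * np.log(x)
    return float(s)


def locus_stats(matrix: BandMatrix, population: str) -> list[LocusStats]:
    """Diversity indices for every locus within one population."""
    idx = matrix.population_indices(population)
    n = len(idx)
    if n < 2:
        raise ValueError(
            f"population {population!r} has {n} individual(s); "
            "uHe requires N >= 2")
    freqs = band_frequencies(matrix, population)
    out = []
    for locus, f in zip(matrix.locus_ids, freqs):
        p, q = estimate_allele_freqs(float(f))
        he = 2.0 * p * q
        out.append(LocusStats(
            locus=locus,
            band_freq=float(f),
            p_hat=p,
            q_hat=q,
            na=int(f > 0),
            ne=1.0 / (p * p + q * q),
            shannon_i=_shannon(p, q),
            he=he,
            uhe=(2.0 * n / (2.0 * n - 1.0)) * he,
            polymorphic=bool(0.0 < f < 1.0),
        ))
    return out


@dataclass(frozen=True)
class PopDiversity:
    """Mean +/- SE of each diversity index over loci, for one population."""

    population: str
    n: int
    n_loci: int
    means: dict[str, float]
    ses: dict[str, float]
    pct_polymorphic: float

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"population": self.population, "N": self.n}
        for s in _STATS:
            row[s] = self.means[s]
            row[f"{s}_se"] = self.ses[s]
        row["pct_polymorphic"] = self.pct_polymorphic
        return row


def population_summary(matrix: BandMatrix, population: str,
                       polymorphic_min_freq: float = 0.0) -> PopDiversity:
    """Mean +/- SE of Na, Ne, I, He, uHe over all loci, and %P.

    Monomorphic loci are included in every mean.  ``polymorphic_min_freq``
    optionally imposes a minor-band-frequency threshold on the %P count
    (default off: any locus with 0 < f < 1 counts).
    """
    stats = locus_stats(matrix, population)
    n_loci = len(stats)
    arrays = {s: np.array([getattr(ls, s) for ls in stats], dtype=float)
              for s in _STATS}
    means = {s: float(a.mean()) for s, a in arrays.items()}
    ses = {s: float(a.std(ddof=1) / np.sqrt(n_loci)) if n_loci > 1 else np.nan
           for s, a in arrays.items()}
    lo = polymorphic_min_freq
    n_poly = sum(1 for ls in stats
                 if lo < ls.band_freq < 1.0 - lo if ls.polymorphic)
    return PopDiversity(
        population=population,
        n=len(matrix.population_indices(population)),
        n_loci=n_loci,
        means=means,
        ses=ses,
        pct_polymorphic=100.0 * n_poly / n_loci,
    )


def diversity_table(matrix: BandMatrix) -> pd.DataFrame:
    """Per-population diversity summary plus a grand-mean row.

    The grand-mean row averages the per-population means; its SE columns
    are SEs over populations (sd of the 17 means / sqrt(17)) — per-locus
    SEs stay in the individual population rows.
    """
    rows = [population_summary(matrix, p).as_row()
            for p in matrix.populations]
    df = pd.DataFrame(rows)
    mean_row: dict[str, object] = {"population": "Mean",
                                   "N": df["N"].mean()}
    k = len(df)
    for s in _STATS:
        mean_row[s] = df[s].mean()
        mean_row[f"{s}_se"] = df[s].std(ddof=1) / np.sqrt(k) if k > 1 else np.nan
    mean_row["pct_polymorphic"] = df["pct_polymorphic"].mean()
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def pic(f: float) -> float:
    """Polymorphic information content of a dominant marker with band freq f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"band frequency {f} outside [0, 1]")
    return 1.0 - (f * f + (1.0 - f) ** 2)


@dataclass(frozen=True)
class PicSummary:
    """PIC per locus (f pooled over all accessions) and its aggregates.

    Two headline aggregates are carried because both conventions occur in
    the literature: ``mean_pic`` (unweighted mean over loci) and
    ``mean_of_primer_means`` (mean of the per-primer means; equal when all
    primers yield the same number of loci).
    """

    per_locus: pd.Series
    per_primer_mean: pd.Series | None
    per_primer_n_loci: pd.Series | None
    mean_pic: float
    mean_of_primer_means: float | None
    group_band_counts: pd.DataFrame | None


def pic_summary(matrix: BandMatrix,
                groups: dict[str, list[str]] | None = None) -> PicSummary:
    """Per-locus PIC over the pooled data set, with per-primer aggregates.

    ``groups`` optionally maps a group label (e.g. a commercial series) to
    a list of populations; for each primer x group the number of member
    loci with band frequency > 0 inside the group is counted.
    """
    f = matrix.values.mean(axis=0)
    per_locus = pd.Series([pic(float(x)) for x in f],
                          index=matrix.locus_ids, name="pic")
    per_primer_mean = per_primer_n = None
    if matrix.locus_primer is not None:
        unassigned = [l for l in matrix.locus_ids
                      if l not in matrix.locus_primer]
        if unassigned:
            raise ValueError(
                f"loci without a primer assignment: {unassigned[:5]}...")
        primer = pd.Series(matrix.locus_primer)[matrix.locus_ids]
        per_primer_mean = per_locus.groupby(primer.values).mean()
        per_primer_n = per_locus.groupby(primer.values).size()
    group_counts = None
    if groups is not None:
        rows = {}
        for label, pops in groups.items():
            idx = np.concatenate([matrix.population_indices(p) for p in pops])
            present = matrix.values[idx].any(axis=0)
            if matrix.locus_primer is not None:
                primer = pd.Series(matrix.locus_primer)[matrix.locus_ids]
                rows[label] = pd.Series(present.astype(int),
                                        index=matrix.locus_ids
                                        ).groupby(primer.values).sum()
            else:
                rows[label] = pd.Series({"all": int(present.sum())})
        group_counts = pd.DataFrame(rows)
    return PicSummary(
        per_locus=per_locus,
        per_primer_mean=per_primer_mean,
        per_primer_n_loci=per_primer_n,
        mean_pic=float(per_locus.mean()),
        mean_of_primer_means=(float(per_primer_mean.mean())
                              if per_primer_mean is not None else None),
        group_band_counts=group_counts,
    )
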