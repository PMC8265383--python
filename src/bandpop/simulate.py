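"""Synthetic dominant-marker datasets with known ground truth.

Simulation is genotype-level: each individual draws two alleles per locus
under Hardy-Weinberg equilibrium, and the band is absent only when both
alleles are null (dominance masking).  The band probability at a locus
with null-allele frequency q is therefore 1 - q^2, so the square-root
estimator q_hat = sqrt(1 - band_freq) is exactly the generative inverse —
parameter-recovery tests on this generator are meaningful, not circular.

Cultivated lines are emulated as founder bottlenecks from a wild source:
founder allele counts are binomially sampled from the source frequencies,
then drift proceeds through Wright-Fisher binomial resampling at a small
effective size.  The paper-shaped scenario produces 17 populations x 8
individuals x 148 loci: one broad high-diversity wild source, one narrow
wild isolate, and 15 independently bottlenecked cultivar lines — low
within-line heterozygosity, strong among-line differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .matrix import BandMatrix

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_population",
    "simulate_bottleneck",
    "simulate_dataset",
    "paper_like_dataset",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population.

    ``q`` describes the per-locus null-allele frequency model: either the
    literal string ``"source"`` (use the shared source vector), a
    ``("beta", a, b)`` tuple for i.i.d. Beta draws, or a
    ``("bottleneck", n_founders, generations, ne)`` tuple applying a
    founder bottleneck plus drift to the source vector.
    """

    label: str
    n: int
    q: object = "source"
    taxon: str | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"population size must be >= 1, got {self.n}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full scenario: loci, source-frequency model, populations, seed."""

    n_loci: int
    populations: tuple[PopulationSpec, ...]
    source_beta: tuple[float, float] = (0.45, 0.45)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimulatedDataset:
    """A band matrix plus its generative truth (per-population q vectors)."""

    matrix: BandMatrix
    true_q: dict[str, np.ndarray]
    config: dict = field(default_factory=dict)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_population(n: int, n_loci: int, q_per_locus, seed,
                        label: str = "P1",
                        accession_prefix: str | None = None
                        ) -> SimulatedDataset:
    """Simulate *n* HWE individuals at loci with null frequencies *q_per_locus*.

    Each individual draws two alleles Bernoulli(q) per locus; the band is
    scored 0 iff both are null, so P(band) = 1 - q^2.
    """
    rng = _as_rng(seed)
    q = np.broadcast_to(np.asarray(q_per_locus, dtype=float),
                        (n_loci,)).copy()
    if ((q < 0) | (q > 1)).any():
        raise ValueError("null-allele frequencies must lie in [0, 1]")
    alleles = rng.random((n, n_loci, 2)) < q[None, :, None]
    values = (~alleles.all(axis=2)).astype(np.int8)
    prefix = accession_prefix or label
    acc = [f"{prefix}{i + 1}" for i in range(n)]
    loci = [f"L{j + 1:03d}" for j in range(n_loci)]
    matrix = BandMatrix(acc, loci, values, {a: label for a in acc})
    return SimulatedDataset(matrix=matrix, true_q={label: q},
                            config={"n": n, "n_loci": n_loci, "label": label})


def simulate_bottleneck(source_q, n_founders: int, generations: int,
                        ne: int, seed) -> np.ndarray:
    """Drifted null-allele frequencies after a founder bottleneck.

    ``n_founders`` diploid founders are sampled from the source (allele
    counts binomial on 2 * n_founders copies), then ``generations`` of
    Wright-Fisher resampling at effective size ``ne`` follow.
    """
    if n_founders < 1 or ne < 1 or generations < 0:
        raise ValueError("n_founders and ne must be >= 1, generations >= 0")
    rng = _as_rng(seed)
    q = np.asarray(source_q, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("null-allele frequencies must lie in [0, 1]")
    copies = 2 * n_founders
    q = rng.binomial(copies, q) / copies
    copies = 2 * ne
    for _ in range(generations):
        q = rng.binomial(copies, q) / copies
    return q


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run a full scenario: draw source frequencies, derive each population."""
    rng = np.random.default_rng(config.seed)
    a, b = config.source_beta
    source_q = rng.beta(a, b, size=config.n_loci)
    blocks, acc_ids, pop_of, taxon_of, true_q = [], [], {}, {}, {}
    for spec in config.populations:
        if spec.q == "source":
            q = source_q
        elif isinstance(spec.q, tuple) and spec.q[0] == "beta":
            q = rng.beta(spec.q[1], spec.q[2], size=config.n_loci)
        elif isinstance(spec.q, tuple) and spec.q[0] == "bottleneck":
            _, founders, gens, ne = spec.q
            q = simulate_bottleneck(source_q, founders, gens, ne, rng)
        else:
            raise ValueError(f"unknown q model {spec.q!r} for {spec.label}")
        true_q[spec.label] = q
        sim = simulate_population(spec.n, config.n_loci, q, rng,
                                  label=spec.label,
                                  accession_prefix=f"{spec.label}_")
        blocks.append(sim.matrix.values)
        acc_ids.extend(sim.matrix.accession_ids)
        for acc in sim.matrix.accession_ids:
            pop_of[acc] = spec.label
        if spec.taxon is not None:
            taxon_of[spec.label] = spec.taxon
    values = np.vstack(blocks)
    loci = [f"L{j + 1:03d}" for j in range(config.n_loci)]
    matrix = BandMatrix(acc_ids, loci, values, pop_of,
                        taxon_of=taxon_of or None)
    return SimulatedDataset(
        matrix=matrix, true_q=true_q,
        config={
            "n_loci": config.n_loci,
            "source_beta": list(config.source_beta),
            "seed": config.seed,
            "populations": [
                {"label": s.label, "n": s.n, "q": list(s.q)
                 if isinstance(s.q, tuple) else s.q, "taxon": s.taxon}
                for s in config.populations],
        })


# Default paper-shaped scenario: 15 cultivar lines in three commercial
# series plus two wild populations, eight individuals each, 148 loci.
_CULTIVAR_BOTTLENECK = ("bottleneck", 2, 16, 6)
_ISOLATE_BOTTLENECK = ("bottleneck", 3, 10, 8)
_SERIES = {
    "A": "Duchess", "B": "Duchess", "C": "Duchess",
    "D": "Kauai", "E": "Kauai", "F": "Kauai", "G": "Kauai",
    "H": "Kauai", "I": "Kauai", "J": "Kauai",
    "K": "LittleKiss", "L": "LittleKiss", "M": "LittleKiss",
    "N": "LittleKiss", "P": "LittleKiss",
    "Q": "Wild", "R": "Wild",
}


def paper_like_config(seed: int) -> SimulationConfig:
    """The default 17 x 8 x 148 scenario (see module docstring)."""
    pops = []
    for label, series in _SERIES.items():
        if label == "R":
            q = "source"
        elif label == "Q":
            q = _ISOLATE_BOTTLENECK
        else:
            q = _CULTIVAR_BOTTLENECK
        pops.append(PopulationSpec(label=label, n=8, q=q, taxon=series))
    return SimulationConfig(n_loci=148, populations=tuple(pops), seed=seed)


def paper_like_dataset(seed: int) -> SimulatedDataset:
    """Simulate the default 17-population, 136 x 148 scenario."""
    return simulate_dataset(paper_like_config(seed))
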