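"""Analysis of molecular variance (AMOVA) and Phi-statistics.

AMOVA partitions the total molecular variance carried by squared pairwise
distances into hierarchical strata.  For binary band data the mismatch
count between two individuals equals their squared Euclidean distance, so
the sums of squares are built directly from the mismatch matrix:

    SS_total  = (1/N)   * sum_{i<j}       d2_ij
    SS_within = sum_pop (1/N_p) * sum_{i<j in pop} d2_ij
    SS_among  = SS_total - SS_within

with df_among = k - 1, df_within = N - k, sigma2_within = MS_within and
sigma2_among = (MS_among - MS_within) / n0, n0 = (N - sum N_p^2 / N) / (k - 1).
PhiPT = sigma2_among / (sigma2_among + sigma2_within) measures the
proportion of molecular variance among populations; its significance comes
from random reassignment of individuals to populations preserving sizes,
with p = (#{Phi* >= Phi_obs} + 1) / (B + 1).

The three-level decomposition (among taxa / among populations within taxa
/ within populations) yields PhiRT, PhiPR and PhiPT with
permutation schemes per statistic: whole populations among taxa for
PhiRT, individuals among populations within their taxon for PhiPR, and
unrestricted individual reassignment for PhiPT.

Negative variance components are floored at zero before Phi and
percentage computation (raw values are retained for inspection), keeping
Phi in [0, 1].

The model-fitting surface follows the statsmodels convention:
``Amova(dist, layout).fit(n_permutations=999, seed=1)`` returns an
:class:`AmovaResults` carrying the strata table, the Phi estimates, their
permutation p-values and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, pairwise_distance
from .matrix import BandMatrix, PopulationLayout

__all__ = [
    "Amova",
    "AmovaResults",
    "PairwisePhiPT",
    "amova_one_level",
    "amova_hierarchical",
    "pairwise_phipt",
]


# ---------------------------------------------------------------------------
# sums-of-squares engine


def _check_layout(dist: DistanceMatrix, layout: PopulationLayout):
    if dist.n != layout.n_individuals:
        raise ValueError(
            f"distance matrix has {dist.n} individuals but layout declares "
            f"{layout.n_individuals}")
    if layout.n_populations < 2:
        raise ValueError("AMOVA needs at least two populations")
    if all(s == 1 for s in layout.sizes):
        raise ValueError("all-singleton layout: within-population df is zero")


def _group_indices(layout: PopulationLayout) -> list[np.ndarray]:
    """Index blocks per population, assuming individuals ordered by population."""
    out, start = [], 0
    for s in layout.sizes:
        out.append(np.arange(start, start + s))
        start += s
    return out


def _ss_within(dsq: np.ndarray, groups: list[np.ndarray]) -> float:
    ss = 0.0
    for g in groups:
        if len(g) > 1:
            ss += dsq[np.ix_(g, g)].sum() / (2.0 * len(g))
    return ss


def _one_level_components(dsq: np.ndarray, groups: list[np.ndarray]):
    """df/SS/MS/sigma2 for a one-level decomposition on squared distances."""
    n = dsq.shape[0]
    k = len(groups)
    sizes = np.array([len(g) for g in groups], dtype=float)
    ss_total = dsq.sum() / (2.0 * n)
    ss_within = _ss_within(dsq, groups)
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (n - (sizes ** 2).sum() / n) / df_among
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    return {
        "n": n, "k": k, "n0": n0,
        "ss_total": ss_total, "ss_among": ss_among, "ss_within": ss_within,
        "df_among": df_among, "df_within": df_within,
        "ms_among": ms_among, "ms_within": ms_within,
        "sigma_among": sigma_among, "sigma_within": sigma_within,
    }


def _phi_from_components(sigma_among: float, sigma_within: float) -> float:
    a = max(sigma_among, 0.0)
    w = max(sigma_within, 0.0)
    tot = a + w
    if not np.isfinite(tot) or tot <= 0.0:
        return np.nan
    return a / tot


def _raw_ratio(num: float, denom: float) -> float:
    """Unfloored component ratio used to rank permutations.

    Flooring negative components is right for reporting but would pile
    null permutation p-values at 1 (every tied-at-zero permutation counts
    as >= an observed 0).  Ranking on the raw ratio keeps the test
    calibrated; a non-positive denominator (strongly negative among-
    component) ranks below everything.
    """
    if not np.isfinite(denom) or denom <= 0.0:
        return -np.inf
    return num / denom


def _phipt_raw(dsq: np.ndarray, groups: list[np.ndarray]) -> float:
    c = _one_level_components(dsq, groups)
    return _raw_ratio(c["sigma_among"],
                      c["sigma_among"] + c["sigma_within"])


def _permute_groups(rng: np.random.Generator, n: int,
                    sizes) -> list[np.ndarray]:
    perm = rng.permutation(n)
    out, start = [], 0
    for s in sizes:
        out.append(perm[start:start + s])
        start += s
    return out


# ---------------------------------------------------------------------------
# results container


@dataclass
class AmovaResults:
    """Fitted AMOVA: strata table, Phi-statistics and permutation tests.

    Attributes
    ----------
    table
        One row per stratum (plus Total): df, SS, MS, variance component
        (floored), percentage of total variation.
    phi
        Phi-statistics by name (``PhiPT``; plus ``PhiRT``/``PhiPR`` for a
        hierarchical fit).  NaN marks an undefined statistic (zero total
        variance or a degenerate stratum) — never reported as 0.
    p_values
        Permutation p-value per Phi-statistic (NaN where undefined).
    raw_sigma2
        Unfloored variance components for inspection.
    """

    design: str
    table: pd.DataFrame
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int | None
    raw_sigma2: dict[str, float]
    n0: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"AMOVA ({self.design})",
                 "=" * 64,
                 self.table.to_string(float_format=lambda x: f"{x:.4f}"),
                 "-" * 64]
        for name, value in self.phi.items():
            p = self.p_values.get(name, np.nan)
            ptxt = "undefined" if np.isnan(p) else f"{p:.4g}"
            vtxt = "undefined" if np.isnan(value) else f"{value:.4f}"
            lines.append(f"{name} = {vtxt}   p(perm) = {ptxt}")
        lines.append(f"permutations = {self.n_permutations}, seed = {self.seed}")
        return "\n".join(lines)


def _strata_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows).set_index("source")
    floored = df["sigma2"].clip(lower=0.0)
    tot = floored.sum()
    df["sigma2"] = floored
    df["pct"] = 100.0 * floored / tot if tot > 0 else np.nan
    total = pd.DataFrame({
        "df": [df["df"].sum()],
        "SS": [df["SS"].sum()],
        "MS": [np.nan],
        "sigma2": [tot],
        "pct": [100.0 if tot > 0 else np.nan],
    }, index=pd.Index(["Total"], name="source"))
    return pd.concat([df, total])


# ---------------------------------------------------------------------------
# public fits


def amova_one_level(dist: DistanceMatrix, layout: PopulationLayout,
                    n_permutations: int = 999,
                    seed: int | None = None) -> AmovaResults:
    """One-level AMOVA (among / within populations) with a PhiPT test.

    Individuals in *dist* must be ordered population-by-population as in
    *layout* (the order produced by :meth:`BandMatrix.layout`).
    """
    _check_layout(dist, layout)
    dsq = dist.squared()
    groups = _group_indices(layout)
    c = _one_level_components(dsq, groups)
    phipt = _phi_from_components(c["sigma_among"], c["sigma_within"])

    rng = np.random.default_rng(seed)
    p = np.nan
    if np.isfinite(phipt) and n_permutations > 0:
        obs = _raw_ratio(c["sigma_among"],
                         c["sigma_among"] + c["sigma_within"])
        hits = 0
        for _ in range(n_permutations):
            stat = _phipt_raw(dsq, _permute_groups(rng, c["n"],
                                                   layout.sizes))
            if stat >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)

    rows = [
        {"source": "Among populations", "df": c["df_among"],
         "SS": c["ss_among"], "MS": c["ms_among"], "sigma2": c["sigma_among"]},
        {"source": "Within populations", "df": c["df_within"],
         "SS": c["ss_within"], "MS": c["ms_within"],
         "sigma2": c["sigma_within"]},
    ]
    return AmovaResults(
        design="one-level",
        table=_strata_table(rows),
        phi={"PhiPT": phipt},
        p_values={"PhiPT": p},
        n_permutations=n_permutations,
        seed=seed,
        raw_sigma2={"among": c["sigma_among"], "within": c["sigma_within"]},
        n0={"n0": c["n0"]},
    )


def _taxon_blocks(layout: PopulationLayout) -> dict[str, list[int]]:
    """Taxon -> list of population positions, in first-appearance order."""
    blocks: dict[str, list[int]] = {}
    for i, p in enumerate(layout.populations):
        blocks.setdefault(layout.taxa[p], []).append(i)
    return blocks


def _hier_components(dsq: np.ndarray, groups: list[np.ndarray],
                     taxon_of_pop: list[int], n_taxa: int):
    """Nested decomposition: among taxa / among pops within taxa / within pops."""
    n = dsq.shape[0]
    k = len(groups)
    sizes = np.array([len(g) for g in groups], dtype=float)
    taxon_groups = [np.concatenate([groups[i] for i in range(k)
                                    if taxon_of_pop[i] == t])
                    for t in range(n_taxa)]
    taxon_sizes = np.array([len(g) for g in taxon_groups], dtype=float)

    ss_total = dsq.sum() / (2.0 * n)
    ss_wp = _ss_within(dsq, groups)
    ss_wg = _ss_within(dsq, taxon_groups)
    ss_ap = ss_wg - ss_wp          # among pops within taxa
    ss_ag = ss_total - ss_wg       # among taxa

    df_ag = n_taxa - 1
    df_ap = k - n_taxa
    df_wp = n - k
    ms_wp = ss_wp / df_wp if df_wp > 0 else np.nan
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ss_ag / df_ag if df_ag > 0 else np.nan

    sum_np2_over_ng = sum(
        (sizes[[i for i in range(k) if taxon_of_pop[i] == t]] ** 2).sum()
        / taxon_sizes[t]
        for t in range(n_taxa))
    sum_np2_over_n = (sizes ** 2).sum() / n
    sum_ng2_over_n = (taxon_sizes ** 2).sum() / n

    n1 = (n - sum_np2_over_ng) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_np2_over_ng - sum_np2_over_n) / df_ag if df_ag > 0 else np.nan
    n3 = (n - sum_ng2_over_n) / df_ag if df_ag > 0 else np.nan

    sigma_w = ms_wp
    sigma_b = (ms_ap - ms_wp) / n1 if df_ap > 0 else 0.0
    sigma_a = ((ms_ag - ms_wp - n2 * sigma_b) / n3) if df_ag > 0 else 0.0
    return {
        "ss_total": ss_total, "ss_ag": ss_ag, "ss_ap": ss_ap, "ss_wp": ss_wp,
        "df_ag": df_ag, "df_ap": df_ap, "df_wp": df_wp,
        "ms_ag": ms_ag, "ms_ap": ms_ap, "ms_wp": ms_wp,
        "n1": n1, "n2": n2, "n3": n3,
        "sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_w": sigma_w,
    }


def _hier_phi(c: dict) -> dict[str, float]:
    a = max(c["sigma_a"], 0.0)
    b = max(c["sigma_b"], 0.0)
    w = max(c["sigma_w"], 0.0)
    tot = a + b + w
    phi = {"PhiRT": np.nan, "PhiPR": np.nan, "PhiPT": np.nan}
    if tot > 0 and np.isfinite(tot):
        if c["df_ag"] > 0:
            phi["PhiRT"] = a / tot
        if c["df_ap"] > 0 and (b + w) > 0:
            phi["PhiPR"] = b / (b + w)
        phi["PhiPT"] = (a + b) / tot
    return phi


def _hier_phi_raw(c: dict) -> dict[str, float]:
    a, b, w = c["sigma_a"], c["sigma_b"], c["sigma_w"]
    return {
        "PhiRT": _raw_ratio(a, a + b + w),
        "PhiPR": _raw_ratio(b, b + w),
        "PhiPT": _raw_ratio(a + b, a + b + w),
    }


def amova_hierarchical(dist: DistanceMatrix, layout: PopulationLayout,
                       n_permutations: int = 999,
                       seed: int | None = None) -> AmovaResults:
    """Three-level AMOVA with PhiRT / PhiPR / PhiPT permutation tests.

    Requires ``layout.taxa`` assigning every population to a taxon; with
    every population its own taxon the middle stratum carries 0 df and the
    decomposition collapses to the one-level partition; with a single
    taxon PhiRT is undefined and PhiPR equals the one-level PhiPT.
    """
    _check_layout(dist, layout)
    if layout.taxa is None:
        raise ValueError("hierarchical AMOVA needs layout.taxa")
    dsq = dist.squared()
    groups = _group_indices(layout)
    taxa_order: list[str] = []
    for p in layout.populations:
        t = layout.taxa[p]
        if t not in taxa_order:
            taxa_order.append(t)
    taxon_of_pop = [taxa_order.index(layout.taxa[p])
                    for p in layout.populations]
    n_taxa = len(taxa_order)

    c = _hier_components(dsq, groups, taxon_of_pop, n_taxa)
    phi = _hier_phi(c)

    rng = np.random.default_rng(seed)
    pvals = {k: np.nan for k in phi}
    k = len(groups)
    if n_permutations > 0:
        obs_raw = _hier_phi_raw(c)
        # PhiRT: permute whole populations among taxa (preserve taxon pop-counts)
        if np.isfinite(phi["PhiRT"]):
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(k)
                t_of = [0] * k
                pos = 0
                for t in range(n_taxa):
                    cnt = taxon_of_pop.count(t)
                    for i in perm[pos:pos + cnt]:
                        t_of[i] = t
                    pos += cnt
                stat = _hier_phi_raw(
                    _hier_components(dsq, groups, t_of, n_taxa))["PhiRT"]
                if stat >= obs_raw["PhiRT"] - 1e-12:
                    hits += 1
            pvals["PhiRT"] = (hits + 1) / (n_permutations + 1)
        # PhiPR: permute individuals among populations within each taxon
        if np.isfinite(phi["PhiPR"]):
            hits = 0
            for _ in range(n_permutations):
                new_groups = [None] * k
                for t in range(n_taxa):
                    members = [i for i in range(k) if taxon_of_pop[i] == t]
                    pool = np.concatenate([groups[i] for i in members])
                    pool = rng.permutation(pool)
                    start = 0
                    for i in members:
                        s = len(groups[i])
                        new_groups[i] = pool[start:start + s]
                        start += s
                stat = _hier_phi_raw(_hier_components(
                    dsq, new_groups, taxon_of_pop, n_taxa))["PhiPR"]
                if stat >= obs_raw["PhiPR"] - 1e-12:
                    hits += 1
            pvals["PhiPR"] = (hits + 1) / (n_permutations + 1)
        # PhiPT: unrestricted reassignment of individuals to populations
        if np.isfinite(phi["PhiPT"]):
            hits = 0
            for _ in range(n_permutations):
                new_groups = _permute_groups(rng, dsq.shape[0], layout.sizes)
                stat = _hier_phi_raw(_hier_components(
                    dsq, new_groups, taxon_of_pop, n_taxa))["PhiPT"]
                if stat >= obs_raw["PhiPT"] - 1e-12:
                    hits += 1
            pvals["PhiPT"] = (hits + 1) / (n_permutations + 1)

    rows = [
        {"source": "Among taxa", "df": c["df_ag"], "SS": c["ss_ag"],
         "MS": c["ms_ag"], "sigma2": c["sigma_a"]},
        {"source": "Among populations within taxa", "df": c["df_ap"],
         "SS": c["ss_ap"], "MS": c["ms_ap"], "sigma2": c["sigma_b"]},
        {"source": "Within populations", "df": c["df_wp"], "SS": c["ss_wp"],
         "MS": c["ms_wp"], "sigma2": c["sigma_w"]},
    ]
    return AmovaResults(
        design="hierarchical",
        table=_strata_table(rows),
        phi=phi,
        p_values=pvals,
        n_permutations=n_permutations,
        seed=seed,
        raw_sigma2={"among_taxa": c["sigma_a"],
                    "among_pops_within_taxa": c["sigma_b"],
                    "within": c["sigma_w"]},
        n0={"n1": c["n1"], "n2": c["n2"], "n3": c["n3"]},
    )


@dataclass
class PairwisePhiPT:
    """Pairwise population PhiPT matrix with permutation p-values."""

    populations: tuple[str, ...]
    phipt: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    seed: int | None

    def lower_triangle_csv(self) -> str:
        df = self.phipt.copy()
        mask = np.triu(np.ones(df.shape, dtype=bool), k=1)
        df = df.mask(mask)
        return df.to_csv(float_format="%.4f")


def pairwise_phipt(dist: DistanceMatrix, layout: PopulationLayout,
                   n_permutations: int = 999,
                   seed: int | None = None) -> PairwisePhiPT:
    """PhiPT of a one-level AMOVA restricted to each pair of populations.

    Negative components are floored, so a population against a copy of
    itself yields 0.  Each pair's permutation stream derives from *seed*
    and the pair index, keeping results independent of evaluation order.
    """
    _check_layout(dist, layout)
    pops = layout.populations
    kk = len(pops)
    groups = _group_indices(layout)
    phi = np.zeros((kk, kk))
    pv = np.full((kk, kk), np.nan)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(kk * kk)
    for a in range(kk):
        for b in range(a + 1, kk):
            idx = np.concatenate([groups[a], groups[b]])
            sub = dist.values[np.ix_(idx, idx)]
            sub_dist = DistanceMatrix(
                tuple(dist.labels[i] for i in idx), sub, dist.metric)
            sub_layout = PopulationLayout(
                (pops[a], pops[b]), (layout.sizes[a], layout.sizes[b]))
            res = amova_one_level(
                sub_dist, sub_layout, n_permutations=n_permutations,
                seed=children[a * kk + b] if seed is not None else None)
            val = res.phi["PhiPT"]
            phi[a, b] = phi[b, a] = 0.0 if np.isnan(val) else val
            pv[a, b] = pv[b, a] = res.p_values["PhiPT"]
    return PairwisePhiPT(
        populations=tuple(pops),
        phipt=pd.DataFrame(phi, index=pops, columns=pops),
        p_values=pd.DataFrame(pv, index=pops, columns=pops),
        n_permutations=n_permutations,
        seed=seed,
    )


class Amova:
    """Distance-based AMOVA model.

    Parameters
    ----------
    dist
        Pairwise :class:`DistanceMatrix` (mismatch-count metric: entries
        enter the sums of squares as squared distances).
    layout
        Population sizes in the order individuals appear in *dist*; when
        ``layout.taxa`` is set, :meth:`fit` performs the three-level
        decomposition.

    Examples
    --------
    >>> model = Amova.from_band_matrix(bm)            # doctest: +SKIP
    >>> res = model.fit(n_permutations=999, seed=1)   # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(self, dist: DistanceMatrix, layout: PopulationLayout):
        _check_layout(dist, layout)
        if dist.metric != "mismatch-count":
            raise ValueError(
                "AMOVA expects the mismatch-count metric (squared Euclidean "
                f"on 0/1 data); got {dist.metric!r}")
        self.dist = dist
        self.layout = layout

    @classmethod
    def from_band_matrix(cls, matrix: BandMatrix,
                         taxa: dict[str, str] | None = None) -> "Amova":
        """Build the model from a band matrix (rows regrouped by population)."""
        order = []
        for p in matrix.populations:
            order.extend(matrix.population_indices(p).tolist())
        labels = [matrix.accession_ids[i] for i in order]
        dist = pairwise_distance(matrix).select(labels)
        layout = matrix.layout()
        if taxa is not None:
            layout = PopulationLayout(layout.populations, layout.sizes, taxa)
        return cls(dist, layout)

    def fit(self, n_permutations: int = 999,
            seed: int | None = None) -> AmovaResults:
        if self.layout.taxa is not None and \
                len(set(self.layout.taxa.values())) >= 2:
            return amova_hierarchical(self.dist, self.layout,
                                      n_permutations, seed)
        return amova_one_level(self.dist, self.layout, n_permutations, seed)

    def fit_pairwise(self, n_permutations: int = 999,
                     seed: int | None = None) -> PairwisePhiPT:
        return pairwise_phipt(self.dist, self.layout, n_permutations, seed)
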