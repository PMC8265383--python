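"""End-to-end analysis orchestration and reference comparison.

:func:`run_full_analysis` runs every stage of the dominant-marker
pipeline on one band matrix — duplicate screening, private bands,
diversity tables, PIC, AMOVA (one-level and, given taxa, hierarchical),
pairwise PhiPT, PCoA, UPGMA, and optionally Evanno delta-K on a supplied
clustering-run table — and returns an :class:`AnalysisReport` whose every
number is reproducible from (input, config, seed).

:func:`compare_to_reference` checks a report's headline quantities
against a table of published values at stated tolerances; the packaged
``data/reference_values.csv`` carries one such table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import AmovaResults, PairwisePhiPT, amova_hierarchical, \
    amova_one_level, pairwise_phipt
from .diversity import diversity_table, pic_summary, PicSummary
from .distance import pairwise_distance, DistanceMatrix
from .matrix import BandMatrix, PopulationLayout, find_duplicates, \
    private_bands, PrivateBands
from .pcoa import PcoaResult, pcoa
from .upgma import UpgmaTree, upgma, total_branch_length, to_newick, \
    leaf_group_purity, GroupPurity
from .evanno import EvannoTable, evanno

__all__ = ["AnalysisReport", "run_full_analysis", "compare_to_reference",
           "reference_values_path"]


@dataclass
class AnalysisReport:
    """Bundle of every pipeline output plus run metadata."""

    diversity: pd.DataFrame
    pic: PicSummary
    duplicates: list[list[str]]
    private_any: PrivateBands
    private_fixed: PrivateBands
    amova: AmovaResults
    amova_hier: AmovaResults | None
    amova_subset: AmovaResults | None
    pairwise: PairwisePhiPT
    pcoa: PcoaResult
    pcoa_raw_distances: PcoaResult
    tree: UpgmaTree
    tree_newick: str
    tree_total_length: float
    purity: GroupPurity
    evanno: EvannoTable | None
    metadata: dict = field(default_factory=dict)

    def values(self) -> dict[str, float]:
        """Flatten the headline quantities for reference comparison."""
        out: dict[str, float] = {
            "n_loci": float(self.metadata["n_loci"]),
            "n_individuals": float(self.metadata["n_individuals"]),
            "n_populations": float(self.metadata["n_populations"]),
            "phipt": self.amova.phi["PhiPT"],
            "pct_among": float(
                self.amova.table.loc["Among populations", "pct"]),
            "pct_within": float(
                self.amova.table.loc["Within populations", "pct"]),
            "ms_within": float(
                self.amova.table.loc["Within populations", "MS"]),
            "sigma2_among": float(
                self.amova.table.loc["Among populations", "sigma2"]),
            "mean_pic": self.pic.mean_pic,
            "upgma_total_length": self.tree_total_length,
            "purity": self.purity.overall,
            "n_private_any": float(self.private_any.total),
            "n_private_fixed": float(self.private_fixed.total),
        }
        if self.pic.mean_of_primer_means is not None:
            out["mean_pic_primer_means"] = self.pic.mean_of_primer_means
        mean_row = self.diversity[self.diversity["population"] == "Mean"]
        for stat, name in (("shannon_i", "mean_I"), ("he", "mean_He"),
                           ("uhe", "mean_uHe"), ("na", "mean_Na"),
                           ("ne", "mean_Ne"),
                           ("pct_polymorphic", "mean_pctP")):
            out[name] = float(mean_row[stat].iloc[0])
        for _, row in self.diversity.iterrows():
            p = row["population"]
            if p == "Mean":
                continue
            out[f"he_{p}"] = float(row["he"])
            out[f"pctP_{p}"] = float(row["pct_polymorphic"])
        for i in range(min(3, self.pcoa.n_positive_axes)):
            out[f"pcoa_axis{i + 1}_pct"] = float(self.pcoa.axis_pct[i])
        n3 = min(3, self.pcoa.n_positive_axes)
        out["pcoa_first3_pct"] = float(self.pcoa.axis_pct[:n3].sum())
        pops = self.pairwise.populations
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                out[f"phipt_{a}_{b}"] = float(self.pairwise.phipt.loc[a, b])
        if self.amova_subset is not None:
            out["phipt_subset"] = self.amova_subset.phi["PhiPT"]
            out["pct_among_subset"] = float(
                self.amova_subset.table.loc["Among populations", "pct"])
            out["pct_within_subset"] = float(
                self.amova_subset.table.loc["Within populations", "pct"])
            out["ms_within_subset"] = float(
                self.amova_subset.table.loc["Within populations", "MS"])
        if self.amova_hier is not None:
            for name, v in self.amova_hier.phi.items():
                out[f"hier_{name}"] = v
        if self.evanno is not None and self.evanno.k_opt is not None:
            out["k_opt"] = float(self.evanno.k_opt)
        return out

    def to_files(self, out_dir) -> None:
        """Write the CSV/Markdown report bundle to *out_dir*."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.diversity.to_csv(out / "diversity.csv", index=False)
        self.pic.per_locus.to_csv(out / "pic_per_locus.csv")
        if self.pic.per_primer_mean is not None:
            self.pic.per_primer_mean.rename("mean_pic").to_csv(
                out / "pic_per_primer.csv")
        self.amova.table.to_csv(out / "amova.csv")
        if self.amova_hier is not None:
            self.amova_hier.table.to_csv(out / "amova_hierarchical.csv")
        if self.amova_subset is not None:
            self.amova_subset.table.to_csv(out / "amova_subset.csv")
        self.pairwise.phipt.to_csv(out / "pairwise_phipt.csv")
        self.pairwise.p_values.to_csv(out / "pairwise_phipt_pvalues.csv")
        self.pcoa.coordinates.to_csv(out / "pcoa_coordinates.csv")
        pd.DataFrame({
            "eigenvalue": self.pcoa.eigenvalues[:self.pcoa.n_positive_axes],
            "pct": self.pcoa.axis_pct,
        }).to_csv(out / "pcoa_axes.csv", index=False)
        (out / "tree.nwk").write_text(self.tree_newick + "\n")
        if self.evanno is not None:
            self.evanno.table.to_csv(out / "evanno.csv")
        (out / "report.md").write_text(self.to_markdown())
        pd.Series(self.values()).rename("value").to_csv(out / "values.csv")

    def to_markdown(self) -> str:
        md = [f"# bandpop analysis report (v{__version__})", ""]
        md.append("## Run metadata")
        for k, v in self.metadata.items():
            md.append(f"- {k}: {v}")
        md += ["", "## Duplicate accessions"]
        if self.duplicates:
            for g in self.duplicates:
                md.append(f"- {', '.join(g)}")
        else:
            md.append("- none")
        md += ["", "## Private bands",
               f"- exclusive presence (freq > 0): {self.private_any.total}",
               f"- exclusive and fixed in owner: {self.private_fixed.total}",
               "", "## Diversity", self.diversity.to_markdown(index=False),
               "", "## AMOVA", "```", self.amova.summary(), "```"]
        if self.amova_hier is not None:
            md += ["", "### Hierarchical", "```", self.amova_hier.summary(),
                   "```"]
        if self.amova_subset is not None:
            md += ["", "### Subset", "```", self.amova_subset.summary(),
                   "```"]
        md += ["", "## PCoA", "```", self.pcoa.summary(), "```",
               "(mismatch counts centred as squared distances; raw-distance "
               f"variant first-3-axis total: "
               f"{self.pcoa_raw_distances.axis_pct[:3].sum():.2f}%)",
               "", "## UPGMA",
               f"- total branch length: {self.tree_total_length:.4f}",
               f"- population purity at k={self.purity.k}: "
               f"{self.purity.overall:.3f}"]
        if self.evanno is not None:
            md += ["", "## Evanno delta-K", "```", self.evanno.summary(),
                   "```"]
        return "\n".join(md) + "\n"


def run_full_analysis(matrix: BandMatrix,
                      taxa: dict[str, str] | None = None,
                      runs: pd.DataFrame | None = None,
                      subset: list[str] | None = None,
                      n_permutations: int = 999,
                      seed: int = 0,
                      tree_metric: str = "p-distance",
                      out_dir=None) -> AnalysisReport:
    """Run the whole pipeline on *matrix*; deterministic given *seed*.

    Parameters
    ----------
    taxa
        Optional population -> taxon map enabling the hierarchical AMOVA
        (falls back to ``matrix.taxon_of``).
    runs
        Optional clustering-run log-likelihood table for Evanno delta-K.
    subset
        Optional population subset (e.g. the cultivated lines) given a
        second one-level AMOVA, reported alongside the full one.
    """
    layout = matrix.layout()
    taxa = taxa if taxa is not None else (
        layout.taxa if layout.taxa else None)
    # order individuals population-by-population for the AMOVA engines
    order = []
    for p in matrix.populations:
        order.extend(matrix.population_indices(p).tolist())
    labels = [matrix.accession_ids[i] for i in order]
    dist = pairwise_distance(matrix).select(labels)

    amova = amova_one_level(dist, layout, n_permutations, seed)
    amova_hier = None
    if taxa is not None and len(set(taxa.values())) >= 2:
        hl = PopulationLayout(layout.populations, layout.sizes, taxa)
        amova_hier = amova_hierarchical(dist, hl, n_permutations, seed)
    amova_subset = None
    if subset:
        sub = matrix.subset(subset)
        sub_order = []
        for p in sub.populations:
            sub_order.extend(sub.population_indices(p).tolist())
        sub_labels = [sub.accession_ids[i] for i in sub_order]
        amova_subset = amova_one_level(
            pairwise_distance(sub).select(sub_labels), sub.layout(),
            n_permutations, seed)
    pw = pairwise_phipt(dist, layout, n_permutations, seed)

    pc = pcoa(dist)
    pc_raw = pcoa(dist, treat_as_squared=False)

    tree_dist = pairwise_distance(matrix, metric=tree_metric)
    tree = upgma(tree_dist)
    newick = to_newick(tree)
    tbl = total_branch_length(tree)
    purity = leaf_group_purity(tree, matrix.pop_of,
                               k_clusters=layout.n_populations)

    ev = evanno(runs) if runs is not None else None

    report = AnalysisReport(
        diversity=diversity_table(matrix),
        pic=pic_summary(matrix),
        duplicates=find_duplicates(matrix),
        private_any=private_bands(matrix, definition="any"),
        private_fixed=private_bands(matrix, definition="fixed"),
        amova=amova,
        amova_hier=amova_hier,
        amova_subset=amova_subset,
        pairwise=pw,
        pcoa=pc,
        pcoa_raw_distances=pc_raw,
        tree=tree,
        tree_newick=newick,
        tree_total_length=tbl,
        purity=purity,
        evanno=ev,
        metadata={
            "bandpop_version": __version__,
            "n_individuals": matrix.n_individuals,
            "n_loci": matrix.n_loci,
            "n_populations": layout.n_populations,
            "n_permutations": n_permutations,
            "seed": seed,
            "amova_distance_metric": "mismatch-count (squared Euclidean)",
            "tree_distance_metric": tree_metric,
            "pcoa_convention": "mismatch counts centred as squared distances",
            "pic_averaging": "unweighted over loci "
                             "(mean of primer means also reported)",
            "subset": list(subset) if subset else None,
        },
    )
    if out_dir is not None:
        report.to_files(out_dir)
    return report


def reference_values_path() -> Path:
    """Path of the packaged published-value reference table."""
    return Path(importlib.resources.files("bandpop") / "data"
                / "reference_values.csv")


def compare_to_reference(values, reference=None) -> pd.DataFrame:
    """Compare computed *values* against a reference table.

    *values* is a mapping quantity -> number (e.g. from
    :meth:`AnalysisReport.values`); *reference* a CSV path or DataFrame
    with columns ``quantity, value, tolerance`` (defaults to the packaged
    table).  Returns a frame with signed deviations and pass/fail
    verdicts; quantities absent from *values* fail with verdict
    ``missing``.
    """
    if reference is None:
        reference = reference_values_path()
    if not isinstance(reference, pd.DataFrame):
        reference = pd.read_csv(reference)
    required = {"quantity", "value", "tolerance"}
    if not required.issubset(reference.columns):
        raise ValueError(f"reference table needs columns {sorted(required)}")
    rows = []
    for _, r in reference.iterrows():
        qid = str(r["quantity"])
        ref = float(r["value"])
        tol = float(r["tolerance"])
        if qid not in values:
            rows.append({"quantity": qid, "reference": ref, "computed":
                         np.nan, "deviation": np.nan, "tolerance": tol,
                         "verdict": "missing"})
            continue
        got = float(values[qid])
        dev = got - ref
        ok = np.isfinite(got) and abs(dev) <= tol
        rows.append({"quantity": qid, "reference": ref, "computed": got,
                     "deviation": dev, "tolerance": tol,
                     "verdict": "pass" if ok else "fail"})
    return pd.DataFrame(rows)
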