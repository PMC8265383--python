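"""Evanno delta-K selection of the number of genetic clusters.

Bayesian clustering programs report a log-likelihood lnP(D) per run for
each assumed cluster count K.  The delta-K method locates the strongest
break in this profile through the second-order rate of change:

    L'(K)  = mean L(K) - mean L(K-1)
    |L''(K)| = | L'(K+1) - L'(K) |
    dK     = |L''(K)| / sd L(K)

The maximiser of dK over interior K suggests the number of clusters.
dK is undefined at the smallest and largest K and wherever sd L(K) = 0;
undefined entries are reported as NaN, never coerced to 0 or infinity,
and are excluded from the argmax.

This module consumes (K, replicate, lnL) tables; it does not run or
reimplement the clustering itself.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EvannoTable", "evanno", "read_likelihood_table"]


@dataclass
class EvannoTable:
    """Per-K Evanno statistics and the selected K.

    ``table`` columns: n_reps, mean_lnL, sd_lnL, l_prime, l_second_abs,
    delta_k (indexed by K).  ``k_opt`` maximises delta_k over defined
    interior K; ties break toward the smaller K with ``k_opt_tied`` set.
    """

    table: pd.DataFrame
    k_opt: int | None
    k_opt_tied: bool

    def summary(self) -> str:
        lines = ["Evanno delta-K",
                 self.table.to_string(float_format=lambda x: f"{x:.4f}")]
        if self.k_opt is None:
            lines.append("k_opt: undefined (no interior K with finite delta-K)")
        else:
            tie = " (tied; smallest K reported)" if self.k_opt_tied else ""
            lines.append(f"k_opt = {self.k_opt}{tie}")
        return "\n".join(lines)


def _summarize(table: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower().strip(): c for c in table.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    kcol = col("k")
    if kcol is None:
        raise ValueError("likelihood table needs a 'K' column")
    if col("lnl", "lnp(d)", "lnpd", "ln_likelihood", "loglik") is not None:
        vcol = col("lnl", "lnp(d)", "lnpd", "ln_likelihood", "loglik")
        g = table.groupby(table[kcol].astype(int))[vcol]
        out = pd.DataFrame({
            "n_reps": g.size(),
            "mean_lnL": g.mean(),
            "sd_lnL": g.std(ddof=1),
        })
    elif col("mean") is not None and col("sd", "stdev") is not None:
        # harvester-style summary layout: one row per K with mean and sd
        out = pd.DataFrame({
            "n_reps": np.nan,
            "mean_lnL": table[col("mean")].astype(float).values,
            "sd_lnL": table[col("sd", "stdev")].astype(float).values,
        }, index=table[kcol].astype(int).values)
        if out.index.duplicated().any():
            raise ValueError("summary layout must have one row per K")
    else:
        raise ValueError(
            "likelihood table needs either a 'lnL' column (long form) or "
            "'mean'/'sd' columns (summary form)")
    out.index.name = "K"
    return out.sort_index()


def evanno(table: pd.DataFrame) -> EvannoTable:
    """Compute the Evanno table from a run table or per-K summary.

    *table* is long form (columns K, replicate, lnL) or summary form
    (columns K, mean, sd).  K values must be consecutive integers and at
    least three, and every interior K needs a finite sd (>= 2 replicates
    in long form).
    """
    s = _summarize(table)
    ks = s.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    if not np.array_equal(ks, np.arange(ks[0], ks[0] + len(ks))):
        missing = sorted(set(range(ks[0], ks[-1] + 1)) - set(ks))
        raise ValueError(f"K values must be consecutive; missing {missing}")
    interior = ks[1:-1]
    if s["n_reps"].notna().any():
        bad = [int(k) for k in interior if s.loc[k, "n_reps"] < 2]
        if bad:
            raise ValueError(
                f"interior K with a single replicate (sd undefined): {bad}")
    mean = s["mean_lnL"].to_numpy(dtype=float)
    sd = s["sd_lnL"].to_numpy(dtype=float)
    lprime = np.full(len(ks), np.nan)
    lprime[1:] = np.diff(mean)
    lsecond = np.full(len(ks), np.nan)
    lsecond[1:-1] = np.abs(lprime[2:] - lprime[1:-1])
    delta = np.full(len(ks), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = np.isfinite(lsecond) & np.isfinite(sd) & (sd > 0)
        delta[ok] = lsecond[ok] / sd[ok]
    s = s.assign(l_prime=lprime, l_second_abs=lsecond, delta_k=delta)
    finite = np.where(np.isfinite(delta))[0]
    if finite.size == 0:
        return EvannoTable(table=s, k_opt=None, k_opt_tied=False)
    best = delta[finite].max()
    winners = [int(ks[i]) for i in finite if delta[i] >= best - 1e-12]
    return EvannoTable(table=s, k_opt=min(winners),
                       k_opt_tied=len(winners) > 1)


def read_likelihood_table(path) -> pd.DataFrame:
    """Read a clustering-run log-likelihood CSV (long or summary layout)."""
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    delim = "\t" if "\t" in sample.splitlines()[0] else ","
    return pd.read_csv(path, sep=delim)
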