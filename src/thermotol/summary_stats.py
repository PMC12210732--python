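"""Pooled summaries and cross-method correlations of threshold parameters.

Works on a long-format parameter table: one row per (sample, parameter)
with the parameter name drawn from the closed set of thresholds the three
methods produce.  Summaries report n, mean, sample sd, median and
quartiles per group; correlations are pairwise-complete over values
measured on the same leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

#: Closed set of threshold parameter names.
PARAMETER_NAMES = ("T_c", "T_p", "T_pII", "T_init", "T_endo", "T_exo",
                   "LT_10", "LT_50")

#: Reading rule: |r| above this is considered informative.
INFORMATIVE_R = 0.5

_REQUIRED = ("sample_id", "species", "parameter", "value")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise DataError("parameter table is empty")
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise DataError(f"parameter table lacks columns {missing}")
    bad = set(table["parameter"]) - set(PARAMETER_NAMES)
    if bad:
        raise DataError(f"unknown parameter names: {sorted(bad)}")
    dup = table.duplicated(subset=["sample_id", "parameter"])
    if dup.any():
        pair = table.loc[dup, ["sample_id", "parameter"]].iloc[0]
        raise DataError(f"duplicate value for ({pair.sample_id}, {pair.parameter})")
    return table


def pool_parameters(table: pd.DataFrame, by: str = "all") -> pd.DataFrame:
    """Summary rows (parameter, group, n, mean, sd, median, q25, q75).

    ``by="all"`` pools every species together (one group, "all");
    ``by="species"`` groups per species.  Sample sd uses the n−1
    denominator and is NaN for n = 1 groups.
    """
    table = _validate(table)
    if by not in ("all", "species"):
        raise ValueError("by must be 'all' or 'species'")
    df = table.copy()
    df["group"] = "all" if by == "all" else df["species"]
    g = df.groupby(["parameter", "group"])["value"]
    out = g.agg(n="count", mean="mean", sd="std", median="median",
                q25=lambda v: v.quantile(0.25),
                q75=lambda v: v.quantile(0.75)).reset_index()
    out["n"] = out["n"].astype(int)
    return out.sort_values(["parameter", "group"]).reset_index(drop=True)


@dataclass
class CorrelationResult:
    """Correlation matrix plus pair sizes for one group of samples."""

    r: pd.DataFrame            # coefficient; NaN where n < min_n
    n: pd.DataFrame            # pairwise-complete sample size
    method: str
    min_n: int
    notes: list[str]

    @property
    def informative(self) -> pd.DataFrame:
        """Boolean mask of |r| > 0.5 (off-diagonal reading rule)."""
        mask = self.r.abs() > INFORMATIVE_R
        np.fill_diagonal(mask.values, False)
        return mask


def _pairwise_corr(wide: pd.DataFrame, method: str, min_n: int) -> CorrelationResult:
    params = list(wide.columns)
    k = len(params)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    notes = []
    for i in range(k):
        for j in range(i, k):
            pair = wide[[params[i], params[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if i == j:
                r[i, j] = 1.0 if len(pair) else np.nan
                continue
            if len(pair) < min_n:
                notes.append(f"{params[i]}~{params[j]}: only {len(pair)} "
                             f"complete pairs (< {min_n}), coefficient omitted")
                continue
            a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                notes.append(f"{params[i]}~{params[j]}: zero variance, "
                             "coefficient undefined")
                continue
            if method == "pearson":
                r[i, j] = r[j, i] = stats.pearsonr(a, b).statistic
            else:
                r[i, j] = r[j, i] = stats.spearmanr(a, b).statistic
    return CorrelationResult(
        r=pd.DataFrame(r, index=params, columns=params),
        n=pd.DataFrame(n, index=params, columns=params),
        method=method, min_n=min_n, notes=notes)


def correlate_parameters(table: pd.DataFrame, scope: str = "pooled",
                         method: str = "pearson", min_n: int = 3
                         ) -> CorrelationResult | dict[str, CorrelationResult]:
    """Correlations between threshold parameters paired on the same leaf.

    ``scope="pooled"`` returns one matrix over all samples;
    ``scope="within_species"`` one matrix per species.  ``method`` is
    ``"pearson"`` (default) or ``"spearman"``; pairs with fewer than
    ``min_n`` complete observations get NaN with a note.
    """
    table = _validate(table)
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if scope == "pooled":
        wide = table.pivot(index="sample_id", columns="parameter", values="value")
        return _pairwise_corr(wide, method, min_n)
    if scope == "within_species":
        out = {}
        for sp, sub in table.groupby("species"):
            wide = sub.pivot(index="sample_id", columns="parameter", values="value")
            out[sp] = _pairwise_corr(wide, method, min_n)
        return out
    raise ValueError("scope must be 'pooled' or 'within_species'")
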