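"""Archaeal community summaries for sewer biofilms.

Mature gravity-sewer biofilms host a small set of archaeal lineages —
hydrogenotrophic *Methanospirillum* and the uncultivated DHVEG-6 group
dominate — whose relative proportions shift strongly with wall-shear
stress.  This module loads taxa × condition relative-abundance tables
(percent), checks their internal consistency, and computes the summary
quantities used in the analysis: combined abundances of taxon subsets,
percent changes between conditions, and dominance rankings.

Values are stored exactly as supplied (no silent renormalization); columns
whose sum strays from 100% are flagged with a warning carrying the actual
sum.  The packaged reference table ships one such column deliberately: its
source prints a column summing to 105.00%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import LookupError_, NormalizationWarning, UndefinedChangeError

__all__ = [
    "AbundanceTable",
    "load_abundance",
    "packaged_archaea_table",
    "combined_abundance",
    "pct_change",
    "dominant_taxa",
]


@dataclass
class AbundanceTable:
    """Relative abundances (%) of taxa across experimental conditions.

    Wraps a DataFrame with taxon labels as the index and condition labels
    (e.g. ``"F=0.8 Pa"``) as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon labels: {dups}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("relative abundances must be >= 0")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def check_normalization(self, tol: float = 0.01) -> pd.Series:
        """Warn for every condition whose column sum is not 100% ± ``tol``.

        Returns the column sums so callers can inspect the actual values.
        """
        sums = self.column_sums()
        for cond, s in sums.items():
            if abs(s - 100.0) > tol:
                warnings.warn(
                    f"abundance column {cond!r} sums to {s:.2f}%, not 100% "
                    f"± {tol}",
                    NormalizationWarning,
                    stacklevel=2,
                )
        return sums

    def renormalized(self) -> "AbundanceTable":
        """A copy with every column rescaled to sum exactly to 100%."""
        return AbundanceTable(self.data / self.data.sum(axis=0) * 100.0)

    def _col(self, condition: str) -> pd.Series:
        if condition not in self.data.columns:
            raise LookupError_(f"unknown condition {condition!r}; "
                               f"have {list(self.data.columns)}")
        return self.data[condition]

    def _cell(self, taxon: str, condition: str) -> float:
        col = self._col(condition)
        if taxon not in col.index:
            raise LookupError_(f"unknown taxon {taxon!r}")
        return float(col.loc[taxon])


def load_abundance(path, check: bool = True, tol: float = 0.01) -> AbundanceTable:
    """Load a taxa × condition abundance table from TSV or CSV.

    The first column holds taxon labels; remaining columns are conditions
    with numeric percentage cells.  Column sums are checked against 100%
    (warnings, never errors) unless ``check=False``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"no abundance data found in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance cell in {path}: {exc}") from exc
    table = AbundanceTable(df)
    if check:
        table.check_normalization(tol=tol)
    return table


def packaged_archaea_table(check: bool = False) -> AbundanceTable:
    """The packaged archaeal reference table (three shear-stress conditions).

    Stored verbatim as published; note the F=2.0 Pa column sums to 105.00%
    (``check=True`` surfaces the warning).
    """
    ref = resources.files("sewerch4.data").joinpath("archaea_abundance.tsv")
    with resources.as_file(ref) as path:
        return load_abundance(path, check=check)


def combined_abundance(
    table: AbundanceTable, taxa_subset, condition: str
) -> float:
    """Summed relative abundance (%) of the named taxa in one condition."""
    taxa = list(taxa_subset)
    if not taxa:
        table._col(condition)  # still validate the condition label
        return 0.0
    return float(sum(table._cell(t, condition) for t in taxa))


def pct_change(
    table: AbundanceTable,
    taxon: str,
    cond_from: str,
    cond_to: str,
    mode: str = "relative",
) -> float:
    """Change of one taxon's abundance between two conditions.

    ``relative`` returns 100·(v_to − v_from)/v_from (percent of the
    baseline); ``absolute`` returns v_to − v_from (percentage points).
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    v_from = table._cell(taxon, cond_from)
    v_to = table._cell(taxon, cond_to)
    if mode == "absolute":
        return v_to - v_from
    if v_from == 0:
        raise UndefinedChangeError(
            f"relative change from zero abundance ({taxon!r} at {cond_from!r})"
        )
    return 100.0 * (v_to - v_from) / v_from


def dominant_taxa(
    table: AbundanceTable, condition: str, threshold: float = 10.0
) -> list[str]:
    """Taxa at or above ``threshold`` % in ``condition``, most abundant first."""
    col = table._col(condition)
    sel = col[col >= threshold].sort_values(ascending=False, kind="stable")
    return list(sel.index)
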