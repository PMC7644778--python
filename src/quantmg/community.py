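"""Family-level community tables: binning, abundance classes, ranks.

Genome-equivalent abundances estimated per taxon are binned to the family
level, placed into four volumetric abundance classes (dominant > 10^8,
abundant > 10^7, minor > 10^6, rare < 10^6 cells L^-1), expressed as percent
composition, reduced to the top-N families by total abundance, and — for
within-family population structure — reference bins are ranked per sample by
the reads they recruit.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ABUNDANCE_CLASSES",
    "DEFAULT_CLASS_THRESHOLDS",
    "bin_by_family",
    "classify_abundance",
    "relative_abundance",
    "top_n_families",
    "rank_recruitment",
]

logger = logging.getLogger(__name__)

ABUNDANCE_CLASSES = ("dominant", "abundant", "minor", "rare")

#: Cells L^-1 lower bounds (strict) for dominant, abundant, minor.
#: Values at or below 10^6 fall to "rare": the class bounds are written as
#: strict ">" so exact boundaries belong to the lower class.
DEFAULT_CLASS_THRESHOLDS = (1e8, 1e7, 1e6)

UNCLASSIFIED = "unclassified"


def bin_by_family(
    taxon_abundances: pd.DataFrame, mapping: pd.Series | dict
) -> pd.DataFrame:
    """Sum a taxa × samples abundance matrix to family × samples.

    Taxa missing from ``mapping`` go to an ``"unclassified"`` family (logged);
    column totals are preserved exactly.
    """
    mapping = pd.Series(mapping, dtype=object)
    families = taxon_abundances.index.map(mapping)
    n_unmapped = int(families.isna().sum())
    if n_unmapped:
        logger.info("%d taxa without a family mapped to %r", n_unmapped, UNCLASSIFIED)
    families = families.fillna(UNCLASSIFIED)
    out = taxon_abundances.groupby(families).sum()
    out.index.name = "family"
    return out


def classify_abundance(value, thresholds=DEFAULT_CLASS_THRESHOLDS):
    """Abundance class of a volumetric abundance (cells L^-1).

    Scalar in, scalar out; array-like in, object array out.
    """
    dom, abund, minor = thresholds
    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be >= 0")
    out = np.select(
        [arr > dom, arr > abund, arr > minor],
        ["dominant", "abundant", "minor"],
        default="rare",
    )
    if np.isscalar(value) or arr.ndim == 0:
        return str(out)
    return out


def relative_abundance(family_table: pd.DataFrame) -> pd.DataFrame:
    """Percent composition per sample; every column sums to 100.

    Samples with a zero total are returned as all-NaN columns with a warning.
    """
    totals = family_table.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"zero-total samples, composition undefined: "
            f"{list(family_table.columns[zero])}",
            stacklevel=2,
        )
    return family_table.div(totals.where(~zero), axis=1) * 100.0


def top_n_families(
    family_table: pd.DataFrame, n: int
) -> tuple[list, float]:
    """The n largest families by total abundance across samples, plus the
    fraction of the grand total they contain.

    Ties at rank n break lexicographically; asking for more families than
    exist returns them all with coverage 1.0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    totals = family_table.sum(axis=1)
    grand = totals.sum()
    order = totals.sort_values(ascending=False, kind="mergesort")
    # stable sort on -total then name implements the lexicographic tie rule
    order = totals.iloc[
        np.lexsort((totals.index.astype(str), -totals.to_numpy()))
    ]
    top = list(order.index[: min(n, len(order))])
    coverage = float(totals.loc[top].sum() / grand) if grand > 0 else 0.0
    return top, coverage


def rank_recruitment(read_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample competition ranks of reference bins by recruited reads.

    Rank 1 is the top-recruiting bin; tied counts share the minimum rank of
    the tied block.  Samples that are entirely missing (all-NaN columns, e.g.
    no metagenome collected) stay NaN.
    """
    if (read_counts.fillna(0) < 0).any().any():
        raise ValueError("read counts must be >= 0")
    out = pd.DataFrame(
        index=read_counts.index, columns=read_counts.columns, dtype=float
    )
    for col in read_counts.columns:
        vals = read_counts[col]
        if vals.isna().all():
            continue
        out[col] = rankdata(-vals.to_numpy(dtype=float), method="min")
    return out
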