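"""Count-table processing for amplicon community data.

Tables are pandas DataFrames with taxa as rows and samples as columns;
counts are nonnegative integers, relative-abundance tables are per-sample
fractions.  These operations cover the standard preprocessing chain for
co-occurrence network analysis: rarefaction to a common depth, Good's
coverage, relative abundance, taxonomic aggregation, and the
mean-abundance filter that defines the network's node set.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def _check_counts(table: pd.DataFrame) -> None:
    if (table.values < 0).any():
        raise ValueError("count table contains negative entries")
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise ValueError("taxon and sample identifiers must be unique")


def rarefy(table: pd.DataFrame, depth: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Draws are multivariate hypergeometric, i.e. true subsampling of the
    observed reads rather than multinomial resampling.  Samples whose total
    is below ``depth`` are dropped with a logged warning (scaling them up
    would break the integrality assumptions of downstream rank tests).

    Parameters
    ----------
    table : DataFrame
        Integer taxon x sample counts.
    depth : int
        Target reads per sample (the study design uses 20,000).
    seed : int or numpy Generator
        Source of randomness; a fixed seed gives bit-identical output.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    _check_counts(table)
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=0)
    kept = []
    out = {}
    for sample in table.columns:
        total = int(totals[sample])
        if total < depth:
            logger.warning(
                "sample %s dropped: total %d < rarefaction depth %d", sample, total, depth
            )
            continue
        counts = table[sample].to_numpy(dtype=np.int64)
        if total == depth:
            out[sample] = counts
        else:
            out[sample] = rng.multivariate_hypergeometric(counts, depth)
        kept.append(sample)
    result = pd.DataFrame(out, index=table.index, columns=kept, dtype=np.int64)
    return result


def goods_coverage(table: pd.DataFrame) -> pd.Series:
    """Good's coverage 1 - F1/N per sample (F1 = singleton taxa, N = reads)."""
    _check_counts(table)
    totals = table.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"empty sample(s): {empty}")
    singletons = (table == 1).sum(axis=0)
    return 1.0 - singletons / totals


def to_relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample fractions; each column sums to 1."""
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample(s): {empty}")
    return table / totals


def aggregate(table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum counts over taxa sharing a label at ``rank``.

    Taxa unclassified at that rank (missing or empty label) are pooled into
    an explicit ``unclassified`` bin rather than dropped, so per-sample
    totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    _check_counts(table)
    labels = taxonomy.reindex(table.index)[rank]
    labels = labels.where(labels.notna() & (labels.astype(str).str.strip() != ""), "unclassified")
    grouped = table.groupby(labels.values).sum()
    grouped.index.name = rank
    return grouped


def filter_mean_abundance(
    table: pd.DataFrame,
    groups: pd.Series,
    threshold: float = 0.01,
    rule: str = "union",
) -> pd.DataFrame:
    """Keep taxa whose mean relative abundance exceeds ``threshold``.

    ``rule`` controls how per-treatment-group means combine:

    - ``union`` (default): keep a taxon if its mean exceeds the threshold in
      at least one group.  This maximises comparability of node sets across
      treatments when networks are compared between fertilization regimes.
    - ``intersection``: the mean must exceed the threshold in every group.
    - ``global``: the overall mean across all samples must exceed it.

    ``table`` is expected to hold relative abundances; ``groups`` maps each
    sample to its treatment label.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    groups = pd.Series(groups).reindex(table.columns)
    if groups.isna().any():
        missing = list(table.columns[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    if rule == "global":
        keep = table.mean(axis=1) > threshold
    else:
        group_means = table.T.groupby(groups.values).mean().T
        if group_means.shape[1] == 0:
            raise ValueError("no treatment groups supplied")
        if rule == "union":
            keep = (group_means > threshold).any(axis=1)
        elif rule == "intersection":
            keep = (group_means > threshold).all(axis=1)
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return table.loc[keep]
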