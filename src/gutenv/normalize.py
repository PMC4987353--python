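"""Rarefaction and relative-abundance transforms.

Every downstream statistic consumes either a rarefied count table (presence
and prevalence logic) or per-sample proportions (abundance logic), so these
two transforms sit in front of the whole pipeline.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import AbundanceTable, CountTable, SampleFrame

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "relative_abundance", "group_mean_abundance"]


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained column is a draw from the multivariate hypergeometric
    distribution over that sample's reads, so the column sum is exactly
    ``depth``. Columns whose total is below ``depth`` are dropped (and
    logged); OTU rows that become all-zero are retained so that OTU ids stay
    aligned across stages.
    """
    if int(depth) != depth or depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    depth = int(depth)
    sums = table.column_sums()
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped)
    if not keep:
        raise ValueError(f"no samples retained at depth {depth}")
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = table.data[s].to_numpy()
        if sums[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(pd.DataFrame(out, index=table.otu_ids))


def relative_abundance(table: CountTable) -> AbundanceTable:
    """Divide each column by its sum; zero-sum samples are an error."""
    sums = table.column_sums()
    empty = list(sums.index[sums == 0])
    if empty:
        raise ValueError(f"sample {empty[0]!r} has zero total count")
    return AbundanceTable(table.data / sums)


def group_mean_abundance(
    ab: AbundanceTable,
    sample_ids: Iterable[str] | None = None,
    samples: SampleFrame | None = None,
    **selector: str,
) -> pd.Series:
    """Unweighted arithmetic mean of per-sample proportions over a group.

    The group is given either as an explicit ``sample_ids`` list or as a
    metadata selector (e.g. ``compartment="plant", site="3694"``) resolved
    against ``samples``. Means are taken over per-sample proportions — NOT
    over pooled counts — so every sample weighs equally regardless of depth.
    The result is again a point on the simplex (sums to 1).
    """
    if sample_ids is None:
        if samples is None:
            raise ValueError("provide sample_ids or a SampleFrame with a selector")
        sample_ids = samples.select(**selector)
    ids = list(sample_ids)
    if not ids:
        raise ValueError("group selects no samples")
    return ab.data[ids].mean(axis=1)
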