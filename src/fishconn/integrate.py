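"""Combine otolith-chemistry ordination and genetic admixture per fish.

Each marker is analysed on its own full dataset; integration is a plain
inner join on fish identity producing three coordinates per individual:
the two NMDS axes from otolith chemistry and the membership probability
for one genetic cluster of the K = 2 admixture solution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .admixture import QMatrix
from .otolith import OrdinationResult

logger = logging.getLogger("fishconn")


def combine_markers(
    ordination: OrdinationResult,
    fish_ids: np.ndarray,
    locations: np.ndarray,
    q: QMatrix,
    id_map: dict[str, str] | None = None,
    cluster: int = 0,
) -> pd.DataFrame:
    """Inner-join chemistry ordination with genetic memberships.

    ``id_map`` translates chemistry fish_ids to genotype individual_ids
    (identity by default). The genetic coordinate is the membership of
    ``cluster`` (0 or 1) in a K = 2 Q matrix; the two columns are
    complementary, so the choice only reflects the coordinate as 1 - q.
    Individuals present in a single marker dataset are dropped with a
    logged count; row order follows the chemistry dataset.
    """
    if q.K != 2:
        raise ValueError(
            "Q matrix must be a K = 2 solution; select a column with "
            "`cluster` after refitting at K = 2"
        )
    if cluster not in (0, 1):
        raise ValueError("cluster must be 0 or 1")
    fish_ids = np.asarray(fish_ids, dtype=object)
    mapped = np.array(
        [id_map.get(str(f), str(f)) if id_map else str(f) for f in fish_ids],
        dtype=object,
    )
    geno_index = {str(gid): i for i, gid in enumerate(q.individual_id)}
    rows = []
    dropped = 0
    for i, fid in enumerate(fish_ids):
        j = geno_index.get(str(mapped[i]))
        if j is None:
            dropped += 1
            continue
        rows.append(
            {
                "fish_id": str(fid),
                "location": str(locations[i]),
                "mds1": float(ordination.coords[i, 0]),
                "mds2": float(ordination.coords[i, 1]),
                "q_cluster1": float(q.q[j, cluster]),
            }
        )
    if not rows:
        raise ValueError("empty intersection between marker datasets")
    if dropped:
        logger.info("dropped %d individuals absent from the genotype data", dropped)
    return pd.DataFrame(rows)
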