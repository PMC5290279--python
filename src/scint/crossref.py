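"""Shared-enrichment comparison against reference interneuron subtypes.

Given the enriched gene set of one type from this pipeline and a
reference DE table (gene, Z-score, subtype family — e.g. Reln-like or
Vip-like grey-matter subtypes from a published atlas), compute the
percentage of the query set that also appears in the reference family's
enriched set, as the reference Z threshold is raised in increments of
0.1.  The query set stays fixed; only the reference set shrinks with the
threshold, so the curve is non-increasing.

Gene symbols are harmonized by uppercased exact match; query symbols
missing from the reference table's gene universe are reported, not
silently dropped (they count in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SharedEnrichmentCurve", "shared_enrichment_curve"]


@dataclass
class SharedEnrichmentCurve:
    table: pd.DataFrame  # columns: z, family, shared_percent, n_query, n_ref
    unmatched_query: list[str]  # query symbols absent from the reference universe


def shared_enrichment_curve(
    query: list[str] | set[str],
    ref: pd.DataFrame,
    family: str,
    z_start: float = 2.0,
    z_step: float = 0.1,
    z_max: float | None = None,
) -> SharedEnrichmentCurve:
    """Percentage of query genes shared with the reference family per Z cut.

    At each threshold z the reference enriched set is the family's genes
    with z_score >= z; shared_percent(z) = 100 * |query ∩ ref(z)| / |query|.
    ``z_max`` defaults to the family's maximum Z (the curve is constant
    beyond it).
    """
    query_list = list(dict.fromkeys(query))
    if not query_list:
        raise ValueError("query gene set must be nonempty")
    fam = ref[ref["family"] == family]
    if fam.empty:
        raise ValueError(f"no reference rows for family '{family}'")
    if fam["gene"].str.upper().duplicated().any():
        raise ValueError(f"reference table has duplicate genes within family '{family}'")

    q_upper = [g.upper() for g in query_list]
    ref_genes = fam["gene"].str.upper().to_numpy()
    ref_z = fam["z_score"].to_numpy(dtype=float)
    universe = set(ref_genes)
    unmatched = [g for g, gu in zip(query_list, q_upper) if gu not in universe]

    if z_max is None:
        z_max = float(ref_z.max())
    n_steps = max(int(np.floor((z_max - z_start) / z_step + 1e-9)) + 1, 1)
    zs = z_start + z_step * np.arange(n_steps)

    q_set = set(q_upper)
    rows = []
    for z in zs:
        enriched = ref_genes[ref_z >= z]
        shared = q_set.intersection(enriched)
        rows.append(
            {
                "z": float(z),
                "family": family,
                "shared_percent": 100.0 * len(shared) / len(q_set),
                "n_query": len(q_set),
                "n_ref": int(enriched.size),
            }
        )
    return SharedEnrichmentCurve(table=pd.DataFrame(rows), unmatched_query=unmatched)
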