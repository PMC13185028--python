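"""Time-course essentiality classification (TDE / TDGI).

Dropout screens sampled at two time points against a common baseline allow a
stronger statement than a single-endpoint hit: a gene whose knockout is
significantly depleted at both time points, with depletion deepening (log2FC
non-increasing) from the earlier to the later point, behaves as a
time-dependent essential (TDE) gene. Symmetrically, significant enrichment at
both points with non-decreasing log2FC marks time-dependent growth inhibition
(TDGI) — the knockout confers a growing relative advantage, so the intact gene
inhibited growth. Monotonicity is non-strict: ties count as consistent.
"""

from __future__ import annotations

import math

import pandas as pd

from .calling import Direction, GeneCallSet
from .library import ValidationError


TDE = "TDE"
TDGI = "TDGI"
NONE = "NONE"


def classify_gene(
    direction_t1: Direction | str,
    direction_t2: Direction | str,
    lfc_t1: float,
    lfc_t2: float,
) -> str:
    """Classify a single gene from its two time-point calls.

    TDE: depleted at both time points and lfc_t2 <= lfc_t1.
    TDGI: enriched at both time points and lfc_t2 >= lfc_t1.
    Anything else (including DISCORDANT calls) is NONE.
    """
    d1, d2 = Direction(direction_t1), Direction(direction_t2)
    if d1 is Direction.DEPLETED and d2 is Direction.DEPLETED:
        if not (math.isnan(lfc_t1) or math.isnan(lfc_t2)) and lfc_t2 <= lfc_t1:
            return TDE
    if d1 is Direction.ENRICHED and d2 is Direction.ENRICHED:
        if not (math.isnan(lfc_t1) or math.isnan(lfc_t2)) and lfc_t2 >= lfc_t1:
            return TDGI
    return NONE


def classify_timecourse(calls_t1: GeneCallSet, calls_t2: GeneCallSet) -> pd.DataFrame:
    """Classify every gene from two same-baseline time-point call sets.

    ``calls_t1`` must be the chronologically earlier comparison. Returns a
    DataFrame with gene, cls, lfc_t1, lfc_t2, called_t1, called_t2; the
    gene-level log2FC is the representative (max-|log2fc| supporting guide)
    value from aggregation.
    """
    a = calls_t1.calls.set_index("gene")
    b = calls_t2.calls.set_index("gene")
    if set(a.index) != set(b.index):
        raise ValidationError("gene universes differ between the two time points")
    rows = []
    for gene in a.index:
        d1, d2 = a.at[gene, "direction"], b.at[gene, "direction"]
        l1 = float(a.at[gene, "gene_log2fc"])
        l2 = float(b.at[gene, "gene_log2fc"])
        rows.append(
            {
                "gene": gene,
                "cls": classify_gene(d1, d2, l1, l2),
                "lfc_t1": l1,
                "lfc_t2": l2,
                "called_t1": d1,
                "called_t2": d2,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["t1"] = calls_t1.comparison_id
    out.attrs["t2"] = calls_t2.comparison_id
    return out


def summarize_timecourse(classifications: pd.DataFrame) -> dict:
    """Counts of TDE and TDGI genes."""
    if len(classifications) == 0:
        return {"n_TDE": 0, "n_TDGI": 0}
    counts = classifications["cls"].value_counts()
    return {"n_TDE": int(counts.get(TDE, 0)), "n_TDGI": int(counts.get(TDGI, 0))}


__all__ = ["TDE", "TDGI", "NONE", "classify_gene", "classify_timecourse", "summarize_timecourse"]
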