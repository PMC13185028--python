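"""Hit calling: guide-level conjunction rule and two-guide gene aggregation.

A guide is significantly depleted (enriched) only when BOTH conditions hold,
with strict inequalities: FDR < fdr_max AND log2FC below the lower (above the
upper) empirical safe-harbor cutoff. A gene is called when at least one of its
two guides is called; a gene whose two guides are called in opposite
directions is reported DISCORDANT and excluded from downstream counts rather
than silently resolved. Safe-harbor guides never produce gene calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .empirical_null import EmpiricalCutoffs
from .library import GuideLibrary, SAFE_HARBOR_GENE, ValidationError


class GuideStatus(str, Enum):
    DEPLETED = "DEPLETED"
    ENRICHED = "ENRICHED"
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
    UNTESTED = "UNTESTED"


class Direction(str, Enum):
    DEPLETED = "DEPLETED"
    ENRICHED = "ENRICHED"
    DISCORDANT = "DISCORDANT"
    NONE = "NONE"


class ScreenType(str, Enum):
    TIMECOURSE = "TIMECOURSE"
    CHEMICAL = "CHEMICAL"


#: Phenotype vocabulary: in a chemical screen, depletion of a knockout means
#: the gene product protected against the toxicant (knockout is sensitive);
#: in a time-course screen it means the gene is needed for growth.
PHENOTYPE_LABELS = {
    (ScreenType.CHEMICAL, Direction.DEPLETED): "sensitive",
    (ScreenType.CHEMICAL, Direction.ENRICHED): "resistant",
    (ScreenType.TIMECOURSE, Direction.DEPLETED): "growth-disadvantage",
    (ScreenType.TIMECOURSE, Direction.ENRICHED): "growth-advantage",
}


@dataclass
class GeneCallSet:
    """Gene-level calls for one comparison, with the thresholds that made them."""

    comparison_id: str
    screen_type: ScreenType
    calls: pd.DataFrame  # gene, direction, phenotype_label, gene_log2fc, supporting_guides
    cutoffs: EmpiricalCutoffs
    fdr_max: float

    @property
    def called(self) -> pd.DataFrame:
        """Genes with a definite direction (DEPLETED or ENRICHED)."""
        return self.calls[
            self.calls["direction"].isin([Direction.DEPLETED.value, Direction.ENRICHED.value])
        ]

    def genes_with_direction(self, direction: Direction | str) -> set[str]:
        d = Direction(direction).value
        return set(self.calls.loc[self.calls["direction"] == d, "gene"])

    def summary(self) -> dict:
        c = self.calls["direction"].value_counts()
        return {
            "comparison_id": self.comparison_id,
            "screen_type": self.screen_type.value,
            "n_depleted": int(c.get(Direction.DEPLETED.value, 0)),
            "n_enriched": int(c.get(Direction.ENRICHED.value, 0)),
            "n_discordant": int(c.get(Direction.DISCORDANT.value, 0)),
            "fdr_max": self.fdr_max,
            "cutoff_lower": self.cutoffs.lower,
            "cutoff_upper": self.cutoffs.upper,
            "n_controls": self.cutoffs.n_controls,
        }


def call_sgrnas(
    diffsel: pd.DataFrame, cutoffs: EmpiricalCutoffs, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Apply the conjunction rule per guide; returns guide_id, status, log2fc, fdr."""
    lfc = diffsel["log2fc"].to_numpy(dtype=float)
    fdr = diffsel["fdr"].to_numpy(dtype=float)
    tested = diffsel["tested"].to_numpy(dtype=bool) & np.isfinite(fdr)

    status = np.full(len(diffsel), GuideStatus.NOT_SIGNIFICANT.value, dtype=object)
    status[~tested] = GuideStatus.UNTESTED.value
    sig = tested & (fdr < fdr_max)
    status[sig & (lfc < cutoffs.lower)] = GuideStatus.DEPLETED.value
    status[sig & (lfc > cutoffs.upper)] = GuideStatus.ENRICHED.value

    out = diffsel[["guide_id"]].copy()
    if "gene" in diffsel.columns:
        out["gene"] = diffsel["gene"]
    out["status"] = status
    out["log2fc"] = lfc
    out["fdr"] = fdr
    out.attrs.update(diffsel.attrs)
    return out


def aggregate_genes(
    sgrna_calls: pd.DataFrame,
    library: GuideLibrary,
    screen_type: ScreenType | str,
    cutoffs: EmpiricalCutoffs | None = None,
    fdr_max: float = 0.05,
) -> GeneCallSet:
    """Aggregate guide calls to gene calls by the at-least-one-guide rule.

    Every non-control library gene appears in the result; genes with no
    significant guide have direction NONE. gene_log2fc is the log2FC of the
    supporting guide with the largest |log2fc| (for NONE genes, the most
    extreme tested guide, as a convenience for ranking).
    """
    screen_type = ScreenType(screen_type)
    by_guide = sgrna_calls.set_index("guide_id")
    lib_guides = set(library.guide_ids)
    unknown = set(by_guide.index) - lib_guides
    if unknown:
        raise ValidationError(f"calls contain guides absent from library: {sorted(unknown)[:10]}")

    gene_to_guides: dict[str, list[str]] = {}
    for r in library.records:
        if not r.is_safe_harbor:
            gene_to_guides.setdefault(r.gene, []).append(r.guide_id)

    rows = []
    for gene, guides in gene_to_guides.items():
        present = [g for g in guides if g in by_guide.index]
        statuses = {g: by_guide.at[g, "status"] for g in present}
        dep = [g for g in present if statuses[g] == GuideStatus.DEPLETED.value]
        enr = [g for g in present if statuses[g] == GuideStatus.ENRICHED.value]
        if dep and enr:
            direction = Direction.DISCORDANT
            supporting = dep + enr
        elif dep:
            direction = Direction.DEPLETED
            supporting = dep
        elif enr:
            direction = Direction.ENRICHED
            supporting = enr
        else:
            direction = Direction.NONE
            supporting = []

        pool = supporting or [
            g for g in present if np.isfinite(by_guide.at[g, "log2fc"])
        ]
        if pool:
            lfcs = {g: float(by_guide.at[g, "log2fc"]) for g in pool}
            rep = max(lfcs, key=lambda g: abs(lfcs[g]))
            gene_lfc = lfcs[rep]
        else:
            gene_lfc = np.nan
        label = PHENOTYPE_LABELS.get((screen_type, direction), "")
        if direction is Direction.DISCORDANT:
            label = "discordant"
        rows.append(
            {
                "gene": gene,
                "direction": direction.value,
                "phenotype_label": label,
                "gene_log2fc": gene_lfc,
                "supporting_guides": ",".join(supporting),
                "n_supporting": len(supporting),
            }
        )

    calls = pd.DataFrame(rows)
    assert SAFE_HARBOR_GENE not in set(calls["gene"])
    if cutoffs is None:
        cutoffs = EmpiricalCutoffs(
            lower=-np.inf, upper=np.inf, central_mass=1.0, n_controls=0
        )
    return GeneCallSet(
        comparison_id=sgrna_calls.attrs.get("comparison_id", ""),
        screen_type=screen_type,
        calls=calls,
        cutoffs=cutoffs,
        fdr_max=fdr_max,
    )


def call_genes(
    diffsel: pd.DataFrame,
    library: GuideLibrary,
    screen_type: ScreenType | str,
    central_mass: float = 0.95,
    fdr_max: float = 0.05,
) -> GeneCallSet:
    """Convenience: empirical cutoffs -> guide calls -> gene calls."""
    from .empirical_null import empirical_cutoffs

    cutoffs = empirical_cutoffs(diffsel, library, central_mass=central_mass)
    guide_calls = call_sgrnas(diffsel, cutoffs, fdr_max=fdr_max)
    return aggregate_genes(guide_calls, library, screen_type, cutoffs=cutoffs, fdr_max=fdr_max)


def compare_screens(set_a: GeneCallSet, set_b: GeneCallSet) -> dict:
    """Genes called in both screens, by direction.

    Both call sets must cover the same gene universe (same library).
    """
    genes_a = set(set_a.calls["gene"])
    genes_b = set(set_b.calls["gene"])
    if genes_a != genes_b:
        raise ValidationError(
            "gene universes differ between call sets: "
            f"{sorted(genes_a ^ genes_b)[:10]} ..."
        )
    common_depleted = sorted(
        set_a.genes_with_direction(Direction.DEPLETED)
        & set_b.genes_with_direction(Direction.DEPLETED)
    )
    common_enriched = sorted(
        set_a.genes_with_direction(Direction.ENRICHED)
        & set_b.genes_with_direction(Direction.ENRICHED)
    )
    called_a = set(set_a.called["gene"])
    called_b = set(set_b.called["gene"])
    common_any = sorted(called_a & called_b)
    return {
        "comparison_a": set_a.comparison_id,
        "comparison_b": set_b.comparison_id,
        "common_depleted": common_depleted,
        "common_enriched": common_enriched,
        "common_any_direction": common_any,
        "n_common_depleted": len(common_depleted),
        "n_common_enriched": len(common_enriched),
        "n_common_any_direction": len(common_any),
    }


__all__ = [
    "GuideStatus",
    "Direction",
    "ScreenType",
    "PHENOTYPE_LABELS",
    "GeneCallSet",
    "call_sgrnas",
    "aggregate_genes",
    "call_genes",
    "compare_screens",
]
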