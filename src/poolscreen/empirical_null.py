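"""Empirical effect-size cutoffs from the safe-harbor log2FC null distribution.

Safe-harbor guides target phenotypically neutral loci, so their log2 fold
changes in any comparison sample the technical null of the screen. Rather than
a fixed fold-change threshold, each comparison gets data-driven cutoffs: the
2.5% and 97.5% quantiles (for the default 95% central mass) of the tested
safe-harbor log2FC values. Quantiles use linear interpolation between order
statistics (type 7, numpy's default), fixed so cutoffs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import N_CTRL_MIN, GuideLibrary, SAFE_HARBOR_GENE


class EmpiricalNullError(ValueError):
    """Raised when the safe-harbor null cannot be formed."""


@dataclass(frozen=True)
class EmpiricalCutoffs:
    """Lower/upper log2FC thresholds for one comparison's empirical null."""

    lower: float
    upper: float
    central_mass: float
    n_controls: int
    comparison_id: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise EmpiricalNullError(
                f"lower cutoff {self.lower} exceeds upper cutoff {self.upper}"
            )


def _control_log2fc(diffsel: pd.DataFrame, library: GuideLibrary) -> np.ndarray:
    ctrl = set(library.safe_harbor_ids)
    sub = diffsel[diffsel["guide_id"].isin(ctrl) & diffsel["tested"]]
    return sub["log2fc"].to_numpy(dtype=float)


def empirical_cutoffs(
    diffsel: pd.DataFrame,
    library: GuideLibrary,
    central_mass: float = 0.95,
    n_ctrl_min: int = N_CTRL_MIN,
) -> EmpiricalCutoffs:
    """Quantile cutoffs of the tested safe-harbor log2FC values.

    lower = quantile((1 - central_mass)/2), upper = quantile(1 - (1 - central_mass)/2),
    computed per comparison (never reused across comparisons).
    """
    if not 0 < central_mass < 1:
        raise EmpiricalNullError(f"central_mass must be in (0, 1), got {central_mass}")
    vals = _control_log2fc(diffsel, library)
    if vals.size < n_ctrl_min:
        raise EmpiricalNullError(
            f"only {vals.size} tested safe-harbor guides in this comparison; "
            f">= {n_ctrl_min} are required for the empirical null"
        )
    tail = (1.0 - central_mass) / 2.0
    lower, upper = np.quantile(vals, [tail, 1.0 - tail])  # linear interpolation (type 7)
    return EmpiricalCutoffs(
        lower=float(lower),
        upper=float(upper),
        central_mass=central_mass,
        n_controls=int(vals.size),
        comparison_id=diffsel.attrs.get("comparison_id", ""),
    )


def null_coverage(
    diffsel: pd.DataFrame, library: GuideLibrary, cutoffs: EmpiricalCutoffs
) -> float:
    """Fraction of tested safe-harbor log2FC values inside [lower, upper].

    By construction this is at least central_mass - 2/n_controls; a markedly
    lower value indicates the cutoffs and table come from different comparisons.
    """
    vals = _control_log2fc(diffsel, library)
    if vals.size == 0:
        raise EmpiricalNullError("no tested safe-harbor guides in this table")
    inside = (vals >= cutoffs.lower) & (vals <= cutoffs.upper)
    return float(inside.mean())


__all__ = [
    "SAFE_HARBOR_GENE",
    "EmpiricalNullError",
    "EmpiricalCutoffs",
    "empirical_cutoffs",
    "null_coverage",
]
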