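"""Gene-set overlap statistics and end-to-end pipeline orchestration.

The overlap test asks whether two gene sets drawn from a common universe share
more members than chance expects — e.g. hits from two screen arms, or screen
hits versus an externally curated phenotype gene list supplied as plain text.
The universe defaults to the library's gene set: a screen can only ever call
library genes, and a genome-wide universe would inflate significance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from . import __version__
from .calling import ScreenType, call_genes, compare_screens
from .diffsel import differential_selection
from .empirical_null import null_coverage
from .library import (
    GuideLibrary,
    ValidationError,
    read_counts,
    read_library,
    read_sample_sheet,
    write_counts,
    write_library,
    write_sample_sheet,
)
from .simulate import SimConfig, make_library, simulate_screen
from .timecourse import classify_timecourse, summarize_timecourse

logger = logging.getLogger("poolscreen")


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    p_hypergeometric: float
    overlap_genes: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_set_a": self.n_set_a,
            "n_set_b": self.n_set_b,
            "n_overlap": self.n_overlap,
            "p_hypergeometric": self.p_hypergeometric,
            "overlap_genes": list(self.overlap_genes),
        }


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """One-sided (enrichment) hypergeometric overlap test.

    p = P(X >= |A ∩ B|) for X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|).
    Both sets must be subsets of the universe.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    offenders = sorted((set_a | set_b) - universe)
    if offenders:
        raise ValidationError(
            f"sets contain genes outside the universe: {offenders[:10]}"
            f"{'...' if len(offenders) > 10 else ''}"
        )
    overlap = sorted(set_a & set_b)
    k = len(overlap)
    p = float(hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return OverlapResult(
        n_universe=len(universe),
        n_set_a=len(set_a),
        n_set_b=len(set_b),
        n_overlap=k,
        p_hypergeometric=min(p, 1.0),
        overlap_genes=tuple(overlap),
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run counts -> differential selection -> cutoffs -> calls -> summaries.

    ``config`` keys:
      seed (int, required when simulating),
      simulate: SimConfig field overrides, OR
      inputs: {library, counts, samples} file paths;
      comparisons: list of {name, group_a, group_b, screen_type};
      timecourse_pairs: list of {t1, t2} referencing comparison names;
      fdr_max (default 0.05), central_mass (default 0.95).

    Writes one diffsel and one gene-call TSV per comparison, a timecourse TSV
    per pair, and a JSON run report with a checksum manifest. Deterministic
    given (inputs, config, seed). Returns the run report.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fdr_max = float(config.get("fdr_max", 0.05))
    central_mass = float(config.get("central_mass", 0.95))
    report: dict = {
        "poolscreen_version": __version__,
        "parameters": {"fdr_max": fdr_max, "central_mass": central_mass},
        "comparisons": {},
        "timecourse": {},
        "files": {},
    }

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", config.get("seed"))
        if "replicate_design" in sim_kwargs:
            sim_kwargs["replicate_design"] = tuple(sim_kwargs["replicate_design"])
        if "group_labels" in sim_kwargs:
            sim_kwargs["group_labels"] = tuple(sim_kwargs["group_labels"])
        sim_config = SimConfig(**sim_kwargs)
        logger.info("simulating screen (seed=%s)", sim_config.seed)
        matrix, truth = simulate_screen(sim_config)
        library = make_library(
            sim_config.n_genes,
            sim_config.n_safe_harbors,
            sim_config.spacer_length,
            seed=sim_config.seed,
        )
        write_library(library, outdir / "library.csv")
        write_sample_sheet(matrix.samples, outdir / "samples.csv")
        write_counts(matrix, outdir / "counts.tsv")
        truth.gene_effects.to_csv(outdir / "truth_genes.tsv", sep="\t")
        report["parameters"]["seed"] = sim_config.seed
    elif "inputs" in config:
        inputs = config["inputs"]
        library = read_library(inputs["library"])
        samples = read_sample_sheet(inputs["samples"])
        matrix = read_counts(inputs["counts"], library, samples)
    else:
        raise ValidationError("config needs either a 'simulate' or an 'inputs' section")

    call_sets: dict[str, object] = {}
    for comp in config.get("comparisons", []):
        name = comp["name"]
        screen_type = ScreenType(comp.get("screen_type", "TIMECOURSE").upper())
        logger.info("comparison %s: %s vs %s", name, comp["group_b"], comp["group_a"])
        table = differential_selection(matrix, library, comp["group_a"], comp["group_b"])
        table.to_csv(outdir / f"diffsel_{name}.tsv", sep="\t", index=False)
        calls = call_genes(
            table, library, screen_type, central_mass=central_mass, fdr_max=fdr_max
        )
        calls.calls.to_csv(outdir / f"calls_{name}.tsv", sep="\t", index=False)
        call_sets[name] = calls
        summary = calls.summary()
        summary["null_coverage"] = null_coverage(table, library, calls.cutoffs)
        report["comparisons"][name] = summary
        logger.info(
            "  %d depleted, %d enriched (cutoffs %.3f / %.3f)",
            summary["n_depleted"],
            summary["n_enriched"],
            summary["cutoff_lower"],
            summary["cutoff_upper"],
        )

    for pair in config.get("timecourse_pairs", []):
        t1, t2 = pair["t1"], pair["t2"]
        if t1 not in call_sets or t2 not in call_sets:
            raise ValidationError(f"timecourse pair references unknown comparison: {pair}")
        cls = classify_timecourse(call_sets[t1], call_sets[t2])
        name = f"{t1}__{t2}"
        cls.to_csv(outdir / f"timecourse_{name}.tsv", sep="\t", index=False)
        report["timecourse"][name] = summarize_timecourse(cls)

    if len(config.get("compare", [])) == 2:
        a, b = config["compare"]
        report["screen_overlap"] = compare_screens(call_sets[a], call_sets[b])

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "run_report.json":
            report["files"][f.name] = _sha256(f)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


__all__ = ["OverlapResult", "overlap_test", "run_pipeline"]
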