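"""Synthetic pooled-screen generator with ground truth.

The generator reproduces the count-generating structure the analysis assumes,
at the study's design scale: ~1551 genes covered by one guide in each of two
library sets, a safe-harbor control set, a founder pool bottlenecked at a
target per-guide cell coverage (500X by default), and unbalanced replicate
groups (3 baseline vs 2 late samples by default). Selection acts once,
multiplicatively on founder abundances, so a gene's true effect is directly a
log2 fold change; sequencing is a Poisson depth draw with gamma-Poisson
(negative binomial) count noise per guide. Everything is deterministic given
the seed; there is no implicit randomness.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import (
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    SAFE_HARBOR_GENE,
    SampleInfo,
)


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of a simulated screen; the defaults are the study design.

    n_genes: number of targeted genes (two guides each: SET1 + SET2).
    n_safe_harbors: number of neutral control guides.
    coverage: cells per guide at the founder bottleneck (500X).
    sequencing_depth: expected reads per sample (Poisson).
    baseline_sdlog: log-normal spread of pre-bottleneck guide abundances.
    dispersion: NB dispersion alpha of the sequencing counts (0 = Poisson).
    n_depleted / n_enriched: number of genes with a true negative / positive
        log2 selection effect.
    effect_depleted / effect_enriched: the true log2 effects (point mass when
        effect_sd = 0, otherwise normal around these centers).
    guide_concordance: probability both guides of an affected gene carry the
        effect; otherwise one randomly chosen guide carries it alone.
    replicate_design: (n baseline samples, n selected samples).
    group_labels: group names for the baseline and selected samples.
    seed: required; the only source of randomness.
    """

    n_genes: int = 1551
    n_safe_harbors: int = 100
    coverage: int = 500
    sequencing_depth: float = 5e6
    baseline_sdlog: float = 0.8
    dispersion: float = 0.05
    n_depleted: int = 0
    n_enriched: int = 0
    effect_depleted: float = -2.0
    effect_enriched: float = 2.0
    effect_sd: float = 0.0
    guide_concordance: float = 1.0
    replicate_design: tuple[int, int] = (3, 2)
    group_labels: tuple[str, str] = ("Day0", "Day20")
    spacer_length: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimError("SimConfig.seed is required; no implicit randomness")
        if min(self.n_genes, self.n_safe_harbors, self.coverage) <= 0:
            raise SimError("n_genes, n_safe_harbors, coverage must be positive")
        if not 0.0 <= self.guide_concordance <= 1.0:
            raise SimError("guide_concordance must be in [0, 1]")
        if self.n_depleted + self.n_enriched > self.n_genes:
            raise SimError("more affected genes than genes")
        if self.dispersion < 0:
            raise SimError("dispersion must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated screen, for recovery scoring."""

    gene_effects: pd.Series  # true log2 effect per gene (0 for nulls)
    guide_effects: pd.Series  # realized log2 effect per guide
    config: SimConfig
    seed: int

    @property
    def affected_genes(self) -> set[str]:
        return set(self.gene_effects.index[self.gene_effects != 0.0])


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random DNA spacers."""
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = alphabet[rng.integers(0, 4, size=(n - len(out) + 8, length))]
        for row in block:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def make_library(
    n_genes: int, n_safe_harbors: int, spacer_length: int = 20, seed: int = 0
) -> GuideLibrary:
    """A synthetic two-set, one-guide-per-gene-per-set library with controls."""
    rng = np.random.default_rng(seed)
    n_guides = 2 * n_genes + n_safe_harbors
    spacers = iter(_random_spacers(rng, n_guides, spacer_length))
    records: list[GuideRecord] = []
    for i in range(n_genes):
        gene = f"GENE{i + 1:05d}"
        for set_label in ("SET1", "SET2"):
            records.append(
                GuideRecord(
                    guide_id=f"{gene}_{set_label}",
                    gene=gene,
                    spacer=next(spacers),
                    set_label=set_label,
                    is_safe_harbor=False,
                )
            )
    for i in range(n_safe_harbors):
        records.append(
            GuideRecord(
                guide_id=f"SH{i + 1:04d}",
                gene=SAFE_HARBOR_GENE,
                spacer=next(spacers),
                set_label="CONTROL",
                is_safe_harbor=True,
            )
        )
    return GuideLibrary(records)


def simulate_screen(
    config: SimConfig, library: GuideLibrary | None = None
) -> tuple[CountMatrix, SimTruth]:
    """Simulate one screen: a CountMatrix plus its ground truth.

    Pipeline: log-normal baseline proportions -> multinomial founder bottleneck
    at coverage * n_guides cells (shared by all samples) -> multiplicative
    2^effect selection on the late/treated group's abundances -> per-sample
    Poisson depth and gamma-Poisson counts.
    """
    rng = np.random.default_rng(config.seed)
    if library is None:
        library = make_library(
            config.n_genes, config.n_safe_harbors, config.spacer_length, seed=config.seed
        )
    guide_ids = library.guide_ids
    G = len(guide_ids)

    # (1) pre-bottleneck abundances
    props = rng.lognormal(mean=0.0, sigma=config.baseline_sdlog, size=G)
    props /= props.sum()
    # (2) founder bottleneck shared by every sample
    founders = rng.multinomial(config.coverage * G, props).astype(float)
    founder_props = founders / founders.sum()

    # (3) true effects
    genes = library.genes
    gene_effects = pd.Series(0.0, index=genes, name="log2_effect")
    n_aff = config.n_depleted + config.n_enriched
    affected = rng.choice(len(genes), size=n_aff, replace=False) if n_aff else np.array([], dtype=int)
    for k, gi in enumerate(affected):
        center = config.effect_depleted if k < config.n_depleted else config.effect_enriched
        eff = center + (config.effect_sd * rng.standard_normal() if config.effect_sd else 0.0)
        gene_effects.iloc[gi] = eff

    guide_effects = pd.Series(0.0, index=guide_ids, name="log2_effect")
    gene_of = {r.guide_id: r.gene for r in library.records if not r.is_safe_harbor}
    guides_by_gene: dict[str, list[str]] = {}
    for gid, gene in gene_of.items():
        guides_by_gene.setdefault(gene, []).append(gid)
    for gene, eff in gene_effects.items():
        if eff == 0.0:
            continue
        gids = guides_by_gene[gene]
        if rng.random() < config.guide_concordance:
            carriers = gids
        else:
            carriers = [gids[rng.integers(len(gids))]]
        for gid in carriers:
            guide_effects[gid] = eff

    selected_props = founder_props * np.power(2.0, guide_effects.to_numpy())
    selected_props /= selected_props.sum()

    # (4-5) samples
    n_a, n_b = config.replicate_design
    lab_a, lab_b = config.group_labels
    samples: list[SampleInfo] = []
    cols = []
    for group, label, prop, n_rep in (
        ("baseline", lab_a, founder_props, n_a),
        ("selected", lab_b, selected_props, n_b),
    ):
        for r in range(1, n_rep + 1):
            depth = rng.poisson(config.sequencing_depth)
            mean = depth * prop
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                lam = rng.gamma(shape, scale=mean / shape)
            else:
                lam = mean
            cols.append(rng.poisson(lam))
            samples.append(
                SampleInfo(
                    sample_id=f"{label}_rep{r}",
                    condition=group,
                    timepoint=label,
                    replicate=r,
                )
            )

    matrix = CountMatrix(
        guide_ids=list(guide_ids),
        samples=samples,
        counts=np.column_stack(cols),
    )
    truth = SimTruth(
        gene_effects=gene_effects,
        guide_effects=guide_effects,
        config=config,
        seed=config.seed,
    )
    return matrix, truth


def simulate_reads(
    column: np.ndarray | dict[str, int],
    library: GuideLibrary,
    path,
    read_length: int = 75,
    offset_range: tuple[int, int] = (0, 30),
    seed: int = 0,
) -> int:
    """Write a FASTQ(.gz) with exactly count_i reads containing guide i's spacer.

    Each read places the spacer at an offset drawn uniformly from
    ``offset_range`` with random flanking nucleotides and constant quality.
    Returns the number of reads written.
    """
    rng = np.random.default_rng(seed)
    L = library.spacer_length
    o_min, o_max = offset_range
    if read_length < o_max + L:
        raise SimError(
            f"read_length {read_length} < max offset {o_max} + spacer length {L}"
        )
    if isinstance(column, dict):
        counts = np.array([column.get(g, 0) for g in library.guide_ids], dtype=np.int64)
    else:
        counts = np.asarray(column, dtype=np.int64)
    alphabet = "ACGT"
    qual = "I" * read_length
    opener = gzip.open if str(path).endswith(".gz") else open
    n_written = 0
    with opener(path, "wt") as fh:
        read_no = itertools.count(1)
        for rec, n in zip(library.records, counts):
            for _ in range(int(n)):
                off = int(rng.integers(o_min, o_max + 1))
                flanks = rng.integers(0, 4, size=read_length - L)
                left = "".join(alphabet[b] for b in flanks[:off])
                right = "".join(alphabet[b] for b in flanks[off:])
                seq = left + rec.spacer + right
                fh.write(f"@sim_{rec.guide_id}_{next(read_no)}\n{seq}\n+\n{qual}\n")
                n_written += 1
    return n_written


def recovery_report(calls, truth: SimTruth) -> dict:
    """Score gene calls against simulation ground truth.

    sensitivity: fraction of true-effect genes called (either direction);
    empirical_fdr: fraction of called genes that are true nulls (0.0 on an
    empty call set); direction_accuracy: among called true-effect genes, the
    fraction whose call sign matches the true effect sign.
    """
    called = calls.called
    called_genes = set(called["gene"])
    true_genes = truth.affected_genes
    n_true = len(true_genes)
    sensitivity = len(called_genes & true_genes) / n_true if n_true else 0.0
    empirical_fdr = (
        len(called_genes - true_genes) / len(called_genes) if called_genes else 0.0
    )
    tp = called[called["gene"].isin(true_genes)]
    if len(tp):
        signs = np.sign(truth.gene_effects[tp["gene"]].to_numpy())
        want = np.where(signs < 0, "DEPLETED", "ENRICHED")
        direction_accuracy = float((tp["direction"].to_numpy() == want).mean())
    else:
        direction_accuracy = 0.0 if n_true else 1.0
    return {
        "sensitivity": sensitivity,
        "empirical_fdr": empirical_fdr,
        "direction_accuracy": direction_accuracy,
        "n_called": len(called_genes),
        "n_true": n_true,
    }


__all__ = [
    "SimError",
    "SimConfig",
    "SimTruth",
    "make_library",
    "simulate_screen",
    "simulate_reads",
    "recovery_report",
]
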