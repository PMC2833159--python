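"""Enrichment/coverage accounting and the species-specific-miRNA control.

Enrichment of a screening stage is the retained fraction of experimentally
verified pairs divided by the retained fraction of predicted pairs; the EC
value multiplies unrounded enrichment by the verified coverage in percent.
The negative control reruns the full screen for miRNAs that have no conserved
family (pretending they were conserved in every species) and compares the
per-miRNA conserved-target counts against those of the real families with
Welch's t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from orthomir.duplex import DuplexHit, EnergyModel, screen_step1, seed_constraint
from orthomir.features import FilterParams, apply_filter, compute_features
from orthomir.io import MatureMiRNA, OrthologMap, UTRRecord
from orthomir.ortho import conserved_pairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationResult:
    """Counts and derived ratios for one screening stage (one table row)."""

    stage_label: str
    n_pred_kept: int
    n_pred_total: int
    n_ver_kept: int
    n_ver_total: int

    @property
    def ratio_pred_pct(self) -> float:
        return 100.0 * self.n_pred_kept / self.n_pred_total

    @property
    def ratio_ver_pct(self) -> float:
        return 100.0 * self.n_ver_kept / self.n_ver_total

    @property
    def enrichment(self) -> float:
        if self.n_pred_kept == 0:
            if self.n_ver_kept == 0:
                return math.nan
            logger.warning("%s: zero predicted kept with verified kept; enrichment = inf", self.stage_label)
            return math.inf
        return self.ratio_ver_pct / self.ratio_pred_pct

    @property
    def ec(self) -> float:
        return ec_value(self.enrichment, self.ratio_ver_pct)

    def rounded(self) -> tuple[float, float, float]:
        """(ratio_pred, ratio_ver, enrichment) at display precision (1 d.p.)."""
        return (
            round(self.ratio_pred_pct, 1),
            round(self.ratio_ver_pct, 1),
            round(self.enrichment, 1),
        )


def enrichment(
    n_ver_kept: int, n_ver_total: int, n_pred_kept: int, n_pred_total: int,
    stage_label: str = "",
) -> EvaluationResult:
    """Enrichment of verified over predicted retention for one stage."""
    if n_ver_total <= 0 or n_pred_total <= 0:
        raise ValueError("totals must be positive")
    if n_ver_kept > n_ver_total or n_pred_kept > n_pred_total:
        raise ValueError("kept counts cannot exceed totals")
    return EvaluationResult(stage_label, n_pred_kept, n_pred_total, n_ver_kept, n_ver_total)


def ec_value(enrichment_unrounded: float, coverage_pct_unrounded: float) -> float:
    """EC value: unrounded enrichment multiplied by coverage in percent."""
    if enrichment_unrounded < 0 or coverage_pct_unrounded < 0:
        raise ValueError("enrichment and coverage must be non-negative")
    return enrichment_unrounded * coverage_pct_unrounded


def welch_t(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Returns ``(t_stat, p_value)``; ``alternative`` may be ``two-sided``,
    ``less`` or ``greater`` (on sample_a relative to sample_b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            # degenerate but well-defined: identical constant samples
            return 0.0, 1.0
        raise ValueError("both samples have zero variance")
    res = sp_stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ControlResult:
    per_mirna_counts_control: tuple[int, ...]
    per_mirna_counts_conserved: tuple[int, ...]
    t_stat: float
    p_value: float

    @property
    def mean_control(self) -> float:
        return float(np.mean(self.per_mirna_counts_control))

    @property
    def mean_conserved(self) -> float:
        return float(np.mean(self.per_mirna_counts_conserved))

    @property
    def n_zero_control(self) -> int:
        return sum(1 for c in self.per_mirna_counts_control if c == 0)


def run_steps_1_to_3(
    mirna_by_species: Mapping[str, MatureMiRNA],
    utrs: Sequence[UTRRecord],
    ortholog_map: OrthologMap,
    model: EnergyModel | None = None,
    dG_max: float = -17.0,
    params: FilterParams | None = None,
    min_species: int = 4,
    anchor_species: str = "H. sapiens",
):
    """Steps 1-3 for one miRNA 'family' given its per-species members."""
    params = params or FilterParams()
    step1 = screen_step1(list(mirna_by_species.values()), utrs, model, dG_max=dG_max)
    seqs = {m.species: m.sequence for m in mirna_by_species.values()}
    step2 = [h for h in step1 if apply_filter(compute_features(h, seqs[h.species]), params)]
    return conserved_pairs(step2, ortholog_map, min_species=min_species, anchor_species=anchor_species)


def control_experiment(
    species_specific_mirnas: Mapping[str, Sequence[MatureMiRNA]],
    utrs: Sequence[UTRRecord],
    ortholog_map: OrthologMap,
    conserved_counts: Sequence[int],
    params: FilterParams | None = None,
    model: EnergyModel | None = None,
    dG_max: float = -17.0,
    min_species: int = 4,
    anchor_species: str = "H. sapiens",
    n_per_species: int = 5,
    seed: int = 0,
    alternative: str = "two-sided",
) -> ControlResult:
    """Negative control: screen species-specific miRNAs as if conserved.

    ``species_specific_mirnas`` maps species → candidate miRNAs with no family
    assignment; ``n_per_species`` are sampled per species with ``seed``.  Each
    sampled miRNA is run through steps 1-3 against *all* species' UTRs
    (pretending the identical sequence were the family member everywhere),
    and the per-miRNA conserved-pair counts are Welch-tested against the real
    families' ``conserved_counts``.
    """
    rng = np.random.default_rng(seed)
    species_list = sorted({u.species for u in utrs})
    chosen: list[MatureMiRNA] = []
    for sp in sorted(species_specific_mirnas):
        cands = sorted(species_specific_mirnas[sp], key=lambda m: m.mirna_id)
        if len(cands) < n_per_species:
            raise ValueError(f"species {sp!r} has only {len(cands)} species-specific candidates")
        idx = rng.choice(len(cands), size=n_per_species, replace=False)
        chosen.extend(cands[i] for i in sorted(idx))

    counts: list[int] = []
    for control in chosen:
        members = {
            sp: MatureMiRNA(
                mirna_id=f"{control.mirna_id}@{sp}",
                species=sp,
                sequence=control.sequence,
                family=control.mirna_id,
            )
            for sp in species_list
        }
        pairs = run_steps_1_to_3(
            members, utrs, ortholog_map, model=model, dG_max=dG_max, params=params,
            min_species=min_species, anchor_species=anchor_species,
        )
        counts.append(len(pairs))

    t_stat, p_value = welch_t(counts, list(conserved_counts), alternative=alternative)
    return ControlResult(
        per_mirna_counts_control=tuple(counts),
        per_mirna_counts_conserved=tuple(int(c) for c in conserved_counts),
        t_stat=t_stat,
        p_value=p_value,
    )


def stage_report(
    stages: Sequence[tuple[str, set[tuple[str, str, str]]]],
    universe: set[tuple[str, str, str]],
    verified: Iterable[tuple[str, str, str]],
) -> list[EvaluationResult]:
    """Table-2-style report: one row per stage of (family, gene, species) sets.

    ``universe`` is the all-possible-pairs baseline; verified pairs are
    intersected with the universe so both ratios share denominators.
    """
    verified_in = set(verified) & universe
    if not verified_in:
        raise ValueError("no verified pairs fall inside the pair universe")
    rows = [
        enrichment(len(verified_in), len(verified_in), len(universe), len(universe), "All possible pairs")
    ]
    for label, kept in stages:
        kept_in = kept & universe
        rows.append(
            enrichment(
                len(kept_in & verified_in), len(verified_in), len(kept_in), len(universe), label
            )
        )
    return rows
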