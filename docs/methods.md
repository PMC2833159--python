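# Methods

## Scope and model overview

`orthomir` screens for miRNA/target-gene pairs whose regulatory relationship
is conserved across five bilaterian species.  The screen is a cascade of
filters over all (miRNA family, gene, species) pairs: duplex free energy with
a complete seed match (step 1), binding-pattern thresholds (step 2), and
ortholog-cluster conservation (step 3), followed by enrichment accounting and
a species-specific-miRNA negative control.  Nothing in the cascade is fitted;
every stage is a deterministic function of its inputs and a small set of
interpretable parameters.

## Conserved-family extraction

A family needs one mature miRNA per species such that

1. all members carry an identical 7-mer at one of the 5'-end windows 1–7,
   2–8 or 3–9 ("complete seed matching");
2. the *minimum* pairwise overall identity across members exceeds a
   threshold (default 75%);
3. optionally, the family name matches a supplied whitelist of highly
   conserved families (an external phylogenetic classification that the
   package consumes rather than recomputes).

Identity is computed from a global pairwise alignment with affine gap costs
(opening 22.50, extension 0.83 — the ClustalX settings used for short RNA
alignments; match 1.9, mismatch 0, free terminal gaps) as identical columns
divided by full alignment length, gap columns counting as non-matching.
Because co-optimal alignments can differ in length, the argument pair is
canonicalized (lexicographic order) so identity is exactly symmetric.  When a
species has several members sharing the seed (paralogs such as let-7a/let-7b),
the member maximizing the minimum cross-species identity is chosen, ties
broken by miRNA id.  The family identity reported is the minimum over member
pairs (conservative); the mean is emitted as a secondary column because the
aggregation behind a single published "Identity (%)" per family is not
uniquely determined.

## Duplex energy model (step 1)

The duplex between a miRNA and a UTR window is an antiparallel, non-crossing
set of base pairs (Watson–Crick or G·U) with no intramolecular structure and
no branching.  Its free energy is

ΔG = ΔG_init + Σ stacks over contiguous pairs + Σ loop penalties over gaps,

with ΔG_init = +4.09 kcal/mol (bimolecular initiation).  Watson–Crick/
Watson–Crick stacks use the Xia/Turner 37 °C nearest-neighbor measurements;
the 16 oriented entries are filled from the 10 unique values by strand
symmetry.  Stacks involving G·U are approximated by substituting each G·U
with the A·U pair obtained by replacing the G, looking up the resulting
Watson–Crick stack, and adding a destabilization offset of +0.45 kcal/mol
per wobble pair.  This keeps wobble stacks weakly stabilizing, in the right
rank order, without hand-maintaining a second measured table; absolute
energies therefore approximate but do not bit-match other duplex predictors,
which is why the screening cutoff (default −17.0 kcal/mol, strict `<`) is an
explicit configuration value.

Loop penalties are affine: bulge(ℓ) = 3.0 + 0.55·ℓ and internal(ℓ₁, ℓ₂) =
1.7 + 0.55·(ℓ₁+ℓ₂) kcal/mol.  A shared extension coefficient is what allows
the minimum to be found by a four-state Gotoh dynamic program (helix,
UTR-side bulge, miRNA-side bulge, internal loop) in O(N·L) time; the state
recurrences charge the internal-loop opening as a "switch" from the bulge
states.  Dangling-end terms are set to zero — they are negligible for
ranking sites against a single cutoff.  The kernel is numba-compiled with a
pure-Python fallback of the same function body.

Suboptimal sites are enumerated greedily: after reporting the global minimum
structure the UTR span of the site is masked and the DP re-run, until the
best attainable ΔG reaches the stop threshold (or 10 sites).  Ties are
resolved deterministically: transitions that extend a helix are preferred
over loops over re-initiation (more paired positions), and among equal-ΔG
end cells the smaller UTR coordinate wins.

The DP is checked in the test suite against two independent oracles: a naive
O(N²L²) evaluation of the energy definition (every predecessor pair scanned
explicitly) on 200 seeded instances, and full enumeration of every legal
pairing on very small instances.

Seed constraint: a hit passes when one of the three windows is completely
paired to seven consecutive UTR positions with no bulge inside the window.
G·U pairs are allowed in the seed here — the step-2 feature that counts
wobbles *within the seed* presupposes they can occur, and its optimal
threshold of 0 is what ultimately removes them.

Coordinates are 1-based and inclusive on the UTR 5'→3'; `dist_from_stop`
= site_start − 1 and `dist_from_3end` = UTR length − site_end, so positional
bias of sites relative to the stop codon or poly-A end can be read off the
hit tables directly.

## Binding features and thresholds (step 2)

Four counts per duplex: unpaired UTR positions within the site span
(`mm_mrna`, scanned 28→0), unpaired miRNA positions over the whole miRNA
including dangling ends (`mm_mirna`, 14→0), G·U pairs anywhere (`gu_whole`,
10→0) and G·U pairs at seed positions (`gu_seed`, 6→0).  The asymmetry —
mRNA-side mismatches counted only inside the site, miRNA-side over the full
molecule — mirrors the scanned maxima (28 vs. 14): UTR loops can exceed the
miRNA's own length, the miRNA side cannot.  Thresholds are inclusive (≤);
the default combination (12, 10, 4, 0) is the published optimum and keeping
`gu_seed = 0` must still admit wobble-free hits, which forces ≤ semantics.

Threshold optimization reproduces the published procedure: per-feature
coverage curves are computed on the verified and the predicted step-1 hit
sets; the 4 or 5 values with the largest verified-minus-predicted coverage
gap per feature (ties toward stricter values) form the candidate grid —
5×5×5×4 = 500 combinations by default, with the 4 assigned to `gu_seed`,
whose scanned range is shortest.  Every combination is scored by
EC = unrounded enrichment × coverage-in-percent and the maximum wins (ties:
higher coverage, then stricter parameters).  EC is stored unrounded and
rounded only for display.  The optimizer's internal baselines are the step-1
output sets themselves; reporting against the all-pairs baseline is a
separate evaluation call, since the two denominators answer different
questions and cannot both be the objective.

## Ortholog filter (step 3)

Step-2 hits are grouped by (family, ortholog cluster) using a gene→cluster
map supplied as input (ortholog inference is out of scope).  A conserved
pair requires sites in ≥ `min_species` species (default 4 — the published
procedure states the filter both as "at least" and "more than" four; "at
least" is adopted and the value is configurable) and must include the anchor
species.  A species contributes once per cluster even when several paralogs
carry sites, and member sites need not share a seed offset or position.  The
per-species representative hit is the lowest-ΔG one.  Genes absent from the
ortholog map are dropped with a logged count.

## Enrichment, EC and the negative control

For a stage keeping `n_pred_kept` of `n_pred_total` predicted pairs and
`n_ver_kept` of `n_ver_total` verified pairs,

Enrichment = (100·n_ver_kept/n_ver_total) / (100·n_pred_kept/n_pred_total).

Keep-everything stages have enrichment exactly 1.0; a stage keeping verified
pairs but zero predicted pairs reports +inf with a warning.  Stage reports
intersect the verified set with the pair universe so numerators and
denominators are commensurable.

The control samples `n_per_species` (default 5) miRNAs per species from
those without a family assignment (the operational definition of
"species-specific"), seeds the sampling explicitly, and runs each through
steps 1–3 against *all* species' UTRs as if it were conserved everywhere.
Per-miRNA conserved-pair counts are compared to the real families' counts
with Welch's unequal-variance t-test (scipy, Welch–Satterthwaite df).
Sidedness is configurable and defaults to two-sided, the conservative choice
when the published report does not state one.

## Synthetic corpora

The generator emulates the four inputs at desk scale with full ground truth:

- **miRNAs**: per family, a random 22-mer archetype; per-species members
  mutate ⌊22·(1−p/100)/2⌋ positions outside the seed region (p = target
  family identity, default 85% — within the 79–95% range of real conserved
  bilaterian families), guaranteeing the pairwise-identity floor under the
  no-gap alignment.  Decoy miRNAs (10/species) are random 22-mers rejected
  if they share any planted family seed.
- **genes/UTRs**: `n_clusters` ortholog clusters with one gene per species
  plus unmapped extra genes; UTRs are i.i.d. nucleotides at configurable GC
  (default 0.5), lengths uniform on 120–300 nt — short enough to keep runs
  fast, long enough that sites sit in realistic background.
- **planted sites**: reverse-complement insertions of the species member
  into orthologous UTRs — in ≥4 species including the anchor for "conserved"
  truth rows, in <4 for "partial" rows.  One G·U wobble per site (default)
  is created by substituting the site base so the pair becomes G·U, keeping
  ΔG near-optimal; `site_mutation_rate` further degrades sites with random
  substitutions.  Placements are non-overlapping; a UTR too short to host a
  site is an error.
- **verified pairs**: sampled from planted conserved truth, topped up with
  random never-planted pairs so verified coverage is not trivially 100% in
  larger corpora.

All randomness flows from one `numpy` generator seeded by the spec; output
files are byte-identical for identical specs.  What the generator does *not*
emulate: real 3'-UTR base composition, phylogenetically correlated sequence
evolution, paralog families in the ortholog map, or the density of weak
near-miss sites in genuine UTRs.  Passing the planted-truth tests therefore
demonstrates the correctness of the machinery (recovery of what was planted,
exact nesting of stages), not the field performance of the screen on real
genomes.

`plant_features` serves the threshold-recovery tests directly with a feature
table (verified rows uniform at/below a planted cut, decoys diffuse over the
scanned ranges) rather than sequences, because realizing exact feature
counts through sequence mutation would make the planted cut only
approximately controllable.

## Problem sizes and numerical choices

The validation battery uses corpora of 5 species × 40–200 genes with UTRs of
120–300 nt and 10 planted conserved sites — sizes at which the whole screen,
including the brute-force duplex oracles, completes in seconds while still
exercising every code path (partial sites, unmapped genes, decoy miRNAs,
verified misses).  Floating-point comparisons in tests use relative
tolerance ~1e-6; EC consistency is asserted to 1e-9.  Degenerate inputs are
defined explicitly: UTRs shorter than 7 nt yield no hits, duplexes with no
pairable positions report no site, empty verified sets make coverage
optimization an error rather than a silent zero.

## Known limitations

- Energy parameters approximate RNA/RNA nearest-neighbor thermodynamics;
  G·U stack values are derived, not measured, and loop penalties are affine
  rather than logarithmic.  Rankings are robust, absolute ΔG values are not
  calibrated against any external predictor — recalibrate the −17 kcal/mol
  cutoff when substituting energy tables.
- No target-site accessibility or intramolecular mRNA structure modeling.
- The published genome-scale counts (357,430 candidate pairs, 153,387 after
  step 1, 31 conserved pairs) depend on specific historical database
  releases and are not reproducible from this package without those inputs;
  the package reproduces the arithmetic and the procedure, and validates the
  machinery on planted synthetic truth.
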