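"""Extraction of miRNA families conserved across all configured species.

A family is a tuple of mature miRNAs, one per species, that (1) share an
identical 7-nt seed at one of the offsets 1-7, 2-8 or 3-9 from the 5' end and
(2) exceed a pairwise overall sequence-identity threshold (default 75%) under
a global alignment with affine gap costs (opening 22.50, extension 0.83 — the
ClustalX parameters used for the original miRNA alignments).  An optional
whitelist of highly conserved family names ("category I") stands in for the
phylogenetic-conservation criterion, which is an external annotation rather
than something recomputed here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

from orthomir.io import MatureMiRNA

logger = logging.getLogger(__name__)

SEED_OFFSET_LABELS = ("1-7", "2-8", "3-9")
SEED_LEN = 7

# Cap on the number of cross-species member combinations examined per shared
# seed; beyond this the per-species member choice is greedy.
_MAX_TUPLE_ENUMERATION = 2000


@dataclass(frozen=True)
class SeedWindow:
    """A 7-mer seed window of a miRNA at a labeled 5'-end offset."""

    offset_label: str
    seed_seq: str

    def __post_init__(self) -> None:
        if self.offset_label not in SEED_OFFSET_LABELS:
            raise ValueError(f"bad seed offset label {self.offset_label!r}")
        if len(self.seed_seq) != SEED_LEN:
            raise ValueError(f"seed must be {SEED_LEN} nt, got {self.seed_seq!r}")

    @property
    def start(self) -> int:
        """1-based start position on the miRNA."""
        return int(self.offset_label.split("-")[0])

    def positions(self) -> range:
        """1-based miRNA positions covered by the window."""
        return range(self.start, self.start + SEED_LEN)


@dataclass(frozen=True)
class MiRNAFamily:
    family_name: str
    members: tuple[MatureMiRNA, ...]  # one per species
    identity_min_pct: float
    identity_mean_pct: float
    shared_seed: SeedWindow

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(m.species for m in self.members)

    def member_for(self, species: str) -> MatureMiRNA:
        for m in self.members:
            if m.species == species:
                return m
        raise KeyError(species)


def seed_variants(mirna: MatureMiRNA | str) -> tuple[SeedWindow, SeedWindow, SeedWindow]:
    """The three candidate seed windows at 5'-end offsets 1-7, 2-8 and 3-9."""
    seq = mirna if isinstance(mirna, str) else mirna.sequence
    if len(seq) < 9:
        raise ValueError(f"sequence length {len(seq)} < 9; cannot take seed windows")
    return tuple(
        SeedWindow(label, seq[i : i + SEED_LEN]) for i, label in enumerate(SEED_OFFSET_LABELS)
    )


def _make_aligner(
    match: float = 1.9,
    mismatch: float = 0.0,
    gap_open: float = 22.50,
    gap_extend: float = 0.83,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython scores gaps as open+extend for the first gap position.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    # terminal overhangs are free, as in a profile alignment of short RNAs
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity of two RNA sequences under a global affine-gap alignment.

    Identity is the number of identical aligned columns divided by the full
    alignment length (gap columns count as non-matching), x100.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if b < a:  # co-optimal alignments can differ by order; canonicalize for symmetry
        a, b = b, a
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(a, b)[0]
    ta, qa = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ta, qa) if x == y and x != "-")
    return 100.0 * matches / len(ta)


def _min_mean_identity(members: Sequence[MatureMiRNA], cache: dict) -> tuple[float, float]:
    vals = []
    for a, b in itertools.combinations(members, 2):
        key = (a.mirna_id, b.mirna_id) if a.mirna_id < b.mirna_id else (b.mirna_id, a.mirna_id)
        if key not in cache:
            cache[key] = pairwise_identity(a.sequence, b.sequence)
        vals.append(cache[key])
    return min(vals), sum(vals) / len(vals)


def strip_species_prefix(mirna_id: str) -> str:
    """``hsa-let-7a`` → ``let-7a``; ids without a prefix pass through."""
    parts = mirna_id.split("-", 1)
    return parts[1] if len(parts) == 2 else mirna_id


def _matches_whitelist(name: str, members: Sequence[MatureMiRNA], whitelist: Iterable[str]) -> bool:
    names = {name.lower()} | {strip_species_prefix(m.mirna_id).lower() for m in members}
    for entry in whitelist:
        e = entry.lower()
        if any(n == e or n.startswith(e) for n in names):
            return True
    return False


def extract_conserved_families(
    mirnas_by_species: Mapping[str, Sequence[MatureMiRNA]],
    identity_threshold: float = 75.0,
    family_whitelist: Iterable[str] | None = None,
    anchor_species: str | None = None,
) -> list[MiRNAFamily]:
    """Extract families conserved in *every* species of ``mirnas_by_species``.

    For each 7-mer seed present (at any offset) in all species, one member per
    species is chosen to maximize the minimum cross-species pairwise identity
    (ties by miRNA id); the family is kept when that minimum exceeds
    ``identity_threshold``.  The reported family identity is the minimum over
    all member pairs, with the mean as a secondary statistic.

    The family name is the anchor-species member's id without its species
    prefix (anchor defaults to the first species key).
    """
    species = list(mirnas_by_species)
    if len(species) < 2:
        raise ValueError("need at least two species to extract conserved families")
    for sp in species:
        if not mirnas_by_species[sp]:
            raise ValueError(f"species {sp!r} has no miRNAs")
    if anchor_species is None:
        anchor_species = species[0]

    # seed 7-mer -> species -> [(offset_label, mirna)]
    by_seed: dict[str, dict[str, list[tuple[str, MatureMiRNA]]]] = {}
    for sp in species:
        for m in mirnas_by_species[sp]:
            if len(m.sequence) < 9:
                continue
            seen_here: set[str] = set()
            for win in seed_variants(m):
                if win.seed_seq in seen_here:
                    continue  # same 7-mer at two offsets: count once, first label
                seen_here.add(win.seed_seq)
                by_seed.setdefault(win.seed_seq, {}).setdefault(sp, []).append(
                    (win.offset_label, m)
                )

    cache: dict = {}
    families: list[MiRNAFamily] = []
    seen_member_sets: set[frozenset] = set()
    for seed_seq in sorted(by_seed):
        per_sp = by_seed[seed_seq]
        if len(per_sp) < len(species):
            continue
        candidates = [sorted(per_sp[sp], key=lambda t: t[1].mirna_id) for sp in species]
        n_tuples = 1
        for c in candidates:
            n_tuples *= len(c)
        best: tuple[float, float, tuple, tuple] | None = None
        if n_tuples <= _MAX_TUPLE_ENUMERATION:
            combos = itertools.product(*candidates)
        else:  # greedy fallback: first (lexicographic) member per species
            logger.warning("seed %s: %d member combinations, using first per species", seed_seq, n_tuples)
            combos = [tuple(c[0] for c in candidates)]
        for combo in combos:
            members = tuple(m for _, m in combo)
            mn, mean = _min_mean_identity(members, cache)
            ids = tuple(m.mirna_id for m in members)
            if best is None or (-mn, ids) < (-best[0], best[3]):
                best = (mn, mean, combo, ids)
        mn, mean, combo, _ = best
        if mn <= identity_threshold:
            continue
        members = tuple(m for _, m in combo)
        key = frozenset(m.mirna_id for m in members)
        if key in seen_member_sets:
            continue
        seen_member_sets.add(key)
        # offset label as seen on the anchor member, falling back to the first
        anchor_idx = species.index(anchor_species) if anchor_species in species else 0
        offset_label = combo[anchor_idx][0]
        name = strip_species_prefix(members[anchor_idx].mirna_id)
        fam = MiRNAFamily(
            family_name=name,
            members=members,
            identity_min_pct=mn,
            identity_mean_pct=mean,
            shared_seed=SeedWindow(offset_label, seed_seq),
        )
        if family_whitelist is not None and not _matches_whitelist(name, members, family_whitelist):
            continue
        families.append(fam)
    families.sort(key=lambda f: f.family_name)
    return families
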