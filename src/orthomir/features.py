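"""Step 2: the four binding-pattern features of a miRNA:mRNA duplex.

* ``mm_mrna`` -- unpaired UTR positions inside the duplex span (mRNA-side
  mismatches/loops); scanned range 28..0.
* ``mm_mirna`` -- unpaired miRNA positions over the whole miRNA, including
  dangling ends; scanned range 14..0.
* ``gu_whole`` -- G-U wobble pairs anywhere in the duplex; scanned range 10..0.
* ``gu_seed`` -- G-U wobble pairs whose miRNA position falls in the matched
  seed window; scanned range 6..0.

Thresholds are inclusive (a hit passes when every feature is ≤ its maximum);
the screen's optimal combination is (12, 10, 4, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

from orthomir.duplex import DuplexHit
from orthomir.families import SEED_LEN
from orthomir.io import MatureMiRNA

#: Upper ends of the scanned threshold ranges, in field order.
SCAN_MAXIMA = (28, 14, 10, 6)
FEATURE_NAMES = ("mm_mrna", "mm_mirna", "gu_whole", "gu_seed")


@dataclass(frozen=True)
class BindingFeatures:
    mm_mrna: int
    mm_mirna: int
    gu_whole: int
    gu_seed: int

    def __post_init__(self) -> None:
        if min(self.mm_mrna, self.mm_mirna, self.gu_whole, self.gu_seed) < 0:
            raise ValueError("binding features must be non-negative")
        if self.gu_seed > self.gu_whole:
            raise ValueError("gu_seed cannot exceed gu_whole")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.mm_mrna, self.mm_mirna, self.gu_whole, self.gu_seed)


@dataclass(frozen=True)
class FilterParams:
    """Inclusive maxima for the four binding features; default = the optimal
    combination found by the EC grid search."""

    max_mm_mrna: int = 12
    max_mm_mirna: int = 10
    max_gu_whole: int = 4
    max_gu_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.as_tuple()) < 0:
            raise ValueError("filter maxima must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.max_mm_mrna, self.max_mm_mirna, self.max_gu_whole, self.max_gu_seed)


def compute_features(hit: DuplexHit, mirna: MatureMiRNA | str) -> BindingFeatures:
    """Pure recount of the four features from a hit's pair list.

    Requires the hit's matched seed window (``seed_offset_label``); a hit that
    never passed the seed constraint has no defined ``gu_seed``.
    """
    if not hit.pairs:
        raise ValueError("hit has no pairs")
    if hit.seed_offset_label is None:
        raise ValueError("hit has no seed_offset_label; run seed_constraint first")
    seq = mirna if isinstance(mirna, str) else mirna.sequence
    length = len(seq)
    paired_utr = {up for up, _, _ in hit.pairs}
    paired_mir = {mp for _, mp, _ in hit.pairs}
    mm_mrna = sum(1 for p in range(hit.site_start, hit.site_end + 1) if p not in paired_utr)
    mm_mirna = sum(1 for p in range(1, length + 1) if p not in paired_mir)
    gu_pairs = [(up, mp) for up, mp, cls in hit.pairs if cls == "GU"]
    seed_start = int(hit.seed_offset_label.split("-")[0])
    seed_window = range(seed_start, seed_start + SEED_LEN)
    gu_seed = sum(1 for _, mp in gu_pairs if mp in seed_window)
    return BindingFeatures(
        mm_mrna=mm_mrna, mm_mirna=mm_mirna, gu_whole=len(gu_pairs), gu_seed=gu_seed
    )


def apply_filter(features: BindingFeatures, params: FilterParams) -> bool:
    """True iff every feature is within its (inclusive) maximum."""
    return all(f <= m for f, m in zip(features.as_tuple(), params.as_tuple()))
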