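"""Step 3: the ortholog-conservation filter.

Hits surviving steps 1-2 are grouped by (miRNA family, ortholog cluster); a
pair is kept when sites are present in at least ``min_species`` species
(default 4) including the anchor species (default *H. sapiens*).  A species
contributes once per cluster even if several paralogous members carry sites,
and sites in different species need not share a seed offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from orthomir.duplex import DuplexHit
from orthomir.io import OrthologMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConservedPair:
    """A (miRNA family, ortholog cluster) pair with per-species best hits."""

    family_name: str
    cluster_id: str
    anchor_gene_id: str
    species_with_site: frozenset[str]
    per_species_hits: Mapping[str, DuplexHit]

    @property
    def n_species(self) -> int:
        return len(self.species_with_site)


def conserved_pairs(
    step2_hits: Iterable[DuplexHit],
    ortholog_map: OrthologMap,
    min_species: int = 4,
    anchor_species: str = "H. sapiens",
) -> list[ConservedPair]:
    """Group step-2 hits by (family, cluster) and keep conserved pairs.

    Hits on genes absent from the ortholog map are dropped (counted in the
    log).  The per-species representative hit is the lowest-dG one.
    """
    groups: dict[tuple[str, str], dict[str, DuplexHit]] = {}
    n_unmapped = 0
    seen_anchor = False
    for hit in step2_hits:
        if hit.species == anchor_species:
            seen_anchor = True
        cluster = ortholog_map.cluster_of(hit.gene_id, hit.species)
        if cluster is None:
            n_unmapped += 1
            continue
        family = hit.family or hit.mirna_id
        key = (family, cluster)
        per_sp = groups.setdefault(key, {})
        cur = per_sp.get(hit.species)
        if cur is None or (hit.dG, hit.site_start, hit.gene_id) < (cur.dG, cur.site_start, cur.gene_id):
            per_sp[hit.species] = hit
    if n_unmapped:
        logger.info("dropped %d hits on genes without ortholog-cluster assignment", n_unmapped)
    if not seen_anchor and not any(s == anchor_species for _, s, _ in ortholog_map.entries):
        raise ValueError(f"anchor species {anchor_species!r} absent from hits and ortholog map")

    out: list[ConservedPair] = []
    for (family, cluster), per_sp in groups.items():
        if len(per_sp) < min_species or anchor_species not in per_sp:
            continue
        out.append(
            ConservedPair(
                family_name=family,
                cluster_id=cluster,
                anchor_gene_id=per_sp[anchor_species].gene_id,
                species_with_site=frozenset(per_sp),
                per_species_hits=dict(per_sp),
            )
        )
    out.sort(key=lambda p: (p.family_name, p.cluster_id))
    return out


def multi_mirna_targets(pairs: Iterable[ConservedPair]) -> dict[str, set[str]]:
    """Cluster → set of targeting families (clusters hit by ≥2 are of note)."""
    out: dict[str, set[str]] = {}
    for p in pairs:
        out.setdefault(p.cluster_id, set()).add(p.family_name)
    return out
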