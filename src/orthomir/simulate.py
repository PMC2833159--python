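"""Seeded synthetic corpora with planted ground truth.

The generator emulates the four external inputs of the screen at desk scale:
a mature-miRNA set per species (planted conserved families among
species-specific decoys), per-species 3'-UTR sets with planted target sites,
an ortholog map, and a verified-pair table.  Planted conserved sites are
reverse-complement insertions of the family member into orthologous UTRs of
at least four species including the anchor; planted G-U wobbles substitute a
site nucleotide so the duplex pair becomes G-U (keeping the site near its
energy optimum), and ``site_mutation_rate`` degrades sites with random
substitutions.  A truth table records every planted site with its intended
stage of survival.  A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from orthomir.features import FEATURE_NAMES, SCAN_MAXIMA
from orthomir.io import (
    DEFAULT_SPECIES_PREFIXES,
    MatureMiRNA,
    OrthologMap,
    UTRRecord,
    VerifiedPairSet,
    write_mirna_fasta,
    write_tables,
    write_utr_fasta,
)

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

MIRNA_LEN = 22
# planted mutations and wobbles stay clear of all three seed windows (1..9)
_NONSEED_START = 10


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic corpus."""

    seed: int = 0
    n_species: int = 5
    n_clusters: int = 40
    n_genes_per_species: int = 50
    utr_length_range: tuple[int, int] = (120, 300)
    n_conserved_families: int = 5
    family_identity_pct: float = 85.0
    n_planted_conserved_sites: int = 10
    n_planted_partial_sites: int = 5
    site_mutation_rate: float = 0.0
    n_verified_pairs: int = 20
    decoy_gc: float = 0.5
    n_decoy_mirnas_per_species: int = 10
    n_gu_per_site: int = 1

    def __post_init__(self) -> None:
        if not (2 <= self.n_species <= len(DEFAULT_SPECIES_PREFIXES)):
            raise ValueError("n_species must be between 2 and the configured species set")
        if self.n_genes_per_species < self.n_clusters:
            raise ValueError("need at least as many genes as ortholog clusters")
        if not (0.0 <= self.site_mutation_rate <= 1.0 and 0.0 < self.decoy_gc < 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_planted_conserved_sites + self.n_planted_partial_sites > (
            self.n_conserved_families * self.n_clusters
        ):
            raise ValueError("more planted sites than (family, cluster) combinations")


@dataclass
class SyntheticCorpus:
    """In-memory corpus plus the planted-site truth table."""

    spec: FixtureSpec
    species: tuple[str, ...]
    mirnas_by_species: dict[str, list[MatureMiRNA]]
    utrs: list[UTRRecord]
    ortholog_map: OrthologMap
    verified: VerifiedPairSet
    truth: pd.DataFrame
    family_names: tuple[str, ...] = field(default_factory=tuple)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all corpus files; deterministic byte-for-byte under one spec."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix_of = {v: k for k, v in DEFAULT_SPECIES_PREFIXES.items()}
        paths: dict[str, Path] = {}
        all_mirnas = [m for sp in sorted(self.mirnas_by_species) for m in self.mirnas_by_species[sp]]
        paths["mirnas"] = outdir / "mirnas.fasta"
        write_mirna_fasta(all_mirnas, paths["mirnas"])
        for sp in self.species:
            p = outdir / f"utr_{prefix_of[sp]}.fasta"
            write_utr_fasta([u for u in self.utrs if u.species == sp], p)
            paths[f"utr:{sp}"] = p
        paths["orthologs"] = outdir / "orthologs.tsv"
        paths["verified"] = outdir / "verified.tsv"
        write_tables(self.ortholog_map, self.verified, paths["orthologs"], paths["verified"])
        paths["truth"] = outdir / "truth.tsv"
        truth = self.truth.sort_values(list(self.truth.columns)).reset_index(drop=True)
        truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: list[str], pos: int) -> None:
    alternatives = [b for b in "ACGU" if b != seq[pos]]
    seq[pos] = alternatives[rng.integers(len(alternatives))]


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def generate_corpus(spec: FixtureSpec) -> SyntheticCorpus:
    """Generate a complete corpus with planted conserved/partial target sites."""
    rng = np.random.default_rng(spec.seed)
    species = tuple(list(DEFAULT_SPECIES_PREFIXES.values())[: spec.n_species])
    prefix_of = {v: k for k, v in DEFAULT_SPECIES_PREFIXES.items()}
    anchor = species[0]
    lo, hi = spec.utr_length_range

    # --- miRNAs: planted families + species-specific decoys -----------------
    n_mut = int(MIRNA_LEN * (1 - spec.family_identity_pct / 100.0) / 2)
    family_names = tuple(f"mir-s{f + 1:02d}" for f in range(spec.n_conserved_families))
    family_seeds: set[str] = set()
    mirnas_by_species: dict[str, list[MatureMiRNA]] = {sp: [] for sp in species}
    members: dict[tuple[str, str], MatureMiRNA] = {}
    for fam in family_names:
        archetype = _random_seq(rng, MIRNA_LEN)
        for off in range(3):
            family_seeds.add(archetype[off : off + 7])
        for sp in species:
            seq = list(archetype)
            if n_mut:
                sites = rng.choice(
                    np.arange(_NONSEED_START - 1, MIRNA_LEN), size=n_mut, replace=False
                )
                for pos in sites:
                    _mutate(rng, seq, int(pos))
            m = MatureMiRNA(
                mirna_id=f"{prefix_of[sp]}-{fam}", species=sp, sequence="".join(seq), family=fam
            )
            mirnas_by_species[sp].append(m)
            members[(fam, sp)] = m
    for sp in species:
        made = 0
        while made < spec.n_decoy_mirnas_per_species:
            seq = _random_seq(rng, MIRNA_LEN)
            windows = {seq[o : o + 7] for o in range(3)}
            if windows & family_seeds:
                continue  # a decoy must not share a planted family seed
            made += 1
            mirnas_by_species[sp].append(
                MatureMiRNA(
                    mirna_id=f"{prefix_of[sp]}-mir-x{made:03d}", species=sp, sequence=seq
                )
            )

    # --- genes, UTRs, ortholog map ------------------------------------------
    omap = OrthologMap()
    utr_seqs: dict[tuple[str, str], list[str]] = {}  # (species, gene) -> mutable seq
    gene_ids: dict[str, list[str]] = {sp: [] for sp in species}
    transcript_of: dict[tuple[str, str], str] = {}
    for g in range(spec.n_genes_per_species):
        for sp in species:
            pfx = prefix_of[sp]
            gene = f"G{g + 1:04d}_{pfx}"
            gene_ids[sp].append(gene)
            transcript_of[(sp, gene)] = f"T{g + 1:04d}_{pfx}"
            length = int(rng.integers(lo, hi + 1))
            utr_seqs[(sp, gene)] = list(_random_seq(rng, length, spec.decoy_gc))
            if g < spec.n_clusters:
                omap.add(gene, sp, f"OG{g + 1:04d}")

    # --- plant sites ----------------------------------------------------------
    combos = [(fam, c) for fam in family_names for c in range(spec.n_clusters)]
    idx = rng.choice(len(combos), size=spec.n_planted_conserved_sites + spec.n_planted_partial_sites, replace=False)
    chosen = [combos[i] for i in idx]
    conserved_combos = chosen[: spec.n_planted_conserved_sites]
    partial_combos = chosen[spec.n_planted_conserved_sites :]

    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    truth_rows: list[dict] = []

    def plant(fam: str, cluster_idx: int, sp: str, stage: str) -> None:
        member = members[(fam, sp)]
        site = list(_revcomp(member.sequence))
        L = len(site)
        # G-U wobbles: substitute the site base paired with a non-seed miRNA
        # G (C->U) or U (A->G); pairing survives as a wobble
        eligible = [
            p for p in range(_NONSEED_START - 1 + 2, MIRNA_LEN)  # keep clear of seed 3-9 too
            if member.sequence[p] in "GU"
        ]
        n_gu = min(spec.n_gu_per_site, len(eligible))
        if n_gu:
            for mp in rng.choice(eligible, size=n_gu, replace=False):
                sp_pos = L - 1 - int(mp)  # site index pairing miRNA position mp (0-based)
                site[sp_pos] = "U" if member.sequence[int(mp)] == "G" else "G"
        for p in range(L):
            if rng.random() < spec.site_mutation_rate:
                _mutate(rng, site, p)
        gene = gene_ids[sp][cluster_idx]
        seq = utr_seqs[(sp, gene)]
        if len(seq) < L:
            raise ValueError(f"UTR of {gene} ({sp}) too short to host a planted site")
        spans = occupied.setdefault((sp, gene), [])
        for _ in range(50):
            start = int(rng.integers(0, len(seq) - L + 1))
            if all(start + L <= s or start >= e for s, e in spans):
                break
        else:
            raise ValueError(f"could not place non-overlapping site in {gene} ({sp})")
        spans.append((start, start + L))
        seq[start : start + L] = site
        truth_rows.append(
            dict(
                family=fam,
                cluster_id=f"OG{cluster_idx + 1:04d}",
                species=sp,
                gene_id=gene,
                transcript_id=transcript_of[(sp, gene)],
                site_start=start + 1,
                site_end=start + L,
                n_gu=n_gu,
                stage=stage,
            )
        )

    for fam, c in conserved_combos:
        k = int(rng.integers(4, spec.n_species + 1)) if spec.n_species > 4 else spec.n_species
        others = [sp for sp in species[1:]]
        extra = rng.choice(len(others), size=k - 1, replace=False)
        for sp in [anchor] + [others[i] for i in sorted(extra)]:
            plant(fam, c, sp, "conserved")
    for fam, c in partial_combos:
        k = int(rng.integers(1, min(4, spec.n_species)))
        which = rng.choice(spec.n_species, size=k, replace=False)
        for i in sorted(which):
            plant(fam, c, species[i], "partial")

    utrs = [
        UTRRecord(
            transcript_id=transcript_of[(sp, gene)],
            gene_id=gene,
            species=sp,
            sequence="".join(utr_seqs[(sp, gene)]),
        )
        for sp in species
        for gene in gene_ids[sp]
    ]

    # --- verified pairs -------------------------------------------------------
    planted = sorted(
        {(r["family"], r["gene_id"], r["species"]) for r in truth_rows if r["stage"] == "conserved"}
    )
    verified = VerifiedPairSet()
    take = min(spec.n_verified_pairs, len(planted))
    for i in rng.choice(len(planted), size=take, replace=False):
        verified.add(*planted[i])
    n_extra = spec.n_verified_pairs - take
    for _ in range(n_extra):  # verified pairs the screen will (rightly) miss
        fam = family_names[rng.integers(len(family_names))]
        sp = species[rng.integers(len(species))]
        gene = gene_ids[sp][rng.integers(len(gene_ids[sp]))]
        verified.add(fam, gene, sp)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "family", "cluster_id", "species", "gene_id", "transcript_id",
            "site_start", "site_end", "n_gu", "stage",
        ],
    )
    return SyntheticCorpus(
        spec=spec,
        species=species,
        mirnas_by_species=mirnas_by_species,
        utrs=utrs,
        ortholog_map=omap,
        verified=verified,
        truth=truth,
        family_names=family_names,
    )


def plant_features(
    cut: Sequence[int] = (2, 1, 1, 0),
    n_verified: int = 60,
    n_decoys: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, tuple[int, int, int, int]]:
    """Feature table with verified features planted at/below a cut, decoys diffuse.

    Verified rows draw each feature uniformly on [0, cut]; decoys uniformly on
    the full scanned range.  Returns (hits table, verified flags, cut); serves
    the grid-search parameter-recovery check.
    """
    cut = tuple(int(c) for c in cut)
    if len(cut) != 4:
        raise ValueError("cut must have four components")
    for c, m in zip(cut, SCAN_MAXIMA):
        if not (0 <= c <= m):
            raise ValueError(f"cut {cut} outside scanned ranges {SCAN_MAXIMA}")
    if cut[3] > cut[2]:
        raise ValueError("infeasible cut: gu_seed bound exceeds gu_whole bound")
    rng = np.random.default_rng(seed)
    rows = {}
    for name, c, m in zip(FEATURE_NAMES, cut, SCAN_MAXIMA):
        ver = rng.integers(0, c + 1, size=n_verified)
        dec = rng.integers(0, m + 1, size=n_decoys)
        rows[name] = np.concatenate([ver, dec])
    # enforce gu_seed <= gu_whole rowwise
    rows["gu_seed"] = np.minimum(rows["gu_seed"], rows["gu_whole"])
    df = pd.DataFrame(rows)
    flags = np.zeros(len(df), dtype=bool)
    flags[:n_verified] = True
    return df, flags, cut
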