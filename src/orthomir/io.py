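"""Corpus I/O: mature miRNA FASTA, 3'-UTR FASTA, ortholog map and verified-pair tables.

All sequence ingest is normalized to uppercase RNA (T→U).  FASTA parsing goes
through :mod:`Bio.SeqIO`; tabular data through :mod:`pandas`.  Output tables
are TSV with a commented provenance header so they can be re-read with
``pandas.read_csv(..., sep="\\t", comment="#")``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Default species set of the screen: five bilaterian model animals.
DEFAULT_SPECIES_PREFIXES: dict[str, str] = {
    "hsa": "H. sapiens",
    "mmu": "M. musculus",
    "gga": "G. gallus",
    "dme": "D. melanogaster",
    "cel": "C. elegans",
}

DEFAULT_SPECIES: tuple[str, ...] = tuple(DEFAULT_SPECIES_PREFIXES.values())

MIRNA_LEN_MIN = 15
MIRNA_LEN_MAX = 30


class CorpusError(ValueError):
    """Raised on malformed or inconsistent corpus input."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U."""
    return str(seq).upper().replace("T", "U")


def _check_rna(seq: str, where: str) -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise CorpusError(f"{where}: non-RNA characters {sorted(bad)!r} in sequence")


@dataclass(frozen=True)
class MatureMiRNA:
    """One mature miRNA sequence with species and optional family labels."""

    mirna_id: str
    species: str
    sequence: str
    family: str | None = None

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        _check_rna(seq, self.mirna_id)
        if not (MIRNA_LEN_MIN <= len(seq) <= MIRNA_LEN_MAX):
            raise CorpusError(
                f"{self.mirna_id}: mature miRNA length {len(seq)} outside "
                f"[{MIRNA_LEN_MIN}, {MIRNA_LEN_MAX}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UTRRecord:
    """One 3'-UTR sequence (5'→3') annotated with transcript, gene and species."""

    transcript_id: str
    gene_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise CorpusError(f"{self.transcript_id}: empty 3'-UTR sequence")
        _check_rna(seq, self.transcript_id)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrthologMap:
    """Gene ↔ ortholog-cluster membership across species.

    Each ``(gene_id, species)`` belongs to at most one cluster.
    """

    entries: set[tuple[str, str, str]] = field(default_factory=set)  # (gene, species, cluster)
    _by_gene: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)

    def add(self, gene_id: str, species: str, cluster_id: str) -> None:
        key = (gene_id, species)
        existing = self._by_gene.get(key)
        if existing is not None and existing != cluster_id:
            raise CorpusError(
                f"gene {gene_id} ({species}) assigned to two clusters: "
                f"{existing} and {cluster_id}"
            )
        self._by_gene[key] = cluster_id
        self.entries.add((gene_id, species, cluster_id))

    def cluster_of(self, gene_id: str, species: str) -> str | None:
        return self._by_gene.get((gene_id, species))

    def members(self, cluster_id: str) -> set[tuple[str, str]]:
        return {(g, s) for g, s, c in self.entries if c == cluster_id}

    def clusters(self) -> set[str]:
        return {c for _, _, c in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class VerifiedPairSet:
    """Experimentally verified (miRNA family, gene, species) pairs."""

    pairs: set[tuple[str, str, str]] = field(default_factory=set)

    def add(self, mirna_family: str, gene_id: str, species: str) -> None:
        self.pairs.add((mirna_family, gene_id, species))

    def __contains__(self, pair: tuple[str, str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def species_from_prefix(
    identifier: str, prefixes: Mapping[str, str] | None = None
) -> str:
    """Resolve a species from a miRBase-style id prefix such as ``hsa-let-7a``."""
    prefixes = DEFAULT_SPECIES_PREFIXES if prefixes is None else prefixes
    token = identifier.split("-", 1)[0].lower()
    try:
        return prefixes[token]
    except KeyError:
        raise CorpusError(
            f"unknown species prefix {token!r} in id {identifier!r}; "
            f"known prefixes: {sorted(prefixes)}"
        ) from None


def read_mirna_fasta(
    path: str | Path,
    species_resolver=None,
    prefixes: Mapping[str, str] | None = None,
) -> list[MatureMiRNA]:
    """Read a miRBase-style mature miRNA FASTA.

    The first whitespace token of each header is the miRNA id; its species
    prefix is mapped through ``species_resolver`` (default:
    :func:`species_from_prefix` with the five bilaterian prefixes).
    """
    if species_resolver is None:
        species_resolver = lambda ident: species_from_prefix(ident, prefixes)
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("no FASTA records in %s", path)
        return []
    out: list[MatureMiRNA] = []
    seen: set[str] = set()
    for rec in records:
        mirna_id = rec.id
        if mirna_id in seen:
            raise CorpusError(f"{path}: duplicate miRNA id {mirna_id}")
        seen.add(mirna_id)
        out.append(
            MatureMiRNA(
                mirna_id=mirna_id,
                species=species_resolver(mirna_id),
                sequence=str(rec.seq),
            )
        )
    return out


_HEADER_FIELD_RE = re.compile(r"\{(transcript|gene)\}")


def _compile_header_pattern(pattern: str) -> re.Pattern:
    """Turn a template like ``"{transcript}|{gene}"`` into a named-group regex."""
    regex = ""
    pos = 0
    for m in _HEADER_FIELD_RE.finditer(pattern):
        regex += re.escape(pattern[pos : m.start()])
        regex += f"(?P<{m.group(1)}>[^|\\s]+)"
        pos = m.end()
    regex += re.escape(pattern[pos:])
    return re.compile(regex)


def read_utr_fasta(
    path: str | Path,
    species: str,
    header_pattern: str = "{transcript}|{gene}",
    longest_per_gene: bool = True,
) -> list[UTRRecord]:
    """Read an Ensembl-style 3'-UTR FASTA for one species.

    ``header_pattern`` describes how transcript and gene ids are laid out in
    the header (first whitespace token).  With ``longest_per_gene`` (default),
    a gene with several transcripts is collapsed to its longest 3'-UTR so that
    downstream pair counting is gene-scaled.
    """
    path = Path(path)
    rx = _compile_header_pattern(header_pattern)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("no FASTA records in %s", path)
        return []
    out: list[UTRRecord] = []
    seen: set[str] = set()
    for rec in records:
        m = rx.match(rec.id)
        if m is None:
            raise CorpusError(
                f"{path}: header {rec.id!r} does not match pattern {header_pattern!r}"
            )
        if len(rec.seq) == 0:
            logger.warning("%s: zero-length UTR %s skipped", path, rec.id)
            continue
        tid = m.group("transcript")
        if tid in seen:
            raise CorpusError(f"{path}: duplicate transcript id {tid} for {species}")
        seen.add(tid)
        out.append(
            UTRRecord(
                transcript_id=tid,
                gene_id=m.group("gene"),
                species=species,
                sequence=str(rec.seq),
            )
        )
    if longest_per_gene:
        out = collapse_longest_per_gene(out)
    return out


def collapse_longest_per_gene(utrs: Sequence[UTRRecord]) -> list[UTRRecord]:
    """Keep the longest 3'-UTR per (gene, species); ties by transcript id."""
    best: dict[tuple[str, str], UTRRecord] = {}
    for u in utrs:
        key = (u.gene_id, u.species)
        cur = best.get(key)
        # longer wins; on equal length the lexicographically smaller transcript
        if cur is None or len(u) > len(cur) or (len(u) == len(cur) and u.transcript_id < cur.transcript_id):
            best[key] = u
    return sorted(best.values(), key=lambda u: (u.species, u.gene_id))


def read_tables(
    ortholog_path: str | Path,
    verified_path: str | Path,
    species: Iterable[str] | None = None,
) -> tuple[OrthologMap, VerifiedPairSet]:
    """Read the ortholog map and verified-pair TSVs.

    Ortholog columns: ``gene_id, species, cluster_id``.
    Verified columns: ``mirna_family, gene_id, species``.
    """
    known = set(DEFAULT_SPECIES if species is None else species)
    omap = OrthologMap()
    df = pd.read_csv(ortholog_path, sep="\t", comment="#", dtype=str)
    for col in ("gene_id", "species", "cluster_id"):
        if col not in df.columns:
            raise CorpusError(f"{ortholog_path}: missing column {col!r}")
    for i, row in enumerate(df.itertuples(index=False)):
        if row.species not in known:
            raise CorpusError(f"{ortholog_path} row {i + 2}: unknown species {row.species!r}")
        try:
            omap.add(row.gene_id, row.species, row.cluster_id)
        except CorpusError as exc:
            raise CorpusError(f"{ortholog_path} row {i + 2}: {exc}") from None

    vset = VerifiedPairSet()
    df = pd.read_csv(verified_path, sep="\t", comment="#", dtype=str)
    for col in ("mirna_family", "gene_id", "species"):
        if col not in df.columns:
            raise CorpusError(f"{verified_path}: missing column {col!r}")
    for i, row in enumerate(df.itertuples(index=False)):
        if row.species not in known:
            raise CorpusError(f"{verified_path} row {i + 2}: unknown species {row.species!r}")
        vset.add(row.mirna_family, row.gene_id, row.species)
    return omap, vset


# ---------------------------------------------------------------------------
# writers

def write_mirna_fasta(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(mirnas, key=lambda m: m.mirna_id):
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")


def write_utr_fasta(
    utrs: Iterable[UTRRecord], path: str | Path, header_pattern: str = "{transcript}|{gene}"
) -> None:
    with open(path, "w") as fh:
        for u in sorted(utrs, key=lambda u: u.transcript_id):
            header = header_pattern.format(transcript=u.transcript_id, gene=u.gene_id)
            fh.write(f">{header}\n{u.sequence}\n")


def write_tables(
    omap: OrthologMap, vset: VerifiedPairSet, ortholog_path: str | Path, verified_path: str | Path
) -> None:
    odf = pd.DataFrame(sorted(omap.entries), columns=["gene_id", "species", "cluster_id"])
    odf.to_csv(ortholog_path, sep="\t", index=False)
    vdf = pd.DataFrame(sorted(vset.pairs), columns=["mirna_family", "gene_id", "species"])
    vdf.to_csv(verified_path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: Mapping[str, object] | None = None) -> None:
    """Write a result table as TSV with a commented provenance header."""
    from orthomir import __version__

    with open(path, "w") as fh:
        fh.write(f"# orthomir {__version__}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
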