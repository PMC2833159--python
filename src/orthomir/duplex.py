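"""Intermolecular miRNA:3'-UTR duplex prediction by free-energy minimization.

The model scores a duplex as bimolecular initiation plus nearest-neighbor
stacking free energies over consecutive base pairs (Watson-Crick and G-U
wobble), with affine penalties for bulges and internal loops.  The structure
space is every antiparallel, non-crossing set of pairs between the UTR
(5'→3') and the miRNA (3'→5' against it) -- no intramolecular structure, no
branching.  The minimum is found by a Gotoh-style dynamic program with four
states (helix, UTR-side bulge, miRNA-side bulge, internal loop) that runs in
O(N·L) time; suboptimal non-overlapping sites are enumerated greedily by
masking each reported site and re-running.

Watson-Crick stack free energies are the Xia/Turner 37°C nearest-neighbor
measurements.  Stacks involving G-U pairs are approximated by looking up the
stack with each G·U replaced by A·U and adding a destabilization offset per
wobble pair; absolute energies therefore approximate, but do not bit-match,
other duplex predictors, and the -17 kcal/mol screening cutoff is exposed as
a configurable parameter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from orthomir.families import SEED_LEN, SEED_OFFSET_LABELS
from orthomir.io import MatureMiRNA, UTRRecord, normalize_rna

logger = logging.getLogger(__name__)

BIG = 1e9

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_BASES = "ACGU"

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

# Xia et al. Watson-Crick nearest-neighbor stacks, kcal/mol at 37°C,
# keyed 5'-xy-3' (top) / 3'-wz-5' (bottom): key = (x, w, y, z) with pairs x·w, y·z.
_XIA_WC: dict[tuple[str, str, str, str], float] = {
    ("A", "U", "A", "U"): -0.93,
    ("A", "U", "U", "A"): -1.10,
    ("U", "A", "A", "U"): -1.33,
    ("C", "G", "U", "A"): -2.08,
    ("C", "G", "A", "U"): -2.11,
    ("G", "C", "U", "A"): -2.24,
    ("G", "C", "A", "U"): -2.35,
    ("C", "G", "G", "C"): -2.36,
    ("G", "C", "G", "C"): -3.26,
    ("G", "C", "C", "G"): -3.42,
}


def _wc_stack_table() -> dict[tuple[str, str, str, str], float]:
    """All 16 WC/WC stacks, filled from the 10 unique values by symmetry.

    Reading a stack from the other strand maps (x,w,y,z) → (z,y,w,x).
    """
    table = dict(_XIA_WC)
    for (x, w, y, z), dg in _XIA_WC.items():
        table.setdefault((z, y, w, x), dg)
    assert len(table) == 16
    return table


def _map_wobble(top: str, bottom: str) -> tuple[str, str]:
    """Replace a G·U pair by the A·U pair obtained by substituting the G."""
    if (top, bottom) == ("G", "U"):
        return ("A", "U")
    if (top, bottom) == ("U", "G"):
        return ("U", "A")
    return (top, bottom)


@dataclass
class EnergyModel:
    """Nearest-neighbor duplex energy parameters (kcal/mol).

    ``bulge_dG`` and ``internal_loop_dG`` are affine in total loop length with
    a shared extension coefficient ``loop_ext`` (required for the O(N·L) DP).
    """

    init_dG: float = 4.09
    bulge_open: float = 3.0
    internal_open: float = 1.7
    loop_ext: float = 0.55
    wobble_offset: float = 0.45
    version_tag: str = "orthomir-nn-1"
    stack_dG: dict[tuple[str, str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stack_dG:
            self.stack_dG = self._build_stacks()
        self._validate()
        self._stack_arr, self._pair_ok = self._to_arrays()

    def _build_stacks(self) -> dict[tuple[str, str, str, str], float]:
        wc = _wc_stack_table()
        pairs = sorted(WC_PAIRS | GU_PAIRS)
        table: dict[tuple[str, str, str, str], float] = {}
        for (x, w), (y, z) in itertools.product(pairs, pairs):
            n_gu = ((x, w) in GU_PAIRS) + ((y, z) in GU_PAIRS)
            mx, mw = _map_wobble(x, w)
            my, mz = _map_wobble(y, z)
            table[(x, w, y, z)] = wc[(mx, mw, my, mz)] + self.wobble_offset * n_gu
        return table

    def _validate(self) -> None:
        for (x, w, y, z), dg in self.stack_dG.items():
            if (x, w) in WC_PAIRS and (y, z) in WC_PAIRS and dg >= 0:
                raise ValueError(f"WC/WC stack {x}{y}/{w}{z} must be negative, got {dg}")
        if self.bulge_dG(1) < 0 or self.internal_loop_dG(1, 1) < 0:
            raise ValueError("loop penalties must be non-negative")

    def bulge_dG(self, length: int) -> float:
        if length < 1:
            raise ValueError("bulge length must be >= 1")
        return self.bulge_open + self.loop_ext * length

    def internal_loop_dG(self, len1: int, len2: int) -> float:
        if len1 < 1 or len2 < 1:
            raise ValueError("internal loop side lengths must be >= 1")
        return self.internal_open + self.loop_ext * (len1 + len2)

    def loop_dG(self, gap_utr: int, gap_mirna: int) -> float:
        """Penalty between consecutive pairs with the given unpaired lengths."""
        if gap_utr == 0 and gap_mirna == 0:
            return 0.0
        if gap_mirna == 0:
            return self.bulge_dG(gap_utr)
        if gap_utr == 0:
            return self.bulge_dG(gap_mirna)
        return self.internal_loop_dG(gap_utr, gap_mirna)

    def stack(self, utr5: str, mir5: str, utr3: str, mir3: str) -> float:
        """Stack energy for pair (utr5·mir5) followed 3'-ward by (utr3·mir3)."""
        return self.stack_dG[(utr5, mir5, utr3, mir3)]

    def pairable(self, top: str, bottom: str) -> bool:
        return (top, bottom) in WC_PAIRS or (top, bottom) in GU_PAIRS

    def _to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        stack = np.full((4, 4, 4, 4), BIG)
        ok = np.zeros((4, 4), dtype=np.bool_)
        for (x, w), ispair in [((a, b), self.pairable(a, b)) for a in _BASES for b in _BASES]:
            ok[_CODE[x], _CODE[w]] = ispair
        for (x, w, y, z), dg in self.stack_dG.items():
            stack[_CODE[x], _CODE[w], _CODE[y], _CODE[z]] = dg
        return stack, ok


@dataclass
class DuplexHit:
    """One predicted miRNA:UTR duplex.

    ``pairs`` lists ``(utr_pos, mirna_pos, pair_class)`` with 1-based
    coordinates, strictly increasing in ``utr_pos`` and strictly decreasing in
    ``mirna_pos`` (antiparallel, non-crossing); ``pair_class`` is ``"WC"`` or
    ``"GU"``.  ``dist_from_stop`` is the gap between the UTR 5' end (stop
    codon) and the site; ``dist_from_3end`` the gap to the UTR 3' end.
    """

    mirna_id: str
    transcript_id: str
    gene_id: str
    species: str
    pairs: tuple[tuple[int, int, str], ...]
    dG: float
    site_start: int
    site_end: int
    utr_length: int
    family: str | None = None
    seed_offset_label: str | None = None

    def __post_init__(self) -> None:
        ups = [p[0] for p in self.pairs]
        mps = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(ups, ups[1:])) or any(b >= a for a, b in zip(mps, mps[1:])):
            raise ValueError("pairs must increase in utr_pos and decrease in mirna_pos")
        if self.pairs and (self.site_start != min(ups) or self.site_end != max(ups)):
            raise ValueError("site_start/site_end inconsistent with pairs")

    @property
    def dist_from_stop(self) -> int:
        return self.site_start - 1

    @property
    def dist_from_3end(self) -> int:
        return self.utr_length - self.site_end

    def utr_pos_of(self, mirna_pos: int) -> int | None:
        for up, mp, _ in self.pairs:
            if mp == mirna_pos:
                return up
        return None

    def encode_pairs(self) -> str:
        return ",".join(f"{u}:{m}:{c}" for u, m, c in self.pairs)

    @staticmethod
    def decode_pairs(text: str) -> tuple[tuple[int, int, str], ...]:
        out = []
        for tok in str(text).split(","):
            u, m, c = tok.split(":")
            out.append((int(u), int(m), c))
        return tuple(out)


# ---------------------------------------------------------------------------
# DP kernel.  States: H = last position is a pair; BU/BM = open bulge on the
# UTR/miRNA side; I = open internal loop.  The miRNA is indexed reversed
# (k = 0 is its 3' end) so both indices increase along the duplex.

def _dp_kernel(u, r, mask, pair_ok, stack, init_dg, b_open, i_open, ext):
    N = u.shape[0]
    L = r.shape[0]
    H = np.full((N, L), BIG)
    BU = np.full((N, L), BIG)
    BM = np.full((N, L), BIG)
    IL = np.full((N, L), BIG)
    bpH = np.full((N, L), -1, dtype=np.int8)
    bpU = np.full((N, L), -1, dtype=np.int8)
    bpM = np.full((N, L), -1, dtype=np.int8)
    bpI = np.full((N, L), -1, dtype=np.int8)
    sw = i_open - b_open
    for i in range(N):
        for k in range(L):
            # UTR-side bulge ending at unpaired utr position i, last pair at mirna index k
            bu = BIG
            bub = -1
            if i > 0:
                v = H[i - 1, k] + b_open + ext
                if v < bu:
                    bu = v
                    bub = 0
                v = BU[i - 1, k] + ext
                if v < bu:
                    bu = v
                    bub = 1
            BU[i, k] = bu
            bpU[i, k] = bub
            # miRNA-side bulge
            bm = BIG
            bmb = -1
            if k > 0:
                v = H[i, k - 1] + b_open + ext
                if v < bm:
                    bm = v
                    bmb = 0
                v = BM[i, k - 1] + ext
                if v < bm:
                    bm = v
                    bmb = 1
            BM[i, k] = bm
            bpM[i, k] = bmb
            # internal loop (both sides have at least one unpaired position)
            il = BIG
            ilb = -1
            if k > 0:
                v = BU[i, k - 1] + sw + ext
                if v < il:
                    il = v
                    ilb = 0
            if i > 0:
                v = BM[i - 1, k] + sw + ext
                if v < il:
                    il = v
                    ilb = 1
                v = IL[i - 1, k] + ext
                if v < il:
                    il = v
                    ilb = 2
            if k > 0:
                v = IL[i, k - 1] + ext
                if v < il:
                    il = v
                    ilb = 3
            IL[i, k] = il
            bpI[i, k] = ilb
            # helix: position i pairs with miRNA (reversed) position k
            h = BIG
            hb = -1
            if mask[i] and pair_ok[u[i], r[k]]:
                if i > 0 and k > 0:
                    v = H[i - 1, k - 1] + stack[u[i - 1], r[k - 1], u[i], r[k]]
                    if v < h:
                        h = v
                        hb = 1
                    v = BU[i - 1, k - 1]
                    if v < h:
                        h = v
                        hb = 2
                    v = BM[i - 1, k - 1]
                    if v < h:
                        h = v
                        hb = 3
                    v = IL[i - 1, k - 1]
                    if v < h:
                        h = v
                        hb = 4
                v = init_dg
                if v < h:
                    h = v
                    hb = 0
            H[i, k] = h
            bpH[i, k] = hb
    return H, BU, BM, IL, bpH, bpU, bpM, bpI


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _dp_kernel = njit(cache=True)(_dp_kernel)
except Exception:  # noqa: BLE001 - numba optional at runtime
    logger.warning("numba unavailable; duplex DP runs in pure Python")


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _traceback(i: int, k: int, bpH, bpU, bpM, bpI) -> list[tuple[int, int]]:
    """Recover the pair list ending at H cell (i, k); 0-based (utr, rev-mirna)."""
    pairs = [(i, k)]
    state = 0  # 0=H,1=BU,2=BM,3=IL
    while True:
        if state == 0:
            code = bpH[i, k]
            if code == 0:
                break
            i, k = i - 1, k - 1
            state = {1: 0, 2: 1, 3: 2, 4: 3}[int(code)]
            if state == 0:
                pairs.append((i, k))
        elif state == 1:
            code = bpU[i, k]
            i -= 1
            state = 0 if code == 0 else 1
            if state == 0:
                pairs.append((i, k))
        elif state == 2:
            code = bpM[i, k]
            k -= 1
            state = 0 if code == 0 else 2
            if state == 0:
                pairs.append((i, k))
        else:
            code = bpI[i, k]
            if code == 0:
                k -= 1
                state = 1
            elif code == 1:
                i -= 1
                state = 2
            elif code == 2:
                i -= 1
                state = 3
            else:
                k -= 1
                state = 3
    pairs.reverse()
    return pairs


def hybridize(
    mirna: MatureMiRNA,
    utr: UTRRecord,
    model: EnergyModel | None = None,
    stop_dg: float = 0.0,
    max_sites: int = 10,
) -> list[DuplexHit]:
    """Greedy enumeration of non-overlapping candidate duplex sites.

    Repeatedly finds the minimum free-energy duplex over the whole UTR, masks
    its span, and re-runs, until the best attainable dG is ≥ ``stop_dg`` or
    ``max_sites`` sites were reported.  Hits come back sorted by ascending dG;
    no seed or dG filtering is applied here (see :func:`screen_step1`).
    """
    model = model or DEFAULT_MODEL
    mseq = mirna.sequence
    useq = utr.sequence
    if len(useq) < SEED_LEN:
        return []
    u = _encode(useq)
    r = _encode(mseq[::-1])
    L = len(mseq)
    mask = np.ones(len(u), dtype=np.bool_)
    hits: list[DuplexHit] = []
    for _ in range(max_sites):
        H, BU, BM, IL, bpH, bpU, bpM, bpI = _dp_kernel(
            u, r, mask, model._pair_ok, model._stack_arr,
            model.init_dG, model.bulge_open, model.internal_open, model.loop_ext,
        )
        best = H.min()
        if best >= stop_dg or best >= BIG / 2:
            break
        # deterministic cell choice on ties: smallest utr end, then largest k
        cand = np.argwhere(H == best)
        cand = sorted((int(i), -int(k)) for i, k in cand)
        ci, ck = cand[0][0], -cand[0][1]
        cells = _traceback(ci, ck, bpH, bpU, bpM, bpI)
        pairs = []
        for i, k in cells:
            top, bottom = useq[i], mseq[L - 1 - k]
            cls = "GU" if (top, bottom) in GU_PAIRS else "WC"
            pairs.append((i + 1, L - k, cls))
        site_start, site_end = pairs[0][0], pairs[-1][0]
        hits.append(
            DuplexHit(
                mirna_id=mirna.mirna_id,
                transcript_id=utr.transcript_id,
                gene_id=utr.gene_id,
                species=utr.species,
                pairs=tuple(pairs),
                dG=float(best),
                site_start=site_start,
                site_end=site_end,
                utr_length=len(useq),
                family=mirna.family,
            )
        )
        mask[site_start - 1 : site_end] = False
    hits.sort(key=lambda h: (h.dG, h.site_start))
    return hits


def seed_constraint(hit: DuplexHit, mirna: MatureMiRNA | str) -> bool:
    """Complete seed match: one 7-nt window fully paired with no internal bulge.

    Windows are scanned in the order 1-7, 2-8, 3-9; G-U pairs are allowed
    (they are penalized later as the ``gu_seed`` binding feature).  On success
    the first satisfying label is recorded on ``hit.seed_offset_label``.
    """
    seq = mirna if isinstance(mirna, str) else mirna.sequence
    if len(seq) < 9:
        raise ValueError("miRNA shorter than 9 nt has no seed windows")
    pos_map = {mp: up for up, mp, _ in hit.pairs}
    for label in SEED_OFFSET_LABELS:
        start = int(label.split("-")[0])
        window = range(start, start + SEED_LEN)
        ups = [pos_map.get(m) for m in window]
        if any(p is None for p in ups):
            continue
        # antiparallel: consecutive miRNA positions must pair consecutive
        # UTR positions, descending as the miRNA position rises
        if all(ups[t] == ups[0] - t for t in range(1, SEED_LEN)):
            hit.seed_offset_label = label
            return True
    return False


def screen_step1(
    mirnas: Iterable[MatureMiRNA],
    utrs: Iterable[UTRRecord],
    model: EnergyModel | None = None,
    dG_max: float = -17.0,
    match_species: bool = True,
    collapse_per_gene: bool = True,
    progress: Callable | None = None,
) -> list[DuplexHit]:
    """Step 1: retain duplexes with dG strictly below ``dG_max`` and a complete
    seed match.

    Each miRNA is scanned against the UTRs of its own species unless
    ``match_species`` is off (used by the species-specific-miRNA control,
    which runs one miRNA against every species).  With ``collapse_per_gene``
    only the lowest-dG hit per (miRNA-or-family, gene, species) survives.
    """
    model = model or DEFAULT_MODEL
    utrs = list(utrs)
    hits: list[DuplexHit] = []
    for mirna in mirnas:
        for utr in utrs:
            if match_species and utr.species != mirna.species:
                continue
            for hit in hybridize(mirna, utr, model, stop_dg=dG_max):
                if hit.dG < dG_max and seed_constraint(hit, mirna):
                    hits.append(hit)
            if progress is not None:
                progress()
    if collapse_per_gene:
        best: dict[tuple, DuplexHit] = {}
        for h in hits:
            key = (h.family or h.mirna_id, h.gene_id, h.species)
            cur = best.get(key)
            if cur is None or (h.dG, h.site_start) < (cur.dG, cur.site_start):
                best[key] = h
        hits = list(best.values())
    hits.sort(key=lambda h: (h.species, h.family or h.mirna_id, h.gene_id, h.dG))
    return hits


#: Shared default parameterization.
DEFAULT_MODEL = EnergyModel()
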