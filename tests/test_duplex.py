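import numpy as np
import pytest

from conftest import random_rna
from oracles import enumerate_min_dg, naive_min_dg

from orthomir.duplex import (
    DuplexHit,
    EnergyModel,
    GU_PAIRS,
    WC_PAIRS,
    hybridize,
    screen_step1,
    seed_constraint,
)
from orthomir.io import MatureMiRNA, UTRRecord
from orthomir.simulate import _revcomp


def _mirna(seq, mid="hsa-mir-t", sp="H. sapiens", family=None):
    return MatureMiRNA(mid, sp, seq, family=family)


def _utr(seq, tid="T1", gene="G1", sp="H. sapiens"):
    return UTRRecord(tid, gene, sp, seq)


class TestEnergyModel:
    def test_wc_stacks_negative_and_complete(self, model):
        pairs = sorted(WC_PAIRS | GU_PAIRS)
        for p1 in pairs:
            for p2 in pairs:
                dg = model.stack_dG[(p1[0], p1[1], p2[0], p2[1])]
                if p1 in WC_PAIRS and p2 in WC_PAIRS:
                    assert dg < 0

    def test_loop_penalties_monotone(self, model):
        bulges = [model.bulge_dG(n) for n in range(1, 8)]
        assert bulges == sorted(bulges) and bulges[0] >= 0
        loops = [model.internal_loop_dG(n, n) for n in range(1, 6)]
        assert loops == sorted(loops) and loops[0] >= 0

    def test_strand_symmetry_of_stack_table(self, model):
        # reading a stack from the opposite strand gives the same energy
        for (x, w, y, z), dg in model.stack_dG.items():
            assert model.stack_dG[(z, y, w, x)] == pytest.approx(dg)


class TestHybridize:
    def test_perfect_complement_energy_decomposition(self, model):
        """An exactly complementary site must score init + the hand-summed
        stack entries of its helix."""
        mseq = "UGAGGUAGUAGGUUGUAUAGUU"
        site = _revcomp(mseq)
        utr = _utr("AAAC" + site + "CAAA")
        hits = hybridize(_mirna(mseq), utr, model)
        assert len(hits) == 1
        h = hits[0]
        assert len(h.pairs) == len(mseq)
        assert all(c == "WC" for _, _, c in h.pairs)
        expected = model.init_dG
        for (u1, m1, _), (u2, m2, _) in zip(h.pairs, h.pairs[1:]):
            expected += model.stack(
                utr.sequence[u1 - 1], mseq[m1 - 1], utr.sequence[u2 - 1], mseq[m2 - 1]
            )
        assert h.dG == pytest.approx(expected)
        assert (h.site_start, h.site_end) == (5, 4 + len(site))
        assert h.dist_from_stop == 4 and h.dist_from_3end == 4

    def test_matches_full_enumeration_on_tiny_instances(self, model):
        """DP minimum equals brute-force enumeration of every legal pairing."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            mseq = random_rna(rng, int(rng.integers(5, 7)))
            useq = random_rna(rng, int(rng.integers(6, 9)))
            dp = _best_dg(mseq, useq, model)
            assert dp == pytest.approx(enumerate_min_dg(mseq, useq, model))

    def test_matches_naive_dp_oracle(self, model):
        rng = np.random.default_rng(7)
        for _ in range(40):
            mseq = random_rna(rng, int(rng.integers(8, 11)))
            useq = random_rna(rng, int(rng.integers(12, 17)))
            assert _best_dg(mseq, useq, model) == pytest.approx(naive_min_dg(mseq, useq, model))

    def test_unpairable_flanks_leave_dg_unchanged(self, model):
        """Padding the UTR with bases the miRNA cannot pair must not change
        the minimum free energy."""
        rng = np.random.default_rng(11)
        mseq = "".join(rng.choice(list("AC"), size=16))  # pairs only U/G
        useq = random_rna(rng, 30)
        base = _best_dg(mseq, useq, model)
        padded = "AC" * 6 + useq + "CA" * 6
        assert _best_dg(mseq, padded, model) == pytest.approx(base)

    def test_short_utr_returns_nothing(self, model):
        assert hybridize(_mirna("UGAGGUAGUAGGUUGUAUAGUU"), _utr("ACGUA"), model) == []

    def test_multiple_nonoverlapping_sites(self, model):
        mseq = "UGAGGUAGUAGGUUGUAUAGUU"
        site = _revcomp(mseq)
        utr = _utr("AA" + site + "AAAAAA" + site + "AA")
        hits = hybridize(_mirna(mseq), utr, model)
        strong = [h for h in hits if h.dG < -17.0]
        assert len(strong) == 2
        spans = sorted((h.site_start, h.site_end) for h in strong)
        assert spans[0][1] < spans[1][0]  # non-overlapping


def _best_dg(mseq, useq, model):
    # call the DP kernel directly so oracle-scale sequences (shorter than a
    # real mature miRNA) can be scored
    from orthomir import duplex as dx

    u = dx._encode(useq)
    r = dx._encode(mseq[::-1])
    mask = np.ones(len(u), dtype=np.bool_)
    H, *_ = dx._dp_kernel(
        u, r, mask, model._pair_ok, model._stack_arr,
        model.init_dG, model.bulge_open, model.internal_open, model.loop_ext,
    )
    best = float(H.min())
    return float("inf") if best >= dx.BIG / 2 else best


class TestSeedConstraint:
    def test_full_helix_gets_first_label(self, model):
        mseq = "UGAGGUAGUAGGUUGUAUAGUU"
        utr = _utr("AA" + _revcomp(mseq) + "AA")
        h = hybridize(_mirna(mseq), utr, model)[0]
        assert seed_constraint(h, mseq) is True
        assert h.seed_offset_label == "1-7"

    def test_unpaired_position4_fails_all_windows(self):
        # hand-built hit: miRNA position 4 missing from the pairs
        pairs = tuple(
            sorted(((20 - k, k + 1, "WC") for k in range(0, 12) if k + 1 != 4))
        )
        hit = DuplexHit("m", "t", "g", "H. sapiens", pairs, -20.0, min(p[0] for p in pairs),
                        max(p[0] for p in pairs), 40)
        assert seed_constraint(hit, "UGAGGUAGUAGGUUGUAUAGUU") is False
        assert hit.seed_offset_label is None

    def test_gu_in_seed_is_allowed(self, model):
        """A contiguous seed containing a G-U wobble still satisfies the
        complete-match requirement (wobbles are penalized later, in step 2)."""
        mseq = "UGAGGUAGUAGGUUGUAUAGUU"
        site = list(_revcomp(mseq))
        # miRNA position 5 is G; give the UTR a U there instead of C → G-U
        pos = len(site) - 5
        assert site[pos] == "C"
        site[pos] = "U"
        utr = _utr("AAA" + "".join(site) + "AAA")
        h = hybridize(_mirna(mseq), utr, model)[0]
        assert ("GU" in {c for _, m, c in h.pairs if m <= 7})
        assert seed_constraint(h, mseq) is True

    def test_bulge_inside_window_fails(self):
        # miRNA 1..8 paired but with a UTR bulge between positions 4 and 5
        ups = [30, 29, 28, 27, 25, 24, 23, 22]
        pairs = tuple(sorted((u, k + 1, "WC") for k, u in enumerate(ups)))
        hit = DuplexHit("m", "t", "g", "H. sapiens", pairs, -20.0, 22, 30, 40)
        assert seed_constraint(hit, "UGAGGUAGUAGGUUGUAUAGUU") is False


class TestScreenStep1:
    def test_boundary_is_strict(self, model):
        """A hit at exactly the cutoff is excluded (dG must be < dG_max)."""
        mseq = "UGAGGUAGUAGGUUGUAUAGUU"
        utr = _utr("AA" + _revcomp(mseq) + "AA")
        h = hybridize(_mirna(mseq), utr, model)[0]
        at_cut = screen_step1([_mirna(mseq)], [utr], model, dG_max=h.dG)
        below_cut = screen_step1([_mirna(mseq)], [utr], model, dG_max=h.dG - 1e-6)
        above_cut = screen_step1([_mirna(mseq)], [utr], model, dG_max=h.dG + 1e-6)
        assert at_cut == [] and below_cut == []
        assert len(above_cut) == 1

    def test_tightening_cutoff_never_adds_hits(self, small_corpus, model):
        fam = small_corpus.family_names[0]
        mirnas = [
            m for sp in small_corpus.mirnas_by_species.values() for m in sp if m.family == fam
        ]
        loose = screen_step1(mirnas, small_corpus.utrs, model, dG_max=-15.0)
        tight = screen_step1(mirnas, small_corpus.utrs, model, dG_max=-25.0)
        key = lambda h: (h.mirna_id, h.gene_id, h.species)
        assert {key(h) for h in tight} <= {key(h) for h in loose}
        assert all(h.seed_offset_label is not None for h in loose)

    def test_planted_sites_recovered(self, small_corpus, model):
        mirnas = [m for sp in small_corpus.mirnas_by_species.values() for m in sp if m.family]
        hits = screen_step1(mirnas, small_corpus.utrs, model)
        found = {(h.family, h.gene_id, h.species) for h in hits}
        planted = {
            (r.family, r.gene_id, r.species) for r in small_corpus.truth.itertuples(index=False)
        }
        assert planted <= found

    def test_empty_mirna_set(self, small_corpus, model):
        assert screen_step1([], small_corpus.utrs, model) == []
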