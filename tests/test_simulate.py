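import numpy as np
import pytest

from orthomir.families import extract_conserved_families, seed_variants
from orthomir.simulate import FixtureSpec, SyntheticCorpus, generate_corpus, plant_features


def _read_all(paths):
    return {k: p.read_bytes() for k, p in paths.items()}


class TestGenerateCorpus:
    def test_same_seed_byte_identical(self, tmp_path):
        spec = FixtureSpec(seed=13, n_clusters=10, n_genes_per_species=12,
                           n_planted_conserved_sites=4, n_planted_partial_sites=2,
                           n_verified_pairs=4)
        a = generate_corpus(spec).write(tmp_path / "a")
        b = generate_corpus(spec).write(tmp_path / "b")
        assert _read_all(a) == _read_all(b)

    def test_different_seed_differs(self, tmp_path):
        base = dict(n_clusters=10, n_genes_per_species=12, n_planted_conserved_sites=4,
                    n_planted_partial_sites=2, n_verified_pairs=4)
        a = generate_corpus(FixtureSpec(seed=1, **base)).write(tmp_path / "a")
        b = generate_corpus(FixtureSpec(seed=2, **base)).write(tmp_path / "b")
        assert _read_all(a) != _read_all(b)

    def test_no_families_requested(self):
        spec = FixtureSpec(seed=4, n_conserved_families=0, n_planted_conserved_sites=0,
                           n_planted_partial_sites=0, n_verified_pairs=0,
                           n_clusters=5, n_genes_per_species=6)
        corpus = generate_corpus(spec)
        assert extract_conserved_families(corpus.mirnas_by_species) == []

    def test_family_members_share_seed_and_identity(self, small_corpus):
        for fam in small_corpus.family_names:
            members = [
                m for ms in small_corpus.mirnas_by_species.values() for m in ms if m.family == fam
            ]
            assert len(members) == len(small_corpus.species)
            seeds = [{w.seed_seq for w in seed_variants(m)} for m in members]
            assert set.intersection(*seeds)

    def test_truth_sites_are_actual_subsequences(self, small_corpus):
        """Planted site coordinates in the truth table point at the reverse
        complement of the family member (up to planted wobbles/mutations)."""
        from orthomir.simulate import _revcomp

        utr_by_key = {(u.species, u.gene_id): u.sequence for u in small_corpus.utrs}
        members = {
            (m.family, m.species): m.sequence
            for ms in small_corpus.mirnas_by_species.values()
            for m in ms
            if m.family
        }
        for r in small_corpus.truth.itertuples(index=False):
            site = utr_by_key[(r.species, r.gene_id)][r.site_start - 1 : r.site_end]
            expected = _revcomp(members[(r.family, r.species)])
            assert len(site) == len(expected)
            diffs = sum(1 for x, y in zip(site, expected) if x != y)
            assert diffs == r.n_gu  # mutation rate 0: only wobble substitutions

    def test_conserved_sites_span_at_least_four_species(self, small_corpus):
        truth = small_corpus.truth
        cons = truth[truth.stage == "conserved"].groupby(["family", "cluster_id"])
        for _, grp in cons:
            assert grp["species"].nunique() >= 4
            assert small_corpus.species[0] in set(grp["species"])
        part = truth[truth.stage == "partial"].groupby(["family", "cluster_id"])
        for _, grp in part:
            assert grp["species"].nunique() < 4

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="planted sites"):
            FixtureSpec(n_conserved_families=1, n_clusters=2, n_genes_per_species=2,
                        n_planted_conserved_sites=3, n_planted_partial_sites=0)
        with pytest.raises(ValueError, match="genes"):
            FixtureSpec(n_clusters=10, n_genes_per_species=5)

    def test_utr_too_short_to_host_site(self):
        spec = FixtureSpec(seed=0, utr_length_range=(10, 12), n_clusters=5,
                           n_genes_per_species=6, n_planted_conserved_sites=2,
                           n_planted_partial_sites=0, n_verified_pairs=2)
        with pytest.raises(ValueError, match="too short"):
            generate_corpus(spec)


class TestPlantFeatures:
    def test_planted_distributions(self):
        df, flags, cut = plant_features(cut=(2, 1, 1, 0), n_verified=50, n_decoys=500, seed=6)
        ver = df[flags]
        dec = df[~flags]
        for name, c in zip(df.columns, cut):
            assert ver[name].max() <= c
        assert dec["mm_mrna"].max() > 2  # decoys diffuse over the scanned range

    def test_all_zero_features_full_coverage_everywhere(self):
        from orthomir.features import FEATURE_NAMES
        from orthomir.optimizer import coverage_curve

        df, flags, _ = plant_features(cut=(0, 0, 0, 0), n_verified=10, n_decoys=0, seed=0)
        df2 = df.copy()
        for n in FEATURE_NAMES:
            df2[n] = 0
        c = coverage_curve(df2, [True] * len(df2), "mm_mrna")
        assert set(c.cov_verified) == {1.0}

    def test_out_of_range_cut_rejected(self):
        with pytest.raises(ValueError, match="scanned ranges"):
            plant_features(cut=(40, 1, 1, 0))
        with pytest.raises(ValueError, match="infeasible"):
            plant_features(cut=(2, 1, 0, 3))


class TestRecallUnderMutation:
    def test_recall_decreases_with_mutation_rate(self, model):
        """Planted-site recall is perfect at mutation rate 0 and degrades as
        sites are randomly substituted."""
        from orthomir.duplex import screen_step1

        def recall(rate, seed):
            spec = FixtureSpec(seed=seed, n_clusters=8, n_genes_per_species=10,
                               n_conserved_families=2, n_planted_conserved_sites=4,
                               n_planted_partial_sites=0, n_verified_pairs=4,
                               site_mutation_rate=rate)
            corpus = generate_corpus(spec)
            mirnas = [m for ms in corpus.mirnas_by_species.values() for m in ms if m.family]
            hits = screen_step1(mirnas, corpus.utrs, model)
            found = {(h.family, h.gene_id, h.species) for h in hits}
            planted = {
                (r.family, r.gene_id, r.species) for r in corpus.truth.itertuples(index=False)
            }
            return len(found & planted) / len(planted)

        r0 = np.mean([recall(0.0, s) for s in range(3)])
        r_hi = np.mean([recall(0.35, s) for s in range(3)])
        assert r0 == 1.0
        assert r_hi < r0
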