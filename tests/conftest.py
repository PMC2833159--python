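import numpy as np
import pytest

from orthomir.duplex import DEFAULT_MODEL
from orthomir.pipeline import PipelineConfig
from orthomir.simulate import FixtureSpec, generate_corpus

_BASES = "ACGU"


@pytest.fixture(scope="session")
def model():
    return DEFAULT_MODEL


@pytest.fixture(scope="session")
def small_corpus():
    """A compact planted corpus shared by the fast stage-level tests."""
    spec = FixtureSpec(
        seed=7,
        n_clusters=30,
        n_genes_per_species=40,
        n_conserved_families=3,
        n_planted_conserved_sites=6,
        n_planted_partial_sites=4,
        n_verified_pairs=10,
    )
    return generate_corpus(spec)


@pytest.fixture()
def corpus_config(tmp_path):
    """Factory: write a SyntheticCorpus to disk and return a PipelineConfig."""

    def make(corpus, **overrides):
        paths = corpus.write(tmp_path / "fixtures")
        cfg = PipelineConfig(
            mirna_fasta=str(paths["mirnas"]),
            utr_fastas={sp: str(paths[f"utr:{sp}"]) for sp in corpus.species},
            ortholog_tsv=str(paths["orthologs"]),
            verified_tsv=str(paths["verified"]),
            outdir=str(tmp_path / "run"),
        )
        for key, val in overrides.items():
            setattr(cfg, key, val)
        return cfg

    return make


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))
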