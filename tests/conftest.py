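import numpy as np
import pandas as pd
import pytest

from genecentric import synthetic as syn


SMALL_DESIGN = [
    ("c1", "healthy", "control", 6),
    ("c1", "MASLD", "disease", 6),
    ("c2", "early", "control", 6),
    ("c2", "advanced", "disease", 6),
]


@pytest.fixture(scope="session")
def small_config() -> syn.TruthConfig:
    return syn.TruthConfig(
        n_families=4, n_uscg=2, s_range=(2, 4), length_range=(60, 120),
        cohort_design=list(SMALL_DESIGN), library_size_range=(50_000, 80_000),
        baseline_range=(200, 2000), seed=11,
    )


@pytest.fixture(scope="session")
def small_samples(small_config):
    return syn.simulate_cohort_design(small_config)


@pytest.fixture(scope="session")
def small_families(small_config):
    fasta, truths = syn.simulate_gene_families(small_config)
    return fasta, truths


@pytest.fixture(scope="session")
def small_hits(small_config, small_samples, small_families):
    _, truths = small_families
    return syn.simulate_alignment_hits(small_config, small_samples, truths)


@pytest.fixture(scope="session")
def screen_config() -> syn.ScreenTruthConfig:
    return syn.ScreenTruthConfig(
        clades=[syn.CladeSpec("Agathobacter", 200, species="Agathobacter rectalis"),
                syn.CladeSpec("Blautia", 200, species="Blautia wexlerae"),
                syn.CladeSpec("Gemmiger", 60)],
        prevalence={
            ("Agathobacter", "buk"): 0.85,
            ("Agathobacter", "yahK"): 0.50,
            ("Blautia", "buk"): 0.05,
            ("Blautia", "yahK"): 0.0,
            ("Gemmiger", "buk"): 0.5,
        },
        plasmid_counts={"yahK": 7, "buk": 2},
        seed=13,
    )


@pytest.fixture(scope="session")
def screen_inputs(screen_config):
    return syn.simulate_screen_inputs(screen_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
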