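import numpy as np
import pytest

import virotax as vt


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete synthetic cohort (segmented genera,
    several hosts, two recode pairs)."""
    cfg = vt.SyntheticConfig(
        seed=42,
        n_genera=12,
        members_per_genus=(3, 6),
        segmented_fraction=0.4,
        recode_pairs=2,
    )
    records, annotations, truth = vt.generate(cfg)
    return cfg, records, annotations, truth


@pytest.fixture(scope="session")
def small_assemblies(small_cohort):
    _, records, annotations, _ = small_cohort
    return vt.assemble_viruses(records, annotations)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_record(rng, length, accession="rnd"):
    bases = rng.choice(np.array(list("ACGT")), size=length)
    return vt.SequenceRecord(accession, accession, "".join(bases))
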