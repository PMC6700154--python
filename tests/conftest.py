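import numpy as np
import pytest

from mempot.structure_io import LabeledStructure, Residue

try:  # derandomize hypothesis wherever it is used
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_structure(specs, structure_id="TEST", topology="unknown"):
    """Build a LabeledStructure from (chain, aa, center, region) tuples."""
    residues = []
    counters = {}
    for spec in specs:
        chain, aa, center = spec[:3]
        region = spec[3] if len(spec) > 3 else "TM"
        counters[chain] = counters.get(chain, 0) + 1
        residues.append(
            Residue(chain_id=chain, seq_index=counters[chain], aa=aa,
                    center=np.asarray(center, float), region=region)
        )
    return LabeledStructure(structure_id, residues, topology_class=topology)


def random_structure(rng, n=50, structure_id="RAND", box=25.0, regions=("TM", "EM")):
    """A random single-chain structure for brute-force comparisons."""
    from mempot.aa import AA_ORDER

    specs = []
    for _ in range(n):
        specs.append(
            ("A",
             AA_ORDER[rng.integers(20)],
             rng.uniform(0, box, size=3),
             regions[rng.integers(len(regions))])
        )
    return make_structure(specs, structure_id=structure_id)


@pytest.fixture(scope="session")
def small_dataset():
    """Eight separable synthetic proteins, shared across tests."""
    from mempot.synthetic import default_config, generate_dataset

    return generate_dataset(default_config(8), seed=1)


@pytest.fixture(scope="session")
def loo_dataset():
    """Ten proteins for leave-one-out exactness checks."""
    from mempot.synthetic import default_config, generate_dataset

    return generate_dataset(default_config(10), seed=2)
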