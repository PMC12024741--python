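import math

import numpy as np
import pytest

from endoqc import FragmentLaw, SimulationConfig, simulate_reference

REF_LENGTH = 20000
REF_SEED = 11


@pytest.fixture(scope="session")
def reference_fasta() -> str:
    return simulate_reference(REF_LENGTH, gc=0.42, seed=REF_SEED)


@pytest.fixture(scope="session")
def reference_seq(reference_fasta) -> str:
    return "".join(reference_fasta.split("\n")[1:])


@pytest.fixture(scope="session")
def reference(reference_seq) -> dict[str, str]:
    return {"ref": reference_seq}


def default_law(mean_bp: float = 50.0, sigma: float = 0.25) -> FragmentLaw:
    return FragmentLaw("lognormal", mu=math.log(mean_bp), sigma=sigma, len_min=20, len_max=140)


def make_config(seed: int = 1, n_reads: int = 1000, endo: float = 0.8, **kw) -> SimulationConfig:
    kw.setdefault("fragment_law", default_law())
    return SimulationConfig(
        seed=seed,
        ref_length=REF_LENGTH,
        n_reads=n_reads,
        endogenous_fraction=endo,
        **kw,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
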