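import numpy as np
import pytest

from isoasm.params import AssemblyParams, validate


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240389)


@pytest.fixture
def default_params() -> AssemblyParams:
    return validate(AssemblyParams())


@pytest.fixture
def small_params() -> AssemblyParams:
    """Defaults with a small expansion sample for closure-equality tests."""
    return validate(AssemblyParams(expansion_sample=12, rng_seed=7))
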