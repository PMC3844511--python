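import numpy as np
import pytest

from famlrt import DyadCounts, FamilyDataset, MonadCounts, RiskModelParams, TriadCounts
from famlrt.model import dyad_probabilities, monad_probabilities, triad_probabilities

# Triad counts exactly proportional to the null cell probabilities at p = 0.5
# (16 families); the MLE under every model is then (p, psi1, psi2) = (0.5, 1, 1).
EXACT_NULL_TRIADS = (1, 2, 2, 2, 1, 2, 1, 2, 2, 1)


@pytest.fixture
def null_triads() -> TriadCounts:
    return TriadCounts(EXACT_NULL_TRIADS)


@pytest.fixture
def null_dataset(null_triads) -> FamilyDataset:
    return FamilyDataset(triads=null_triads)


def random_params(rng: np.random.Generator, psi_max: float = 5.0) -> RiskModelParams:
    return RiskModelParams(
        p=float(rng.uniform(0.05, 0.95)),
        psi1=float(rng.uniform(0.1, psi_max)),
        psi2=float(rng.uniform(0.1, psi_max)),
    )


def random_dataset(
    rng: np.random.Generator,
    n: int = 60,
    m: int = 30,
    s: int = 20,
    params: RiskModelParams | None = None,
) -> FamilyDataset:
    """A multinomial draw from the probability model itself."""
    params = params or random_params(rng)
    return FamilyDataset(
        triads=TriadCounts(rng.multinomial(n, triad_probabilities(params))),
        dyads=DyadCounts(rng.multinomial(m, dyad_probabilities(params))),
        monads=MonadCounts(*rng.multinomial(s, monad_probabilities(params))),
    )
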