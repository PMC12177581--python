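import numpy as np
import pytest

from igtrl import EEFAgent, EEFParams, build_bechara_scheme, generate_synthetic_cohort


class UniformAgent:
    """Chance-level chooser; ignores feedback."""

    def reset(self):
        pass

    def choice_probabilities(self):
        return np.full(4, 0.25)

    def update(self, deck, gain, loss):
        pass


class FixedDeckAgent:
    """Deterministically picks one deck forever."""

    def __init__(self, deck: int):
        self.deck = deck

    def reset(self):
        pass

    def choice_probabilities(self):
        p = np.zeros(4)
        p[self.deck - 1] = 1.0
        return p

    def update(self, deck, gain, loss):
        pass


@pytest.fixture(scope="session")
def scheme():
    return build_bechara_scheme()


@pytest.fixture
def uniform_agent():
    return UniformAgent()


@pytest.fixture(scope="session")
def small_eef_cohort():
    """Six EEF sessions with known generating parameters (fast fixture)."""
    return generate_synthetic_cohort("EEF", 6, 100, seed=42)


def make_eef_agent(lam=0.5, theta=0.5, phi=2.0, beta=2.0, la=1.0, use_prior=True):
    return EEFAgent(EEFParams(lam=lam, theta=theta, phi=phi, beta=beta, la=la),
                    use_prior=use_prior)
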