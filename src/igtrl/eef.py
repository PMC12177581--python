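"""The Exploitation and Exploration with Forgetting model (EEF) and its
loss-averse extension (EEFLA).

The model carries two per-deck latent weight vectors. The *exploitation*
weight of a deck accumulates scaled monetary utility and decays by a factor
(1 - lambda) per trial, so unused value information is forgotten at an
individual-specific rate. The *exploration* weight of an unchosen deck drifts
toward an exploration incentive phi at rate (1 - lambda) and resets to zero
when the deck is picked, so decks ignored for a while become (for phi > 0)
progressively more attractive. Choice probabilities are a softmax of the
summed weights scaled by a consistency C = 3**beta - 1.

Parameters
----------
lam : forgetting rate, in [0, 1]. lam = 1 means only the current trial's
    outcome matters; lam = 0 means nothing is ever forgotten.
theta : outcome sensitivity exponent, in [0, 1], applied separately to the
    (scaled) gain and loss magnitudes.
phi : exploration incentive, in [-5, 5]; the asymptote of an unchosen deck's
    exploration weight (negative phi discourages revisiting).
beta : inverse-temperature parameter, in [0, 5]; consistency C = 3**beta - 1,
    so beta = 0 gives uniform choice and beta = 5 gives C = 242.
la : loss aversion, in [0, 5]; multiplies the loss term of the utility.
    EEF fixes la = 1, EEFLA fits it.

Utilities are computed on currency divided by ``scale_divisor`` (default 100),
keeping weight magnitudes commensurate with the first-choice prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EEFParams",
    "LatentState",
    "PriorWeights",
    "FIRST_CHOICE_COUNTS",
    "utility",
    "consistency",
    "init_state",
    "update_state",
    "choice_probabilities",
    "derive_first_choice_prior",
    "default_first_choice_prior",
    "EEFAgent",
]

#: Pooled first choices over decks A-D in the public 504-participant
#: 100-trial dataset; the source of the default first-choice prior.
FIRST_CHOICE_COUNTS = (193, 126, 105, 80)

PARAM_BOUNDS = {
    "lam": (0.0, 1.0),
    "theta": (0.0, 1.0),
    "phi": (-5.0, 5.0),
    "beta": (0.0, 5.0),
}
LA_BOUNDS = (0.0, 5.0)


@dataclass(frozen=True)
class EEFParams:
    """EEF parameters; ``la`` (loss aversion) is only free in EEFLA."""

    lam: float
    theta: float
    phi: float
    beta: float
    la: float = 1.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not LA_BOUNDS[0] <= self.la <= LA_BOUNDS[1]:
            raise ValueError(f"la={self.la} outside {LA_BOUNDS}")


@dataclass(frozen=True)
class LatentState:
    """Per-deck exploitation and exploration weights at one trial."""

    exploitation: np.ndarray
    exploration: np.ndarray
    trial_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exploitation", np.asarray(self.exploitation, dtype=float))
        object.__setattr__(self, "exploration", np.asarray(self.exploration, dtype=float))
        if self.exploitation.shape != (4,) or self.exploration.shape != (4,):
            raise ValueError("state vectors must have shape (4,)")
        if not (np.all(np.isfinite(self.exploitation)) and np.all(np.isfinite(self.exploration))):
            raise ValueError("state must be finite")


@dataclass(frozen=True)
class PriorWeights:
    """Initial exploitation weights inverted from first-choice frequencies."""

    w_ini: np.ndarray
    beta_prior: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "w_ini", np.asarray(self.w_ini, dtype=float))
        if self.w_ini.shape != (4,):
            raise ValueError("w_ini must have 4 entries")
        if abs(self.w_ini.mean()) > 1e-9:
            raise ValueError("w_ini must be mean-centred")


def utility(gain: float, loss: float, theta: float, la: float = 1.0,
            scale_divisor: float = 100.0) -> float:
    """Subjective value of an outcome: (gain/s)**theta - la*(loss/s)**theta.

    ``loss`` is a magnitude. 0**theta is taken as 0 for any theta in [0, 1],
    so a no-gain or no-loss side contributes nothing.
    """
    if gain < 0 or loss < 0:
        raise ValueError("gain and loss must be non-negative magnitudes")
    s = scale_divisor
    g = (gain / s) ** theta if gain > 0 else 0.0
    l = (loss / s) ** theta if loss > 0 else 0.0
    return g - la * l


def consistency(beta: float) -> float:
    """Softmax consistency C = 3**beta - 1 for beta in [0, 5]."""
    if not 0.0 <= beta <= 5.0:
        raise ValueError(f"beta={beta} outside [0, 5]")
    return 3.0**beta - 1.0


def init_state(prior: PriorWeights | None = None) -> LatentState:
    """Fresh latent state: exploitation = prior weights (or zeros),
    exploration = zeros. The prior enters the exploitation channel so that it
    decays by (1 - lambda) per trial like any other value memory."""
    w = prior.w_ini.copy() if prior is not None else np.zeros(4)
    return LatentState(exploitation=w, exploration=np.zeros(4), trial_index=0)


def update_state(state: LatentState, choice: int, outcome, params: EEFParams,
                 scale_divisor: float = 100.0) -> LatentState:
    """One learning step after drawing ``choice`` (1-4) and observing
    ``outcome`` (anything with .gain and .loss magnitudes).

    Chosen deck:   exploitation <- (1-lam)*prev + V(t);   exploration <- 0
    Unchosen deck: exploitation <- (1-lam)*prev;
                   exploration  <- lam*prev + (1-lam)*phi

    Pure: the input state is not mutated.
    """
    if not 1 <= choice <= 4:
        raise ValueError(f"choice must be in 1..4, got {choice}")
    lam, phi = params.lam, params.phi
    v = utility(outcome.gain, outcome.loss, params.theta, params.la, scale_divisor)
    c = choice - 1
    exploit = (1.0 - lam) * state.exploitation
    explore = lam * state.exploration + (1.0 - lam) * phi
    exploit = exploit.copy()
    exploit[c] += v
    explore = explore.copy()
    explore[c] = 0.0
    return LatentState(exploitation=exploit, exploration=explore,
                       trial_index=state.trial_index + 1)


def choice_probabilities(state: LatentState, C: float) -> np.ndarray:
    """Softmax over w_d = (exploration_d + exploitation_d) * C, computed with
    max-subtraction for stability. C = 0 gives the uniform distribution."""
    if C < 0:
        raise ValueError("consistency must be >= 0")
    w = (state.exploration + state.exploitation) * C
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite choice weights")
    w = w - w.max()
    e = np.exp(w)
    return e / e.sum()


def derive_first_choice_prior(first_choice_counts=FIRST_CHOICE_COUNTS,
                              beta: float = 3.0) -> PriorWeights:
    """Invert pooled first-choice frequencies through the softmax.

    With p_d = count_d / total, the weights are the mean-centred log
    frequencies divided by C = 3**beta - 1, so that a fresh state built from
    them reproduces p exactly under ``choice_probabilities`` at that beta.
    """
    counts = np.asarray(first_choice_counts, dtype=float)
    if counts.shape != (4,):
        raise ValueError("need one count per deck")
    if np.any(counts <= 0):
        raise ValueError("all first-choice counts must be positive")
    C = consistency(beta)
    if C == 0:
        raise ValueError("beta=0 makes the softmax non-invertible")
    logp = np.log(counts / counts.sum())
    w = (logp - logp.mean()) / C
    return PriorWeights(w_ini=w, beta_prior=beta)


def default_first_choice_prior() -> PriorWeights:
    """The standard prior: counts (193, 126, 105, 80) inverted at beta = 3,
    giving w_ini ~= [0.0184, 0.0020, -0.0050, -0.0155]."""
    return derive_first_choice_prior(FIRST_CHOICE_COUNTS, beta=3.0)


class EEFAgent:
    """Agent wrapper exposing reset / choice_probabilities / update.

    ``prior`` defaults to the first-choice prior; pass ``prior=None`` via
    ``use_prior=False`` for a zero-initialized variant.
    """

    def __init__(self, params: EEFParams, prior: PriorWeights | None = None,
                 use_prior: bool = True, scale_divisor: float = 100.0):
        self.params = params
        self.prior = (prior if prior is not None else default_first_choice_prior()) if use_prior else None
        self.scale_divisor = scale_divisor
        self._C = consistency(params.beta)
        self.reset()

    def reset(self) -> None:
        self.state = init_state(self.prior)

    def choice_probabilities(self) -> np.ndarray:
        return choice_probabilities(self.state, self._C)

    def update(self, deck: int, gain: float, loss: float) -> None:
        from .env import TrialOutcome

        self.state = update_state(self.state, deck, TrialOutcome(gain, loss),
                                  self.params, self.scale_divisor)
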