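"""Baseline computational models of IGT choice, under the same agent
interface as the EEF model.

Formulations follow the original publications:

* EV — expected-valence delta-rule model (Busemeyer & Stout 2002).
* PVL — prospect-valence learning with decay-reinforcement (Ahn et al. 2008).
* PVL-Delta — prospect valence with a delta rule on the chosen deck
  (Ahn et al. 2008 "PVL-delta" hybrid).
* ORL — outcome-representation learning: separate reward/punishment learning
  rates plus win-frequency and perseveration signals (Haines et al. 2018).
* VPP — value-plus-perseveration, an 8-parameter PVL-Delta extension with a
  decaying perseveration trace (Worthy et al. 2013).
* VSE — value and sequential exploration: value module with multiplicative
  decay plus an exploration module with a delta rule toward an exploration
  bonus (Ligneul 2019).

All models consume currency scaled by the scheme's ``scale_divisor`` (default
100), as the EEF model does, so fitted consistency parameters live on
comparable scales. None of the baselines receives the first-choice prior;
their value traces start at zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BaselineAgent", "EVAgent", "PVLAgent", "PVLDeltaAgent",
           "ORLAgent", "VPPAgent", "VSEAgent"]


def _softmax(w: np.ndarray) -> np.ndarray:
    w = w - w.max()
    e = np.exp(w)
    return e / e.sum()


def _prospect(net: float, shape: float, loss_aversion: float) -> float:
    """Prospect utility of a net outcome: x**A for gains, -w*|x|**A for losses."""
    if net >= 0:
        return net**shape if net > 0 else 0.0
    return -loss_aversion * (-net) ** shape


class BaselineAgent:
    """Common plumbing: parameter dict, scaling, trial counter."""

    param_names: tuple[str, ...] = ()

    def __init__(self, params: dict, scale_divisor: float = 100.0):
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"{type(self).__name__} missing parameters {sorted(missing)}")
        self.params = {k: float(params[k]) for k in self.param_names}
        self.scale = scale_divisor
        self.reset()

    def reset(self) -> None:
        self.t = 0

    def update(self, deck: int, gain: float, loss: float) -> None:
        if not 1 <= deck <= 4:
            raise ValueError("deck must be in 1..4")
        self._learn(deck - 1, gain / self.scale, loss / self.scale)
        self.t += 1

    def _learn(self, d: int, gain: float, loss: float) -> None:  # pragma: no cover
        raise NotImplementedError


class EVAgent(BaselineAgent):
    """Expected-valence model: valence v = (1-w)*gain - w*loss, delta rule on
    the chosen deck, and trial-dependent sensitivity theta(t) = (t/10)**c."""

    param_names = ("w", "a", "c")

    def reset(self) -> None:
        super().reset()
        self.ev = np.zeros(4)

    def choice_probabilities(self) -> np.ndarray:
        theta = ((self.t + 1) / 10.0) ** self.params["c"]
        return _softmax(theta * self.ev)

    def _learn(self, d, gain, loss):
        v = (1.0 - self.params["w"]) * gain - self.params["w"] * loss
        self.ev[d] += self.params["a"] * (v - self.ev[d])


class PVLAgent(BaselineAgent):
    """Prospect-valence learning with the decay-reinforcement rule: every
    deck's valence decays by factor a each trial and the chosen deck's is
    incremented by the prospect utility. Sensitivity 3**c - 1."""

    param_names = ("shape", "loss_aversion", "decay", "c")

    def reset(self) -> None:
        super().reset()
        self.ev = np.zeros(4)

    def choice_probabilities(self) -> np.ndarray:
        return _softmax((3.0 ** self.params["c"] - 1.0) * self.ev)

    def _learn(self, d, gain, loss):
        u = _prospect(gain - loss, self.params["shape"], self.params["loss_aversion"])
        self.ev *= self.params["decay"]
        self.ev[d] += u


class PVLDeltaAgent(BaselineAgent):
    """Prospect utility with a delta rule on the chosen deck only."""

    param_names = ("shape", "loss_aversion", "a", "c")

    def reset(self) -> None:
        super().reset()
        self.ev = np.zeros(4)

    def choice_probabilities(self) -> np.ndarray:
        return _softmax((3.0 ** self.params["c"] - 1.0) * self.ev)

    def _learn(self, d, gain, loss):
        u = _prospect(gain - loss, self.params["shape"], self.params["loss_aversion"])
        self.ev[d] += self.params["a"] * (u - self.ev[d])


class ORLAgent(BaselineAgent):
    """Outcome-representation learning.

    Chosen-deck value learns with a reward (a_rew) or punishment (a_pun) rate
    depending on outcome sign; a win-frequency trace learns the outcome sign
    with a fictive update of the three unchosen decks; a perseveration trace
    is set to 1 on the chosen deck and decays by 1/(1+k) elsewhere. Decision
    weight: EV + beta_f*EF + beta_p*PS, softmax with unit sensitivity.
    """

    param_names = ("a_rew", "a_pun", "k", "beta_f", "beta_p")

    def reset(self) -> None:
        super().reset()
        self.ev = np.zeros(4)
        self.ef = np.zeros(4)
        self.ps = np.zeros(4)

    def choice_probabilities(self) -> np.ndarray:
        w = self.ev + self.params["beta_f"] * self.ef + self.params["beta_p"] * self.ps
        return _softmax(w)

    def _learn(self, d, gain, loss):
        net = gain - loss
        sgn = 1.0 if net > 0 else (-1.0 if net < 0 else 0.0)
        lr = self.params["a_rew"] if net >= 0 else self.params["a_pun"]
        lr_fic = self.params["a_pun"] if net >= 0 else self.params["a_rew"]
        self.ev[d] += lr * (net - self.ev[d])
        for j in range(4):
            if j == d:
                self.ef[j] += lr * (sgn - self.ef[j])
            else:
                self.ef[j] += lr_fic * (-sgn / 3.0 - self.ef[j])
        decay = 1.0 / (1.0 + self.params["k"])
        self.ps *= decay
        self.ps[d] = 1.0


class VPPAgent(BaselineAgent):
    """Value-plus-perseveration: PVL-Delta value learning mixed with a
    decaying perseveration trace that gets an impulse ep_pos after non-losing
    outcomes and ep_neg after losses. Weight: w*EV + (1-w)*P."""

    param_names = ("a", "shape", "loss_aversion", "ep_pos", "ep_neg", "k", "w", "c")

    def reset(self) -> None:
        super().reset()
        self.ev = np.zeros(4)
        self.pers = np.zeros(4)

    def choice_probabilities(self) -> np.ndarray:
        w = self.params["w"] * self.ev + (1.0 - self.params["w"]) * self.pers
        return _softmax((3.0 ** self.params["c"] - 1.0) * w)

    def _learn(self, d, gain, loss):
        net = gain - loss
        u = _prospect(net, self.params["shape"], self.params["loss_aversion"])
        self.ev[d] += self.params["a"] * (u - self.ev[d])
        self.pers *= self.params["k"]
        self.pers[d] += self.params["ep_pos"] if net >= 0 else self.params["ep_neg"]


class VSEAgent(BaselineAgent):
    """Value and sequential exploration.

    Value module: v = gain**theta - loss**theta; every deck's value decays by
    factor ``decay`` and the chosen deck gains v. Exploration module: the
    chosen deck's exploration weight resets to 0; unchosen decks move toward
    the exploration bonus phi at learning rate alpha. Softmax of the summed
    weights with sensitivity 3**c - 1.
    """

    param_names = ("theta", "decay", "alpha", "phi", "c")

    def reset(self) -> None:
        super().reset()
        self.exploit = np.zeros(4)
        self.explore = np.zeros(4)

    def choice_probabilities(self) -> np.ndarray:
        w = self.exploit + self.explore
        return _softmax((3.0 ** self.params["c"] - 1.0) * w)

    def _learn(self, d, gain, loss):
        th = self.params["theta"]
        v = (gain**th if gain > 0 else 0.0) - (loss**th if loss > 0 else 0.0)
        self.exploit *= self.params["decay"]
        self.exploit[d] += v
        alpha, phi = self.params["alpha"], self.params["phi"]
        self.explore += alpha * (phi - self.explore)
        self.explore[d] = 0.0
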