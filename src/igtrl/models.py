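"""Model registry: one place mapping model names to parameter boxes, agent
factories and likelihood kernels.

Registered models: EEF, EEFLA, and the six baselines (EV, PVL, PVLDelta, ORL,
VPP, VSE). Parameter counts feed the information criteria (EEF=4, EEFLA=5,
EV=3, PVL=4, PVLDelta=4, ORL=5, VPP=8, VSE=5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import _kernels, baselines
from .eef import EEFAgent, EEFParams, default_first_choice_prior

__all__ = ["ModelSpec", "MODELS", "get_model", "make_agent", "model_registry"]


@dataclass(frozen=True)
class ModelSpec:
    """Everything the fitting and recovery machinery needs about one model."""

    name: str
    param_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    agent_factory: Callable
    nll_kernel: Callable
    uses_prior: bool = False

    @property
    def k(self) -> int:
        return len(self.param_names)

    def make_agent(self, params: dict, scheme=None):
        """Instantiate an agent with in-bounds parameters."""
        self.validate(params)
        scale = scheme.scale_divisor if scheme is not None else 100.0
        return self.agent_factory(params, scale)

    def validate(self, params: dict) -> None:
        for name in self.param_names:
            if name not in params:
                raise ValueError(f"{self.name}: missing parameter {name!r}")
            lo, hi = self.bounds[name]
            if not lo <= params[name] <= hi:
                raise ValueError(f"{self.name}: {name}={params[name]} outside [{lo}, {hi}]")

    def params_array(self, params: dict) -> np.ndarray:
        return np.array([params[n] for n in self.param_names], dtype=float)

    def prior_weights(self) -> np.ndarray:
        return default_first_choice_prior().w_ini if self.uses_prior else np.zeros(4)

    def nll(self, params, session, scale_divisor: float = 100.0) -> float:
        """Teacher-forced negative log-likelihood of one session."""
        if isinstance(params, dict):
            params = self.params_array(params)
        x = np.ascontiguousarray(params, dtype=np.float64)
        if self.name == "EEF":  # kernel carries the LA slot; EEF pins it at 1
            x = np.append(x, 1.0)
        return float(
            self.nll_kernel(
                x,
                np.ascontiguousarray(session.choices, dtype=np.int64),
                np.ascontiguousarray(session.gains, dtype=np.float64),
                np.ascontiguousarray(session.losses, dtype=np.float64),
                self.prior_weights(),
                float(scale_divisor),
            )
        )


def _eef_factory(params: dict, scale: float) -> EEFAgent:
    return EEFAgent(EEFParams(**params), scale_divisor=scale)


def _baseline_factory(cls):
    def factory(params: dict, scale: float):
        return cls(params, scale_divisor=scale)

    return factory


MODELS: dict[str, ModelSpec] = {
    "EEF": ModelSpec(
        "EEF",
        ("lam", "theta", "phi", "beta"),
        {"lam": (0.0, 1.0), "theta": (0.0, 1.0), "phi": (-5.0, 5.0), "beta": (0.0, 5.0)},
        _eef_factory,
        _kernels.nll_eef,
        uses_prior=True,
    ),
    "EEFLA": ModelSpec(
        "EEFLA",
        ("lam", "theta", "phi", "beta", "la"),
        {"lam": (0.0, 1.0), "theta": (0.0, 1.0), "phi": (-5.0, 5.0),
         "beta": (0.0, 5.0), "la": (0.0, 5.0)},
        _eef_factory,
        _kernels.nll_eef,
        uses_prior=True,
    ),
    "EV": ModelSpec(
        "EV",
        ("w", "a", "c"),
        {"w": (0.0, 1.0), "a": (0.0, 1.0), "c": (-5.0, 5.0)},
        _baseline_factory(baselines.EVAgent),
        _kernels.nll_ev,
    ),
    "PVL": ModelSpec(
        "PVL",
        ("shape", "loss_aversion", "decay", "c"),
        {"shape": (0.0, 1.0), "loss_aversion": (0.0, 5.0), "decay": (0.0, 1.0), "c": (0.0, 5.0)},
        _baseline_factory(baselines.PVLAgent),
        _kernels.nll_pvl,
    ),
    "PVLDelta": ModelSpec(
        "PVLDelta",
        ("shape", "loss_aversion", "a", "c"),
        {"shape": (0.0, 1.0), "loss_aversion": (0.0, 5.0), "a": (0.0, 1.0), "c": (0.0, 5.0)},
        _baseline_factory(baselines.PVLDeltaAgent),
        _kernels.nll_pvldelta,
    ),
    "ORL": ModelSpec(
        "ORL",
        ("a_rew", "a_pun", "k", "beta_f", "beta_p"),
        {"a_rew": (0.0, 1.0), "a_pun": (0.0, 1.0), "k": (0.0, 5.0),
         "beta_f": (-5.0, 5.0), "beta_p": (-5.0, 5.0)},
        _baseline_factory(baselines.ORLAgent),
        _kernels.nll_orl,
    ),
    "VPP": ModelSpec(
        "VPP",
        ("a", "shape", "loss_aversion", "ep_pos", "ep_neg", "k", "w", "c"),
        {"a": (0.0, 1.0), "shape": (0.0, 1.0), "loss_aversion": (0.0, 5.0),
         "ep_pos": (-1.0, 1.0), "ep_neg": (-1.0, 1.0), "k": (0.0, 1.0),
         "w": (0.0, 1.0), "c": (0.0, 5.0)},
        _baseline_factory(baselines.VPPAgent),
        _kernels.nll_vpp,
    ),
    "VSE": ModelSpec(
        "VSE",
        ("theta", "decay", "alpha", "phi", "c"),
        {"theta": (0.0, 1.0), "decay": (0.0, 1.0), "alpha": (0.0, 1.0),
         "phi": (-5.0, 5.0), "c": (0.0, 5.0)},
        _baseline_factory(baselines.VSEAgent),
        _kernels.nll_vse,
    ),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; known: {sorted(MODELS)}") from None


def make_agent(name: str, params: dict, scheme=None):
    """Agent for any registered model, under the shared interface."""
    return get_model(name).make_agent(params, scheme=scheme)


def model_registry() -> pd.DataFrame:
    """Table of (model, k, parameter names, bounds), one row per model."""
    rows = [
        {
            "model": spec.name,
            "k": spec.k,
            "parameters": ", ".join(spec.param_names),
            "bounds": "; ".join(f"{n}:[{lo},{hi}]" for n, (lo, hi) in spec.bounds.items()),
        }
        for spec in MODELS.values()
    ]
    return pd.DataFrame(rows).set_index("model")
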