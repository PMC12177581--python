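"""Iowa Gambling Task environment: payoff schemes, outcome scheduling, and
session simulation.

The classic task presents four card decks. Every draw pays a fixed gain; losses
are dispensed so that each consecutive block of ten draws from a deck delivers
a fixed multiset of loss amounts. Decks A and B pay 100 per draw but lose 250
net per ten draws; decks C and D pay 50 per draw and gain 250 net per ten
draws. Decks are labeled A-D and indexed 1-4 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DECK_LABELS = ("A", "B", "C", "D")

__all__ = [
    "DECK_LABELS",
    "DeckSpec",
    "PayoffScheme",
    "TrialOutcome",
    "Session",
    "Cohort",
    "build_bechara_scheme",
    "draw_outcome",
    "PayoffScheduler",
    "simulate_session",
    "generate_synthetic_cohort",
]


@dataclass(frozen=True)
class DeckSpec:
    """One deck: a fixed gain per draw plus a per-block loss multiset.

    ``loss_multiset`` holds loss magnitudes (positive numbers) dispensed once
    per block of ``block_length`` draws. ``fixed_positions`` gives the 1-based
    within-block positions at which each loss lands in "fixed-order" mode; it
    must align element-wise with ``loss_multiset``.
    """

    label: str
    gain_per_draw: float
    loss_multiset: tuple[float, ...]
    block_net: float
    fixed_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.gain_per_draw < 0:
            raise ValueError("gain_per_draw must be >= 0")
        if any(x <= 0 for x in self.loss_multiset):
            raise ValueError("loss magnitudes must be > 0")
        if self.fixed_positions and len(self.fixed_positions) != len(self.loss_multiset):
            raise ValueError("fixed_positions must align with loss_multiset")


@dataclass(frozen=True)
class PayoffScheme:
    """Four decks plus the block bookkeeping shared by all of them.

    ``scale_divisor`` is the monetary unit used inside utility computations
    (raw currency is divided by it before any value update); stored session
    data always keeps raw currency.
    """

    decks: tuple[DeckSpec, DeckSpec, DeckSpec, DeckSpec]
    block_length: int = 10
    scale_divisor: float = 100.0

    def __post_init__(self) -> None:
        if len(self.decks) != 4:
            raise ValueError("a payoff scheme has exactly 4 decks")
        if self.block_length <= 0 or self.scale_divisor <= 0:
            raise ValueError("block_length and scale_divisor must be positive")
        for d in self.decks:
            net = d.gain_per_draw * self.block_length - sum(d.loss_multiset)
            if abs(net - d.block_net) > 1e-9:
                raise ValueError(
                    f"deck {d.label}: gains x block - losses = {net} != "
                    f"declared block_net {d.block_net}"
                )

    def deck(self, index: int) -> DeckSpec:
        """Deck by 1-based index (1=A ... 4=D)."""
        if not 1 <= index <= 4:
            raise ValueError(f"deck index must be in 1..4, got {index}")
        return self.decks[index - 1]


@dataclass(frozen=True)
class TrialOutcome:
    """Monetary feedback of one draw; ``loss`` is a magnitude."""

    gain: float
    loss: float

    @property
    def net(self) -> float:
        return self.gain - self.loss


def build_bechara_scheme() -> PayoffScheme:
    """The original 100-trial scheme of Bechara et al.

    Per ten draws: A pays 100/draw with losses {150,200,250,300,350} (net
    -250); B pays 100/draw with one loss of 1250 (net -250); C pays 50/draw
    with losses {25,50,50,50,75} (net +250); D pays 50/draw with one loss of
    250 (net +250). The fixed-order positions replicate the commonly used
    first-block card order of the original task.
    """
    return PayoffScheme(
        decks=(
            DeckSpec("A", 100.0, (150.0, 300.0, 200.0, 250.0, 350.0), -250.0,
                     fixed_positions=(3, 5, 7, 9, 10)),
            DeckSpec("B", 100.0, (1250.0,), -250.0, fixed_positions=(9,)),
            DeckSpec("C", 50.0, (50.0, 50.0, 50.0, 25.0, 75.0), 250.0,
                     fixed_positions=(3, 5, 7, 9, 10)),
            DeckSpec("D", 50.0, (250.0,), 250.0, fixed_positions=(10,)),
        )
    )


def _block_loss_layout(
    deck: DeckSpec, block_length: int, block_index: int, seed: int, mode: str
) -> np.ndarray:
    """Loss magnitude at each within-block position (length block_length)."""
    layout = np.zeros(block_length)
    if mode == "fixed-order":
        positions = deck.fixed_positions or tuple(range(1, len(deck.loss_multiset) + 1))
        for pos, loss in zip(positions, deck.loss_multiset):
            layout[pos - 1] = loss
    elif mode == "random-position":
        # Each (seed, deck, block) triple pins its own arrangement so that
        # successive stateless calls within one block agree with each other.
        rng = np.random.default_rng(
            [int(seed), DECK_LABELS.index(deck.label), int(block_index)]
        )
        positions = rng.choice(block_length, size=len(deck.loss_multiset), replace=False)
        for pos, loss in zip(positions, deck.loss_multiset):
            layout[pos] = loss
    else:
        raise ValueError(f"unknown scheduling mode {mode!r}")
    return layout


def draw_outcome(
    scheme: PayoffScheme,
    deck: int,
    deck_draw_count: int,
    seed: int = 0,
    mode: str = "random-position",
) -> TrialOutcome:
    """Outcome of the (deck_draw_count+1)-th draw from a deck.

    ``deck_draw_count`` counts prior draws from this deck only. Within each
    consecutive block of ``block_length`` draws the deck's loss multiset is
    dispensed exactly once: at uniformly random positions without replacement
    (``random-position``, keyed by ``seed``) or at the deck's canonical
    positions (``fixed-order``). The gain is always ``gain_per_draw``.
    """
    spec = scheme.deck(deck)
    if deck_draw_count < 0:
        raise ValueError("deck_draw_count must be >= 0")
    block, pos = divmod(deck_draw_count, scheme.block_length)
    layout = _block_loss_layout(spec, scheme.block_length, block, seed, mode)
    return TrialOutcome(gain=spec.gain_per_draw, loss=float(layout[pos]))


class PayoffScheduler:
    """Stateful outcome dealer used by :func:`simulate_session`.

    Tracks per-deck draw counts and deals each block's losses from a fresh
    arrangement drawn at the block boundary.
    """

    def __init__(self, scheme: PayoffScheme, seed: int, mode: str = "random-position"):
        self.scheme = scheme
        self.mode = mode
        self._seed = int(seed)
        self._counts = [0, 0, 0, 0]

    def draw(self, deck: int) -> TrialOutcome:
        count = self._counts[deck - 1]
        out = draw_outcome(self.scheme, deck, count, seed=self._seed, mode=self.mode)
        self._counts[deck - 1] = count + 1
        return out


@dataclass
class Session:
    """One participant's trial-by-trial record.

    ``choices`` are deck indices 1-4; ``losses`` are magnitudes (>= 0).
    """

    subject_id: str
    choices: np.ndarray
    gains: np.ndarray
    losses: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.gains = np.asarray(self.gains, dtype=np.float64)
        self.losses = np.asarray(self.losses, dtype=np.float64)
        if not (len(self.choices) == len(self.gains) == len(self.losses)):
            raise ValueError("choices, gains, losses must have equal length")
        if len(self.choices) and not np.all((self.choices >= 1) & (self.choices <= 4)):
            raise ValueError("choices must be deck indices in 1..4")
        if np.any(self.gains < 0) or np.any(self.losses < 0):
            raise ValueError("gains and losses must be non-negative")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def nets(self) -> np.ndarray:
        return self.gains - self.losses

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and np.array_equal(self.choices, other.choices)
            and np.array_equal(self.gains, other.gains)
            and np.array_equal(self.losses, other.losses)
        )


@dataclass
class Cohort:
    """A collection of sessions plus free-text provenance."""

    sessions: list[Session]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("a cohort must contain at least one session")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def __getitem__(self, i: int) -> Session:
        return self.sessions[i]

    @property
    def n_trials(self) -> int:
        counts = {s.n_trials for s in self.sessions}
        if len(counts) > 1:
            raise ValueError(f"ragged cohort: trial counts {sorted(counts)}")
        return counts.pop()


def simulate_session(
    agent,
    scheme: PayoffScheme,
    n_trials: int = 100,
    seed: int = 0,
    subject_id: str = "sim",
    mode: str = "random-position",
) -> Session:
    """Run one agent through the task for ``n_trials`` draws.

    The agent must expose ``reset()``, ``choice_probabilities() -> 4-vector``
    and ``update(deck, gain, loss)``. Choices are sampled from the agent's
    probabilities; outcomes come from the payoff scheduler. Reproducible given
    the seed (one child stream for choices, one for loss placement).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    choice_seed, sched_seed = ss.spawn(2)
    rng = np.random.default_rng(choice_seed)
    scheduler = PayoffScheduler(scheme, seed=int(sched_seed.generate_state(1)[0] % 2**31), mode=mode)

    agent.reset()
    choices = np.empty(n_trials, dtype=np.int64)
    gains = np.empty(n_trials)
    losses = np.empty(n_trials)
    for t in range(n_trials):
        p = np.asarray(agent.choice_probabilities(), dtype=float)
        if p.shape != (4,) or not np.all(np.isfinite(p)) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"agent probabilities are not a valid simplex: {p}")
        deck = int(rng.choice(4, p=p / p.sum())) + 1
        out = scheduler.draw(deck)
        agent.update(deck, out.gain, out.loss)
        choices[t] = deck
        gains[t] = out.gain
        losses[t] = out.loss
    return Session(subject_id=subject_id, choices=choices, gains=gains, losses=losses,
                   metadata={"seed": seed, "mode": mode})


def generate_synthetic_cohort(
    model: str,
    n_subjects: int,
    n_trials: int = 100,
    seed: int = 0,
    param_sampler=None,
    scheme: PayoffScheme | None = None,
    mode: str = "random-position",
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort of agents with independently drawn parameters.

    ``param_sampler`` may be None (uniform over the model's parameter box), a
    dict of name -> (low, high) overriding individual ranges, or a callable
    ``sampler(rng) -> dict`` returning one in-bounds parameter draw. Returns
    the cohort and a truth table (one row per subject, indexed by subject_id)
    of the generating parameters.
    """
    from .models import get_model  # local import to avoid a cycle

    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    spec = get_model(model)
    scheme = scheme or build_bechara_scheme()
    ss = np.random.SeedSequence(seed)
    param_ss, sim_ss = ss.spawn(2)
    param_rng = np.random.default_rng(param_ss)
    sim_seeds = sim_ss.generate_state(n_subjects) % 2**31

    bounds = dict(spec.bounds)
    if isinstance(param_sampler, dict):
        for name, rng_pair in param_sampler.items():
            lo, hi = rng_pair
            blo, bhi = bounds[name]
            if lo < blo or hi > bhi:
                raise ValueError(f"sampler range for {name} outside model bounds")
            bounds[name] = (float(lo), float(hi))

    sessions, rows = [], []
    for i in range(n_subjects):
        if callable(param_sampler):
            params = dict(param_sampler(param_rng))
            for name, (lo, hi) in spec.bounds.items():
                if not lo <= params[name] <= hi:
                    raise ValueError(f"sampled {name}={params[name]} outside [{lo},{hi}]")
        else:
            params = {name: float(param_rng.uniform(lo, hi)) for name, (lo, hi) in bounds.items()}
        sid = f"{model.lower()}-{i:04d}"
        agent = spec.make_agent(params, scheme=scheme)
        sessions.append(
            simulate_session(agent, scheme, n_trials=n_trials, seed=int(sim_seeds[i]),
                             subject_id=sid, mode=mode)
        )
        rows.append({"subject_id": sid, **params})
    truth = pd.DataFrame(rows).set_index("subject_id")
    cohort = Cohort(
        sessions,
        provenance=f"synthetic:{model} N={n_subjects} T={n_trials} seed={seed} mode={mode}",
    )
    return cohort, truth
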