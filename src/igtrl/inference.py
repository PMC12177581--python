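"""Likelihood evaluation, maximum-likelihood fitting, information criteria,
Laplace free energy, and fixed-/random-effects model comparison.

Fitting is multi-start Nelder-Mead in an unconstrained space obtained by a
scaled-logit transform of each bounded parameter. Model evidence for the
random-effects analysis can be supplied as -BIC/2, -AIC/2 or the Laplace free
energy; the Bayesian model selection routine is the standard variational
Dirichlet-multinomial scheme over per-session evidences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, logit

from .env import Cohort, Session
from .models import ModelSpec, get_model

__all__ = [
    "FitConfig",
    "FitResult",
    "FreeEnergyBreakdown",
    "BMSResult",
    "negative_log_likelihood",
    "fit_mle",
    "fit_cohort",
    "information_criteria",
    "laplace_free_energy",
    "fixed_effects_table",
    "random_effects_bms",
    "fits_to_frame",
]

P_FLOOR = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for one maximum-likelihood fit."""

    n_starts: int = 20
    seed: int = 0
    tolerance: float = 1e-6
    max_evals_per_start: int = 2000

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Parameter estimates and fit statistics for one session x model."""

    model_name: str
    subject_id: str
    params: dict[str, float]
    nll: float
    k: int
    n: int
    aic: float = field(init=False)
    bic: float = field(init=False)
    free_energy: float | None = None
    fe_fallback: bool = False

    def __post_init__(self) -> None:
        self.aic, self.bic = information_criteria(self.nll, self.k, self.n)

    @property
    def minus2f(self) -> float | None:
        return None if self.free_energy is None else -2.0 * self.free_energy

    def to_dict(self) -> dict:
        out = {
            "model": self.model_name,
            "subject_id": self.subject_id,
            "nll": self.nll,
            "k": self.k,
            "n": self.n,
            "aic": self.aic,
            "bic": self.bic,
            "free_energy": self.free_energy,
            "minus2f": self.minus2f,
        }
        out.update({f"param_{k}": v for k, v in self.params.items()})
        return out


def information_criteria(nll: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k + 2*nll and BIC = k*ln(n) + 2*nll (nll = -ln max likelihood)."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    return 2.0 * k + 2.0 * nll, k * math.log(n) + 2.0 * nll


def negative_log_likelihood(model: str | ModelSpec, params, session: Session,
                            scale_divisor: float = 100.0) -> float:
    """Teacher-forced -sum_t ln P(choice_t | history_<t, params).

    The model is updated on the participant's actual choices and outcomes;
    probabilities are floored at 1e-12 before the log.
    """
    spec = get_model(model) if isinstance(model, str) else model
    return spec.nll(params, session, scale_divisor)


def nll_agent_route(model: str | ModelSpec, params: dict, session: Session,
                    scale_divisor: float = 100.0) -> float:
    """Same quantity via the (slow) agent objects; the cross-check route."""
    spec = get_model(model) if isinstance(model, str) else model

    class _Scheme:
        pass

    sc = _Scheme()
    sc.scale_divisor = scale_divisor
    agent = spec.make_agent(params, scheme=sc)
    agent.reset()
    nll = 0.0
    for t in range(session.n_trials):
        p = np.asarray(agent.choice_probabilities(), dtype=float)
        nll -= math.log(max(p[session.choices[t] - 1], P_FLOOR))
        agent.update(int(session.choices[t]), float(session.gains[t]), float(session.losses[t]))
    return nll


# ---------------------------------------------------------------- transforms

def _to_unconstrained(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip((x - lo) / (hi - lo), 1e-9, 1.0 - 1e-9)
    return logit(frac)


def _to_bounded(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * expit(z)


def fit_mle(model: str | ModelSpec, session: Session, config: FitConfig = FitConfig(),
            scale_divisor: float = 100.0) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of one session.

    Starts are drawn uniformly inside the parameter box (seeded); each start
    runs Nelder-Mead on the logit-transformed parameters. The best NLL wins;
    ties break toward the lowest start index. Deterministic given the seed.
    """
    spec = get_model(model) if isinstance(model, str) else model
    lo = np.array([spec.bounds[n][0] for n in spec.param_names])
    hi = np.array([spec.bounds[n][1] for n in spec.param_names])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _name_tag(spec.name)]))

    def objective(z: np.ndarray) -> float:
        return spec.nll(_to_bounded(z, lo, hi), session, scale_divisor)

    best_z, best_nll = None, np.inf
    margin = 0.05 * (hi - lo)
    for _ in range(config.n_starts):
        x0 = rng.uniform(lo + margin, hi - margin)
        res = minimize(
            objective,
            _to_unconstrained(x0, lo, hi),
            method="Nelder-Mead",
            options={
                "fatol": config.tolerance,
                "xatol": 1e-4,
                "maxfev": config.max_evals_per_start,
            },
        )
        if np.isfinite(res.fun) and res.fun < best_nll - 1e-12:
            best_nll, best_z = float(res.fun), res.x
    if best_z is None:
        raise RuntimeError(f"{spec.name}: optimizer failed on all {config.n_starts} starts")
    x = _to_bounded(best_z, lo, hi)
    return FitResult(
        model_name=spec.name,
        subject_id=session.subject_id,
        params={n: float(v) for n, v in zip(spec.param_names, x)},
        nll=best_nll,
        k=spec.k,
        n=session.n_trials,
    )


def _name_tag(name: str) -> int:
    return sum(ord(c) * 31**i for i, c in enumerate(name)) % 2**31


def fit_cohort(model: str | ModelSpec, cohort: Cohort, config: FitConfig = FitConfig(),
               scale_divisor: float = 100.0, progress: bool = False) -> list[FitResult]:
    """Fit every session of a cohort; per-session seeds derive from the
    config seed so results do not depend on cohort ordering tricks."""
    spec = get_model(model) if isinstance(model, str) else model
    fits = []
    for i, session in enumerate(cohort):
        cfg = FitConfig(n_starts=config.n_starts, seed=config.seed + 7919 * i,
                        tolerance=config.tolerance,
                        max_evals_per_start=config.max_evals_per_start)
        fits.append(fit_mle(spec, session, cfg, scale_divisor))
        if progress and (i + 1) % 25 == 0:
            print(f"  {spec.name}: fitted {i + 1}/{len(cohort)} sessions")
    return fits


# ------------------------------------------------------------- free energy

@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Additive components of the Laplace log-evidence approximation.

    accuracy_term: log-likelihood at the posterior mode (data fit).
    prior_precision_term: log prior density at the mode.
    dimensionality_term: (k/2) * log(2*pi).
    entropy_term: -(1/2) * log det H, H the Hessian of the negative log joint
        at the mode (posterior-width/Occam term).
    divergence_term: residual; zero unless a fallback evidence was used.
    """

    accuracy_term: float
    prior_precision_term: float
    dimensionality_term: float
    entropy_term: float
    divergence_term: float = 0.0

    @property
    def total(self) -> float:
        return (self.accuracy_term + self.prior_precision_term
                + self.dimensionality_term + self.entropy_term + self.divergence_term)


def laplace_free_energy(
    model: str | ModelSpec,
    session: Session,
    map_fit: FitResult,
    prior_sd: float = 1.5,
    scale_divisor: float = 100.0,
    fd_step: float = 1e-3,
) -> tuple[float, FreeEnergyBreakdown, bool]:
    """Laplace approximation to the log model evidence.

    Starting from the supplied fit, the negative log joint (NLL plus an
    independent N(0, prior_sd^2) prior on each logit-transformed parameter) is
    re-optimized to its mode z*, and

        F = log L(z*) + log p(z*) + (k/2) log 2pi - (1/2) log det H(z*)

    with H finite-differenced. If H is not positive definite the routine
    falls back to the BIC-based evidence -BIC/2 and sets the fallback flag.
    Returns (F, breakdown, fallback).
    """
    spec = get_model(model) if isinstance(model, str) else model
    lo = np.array([spec.bounds[n][0] for n in spec.param_names])
    hi = np.array([spec.bounds[n][1] for n in spec.param_names])
    k = spec.k

    def neg_log_joint(z: np.ndarray) -> float:
        nll = spec.nll(_to_bounded(z, lo, hi), session, scale_divisor)
        return nll + 0.5 * np.sum((z / prior_sd) ** 2) + k * math.log(prior_sd * math.sqrt(2 * math.pi))

    z0 = _to_unconstrained(spec.params_array(map_fit.params), lo, hi)
    res = minimize(neg_log_joint, z0, method="Nelder-Mead",
                   options={"fatol": 1e-8, "xatol": 1e-6, "maxfev": 4000})
    z = res.x

    # central-difference Hessian of the negative log joint
    H = np.empty((k, k))
    f0 = neg_log_joint(z)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = fd_step
            ej = np.zeros(k); ej[j] = fd_step
            if i == j:
                H[i, i] = (neg_log_joint(z + ei) - 2 * f0 + neg_log_joint(z - ei)) / fd_step**2
            else:
                fpp = neg_log_joint(z + ei + ej)
                fpm = neg_log_joint(z + ei - ej)
                fmp = neg_log_joint(z - ei + ej)
                fmm = neg_log_joint(z - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * fd_step**2)

    sign, logdet = np.linalg.slogdet(H)
    nll_star = spec.nll(_to_bounded(z, lo, hi), session, scale_divisor)
    log_prior = -0.5 * np.sum((z / prior_sd) ** 2) - k * math.log(prior_sd * math.sqrt(2 * math.pi))
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn(
            f"{spec.name}/{session.subject_id}: Hessian not positive definite; "
            "falling back to BIC-based evidence",
            RuntimeWarning,
        )
        _, bic = information_criteria(nll_star, k, session.n_trials)
        f_val = -0.5 * bic
        br = FreeEnergyBreakdown(
            accuracy_term=-nll_star,
            prior_precision_term=0.0,
            dimensionality_term=0.0,
            entropy_term=0.0,
            divergence_term=f_val + nll_star,
        )
        return f_val, br, True
    br = FreeEnergyBreakdown(
        accuracy_term=-nll_star,
        prior_precision_term=float(log_prior),
        dimensionality_term=0.5 * k * math.log(2 * math.pi),
        entropy_term=-0.5 * float(logdet),
    )
    return br.total, br, False


# ------------------------------------------------------- model comparison

def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits])


def fixed_effects_table(fits: dict[str, list[FitResult]], reference: str = "EEF") -> pd.DataFrame:
    """Summed criteria per model and deltas versus a reference model.

    Columns: sum_aic, sum_bic, sum_minus2f (NaN if free energies absent) and
    delta_* versus the reference (positive = worse than the reference).
    Requires a complete sessions x models grid.
    """
    if reference not in fits:
        raise ValueError(f"reference model {reference!r} has no fits")
    sizes = {m: len(v) for m, v in fits.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"incomplete fit grid: {sizes}")
    subjects = {m: sorted(f.subject_id for f in v) for m, v in fits.items()}
    if any(s != subjects[reference] for s in subjects.values()):
        raise ValueError("fit grids cover different sessions")
    rows = {}
    for m, v in fits.items():
        m2f = [f.minus2f for f in v]
        rows[m] = {
            "sum_aic": sum(f.aic for f in v),
            "sum_bic": sum(f.bic for f in v),
            "sum_minus2f": sum(m2f) if all(x is not None for x in m2f) else np.nan,
        }
    table = pd.DataFrame(rows).T
    for col in table.columns:
        table["delta_" + col.removeprefix("sum_")] = table[col] - table.loc[reference, col]
    return table.sort_values("sum_bic")


@dataclass(frozen=True)
class BMSResult:
    """Random-effects Bayesian model selection output."""

    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    assignment_weights: np.ndarray  # sessions x models responsibilities
    n_iterations: int

    def best_model(self) -> str:
        return self.model_names[int(np.argmax(self.expected_frequencies))]


def random_effects_bms(log_evidence: pd.DataFrame | np.ndarray,
                       model_names=None, prior_count: float = 1.0,
                       tol: float = 1e-6, max_iter: int = 10_000) -> BMSResult:
    """Variational Dirichlet-multinomial model selection.

    ``log_evidence`` is sessions x models (e.g. -BIC/2, -AIC/2, or F).
    Iterates responsibilities u_nk proportional to
    exp(digamma(alpha_k) - digamma(sum alpha) + logE_nk) and
    alpha = alpha0 + sum_n u_n until max|delta alpha| < tol. Expected model
    frequencies are alpha / sum(alpha).
    """
    if isinstance(log_evidence, pd.DataFrame):
        model_names = tuple(log_evidence.columns)
        E = log_evidence.to_numpy(dtype=float)
    else:
        E = np.asarray(log_evidence, dtype=float)
        model_names = tuple(model_names or [f"M{i}" for i in range(E.shape[1])])
    if not np.all(np.isfinite(E)):
        raise ValueError("log evidences must be finite")
    n, K = E.shape
    alpha = np.full(K, prior_count, dtype=float)
    for it in range(1, max_iter + 1):
        w = E + digamma(alpha) - digamma(alpha.sum())
        w -= w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = prior_count + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise RuntimeError(f"BMS did not converge in {max_iter} iterations")
    return BMSResult(
        model_names=model_names,
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        assignment_weights=u,
        n_iterations=it,
    )
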