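"""Candidate utility models for allocation choice and the softmax choice rule.

Five nested inequity-sensitive utility functions over the payoff pair
(Ms, Mo), all of the Fehr-Schmidt family:

* ``M1`` — advantageous-inequity only: ``U = Ms - alpha_k * max(Ms - Mo, 0)``
* ``M2`` — disadvantageous-inequity only: ``U = Ms - beta_k * max(Mo - Ms, 0)``
* ``M3`` — general (undissociated) inequity: ``U = Ms - omega_k * |Ms - Mo|``
* ``M4`` — full Fehr-Schmidt:
  ``U = Ms - alpha_k * max(Ms - Mo, 0) - beta_k * max(Mo - Ms, 0)``
* ``M5`` — M4 with both weights constrained positive (pure aversion).

Each inequity weight is indexed by the condition ``k`` (role x frame cell);
choice follows a softmax with a single inverse temperature ``lambda > 0``
shared across conditions: ``P(option) ∝ exp(lambda * U(option))`` over the
trial's full choice set.  ``lambda = 0`` (uniform choice) is permitted for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .task import Trial, choice_set, payoffs

__all__ = [
    "ModelSpec",
    "ParamSet",
    "MODELS",
    "get_model",
    "utility",
    "choice_probs",
    "log_likelihood",
    "pointwise_log_likelihood",
]

N_CONDITIONS = 4


@dataclass(frozen=True)
class ModelSpec:
    """A registered candidate model: which inequity weights it uses and
    whether they are constrained to be positive."""

    id: str
    description: str
    uses_alpha: bool = False
    uses_beta: bool = False
    uses_omega: bool = False
    positive_constrained: bool = False

    @property
    def weight_names(self) -> tuple[str, ...]:
        names = []
        if self.uses_alpha:
            names.append("alpha")
        if self.uses_beta:
            names.append("beta")
        if self.uses_omega:
            names.append("omega")
        return tuple(names)


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", "advantageous inequity aversion", uses_alpha=True),
    "M2": ModelSpec("M2", "disadvantageous inequity aversion", uses_beta=True),
    "M3": ModelSpec("M3", "general inequity aversion", uses_omega=True),
    "M4": ModelSpec("M4", "Fehr-Schmidt inequity aversion", uses_alpha=True, uses_beta=True),
    "M5": ModelSpec(
        "M5",
        "Fehr-Schmidt, positivity-constrained",
        uses_alpha=True,
        uses_beta=True,
        positive_constrained=True,
    ),
}


def get_model(model: "str | ModelSpec") -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise KeyError(f"unknown model id {model!r}; registered: {sorted(MODELS)}") from None


@dataclass
class ParamSet:
    """Per-participant parameters: condition-indexed inequity weights and one
    softmax inverse temperature.

    ``alpha``/``beta``/``omega`` are length-4 arrays indexed by condition
    ``k-1`` (units: utility per cent of inequity); ``lam`` is the inverse
    temperature in 1/cents.  Only the weights a model uses need be set.
    """

    lam: float
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"inverse temperature must be >= 0, got {self.lam}")
        for name in ("alpha", "beta", "omega"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (N_CONDITIONS,):
                    raise ValueError(f"{name} must have shape ({N_CONDITIONS},), got {v.shape}")
                object.__setattr__(self, name, v)

    def validate_for(self, model: "str | ModelSpec") -> None:
        spec = get_model(model)
        for name in spec.weight_names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"model {spec.id} requires parameter {name!r}")
            if spec.positive_constrained and np.any(v <= 0):
                raise ValueError(f"model {spec.id} requires strictly positive {name}")

    def weights_for(self, model: "str | ModelSpec", k: int) -> dict[str, float]:
        spec = get_model(model)
        return {name: float(getattr(self, name)[k - 1]) for name in spec.weight_names}


def utility(model: "str | ModelSpec", weights: dict[str, float], ms, mo):
    """Utility of payoff pair(s) (Ms, Mo) under a model's condition-k weights.

    ``weights`` maps the model's weight names (subset of alpha/beta/omega) to
    scalars.  Accepts scalars or arrays; broadcasts elementwise.
    """
    spec = get_model(model)
    ms = np.asarray(ms, dtype=float)
    mo = np.asarray(mo, dtype=float)
    u = ms.astype(float).copy()
    if spec.uses_alpha:
        u = u - weights["alpha"] * np.maximum(ms - mo, 0.0)
    if spec.uses_beta:
        u = u - weights["beta"] * np.maximum(mo - ms, 0.0)
    if spec.uses_omega:
        u = u - weights["omega"] * np.abs(ms - mo)
    return u if u.ndim else float(u)


def trial_utilities(model: "str | ModelSpec", params: ParamSet, trial: Trial) -> np.ndarray:
    """Utility of every option in the trial's choice set, in kept-tokens order."""
    params.validate_for(model)
    opts = choice_set(trial)
    pp = [payoffs(trial, a) for a in opts]
    ms = np.array([p.m_self for p in pp])
    mo = np.array([p.m_other for p in pp])
    w = params.weights_for(model, trial.condition.k)
    return np.asarray(utility(model, w, ms, mo))


def choice_probs(model: "str | ModelSpec", params: ParamSet, trial: Trial) -> np.ndarray:
    """Softmax choice probabilities over the trial's T+1 options.

    Computed through a log-sum-exp guard so arbitrarily large ``lambda * U``
    magnitudes cannot overflow; the output sums to 1 to machine precision.
    ``lambda = 0`` yields the uniform distribution.
    """
    u = trial_utilities(model, params, trial)
    logits = params.lam * u
    ex = np.exp(logits - logits.max())
    return ex / ex.sum()


def log_choice_prob(model, params: ParamSet, trial: Trial, tokens_kept: int) -> float:
    u = trial_utilities(model, params, trial)
    if not 0 <= tokens_kept <= trial.total_tokens:
        raise ValueError(
            f"tokens_kept={tokens_kept} outside the choice set of a T={trial.total_tokens} trial"
        )
    logits = params.lam * u
    return float(logits[tokens_kept] - logsumexp(logits))


def pointwise_log_likelihood(model, params: ParamSet, dataset) -> np.ndarray:
    """Per-trial log-likelihood vector, in dataset row order.

    ``dataset`` is a :class:`~fairshare.data.ChoiceDataset` for a single
    participant (or any dataset whose every row is governed by ``params``).
    """
    params.validate_for(model)
    out = np.empty(len(dataset.table))
    for i, (trial, kept) in enumerate(dataset.iter_trials()):
        out[i] = log_choice_prob(model, params, trial, kept)
    return out


def log_likelihood(model, params: ParamSet, dataset) -> float:
    """Summed log-likelihood of a dataset under one parameter set."""
    return float(pointwise_log_likelihood(model, params, dataset).sum())
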