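"""Synthetic study-design schedules and generative choice simulation.

The generator emulates the study design: a 2 (Role: first-/third-party) x
2 (Frame: gain/loss) within-subjects by 2 (Group: children/adults)
between-subjects dictator game.  Each participant completes 4 blocks (one per
Role x Frame condition) of 20 rounds; within a block each of the five exchange
ratios (3:1, 2:1, 1:1, 1:2, 1:3) appears exactly 4 times; the condition order
follows a balanced (Williams) 4x4 Latin square cycled over participants.
Token budgets are drawn per round from a configurable pool; the default pool
{12, 24, 36, 48} makes the payoff-equalizing split integral at all five
ratios.

Agents choose by the softmax inequity-aversion models of
:mod:`fairshare.models`.  Cohorts draw each participant's condition-specific
weights from group-level normal distributions on the unconstrained scale
(matching the hierarchical estimation model), with the inverse temperature
log-normal, and return the generating parameters alongside the data so that
parameter-recovery studies can score the fit against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ChoiceDataset
from .models import ModelSpec, ParamSet, choice_probs, get_model
from .task import Condition, DESIGN_RATIOS, ExchangeRatio, Trial

__all__ = [
    "Schedule",
    "CohortSpec",
    "make_schedule",
    "simulate_participant",
    "simulate_cohort",
    "default_cohort_specs",
    "WILLIAMS_SQUARE",
]

ROUNDS_PER_BLOCK = 20
N_BLOCKS = 4
RATIO_REPEATS = ROUNDS_PER_BLOCK // len(DESIGN_RATIOS)  # 4 per block

#: Balanced (Williams) Latin square on the four condition indices: every
#: condition appears once per row and per column, and each condition precedes
#: every other equally often across rows.
WILLIAMS_SQUARE: tuple[tuple[int, ...], ...] = (
    (1, 2, 4, 3),
    (2, 3, 1, 4),
    (3, 4, 2, 1),
    (4, 1, 3, 2),
)


@dataclass
class Schedule:
    """Per-participant trial lists plus the condition order each received."""

    trials: dict  # participant index -> list[Trial]
    condition_orders: dict  # participant index -> tuple of k

    @property
    def n_participants(self) -> int:
        return len(self.trials)


def make_schedule(n_participants: int, token_pool=(12, 24, 36, 48), seed: int = 0) -> Schedule:
    """Build the counterbalanced trial schedule for ``n_participants``.

    Each participant gets 4 blocks x 20 rounds; ratios are balanced (4 of
    each per block) and shuffled within block; budgets are drawn uniformly
    from ``token_pool``.  Participant ``i`` receives Latin-square row
    ``i mod 4``.  Deterministic given the arguments.
    """
    pool = sorted(set(int(t) for t in token_pool))
    if not pool:
        raise ValueError("token pool must be nonempty")
    if any(t <= 0 for t in pool):
        raise ValueError("token budgets must be positive")
    if n_participants < 1:
        raise ValueError("need at least one participant")

    root = np.random.SeedSequence([int(seed), 0x5C4ED])
    streams = root.spawn(n_participants)
    trials: dict = {}
    orders: dict = {}
    for i in range(n_participants):
        rng = np.random.default_rng(streams[i])
        order = WILLIAMS_SQUARE[i % 4]
        orders[i] = order
        plist = []
        for b, k in enumerate(order, start=1):
            cond = Condition.from_k(k)
            ratios = [r for r in DESIGN_RATIOS for _ in range(RATIO_REPEATS)]
            rng.shuffle(ratios)
            budgets = rng.choice(pool, size=ROUNDS_PER_BLOCK, replace=True)
            for rnd, (ratio, T) in enumerate(zip(ratios, budgets), start=1):
                plist.append(
                    Trial(
                        condition=cond,
                        ratio=ExchangeRatio(*ratio),
                        total_tokens=int(T),
                        block=b,
                        round=rnd,
                    )
                )
        trials[i] = plist
    return Schedule(trials, orders)


def _simulate_trials(model, params: ParamSet, trial_list, rng) -> list[int]:
    kept = []
    for trial in trial_list:
        p = choice_probs(model, params, trial)
        kept.append(int(rng.choice(trial.total_tokens + 1, p=p)))
    return kept


def simulate_participant(
    params: ParamSet,
    model: "str | ModelSpec",
    schedule: Schedule,
    seed: int = 0,
    participant: int = 0,
    participant_id: str = "p000",
    group: str = "synthetic",
) -> ChoiceDataset:
    """Simulate one agent through its scheduled trials.

    Every trial draws one allocation from the model's softmax choice
    distribution under the trial's condition-k weights; reproducible given
    the seed.
    """
    params.validate_for(model)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(participant), 0xA6E7]))
    trial_list = schedule.trials[participant]
    kept = _simulate_trials(model, params, trial_list, rng)
    rows = [
        {
            "participant_id": participant_id,
            "group": group,
            "role": t.condition.role.value,
            "frame": t.condition.frame.value,
            "block": t.block,
            "round": t.round,
            "r_self": t.ratio.r_self,
            "r_other": t.ratio.r_other,
            "total_tokens": t.total_tokens,
            "tokens_kept": ts,
        }
        for t, ts in zip(trial_list, kept)
    ]
    return ChoiceDataset(pd.DataFrame(rows))


@dataclass
class CohortSpec:
    """Population recipe for one between-subjects group.

    ``hyper`` maps each weight family the generating model uses ("alpha",
    "beta" or "omega") to a pair of length-4 arrays ``(mu0, sigma0)`` — the
    group-level mean and SD per condition k, on the sampling scale (natural
    scale for unconstrained weights, log scale for positivity-constrained
    ones).  ``lam_log_mean``/``lam_log_sd`` parameterize the log-normal
    inverse temperature (one lambda per participant, shared across
    conditions).
    """

    group: str
    n_participants: int
    hyper: dict
    lam_log_mean: float = np.log(0.2)
    lam_log_sd: float = 0.4
    token_pool: tuple = (12, 24, 36, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.lam_log_sd < 0:
            raise ValueError("lam_log_sd must be >= 0")
        for name, (mu, sd) in self.hyper.items():
            mu = np.broadcast_to(np.asarray(mu, dtype=float), (4,)).copy()
            sd = np.broadcast_to(np.asarray(sd, dtype=float), (4,)).copy()
            if np.any(sd < 0):
                raise ValueError(f"sigma0 for {name} must be >= 0")
            self.hyper[name] = (mu, sd)


def simulate_cohort(
    spec: CohortSpec,
    model: "str | ModelSpec" = "M4",
    schedule: Schedule | None = None,
    seed: int | None = None,
) -> ChoiceDataset:
    """Draw a cohort from the hierarchical population and simulate its choices.

    Individual condition-k weights are drawn Normal(mu0_k, sigma0_k) on the
    unconstrained scale and transformed where the model constrains them
    (exponential link, matching the estimation hierarchy); lambda is
    log-normal.  Returns the dataset with the ground-truth parameters
    attached.
    """
    mspec = get_model(model)
    seed = spec.seed if seed is None else seed
    if schedule is None:
        schedule = make_schedule(spec.n_participants, spec.token_pool, seed=seed)
    root = np.random.SeedSequence([int(seed), 0xC0407])
    param_rng = np.random.default_rng(root)

    frames = []
    truth_rows = []
    for i in range(spec.n_participants):
        pid = f"{spec.group}-{i:03d}"
        kwargs: dict = {}
        for name in mspec.weight_names:
            if name not in spec.hyper:
                raise ValueError(f"cohort spec lacks hyperparameters for {name!r}")
            mu, sd = spec.hyper[name]
            raw = param_rng.normal(mu, sd)
            vals = np.exp(raw) if mspec.positive_constrained else raw
            kwargs[name] = vals
            for k in range(1, 5):
                truth_rows.append(
                    {"participant_id": pid, "k": k, "parameter": name, "value": vals[k - 1]}
                )
        lam = float(np.exp(param_rng.normal(spec.lam_log_mean, spec.lam_log_sd)))
        truth_rows.append({"participant_id": pid, "k": 0, "parameter": "lam", "value": lam})
        params = ParamSet(lam=lam, **kwargs)
        ds = simulate_participant(
            params,
            mspec,
            schedule,
            seed=seed,
            participant=i,
            participant_id=pid,
            group=spec.group,
        )
        frames.append(ds.table)

    table = pd.concat(frames, ignore_index=True)
    return ChoiceDataset(table, pd.DataFrame(truth_rows))


def default_cohort_specs(
    n_children: int = 34, n_adults: int = 31, sigma0: float = 0.5, seed: int = 0
) -> dict:
    """Study-condition cohort recipes for the two age groups.

    Group-level means follow the qualitative pattern the task is built to
    expose — children: advantage-seeking in first-party (alpha < 0) but strong
    advantageous-inequity aversion in third-party (alpha ~ 3.3); adults:
    moderate advantageous-inequity aversion everywhere (alpha ~ 1.4-2.1);
    both groups averse to disadvantageous inequity (beta ~ 2.4-3.9).
    Condition order of k: first/gain, first/loss, third/gain, third/loss.
    """
    children = CohortSpec(
        group="children",
        n_participants=n_children,
        hyper={
            "alpha": (np.array([-0.190, -0.241, 3.268, 3.348]), np.full(4, sigma0)),
            "beta": (np.array([3.919, 2.809, 2.525, 2.735]), np.full(4, sigma0)),
        },
        seed=seed,
    )
    adults = CohortSpec(
        group="adults",
        n_participants=n_adults,
        hyper={
            "alpha": (np.array([1.361, 1.478, 1.992, 2.077]), np.full(4, sigma0)),
            "beta": (np.array([2.489, 2.784, 2.353, 2.476]), np.full(4, sigma0)),
        },
        seed=seed + 1,
    )
    return {"children": children, "adults": adults}
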