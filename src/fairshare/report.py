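"""Posterior inference reporting: HDIs, evidence categories, contrasts, PPC.

Evidence about a scalar quantity (a group-level parameter or a contrast of
group-level parameters) is categorized from its posterior draws by an
HDI-exclusion rule: *meaningful* when the 97.5% highest-density interval
excludes zero, *limited* when only the 85% HDI excludes zero, *none*
otherwise.  Reports always carry the posterior mean and 95% HDI for display.

Cross-condition contrasts operate on the group-level mean draws, summing the
two cells of the collapsed factor before differencing (role contrast:
``(theta_1 + theta_2) - (theta_3 + theta_4)``; frame contrast:
``(theta_1 + theta_3) - (theta_2 + theta_4)``).  Cross-group contrasts pair
draws index-wise across two independently fitted groups after an independent
within-fit shuffle, which preserves both marginal posteriors while breaking
any chain-order artifacts.

The posterior predictive check simulates replicate datasets from the fitted
model (posterior-mean parameters by default, or full joint draws) on each
participant's actual trial schedule, then correlates replicate and observed
mean kept fractions across participants and across trial positions, and
reruns the behavioral ANOVA on the replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .data import ChoiceDataset
from .models import ParamSet
from .simulate import Schedule, simulate_participant

__all__ = [
    "hdi",
    "EvidenceReport",
    "evidence_category",
    "condition_contrast",
    "group_contrast",
    "schedule_from_dataset",
    "posterior_predict",
    "ppc_correlations",
    "PpcResult",
]

#: role contrast: first-party cells minus third-party cells (k: 1,2 vs 3,4);
#: frame contrast: gain cells minus loss cells (k: 1,3 vs 2,4).
_CONTRAST_CELLS = {"role": ((1, 2), (3, 4)), "frame": ((1, 3), (2, 4))}
_ROLE_CELLS = {"first": (1, 2), "third": (3, 4)}


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval by the shortest-window method on sorted draws."""
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    d = np.sort(np.asarray(draws, dtype=float).ravel())
    n = d.size
    if n == 0:
        raise ValueError("empty draws")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(d[0]), float(d[-1])
    widths = d[m - 1 :] - d[: n - m + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + m - 1])


@dataclass
class EvidenceReport:
    """Posterior summary plus a categorical evidence label for one quantity.

    Carries both the 95% HDI (display convention) and the 97.5% HDI (the
    interval the evidence rule is anchored on)."""

    name: str
    mean: float
    hdi95: tuple[float, float]
    hdi975: tuple[float, float]
    category: str  # meaningful | limited | none
    direction: str  # above | below | -

    def __str__(self) -> str:
        lo, hi = self.hdi95
        return (
            f"{self.name}: (mean = {self.mean:.3f}, 95% HDI: [{lo:.3f}, {hi:.3f}]) "
            f"-> {self.category}"
            + (f" ({self.direction} 0)" if self.category != "none" else "")
        )


def evidence_category(draws: np.ndarray, name: str = "quantity") -> EvidenceReport:
    """Categorize evidence that a quantity differs from zero.

    meaningful: the 97.5% HDI excludes 0; limited: the 97.5% HDI contains 0
    but the 85% HDI excludes it; none otherwise.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("empty draws")
    if draws.size < 1000:
        warnings.warn(
            f"only {draws.size} draws; evidence categories are noisy below ~1000",
            stacklevel=2,
        )
    lo975, hi975 = hdi(draws, 0.975)
    lo85, hi85 = hdi(draws, 0.85)
    if lo975 > 0 or hi975 < 0:
        category = "meaningful"
    elif lo85 > 0 or hi85 < 0:
        category = "limited"
    else:
        category = "none"
    mean = float(draws.mean())
    direction = "-" if category == "none" else ("above" if mean > 0 else "below")
    return EvidenceReport(name, mean, hdi(draws, 0.95), (lo975, hi975), category, direction)


def condition_contrast(fit, parameter: str, axis: str = "role"):
    """Within-group contrast of group-level means across conditions.

    ``axis='role'`` sums each role's two frame cells then differences
    (first minus third); ``axis='frame'`` sums each frame's two role cells
    (gain minus loss).  Returns ``(contrast draws, EvidenceReport)``.
    """
    if axis not in _CONTRAST_CELLS:
        raise ValueError(f"axis must be 'role' or 'frame', got {axis!r}")
    pos, neg = _CONTRAST_CELLS[axis]
    d = sum(fit.group_level(parameter, k) for k in pos) - sum(
        fit.group_level(parameter, k) for k in neg
    )
    label = {"role": "first - third", "frame": "gain - loss"}[axis]
    name = f"{parameter} {axis} contrast ({label}), group={fit.group}"
    return d, evidence_category(d, name)


def group_contrast(fit_a, fit_b, parameter: str, role: str = "first", seed: int = 0):
    """Between-group contrast of a parameter within one role.

    Sums the role's two frame cells per group, shuffles each group's draws
    independently (fixed seed), and differences them index-wise (A minus B).
    Unequal draw counts are resampled to match with a warning.
    """
    if role not in _ROLE_CELLS:
        raise ValueError(f"role must be 'first' or 'third', got {role!r}")
    ks = _ROLE_CELLS[role]
    da = sum(fit_a.group_level(parameter, k) for k in ks)
    db = sum(fit_b.group_level(parameter, k) for k in ks)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    if da.size != db.size:
        warnings.warn(
            f"draw counts differ ({da.size} vs {db.size}); resampling to match",
            stacklevel=2,
        )
        n = min(da.size, db.size)
        da = rng.choice(da, size=n, replace=False) if da.size > n else da
        db = rng.choice(db, size=n, replace=False) if db.size > n else db
    da = rng.permutation(da)
    db = rng.permutation(db)
    d = da - db
    name = f"{parameter} group contrast ({fit_a.group} - {fit_b.group}), role={role}"
    return d, evidence_category(d, name)


# ----------------------------------------------------------------------- PPC


def schedule_from_dataset(dataset: ChoiceDataset) -> Schedule:
    """Rebuild each fitted participant's actual trial list as a Schedule."""
    trials: dict = {}
    orders: dict = {}
    for i, pid in enumerate(dataset.participants):
        sub = dataset.for_participant(pid)
        tlist = [t for t, _ in sub.iter_trials()]
        trials[i] = tlist
        seen: list[int] = []
        for t in tlist:
            if t.condition.k not in seen:
                seen.append(t.condition.k)
        orders[i] = tuple(seen)
    return Schedule(trials, orders)


def _paramset_from_draw(fit, pid, draws_index=None) -> ParamSet:
    """One participant's ParamSet from posterior means (index None) or from a
    single joint draw."""
    kwargs: dict = {}
    for fam in fit.model.families:
        vals = np.empty(fam.K)
        for k in range(1, fam.K + 1):
            d = fit._individual_draws(fam, pid, k)
            vals[k - 1] = d.mean() if draws_index is None else d[draws_index]
        if fam.name == "lam":
            kwargs["lam"] = float(vals[0])
        else:
            kwargs[fam.name] = vals
    return ParamSet(**kwargs)


def posterior_predict(
    fit,
    schedule: Schedule | None = None,
    mode: str = "means",
    n_rep: int = 1,
    seed: int = 0,
):
    """Simulate replicate dataset(s) from a fitted model.

    ``mode='means'`` simulates once from each participant's posterior-mean
    parameters; ``mode='draws'`` samples ``n_rep`` joint posterior draws and
    simulates one replicate dataset per draw (returned as a list).
    """
    if schedule is None:
        schedule = schedule_from_dataset(fit.model.dataset)
    if schedule.n_participants != len(fit.participants):
        raise ValueError(
            f"schedule has {schedule.n_participants} participants, fit has "
            f"{len(fit.participants)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFFC]))

    def one_replicate(draw_index, rep_seed):
        frames = []
        for i, pid in enumerate(fit.participants):
            params = _paramset_from_draw(fit, pid, draw_index)
            ds = simulate_participant(
                params,
                fit.spec,
                schedule,
                seed=rep_seed,
                participant=i,
                participant_id=pid,
                group=fit.group,
            )
            frames.append(ds.table)
        return ChoiceDataset(pd.concat(frames, ignore_index=True))

    if mode == "means":
        return one_replicate(None, int(rng.integers(2**31 - 1)))
    if mode == "draws":
        idx = rng.integers(fit.n_draws, size=n_rep)
        return [one_replicate(int(j), int(rng.integers(2**31 - 1))) for j in idx]
    raise ValueError(f"mode must be 'means' or 'draws', got {mode!r}")


@dataclass
class PpcResult:
    """Posterior-predictive agreement between replicate and observed data."""

    correlations: pd.DataFrame  # per condition: across-participant / across-round r
    anova_selfish: object | None  # behavioral recovery (needs 2 groups)
    anova_equal: object | None

    def __str__(self) -> str:
        return self.correlations.to_string(index=False)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), True
    return float(sstats.pearsonr(a, b)[0]), False


def ppc_correlations(
    actual: ChoiceDataset, simulated: ChoiceDataset, concatenate_trials: bool = False
) -> PpcResult:
    """Correlate replicate with observed behavior per role x frame condition.

    Across participants: each participant's condition-mean kept fraction.
    Across trial positions: per-round kept fraction averaged over
    participants (or concatenated participant x round vectors with
    ``concatenate_trials=True``).  Zero-variance vectors yield an undefined-
    correlation flag rather than an error.  The behavioral-recovery ANOVA is
    run on the replicate when both between-subject groups are present.
    """
    from .metrics import aggregate, mixed_anova

    a = actual.table.assign(kf=actual.table.tokens_kept / actual.table.total_tokens)
    s = simulated.table.assign(kf=simulated.table.tokens_kept / simulated.table.total_tokens)
    if len(a) != len(s):
        raise ValueError("actual and simulated datasets must share one design")
    rows = []
    for (role, frame), asub in a.groupby(["role", "frame"]):
        ssub = s[(s.role == role) & (s.frame == frame)]
        pa = asub.groupby("participant_id")["kf"].mean()
        ps = ssub.groupby("participant_id")["kf"].mean().reindex(pa.index)
        r_part, flag_p = _safe_pearson(pa.to_numpy(), ps.to_numpy())
        if concatenate_trials:
            ta = asub.sort_values(["participant_id", "round"])["kf"].to_numpy()
            ts = ssub.sort_values(["participant_id", "round"])["kf"].to_numpy()
        else:
            ta = asub.groupby("round")["kf"].mean().to_numpy()
            ts = ssub.groupby("round")["kf"].mean().reindex(
                asub.groupby("round")["kf"].mean().index
            ).to_numpy()
        r_trial, flag_t = _safe_pearson(ta, ts)
        rows.append(
            {
                "role": role,
                "frame": frame,
                "r_participants": r_part,
                "r_trials": r_trial,
                "undefined": flag_p or flag_t,
            }
        )
    corr = pd.DataFrame(rows)
    anova_s = anova_e = None
    if len(simulated.groups) == 2:
        summ = aggregate(simulated)
        anova_s = mixed_anova(summ, "selfish_dev")
        anova_e = mixed_anova(summ, "equal_dev")
    return PpcResult(corr, anova_s, anova_e)
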