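"""Model-free behavioral statistics: selfish/equal deviations and the mixed ANOVA.

Choices are normalized to the kept fraction ``T_s / T`` so that rounds with
different token budgets are comparable.  Two rule-based deviation scores are
computed per trial:

* **selfish deviation** — distance from the payoff-maximizing rule, which
  keeps 100% of tokens in the gain frame and 0% in the loss frame (kept
  tokens are kept losses there); ratio-independent.
* **equal deviation** — distance from the payoff-equalizing kept fraction
  ``r_other / (r_self + r_other)``; frame-independent.

Per-participant condition means feed a 2 (Role) x 2 (Frame) within x
2 (Group) between mixed-design ANOVA.  The decomposition is written out from
sums of squares (between-subject stratum for Group; per-contrast
within-subject strata with subject-nested error terms) rather than delegated,
so it can be validated cell-by-cell against a brute-force oracle.  With
two-level factors every within effect has one numerator degree of freedom and
sphericity holds trivially.  Unequal group sizes are handled with Type III
(unweighted-marginal) sums of squares for the within-stratum main effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ChoiceDataset

__all__ = [
    "selfish_deviation",
    "equal_deviation",
    "add_deviations",
    "aggregate",
    "mixed_anova",
    "posthoc_pairwise",
    "EFFECTS",
]

EFFECTS = [
    "group",
    "role",
    "role:group",
    "frame",
    "frame:group",
    "role:frame",
    "role:frame:group",
]


def selfish_deviation(frame, tokens_kept, total_tokens):
    """Absolute deviation of the kept fraction from the selfish rule.

    Gain frame: ``|1 - T_s/T|``; loss frame: ``|0 - T_s/T|``.  Vectorized;
    ``frame`` is "gain"/"loss" (scalar or array).
    """
    total = np.asarray(total_tokens, dtype=float)
    if np.any(total <= 0):
        raise ZeroDivisionError("deviations are undefined for a zero token budget")
    c = np.asarray(tokens_kept, dtype=float) / total
    is_gain = np.asarray(frame) == "gain"
    out = np.where(is_gain, np.abs(1.0 - c), c)
    return float(out) if out.ndim == 0 else out


def equal_deviation(r_self, r_other, tokens_kept, total_tokens):
    """Absolute deviation of the kept fraction from the payoff-equalizing rule
    ``r_other / (r_self + r_other)``; identical in both frames."""
    total = np.asarray(total_tokens, dtype=float)
    if np.any(total <= 0):
        raise ZeroDivisionError("deviations are undefined for a zero token budget")
    c = np.asarray(tokens_kept, dtype=float) / total
    rs = np.asarray(r_self, dtype=float)
    ro = np.asarray(r_other, dtype=float)
    if np.any(rs <= 0) or np.any(ro <= 0):
        raise ValueError("exchange ratio components must be positive")
    out = np.abs(ro / (rs + ro) - c)
    return float(out) if out.ndim == 0 else out


def add_deviations(dataset: ChoiceDataset) -> pd.DataFrame:
    """Trial table with ``kept_fraction``, ``selfish_dev`` and ``equal_dev`` columns."""
    df = dataset.table.copy()
    df["kept_fraction"] = df["tokens_kept"] / df["total_tokens"]
    df["selfish_dev"] = selfish_deviation(df["frame"], df["tokens_kept"], df["total_tokens"])
    df["equal_dev"] = equal_deviation(
        df["r_self"], df["r_other"], df["tokens_kept"], df["total_tokens"]
    )
    return df


def aggregate(dataset: ChoiceDataset) -> pd.DataFrame:
    """Per participant x (role, frame) mean deviations.

    Returns one row per design cell with columns ``participant_id, group,
    role, frame, selfish_dev, equal_dev``; raises if any participant is
    missing a cell of the 2x2 within design.
    """
    df = add_deviations(dataset)
    out = (
        df.groupby(["participant_id", "group", "role", "frame"], as_index=False)[
            ["selfish_dev", "equal_dev"]
        ]
        .mean()
        .sort_values(["group", "participant_id", "role", "frame"])
        .reset_index(drop=True)
    )
    counts = out.groupby("participant_id").size()
    short = counts[counts < 4]
    if not short.empty:
        raise ValueError(
            f"incomplete within design for participant(s) {list(short.index)}: "
            "need all four role x frame cells"
        )
    return out


# --------------------------------------------------------------------------- ANOVA


@dataclass
class AnovaResult:
    """Mixed-ANOVA table with one row per effect (F, dfs, p, partial eta^2)."""

    table: pd.DataFrame

    def __str__(self) -> str:
        lines = []
        for row in self.table.itertuples():
            lines.append(
                f"{row.effect:>18s}: F({row.df1:d}, {row.df2:d}) = {row.F:.3f}, "
                f"p = {row.p:.4g}, eta_p^2 = {row.eta_p2:.3f}"
            )
        return "\n".join(lines)


def _cell_matrix(summaries: pd.DataFrame, response: str):
    """Pivot to per-subject cell values y[subject, (role, frame)] plus group labels."""
    req = {"participant_id", "group", "role", "frame", response}
    missing = req - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries lack columns: {sorted(missing)}")
    wide = summaries.pivot_table(
        index=["group", "participant_id"], columns=["role", "frame"], values=response
    )
    cols = [(r, f) for r in ("first", "third") for f in ("gain", "loss")]
    if wide.isna().any().any() or set(wide.columns) != set(cols):
        raise ValueError("within design incomplete: every subject needs all 4 cells")
    wide = wide[cols]
    groups = wide.index.get_level_values("group").to_numpy()
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"mixed ANOVA needs exactly 2 groups, found {labels}")
    y = wide.to_numpy()  # (N, 4) ordered first/gain, first/loss, third/gain, third/loss
    return y, groups, labels


def _oneway_ss(x: np.ndarray, groups: np.ndarray, labels) -> tuple[float, float, np.ndarray]:
    """Weighted group SS and residual SS of a one-way layout on scores x."""
    means = np.array([x[groups == g].mean() for g in labels])
    ns = np.array([(groups == g).sum() for g in labels])
    grand = x.mean()
    ss_group = float(np.sum(ns * (means - grand) ** 2))
    fitted = np.array([means[labels.index(g)] for g in groups])
    ss_err = float(np.sum((x - fitted) ** 2))
    return ss_group, ss_err, means


def mixed_anova(summaries: pd.DataFrame, response: str = "selfish_dev") -> AnovaResult:
    """2 (Role) x 2 (Frame) within x 2 (Group) between mixed-design ANOVA.

    ``summaries`` is the output of :func:`aggregate` (one row per subject per
    role x frame cell).  Each within-subject effect is tested against its own
    subject-nested error stratum; partial eta squared is
    ``SS_effect / (SS_effect + SS_error)``.
    """
    y, groups, labels = _cell_matrix(summaries, response)
    N = y.shape[0]
    ns = np.array([(groups == g).sum() for g in labels])
    if ns.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    n_harm4 = 4.0 * ns[0] * ns[1] / (ns[0] + ns[1])  # Type III multiplier

    # Per-subject scores: overall mean and halved within contrasts.
    m = y.mean(axis=1)
    c_role = (y[:, 0] + y[:, 1] - y[:, 2] - y[:, 3]) / 2.0
    c_frame = (y[:, 0] - y[:, 1] + y[:, 2] - y[:, 3]) / 2.0
    c_rf = (y[:, 0] - y[:, 1] - y[:, 2] + y[:, 3]) / 2.0

    rows = []

    def add_row(effect, ss_eff, ss_err, df2):
        if ss_err <= 0:
            raise ValueError(f"degenerate data: zero error variance in the {effect} stratum")
        F = (ss_eff / 1.0) / (ss_err / df2)
        p = float(stats.f.sf(F, 1, df2))
        rows.append(
            {
                "effect": effect,
                "SS": ss_eff,
                "SS_error": ss_err,
                "df1": 1,
                "df2": df2,
                "F": F,
                "p": p,
                "eta_p2": ss_eff / (ss_eff + ss_err),
            }
        )

    # Between-subject stratum (subject means carry 4 observations each).
    ss_g, ss_sg, _ = _oneway_ss(m, groups, labels)
    add_row("group", 4.0 * ss_g, 4.0 * ss_sg, N - 2)

    # Within strata: one-way layouts on the contrast scores.
    for effect, c in (("role", c_role), ("frame", c_frame), ("role:frame", c_rf)):
        ss_int, ss_err, means = _oneway_ss(c, groups, labels)
        unweighted = means.mean()
        ss_main = n_harm4 * unweighted**2
        add_row(effect, ss_main, ss_err, N - 2)
        add_row(f"{effect}:group", ss_int, ss_err, N - 2)

    table = pd.DataFrame(rows).set_index("effect").loc[EFFECTS].reset_index()
    return AnovaResult(table)


def posthoc_pairwise(
    summaries: pd.DataFrame,
    response: str = "selfish_dev",
    effect: str = "role:group",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Simple-effects comparisons unpacking the Role x Group interaction.

    For each role: the group difference in subject means (averaged over
    frames), with a pooled two-sample standard error.  For each group: the
    first-minus-third role difference, with the pooled within-subject error
    stratum.  P-values are uncorrected t-tests on N-2 df unless
    ``bonferroni`` is set (multiplies by the number of contrasts).
    """
    if effect != "role:group":
        raise NotImplementedError("only the role:group simple effects are implemented")
    y, groups, labels = _cell_matrix(summaries, response)
    N = y.shape[0]
    if len(labels) < 2:
        raise ValueError("group contrasts need two groups")
    ns = {g: (groups == g).sum() for g in labels}
    role_means = {"first": y[:, :2].mean(axis=1), "third": y[:, 2:].mean(axis=1)}
    rows = []
    # Group difference within each role.
    for role, x in role_means.items():
        xa, xb = x[groups == labels[0]], x[groups == labels[1]]
        sp2 = (np.sum((xa - xa.mean()) ** 2) + np.sum((xb - xb.mean()) ** 2)) / (N - 2)
        se = np.sqrt(sp2 * (1 / ns[labels[0]] + 1 / ns[labels[1]]))
        diff = xa.mean() - xb.mean()
        t = diff / se
        rows.append(
            {
                "contrast": f"{labels[0]} - {labels[1]} | role={role}",
                "estimate": diff,
                "se": se,
                "df": N - 2,
                "p": 2 * float(stats.t.sf(abs(t), N - 2)),
            }
        )
    # Role difference within each group (paired, pooled error across groups).
    d = role_means["first"] - role_means["third"]
    sp2 = sum(np.sum((d[groups == g] - d[groups == g].mean()) ** 2) for g in labels) / (N - 2)
    for g in labels:
        dg = d[groups == g]
        se = np.sqrt(sp2 / ns[g])
        t = dg.mean() / se
        rows.append(
            {
                "contrast": f"first - third | group={g}",
                "estimate": dg.mean(),
                "se": se,
                "df": N - 2,
                "p": 2 * float(stats.t.sf(abs(t), N - 2)),
            }
        )
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p"] = np.minimum(1.0, out["p"] * len(out))
    return out
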