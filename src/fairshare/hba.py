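"""Hierarchical Bayesian estimation of the inequity-aversion choice models.

The statistical model, for one between-subjects group fitted on its own:

* each individual-level parameter (a condition-k inequity weight, or the
  participant's log inverse temperature) is drawn from a group-level normal,
  ``theta_ik ~ Normal(mu_k, sigma_k)``, on an unconstrained scale;
* positivity-constrained parameters (lambda always; alpha and beta under M5)
  are the exponential of their unconstrained draw;
* weakly informative hyperpriors ``mu ~ Normal(0, 1)`` and
  ``sigma ~ half-Cauchy(0, 2)``;
* the likelihood is the softmax choice rule over each trial's full option
  set (:mod:`fairshare.models`).

Sampling uses the package's Hamiltonian Monte Carlo implementation
(:mod:`fairshare.sampler`) on the non-centered parameterization
(``theta = mu + sigma * z`` with standard-normal ``z``), which removes the
funnel geometry that otherwise cripples hierarchical scale parameters at
small sample sizes.  Gradients of the log posterior are computed analytically
and vectorized across trials, so a fit involves no autodiff framework.

The public surface follows the statsmodels convention: build a
:class:`HierarchicalChoiceModel` from a dataset, call :meth:`fit`, and work
with the returned :class:`PosteriorFit` results object (draw access,
``summary()``, R-hat, pointwise log-likelihood for information criteria).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ChoiceDataset
from .models import ModelSpec, get_model
from .sampler import ChainStats, hmc_chain
from .task import Frame

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "HierarchicalChoiceModel",
    "PosteriorFit",
    "rhat",
    "summarize",
    "load_fit",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors for the group-level normal populations.

    ``mean_loc``/``mean_scale`` parameterize the Normal prior on each
    group-level mean; ``sd_scale`` is the scale of the half-Cauchy prior on
    each group-level standard deviation.
    """

    mean_loc: float = 0.0
    mean_scale: float = 1.0
    sd_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_scale <= 0 or self.sd_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration; the defaults retain 3 x 2000 = 6000 draws."""

    chains: int = 3
    warmup: int = 2000
    samples: int = 2000
    seed: int = 0
    target_accept: float = 0.9
    trajectory_length: float = 2.0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.samples < 1:
            raise ValueError("chains, warmup and samples must all be positive")

    @property
    def total_draws(self) -> int:
        return self.chains * self.samples


@dataclass(frozen=True)
class _Family:
    """One hierarchical parameter family: K condition-indexed columns
    (K=4 for inequity weights, K=1 for the shared log inverse temperature)
    with an identity or exponential link to the natural scale."""

    name: str
    K: int
    transform: str  # "identity" | "exp"


class _Layout:
    """Flat-vector layout: group-level block then per-participant z blocks."""

    def __init__(self, families: list[_Family], n_participants: int):
        self.families = families
        self.N = n_participants
        self.slices: dict = {}
        pos = 0
        for f in families:
            self.slices[f"mu_{f.name}"] = slice(pos, pos + f.K)
            pos += f.K
            self.slices[f"log_sigma_{f.name}"] = slice(pos, pos + f.K)
            pos += f.K
        for f in families:
            self.slices[f"z_{f.name}"] = slice(pos, pos + self.N * f.K)
            pos += self.N * f.K
        self.dim = pos

    def unpack(self, x: np.ndarray, fam: _Family):
        mu = x[self.slices[f"mu_{fam.name}"]]
        log_sigma = x[self.slices[f"log_sigma_{fam.name}"]]
        z = x[self.slices[f"z_{fam.name}"]].reshape(self.N, fam.K)
        return mu, log_sigma, z

    def coord_names(self, participant_ids) -> list[str]:
        names = []
        for f in self.families:
            ks = range(1, f.K + 1)
            names += [f"mu_{f.name}[{k}]" for k in ks] if f.K > 1 else [f"mu_{f.name}"]
            names += (
                [f"log_sigma_{f.name}[{k}]" for k in ks]
                if f.K > 1
                else [f"log_sigma_{f.name}"]
            )
        for f in self.families:
            for pid in participant_ids:
                if f.K > 1:
                    names += [f"z_{f.name}[{pid},{k}]" for k in range(1, f.K + 1)]
                else:
                    names += [f"z_{f.name}[{pid}]"]
        return names


class _TrialArrays:
    """Padded per-trial payoff geometry shared by the likelihood and PPC.

    For trial t and option j (tokens kept = j): self payoff ``ms[t, j]``,
    advantageous inequity ``dp = max(Ms - Mo, 0)`` and disadvantageous
    inequity ``dm = max(Mo - Ms, 0)``, with ``mask`` marking real options.
    """

    def __init__(self, dataset: ChoiceDataset, participants: list):
        df = dataset.with_condition_index()
        pindex = {pid: i for i, pid in enumerate(participants)}
        T = df["total_tokens"].to_numpy(int)
        self.n_trials = len(df)
        self.Jmax = int(T.max()) + 1
        j = np.arange(self.Jmax)
        self.mask = j[None, :] <= T[:, None]
        rs = df["r_self"].to_numpy(float)[:, None]
        ro = df["r_other"].to_numpy(float)[:, None]
        ms = rs * j[None, :]
        mo = ro * (T[:, None] - j[None, :])
        loss = (df["frame"] == Frame.LOSS.value).to_numpy()
        sign = np.where(loss, -1.0, 1.0)[:, None]
        ms, mo = sign * ms, sign * mo
        self.ms = np.where(self.mask, ms, 0.0)
        self.dp = np.where(self.mask, np.maximum(ms - mo, 0.0), 0.0)
        self.dm = np.where(self.mask, np.maximum(mo - ms, 0.0), 0.0)
        self.obs = df["tokens_kept"].to_numpy(int)
        self.part = np.array([pindex[p] for p in df["participant_id"]], dtype=int)
        self.cond = df["k"].to_numpy(int) - 1
        self.rows = np.arange(self.n_trials)

    def loglik_terms(self, c_dp, c_dm, lam):
        """Per-trial log-likelihood and softmax probabilities for per-trial
        coefficient vectors (advantageous weight, disadvantageous weight,
        inverse temperature)."""
        U = self.ms - c_dp[:, None] * self.dp - c_dm[:, None] * self.dm
        logits = lam[:, None] * U
        logits = np.where(self.mask, logits, -np.inf)
        mx = logits.max(axis=1)
        ex = np.exp(logits - mx[:, None])
        sumex = ex.sum(axis=1)
        lse = mx + np.log(sumex)
        ll = logits[self.rows, self.obs] - lse
        P = ex / sumex[:, None]
        return ll, P, U


class HierarchicalChoiceModel:
    """Hierarchical softmax inequity-aversion model for one participant group.

    Parameters
    ----------
    dataset : ChoiceDataset
        Trials from a single between-subjects group (groups are fitted
        independently); all four role x frame conditions must be present.
    model : str or ModelSpec
        Candidate utility model id (``M1`` .. ``M5``).
    priors : PriorSpec
        Hyperpriors for the group-level means and SDs.

    Examples
    --------
    >>> fit = HierarchicalChoiceModel(ds, "M4").fit(chains=2, warmup=500,
    ...                                             samples=500, seed=1)
    >>> fit.summary().head()
    """

    def __init__(
        self,
        dataset: ChoiceDataset,
        model: "str | ModelSpec" = "M4",
        priors: PriorSpec = PriorSpec(),
    ):
        self.spec = get_model(model)
        self.priors = priors
        if len(dataset.groups) != 1:
            raise ValueError(
                f"fit one between-subjects group at a time; dataset has {dataset.groups}"
            )
        ks = set(dataset.with_condition_index()["k"])
        if ks != {1, 2, 3, 4}:
            raise ValueError(f"all four conditions must be present, found k={sorted(ks)}")
        self.dataset = dataset
        self.group = dataset.groups[0]
        self.participants = dataset.participants
        self.N = len(self.participants)
        exp_w = "exp" if self.spec.positive_constrained else "identity"
        self.families = [_Family(w, 4, exp_w) for w in self.spec.weight_names]
        self.families.append(_Family("lam", 1, "exp"))
        self.layout = _Layout(self.families, self.N)
        self._arrays = _TrialArrays(dataset, self.participants)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model="M4", priors: PriorSpec = PriorSpec()):
        return cls(ChoiceDataset(df), model, priors)

    # ------------------------------------------------------------- log posterior
    def _natural_values(self, x: np.ndarray) -> dict:
        """Per-family natural-scale individual parameter matrix (N, K)."""
        out = {}
        for fam in self.families:
            mu, log_sigma, z = self.layout.unpack(x, fam)
            theta = mu[None, :] + np.exp(log_sigma)[None, :] * z
            out[fam.name] = np.exp(theta) if fam.transform == "exp" else theta
        return out

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log posterior density (unnormalized) and its gradient.

        Returns ``-inf`` (with a zero gradient) for numerically overflowing
        states, which the sampler rejects.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp, grad = self._logp_and_grad_impl(x)
        if not (np.isfinite(lp) and np.all(np.isfinite(grad))):
            return -np.inf, np.zeros_like(x)
        return lp, grad

    def _logp_and_grad_impl(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        arr = self._arrays
        pr = self.priors
        grad = np.zeros_like(x)
        lp = 0.0

        theta_nat: dict = {}
        cache: dict = {}
        for fam in self.families:
            mu, log_sigma, z = self.layout.unpack(x, fam)
            sigma = np.exp(log_sigma)
            theta = mu[None, :] + sigma[None, :] * z
            nat = np.exp(theta) if fam.transform == "exp" else theta
            theta_nat[fam.name] = nat
            cache[fam.name] = (mu, log_sigma, sigma, z, nat)
            # Hyperpriors and z prior.
            lp += -0.5 * np.sum(((mu - pr.mean_loc) / pr.mean_scale) ** 2)
            r2 = (sigma / pr.sd_scale) ** 2
            lp += np.sum(-np.log1p(r2) + log_sigma)  # half-Cauchy + log Jacobian
            lp += -0.5 * np.sum(z**2)

        # Per-trial coefficients on the two inequity branches.
        i_t, k_t = arr.part, arr.cond
        c_dp = np.zeros(arr.n_trials)
        c_dm = np.zeros(arr.n_trials)
        if self.spec.uses_alpha:
            c_dp += theta_nat["alpha"][i_t, k_t]
        if self.spec.uses_beta:
            c_dm += theta_nat["beta"][i_t, k_t]
        if self.spec.uses_omega:
            om = theta_nat["omega"][i_t, k_t]
            c_dp += om
            c_dm += om
        lam = theta_nat["lam"][i_t, 0]

        ll, P, U = arr.loglik_terms(c_dp, c_dm, lam)
        lp += float(ll.sum())

        # Likelihood gradients w.r.t. the per-trial natural coefficients.
        e_dp = np.sum(P * arr.dp, axis=1)
        e_dm = np.sum(P * arr.dm, axis=1)
        e_u = np.sum(P * U, axis=1)
        g_cdp = lam * (e_dp - arr.dp[arr.rows, arr.obs])
        g_cdm = lam * (e_dm - arr.dm[arr.rows, arr.obs])
        g_lam = U[arr.rows, arr.obs] - e_u

        flat = i_t * 4 + k_t
        per_fam_nat_grad: dict = {}
        if self.spec.uses_alpha:
            per_fam_nat_grad["alpha"] = np.bincount(flat, g_cdp, minlength=self.N * 4).reshape(
                self.N, 4
            )
        if self.spec.uses_beta:
            per_fam_nat_grad["beta"] = np.bincount(flat, g_cdm, minlength=self.N * 4).reshape(
                self.N, 4
            )
        if self.spec.uses_omega:
            per_fam_nat_grad["omega"] = np.bincount(
                flat, g_cdp + g_cdm, minlength=self.N * 4
            ).reshape(self.N, 4)
        per_fam_nat_grad["lam"] = np.bincount(i_t, g_lam, minlength=self.N).reshape(self.N, 1)

        # Chain rule back to (mu, log_sigma, z) and add prior gradients.
        for fam in self.families:
            mu, log_sigma, sigma, z, nat = cache[fam.name]
            g_nat = per_fam_nat_grad[fam.name]
            g_theta = g_nat * nat if fam.transform == "exp" else g_nat
            sl = self.layout.slices
            grad[sl[f"mu_{fam.name}"]] = g_theta.sum(axis=0) - (mu - pr.mean_loc) / (
                pr.mean_scale**2
            )
            r2 = (sigma / pr.sd_scale) ** 2
            grad[sl[f"log_sigma_{fam.name}"]] = (
                np.sum(g_theta * z, axis=0) * sigma - 2.0 * r2 / (1.0 + r2) + 1.0
            )
            grad[sl[f"z_{fam.name}"]] = (g_theta * sigma[None, :] - z).ravel()
        return lp, grad

    # ------------------------------------------------------------------- fitting
    def _initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Jittered prior-scale initialization (means near 0, modest SDs)."""
        x = np.zeros(self.layout.dim)
        for fam in self.families:
            sl = self.layout.slices
            x[sl[f"mu_{fam.name}"]] = rng.normal(0.0, 0.5, fam.K)
            x[sl[f"log_sigma_{fam.name}"]] = rng.normal(-0.7, 0.3, fam.K)
            x[sl[f"z_{fam.name}"]] = rng.normal(0.0, 0.5, self.N * fam.K)
        if any(f.name == "lam" for f in self.families):
            # Start the temperature small so early utilities cannot saturate.
            x[self.layout.slices["mu_lam"]] = rng.normal(-2.0, 0.3)
        return x

    def fit(
        self,
        chains: int | None = None,
        warmup: int | None = None,
        samples: int | None = None,
        seed: int | None = None,
        target_accept: float | None = None,
        trajectory_length: float | None = None,
        config: McmcConfig | None = None,
    ) -> "PosteriorFit":
        """Sample the posterior; returns a :class:`PosteriorFit`.

        Keyword overrides take precedence over ``config``; the default
        configuration is the 3-chain 2000+2000 scheme.
        """
        base = config or McmcConfig()
        cfg = McmcConfig(
            chains=chains if chains is not None else base.chains,
            warmup=warmup if warmup is not None else base.warmup,
            samples=samples if samples is not None else base.samples,
            seed=seed if seed is not None else base.seed,
            target_accept=target_accept if target_accept is not None else base.target_accept,
            trajectory_length=(
                trajectory_length if trajectory_length is not None else base.trajectory_length
            ),
        )
        root = np.random.SeedSequence([int(cfg.seed), 0xABA])
        chain_seeds = root.spawn(cfg.chains)
        draws = np.empty((cfg.chains, cfg.samples, self.layout.dim))
        stats: list[ChainStats] = []
        for c in range(cfg.chains):
            rng = np.random.default_rng(chain_seeds[c])
            x0 = None
            for attempt in range(5):
                cand = self._initial_point(rng)
                lp, g = self.logp_and_grad(cand)
                if np.isfinite(lp) and np.all(np.isfinite(g)):
                    x0 = cand
                    break
            if x0 is None:
                raise RuntimeError("could not find a finite initialization in 5 attempts")
            s, st = hmc_chain(
                self.logp_and_grad,
                x0,
                cfg.warmup,
                cfg.samples,
                rng,
                target_accept=cfg.target_accept,
                trajectory_length=cfg.trajectory_length,
            )
            draws[c] = s
            stats.append(st)
        fit = PosteriorFit(self, draws, cfg, stats)
        bad = fit.max_rhat
        if np.isfinite(bad) and bad > 1.01:
            warnings.warn(
                f"convergence flagged: max split R-hat = {bad:.3f} > 1.01 "
                f"(model {self.spec.id}, group {self.group})",
                stacklevel=2,
            )
            fit.converged = False
        return fit


def rhat(chain_draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chain_draws`` has shape (chains, draws); each chain is split in half
    before computing the between/within variance ratio.  Returns NaN for
    degenerate (zero-variance) draws.
    """
    chain_draws = np.asarray(chain_draws, dtype=float)
    if chain_draws.ndim != 2 or chain_draws.shape[0] < 1:
        raise ValueError("rhat expects a (chains, draws) array")
    m, n = chain_draws.shape
    if m < 2 and n < 4:
        raise ValueError("need at least 2 chains or 4 draws to split")
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    split = np.concatenate([chain_draws[:, :half], chain_draws[:, half : 2 * half]], axis=0)
    if m == 1 and split.shape[0] < 2:
        raise ValueError("a single chain cannot be split into comparable halves")
    w = split.var(axis=1, ddof=1).mean()
    if w == 0:
        return float("nan")
    b = half * split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def summarize(fit: "PosteriorFit", parameter: str, mass: float = 0.95):
    """Posterior mean and highest-density interval of one parameter."""
    from .report import hdi

    d = fit.draws_of(parameter)
    return float(d.mean()), hdi(d, mass)


class PosteriorFit:
    """Posterior draws and diagnostics for one fitted group-level model.

    Attributes
    ----------
    draws : ndarray, shape (chains, samples, dim)
        Retained unconstrained draws.
    config : McmcConfig
    chain_stats : list of ChainStats
    converged : bool
        False when any split R-hat exceeds 1.01 (also warned at fit time).
    """

    def __init__(self, model: HierarchicalChoiceModel, draws, config, chain_stats):
        self.model = model
        self.spec = model.spec
        self.group = model.group
        self.participants = model.participants
        self.draws = draws
        self.config = config
        self.chain_stats = chain_stats
        self.converged = True
        self._names = model.layout.coord_names(model.participants)
        self._rhat: dict | None = None
        self._pointwise: np.ndarray | None = None

    # ------------------------------------------------------------------ access
    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def coord_names(self) -> list[str]:
        return list(self._names)

    def _flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def draws_of(self, parameter: str) -> np.ndarray:
        """Flattened draws of a named quantity, on the natural scale.

        Recognized names: raw coordinates (``mu_alpha[2]``,
        ``log_sigma_beta[1]``, ``mu_lam`` ...), ``sigma_<fam>[k]``
        (exponentiated log SD), individual-level ``alpha[pid,k]`` /
        ``beta[pid,k]`` / ``omega[pid,k]`` and ``lam[pid]``.
        """
        flat = self._flat()
        if parameter in self._names:
            return flat[:, self._names.index(parameter)].copy()
        if parameter.startswith("sigma_"):
            raw = "log_" + parameter
            if raw in self._names:
                return np.exp(flat[:, self._names.index(raw)])
        # individual-level natural-scale parameters
        for fam in self.model.families:
            pre = fam.name + "["
            if parameter.startswith(pre) and parameter.endswith("]"):
                inner = parameter[len(pre) : -1]
                if fam.K > 1:
                    pid, kstr = inner.rsplit(",", 1)
                    k = int(kstr)
                else:
                    pid, k = inner, 1
                return self._individual_draws(fam, pid, k)
        raise KeyError(f"unknown parameter {parameter!r}")

    def _individual_draws(self, fam: _Family, pid, k: int) -> np.ndarray:
        if pid not in self.participants:
            # participant ids may be non-string (e.g. ints) in the dataset
            matches = [p for p in self.participants if str(p) == str(pid)]
            if not matches:
                raise KeyError(f"unknown participant {pid!r}")
            pid = matches[0]
        flat = self._flat()
        nm = fam.name
        mu = flat[:, self._names.index(f"mu_{nm}[{k}]" if fam.K > 1 else f"mu_{nm}")]
        ls = flat[
            :, self._names.index(f"log_sigma_{nm}[{k}]" if fam.K > 1 else f"log_sigma_{nm}")
        ]
        zname = f"z_{nm}[{pid},{k}]" if fam.K > 1 else f"z_{nm}[{pid}]"
        z = flat[:, self._names.index(zname)]
        theta = mu + np.exp(ls) * z
        return np.exp(theta) if fam.transform == "exp" else theta

    def group_level(self, family: str, k: int | None = None) -> np.ndarray:
        """Draws of the group-level mean mu for a family (sampling scale)."""
        name = f"mu_{family}[{k}]" if k is not None else f"mu_{family}"
        return self.draws_of(name)

    def individual_posterior_means(self, family: str) -> pd.DataFrame:
        """Posterior mean of each participant's natural-scale parameters."""
        fam = next(f for f in self.model.families if f.name == family)
        rows = []
        for pid in self.participants:
            for k in range(1, fam.K + 1):
                d = self._individual_draws(fam, pid, k)
                rows.append({"participant_id": pid, "k": k, "mean": float(d.mean())})
        return pd.DataFrame(rows)

    # -------------------------------------------------------------- diagnostics
    @property
    def rhats(self) -> dict:
        if self._rhat is None:
            self._rhat = {
                name: rhat(self.draws[:, :, i]) for i, name in enumerate(self._names)
            }
        return self._rhat

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhats.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    @property
    def n_divergent(self) -> int:
        return int(sum(s.n_divergent for s in self.chain_stats))

    # ---------------------------------------------------------- log likelihood
    def pointwise_loglik(self, thin: int = 1) -> np.ndarray:
        """Per-draw per-trial log-likelihood matrix (draws x trials), row
        order matching the dataset; consumed by WAIC / PSIS-LOO."""
        if self._pointwise is not None and thin == 1:
            return self._pointwise
        arr = self.model._arrays
        flat = self._flat()[::thin]
        out = np.empty((flat.shape[0], arr.n_trials))
        i_t, k_t = arr.part, arr.cond
        for d, x in enumerate(flat):
            nat = self.model._natural_values(x)
            c_dp = np.zeros(arr.n_trials)
            c_dm = np.zeros(arr.n_trials)
            if self.spec.uses_alpha:
                c_dp += nat["alpha"][i_t, k_t]
            if self.spec.uses_beta:
                c_dm += nat["beta"][i_t, k_t]
            if self.spec.uses_omega:
                om = nat["omega"][i_t, k_t]
                c_dp += om
                c_dm += om
            lam = nat["lam"][i_t, 0]
            ll, _, _ = arr.loglik_terms(c_dp, c_dm, lam)
            out[d] = ll
        if thin == 1:
            self._pointwise = out
        return out

    # -------------------------------------------------------------- summaries
    def summary(self, mass: float = 0.95, group_level_only: bool = True) -> pd.DataFrame:
        """Posterior summary table: mean, sd, HDI bounds and split R-hat."""
        from .report import hdi

        rows = []
        names = [
            n
            for n in self._names
            if (not group_level_only) or n.startswith(("mu_", "log_sigma_"))
        ]
        for name in names:
            d = self.draws_of(name)
            lo, hi = hdi(d, mass)
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    f"hdi_{mass:g}_lo": lo,
                    f"hdi_{mass:g}_hi": hi,
                    "rhat": self.rhats[name],
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PosteriorFit {self.spec.id} group={self.group!r} "
            f"draws={self.n_draws} max_rhat={self.max_rhat:.4f}>"
        )

    def plot_posterior(self, parameters=None, ax=None):
        """Histogram the posteriors of group-level means (or named draws)."""
        import matplotlib.pyplot as plt

        if parameters is None:
            parameters = [
                f"mu_{fam}[{k}]"
                for fam in self.spec.weight_names
                for k in range(1, 5)
            ]
        if ax is None:
            _, ax = plt.subplots()
        for name in parameters:
            ax.hist(self.draws_of(name), bins=50, density=True, alpha=0.5, label=name)
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("parameter value")
        ax.set_ylabel("posterior density")
        ax.legend(fontsize="small")
        ax.set_title(f"{self.spec.id}, group {self.group}")
        return ax

    # ------------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Persist draws as a long CSV plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        chains, samples, dim = self.draws.shape
        recs = {
            "chain": np.repeat(np.arange(chains), samples * dim),
            "draw": np.tile(np.repeat(np.arange(samples), dim), chains),
            "parameter": np.tile(self._names, chains * samples),
            "value": self.draws.ravel(),
        }
        pd.DataFrame(recs).to_csv(path, index=False)
        meta = {
            "model": self.spec.id,
            "group": str(self.group),
            "chains": chains,
            "samples": samples,
            "warmup": self.config.warmup,
            "seed": self.config.seed,
            "max_rhat": float(self.max_rhat),
            "n_divergent": self.n_divergent,
            "converged": bool(self.converged),
            "participants": [str(p) for p in self.participants],
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def load_fit(path, dataset: ChoiceDataset) -> PosteriorFit:
    """Rebuild a :class:`PosteriorFit` from a saved draws CSV + metadata,
    given the dataset it was fitted on (full dataset is fine; the fitted
    group is selected by the metadata)."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    sub = dataset
    if len(dataset.groups) > 1:
        matches = [g for g in dataset.groups if str(g) == meta["group"]]
        if not matches:
            raise KeyError(f"group {meta['group']!r} not in dataset")
        sub = dataset.for_group(matches[0])
    model = HierarchicalChoiceModel(sub, meta["model"])
    long = pd.read_csv(path)
    names = model.layout.coord_names(model.participants)
    chains, samples = meta["chains"], meta["samples"]
    draws = (
        long["value"].to_numpy().reshape(chains, samples, len(names))
        if list(long["parameter"][: len(names)]) == names
        else None
    )
    if draws is None:
        raise ValueError("draws file does not match the model layout")
    cfg = McmcConfig(chains=chains, warmup=meta["warmup"], samples=samples, seed=meta["seed"])
    stats = [ChainStats(np.nan, np.nan, 0, 0) for _ in range(chains)]
    fit = PosteriorFit(model, draws, cfg, stats)
    fit.converged = bool(meta.get("converged", True))
    return fit
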