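"""Survey-seeded agent-based models of social influence.

Five classic models, all seeded by bootstrap-resampling real (or synthetic)
respondents of one country:

* Deffuant — random pairwise encounters; both agents move toward each
  other by a fraction mu of their difference when it is below the
  confidence threshold eps (scalar opinions on the 3-15 vaccine score).
* Hegselmann-Krause (HK) and its geometric (HK-G) and harmonic (HK-H)
  variants — synchronous updates to the arithmetic / geometric / harmonic
  mean of all opinions within eps (self included).
* Axelrod — categorical opinions: 3 features (the three vaccine items)
  with 5 traits each; pairs interact with probability equal to their
  fraction of shared features, copying one differing feature.

Skeptics are agents whose initial summed vaccine score is <= 9 (neutral or
negative); each run records their mean score before and after the dynamics.
A :func:`run_study` correlates the seeding country's attitude-isolation
with the skeptics' final mean across many runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .attitude_network import attitude_isolation
from .survey_core import SKEPTIC_THRESHOLD, SurveyDataset, vaccine_score

__all__ = [
    "MODELS",
    "ModelConfig",
    "AgentPopulation",
    "RunRecord",
    "SimulationStudy",
    "seed_population",
    "run_deffuant",
    "run_hk",
    "run_axelrod",
    "run_model",
    "run_study",
]

logger = logging.getLogger(__name__)

MODELS = ("deffuant", "hk", "hk_g", "hk_h", "axelrod")
_HK_MEANS = {"hk": "arithmetic", "hk_g": "geometric", "hk_h": "harmonic"}


@dataclass
class ModelConfig:
    """Model choice and dynamics parameters.

    ``eps`` is the confidence threshold on the 3-15 score scale (ignored by
    Axelrod).  ``max_steps`` counts pairwise encounter events for Deffuant
    and Axelrod and synchronous sweeps for HK; ``None`` uses 100 * n_agents
    events or 100 sweeps respectively.
    """

    model: str = "deffuant"
    eps: float = 6.0
    mu: float = 0.5  # Deffuant convergence rate; 0.5 = meet at the midpoint
    max_steps: int | None = None
    convergence_tol: float = 1e-4
    n_agents: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.model != "axelrod" and self.eps <= 0:
            raise ValueError("eps must be > 0 for bounded-confidence models")
        if not 0.0 < self.mu <= 0.5:
            raise ValueError("mu must be in (0, 0.5]")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")

    def steps(self, n_agents: int) -> int:
        if self.max_steps is not None:
            return self.max_steps
        return 100 * n_agents if self.model in ("deffuant", "axelrod") else 100


@dataclass
class AgentPopulation:
    """Agents in scalar (opinion in [3, 15]) or categorical (3 features x 5
    traits) mode, with skeptic flags frozen at initialization."""

    mode: str  # "scalar" | "categorical"
    opinions: np.ndarray | None = None
    features: np.ndarray | None = None
    skeptic: np.ndarray = field(default=None)  # type: ignore[assignment]
    country: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("scalar", "categorical"):
            raise ValueError("mode must be 'scalar' or 'categorical'")
        if self.skeptic is None:
            self.skeptic = self.scores() <= SKEPTIC_THRESHOLD

    @property
    def n(self) -> int:
        arr = self.opinions if self.mode == "scalar" else self.features
        return len(arr)

    def scores(self) -> np.ndarray:
        """Per-agent summed vaccine score (trait sum in categorical mode)."""
        if self.mode == "scalar":
            return self.opinions
        return self.features.sum(axis=1).astype(float)

    def skeptic_mean(self) -> float:
        """Mean score of the initially skeptical agents (NaN if none)."""
        if not self.skeptic.any():
            return float("nan")
        return float(self.scores()[self.skeptic].mean())


@dataclass
class RunRecord:
    country: str
    isolation: float
    skeptic_mean_initial: float
    skeptic_mean_final: float
    model: str
    eps: float


@dataclass
class SimulationStudy:
    """A collection of runs and the isolation-vs-final-skeptic-trust r."""

    records: pd.DataFrame
    r: float
    p_value: float
    n_runs: int
    n_excluded: int  # runs without skeptics, excluded from r

    def spearman(self) -> tuple[float, float]:
        ok = self.records["skeptic_mean_final"].notna()
        r, p = stats.spearmanr(
            self.records.loc[ok, "isolation"], self.records.loc[ok, "skeptic_mean_final"]
        )
        return float(r), float(p)


def seed_population(
    data: SurveyDataset,
    country: str,
    n_agents: int,
    rng: np.random.Generator,
    mode: str = "scalar",
) -> AgentPopulation:
    """Bootstrap-sample one country's complete-vaccine respondents.

    Sampling is with replacement, so countries smaller than ``n_agents``
    still seed a full population.  Scalar mode initializes opinions to the
    summed score; categorical mode to the three raw codes.
    """
    sub = data.restrict(country)
    vax_ids = [it.item_id for it in sub.vaccine_items]
    complete = sub.complete_mask(vax_ids)
    if not complete.any():
        raise ValueError(f"country {country!r} has no complete vaccine respondents")
    pick = rng.integers(0, int(complete.sum()), size=n_agents)
    if mode == "scalar":
        scores = vaccine_score(sub)[complete].to_numpy(dtype=float)[pick]
        return AgentPopulation("scalar", opinions=scores, country=country)
    codes = sub.codes(vax_ids).to_numpy(dtype=float)[complete][pick]
    return AgentPopulation("categorical", features=codes.astype(np.int64), country=country)


# -- Deffuant ----------------------------------------------------------


@njit(cache=True)
def _deffuant_events(x, pi, pj, eps, mu):  # pragma: no cover - jitted
    for k in range(pi.shape[0]):
        i, j = pi[k], pj[k]
        if i == j:
            continue
        diff = x[j] - x[i]
        if diff < eps and -diff < eps:
            x[i] += mu * diff
            x[j] -= mu * diff


def _scalar_converged(x: np.ndarray, eps: float, move_tol: float, mu: float) -> bool:
    # Converged when every eps-separated opinion cluster has spread small
    # enough that no admissible pair can move more than move_tol.
    xs = np.sort(x)
    gaps = np.diff(xs)
    bounds = np.flatnonzero(gaps >= eps)
    start = 0
    for b in list(bounds) + [len(xs) - 1]:
        if xs[b] - xs[start] > move_tol / mu:
            return False
        start = b + 1
    return True


def run_deffuant(pop: AgentPopulation, cfg: ModelConfig) -> AgentPopulation:
    """Pairwise bounded-confidence averaging; conserves the mean opinion."""
    if pop.mode != "scalar":
        raise ValueError("Deffuant requires a scalar population")
    x = pop.opinions.astype(np.float64).copy()
    n = len(x)
    rng = np.random.default_rng(cfg.seed)
    budget = cfg.steps(n)
    chunk = max(n, 1)
    done = 0
    while done < budget:
        m = min(chunk, budget - done)
        pairs = rng.integers(0, n, size=(m, 2))
        _deffuant_events(x, pairs[:, 0], pairs[:, 1], cfg.eps, cfg.mu)
        done += m
        if _scalar_converged(x, cfg.eps, cfg.convergence_tol, cfg.mu):
            break
    return replace(pop, opinions=x)


# -- Hegselmann-Krause -------------------------------------------------


def _hk_sweep(x: np.ndarray, eps: float, mean_type: str) -> np.ndarray:
    """One synchronous update: each agent adopts the chosen mean of all
    opinions within eps (closed neighbourhood, self included)."""
    order = np.argsort(x)
    xs = x[order]
    lo = np.searchsorted(xs, x - eps, side="left")
    hi = np.searchsorted(xs, x + eps, side="right")
    cnt = hi - lo
    if mean_type == "arithmetic":
        cs = np.concatenate(([0.0], np.cumsum(xs)))
        return (cs[hi] - cs[lo]) / cnt
    if mean_type == "geometric":
        cs = np.concatenate(([0.0], np.cumsum(np.log(xs))))
        return np.exp((cs[hi] - cs[lo]) / cnt)
    if mean_type == "harmonic":
        cs = np.concatenate(([0.0], np.cumsum(1.0 / xs)))
        return cnt / (cs[hi] - cs[lo])
    raise ValueError(f"unknown mean_type {mean_type!r}")


def run_hk(
    pop: AgentPopulation, cfg: ModelConfig, mean_type: str | None = None
) -> AgentPopulation:
    """Synchronous bounded-confidence model with a choice of update mean.

    Opinions live on [3, 15] (> 0), so geometric and harmonic means are
    well defined.  Stops when the largest per-sweep change is below
    ``convergence_tol`` or after ``max_steps`` sweeps.
    """
    if pop.mode != "scalar":
        raise ValueError("HK requires a scalar population")
    if mean_type is None:
        mean_type = _HK_MEANS.get(cfg.model, "arithmetic")
    x = pop.opinions.astype(np.float64).copy()
    if (x <= 0).any():
        raise ValueError("HK variants require strictly positive opinions")
    for _ in range(cfg.steps(len(x))):
        new = _hk_sweep(x, cfg.eps, mean_type)
        delta = np.abs(new - x).max()
        x = new
        if delta < cfg.convergence_tol:
            break
    return replace(pop, opinions=x)


# -- Axelrod -----------------------------------------------------------


@njit(cache=True)
def _axelrod_events(f, pi, pj, u, r):  # pragma: no cover - jitted
    nf = f.shape[1]
    for k in range(pi.shape[0]):
        i, j = pi[k], pj[k]
        if i == j:
            continue
        shared = 0
        for q in range(nf):
            if f[i, q] == f[j, q]:
                shared += 1
        if shared == 0 or shared == nf:
            continue
        if u[k] < shared / nf:
            pick = int(r[k] * (nf - shared))
            c = 0
            for q in range(nf):
                if f[i, q] != f[j, q]:
                    if c == pick:
                        f[i, q] = f[j, q]
                        break
                    c += 1


def _axelrod_absorbed(f: np.ndarray) -> bool:
    # Absorbing iff every pair of distinct cultures shares no feature.
    cultures = np.unique(f, axis=0)
    k = len(cultures)
    for a in range(k):
        for b in range(a + 1, k):
            if (cultures[a] == cultures[b]).any():
                return False
    return True


def run_axelrod(pop: AgentPopulation, cfg: ModelConfig) -> AgentPopulation:
    """Cultural-dissemination dynamics on the three vaccine items.

    Interaction probability equals the fraction of shared features; on
    interaction the first agent copies one randomly chosen differing
    feature.  Halts at the absorbing state (every pair shares all or no
    features) or after the event budget.
    """
    if pop.mode != "categorical":
        raise ValueError("Axelrod requires a categorical population")
    f = pop.features.astype(np.int64).copy()
    n = len(f)
    rng = np.random.default_rng(cfg.seed)
    budget = cfg.steps(n)
    chunk = max(10 * n, 1)
    done = 0
    if _axelrod_absorbed(f):
        return replace(pop, features=f)
    while done < budget:
        m = min(chunk, budget - done)
        pairs = rng.integers(0, n, size=(m, 2))
        _axelrod_events(f, pairs[:, 0], pairs[:, 1], rng.random(m), rng.random(m))
        done += m
        if _axelrod_absorbed(f):
            break
    return replace(pop, features=f)


def run_model(pop: AgentPopulation, cfg: ModelConfig) -> AgentPopulation:
    """Dispatch to the configured model."""
    if cfg.model == "deffuant":
        return run_deffuant(pop, cfg)
    if cfg.model in _HK_MEANS:
        return run_hk(pop, cfg)
    return run_axelrod(pop, cfg)


# -- study -------------------------------------------------------------


def run_study(
    data: SurveyDataset,
    cfg: ModelConfig,
    n_runs: int = 1000,
    countries: list[str] | None = None,
) -> SimulationStudy:
    """Correlate country attitude-isolation with final skeptic trust.

    Each run picks a country uniformly at random, bootstrap-seeds the
    agents from it, runs the dynamics and records the skeptics' initial
    and final mean score together with the country's isolation.  The study
    statistic is the Pearson r between isolation and the final skeptic
    mean over runs; runs with no skeptics are recorded with NaN and
    excluded from r.
    """
    countries = countries if countries is not None else data.countries
    iso = {}
    for c in countries:
        try:
            iso[c] = attitude_isolation(data, country=c).isolation
        except ValueError:
            logger.warning("country %s skipped: isolation undefined", c)
    usable = sorted(iso)
    if not usable:
        raise ValueError("no country with computable isolation")
    if len(usable) < 2:
        warnings.warn("single country: study correlation will be undefined")

    mode = "categorical" if cfg.model == "axelrod" else "scalar"
    root = np.random.SeedSequence(cfg.seed)
    records = []
    for run_seed in root.spawn(n_runs):
        rng = np.random.default_rng(run_seed)
        country = usable[rng.integers(0, len(usable))]
        pop = seed_population(data, country, cfg.n_agents, rng, mode=mode)
        run_cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        final = run_model(pop, run_cfg)
        records.append(
            RunRecord(
                country,
                iso[country],
                pop.skeptic_mean(),
                final.skeptic_mean(),
                cfg.model,
                cfg.eps,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    ok = df["skeptic_mean_final"].notna()
    n_excl = int((~ok).sum())
    if n_excl:
        logger.info("%d runs without skeptics excluded from r", n_excl)
    x, y = df.loc[ok, "isolation"], df.loc[ok, "skeptic_mean_final"]
    if ok.sum() < 3 or x.nunique() < 2 or y.nunique() < 2:
        warnings.warn("study correlation undefined (too few runs or zero variance)")
        r = p = float("nan")
    else:
        r, p = stats.pearsonr(x, y)
    return SimulationStudy(df, float(r), float(p), n_runs, n_excl)
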