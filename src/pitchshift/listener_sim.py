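"""Synthetic listener cohorts for the pitch-shift experiments.

Individual listeners differ stably in whether they judge the pitch of a
band-limited complex tone by its (possibly missing) fundamental or by the
audible partials.  The simulator captures this with a latent
spectral-listening trait per participant on the logit scale and a logistic
response model over condition features:

    P(spectral response) = logistic(trait + beta_lowcut · (k − 1)
                                          + beta_series · 1[Y series])

where k ∈ {1..4} indexes the low-frequency cutoff (250/500/750/1000 Hz)
and the Y indicator marks the narrower 1300-Hz high cut.  Positive betas
make spectral responses more likely as more low partials are removed and
when the high partials are also removed — the two qualitative effects the
experiments demonstrate.  Each participant answers every condition twice,
the repetitions conditionally independent given the trait; disagreement
between the two repetitions is what the analysis stage calls an ambiguous
response.

The default population (trait ~ Normal(−1.3, 1.2²), beta_lowcut = 0.7,
beta_series = 0.8) yields cohort-mean SI rising from about −0.5 at X1 to
about +0.3 at X4, uniformly higher for the Y series — the pattern of the
human data in direction, not in exact figure values.  Age group is a
label only: the default model has no age effect, matching the absence of
age differences in the human cohorts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

from .errors import ConfigurationError
from .si_analysis import F0, SPECTRAL
from .stimulus import CONDITION_NAMES

__all__ = [
    "SimulationConfig",
    "ListenerProfile",
    "default_config",
    "condition_features",
    "spectral_probability",
    "simulate_cohort",
    "export_responses",
    "load_responses",
    "fit_population_model",
    "PopulationFit",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = (
    "participant_id",
    "age_group",
    "experiment",
    "condition",
    "repetition",
    "response",
)

YOUNG = "young"  # <= 39 years
OLD = "old"      # >= 40 years

#: Cohort sizes of the two experiments: (younger, older) participants.
COHORT_SIZES = {1: (19, 20), 2: (18, 20)}


@dataclass(frozen=True)
class SimulationConfig:
    """Population and design parameters for one simulated cohort.

    ``mu_trait``/``sd_trait`` give the Normal distribution of the latent
    spectral-listening trait (logit scale); ``beta_lowcut`` is the logit
    increase per low-cutoff step (250→500→750→1000 Hz); ``beta_series``
    is the logit increase for the Y series (1300-Hz high cut).
    """

    n_young: int = 19
    n_old: int = 20
    mu_trait: float = -1.3
    sd_trait: float = 1.2
    beta_lowcut: float = 0.7
    beta_series: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 0 or self.n_old < 0:
            raise ConfigurationError("cohort counts must be non-negative")
        if self.sd_trait < 0:
            raise ConfigurationError("sd_trait must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_young + self.n_old

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(experiment: int = 1, seed: int = 0, **overrides) -> SimulationConfig:
    """The default population at the cohort size of the given experiment."""
    if experiment not in COHORT_SIZES:
        raise ConfigurationError(f"experiment must be 1 or 2, got {experiment}")
    n_young, n_old = COHORT_SIZES[experiment]
    return replace(
        SimulationConfig(n_young=n_young, n_old=n_old, seed=seed), **overrides
    )


@dataclass(frozen=True)
class ListenerProfile:
    """One simulated participant: id, age-group label, latent trait (logit scale)."""

    participant_id: int
    age_group: str
    trait: float


def condition_features(condition: str) -> tuple[int, bool]:
    """(low-cut index k in 1..4, is_Y_series) for a condition name."""
    if condition not in CONDITION_NAMES:
        raise ConfigurationError(f"unknown condition {condition!r}")
    return int(condition[1]), condition[0] == "Y"


def _linear_predictor(trait, config: SimulationConfig) -> np.ndarray:
    """trait (scalar or array) broadcast against the 8 conditions -> (..., 8)."""
    k = np.array([condition_features(c)[0] for c in CONDITION_NAMES])
    is_y = np.array([condition_features(c)[1] for c in CONDITION_NAMES], dtype=float)
    trait = np.asarray(trait, dtype=np.float64)
    return (
        trait[..., None]
        + config.beta_lowcut * (k - 1)
        + config.beta_series * is_y
    )


def spectral_probability(
    profile: ListenerProfile | float, condition: str, config: SimulationConfig
) -> float:
    """P(spectral response) for one listener in one condition."""
    trait = profile.trait if isinstance(profile, ListenerProfile) else float(profile)
    idx = CONDITION_NAMES.index(condition)
    return float(expit(_linear_predictor(trait, config)[..., idx]))


def draw_cohort(config: SimulationConfig, rng: np.random.Generator) -> list[ListenerProfile]:
    """Sample participant traits; younger participants get the lower ids."""
    traits = rng.normal(config.mu_trait, config.sd_trait, size=config.n_total)
    groups = [YOUNG] * config.n_young + [OLD] * config.n_old
    return [
        ListenerProfile(participant_id=i + 1, age_group=g, trait=float(t))
        for i, (g, t) in enumerate(zip(groups, traits))
    ]


def simulate_cohort(
    config: SimulationConfig,
    experiment: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one cohort: every participant × 8 conditions × 2 repetitions.

    Each response is an independent Bernoulli(spectral_probability) draw
    given the participant's trait.  Fully reproducible: the stream is
    seeded from (seed or config.seed, experiment).
    """
    if experiment not in (1, 2):
        raise ConfigurationError(f"experiment must be 1 or 2, got {experiment}")
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(base), int(experiment)]))
    cohort = draw_cohort(config, rng)
    n = len(cohort)
    if n == 0:
        return pd.DataFrame(columns=list(RESPONSE_COLUMNS))

    traits = np.array([p.trait for p in cohort])
    probs = expit(_linear_predictor(traits, config))  # (n, 8)
    draws = rng.random((n, 8, 2)) < probs[..., None]  # True -> spectral

    ids = np.repeat([p.participant_id for p in cohort], 16)
    ages = np.repeat([p.age_group for p in cohort], 16)
    conds = np.tile(np.repeat(CONDITION_NAMES, 2), n)
    reps = np.tile([1, 2], 8 * n)
    resp = np.where(draws.reshape(-1), SPECTRAL, F0)
    return pd.DataFrame(
        {
            "participant_id": ids,
            "age_group": ages,
            "experiment": experiment,
            "condition": conds,
            "repetition": reps,
            "response": resp,
        }
    )


def export_responses(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a response table as CSV with the fixed schema."""
    missing = set(RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"response table missing columns: {sorted(missing)}")
    path = Path(path)
    table.loc[:, list(RESPONSE_COLUMNS)].to_csv(path, index=False)
    return path


def load_responses(path: str | Path) -> pd.DataFrame:
    """Read a response CSV back; inverse of export_responses."""
    df = pd.read_csv(path, dtype={"response": str, "age_group": str, "condition": str})
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"response CSV missing columns: {sorted(missing)}")
    return df


@dataclass(frozen=True)
class PopulationFit:
    """Maximum-likelihood estimates of the four population parameters."""

    params: dict[str, float]
    se: dict[str, float]
    loglik: float
    converged: bool


def _tally_matrix(responses: pd.DataFrame) -> np.ndarray:
    """(n_participants, 8) matrix of spectral counts per condition."""
    counts = (
        responses.assign(sp=(responses["response"] == SPECTRAL).astype(int))
        .pivot_table(index="participant_id", columns="condition", values="sp", aggfunc="sum")
        .reindex(columns=list(CONDITION_NAMES))
    )
    if counts.isna().any().any():
        raise ConfigurationError("every participant needs responses in all 8 conditions")
    return counts.to_numpy(dtype=np.float64)


def _neg_loglik(theta: np.ndarray, sp: np.ndarray, reps: int, nodes: int) -> float:
    mu, sd, b_lc, b_se = theta
    sd = max(sd, 1e-6)
    z, w = np.polynomial.hermite_e.hermegauss(nodes)  # weight exp(-z^2/2)
    t = mu + sd * z  # (J,)
    cfg = SimulationConfig(mu_trait=mu, sd_trait=sd, beta_lowcut=b_lc, beta_series=b_se)
    eta = _linear_predictor(t, cfg)  # (J, 8)
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    # per-participant log-integrand at each node: (n, J)
    m = sp @ logp.T + (reps - sp) @ log1mp.T
    logw = np.log(w / w.sum())  # Hermite weights normalized to a probability measure
    return -float(logsumexp(m + logw, axis=1).sum())


def fit_population_model(
    responses: pd.DataFrame,
    repetitions: int = 2,
    nodes: int = 31,
    x0: Iterable[float] = (0.0, 1.0, 0.0, 0.0),
) -> PopulationFit:
    """Marginal maximum likelihood for (mu_trait, sd_trait, beta_lowcut, beta_series).

    The trait is integrated out per participant by Gauss–Hermite quadrature
    and the four population parameters are optimized directly; standard
    errors come from the inverse of a central-difference Hessian at the
    optimum.  Intended for parameter-recovery checks on large simulated
    cohorts rather than for small human samples.
    """
    sp = _tally_matrix(responses)
    args = (sp, repetitions, nodes)
    res = optimize.minimize(
        _neg_loglik,
        np.asarray(list(x0), dtype=float),
        args=args,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
    )
    theta = res.x

    # central-difference Hessian for standard errors
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    hess = np.zeros((k, k))
    f0 = _neg_loglik(theta, *args)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fpp = _neg_loglik(theta + ei, *args)
                fmm = _neg_loglik(theta - ei, *args)
                hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            else:
                fpp = _neg_loglik(theta + ei + ej, *args)
                fpm = _neg_loglik(theta + ei - ej, *args)
                fmp = _neg_loglik(theta - ei + ej, *args)
                fmm = _neg_loglik(theta - ei - ej, *args)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(k, np.nan)

    names = ("mu_trait", "sd_trait", "beta_lowcut", "beta_series")
    return PopulationFit(
        params=dict(zip(names, map(float, theta))),
        se=dict(zip(names, map(float, se))),
        loglik=-float(res.fun),
        converged=bool(res.success),
    )
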