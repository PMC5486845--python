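"""Per-time-point Bayesian estimation of Malpighian guanine occurrence.

The study design is saturated in time (one free occurrence probability
per distinct sampling time), so with a Jeffreys Beta(1/2, 1/2) prior the
posterior at each time is conjugate:

    pi_t | data  ~  Beta(n_pos + 1/2, n_obs - n_pos + 1/2)

which is exactly what a logit-link Gibbs sampler converges to for the
saturated model.  The conjugate closed form is the default path; an
MCMC cross-check (emcee, logit parameterisation, mirroring the original
30,000-update burn-in + 30,000-update summary scheme) is optional.

The anterior-vs-posterior contrast is the log odds ratio
ln[pi1/(1-pi1) * (1-pi2)/pi2], summarised by Monte-Carlo draws from the
two independent Beta posteriors, alongside the Woolf asymptotic
standard deviation sqrt(1/x1 + 1/(n1-x1) + 1/x2 + 1/(n2-x2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ANTERIOR_REGIONS,
    POSTERIOR_REGIONS,
    GutRegion,
    ScoreTable,
    register_result,
)

JEFFREYS = 0.5


@register_result
@dataclass(frozen=True)
class OccurrenceEstimate:
    """Beta posterior for guanine occurrence at one sampling time."""

    time_min: float
    n_obs: int
    n_pos: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if not 0 <= self.n_pos <= self.n_obs:
            raise ValueError("n_pos must be in [0, n_obs]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("posterior must be proper (alpha, beta > 0)")

    @property
    def posterior_mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def posterior_sd(self) -> float:
        a, b = self.alpha, self.beta
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))


@register_result
@dataclass
class OddsRatioSummary:
    """Monte-Carlo summary of the anterior-vs-posterior log odds ratio."""

    log_or_mean: float
    log_or_sd: float
    asymptotic_sd: float
    n_draws: int
    ci_low: float
    ci_high: float
    per_time: list = field(default_factory=list)  # (time_min, mean, sd) rows

    @property
    def mc_se(self) -> float:
        return self.log_or_sd / np.sqrt(self.n_draws)


def dichotomize(
    table: ScoreTable,
    threshold: int = 1,
    exclude: frozenset[GutRegion] | set[GutRegion] = frozenset({GutRegion.RECTALV}),
    include: set[GutRegion] | None = None,
) -> pd.DataFrame:
    """Pool positive/total counts over mites and regions at each time.

    A record is positive when malpighian_score >= threshold.  The
    rectal vesicle is excluded by default (occurrence is averaged over
    all gut regions bar the rectal vesicle).  ``include`` restricts to
    an explicit region set (applied after ``exclude``).

    Returns a DataFrame with columns time_min, n_pos, n_obs.
    """
    if threshold not in (1, 2):
        raise ValueError("threshold must be 1 or 2")
    frame = table.to_frame()
    keep = ~frame["region"].isin([r.value for r in exclude])
    if include is not None:
        keep &= frame["region"].isin([r.value for r in include])
    frame = frame[keep]
    if frame.empty:
        raise ValueError("no records left after region filtering")
    frame = frame.assign(pos=(frame["malpighian_score"] >= threshold).astype(int))
    out = (
        frame.groupby("time_min", sort=True)
        .agg(n_pos=("pos", "sum"), n_obs=("pos", "size"))
        .reset_index()
    )
    return out


def estimate_probabilities(
    counts: pd.DataFrame,
    prior_a: float = JEFFREYS,
    prior_b: float = JEFFREYS,
) -> list[OccurrenceEstimate]:
    """Conjugate Beta posteriors from pooled counts (one per time)."""
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError("prior parameters must be positive")
    estimates = []
    for row in counts.itertuples(index=False):
        n_pos, n_obs = int(row.n_pos), int(row.n_obs)
        if n_pos < 0 or n_obs < 1 or n_pos > n_obs:
            raise ValueError(f"invalid counts ({n_pos}, {n_obs}) at t={row.time_min}")
        estimates.append(
            OccurrenceEstimate(
                time_min=float(row.time_min),
                n_obs=n_obs,
                n_pos=n_pos,
                alpha=n_pos + prior_a,
                beta=n_obs - n_pos + prior_b,
            )
        )
    return estimates


def estimates_to_frame(estimates: list[OccurrenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_min": [e.time_min for e in estimates],
            "n_obs": [e.n_obs for e in estimates],
            "n_pos": [e.n_pos for e in estimates],
            "alpha": [e.alpha for e in estimates],
            "beta": [e.beta for e in estimates],
            "posterior_mean": [e.posterior_mean for e in estimates],
        }
    )


def estimates_from_frame(frame: pd.DataFrame) -> list[OccurrenceEstimate]:
    return [
        OccurrenceEstimate(
            time_min=float(r.time_min),
            n_obs=int(r.n_obs),
            n_pos=int(r.n_pos),
            alpha=float(r.alpha),
            beta=float(r.beta),
        )
        for r in frame.itertuples(index=False)
    ]


def woolf_sd(x1: int, n1: int, x2: int, n2: int) -> float:
    """Asymptotic sd of the log odds ratio (infinite for zero cells)."""
    cells = np.array([x1, n1 - x1, x2, n2 - x2], dtype=float)
    if np.any(cells == 0):
        return float("inf")
    return float(np.sqrt((1.0 / cells).sum()))


def log_odds_ratio(
    anterior_counts: pd.DataFrame,
    posterior_counts: pd.DataFrame,
    n_draws: int = 30_000,
    burn_in: int = 30_000,
    seed: int | None = None,
    prior_a: float = JEFFREYS,
    prior_b: float = JEFFREYS,
) -> OddsRatioSummary:
    """Posterior of ln[pi1/(1-pi1) * (1-pi2)/pi2], anterior vs posterior.

    Counts frames carry (time_min, n_pos, n_obs).  The pooled contrast
    uses counts summed over times; per-time contrasts are summarised
    for every time present in both frames.  Draws are exact independent
    Beta samples, so ``burn_in`` is accepted for interface parity with
    the MCMC path but not needed here.
    """
    for name, c in (("anterior", anterior_counts), ("posterior", posterior_counts)):
        if c.empty or (c["n_obs"] < 1).any():
            raise ValueError(f"{name} group must have n_obs >= 1 everywhere")
    rng = np.random.default_rng(seed)

    def draw_lor(x1, n1, x2, n2):
        p1 = rng.beta(x1 + prior_a, n1 - x1 + prior_b, size=n_draws)
        p2 = rng.beta(x2 + prior_a, n2 - x2 + prior_b, size=n_draws)
        return np.log(p1 / (1 - p1)) - np.log(p2 / (1 - p2))

    x1, n1 = int(anterior_counts["n_pos"].sum()), int(anterior_counts["n_obs"].sum())
    x2, n2 = int(posterior_counts["n_pos"].sum()), int(posterior_counts["n_obs"].sum())
    pooled = draw_lor(x1, n1, x2, n2)
    lo, hi = np.quantile(pooled, [0.025, 0.975])

    per_time = []
    ant = anterior_counts.set_index("time_min")
    post = posterior_counts.set_index("time_min")
    for t in sorted(set(ant.index) & set(post.index)):
        lor = draw_lor(
            int(ant.loc[t, "n_pos"]), int(ant.loc[t, "n_obs"]),
            int(post.loc[t, "n_pos"]), int(post.loc[t, "n_obs"]),
        )
        per_time.append([float(t), float(lor.mean()), float(lor.std(ddof=1))])

    return OddsRatioSummary(
        log_or_mean=float(pooled.mean()),
        log_or_sd=float(pooled.std(ddof=1)),
        asymptotic_sd=woolf_sd(x1, n1, x2, n2),
        n_draws=n_draws,
        ci_low=float(lo),
        ci_high=float(hi),
        per_time=per_time,
    )


def split_counts(
    table: ScoreTable,
    threshold: int = 1,
    anterior: set[GutRegion] = ANTERIOR_REGIONS,
    posterior: set[GutRegion] = POSTERIOR_REGIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts for the anterior/posterior contrast (rectal vesicle excluded)."""
    ant = dichotomize(table, threshold=threshold, include=set(anterior))
    post = dichotomize(table, threshold=threshold, include=set(posterior))
    return ant, post


def mean_scores(table: ScoreTable, value: str = "malpighian_score") -> pd.DataFrame:
    """Arithmetic mean score per time x region (the 0-2 schematic summaries)."""
    if value not in ("malpighian_score", "lumen_score"):
        raise ValueError("value must be a score column")
    frame = table.to_frame()
    return (
        frame.groupby(["time_min", "region"], sort=True)[value]
        .mean()
        .reset_index(name="mean_score")
    )


def posterior_mean_mcmc(
    n_pos: int,
    n_obs: int,
    prior_a: float = JEFFREYS,
    prior_b: float = JEFFREYS,
    n_draws: int = 30_000,
    burn_in: int = 30_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """MCMC cross-check of the conjugate posterior mean on the logit scale.

    Samples the Beta posterior via an ensemble sampler with a logit-link
    parameterisation; returns (mean of draws, Monte-Carlo standard error
    of that mean, estimated via autocorrelation-naive batching).
    Requires emcee.
    """
    import emcee  # optional dependency

    a, b = n_pos + prior_a, n_obs - n_pos + prior_b

    def log_post(theta):
        # theta = logit(pi); Beta(a,b) density plus Jacobian d pi/d theta
        t = theta[0]
        if abs(t) > 35:
            return -np.inf
        return a * t - (a + b) * np.log1p(np.exp(t))

    nwalkers = 8
    rng = np.random.default_rng(seed)
    p0 = rng.normal(0, 0.5, size=(nwalkers, 1))
    sampler = emcee.EnsembleSampler(nwalkers, 1, log_post)
    steps = max(1, (burn_in + n_draws) // nwalkers)
    keep = max(1, n_draws // nwalkers)
    sampler.run_mcmc(p0, steps, progress=False)
    theta = sampler.get_chain()[-keep:, :, 0].ravel()
    pi = 1.0 / (1.0 + np.exp(-theta))
    mean = float(pi.mean())
    # batch-means MC standard error (accounts for walker autocorrelation)
    nb = 20
    batches = np.array_split(pi, nb)
    bm = np.array([b.mean() for b in batches])
    se = float(bm.std(ddof=1) / np.sqrt(nb))
    return mean, se
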