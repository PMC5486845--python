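"""Posterior-predictive inference of time-since-feeding from field data.

Groups are the study's discrete sampling times (or any user grid).  With
a per-group Beta posterior for the occurrence probability and a uniform
prior over group membership, a new field observation updates group
membership by the beta-binomial posterior predictive:

    P(group g | k of N positive)  propto  prior(g) * BetaBin(k; N, alpha_g, beta_g)

For a single mite the predictive reduces to alpha_g/(alpha_g+beta_g)
(positive) or beta_g/(alpha_g+beta_g) (negative).  Nomograms stack these
distributions over k for ecologists reading prevalence in field samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import betabinom, binom

from .data import register_result
from .occurrence import OccurrenceEstimate


@register_result
@dataclass
class PredictiveDistribution:
    """Posterior-predictive mass over time-since-feeding groups."""

    group_times_min: list
    mass: list

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if np.any(m < 0):
            raise ValueError("mass entries must be >= 0")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1")

    @property
    def group_index(self) -> list[int]:
        """1-based group indices in time order."""
        return list(range(1, len(self.group_times_min) + 1))

    @property
    def mode_index(self) -> int:
        """1-based index of the most probable group."""
        return int(np.argmax(self.mass)) + 1

    @property
    def mode_time_min(self) -> float:
        return float(self.group_times_min[self.mode_index - 1])

    @property
    def central_band(self) -> tuple[int, int]:
        """Smallest contiguous run of groups holding >= 50% mass
        (1-based inclusive index pair; ties broken by larger mass)."""
        m = np.asarray(self.mass, dtype=float)
        n = len(m)
        best = None
        for width in range(1, n + 1):
            sums = np.convolve(m, np.ones(width), mode="valid")
            i = int(np.argmax(sums))
            if sums[i] >= 0.5:
                best = (i + 1, i + width)
                break
        return best if best is not None else (1, n)

    @property
    def central_band_times_min(self) -> tuple[float, float]:
        lo, hi = self.central_band
        return (
            float(self.group_times_min[lo - 1]),
            float(self.group_times_min[hi - 1]),
        )


def _validate_prior(
    prior: Sequence[float] | None, n_groups: int
) -> np.ndarray:
    if prior is None:
        p = np.full(n_groups, 1.0 / n_groups)
    else:
        p = np.asarray(prior, dtype=float)
        if len(p) != n_groups:
            raise ValueError("prior length must match number of groups")
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError("prior must be non-negative and not all zero")
    return p


def _sorted_estimates(
    estimates: Sequence[OccurrenceEstimate],
) -> list[OccurrenceEstimate]:
    return sorted(estimates, key=lambda e: e.time_min)


def predictive_single(
    estimates: Sequence[OccurrenceEstimate],
    positive: bool,
    prior: Sequence[float] | None = None,
) -> PredictiveDistribution:
    """Group membership posterior for one field mite scored +/-.

    Uses the posterior-predictive probability of the observation under
    each group's Beta posterior: p_g = alpha/(alpha+beta) for positive,
    1 - p_g for negative.
    """
    est = _sorted_estimates(estimates)
    p = np.array([e.posterior_mean for e in est])
    prior_m = _validate_prior(prior, len(est))
    like = p if positive else 1.0 - p
    mass = prior_m * like
    if mass.sum() == 0:
        raise ValueError("observation impossible under every group")
    mass = mass / mass.sum()
    return PredictiveDistribution(
        group_times_min=[e.time_min for e in est],
        mass=list(mass),
    )


def predictive_count(
    estimates: Sequence[OccurrenceEstimate],
    k: int,
    N: int = 20,
    prior: Sequence[float] | None = None,
    plug_in: bool = False,
) -> PredictiveDistribution:
    """Group membership posterior for k positives out of N field mites.

    Beta-binomial by default so the sampling uncertainty of each small
    per-group posterior propagates; ``plug_in`` substitutes a plain
    binomial at the posterior-mean occurrence (sensitivity variant).
    """
    if not 0 <= k <= N:
        raise ValueError("require 0 <= k <= N")
    est = _sorted_estimates(estimates)
    prior_m = _validate_prior(prior, len(est))
    if plug_in:
        p = np.array([e.posterior_mean for e in est])
        like = binom.pmf(k, N, p)
    else:
        a = np.array([e.alpha for e in est])
        b = np.array([e.beta for e in est])
        like = betabinom.pmf(k, N, a, b)
    mass = prior_m * like
    if mass.sum() == 0:
        raise ValueError("observation impossible under every group")
    mass = mass / mass.sum()
    return PredictiveDistribution(
        group_times_min=[e.time_min for e in est],
        mass=list(mass),
    )


def nomogram_table(
    estimates: Sequence[OccurrenceEstimate],
    k_range: Sequence[int],
    N: int = 20,
    prior: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Stacked predictive distributions over k: (k, group_index,
    group_time_min, mass) rows, normalized within each k."""
    rows = []
    for k in k_range:
        dist = predictive_count(estimates, k=k, N=N, prior=prior)
        for i, (t, m) in enumerate(zip(dist.group_times_min, dist.mass), start=1):
            rows.append({"k": int(k), "group_index": i, "group_time_min": t, "mass": m})
    return pd.DataFrame(rows)


def plot_nomogram(table: pd.DataFrame, path: str, N: int = 20) -> None:
    """Line plot of predictive mass against log_e time in minutes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for k, sub in table.groupby("k"):
        sub = sub[sub["group_time_min"] > 0]
        ax.plot(
            np.log(sub["group_time_min"]),
            sub["mass"],
            marker="o",
            markersize=2.5,
            label=f"{k} of {N}",
        )
    ax.set_xlabel(r"$\log_e$ time (min) since start of feeding")
    ax.set_ylabel("posterior predictive mass")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
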