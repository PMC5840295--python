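"""SAINT-style probabilistic interaction scoring.

Posterior probability that a prey's bait-run spectral counts arise from a
true-interaction component rather than the control-derived background.  The
model is a deterministic two-component negative-binomial mixture:

* background component: NB with the prey's control mean and a dispersion
  shared across preys (method of moments on control replicates);
* true component: the same NB with the mean multiplied by a single
  enrichment factor shared across preys, fitted by expectation-maximisation
  on the bait runs and bounded to [2, 100].

Per replicate, posterior = pi * f_true / (pi * f_true + (1 - pi) * f_bg)
with prior pi; the score is the mean posterior across a prey's bait
replicates.  The published SAINT software fits a Bayesian model by MCMC;
this is a deliberately deterministic SAINT-style score used only through
its threshold, not a reimplementation of SAINT's numerics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .enrichment import CONTROL_LABEL, SpectralCountMatrix

logger = logging.getLogger(__name__)

MEAN_FLOOR = 0.1
FACTOR_BOUNDS = (2.0, 100.0)

__all__ = ["BackgroundModel", "SaintScore", "fit_background", "saint_score",
           "fit_true_factor", "score_construct"]


@dataclass
class BackgroundModel:
    """Per-prey background means (floored) plus shared dispersion and prior."""

    mean: pd.Series          # per prey, floored at MEAN_FLOOR
    dispersion: float        # NB dispersion alpha: var = mu + alpha*mu^2
    pi: float = 0.1          # prior probability of a true interaction

    def __post_init__(self) -> None:
        if (self.mean <= 0).any():
            raise ValueError("background means must be positive (floored)")
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class SaintScore:
    protein_id: str
    score: float
    per_replicate: list[float]


def nb_logpmf(k, mu, alpha: float) -> np.ndarray:
    """Negative-binomial log density, continuous in k (corrected counts).

    Mean ``mu``, variance ``mu + alpha*mu**2``; the Poisson limit is used
    when alpha is (near) zero.
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-10:
        return k * np.log(mu) - mu - gammaln(k + 1.0)
    r = 1.0 / alpha
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mu))
        + k * np.log(mu / (r + mu))
    )


def fit_background(
    matrix: SpectralCountMatrix,
    control_label: str = CONTROL_LABEL,
    floor: float = MEAN_FLOOR,
    pi: float = 0.1,
) -> BackgroundModel:
    """Estimate the background model from control runs.

    Per-prey mean = control mean floored at ``floor`` (preys never seen in
    controls still need a likelihood); dispersion by method of moments
    pooled over preys: alpha = sum(var - mean) / sum(mean^2), clipped at 0.
    """
    runs = matrix.runs_for(control_label)
    if len(runs) < 2:
        raise ValueError(
            f"background fitting needs >= 2 control runs, found {len(runs)}"
        )
    ctrl = matrix.counts[runs].astype(float)
    m = ctrl.mean(axis=1)
    v = ctrl.var(axis=1, ddof=1)
    denom = float((m**2).sum())
    alpha = max(0.0, float((v - m).sum()) / denom) if denom > 0 else 0.0
    return BackgroundModel(mean=m.clip(lower=floor), dispersion=alpha, pi=pi)


def saint_score(
    counts,
    bg_mean: float,
    bg: BackgroundModel,
    true_component_factor: float,
    protein_id: str = "",
) -> SaintScore:
    """Score one prey's bait-replicate counts under the two-component mixture."""
    if true_component_factor <= 1:
        raise ValueError("true_component_factor must exceed 1")
    k = np.asarray(counts, dtype=float)
    if (k < 0).any():
        raise ValueError("counts must be non-negative")
    l_bg = nb_logpmf(k, bg_mean, bg.dispersion)
    l_true = nb_logpmf(k, bg_mean * true_component_factor, bg.dispersion)
    log_num = np.log(bg.pi) + l_true
    log_den = logsumexp(
        np.stack([log_num, np.log1p(-bg.pi) + l_bg]), axis=0
    )
    post = np.exp(log_num - log_den)
    return SaintScore(
        protein_id=protein_id, score=float(post.mean()), per_replicate=post.tolist()
    )


def _responsibilities(
    bait: np.ndarray, mu: np.ndarray, alpha: float, pi: float, factor: float
) -> np.ndarray:
    """Per-prey posterior of the true component given all bait replicates."""
    lt = nb_logpmf(bait, mu[:, None] * factor, alpha).sum(axis=1)
    lb = nb_logpmf(bait, mu[:, None], alpha).sum(axis=1)
    a = np.log(pi) + lt
    b = np.log1p(-pi) + lb
    return np.exp(a - logsumexp(np.stack([a, b]), axis=0))


def fit_true_factor(
    bait_counts: pd.DataFrame,
    bg: BackgroundModel,
    bounds: tuple[float, float] = FACTOR_BOUNDS,
    init: float = 4.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """EM estimate of the shared true-component enrichment factor.

    Maximises the mixture marginal likelihood of the bait runs over the
    factor, holding the background model fixed.  Deterministic: initialised
    at ``init``, bounded to ``bounds`` (violations are clamped and logged).
    """
    bait = bait_counts.to_numpy(dtype=float)
    mu = bg.mean.loc[bait_counts.index].to_numpy(dtype=float)
    factor = float(np.clip(init, *bounds))
    for _ in range(max_iter):
        z = _responsibilities(bait, mu, bg.dispersion, bg.pi, factor)

        def neg_q(f: float) -> float:
            return -float(
                (z * nb_logpmf(bait, mu[:, None] * f, bg.dispersion).sum(axis=1)).sum()
            )

        res = minimize_scalar(neg_q, bounds=bounds, method="bounded")
        new = float(res.x)
        if not bounds[0] <= new <= bounds[1]:
            logger.warning("factor %.3f outside bounds %s; clamped", new, bounds)
            new = float(np.clip(new, *bounds))
        if abs(new - factor) < tol:
            factor = new
            break
        factor = new
    return factor


def score_construct(
    matrix: SpectralCountMatrix,
    construct: str,
    bg: BackgroundModel,
    factor: float | None = None,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """SAINT-style scores for every prey against one bait construct.

    When ``factor`` is None it is fitted by EM on this construct's runs.
    ``exclude`` drops proteins (typically the bait itself) before fitting
    and scoring.  Returns a DataFrame with ``saint_score`` and the
    per-replicate posteriors, indexed by protein id.
    """
    runs = matrix.runs_for(construct)
    if not runs:
        raise ValueError(f"no runs for construct '{construct}'")
    counts = matrix.counts[runs]
    if exclude:
        counts = counts.drop(index=[p for p in exclude if p in counts.index])
    if factor is None:
        factor = fit_true_factor(counts, bg)
    out = pd.DataFrame(index=counts.index)
    mu = bg.mean.loc[counts.index]
    posts = []
    for pid in counts.index:
        s = saint_score(
            counts.loc[pid].to_numpy(), float(mu.loc[pid]), bg, factor, pid
        )
        posts.append(s)
    out["saint_score"] = [s.score for s in posts]
    for i, run in enumerate(runs):
        out[f"posterior_{run}"] = [s.per_replicate[i] for s in posts]
    out.attrs["true_component_factor"] = factor
    return out
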