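"""Posterior summaries, weak-item flags, rank probabilities and diagnostics.

Turns retained Gibbs draws into the reporting quantities of the index
construction: item tables of discrimination/difficulty posterior means and
standard deviations (ordered by discrimination, weakly identified items
flagged and sorted last), per-country latent-score tables with 90% credible
intervals, pairwise and group rank probabilities computed on the *joint*
draws (so posterior correlation between countries is honoured), and basic
chain diagnostics (Geweke z, effective sample size).
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .irt_sampler import PosteriorDraws

logger = logging.getLogger(__name__)

#: Fraction of posterior mass left of zero at which an item's discrimination
#: is flagged as weakly identified.
DEFAULT_FLAG_THRESHOLD = 0.10


def _ess(chain: np.ndarray) -> float:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.ess(chain[None, :])))


def flag_negative_mass(
    lambda_draws: np.ndarray, threshold: float = DEFAULT_FLAG_THRESHOLD
) -> np.ndarray:
    """Boolean flag per item: fraction of draws with lambda_j < 0 >= threshold."""
    if not 0.0 < threshold <= 0.5:
        raise ValueError(f"flag threshold must be in (0, 0.5], got {threshold}")
    lam = np.atleast_2d(np.asarray(lambda_draws, float))
    return (lam < 0).mean(axis=0) >= threshold


def summarize(
    draws: PosteriorDraws,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    item_labels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item and country posterior summary tables.

    Returns ``(item_summary, country_scores)``.  Item rows are ordered by
    posterior-mean discrimination, descending, with flagged items (a
    ``flag_threshold`` portion of posterior mass left of zero) listed last.
    Country rows are ordered by posterior-mean score, descending.  Moments
    are empirical over retained draws (population SD convention); intervals
    are equal-tailed 90% (5th-95th percentile).
    """
    if draws.n_draws < 100:
        raise ValueError(f"need at least 100 retained draws to summarize, got {draws.n_draws}")
    lam, alp, phi = draws.discriminations, draws.difficulties, draws.scores
    flagged = flag_negative_mass(lam, flag_threshold)
    items = pd.DataFrame(
        {
            "item_id": draws.item_ids,
            "label": [
                (item_labels or {}).get(i, i) for i in draws.item_ids
            ],
            "discrimination_mean": lam.mean(axis=0),
            "discrimination_sd": lam.std(axis=0),
            "discrimination_q5": np.quantile(lam, 0.05, axis=0),
            "discrimination_q95": np.quantile(lam, 0.95, axis=0),
            "difficulty_mean": alp.mean(axis=0),
            "difficulty_sd": alp.std(axis=0),
            "difficulty_q5": np.quantile(alp, 0.05, axis=0),
            "difficulty_q95": np.quantile(alp, 0.95, axis=0),
            "prob_negative": (lam < 0).mean(axis=0),
            "flagged": flagged,
        }
    )
    items = items.sort_values(
        ["flagged", "discrimination_mean"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    countries = pd.DataFrame(
        {
            "country_id": draws.country_ids,
            "score_mean": phi.mean(axis=0),
            "score_sd": phi.std(axis=0),
            "ci90_low": np.quantile(phi, 0.05, axis=0),
            "ci90_high": np.quantile(phi, 0.95, axis=0),
        }
    ).sort_values("score_mean", ascending=False, kind="stable").reset_index(drop=True)
    return items, countries


def rank_pair_probability(draws: PosteriorDraws, a: str, b: str) -> float:
    """P(phi_a > phi_b) as the fraction of joint draws; ties count as not-greater."""
    if a == b:
        raise ValueError("rank_pair_probability needs two distinct countries")
    ia, ib = draws.country_index(a), draws.country_index(b)
    return float(np.mean(draws.scores[:, ia] > draws.scores[:, ib]))


def extreme_probability(
    draws: PosteriorDraws,
    group: Iterable[str],
    direction: str = "highest",
    universe: Iterable[str] | None = None,
) -> float:
    """P(the extreme score among ``universe`` belongs to a country in ``group``).

    ``direction`` is ``"highest"`` or ``"lowest"``; ``universe`` defaults to
    all countries in the draws.  Evaluated per joint draw via the argmax
    (argmin) over the universe columns.
    """
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    if direction not in ("highest", "lowest"):
        raise ValueError(f"direction must be 'highest' or 'lowest', got {direction!r}")
    uni = list(universe) if universe is not None else list(draws.country_ids)
    cols = [draws.country_index(c) for c in uni]
    missing = set(group) - set(uni)
    if missing:
        raise KeyError(f"group countries not in universe: {sorted(missing)}")
    sub = draws.scores[:, cols]
    ext = np.argmax(sub, axis=1) if direction == "highest" else np.argmin(sub, axis=1)
    in_group = np.array([c in group for c in uni])
    return float(np.mean(in_group[ext]))


def diagnostics(draws: PosteriorDraws, first: float = 0.1, last: float = 0.5) -> pd.DataFrame:
    """Per-parameter Geweke z-score and effective sample size.

    The Geweke statistic compares the mean of the first ``first`` fraction of
    the chain with the mean of the last ``last`` fraction, standardised by
    autocorrelation-adjusted (ESS-based) standard errors of each segment.
    Parameters with |z| > 3 or ESS < 100 are logged as warnings.
    """
    if draws.n_draws < 200:
        raise ValueError(f"diagnostics need at least 200 retained draws, got {draws.n_draws}")
    chains = {
        **{f"lambda[{i}]": draws.discriminations[:, k] for k, i in enumerate(draws.item_ids)},
        **{f"alpha[{i}]": draws.difficulties[:, k] for k, i in enumerate(draws.item_ids)},
        **{f"phi[{c}]": draws.scores[:, k] for k, c in enumerate(draws.country_ids)},
    }
    rows = []
    for name, chain in chains.items():
        m = chain.shape[0]
        seg1 = chain[: max(int(first * m), 2)]
        seg2 = chain[m - max(int(last * m), 2):]
        se1 = seg1.std(ddof=1) / np.sqrt(max(_ess(seg1), 1.0))
        se2 = seg2.std(ddof=1) / np.sqrt(max(_ess(seg2), 1.0))
        denom = np.sqrt(se1**2 + se2**2)
        z = (seg1.mean() - seg2.mean()) / denom if denom > 0 else 0.0
        ess = _ess(chain)
        rows.append({"parameter": name, "geweke_z": float(z), "ess": ess})
        if abs(z) > 3:
            logger.warning("parameter %s: |Geweke z| = %.2f > 3", name, abs(z))
        if ess < 100:
            logger.warning("parameter %s: ESS = %.0f < 100", name, ess)
    return pd.DataFrame(rows)
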