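"""Synthetic WHO-style binary survey matrices with known ground truth.

Responses follow the one-factor probit measurement model used throughout the
package: country i answers item j positively when

    x*_ij = lambda_j * phi_i - alpha_j + e_ij > 0,   e_ij ~ N(0, 1),

with latent regulatory quality phi_i ~ N(0, 1), item discrimination
lambda_j and item difficulty alpha_j.  Entries are then masked missing
completely at random.  Because the true parameters are returned alongside
the matrix, every downstream stage (sampling, summarisation, comparison)
can be tested for recovery at desk scale.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .item_registry import INDEX_SIZES, ResponseMatrix, load_registry

#: Number of countries in the survey wave the generator emulates.
DEFAULT_N_COUNTRIES = 78

#: Default completely-at-random missingness per cell.
DEFAULT_MISSING_RATE = 0.05

#: Ranges bracketing realistic item parameters for the survey instrument.
LAMBDA_RANGE = (0.2, 2.2)
ALPHA_RANGE = (-1.0, 1.5)


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth generating parameters for one synthetic dataset."""

    discriminations: np.ndarray  # lambda_j, shape (J,)
    difficulties: np.ndarray  # alpha_j, shape (J,)
    latent_scores: np.ndarray  # phi_i, shape (N,)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "discriminations", np.asarray(self.discriminations, float))
        object.__setattr__(self, "difficulties", np.asarray(self.difficulties, float))
        object.__setattr__(self, "latent_scores", np.asarray(self.latent_scores, float))
        if self.discriminations.shape != self.difficulties.shape:
            raise ValueError("discriminations and difficulties must have equal length")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")

    @property
    def n_countries(self) -> int:
        return self.latent_scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.discriminations.shape[0]


def synthetic_country_codes(n: int) -> list[str]:
    """Deterministic ISO-alpha-3-shaped placeholder codes: AAA, AAB, ..."""
    codes = ("".join(t) for t in itertools.product(string.ascii_uppercase, repeat=3))
    return list(itertools.islice(codes, n))


def marginal_prevalence(discrimination: float, difficulty: float) -> float:
    """P(x=1) for a random standard-normal latent score: Phi(-alpha/sqrt(1+lambda^2))."""
    return float(ndtr(-difficulty / np.sqrt(1.0 + discrimination**2)))


def generate(
    truth: TrueParameters,
    country_ids: list[str] | None = None,
    item_ids: list[str] | None = None,
) -> tuple[ResponseMatrix, TrueParameters]:
    """Draw one binary response matrix from the probit model at ``truth``.

    Reproducible given ``truth.seed``; the truth object is returned unchanged
    so recovery tests can compare estimates against it.
    """
    n, j = truth.n_countries, truth.n_items
    if n < 2 or j < 2:
        raise ValueError(f"need at least 2 countries and 2 items, got N={n}, J={j}")
    rng = np.random.default_rng(truth.seed)
    eta = np.outer(truth.latent_scores, truth.discriminations) - truth.difficulties
    x = (eta + rng.standard_normal((n, j)) > 0).astype(float)
    if truth.missing_rate > 0:
        x[rng.random((n, j)) < truth.missing_rate] = np.nan
    matrix = ResponseMatrix(
        country_ids=country_ids or synthetic_country_codes(n),
        item_ids=item_ids or [f"Q{k + 1:02d}" for k in range(j)],
        values=x,
    )
    return matrix, truth


def draw_true_parameters(
    n_countries: int,
    n_items: int,
    seed: int,
    missing_rate: float = DEFAULT_MISSING_RATE,
) -> TrueParameters:
    """Draw regime-realistic ground truth: lambda ~ U[0.2, 2.2], alpha ~ U[-1, 1.5]."""
    rng = np.random.default_rng(seed)
    return TrueParameters(
        discriminations=rng.uniform(*LAMBDA_RANGE, size=n_items),
        difficulties=rng.uniform(*ALPHA_RANGE, size=n_items),
        latent_scores=rng.standard_normal(n_countries),
        missing_rate=missing_rate,
        # independent stream for the response noise
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def paperlike_scenario(
    index: str,
    seed: int,
    missing_rate: float = DEFAULT_MISSING_RATE,
) -> tuple[ResponseMatrix, TrueParameters]:
    """A survey-scale dataset for one index: 78 countries, the index's items.

    Item counts (14 / 26 / 18) and identifiers come from the packaged
    registry, so the output is directly consumable by the fitting pipeline.
    """
    if index not in INDEX_SIZES:
        raise ValueError(f"unknown index {index!r}; expected one of {sorted(INDEX_SIZES)}")
    reg = load_registry()
    item_ids = list(reg[index].item_ids)
    truth = draw_true_parameters(
        DEFAULT_N_COUNTRIES, len(item_ids), seed=seed, missing_rate=missing_rate
    )
    return generate(truth, item_ids=item_ids)


def write_truth(truth: TrueParameters, matrix: ResponseMatrix, out_dir: str | Path) -> None:
    """Write ground truth as sidecar CSVs (item parameters, country scores)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "item_id": matrix.item_ids,
            "discrimination": truth.discriminations,
            "difficulty": truth.difficulties,
        }
    ).to_csv(out / "truth_items.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        {"country_id": matrix.country_ids, "latent_score": truth.latent_scores}
    ).to_csv(out / "truth_scores.csv", index=False, float_format="%.10g")


def read_truth(matrix: ResponseMatrix, in_dir: str | Path, missing_rate: float = 0.0,
               seed: int = 0) -> TrueParameters:
    """Load sidecar truth CSVs back into a :class:`TrueParameters`."""
    inp = Path(in_dir)
    items = pd.read_csv(inp / "truth_items.csv").set_index("item_id")
    scores = pd.read_csv(inp / "truth_scores.csv").set_index("country_id")
    return TrueParameters(
        discriminations=items.loc[matrix.item_ids, "discrimination"].to_numpy(),
        difficulties=items.loc[matrix.item_ids, "difficulty"].to_numpy(),
        latent_scores=scores.loc[matrix.country_ids, "latent_score"].to_numpy(),
        missing_rate=missing_rate,
        seed=seed,
    )
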