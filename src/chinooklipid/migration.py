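"""Migration-difficulty indices and their correlation with lipid content.

Chinook stocks with harder freshwater migrations accumulate more lipid at
sea. Difficulty is proxied by four per-stock indices: migratory distance
(km from freshwater entry), spawning-ground elevation (m), and two
combinations — work = (elevation × distance)/1000 and
slope = 500 × elevation/distance. Indices are computed per stock, then
averaged within management unit, and the MU means are correlated
(Pearson) with MU mean whole-body lipid content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import reference

INDEX_NAMES = ("elevation_m", "distance_km", "work", "slope_index")


def stock_indices(distance_km: float, elevation_m: float) -> Tuple[float, float]:
    """(work, slope_index) for one stock.

    work = elevation × distance / 1000 (unit: m·km/1000);
    slope_index = 500 × elevation / distance.
    """
    if distance_km <= 0:
        raise ValueError("distance must be positive")
    if elevation_m < 0:
        raise ValueError("elevation must be nonnegative")
    work = elevation_m * distance_km / 1000.0
    slope_index = 500.0 * elevation_m / distance_km
    return work, slope_index


@dataclass(frozen=True)
class StockMigration:
    """Per-stock migration difficulty record."""

    stock: str
    mu: str
    distance_km: float
    elevation_m: float
    work: float = field(init=False)
    slope_index: float = field(init=False)

    def __post_init__(self) -> None:
        w, s = stock_indices(self.distance_km, self.elevation_m)
        object.__setattr__(self, "work", w)
        object.__setattr__(self, "slope_index", s)


def mu_mean_indices(stocks: Iterable[StockMigration]) -> pd.DataFrame:
    """Average the four per-stock indices within each MU.

    Work and slope are computed for each stock first and then averaged —
    the MU mean work is the mean of products, not the product of the MU
    mean elevation and distance.
    """
    stocks = list(stocks)
    if not stocks:
        raise ValueError("no stocks provided")
    df = pd.DataFrame(
        {
            "mu": [s.mu for s in stocks],
            "elevation_m": [s.elevation_m for s in stocks],
            "distance_km": [s.distance_km for s in stocks],
            "work": [s.work for s in stocks],
            "slope_index": [s.slope_index for s in stocks],
        }
    )
    return df.groupby("mu", sort=False)[list(INDEX_NAMES)].mean()


def published_mu_indices() -> pd.DataFrame:
    """The packaged MU-level index table (per-stock sources unpublished)."""
    return pd.DataFrame.from_dict(reference.MU_MIGRATION, orient="index")[
        list(INDEX_NAMES)
    ]


@dataclass(frozen=True)
class DifficultyCorrelation:
    index: str
    pearson_r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 MUs")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def difficulty_correlation(
    mu_indices: pd.DataFrame,
    mu_lipid_means: Mapping[str, float],
) -> List[DifficultyCorrelation]:
    """Pearson correlation of each difficulty index with MU mean lipid.

    ``mu_indices`` is indexed by MU with the four index columns;
    ``mu_lipid_means`` maps MU → mean whole-body lipid (%). MUs present
    in both are used; the two-sided p-value comes from the t transform
    with n − 2 degrees of freedom.
    """
    mus = [mu for mu in mu_indices.index if mu in mu_lipid_means]
    if len(mus) < 3:
        raise ValueError("need at least 3 MUs with both indices and lipid means")
    lipid = np.array([mu_lipid_means[mu] for mu in mus], dtype=float)
    out: List[DifficultyCorrelation] = []
    for name in INDEX_NAMES:
        v = mu_indices.loc[mus, name].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(lipid) == 0:
            raise ValueError(f"zero variance in {name} or lipid means")
        r, p = stats.pearsonr(v, lipid)
        out.append(DifficultyCorrelation(index=name, pearson_r=float(r),
                                         p_value=float(p), n=len(mus)))
    return out


def published_difficulty_correlations() -> List[DifficultyCorrelation]:
    """Replay the correlation analysis from the packaged MU tables."""
    return difficulty_correlation(published_mu_indices(), reference.MU_LIPID_MEANS)
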