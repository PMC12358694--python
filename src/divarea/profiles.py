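"""DAR-based diversity profiles.

From the permutation-averaged PL and PLEC parameters at each diversity
order q, four profiles are derived:

* DAR profile      — the scaling exponent z as a function of q;
* PDO profile      — pairwise diversity overlap g = 2 - 2^z between two
                     adjacent areas of equal size (z = 1 -> g = 0, no
                     overlap; z = 0 -> g = 1, complete overlap);
* MAD profile      — maximal accrued diversity of the PLEC curve,
                     D_max = c (-z/d)^z exp(-z), attained at
                     A_max = -z/d pooled samples;
* LGD profile      — ratio of local (one-sample) diversity, the PL
                     parameter c, to global accrued diversity D_max,
                     reported as a percentage.

g always comes from the PL exponent (its derivation assumes the pure
power law); A_max and D_max come from the PLEC fit, which is the only
model with an interior maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityTable
from .fitting import PermutedFitSummary, permuted_fit

__all__ = [
    "pdo_from_z",
    "a_max",
    "d_max",
    "lgd",
    "ProfileRecord",
    "DarProfileSet",
    "build_profiles",
]


def pdo_from_z(z: float) -> float:
    """Pairwise diversity overlap g = 2 - 2^z.

    Values of z outside [0, 1] are allowed (g then leaves [0, 1]) but
    trigger a warning, since the overlap interpretation only holds on the
    unit interval.
    """
    z = float(z)
    if not 0.0 <= z <= 1.0:
        warnings.warn(
            f"z={z} outside [0, 1]; overlap interpretation of g does not hold",
            UserWarning,
            stacklevel=2,
        )
    return 2.0 - 2.0**z


def a_max(z: float, d: float) -> float:
    """Area (number of pooled samples) at which the PLEC curve peaks:
    A_max = -z/d, defined only for z > 0 and d < 0."""
    if d >= 0:
        raise ValueError("no interior maximum: PLEC taper-off d must be < 0")
    if z <= 0:
        raise ValueError("A_max requires a positive scaling exponent z")
    return -z / d


def d_max(c: float, z: float, d: float) -> float:
    """Maximal accrued diversity of the PLEC curve c A^z exp(dA):

        D_max = c (-z/d)^z exp(-z)

    which is the analytic maximum of the curve over A > 0 (for z > 0,
    d < 0).  With z = 0 the curve is decreasing and the supremum is c.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    if d >= 0:
        raise ValueError("no finite maximum: PLEC taper-off d must be < 0")
    if z < 0:
        raise ValueError("z must be >= 0")
    if z == 0:
        return float(c)
    return float(c * (-z / d) ** z * math.exp(-z))


def lgd(c_pl: float, d_max_value: float) -> float:
    """Local-to-global diversity ratio 100 * c / D_max (percent).

    ``c_pl`` is the PL-model c (diversity of one area unit); ``d_max_value``
    the PLEC-derived maximal accrued diversity.
    """
    if d_max_value <= 0:
        raise ValueError("D_max must be positive")
    if c_pl <= 0:
        raise ValueError("c must be positive")
    return 100.0 * c_pl / d_max_value


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileRecord:
    """Profile quantities for one diversity order q.

    Derived cells are NaN when the underlying fit summary has N = 0 or
    (for A_max/D_max/LGD) when the averaged PLEC d is non-negative.
    """

    q: float
    pl: PermutedFitSummary
    plec: PermutedFitSummary
    g: float
    a_max: float
    d_max: float
    lgd_percent: float


class DarProfileSet:
    """Per-q DAR/PDO/MAD/LGD profiles for one cohort."""

    def __init__(self, records: list[ProfileRecord], group: str | None = None,
                 seed: int | None = None):
        self.records = list(records)
        self.group = group
        self.seed = seed

    @property
    def q_grid(self) -> list[float]:
        return [r.q for r in self.records]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-q table with the PL block, PLEC block and derived
        profile columns (mirrors the usual DAR results layout)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "group": self.group,
                    "q": r.q,
                    "z": r.pl.mean_z,
                    "c": r.pl.mean_c,
                    "R": r.pl.mean_R,
                    "g": r.g,
                    "p_value": r.pl.mean_p,
                    "N": r.pl.N,
                    "z_plec": r.plec.mean_z,
                    "d": r.plec.mean_d,
                    "c_plec": r.plec.mean_c,
                    "R_plec": r.plec.mean_R,
                    "p_value_plec": r.plec.mean_p,
                    "N_plec": r.plec.N,
                    "A_max": r.a_max,
                    "D_max": r.d_max,
                    "LGD_percent": r.lgd_percent,
                }
            )
        return pd.DataFrame(rows)


def _derive_record(q: float, pl: PermutedFitSummary,
                   plec: PermutedFitSummary) -> ProfileRecord:
    g = amax = dmax = ratio = np.nan
    if pl.N > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            g = pdo_from_z(pl.mean_z)
    if plec.N > 0 and plec.mean_d is not None and plec.mean_d < 0 and plec.mean_z > 0:
        amax = a_max(plec.mean_z, plec.mean_d)
        dmax = d_max(plec.mean_c, plec.mean_z, plec.mean_d)
        if pl.N > 0 and pl.mean_c > 0:
            ratio = lgd(pl.mean_c, dmax)
    return ProfileRecord(q=q, pl=pl, plec=plec, g=g, a_max=amax,
                         d_max=dmax, lgd_percent=ratio)


def build_profiles(
    table: CommunityTable,
    q_grid=(0, 1, 2, 3),
    n_permutations: int = 100,
    seed: int | None = None,
    group: str | None = None,
) -> DarProfileSet:
    """Fit PL and PLEC at every q and derive the four profiles.

    At each q both models are fitted to the same set of random orderings
    (one derived seed per q), so PL and PLEC parameters describe the same
    accumulation curves.  Cells whose underlying summary has N = 0 are
    reported as NaN with a warning.
    """
    q_grid = [float(q) for q in q_grid]
    if len(q_grid) == 0:
        raise ValueError("q_grid must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(q_grid))
    records = []
    for q, child in zip(q_grid, children):
        pl = permuted_fit(table, q, "PL", n_permutations,
                          seed=seed, rng=np.random.default_rng(child))
        plec = permuted_fit(table, q, "PLEC", n_permutations,
                            seed=seed, rng=np.random.default_rng(child))
        records.append(_derive_record(q, pl, plec))
    return DarProfileSet(records, group=group, seed=seed)
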