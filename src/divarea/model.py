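"""Model/results interface for diversity-area analysis.

`DiversityAreaModel` is constructed from a community count table and a
grid of diversity orders; `fit()` runs the full permutation-averaged
PL + PLEC fitting protocol and returns a `DARResults` object carrying
the averaged parameters, the derived DAR/PDO/MAD/LGD profiles, success
diagnostics, a `summary()` table, group comparison tests and profile
plots.

Example
-------
>>> from divarea import DiversityAreaModel, SyntheticConfig, generate_cohort
>>> table = generate_cohort(SyntheticConfig(n_samples=30, seed=7))
>>> res = DiversityAreaModel(table).fit(n_permutations=100, seed=1)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import CommunityTable
from .comparison import ComparisonResult, compare_groups
from .profiles import DarProfileSet, build_profiles

__all__ = ["DiversityAreaModel", "DARResults"]


class DiversityAreaModel:
    """Diversity-area scaling model for one cohort of samples.

    Parameters
    ----------
    table:
        Samples x taxa count table; one sample is one unit of area.
    q_grid:
        Diversity orders at which to fit (default 0, 1, 2, 3: richness,
        typical, highly-abundant and dominant species).
    """

    def __init__(self, table: CommunityTable, q_grid: Sequence[float] = (0, 1, 2, 3)):
        if table.n_samples < 4:
            raise ValueError("diversity-area fitting needs at least 4 samples")
        self.table = table
        self.q_grid = [float(q) for q in q_grid]
        if not self.q_grid:
            raise ValueError("q_grid must be non-empty")

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series | None = None,
        q_grid: Sequence[float] = (0, 1, 2, 3),
    ) -> "DiversityAreaModel":
        """Build from a samples x taxa DataFrame of counts."""
        return cls(CommunityTable.from_dataframe(counts, groups=groups), q_grid)

    def fit(
        self,
        n_permutations: int = 100,
        seed: int | None = None,
        group: str | None = None,
    ) -> "DARResults":
        """Fit PL and PLEC over random sample orderings and average.

        ``group`` optionally restricts the fit to samples with that
        label (the whole table is used otherwise).
        """
        table = self.table.by_group(group) if group is not None else self.table
        profiles = build_profiles(
            table, self.q_grid, n_permutations=n_permutations, seed=seed,
            group=group,
        )
        return DARResults(self, profiles, n_permutations=n_permutations, seed=seed)

    def compare(
        self,
        group_a: str,
        group_b: str,
        parameter: str = "z",
        q: float = 0.0,
        model: str = "PL",
        n_iterations: int = 100,
        inner_permutations: int = 10,
        seed: int | None = None,
    ) -> ComparisonResult:
        """Randomization test for a parameter difference between two
        labelled groups of this model's table."""
        return compare_groups(
            self.table, group_a, group_b, parameter=parameter, q=q,
            model=model, n_iterations=n_iterations,
            inner_permutations=inner_permutations, seed=seed,
        )


class DARResults:
    """Fitted diversity-area scaling results.

    Wraps the per-q permutation-averaged PL/PLEC summaries and derived
    profiles; exposes them as a tidy DataFrame, a text summary and plots.
    """

    def __init__(self, model: DiversityAreaModel, profiles: DarProfileSet,
                 n_permutations: int, seed: int | None):
        self.model = model
        self.profile_set = profiles
        self.n_permutations = n_permutations
        self.seed = seed

    # ------------------------------------------------------------------
    @property
    def profiles(self) -> pd.DataFrame:
        """Tidy per-q table (PL block, PLEC block, g, A_max, D_max, LGD%)."""
        return self.profile_set.to_frame()

    def params(self, q: float, model: str = "PL") -> dict[str, float]:
        """Averaged parameters at one diversity order."""
        for rec in self.profile_set:
            if rec.q == float(q):
                s = rec.plec if model == "PLEC" else rec.pl
                out = {"z": s.mean_z, "c": s.mean_c, "R": s.mean_R,
                       "p": s.mean_p, "N": s.N}
                if model == "PLEC":
                    out["d"] = s.mean_d
                return out
        raise KeyError(f"q={q} not in fitted grid {self.profile_set.q_grid}")

    def summary(self) -> str:
        """Plain-text results table in the usual DAR layout."""
        df = self.profiles.drop(columns=["group"])
        lines = [
            "Diversity-Area Relationship fit",
            "=" * 72,
            f"samples: {self.model.table.n_samples}   "
            f"taxa: {self.model.table.n_taxa}   "
            f"permutations: {self.n_permutations}   seed: {self.seed}",
            "-" * 72,
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
            ),
            "-" * 72,
            "z, c, R, g, p, N: power-law (PL) block; *_plec, d, A_max, "
            "D_max, LGD%: PLEC block.",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_dar_pdo(self, ax=None):
        """z(q) and g(q) overlaid on one axis pair."""
        from .plotting import plot_dar_pdo

        return plot_dar_pdo(self.profile_set, ax=ax)

    def plot_mad(self, ax=None):
        from .plotting import plot_mad

        return plot_mad({self.profile_set.group or "all": self.profile_set}, ax=ax)

    def plot_lgd(self, ax=None):
        from .plotting import plot_lgd

        return plot_lgd({self.profile_set.group or "all": self.profile_set}, ax=ax)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        qs = ", ".join(f"{q:g}" for q in self.profile_set.q_grid)
        return f"<DARResults q=[{qs}] permutations={self.n_permutations}>"
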