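"""Diversity-area model fitting.

Two models are fitted to an accumulation curve by ordinary least squares
on their log-linear transforms (natural logarithms):

    PL    D = c A^z            ->  ln D = ln c + z ln A
    PLEC  D = c A^z exp(d A)   ->  ln D = ln c + z ln A + d A

z is the diversity scaling exponent, c the diversity of the first unit of
area, and d the PLEC taper-off parameter (typically negative, so the
curve eventually bends down).  Because the ordering of samples affects c,
parameters are estimated by fitting the model to many random orderings
and averaging the estimates over the successful fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .community import AccumulationCurve, CommunityTable, accumulation_diversities

__all__ = ["DarFit", "PermutedFitSummary", "fit_pl", "fit_plec", "permuted_fit"]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class DarFit:
    """A single PL or PLEC fit to one accumulation curve.

    ``R`` is the correlation between observed and fitted ln D (the square
    root of the OLS R-squared); ``p_value`` is the overall regression
    F-test p-value.  ``degenerate`` flags curves that cannot be fitted
    (e.g. constant diversity), in which case R and p are NaN.
    """

    model: str  # "PL" | "PLEC"
    q: float
    z: float
    c: float
    d: float | None
    R: float
    p_value: float
    n_points: int
    degenerate: bool = False

    def is_successful(self, alpha: float = 0.05) -> bool:
        """Non-degenerate, significant at ``alpha``, and (PLEC) d < 0."""
        if self.degenerate or not np.isfinite(self.p_value):
            return False
        if self.p_value >= alpha:
            return False
        if self.model == "PLEC" and (self.d is None or self.d >= 0):
            return False
        return True


def _log_curve(curve: AccumulationCurve, min_points: int, model: str):
    n = len(curve)
    if n < min_points:
        raise ValueError(
            f"{model} fit requires at least {min_points} points, got {n}"
        )
    A = curve.areas.astype(float)
    return np.log(A), np.log(curve.diversities), A, n


def fit_pl(curve: AccumulationCurve) -> DarFit:
    """OLS fit of ln D = ln c + z ln A (needs >= 3 points, D > 0).

    A curve with zero variance in ln D is flagged degenerate (z = 0,
    R and p undefined) rather than raising.
    """
    lnA, lnD, _, n = _log_curve(curve, 3, "PL")
    if np.ptp(lnD) < _DEGENERATE_TOL:
        return DarFit("PL", curve.q, 0.0, float(np.exp(lnD.mean())), None,
                      np.nan, np.nan, n, degenerate=True)
    res = stats.linregress(lnA, lnD)
    # |r|: correlation between observed and fitted values of ln D
    return DarFit(
        model="PL",
        q=curve.q,
        z=float(res.slope),
        c=float(np.exp(res.intercept)),
        d=None,
        R=float(abs(res.rvalue)),
        p_value=float(res.pvalue),
        n_points=n,
    )


def fit_plec(curve: AccumulationCurve) -> DarFit:
    """OLS fit of ln D = ln c + z ln A + d A (needs >= 4 points, D > 0)."""
    lnA, lnD, A, n = _log_curve(curve, 4, "PLEC")
    if np.ptp(lnD) < _DEGENERATE_TOL:
        return DarFit("PLEC", curve.q, 0.0, float(np.exp(lnD.mean())), 0.0,
                      np.nan, np.nan, n, degenerate=True)
    X = np.column_stack([np.ones(n), lnA, A])
    if np.linalg.matrix_rank(X) < 3:
        return DarFit("PLEC", curve.q, 0.0, float(np.exp(lnD.mean())), 0.0,
                      np.nan, np.nan, n, degenerate=True)
    beta, _, _, _ = np.linalg.lstsq(X, lnD, rcond=None)
    fitted = X @ beta
    ss_res = float(np.sum((lnD - fitted) ** 2))
    ss_tot = float(np.sum((lnD - lnD.mean()) ** 2))
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    k, dof = 2, n - 3
    if ss_res <= _DEGENERATE_TOL * max(1.0, ss_tot):
        p_value = 0.0
    else:
        F = (r2 / k) / ((1.0 - r2) / dof)
        p_value = float(stats.f.sf(F, k, dof))
    return DarFit(
        model="PLEC",
        q=curve.q,
        z=float(beta[1]),
        c=float(np.exp(beta[0])),
        d=float(beta[2]),
        R=float(np.sqrt(r2)),
        p_value=p_value,
        n_points=n,
    )


_FITTERS = {"PL": fit_pl, "PLEC": fit_plec}


@dataclass(frozen=True)
class PermutedFitSummary:
    """Permutation-averaged DAR parameters for one (model, q).

    Means are arithmetic averages over the N successful fits (success:
    non-degenerate, p < 0.05 and, for PLEC, d < 0); NaN when N = 0.
    ``fits`` keeps the individual per-ordering fits for diagnostics.
    """

    model: str
    q: float
    mean_z: float
    mean_c: float
    mean_d: float | None
    mean_R: float
    mean_p: float
    N: int
    n_permutations: int
    seed: int | None
    fits: tuple[DarFit, ...] = field(default=(), repr=False)

    @property
    def success_rate(self) -> float:
        return self.N / self.n_permutations if self.n_permutations else np.nan

    def successful_values(self, name: str) -> np.ndarray:
        """Array of a parameter (``z``/``c``/``d``/``R``) over successful fits."""
        return np.array(
            [getattr(f, name) for f in self.fits if f.is_successful()], dtype=float
        )


def permuted_fit(
    table: CommunityTable,
    q: float,
    model: str = "PL",
    n_permutations: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutedFitSummary:
    """Fit a DAR model to ``n_permutations`` random sample orderings.

    Each ordering is a uniform permutation of all samples drawn without
    replacement from a seeded generator; the accumulation curve is built
    and the requested model fitted to it.  Parameters are averaged over
    the successful fits.  With the same table and seed the summary is
    bitwise reproducible.
    """
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}; expected 'PL' or 'PLEC'")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = table.n_samples
    if n < 4:
        raise ValueError("permuted_fit requires at least 4 non-empty samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    fitter = _FITTERS[model]

    fits: list[DarFit] = []
    counts = table.counts
    areas = np.arange(1, n + 1)
    for _ in range(n_permutations):
        ordering = rng.permutation(n)
        div = accumulation_diversities(counts, ordering, q)
        curve = AccumulationCurve(q=float(q), areas=areas, diversities=div,
                                  ordering=ordering)
        fits.append(fitter(curve))

    good = [f for f in fits if f.is_successful()]
    N = len(good)
    if N == 0:
        warnings.warn(
            f"no successful {model} fits at q={q} over "
            f"{n_permutations} permutations",
            UserWarning,
            stacklevel=2,
        )
        mean = dict(z=np.nan, c=np.nan, d=np.nan, R=np.nan, p=np.nan)
    else:
        mean = dict(
            z=float(np.mean([f.z for f in good])),
            c=float(np.mean([f.c for f in good])),
            d=float(np.mean([f.d for f in good])) if model == "PLEC" else None,
            R=float(np.mean([f.R for f in good])),
            p=float(np.mean([f.p_value for f in good])),
        )
    return PermutedFitSummary(
        model=model,
        q=float(q),
        mean_z=mean["z"],
        mean_c=mean["c"],
        mean_d=mean["d"] if model == "PLEC" else None,
        mean_R=mean["R"],
        mean_p=mean["p"],
        N=N,
        n_permutations=n_permutations,
        seed=seed,
        fits=tuple(fits),
    )
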