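"""Synthetic OTU-table cohorts with tunable inter-individual overlap.

The generator produces per-sample taxon count vectors with the
statistical structure the DAR analysis assumes:

* a global species pool with heavy-tailed (lognormal) abundances, the
  standard microbial species-abundance distribution;
* a core/satellite occupancy structure: a ``core_fraction`` of the pool
  is present in every sample, while each satellite species receives a
  per-species occupancy probability drawn from a Beta law and is present
  in each sample independently with that probability — the single knob
  that moves the scaling exponent z between its complete-overlap (z -> 0)
  and no-overlap (z -> 1) limits;
* finite sequencing depth: reads are drawn multinomially from the
  renormalized abundances of the species present in each sample.

A ``disjoint`` mode partitions the pool evenly across samples with no
sharing at all, the exact z = 1 limit.  ``generate_exact_power_curve``
bypasses count tables entirely and returns noiseless PL/PLEC curves for
fit-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .community import AccumulationCurve, CommunityTable

__all__ = ["SyntheticConfig", "generate_cohort", "generate_exact_power_curve"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the cohort generator.

    Defaults echo the scale of published lung-tissue 16S cohorts (pools
    of several hundred species, thousands of reads per sample, few core
    species) while staying fast enough for desk-side simulation.
    """

    n_samples: int = 50
    pool_size: int = 600
    core_fraction: float = 0.1
    satellite_occupancy: tuple[float, float] = (0.5, 2.0)  # Beta(a, b)
    abundance_law: tuple[float, float] = (0.0, 1.5)  # lognormal (mu, sigma)
    reads_per_sample: int | tuple[int, ...] = 2000
    disjoint: bool = False
    seed: int | None = None
    group: str | None = None
    sample_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.pool_size < 1:
            raise ValueError("n_samples and pool_size must be >= 1")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        a, b = self.satellite_occupancy
        if a <= 0 or b <= 0:
            raise ValueError("Beta occupancy shapes must be positive")
        reads = self.reads_per_sample
        if isinstance(reads, (tuple, list)):
            if len(reads) != self.n_samples or any(r < 1 for r in reads):
                raise ValueError(
                    "per-sample reads list must have n_samples entries >= 1"
                )
        elif reads < 1:
            raise ValueError("reads_per_sample must be >= 1")

    def reads_vector(self) -> np.ndarray:
        r = self.reads_per_sample
        if isinstance(r, (tuple, list)):
            return np.asarray(r, dtype=int)
        return np.full(self.n_samples, int(r), dtype=int)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["reads_per_sample"], tuple):
            d["reads_per_sample"] = list(d["reads_per_sample"])
        d["satellite_occupancy"] = list(d["satellite_occupancy"])
        d["abundance_law"] = list(d["abundance_law"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("satellite_occupancy", "abundance_law"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("reads_per_sample"), list):
            d["reads_per_sample"] = tuple(d["reads_per_sample"])
        return cls(**d)


def _presence_matrix(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n, S = cfg.n_samples, cfg.pool_size
    if cfg.disjoint:
        present = np.zeros((n, S), dtype=bool)
        blocks = np.array_split(np.arange(S), n)
        for i, block in enumerate(blocks):
            present[i, block] = True
        return present
    n_core = math.ceil(cfg.core_fraction * S)
    present = np.zeros((n, S), dtype=bool)
    present[:, :n_core] = True
    n_sat = S - n_core
    if n_sat > 0:
        a, b = cfg.satellite_occupancy
        occ = rng.beta(a, b, size=n_sat)
        present[:, n_core:] = rng.random((n, n_sat)) < occ[np.newaxis, :]
    return present


def generate_cohort(config: SyntheticConfig) -> CommunityTable:
    """Draw one synthetic cohort as a :class:`CommunityTable`.

    Deterministic for a given config (including seed).  A sample that
    ends up with no present species is re-drawn once; a second failure
    raises.
    """
    rng = np.random.default_rng(config.seed)
    S = config.pool_size
    mu, sigma = config.abundance_law
    pool_abundance = rng.lognormal(mean=mu, sigma=sigma, size=S)
    present = _presence_matrix(config, rng)
    reads = config.reads_vector()

    counts = np.zeros((config.n_samples, S), dtype=np.int64)
    for i in range(config.n_samples):
        row = present[i]
        if not row.any():
            # one retry with a fresh occupancy draw for this sample
            a, b = config.satellite_occupancy
            occ = rng.beta(a, b, size=S)
            row = rng.random(S) < occ
            if not row.any():
                raise RuntimeError(
                    f"sample {i} has no present species after one retry; "
                    "increase core_fraction or occupancy"
                )
        w = pool_abundance * row
        counts[i] = rng.multinomial(reads[i], w / w.sum())

    ids = [f"{config.sample_prefix}{i + 1:03d}" for i in range(config.n_samples)]
    taxa = [f"OTU{j + 1:04d}" for j in range(S)]
    groups = {s: config.group for s in ids} if config.group else None
    return CommunityTable(counts, ids, taxa, group_of=groups)


def generate_exact_power_curve(
    c: float,
    z: float,
    n_areas: int,
    d: float | None = None,
    q: float = 0.0,
) -> AccumulationCurve:
    """Noiseless D(A) = c A^z (optionally * exp(dA)) for A = 1..n_areas.

    Real-valued oracle fixture for exact fit-recovery tests; not backed
    by a count table.
    """
    if n_areas < 4:
        raise ValueError("n_areas must be >= 4")
    if c <= 0:
        raise ValueError("c must be positive")
    A = np.arange(1, n_areas + 1, dtype=float)
    D = c * A**z
    if d is not None:
        D = D * np.exp(d * A)
    return AccumulationCurve(q=float(q), areas=A.astype(int), diversities=D)
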