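"""Community count tables and Hill-number diversity.

The data model is a samples x taxa table of non-negative integer read
counts.  One sample is one unit of "area": accumulating A samples means
pooling their raw counts into a single community, and the diversity of
that pooled community is measured with Hill numbers

    D_q = (sum_i p_i^q)^(1/(1-q)),        q != 1
    D_1 = exp(-sum_i p_i ln p_i),         (continuity limit at q = 1)

where p_i are relative abundances and the sum runs over taxa actually
present (p_i > 0).  D_0 is observed richness, D_1 the exponential of
Shannon entropy, D_2 the inverse Simpson concentration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "AccumulationCurve",
    "relative_abundances",
    "hill_number",
    "pooled_diversity",
    "accumulation_curve",
    "accumulation_diversities",
    "read_counts_tsv",
    "read_biom_json",
    "read_metadata_tsv",
]

# |q - 1| below this uses the analytic Shannon limit instead of the general form
_Q1_TOL = 1e-9


def _check_q(q: float) -> float:
    q = float(q)
    if not np.isfinite(q) or q < 0:
        raise ValueError(f"diversity order q must be finite and >= 0, got {q}")
    return q


def relative_abundances(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize a non-negative count vector to relative abundances.

    Zero-count taxa are retained with p_i = 0.  An all-zero vector is an
    empty community and raises ``ValueError``.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("empty community: count vector sums to zero")
    return c / total


def hill_number(p: Sequence[float] | np.ndarray, q: float) -> float:
    """Hill number (effective number of taxa) of order ``q``.

    ``p`` must be a relative-abundance vector (non-negative, summing to 1
    within 1e-9).  Taxa with p_i = 0 are excluded from the sum at every q,
    so D_0 counts only taxa actually present.
    """
    q = _check_q(q)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1 (within 1e-9)")
    return float(_hill_rows(p[np.newaxis, :], q)[0])


def _hill_rows(P: np.ndarray, q: float) -> np.ndarray:
    """Row-wise Hill numbers of a matrix of abundance vectors."""
    present = P > 0
    if q == 0:
        return present.sum(axis=1).astype(float)
    if abs(q - 1.0) < _Q1_TOL:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(present, P * np.log(np.where(present, P, 1.0)), 0.0)
        return np.exp(-terms.sum(axis=1))
    terms = np.where(present, np.where(present, P, 1.0) ** q, 0.0)
    return terms.sum(axis=1) ** (1.0 / (1.0 - q))


@dataclass(frozen=True)
class AccumulationCurve:
    """Diversity accrual along one ordering of samples.

    ``areas`` is 1..n (number of pooled samples); ``diversities[k]`` is the
    Hill number of order ``q`` of the community pooled from the first
    ``areas[k]`` samples of ``ordering``.  Synthetic curves (not derived
    from a table) may carry ``ordering=None``.
    """

    q: float
    areas: np.ndarray
    diversities: np.ndarray
    ordering: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=int))
        object.__setattr__(
            self, "diversities", np.asarray(self.diversities, dtype=float)
        )
        if self.areas.shape != self.diversities.shape:
            raise ValueError("areas and diversities must have equal length")
        if np.any(np.diff(self.areas) <= 0) or np.any(self.areas < 1):
            raise ValueError("areas must be strictly increasing positive integers")
        if np.any(self.diversities <= 0):
            raise ValueError("diversities must be positive")

    def __len__(self) -> int:
        return len(self.areas)


class CommunityTable:
    """Samples x taxa count matrix with optional per-sample group labels.

    Counts must be non-negative integers; duplicate sample or taxon
    identifiers are rejected.  Samples whose row sum is zero carry no
    community and are dropped with a warning (public OTU tables commonly
    contain them).
    """

    def __init__(
        self,
        counts: np.ndarray,
        sample_ids: Sequence[str],
        taxon_ids: Sequence[str],
        group_of: Mapping[str, str] | None = None,
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        sample_ids = [str(s) for s in sample_ids]
        taxon_ids = [str(t) for t in taxon_ids]
        if len(sample_ids) != counts.shape[0]:
            raise ValueError("sample_ids length does not match counts rows")
        if len(taxon_ids) != counts.shape[1]:
            raise ValueError("taxon_ids length does not match counts columns")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(taxon_ids)) != len(taxon_ids):
            raise ValueError("duplicate taxon identifiers")

        row_sums = counts.sum(axis=1)
        if np.any(row_sums == 0):
            dropped = [s for s, r in zip(sample_ids, row_sums) if r == 0]
            warnings.warn(
                f"dropping {len(dropped)} zero-count sample(s): "
                + ", ".join(dropped[:5])
                + ("..." if len(dropped) > 5 else ""),
                UserWarning,
                stacklevel=2,
            )
            keep = row_sums > 0
            counts = counts[keep]
            sample_ids = [s for s, k in zip(sample_ids, keep) if k]

        self.counts: np.ndarray = np.ascontiguousarray(counts, dtype=np.int64)
        self.sample_ids: list[str] = list(sample_ids)
        self.taxon_ids: list[str] = list(taxon_ids)
        self.group_of: dict[str, str] | None = (
            {str(k): str(v) for k, v in group_of.items()}
            if group_of is not None
            else None
        )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def groups(self) -> pd.Series | None:
        if self.group_of is None:
            return None
        return pd.Series(
            [self.group_of.get(s) for s in self.sample_ids],
            index=self.sample_ids,
            name="group",
        )

    def group_labels(self) -> list[str]:
        """Distinct group labels in table order of first appearance."""
        if self.group_of is None:
            return []
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.group_of.get(s)
            if g is not None and g not in seen:
                seen.append(g)
        return seen

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series | None = None,
    ) -> "CommunityTable":
        """Build from a samples x taxa DataFrame (index = sample IDs)."""
        if isinstance(groups, pd.Series):
            groups = groups.dropna().to_dict()
        return cls(
            counts.to_numpy(),
            [str(i) for i in counts.index],
            [str(c) for c in counts.columns],
            group_of=groups,
        )

    def subset(self, indices: Iterable[int]) -> "CommunityTable":
        idx = list(indices)
        if len(idx) == 0:
            raise ValueError("empty sample subset")
        ids = [self.sample_ids[i] for i in idx]
        grp = (
            {s: self.group_of[s] for s in ids if s in self.group_of}
            if self.group_of
            else None
        )
        return CommunityTable(self.counts[idx], ids, self.taxon_ids, group_of=grp)

    def subset_ids(self, sample_ids: Iterable[str]) -> "CommunityTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[str(s)] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return self.subset(idx)

    def by_group(self, label: str) -> "CommunityTable":
        if self.group_of is None:
            raise ValueError("table carries no group labels")
        ids = [s for s in self.sample_ids if self.group_of.get(s) == label]
        if not ids:
            raise ValueError(f"no samples with group label {label!r}")
        return self.subset_ids(ids)

    @classmethod
    def concat(cls, tables: Sequence["CommunityTable"]) -> "CommunityTable":
        """Stack tables over samples, taking the union of taxa."""
        if not tables:
            raise ValueError("no tables to concatenate")
        frames = [t.to_dataframe() for t in tables]
        merged = pd.concat(frames, axis=0).fillna(0).astype(np.int64)
        groups: dict[str, str] = {}
        for t in tables:
            if t.group_of:
                groups.update(t.group_of)
        return cls.from_dataframe(merged, groups=groups or None)

    def with_groups(self, group_of: Mapping[str, str]) -> "CommunityTable":
        return CommunityTable(
            self.counts, self.sample_ids, self.taxon_ids, group_of=group_of
        )

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g = len(self.group_labels()) if self.group_of else 0
        return (
            f"CommunityTable({self.n_samples} samples x {self.n_taxa} taxa, "
            f"{g} groups)"
        )


# ----------------------------------------------------------------------
# Pooled diversity and accumulation curves


def pooled_diversity(
    table: CommunityTable, sample_subset: Iterable[int], q: float
) -> float:
    """Hill number of the community pooled (summed raw counts) over a
    subset of sample row indices."""
    idx = list(sample_subset)
    if len(idx) == 0:
        raise ValueError("empty sample subset")
    pooled = table.counts[idx].sum(axis=0)
    return hill_number(relative_abundances(pooled), q)


def accumulation_diversities(
    counts: np.ndarray, ordering: np.ndarray, q: float
) -> np.ndarray:
    """Diversity of the cumulative pooled community along ``ordering``.

    Vectorized core of :func:`accumulation_curve`: cumulative raw-count
    sums are normalized row-wise and converted to Hill numbers in one
    pass.
    """
    q = _check_q(q)
    cum = np.cumsum(counts[ordering], axis=0, dtype=np.float64)
    totals = cum.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cumulative community with zero total count")
    return _hill_rows(cum / totals, q)


def accumulation_curve(
    table: CommunityTable, ordering: Sequence[int] | np.ndarray, q: float
) -> AccumulationCurve:
    """Build the (A, D_q(A)) accumulation curve for one sample ordering.

    ``ordering`` must be a permutation of ``range(n_samples)``; the unit of
    area A is the number of pooled samples.
    """
    ordering = np.asarray(ordering, dtype=int)
    n = table.n_samples
    if sorted(ordering.tolist()) != list(range(n)):
        raise ValueError("ordering must be a permutation of all sample indices")
    div = accumulation_diversities(table.counts, ordering, q)
    return AccumulationCurve(
        q=float(q),
        areas=np.arange(1, n + 1),
        diversities=div,
        ordering=ordering,
    )


# ----------------------------------------------------------------------
# Readers


def read_counts_tsv(path, transpose: bool = False) -> CommunityTable:
    """Read a TSV count table: first column sample IDs, header taxon IDs.

    Set ``transpose=True`` for taxa-as-rows tables; orientation is never
    guessed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    return CommunityTable.from_dataframe(df)


def read_biom_json(path) -> CommunityTable:
    """Read a BIOM v1.0 JSON table (dense or sparse).

    BIOM stores observations (taxa) x samples; the result is transposed to
    the samples x taxa convention used here.
    """
    with open(path) as fh:
        doc = json.load(fh)
    n_obs, n_samp = doc["shape"]
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((n_obs, n_samp), dtype=np.int64)
    data = doc["data"]
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:, :] = np.asarray(data, dtype=np.int64)
    else:
        for r, c, v in data:
            mat[int(r), int(c)] = int(v)
    return CommunityTable(mat.T, samples, taxa)


def read_metadata_tsv(path) -> dict[str, str]:
    """Read a metadata TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    return dict(zip(df["sample_id"], df["group"]))
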