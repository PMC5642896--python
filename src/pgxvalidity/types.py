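"""Core data containers shared across the analysis stages.

Genotypes are stored as minor/counted-allele dosages in {0, 1, 2} with an
explicit missing sentinel (:data:`MISSING`), never as an implicit zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call inside a :class:`GenotypeMatrix`.
MISSING: int = -1

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One variant: identifier, locus and allele orientation.

    ``counted_allele`` is the allele whose copies the dosage counts; for the
    NAT2 panel it is the acetylation-slowing (variant) allele.
    """

    id: str
    chrom: str
    pos: int
    counted_allele: str
    other_allele: str
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.counted_allele not in _BASES:
            raise ValueError(
                f"counted allele must be a single base in ACGT, got {self.counted_allele!r}"
            )
        if self.other_allele not in _BASES:
            raise ValueError(
                f"other allele must be a single base in ACGT, got {self.other_allele!r}"
            )
        if self.pos < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class SampleRecord:
    """One participant's phenotype and covariates."""

    sample_id: str
    sex: str            # 'M' or 'F'
    ethnicity: str
    status: str         # 'case' or 'control'
    grade: int          # 0 for controls, {2, 3, 4} for cases
    age: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")
        if self.status == "control" and self.grade != 0:
            raise ValueError("controls must have grade 0")
        if self.status == "case" and self.grade not in (2, 3, 4):
            raise ValueError("cases must have grade in {2, 3, 4}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


def samples_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabulate sample records (one row per sample, sample sheet columns)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "sex": [s.sex for s in samples],
            "ethnicity": [s.ethnicity for s in samples],
            "status": [s.status for s in samples],
            "grade": [s.grade for s in samples],
            "age": [s.age for s in samples],
        }
    )


def frame_to_samples(frame: pd.DataFrame) -> list[SampleRecord]:
    return [
        SampleRecord(
            sample_id=str(r.sample_id),
            sex=str(r.sex),
            ethnicity=str(r.ethnicity),
            status=str(r.status),
            grade=int(r.grade),
            age=float(r.age),
        )
        for r in frame.itertuples(index=False)
    ]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``calls[i, j]`` is the number of copies of ``variants[j].counted_allele``
    carried by ``sample_ids[i]`` (0/1/2), or :data:`MISSING`.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or MISSING")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        self._variant_index = {v.id: j for j, v in enumerate(self.variants)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._variant_index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self.variant_index(variant_id)]

    # -- views ----------------------------------------------------------
    def dosages(self, variant_id: str) -> np.ndarray:
        """Dosage column as float with NaN for missing calls."""
        col = self.calls[:, self.variant_index(variant_id)].astype(float)
        col[col == MISSING] = np.nan
        return col

    def sample_call_rate(self) -> pd.Series:
        rate = (self.calls != MISSING).mean(axis=1)
        return pd.Series(rate, index=self.sample_ids, name="call_rate")

    def variant_call_rate(self) -> pd.Series:
        rate = (self.calls != MISSING).mean(axis=0)
        return pd.Series(rate, index=self.variant_ids, name="call_rate")

    def subset(
        self,
        samples: Iterable[str] | np.ndarray | None = None,
        variants: Iterable[str] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given sample/variant ids (or boolean masks)."""
        si = np.arange(self.n_samples)
        vi = np.arange(self.n_variants)
        if samples is not None:
            samples = list(samples)
            if samples and isinstance(samples[0], (bool, np.bool_)):
                si = np.flatnonzero(np.asarray(samples, dtype=bool))
            else:
                pos = {s: i for i, s in enumerate(self.sample_ids)}
                si = np.array([pos[s] for s in samples], dtype=int)
        if variants is not None:
            variants = list(variants)
            if variants and isinstance(variants[0], (bool, np.bool_)):
                vi = np.flatnonzero(np.asarray(variants, dtype=bool))
            else:
                vi = np.array([self.variant_index(v) for v in variants], dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            variants=[self.variants[j] for j in vi],
            calls=self.calls[np.ix_(si, vi)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame (samples x variant ids), NaN for missing."""
        arr = self.calls.astype(float)
        arr[arr == MISSING] = np.nan
        return pd.DataFrame(arr, index=self.sample_ids, columns=self.variant_ids)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: a = exposed cases, b = exposed controls,
    c = unexposed cases, d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposed"
    outcome_label: str = "case"

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("table counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)
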