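"""Core in-memory containers for AIM-panel analyses.

The containers mirror the objects the workflow passes around: a SNP's map
metadata (:class:`LocusRecord`), per-group ancestral-allele frequencies
(:class:`FrequencyTable`), ancestral-allele dosage genotypes
(:class:`GenotypeMatrix`) and the population-to-group mapping
(:class:`GroupAssignment`).

Genotypes are coded as the number of copies of the *ancestral* allele
(0/1/2), because the reference frequency tables report ancestral-allele
frequencies; this keeps frequencies and genotypes directly comparable.
Missing genotypes use the sentinel :data:`MISSING` (-1) and are never
conflated with dosage 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "LocusRecord",
    "FrequencyTable",
    "GenotypeMatrix",
    "GroupAssignment",
]

#: Sentinel for a missing diploid genotype in :class:`GenotypeMatrix`.
MISSING: int = -1

_VALID_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}
_NUCLEOTIDES = set("ACGT")


@dataclass(frozen=True)
class LocusRecord:
    """Identity and map metadata of one bi-allelic SNP.

    Parameters
    ----------
    rs_id : str
        dbSNP identifier (or any unique locus name).
    allele_ancestral, allele_derived : str
        Single-character nucleotides; must differ (bi-allelic marker).
    chromosome : str
        Chromosome label ("1"–"22", "X", "Y", "MT").
    position_bp : int
        1-based physical position.
    intronic : bool
        Metadata flag stating whether the SNP lies in an intron.  It is
        consumed as-is by the selection filters; no annotation lookup is
        performed.
    """

    rs_id: str
    allele_ancestral: str
    allele_derived: str
    chromosome: str
    position_bp: int
    intronic: bool = True

    def validate(self) -> "LocusRecord":
        """Check the bi-allelic and coordinate invariants; return self."""
        if self.allele_ancestral == self.allele_derived:
            raise ValueError(
                f"{self.rs_id}: ancestral and derived alleles are identical "
                f"({self.allele_ancestral!r}); markers must be bi-allelic"
            )
        for a in (self.allele_ancestral, self.allele_derived):
            if len(a) != 1 or a.upper() not in _NUCLEOTIDES:
                raise ValueError(f"{self.rs_id}: invalid allele {a!r}")
        if str(self.chromosome) not in _VALID_CHROMOSOMES:
            raise ValueError(f"{self.rs_id}: invalid chromosome {self.chromosome!r}")
        if self.position_bp < 1:
            raise ValueError(f"{self.rs_id}: position must be >= 1, got {self.position_bp}")
        return self

    @property
    def is_biallelic(self) -> bool:
        return (
            self.allele_ancestral != self.allele_derived
            and len(self.allele_ancestral) == 1
            and len(self.allele_derived) == 1
            and self.allele_ancestral.upper() in _NUCLEOTIDES
            and self.allele_derived.upper() in _NUCLEOTIDES
        )

    @property
    def alleles(self) -> str:
        return f"{self.allele_ancestral}/{self.allele_derived}"


class FrequencyTable:
    """Ancestral-allele frequencies of a set of loci in a set of groups.

    Stores the frequency matrix ``freq`` (loci x groups, values in [0, 1],
    NaN for undefined cells), the ordered :class:`LocusRecord` list and
    group names, and optionally per-group diploid sample sizes (used to
    weight pooled "rest" frequencies in one-vs-rest informativeness and
    for classifier pseudocounts).
    """

    def __init__(
        self,
        loci: Sequence[LocusRecord],
        group_names: Sequence[str],
        freq: np.ndarray,
        sample_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.loci = list(loci)
        self.group_names = list(group_names)
        freq = np.asarray(freq, dtype=float)
        if freq.shape != (len(self.loci), len(self.group_names)):
            raise ValueError(
                f"frequency matrix shape {freq.shape} does not match "
                f"{len(self.loci)} loci x {len(self.group_names)} groups"
            )
        with np.errstate(invalid="ignore"):
            bad = (freq < 0) | (freq > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"frequency out of [0,1] at locus {self.loci[i].rs_id}, "
                f"group {self.group_names[j]}: {freq[i, j]}"
            )
        self.freq = freq
        if sample_sizes is not None:
            missing = [g for g in self.group_names if g not in sample_sizes]
            if missing:
                raise ValueError(f"sample_sizes missing groups: {missing}")
            sample_sizes = {g: int(sample_sizes[g]) for g in self.group_names}
        self.sample_sizes = sample_sizes
        self._index = {rec.rs_id: i for i, rec in enumerate(self.loci)}
        if len(self._index) != len(self.loci):
            raise ValueError("duplicate rs_ids in frequency table")

    @property
    def rs_ids(self) -> list[str]:
        return [rec.rs_id for rec in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def locus_index(self, rs_id: str) -> int:
        try:
            return self._index[rs_id]
        except KeyError:
            raise KeyError(f"locus {rs_id!r} not in frequency table") from None

    def row(self, rs_id: str) -> np.ndarray:
        """Frequency vector (one value per group) of one locus."""
        return self.freq[self.locus_index(rs_id)]

    def group_index(self, group: str) -> int:
        try:
            return self.group_names.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in frequency table") from None

    def group_weights(self, groups: Sequence[str] | None = None) -> np.ndarray:
        """Relative weights of (a subset of) groups.

        Proportional to diploid sample sizes when known, equal otherwise.
        """
        groups = list(groups) if groups is not None else self.group_names
        if self.sample_sizes is None:
            w = np.full(len(groups), 1.0 / len(groups))
        else:
            w = np.array([self.sample_sizes[g] for g in groups], dtype=float)
            w = w / w.sum()
        return w

    def subset(self, rs_ids: Iterable[str]) -> "FrequencyTable":
        idx = [self.locus_index(r) for r in rs_ids]
        return FrequencyTable(
            [self.loci[i] for i in idx],
            self.group_names,
            self.freq[idx],
            self.sample_sizes,
        )

    def to_frame(self) -> pd.DataFrame:
        """Frequencies as a DataFrame indexed by rs_id."""
        return pd.DataFrame(self.freq, index=self.rs_ids, columns=self.group_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FrequencyTable {self.n_loci} loci x {self.n_groups} groups "
            f"{self.group_names}>"
        )


class GenotypeMatrix:
    """Individuals x loci ancestral-allele dosages (0/1/2, MISSING=-1)."""

    def __init__(
        self,
        individual_ids: Sequence[str],
        population_labels: Sequence[str],
        loci: Sequence[LocusRecord],
        geno: np.ndarray,
    ) -> None:
        self.individual_ids = list(individual_ids)
        self.population_labels = list(population_labels)
        self.loci = list(loci)
        geno = np.asarray(geno)
        if geno.dtype.kind == "f":
            g = np.where(np.isnan(geno), MISSING, geno)
            geno = g.astype(np.int8)
        else:
            geno = geno.astype(np.int8)
        if len(self.population_labels) != len(self.individual_ids):
            raise ValueError("population_labels length != individual count")
        if geno.shape != (len(self.individual_ids), len(self.loci)):
            raise ValueError(
                f"genotype shape {geno.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(geno, (0, 1, 2, MISSING))
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {geno[i, j]} for individual "
                f"{self.individual_ids[i]} at {self.loci[j].rs_id}"
            )
        self.geno = geno

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def rs_ids(self) -> list[str]:
        return [rec.rs_id for rec in self.loci]

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN at missing entries."""
        g = self.geno.astype(float)
        g[self.geno == MISSING] = np.nan
        return g

    def missing_mask(self) -> np.ndarray:
        return self.geno == MISSING

    def subset_individuals(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            [self.population_labels[i] for i in idx],
            self.loci,
            self.geno[idx],
        )

    def subset_loci(self, rs_ids: Iterable[str]) -> "GenotypeMatrix":
        index = {rec.rs_id: j for j, rec in enumerate(self.loci)}
        cols = [index[r] for r in rs_ids]
        return GenotypeMatrix(
            self.individual_ids,
            self.population_labels,
            [self.loci[j] for j in cols],
            self.geno[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage_float(), index=self.individual_ids, columns=self.rs_ids)
        df.insert(0, "population", self.population_labels)
        return df

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GenotypeMatrix {self.n_individuals} individuals x {self.n_loci} loci>"


@dataclass
class GroupAssignment:
    """Total mapping from population label to (usually continental) group."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def identity(cls, labels: Iterable[str]) -> "GroupAssignment":
        """Each population is its own group."""
        return cls({lab: lab for lab in labels})

    def group_of(self, population: str) -> str:
        try:
            return self.mapping[population]
        except KeyError:
            raise KeyError(f"population {population!r} has no group assignment") from None

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g)
        return list(seen)

    def check_covers(self, geno: GenotypeMatrix) -> None:
        unmapped = sorted(set(geno.population_labels) - set(self.mapping))
        if unmapped:
            raise KeyError(f"populations without group assignment: {unmapped}")

    def groups_for(self, geno: GenotypeMatrix) -> list[str]:
        self.check_covers(geno)
        return [self.mapping[p] for p in geno.population_labels]
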