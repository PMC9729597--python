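"""Core domain types for pedigree-based rare-variant analysis.

A cohort mixes three sample roles: affected *cases* drawn from multiplex
families, unaffected *family controls* from the same families, and
*unrelated controls* from the population. Variants are biallelic (multi-
allelic sites are split upstream) and carry the annotations the analysis
consumes: gene symbol, functional consequence, gnomAD-style population
frequencies for two panels (South-Asian and global), and calls from five
deleteriousness predictors (SIFT, LRT, MutationTaster, MutationAssessor,
MetaSVM).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Consequence",
    "PredictorCall",
    "Role",
    "Diagnosis",
    "PREDICTOR_NAMES",
    "MISSING_GT",
    "AnnotatedVariant",
    "Sample",
    "Cohort",
    "GeneSet",
]

#: Order of the five deleteriousness predictors in ``predictor_calls``.
PREDICTOR_NAMES = ("SIFT", "LRT", "MutationTaster", "MutationAssessor", "MetaSVM")

#: Sentinel for a missing genotype in the int8 allele-count vector.
MISSING_GT = -1


class Consequence(str, enum.Enum):
    """Functional consequence class of a coding variant."""

    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    STARTLOSS = "startloss"
    CANONICAL_SPLICE = "canonical_splice"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class PredictorCall(str, enum.Enum):
    """One deleteriousness predictor's verdict on a variant."""

    DELETERIOUS = "D"
    TOLERATED = "T"
    MISSING = "."


class Role(str, enum.Enum):
    CASE = "case"
    FAMILY_CONTROL = "family_control"
    UNRELATED_CONTROL = "unrelated_control"


class Diagnosis(str, enum.Enum):
    """Trans-diagnostic serious-mental-illness categories."""

    SCZ = "SCZ"
    BD = "BD"
    OCD = "OCD"
    SUD = "SUD"
    MIXED = "mixed"


@dataclass
class AnnotatedVariant:
    """One normalized biallelic variant with genotypes and annotations.

    Parameters
    ----------
    chrom, pos, ref, alt
        Genomic identity; ``pos`` is 1-based (VCF convention).
    gene
        Gene symbol the variant is annotated to. A variant overlapping two
        genes is represented as two records, one per gene.
    consequence
        Functional class (see :class:`Consequence`).
    maf_sas, maf_global
        Alternate-allele frequencies in the South-Asian and global reference
        panels; ``None`` when the variant is absent from the panel. The
        rare/common decision interprets missing as unobserved (frequency 0)
        — that rule lives in :mod:`pedseg.prioritize`, not here.
    predictor_calls
        Tuple of exactly five :class:`PredictorCall` in the order
        ``PREDICTOR_NAMES``.
    genotypes
        ``int8`` array of per-sample alternate-allele counts in {0, 1, 2},
        with :data:`MISSING_GT` for missing calls; aligned to the cohort's
        sample order. Phase is ignored throughout.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    maf_sas: float | None
    maf_global: float | None
    predictor_calls: tuple[PredictorCall, ...]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.predictor_calls) != len(PREDICTOR_NAMES):
            raise ValueError(
                f"expected {len(PREDICTOR_NAMES)} predictor calls, "
                f"got {len(self.predictor_calls)}"
            )
        for maf, label in ((self.maf_sas, "maf_sas"), (self.maf_global, "maf_global")):
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise ValueError(f"{label} must be in [0, 1], got {maf}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity ignoring the gene annotation."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def carrier_mask(self) -> np.ndarray:
        """Boolean mask of samples carrying >= 1 alternate allele.

        Missing genotypes count as non-carriers.
        """
        return self.genotypes >= 1


@dataclass
class Sample:
    """One sequenced individual with pedigree links and affection status."""

    sample_id: str
    family_id: str  # empty string for unrelated controls
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    affected: bool = False
    role: Role = Role.UNRELATED_CONTROL
    diagnosis: Diagnosis | None = None

    def __post_init__(self) -> None:
        if self.role is Role.CASE and not self.affected:
            raise ValueError(f"case {self.sample_id} must be affected")
        if self.role is Role.UNRELATED_CONTROL and self.family_id:
            raise ValueError(
                f"unrelated control {self.sample_id} must have empty family_id"
            )


@dataclass
class Cohort:
    """Sample collection with family membership.

    The sample order fixed here is the canonical order every genotype
    vector in the analysis is aligned to.
    """

    samples: list[Sample]
    families: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not self.families:
            fams: dict[str, list[str]] = {}
            for s in self.samples:
                if s.family_id:
                    fams.setdefault(s.family_id, []).append(s.sample_id)
            self.families = fams
        self._index = {sid: i for i, sid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def index_of(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def indices_of(self, sample_ids) -> np.ndarray:
        return np.array([self.index_of(s) for s in sample_ids], dtype=np.intp)

    def by_role(self, role: Role) -> list[Sample]:
        return [s for s in self.samples if s.role is role]

    def cases_in_family(self, family_id: str) -> list[str]:
        members = self.families.get(family_id, [])
        return [
            sid
            for sid in members
            if self.samples[self.index_of(sid)].role is Role.CASE
        ]

    def family_controls_in_family(self, family_id: str) -> list[str]:
        members = self.families.get(family_id, [])
        return [
            sid
            for sid in members
            if self.samples[self.index_of(sid)].role is Role.FAMILY_CONTROL
        ]


@dataclass
class GeneSet:
    """A named set of gene symbols drawn from a finite coding-gene universe."""

    name: str
    genes: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        self.genes = frozenset(g.strip().upper() for g in self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(self.genes) > self.universe_size:
            raise ValueError(
                f"gene set {self.name!r} larger than its universe "
                f"({len(self.genes)} > {self.universe_size})"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.genes
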