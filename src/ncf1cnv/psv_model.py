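"""Forward model for the two paralog-specific variants (PSVs) of the NCF1 locus.

The three ~106-kb duplicons at 7q11.23 carry near-identical copies of NCF1:
the functional gene plus the pseudogenes NCF1B and NCF1C. Two sites separate
them in a joint pyrosequencing read-out of all copies:

* exon-2 GT/GTGT indel — NCF1 carries GTGT, both pseudogenes carry the 2-bp
  GT deletion, so the GT allele fraction is ``f_GT = (b + c) / (b + n + c)``;
* exon-9 A/G substitution — NCF1B and NCF1 carry A, NCF1C carries G, so the
  A allele fraction is ``f_A = (b + n) / (b + n + c)``.

Together the two fractions determine the copy-number trio ``(b, n, c)`` up to
an overall scale factor (``expected_fractions`` is invariant under
``(b,n,c) -> (kb,kn,kc)``); breaking that non-identifiability is the job of
the integer caller in :mod:`ncf1cnv.copy_caller`.

Raw pyrograms deliver light-peak heights proportional to incorporated
nucleotides; ``peaks_to_fractions`` converts a pair of informative peak
heights into an allele fraction, with an optional multiplicative calibration
factor absorbing incorporation-yield differences between alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .errors import DomainError, InputError

__all__ = [
    "Paralog",
    "PsvSite",
    "PsvAssay",
    "CopyNumberTrio",
    "AlleleFractionProfile",
    "PeakPair",
    "EXON2_INDEL",
    "EXON9_SNV",
    "expected_fractions",
    "expected_gt_ratio",
    "peaks_to_fractions",
    "peak_pair_to_fraction",
]


class Paralog(str, Enum):
    NCF1B = "NCF1B"
    NCF1 = "NCF1"
    NCF1C = "NCF1C"


class PsvSite(str, Enum):
    exon2_indel = "exon2_indel"
    exon9_snv = "exon9_snv"


@dataclass(frozen=True)
class PsvAssay:
    """One paralog-distinguishing pyrosequencing assay.

    ``allele_of_paralog`` maps each paralog to the allele label it carries at
    this site; ``allele1`` is the allele whose fraction the assay reports
    (GT at exon 2, A at exon 9).  ``calibration_factor`` is the relative peak
    yield of allele 2 versus allele 1 (1.0 = uncalibrated heights).
    """

    site_id: PsvSite
    allele_of_paralog: Mapping[Paralog, str]
    allele1: str
    allele2: str
    calibration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.calibration_factor <= 0:
            raise InputError(
                f"calibration_factor must be positive, got {self.calibration_factor}"
            )
        labels = set(self.allele_of_paralog.values())
        if labels != {self.allele1, self.allele2}:
            raise InputError(
                f"assay {self.site_id}: paralog alleles {labels} do not match "
                f"declared alleles ({self.allele1}, {self.allele2})"
            )
        if set(self.allele_of_paralog) != set(Paralog):
            raise InputError(f"assay {self.site_id}: every paralog needs an allele")


#: Exon-2 2-bp indel: NCF1 = GTGT, NCF1B = NCF1C = GT (the CGD signature deletion).
EXON2_INDEL = PsvAssay(
    site_id=PsvSite.exon2_indel,
    allele_of_paralog={Paralog.NCF1B: "GT", Paralog.NCF1: "GTGT", Paralog.NCF1C: "GT"},
    allele1="GT",
    allele2="GTGT",
)

#: Exon-9 substitution: NCF1B = NCF1 = A, NCF1C = G.
EXON9_SNV = PsvAssay(
    site_id=PsvSite.exon9_snv,
    allele_of_paralog={Paralog.NCF1B: "A", Paralog.NCF1: "A", Paralog.NCF1C: "G"},
    allele1="A",
    allele2="G",
)


@dataclass(frozen=True, order=True)
class CopyNumberTrio:
    """Integer copies of (NCF1B, NCF1, NCF1C) in one diploid genome."""

    b: int
    n: int
    c: int

    def __post_init__(self) -> None:
        for name in ("b", "n", "c"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise DomainError(f"copy count {name}={v!r} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.b + self.n + self.c

    @property
    def pseudogene_copies(self) -> int:
        """Total pseudogene copies b + c (the ΔGT numerator)."""
        return self.b + self.c

    @property
    def class_label(self) -> str:
        """Diploid ratio-class label 'p:q' = pseudogene copies : NCF1 copies."""
        return f"{self.pseudogene_copies}:{self.n}"

    def scaled(self, k: int) -> "CopyNumberTrio":
        return CopyNumberTrio(self.b * k, self.n * k, self.c * k)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.b, self.n, self.c)


@dataclass(frozen=True)
class AlleleFractionProfile:
    """The two PSV read-outs for one DNA or cDNA sample.

    ``f_gt`` — fraction of GT (deletion) alleles at exon 2;
    ``f_a`` — fraction of A alleles at exon 9.
    NaN marks a no-call (e.g. a failed pyrogram), which downstream callers
    propagate rather than raise on.
    """

    f_gt: float
    f_a: float
    sample_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name, v in (("f_gt", self.f_gt), ("f_a", self.f_a)):
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                who = f" (sample {self.sample_id})" if self.sample_id else ""
                raise InputError(f"{name}={v} outside [0, 1]{who}")

    @property
    def f_g(self) -> float:
        """Fraction of G alleles at exon 9 (the NCF1C share)."""
        return 1.0 - self.f_a

    @property
    def r_gt(self) -> float:
        """ΔGT/GTGT ratio f_GT / (1 - f_GT); defined only for f_GT < 1."""
        if self.f_gt >= 1.0:
            raise DomainError(
                "ΔGT/GTGT ratio undefined at f_GT = 1 (no GTGT alleles: "
                "CGD-like genotype with zero NCF1 copies)"
            )
        return self.f_gt / (1.0 - self.f_gt)

    @property
    def is_no_call(self) -> bool:
        return math.isnan(self.f_gt) or math.isnan(self.f_a)


@dataclass(frozen=True)
class PeakPair:
    """Informative pyrogram peak heights for the two alleles of one assay."""

    h1: float
    h2: float

    def __post_init__(self) -> None:
        if self.h1 < 0 or self.h2 < 0:
            raise InputError(f"peak heights must be non-negative, got ({self.h1}, {self.h2})")


def expected_fractions(trio: CopyNumberTrio, sample_id: str | None = None) -> AlleleFractionProfile:
    """Expected allele fractions for a genome with copy numbers ``trio``.

    f_GT = (b + c) / T and f_A = (b + n) / T with T = b + n + c; every copy
    contributes one template molecule, so fractions are copy-weighted.
    """
    t = trio.total
    if t == 0:
        who = f"sample {sample_id}" if sample_id else "trio"
        raise DomainError(f"{who}: zero total copy number, fractions undefined")
    return AlleleFractionProfile(
        f_gt=(trio.b + trio.c) / t,
        f_a=(trio.b + trio.n) / t,
        sample_id=sample_id,
    )


def expected_gt_ratio(trio: CopyNumberTrio) -> float:
    """Expected ΔGT/GTGT ratio (b + c) / n, i.e. pseudogene : NCF1 copies."""
    if trio.n == 0:
        raise DomainError(
            "ΔGT/GTGT ratio undefined for n = 0 (no NCF1 copies: CGD-like genotype)"
        )
    return (trio.b + trio.c) / trio.n


def peak_pair_to_fraction(peaks: PeakPair, assay: PsvAssay) -> float:
    """Allele-1 fraction from one peak pair: h1 / (h1 + cal * h2).

    A zero-sum pair yields NaN (no-call marker) rather than an exception.
    """
    denom = peaks.h1 + assay.calibration_factor * peaks.h2
    if denom == 0:
        return math.nan
    return peaks.h1 / denom


def peaks_to_fractions(
    peaks_exon2: PeakPair,
    peaks_exon9: PeakPair,
    assay_exon2: PsvAssay = EXON2_INDEL,
    assay_exon9: PsvAssay = EXON9_SNV,
    sample_id: str | None = None,
) -> AlleleFractionProfile:
    """Convert raw pyrogram peak pairs at both PSV sites into a fraction profile."""
    return AlleleFractionProfile(
        f_gt=peak_pair_to_fraction(peaks_exon2, assay_exon2),
        f_a=peak_pair_to_fraction(peaks_exon9, assay_exon9),
        sample_id=sample_id,
    )
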