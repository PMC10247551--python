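"""Shared domain types for biallelic identity-SNP typing.

The data model mirrors how massively parallel sequencing identity panels are
analysed in forensic genetics: a fixed panel of biallelic SNP loci (autosomal
plus Y-specific), per-locus per-allele per-strand read counts for each sample,
threshold-based genotype calls with quality flags, and population allele
frequencies that feed likelihood-ratio computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

AUTOSOMAL = "autosomal"
Y = "Y"

CALLED = "called"
NO_CALL = "no_call"

MAF_FLAG = "MAF_FLAG"
HOM_IMBALANCE_ALERT = "HOM_IMBALANCE_ALERT"
SINGLE_ALLELE = "SINGLE_ALLELE"  # consensus locus supported by one allele only

NUCLEOTIDES = ("A", "C", "G", "T")

# Notional reference-database size used to floor allele frequencies before any
# likelihood-ratio use; theta-corrected formulas divide by frequency-bearing
# terms, so a hard zero is never allowed through.
FREQ_FLOOR_N = 1000
FREQ_FLOOR = 1.0 / (2 * FREQ_FLOOR_N + 2)


@dataclass(frozen=True)
class LocusDef:
    """One biallelic SNP locus of the panel.

    amplicon_length matters only to the simulator's degradation model: longer
    amplicons are less likely to survive in fragmented ancient DNA.
    """

    locus_id: str
    chrom_class: str
    alleles: tuple[str, str]
    amplicon_length: int

    def __post_init__(self) -> None:
        if self.chrom_class not in (AUTOSOMAL, Y):
            raise ValueError(f"unknown chrom_class {self.chrom_class!r}")
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.locus_id}: a locus needs two distinct alleles")
        if self.amplicon_length <= 0:
            raise ValueError(f"{self.locus_id}: amplicon_length must be positive")


def make_panel(n_autosomal: int, n_y: int, seed: int) -> list[LocusDef]:
    """Build a deterministic synthetic panel of biallelic SNP loci.

    Defaults elsewhere assume the identity-panel geometry of 90 autosomal plus
    34 Y-specific markers, but any total >= 1 is accepted. Amplicon lengths are
    drawn uniformly in [60, 160] bp, the short-amplicon range such panels use.
    """
    if n_autosomal < 0 or n_y < 0 or n_autosomal + n_y < 1:
        raise ValueError("panel must contain at least one locus")
    rng = np.random.default_rng(seed)
    loci: list[LocusDef] = []
    for i in range(n_autosomal + n_y):
        chrom = AUTOSOMAL if i < n_autosomal else Y
        prefix = "rsA" if chrom == AUTOSOMAL else "rsY"
        a1, a2 = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
        loci.append(
            LocusDef(
                locus_id=f"{prefix}{i:04d}",
                chrom_class=chrom,
                alleles=(NUCLEOTIDES[a1], NUCLEOTIDES[a2]),
                amplicon_length=int(rng.integers(60, 161)),
            )
        )
    return loci


def panel_index(panel: Sequence[LocusDef]) -> dict[str, LocusDef]:
    idx = {l.locus_id: l for l in panel}
    if len(idx) != len(panel):
        raise ValueError("duplicate locus_id in panel")
    return idx


def autosomal_loci(panel: Sequence[LocusDef]) -> list[LocusDef]:
    return [l for l in panel if l.chrom_class == AUTOSOMAL]


def y_loci(panel: Sequence[LocusDef]) -> list[LocusDef]:
    return [l for l in panel if l.chrom_class == Y]


@dataclass
class AlleleCounts:
    """Per-locus, per-allele, per-strand read counts for one sample.

    counts maps locus_id -> allele -> (reads_fwd, reads_rev).
    """

    sample_id: str
    counts: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, alleles in self.counts.items():
            for allele, (fwd, rev) in alleles.items():
                if fwd < 0 or rev < 0:
                    raise ValueError(
                        f"{self.sample_id}/{locus}/{allele}: negative read count"
                    )

    def locus_total(self, locus_id: str) -> int:
        return sum(f + r for f, r in self.counts.get(locus_id, {}).values())

    def allele_total(self, locus_id: str, allele: str) -> int:
        f, r = self.counts.get(locus_id, {}).get(allele, (0, 0))
        return f + r


@dataclass(frozen=True)
class GenotypeCall:
    """A called (or failed) genotype at one locus.

    genotype is a sorted allele tuple: two alleles for an autosomal call, one
    for a hemizygous Y call, empty when no_call. minor_fraction is the
    minor-allele read fraction (autosomal only). y_dropin_allele records a
    second allele above the heterozygote threshold at a Y locus — a spurious
    haplotype / contamination signal.
    """

    locus_id: str
    status: str
    genotype: tuple[str, ...] = ()
    coverage: int = 0
    minor_fraction: Optional[float] = None
    flags: frozenset[str] = frozenset()
    no_call_reason: str = "none"
    y_dropin_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in (CALLED, NO_CALL):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == NO_CALL) != (len(self.genotype) == 0):
            raise ValueError(f"{self.locus_id}: genotype must be empty iff no_call")
        if self.status == NO_CALL and self.no_call_reason not in (
            "low_coverage",
            "strand_fail",
        ):
            raise ValueError(f"{self.locus_id}: no_call needs a reason")
        if self.coverage < 0:
            raise ValueError(f"{self.locus_id}: negative coverage")
        if self.minor_fraction is not None and not 0.0 <= self.minor_fraction <= 0.5:
            raise ValueError(f"{self.locus_id}: minor_fraction outside [0, 0.5]")
        if MAF_FLAG in self.flags and not self.is_het:
            raise ValueError(f"{self.locus_id}: MAF_FLAG on a non-heterozygous call")
        if HOM_IMBALANCE_ALERT in self.flags and (len(self.genotype) != 2 or self.is_het):
            raise ValueError(f"{self.locus_id}: imbalance alert on a non-homozygote")
        object.__setattr__(self, "genotype", tuple(sorted(self.genotype)))

    @property
    def is_called(self) -> bool:
        return self.status == CALLED

    @property
    def is_het(self) -> bool:
        return len(self.genotype) == 2 and self.genotype[0] != self.genotype[1]

    @property
    def is_autosomal_call(self) -> bool:
        return self.is_called and len(self.genotype) == 2

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.genotype)


@dataclass
class Profile:
    """A sample's called genotypes across the panel (autosomal + Y)."""

    sample_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    sex_markers_present: bool = False

    def __post_init__(self) -> None:
        for locus_id, call in self.calls.items():
            if call.locus_id != locus_id:
                raise ValueError(f"call keyed {locus_id} carries id {call.locus_id}")

    def called_autosomal(self) -> dict[str, GenotypeCall]:
        return {k: c for k, c in self.calls.items() if c.is_autosomal_call}

    def called_y(self) -> dict[str, GenotypeCall]:
        return {
            k: c for k, c in self.calls.items() if c.is_called and len(c.genotype) == 1
        }

    def typed_autosomal(self) -> int:
        """Number of autosomal markers with a genotype call."""
        return len(self.called_autosomal())


@dataclass
class FrequencyTable:
    """Population allele frequencies per panel locus.

    freqs maps locus_id -> allele -> frequency; per locus the frequencies are
    strictly positive and sum to 1 within 1e-9.
    """

    population: str
    freqs: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, fr in self.freqs.items():
            if any(p <= 0 for p in fr.values()):
                raise ValueError(f"{locus}: frequencies must be > 0")
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{locus}: frequencies sum to {total}, not 1")

    def locus(self, locus_id: str) -> dict[str, float]:
        try:
            return self.freqs[locus_id]
        except KeyError:
            raise KeyError(f"locus {locus_id} missing from frequency table") from None

    def locus_floored(self, locus_id: str) -> dict[str, float]:
        """Frequencies with the 1/(2N+2) floor applied, for likelihood use."""
        return {a: max(p, FREQ_FLOOR) for a, p in self.locus(locus_id).items()}


@dataclass(frozen=True)
class LRParams:
    """Drop-out/drop-in/θ parameter set for a semi-continuous LR run.

    setting records which of the three analysis conventions produced it:
    'default' (ADO 0.1, ADI 0.05), 'estimated' (grid-MLE ADO with a 0.1
    floor), or 'actual' (sample-specific frequencies from truth accounting).
    """

    ado: float
    adi: float
    theta: float = 0.01
    setting: str = "custom"

    def __post_init__(self) -> None:
        for name, v in (("ado", self.ado), ("adi", self.adi), ("theta", self.theta)):
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")

    @classmethod
    def default(cls) -> "LRParams":
        return cls(ado=0.1, adi=0.05, theta=0.01, setting="default")


@dataclass
class LRResult:
    """Combined and per-locus likelihood ratio for one comparison.

    per_locus maps locus_id -> (numerator, denominator) locus likelihoods;
    log10_lr is the sum of per-locus log10 ratios (−inf when a numerator is
    exactly zero, as happens under 'actual' parameters of zero).
    """

    log10_lr: float
    per_locus: dict[str, tuple[float, float]]
    params: Optional[LRParams]
    n_loci_used: int
    model: str
    verbal: str
    direction: str

    @property
    def total_lr(self) -> float:
        return 10.0 ** self.log10_lr if math.isfinite(self.log10_lr) else (
            0.0 if self.log10_lr < 0 else math.inf
        )


def combine_log10(per_locus: Mapping[str, tuple[float, float]]) -> float:
    """Sum of per-locus log10(num/den), tolerating exact-zero numerators."""
    total = 0.0
    for num, den in per_locus.values():
        if den <= 0:
            raise ValueError("zero denominator in locus likelihood")
        if num == 0.0:
            return -math.inf
        total += math.log10(num) - math.log10(den)
    return total
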