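"""Threshold-based genotype calling from per-allele, per-strand read counts.

Implements the default rule set of MPS identity-panel genotyping software:
a locus is typed only with >= 20 total reads and more than 10 reads on each
strand; heterozygotes whose minor-allele read fraction falls in the unbalanced
band get a MAF flag; homozygotes whose second allele carries 5-10% of the
reads get an imbalance alert. Band edges are configurable; the defaults read
the printed percentage bands as continuous, gap-free cut-points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import (
    AUTOSOMAL,
    CALLED,
    HOM_IMBALANCE_ALERT,
    MAF_FLAG,
    NO_CALL,
    AlleleCounts,
    GenotypeCall,
    LocusDef,
    Profile,
    panel_index,
)

StrandCounts = Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class CallThresholds:
    """Locus-call gates and allele-balance bands.

    min_coverage: minimum total reads for a genotype (inclusive).
    min_strand: per-strand read total must strictly exceed this.
    hom_alert_band: closed minor-fraction interval flagged on homozygotes.
    het_min_minor: minor fraction strictly above this is heterozygous.
    het_flag_max_minor: heterozygote MAF flag when minor fraction is strictly
        below this (and above het_min_minor).
    """

    min_coverage: int = 20
    min_strand: int = 10
    hom_alert_band: tuple[float, float] = (0.05, 0.10)
    het_min_minor: float = 0.10
    het_flag_max_minor: float = 0.35

    def __post_init__(self) -> None:
        lo, hi = self.hom_alert_band
        if not (0.0 <= lo < hi <= self.het_min_minor <= 0.5):
            raise ValueError("require 0 <= alert lo < alert hi <= het_min_minor <= 0.5")
        if not self.het_min_minor < self.het_flag_max_minor <= 0.5:
            raise ValueError("require het_min_minor < het_flag_max_minor <= 0.5")


def _gate(
    locus: LocusDef, counts: StrandCounts, th: CallThresholds
) -> tuple[int, int, int] | GenotypeCall:
    """Coverage/strand gates; returns (total, fwd, rev) or a no_call."""
    for allele, (f, r) in counts.items():
        if f < 0 or r < 0:
            raise ValueError(f"{locus.locus_id}/{allele}: negative read count")
        if allele not in locus.alleles:
            raise ValueError(f"{locus.locus_id}: unexpected allele {allele!r}")
    fwd = sum(f for f, _ in counts.values())
    rev = sum(r for _, r in counts.values())
    total = fwd + rev
    if total < th.min_coverage:
        return GenotypeCall(
            locus.locus_id, NO_CALL, coverage=total, no_call_reason="low_coverage"
        )
    if fwd <= th.min_strand or rev <= th.min_strand:
        return GenotypeCall(
            locus.locus_id, NO_CALL, coverage=total, no_call_reason="strand_fail"
        )
    return total, fwd, rev


def _allele_totals(locus: LocusDef, counts: StrandCounts) -> list[tuple[str, int]]:
    totals = []
    for allele in locus.alleles:
        f, r = counts.get(allele, (0, 0))
        totals.append((allele, f + r))
    totals.sort(key=lambda ar: (-ar[1], ar[0]))
    return totals


def call_locus(locus: LocusDef, counts: StrandCounts, th: CallThresholds) -> GenotypeCall:
    """Call one autosomal biallelic locus from per-strand counts.

    After the coverage and strand gates, the minor-allele read fraction m
    decides the genotype: m < 0.05 clean homozygote; 0.05 <= m <= 0.10
    homozygote with imbalance alert; m > 0.10 heterozygote, MAF-flagged when
    m < 0.35. A 50/50 split is an unflagged heterozygote.
    """
    if locus.chrom_class != AUTOSOMAL:
        raise ValueError(f"{locus.locus_id} is not autosomal")
    gated = _gate(locus, counts, th)
    if isinstance(gated, GenotypeCall):
        return gated
    total, _, _ = gated
    (major, major_n), (minor, minor_n) = _allele_totals(locus, counts)
    m = minor_n / total
    alert_lo, alert_hi = th.hom_alert_band
    if m > th.het_min_minor:
        flags = frozenset({MAF_FLAG}) if m < th.het_flag_max_minor else frozenset()
        genotype = (major, minor)
    elif m >= alert_lo:
        flags = frozenset({HOM_IMBALANCE_ALERT})
        genotype = (major, major)
    else:
        flags = frozenset()
        genotype = (major, major)
    return GenotypeCall(
        locus.locus_id,
        CALLED,
        genotype=genotype,
        coverage=total,
        minor_fraction=m,
        flags=flags,
    )


def call_y_locus(locus: LocusDef, counts: StrandCounts, th: CallThresholds) -> GenotypeCall:
    """Call one hemizygous Y locus: majority allele under the same gates.

    A second allele above the heterozygote threshold cannot be genuine on a
    single-source male sample, so it is recorded as a Y drop-in annotation —
    the spurious-haplotype contamination signal.
    """
    gated = _gate(locus, counts, th)
    if isinstance(gated, GenotypeCall):
        return gated
    total, _, _ = gated
    (major, _), (minor, minor_n) = _allele_totals(locus, counts)
    dropin = minor if minor_n / total > th.het_min_minor else None
    return GenotypeCall(
        locus.locus_id,
        CALLED,
        genotype=(major,),
        coverage=total,
        y_dropin_allele=dropin,
    )


def call_profile(
    counts: AlleleCounts, panel: Sequence[LocusDef], th: CallThresholds | None = None
) -> Profile:
    """Call every panel locus for one sample; absent loci become no_calls."""
    th = th or CallThresholds()
    idx = panel_index(panel)
    for locus_id in counts.counts:
        if locus_id not in idx:
            raise ValueError(f"locus {locus_id} in counts but not in panel")
    calls: dict[str, GenotypeCall] = {}
    for locus in panel:
        locus_counts = counts.counts.get(locus.locus_id, {})
        if locus.chrom_class == AUTOSOMAL:
            calls[locus.locus_id] = call_locus(locus, locus_counts, th)
        else:
            calls[locus.locus_id] = call_y_locus(locus, locus_counts, th)
    profile = Profile(
        sample_id=counts.sample_id,
        calls=calls,
        sex_markers_present=any(
            c.is_called and len(c.genotype) == 1 for c in calls.values()
        ),
    )
    return profile
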