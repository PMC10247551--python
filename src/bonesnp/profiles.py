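"""Reference and consensus profile construction, and fidelity accounting.

A *reference* profile is built from replicate high-input libraries of the
same skeleton, which must be full and mutually concordant. A *consensus*
profile is built Turchi-style from many partial low-template libraries: an
allele enters the consensus when at least `min_support` samples called it.
Fidelity of a single test against a reference is summarised as allelic
drop-out (ADO, per reference allele at called loci), allelic drop-in (ADI,
per locus carrying a non-reference allele, classified by how it changed the
genotype), MAF-flag frequency and observed heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import (
    CALLED,
    MAF_FLAG,
    NO_CALL,
    SINGLE_ALLELE,
    FrequencyTable,
    GenotypeCall,
    LocusDef,
    Profile,
    autosomal_loci,
)


class ReferenceDiscordanceError(ValueError):
    """Replicate reference libraries disagree (or are incomplete) at a locus."""

    def __init__(self, locus_id: str, detail: str):
        self.locus_id = locus_id
        super().__init__(f"reference discordance at {locus_id}: {detail}")


def build_reference(replicates: Sequence[Profile]) -> Profile:
    """Merge fully concordant replicate profiles into one reference profile.

    Reference libraries come from nanogram inputs and must agree exactly;
    any uncalled or discordant locus raises ReferenceDiscordanceError naming
    the locus rather than silently producing a majority call.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to build a reference")
    loci = sorted({l for r in replicates for l in r.calls})
    calls: dict[str, GenotypeCall] = {}
    for locus_id in loci:
        genotypes = []
        for rep in replicates:
            call = rep.calls.get(locus_id)
            if call is None or not call.is_called:
                raise ReferenceDiscordanceError(
                    locus_id, f"uncalled in replicate {rep.sample_id}"
                )
            genotypes.append(call.genotype)
        if len(set(genotypes)) != 1:
            raise ReferenceDiscordanceError(locus_id, f"discordant calls {set(genotypes)}")
        calls[locus_id] = GenotypeCall(locus_id, CALLED, genotype=genotypes[0])
    return Profile(
        sample_id=f"reference({replicates[0].sample_id}+{len(replicates) - 1})",
        calls=calls,
        sex_markers_present=any(r.sex_markers_present for r in replicates),
    )


def build_consensus(samples: Sequence[Profile], min_support: int = 2) -> Profile:
    """Turchi-style consensus across partial replicate typings.

    Per locus, an allele is *supported* when it appears in the calls of at
    least min_support samples. Two or more supported alleles give a
    heterozygous consensus of the two best supported (ties broken by total
    supporting read depth, then lexicographically); exactly one gives a
    single-allele consensus exported as homozygous but tagged SINGLE_ALLELE
    (it cannot be distinguished from a heterozygote with drop-out); none
    leaves the locus uncalled.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for a consensus")
    loci = sorted({l for s in samples for l in s.calls})
    calls: dict[str, GenotypeCall] = {}
    for locus_id in loci:
        support: dict[str, int] = {}
        depth: dict[str, int] = {}
        hemizygous = False
        for s in samples:
            call = s.calls.get(locus_id)
            if call is None or not call.is_called:
                continue
            if len(call.genotype) == 1:
                hemizygous = True
            for allele in set(call.genotype):
                support[allele] = support.get(allele, 0) + 1
                depth[allele] = depth.get(allele, 0) + call.coverage
        supported = [a for a, n in support.items() if n >= min_support]
        supported.sort(key=lambda a: (-support[a], -depth[a], a))
        if not supported:
            calls[locus_id] = GenotypeCall(
                locus_id, NO_CALL, no_call_reason="low_coverage"
            )
        elif hemizygous:
            calls[locus_id] = GenotypeCall(locus_id, CALLED, genotype=(supported[0],))
        elif len(supported) == 1:
            calls[locus_id] = GenotypeCall(
                locus_id,
                CALLED,
                genotype=(supported[0], supported[0]),
                flags=frozenset({SINGLE_ALLELE}),
            )
        else:
            calls[locus_id] = GenotypeCall(
                locus_id, CALLED, genotype=(supported[0], supported[1])
            )
    return Profile(
        sample_id=f"consensus({len(samples)})",
        calls=calls,
        sex_markers_present=any(s.sex_markers_present for s in samples),
    )


@dataclass
class ConcordanceSummary:
    """ADO/ADI/MAF fidelity of one test profile against a reference.

    Frequencies are None when no autosomal locus was typed. ado_freq is per
    reference allele at called loci (2 per locus); adi_freq, maf_flag_freq
    and het_observed are per called locus.
    """

    n_typed: int
    ado_count: int
    adi_count: int
    adi_hom_swap_count: int
    adi_hom_to_het_count: int
    adi_het_ref_count: int
    maf_flag_count: int
    het_count: int
    ado_freq: Optional[float]
    adi_freq: Optional[float]
    maf_flag_freq: Optional[float]
    het_observed: Optional[float]


def concordance_stats(test: Profile, reference: Profile) -> ConcordanceSummary:
    """Count drop-out and drop-in events of `test` against `reference`.

    Only autosomal loci called in both profiles are scored. ADO counts each
    reference allele copy absent from the test call (an opposite-homozygote
    swap from AA to GG scores 2 ADO plus 1 ADI); ADI counts one event per
    locus whose call carries any non-reference allele, classified as
    hom_swap (hom reference replaced by the opposite hom), hom_to_het (hom
    reference replaced by a het) or het_ref (heterozygous reference gaining
    an allele — impossible for strictly biallelic loci, kept for generality).
    """
    ado = adi = hom_swap = hom_to_het = het_ref = 0
    maf = het = n_typed = 0
    for locus_id, call in sorted(test.calls.items()):
        if not call.is_autosomal_call:
            continue
        ref_call = reference.calls.get(locus_id)
        if ref_call is None or not ref_call.is_autosomal_call:
            continue
        n_typed += 1
        ref_gt = ref_call.genotype
        test_set = call.allele_set
        ado += sum(1 for a in ref_gt if a not in test_set)
        novel = test_set - ref_call.allele_set
        if novel:
            adi += 1
            if ref_call.is_het:
                het_ref += 1
            elif call.is_het:
                hom_to_het += 1
            else:
                hom_swap += 1
        if MAF_FLAG in call.flags:
            maf += 1
        if call.is_het:
            het += 1
    if n_typed == 0:
        return ConcordanceSummary(0, 0, 0, 0, 0, 0, 0, 0, None, None, None, None)
    return ConcordanceSummary(
        n_typed=n_typed,
        ado_count=ado,
        adi_count=adi,
        adi_hom_swap_count=hom_swap,
        adi_hom_to_het_count=hom_to_het,
        adi_het_ref_count=het_ref,
        maf_flag_count=maf,
        het_count=het,
        ado_freq=ado / (2 * n_typed),
        adi_freq=adi / n_typed,
        maf_flag_freq=maf / n_typed,
        het_observed=het / n_typed,
    )


def heterozygosity(profile: Profile) -> float:
    """Fraction of called autosomal loci that are heterozygous."""
    calls = profile.called_autosomal()
    if not calls:
        raise ValueError(f"{profile.sample_id}: no called autosomal loci")
    return sum(1 for c in calls.values() if c.is_het) / len(calls)


def expected_heterozygosity(freqs: FrequencyTable, panel: Sequence[LocusDef]) -> float:
    """Mean Hardy-Weinberg heterozygosity 2pq over the autosomal panel."""
    loci = autosomal_loci(panel)
    if not loci:
        raise ValueError("no autosomal loci in panel")
    total = 0.0
    for locus in loci:
        fr = freqs.locus(locus.locus_id)
        p = fr[locus.alleles[0]]
        total += 2.0 * p * (1.0 - p)
    return total / len(loci)


def min_marker_filter(profiles: Sequence[Profile], k: int = 19) -> list[Profile]:
    """Keep profiles with at least k typed autosomal markers.

    The default of 19 reflects the smallest marker count at which a known
    2 pg control still produced an interpretable comparison.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return [p for p in profiles if p.typed_autosomal() >= k]
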