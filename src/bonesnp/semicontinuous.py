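"""Semi-continuous single-source likelihood ratios with drop-out, drop-in
and Balding-Nichols θ correction.

The model is the LRMix-family presence/absence model: each allele copy of the
contributor drops out independently with probability d (a homozygote is lost
with d²); an allele the contributor does not carry appears as drop-in with
probability c·p_a; the evidence at a locus is the set of observed alleles.
The prosecution hypothesis (PH) fixes the reference genotype as the single
contributor; the defence hypothesis (DH) marginalises one unknown contributor
whose genotype probabilities are θ-corrected and conditioned on the reference
profile's alleles (the standard subpopulation match-probability treatment).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    FrequencyTable,
    LRParams,
    LRResult,
    Profile,
    combine_log10,
)
from .diagnostics import verbal_scale_log10

Genotype = tuple[str, str]

UNKNOWN = None  # sentinel: marginalise the contributor genotype


def _sampling_prob(
    allele: str,
    prior_counts: Mapping[str, int],
    n_prior: int,
    theta: float,
    p: Mapping[str, float],
) -> float:
    """Balding-Nichols sequential sampling probability of the next allele."""
    m = prior_counts.get(allele, 0)
    return (m * theta + (1.0 - theta) * p[allele]) / (1.0 + (n_prior - 1) * theta)


def genotype_prob(
    genotype: Genotype,
    locus_freqs: Mapping[str, float],
    theta: float = 0.0,
    conditioning: Iterable[str] = (),
) -> float:
    """θ-corrected genotype probability, conditioned on already-seen alleles.

    With no conditioning and θ=0 this reduces to Hardy-Weinberg (p², 2pq, q²).
    The heterozygote carries the ×2 ordering factor.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must be in [0, 1)")
    counts: dict[str, int] = {}
    n = 0
    for a in conditioning:
        counts[a] = counts.get(a, 0) + 1
        n += 1
    a1, a2 = genotype
    p1 = _sampling_prob(a1, counts, n, theta, locus_freqs)
    counts[a1] = counts.get(a1, 0) + 1
    p2 = _sampling_prob(a2, counts, n + 1, theta, locus_freqs)
    prob = p1 * p2
    if a1 != a2:
        prob *= 2.0
    return prob


def _known_contributor_likelihood(
    observed: frozenset[str],
    contributor: Genotype,
    d: float,
    c: float,
    locus_freqs: Mapping[str, float],
) -> float:
    """P(observed allele set | known single contributor, d, c).

    Product over the locus's two alleles: a carried allele (n copies) is seen
    with 1−dⁿ and missed with dⁿ; an uncarried allele drops in with c·p and
    stays absent with 1−c·p.
    """
    like = 1.0
    for allele, p in locus_freqs.items():
        n = contributor.count(allele)
        seen = allele in observed
        if n > 0:
            like *= (1.0 - d**n) if seen else d**n
        else:
            like *= (c * p) if seen else (1.0 - c * p)
    return like


def locus_likelihood(
    observed: Iterable[str],
    contributor: Optional[Genotype],
    d: float,
    c: float,
    locus_freqs: Mapping[str, float],
    theta: float = 0.0,
    conditioning: Iterable[str] = (),
) -> float:
    """Likelihood of one locus's evidence under a single-source hypothesis.

    contributor=None marginalises the three possible genotypes with
    θ-corrected probabilities conditioned on `conditioning`.
    """
    if not (0.0 <= d < 1.0 and 0.0 <= c < 1.0):
        raise ValueError("d and c must be in [0, 1)")
    obs = frozenset(observed)
    alleles = tuple(locus_freqs)
    if len(alleles) != 2:
        raise ValueError("locus must be biallelic")
    if not obs <= set(alleles):
        raise ValueError(f"evidence alleles {obs} outside locus alleles {alleles}")
    if contributor is not None:
        return _known_contributor_likelihood(obs, contributor, d, c, locus_freqs)
    a, b = alleles
    total = 0.0
    for g in ((a, a), (a, b), (b, b)):
        total += genotype_prob(g, locus_freqs, theta, conditioning) * (
            _known_contributor_likelihood(obs, g, d, c, locus_freqs)
        )
    return total


def evidence_set(call) -> frozenset[str]:
    """Observed allele set of a called genotype (het → both, hom → one)."""
    return call.allele_set


def _shared_loci(
    evidence: Profile, reference: Profile, freqs: FrequencyTable
) -> list[str]:
    loci = []
    for locus_id, call in sorted(evidence.calls.items()):
        if not call.is_autosomal_call:
            continue
        ref = reference.calls.get(locus_id)
        if ref is None or not ref.is_autosomal_call:
            continue
        if locus_id not in freqs.freqs:
            continue
        loci.append(locus_id)
    return loci


def profile_lr(
    evidence: Profile,
    reference: Profile,
    params: LRParams,
    freqs: FrequencyTable,
) -> LRResult:
    """Single-source LR of an evidence profile against a reference profile.

    PH: the reference individual is the contributor (no unknowns); DH: one
    unknown, θ-conditioned on the reference genotype. Uncalled evidence loci
    carry no information and are excluded; the product is accumulated in log
    space.
    """
    loci = _shared_loci(evidence, reference, freqs)
    if not loci:
        raise ValueError("no usable autosomal loci shared by evidence and reference")
    per_locus: dict[str, tuple[float, float]] = {}
    for locus_id in loci:
        fr = freqs.locus_floored(locus_id)
        obs = evidence.calls[locus_id].allele_set
        ref_gt = reference.calls[locus_id].genotype
        num = locus_likelihood(obs, ref_gt, params.ado, params.adi, fr)
        den = locus_likelihood(
            obs, UNKNOWN, params.ado, params.adi, fr, params.theta, conditioning=ref_gt
        )
        per_locus[locus_id] = (num, den)
    log10_lr = combine_log10(per_locus)
    verbal, direction = verbal_scale_log10(log10_lr)
    return LRResult(
        log10_lr=log10_lr,
        per_locus=per_locus,
        params=params,
        n_loci_used=len(loci),
        model="semicontinuous",
        verbal=verbal,
        direction=direction,
    )


def estimate_dropout(
    evidence: Profile,
    reference: Profile,
    c: float,
    freqs: FrequencyTable,
    theta: float = 0.01,
    d_min: float = 0.1,
) -> float:
    """Grid-MLE of the drop-out probability under PH, floored at d_min.

    Maximises the prosecution likelihood over d ∈ {0.01, …, 0.99} (step
    0.01; ties to the smallest d). Reference loci at which the evidence is
    uncalled enter as empty observed sets — a fully dropped-out locus is two
    drop-out events and is informative about d; ignoring such loci would
    systematically underestimate drop-out in heavily degraded samples.
    """
    loci = []
    for locus_id, ref in sorted(reference.calls.items()):
        if not ref.is_autosomal_call or locus_id not in freqs.freqs:
            continue
        ev_call = evidence.calls.get(locus_id)
        obs = ev_call.allele_set if ev_call is not None and ev_call.is_called else frozenset()
        loci.append((locus_id, obs, ref.genotype))
    if not loci:
        raise ValueError("no usable loci for drop-out estimation")
    best_d, best_ll = None, -math.inf
    for i in range(1, 100):
        d = i / 100.0
        ll = 0.0
        for locus_id, obs, ref_gt in loci:
            fr = freqs.locus_floored(locus_id)
            like = locus_likelihood(obs, ref_gt, d, c, fr)
            if like == 0.0:
                ll = -math.inf
                break
            ll += math.log(like)
        if ll > best_ll:
            best_d, best_ll = d, ll
    return max(best_d, d_min)


def lr_three_settings(
    evidence: Profile,
    reference: Profile,
    freqs: FrequencyTable,
    actual_ado: Optional[float] = None,
    actual_adi: Optional[float] = None,
    theta: float = 0.01,
) -> dict[str, LRResult]:
    """The three conventional parameterisations: LRd, LRe, LRa.

    LRd uses the default ADO 0.1 / ADI 0.05; LRe replaces ADO with the
    grid-MLE estimate (floor 0.1, ADI kept at 0.05); LRa uses the
    sample-specific 'actual' frequencies, which are only knowable when the
    donor genotype is known (proof-of-concept accounting, not casework).
    """
    out: dict[str, LRResult] = {}
    out["LRd"] = profile_lr(evidence, reference, LRParams(0.1, 0.05, theta, "default"), freqs)
    d_e = estimate_dropout(evidence, reference, c=0.05, freqs=freqs, theta=theta)
    out["LRe"] = profile_lr(
        evidence, reference, LRParams(d_e, 0.05, theta, "estimated"), freqs
    )
    if actual_ado is not None and actual_adi is not None:
        out["LRa"] = profile_lr(
            evidence, reference, LRParams(actual_ado, actual_adi, theta, "actual"), freqs
        )
    elif actual_ado is not None or actual_adi is not None:
        raise ValueError("LRa needs both actual_ado and actual_adi")
    return out
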