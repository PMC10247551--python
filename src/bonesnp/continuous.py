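"""Continuous (read-count) single-source likelihood ratios.

EuroForMix-style quantitative model: the reads supporting an allele carried
with n copies by the contributor follow a gamma distribution with shape
(n/2)/ω² and scale μω² (so a full contributor yields μ expected reads per
locus with coefficient of variation ω); reads below the analytical threshold
AT are treated as drop-out and contribute the gamma mass below AT; alleles
the contributor does not carry appear above AT only as drop-in, with
probability c·p and exponentially distributed excess reads. μ and ω are fit
by maximum likelihood separately under each hypothesis; drop-in parameters
and AT stay fixed (AT matches the 20-read genotyping threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .core import AlleleCounts, FrequencyTable, LRResult, Profile
from .diagnostics import verbal_scale_log10
from .semicontinuous import genotype_prob

LOG10E = math.log10(math.e)


@dataclass(frozen=True)
class ContinuousParams:
    """Gamma read-count model parameters.

    mu: expected total locus reads from a full single contributor.
    omega: coefficient of variation of locus reads.
    c: per-allele drop-in probability.
    lambda_dropin: rate of the exponential drop-in read-count tail above AT.
    at: analytical threshold in reads; counts below it are drop-out.
    """

    mu: float
    omega: float
    c: float = 0.05
    lambda_dropin: float = 0.05
    at: int = 20

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.omega <= 0 or self.lambda_dropin <= 0:
            raise ValueError("mu, omega, lambda_dropin must be > 0")
        if not 0.0 <= self.c < 1.0:
            raise ValueError("c must be in [0, 1)")
        if self.at < 0:
            raise ValueError("at must be >= 0")


def _allele_logterm(
    y: np.ndarray,
    n: np.ndarray,
    mu: float,
    omega: float,
    c_p: np.ndarray,
    lam: float,
    at: float,
) -> np.ndarray:
    """Vectorised log factor for one allele across loci."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    c_p = np.asarray(c_p, dtype=float)
    out = np.empty_like(y)
    scale = mu * omega**2
    shape = n / (2.0 * omega**2)
    carried = n > 0
    above = y >= at
    m = carried & above
    if m.any():
        out[m] = stats.gamma.logpdf(y[m], shape[m], scale=scale)
    m = carried & ~above
    if m.any():
        out[m] = stats.gamma.logcdf(at, shape[m], scale=scale)
    m = ~carried & above
    if m.any():
        with np.errstate(divide="ignore"):
            out[m] = np.log(c_p[m] * lam) - lam * (y[m] - at)
    m = ~carried & ~above
    if m.any():
        out[m] = np.log1p(-c_p[m])
    return out


@dataclass
class _LocusData:
    """Evidence arrays for the loci entering the continuous likelihood."""

    locus_ids: list[str]
    y1: np.ndarray  # reads for the locus's first allele
    y2: np.ndarray
    cp1: np.ndarray  # c * p per allele
    cp2: np.ndarray
    # known-contributor copy numbers (PH), or None under DH
    n1: Optional[np.ndarray]
    n2: Optional[np.ndarray]
    # DH: log prior of the 3 genotypes (rows) per locus (cols)
    log_priors: Optional[np.ndarray]


_GENOTYPE_COPIES = np.array([[2, 1, 0], [0, 1, 2]])  # rows: allele1/2; cols: AA, AB, BB


def prepare_locus_data(
    counts: AlleleCounts,
    freqs: FrequencyTable,
    params: ContinuousParams,
    contributor: Optional[Profile],
    conditioning: Optional[Profile],
    theta: float,
) -> _LocusData:
    """Assemble per-locus arrays; loci with all alleles below AT are dropped.

    Under DH (contributor=None) the unknown's genotype log-priors are
    θ-corrected and conditioned on the `conditioning` profile's genotype.
    """
    ids, y1, y2, cp1, cp2, n1, n2, priors = [], [], [], [], [], [], [], []
    for locus_id in sorted(counts.counts):
        if locus_id not in freqs.freqs:
            continue
        fr = freqs.locus_floored(locus_id)
        alleles = sorted(fr)
        if len(alleles) != 2:
            raise ValueError(f"{locus_id}: locus must be biallelic")
        reads = []
        for a in alleles:
            f, r = counts.counts[locus_id].get(a, (0, 0))
            if f < 0 or r < 0 or (f, r) != (int(f), int(r)):
                raise ValueError(f"{locus_id}/{a}: reads must be non-negative integers")
            reads.append(f + r)
        if max(reads) < params.at:
            continue  # locus drop-out: no called allele
        ref_gt: Optional[tuple[str, ...]] = None
        if contributor is not None or conditioning is not None:
            src = contributor if contributor is not None else conditioning
            call = src.calls.get(locus_id)
            if call is None or not call.is_autosomal_call:
                continue
            ref_gt = call.genotype
        ids.append(locus_id)
        y1.append(reads[0])
        y2.append(reads[1])
        cp1.append(params.c * fr[alleles[0]])
        cp2.append(params.c * fr[alleles[1]])
        if contributor is not None:
            n1.append(ref_gt.count(alleles[0]))
            n2.append(ref_gt.count(alleles[1]))
        else:
            a, b = alleles
            cond = ref_gt if ref_gt is not None else ()
            priors.append(
                [
                    math.log(genotype_prob((a, a), fr, theta, cond)),
                    math.log(genotype_prob((a, b), fr, theta, cond)),
                    math.log(genotype_prob((b, b), fr, theta, cond)),
                ]
            )
    return _LocusData(
        locus_ids=ids,
        y1=np.array(y1, dtype=float),
        y2=np.array(y2, dtype=float),
        cp1=np.array(cp1),
        cp2=np.array(cp2),
        n1=np.array(n1) if contributor is not None else None,
        n2=np.array(n2) if contributor is not None else None,
        log_priors=np.array(priors).T if contributor is None else None,
    )


def _per_locus_loglik(data: _LocusData, mu: float, omega: float, params: ContinuousParams) -> np.ndarray:
    lam, at = params.lambda_dropin, params.at
    if data.n1 is not None:
        t1 = _allele_logterm(data.y1, data.n1, mu, omega, data.cp1, lam, at)
        t2 = _allele_logterm(data.y2, data.n2, mu, omega, data.cp2, lam, at)
        return t1 + t2
    terms = np.empty((3, len(data.locus_ids)))
    for g in range(3):
        n1 = np.full(len(data.locus_ids), _GENOTYPE_COPIES[0, g])
        n2 = np.full(len(data.locus_ids), _GENOTYPE_COPIES[1, g])
        terms[g] = (
            _allele_logterm(data.y1, n1, mu, omega, data.cp1, lam, at)
            + _allele_logterm(data.y2, n2, mu, omega, data.cp2, lam, at)
        )
    return logsumexp(terms + data.log_priors, axis=0)


def continuous_locus_likelihood(
    reads: Mapping[str, int],
    genotype: Optional[tuple[str, str]],
    params: ContinuousParams,
    locus_freqs: Mapping[str, float],
    theta: float = 0.0,
    conditioning: Sequence[str] = (),
) -> float:
    """Likelihood of one locus's per-allele read counts.

    genotype=None marginalises the unknown contributor's three genotypes with
    θ-corrected probabilities conditioned on `conditioning`.
    """
    alleles = sorted(locus_freqs)
    if len(alleles) != 2:
        raise ValueError("locus must be biallelic")
    y = []
    for a in alleles:
        v = reads.get(a, 0)
        if v < 0 or v != int(v):
            raise ValueError("reads must be non-negative integers")
        y.append(float(v))
    cp = np.array([params.c * locus_freqs[a] for a in alleles])
    if genotype is not None:
        n = np.array([genotype.count(a) for a in alleles])
        t = _allele_logterm(np.array(y), n, params.mu, params.omega, cp,
                            params.lambda_dropin, params.at)
        return float(np.exp(t.sum()))
    a, b = alleles
    total = 0.0
    for g in ((a, a), (a, b), (b, b)):
        total += genotype_prob(g, locus_freqs, theta, conditioning) * (
            continuous_locus_likelihood(reads, g, params, locus_freqs)
        )
    return total


def fit_mle(
    counts: AlleleCounts,
    contributor: Optional[Profile],
    freqs: FrequencyTable,
    theta: float = 0.01,
    params0: Optional[ContinuousParams] = None,
    conditioning: Optional[Profile] = None,
) -> tuple[ContinuousParams, float, _LocusData]:
    """Maximum-likelihood (μ, ω) for one hypothesis; c, λ, AT stay fixed.

    Bounded quasi-Newton in (log μ, log ω) from a deterministic multi-start
    grid: five μ starts on a decade ladder around the mean called-locus read
    total, crossed with ω ∈ {0.2, 0.5, 1.0}. Returns the fitted parameters,
    the maximised log-likelihood, and the locus data used.
    """
    base = params0 or ContinuousParams(mu=500.0, omega=0.5)
    data = prepare_locus_data(counts, freqs, base, contributor, conditioning, theta)
    if len(data.locus_ids) < 3:
        raise ValueError("need at least 3 called loci for the continuous model")

    def negll(x: np.ndarray) -> float:
        mu, omega = math.exp(x[0]), math.exp(x[1])
        ll = _per_locus_loglik(data, mu, omega, base).sum()
        return -ll if np.isfinite(ll) else 1e12

    mu_anchor = float(np.mean(data.y1 + data.y2))
    mu_starts = [mu_anchor * f for f in (0.1, 0.316, 1.0, 3.16, 10.0)]
    omega_starts = [0.2, 0.5, 1.0]
    bounds = [(math.log(1e-3), math.log(1e9)), (math.log(1e-3), math.log(50.0))]
    best = None
    for mu0 in mu_starts:
        for om0 in omega_starts:
            res = optimize.minimize(
                negll,
                x0=np.array([math.log(mu0), math.log(om0)]),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"continuous MLE failed; best objective: {best}")
    mu, omega = math.exp(best.x[0]), math.exp(best.x[1])
    fitted = replace(base, mu=mu, omega=omega)
    return fitted, -float(best.fun), data


def continuous_lr(
    evidence: AlleleCounts,
    reference: Profile,
    freqs: FrequencyTable,
    theta: float = 0.01,
    params0: Optional[ContinuousParams] = None,
    fixed_params: Optional[ContinuousParams] = None,
) -> LRResult:
    """Continuous-model LR: max-likelihood fit under each hypothesis.

    LR = max_{μ,ω} L(reads | reference contributor) /
         max_{μ,ω} L(reads | one unknown, θ-conditioned on the reference).
    With fixed_params given, both hypotheses are evaluated at those
    parameters instead of being refit (useful for model checks).
    """
    if fixed_params is not None:
        base = fixed_params
        data_ph = prepare_locus_data(evidence, freqs, base, reference, None, theta)
        if len(data_ph.locus_ids) < 1:
            raise ValueError("no called loci shared with the reference")
        data_dh = prepare_locus_data(evidence, freqs, base, None, reference, theta)
        ph_params = dh_params = base
        ll_ph = float(_per_locus_loglik(data_ph, base.mu, base.omega, base).sum())
        ll_dh = float(_per_locus_loglik(data_dh, base.mu, base.omega, base).sum())
    else:
        ph_params, ll_ph, data_ph = fit_mle(
            evidence, reference, freqs, theta=theta, params0=params0
        )
        dh_params, ll_dh, data_dh = fit_mle(
            evidence, None, freqs, theta=theta, params0=params0, conditioning=reference
        )
    num_terms = _per_locus_loglik(data_ph, ph_params.mu, ph_params.omega, ph_params)
    den_terms = _per_locus_loglik(data_dh, dh_params.mu, dh_params.omega, dh_params)
    den_by_locus = dict(zip(data_dh.locus_ids, den_terms))
    per_locus = {
        lid: (float(np.exp(num_terms[i])), float(np.exp(den_by_locus[lid])))
        for i, lid in enumerate(data_ph.locus_ids)
        if lid in den_by_locus
    }
    log10_lr = (ll_ph - ll_dh) * LOG10E
    verbal, direction = verbal_scale_log10(log10_lr)
    return LRResult(
        log10_lr=log10_lr,
        per_locus=per_locus,
        params=None,
        n_loci_used=len(data_ph.locus_ids),
        model="continuous",
        verbal=verbal,
        direction=direction,
    )
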