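"""Verbal LR scale, contamination diagnostics, and cohort reporting.

Covers the reporting layer of the pipeline: ENFSI-style verbal equivalents
of likelihood ratios, heterozygosity-excess and Hardy-Weinberg consistency
tests (the biallelic-panel analogues of the >2-alleles mixture signal),
two-group proportion comparisons, Y-haplotype drop-in accounting, and the
deterministic cohort report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import FrequencyTable, Profile

NO_SUPPORT = "no_support"
WEAK_MODERATE = "weak_moderate"
STRONG = "strong"
EXTREMELY_STRONG = "extremely_strong"

# log10 cut-points of the verbal bands, read as continuous, gap-free
# boundaries of the printed ranges 0.5-2.0 / 2.1-999 / 1000-1e6 / >1e6.
_LOG10_2 = math.log10(2.0)
_BAND_EDGES = (_LOG10_2, 3.0, 6.0)


def verbal_scale_log10(log10_lr: float) -> tuple[str, str]:
    """Verbal band and supported hypothesis for a log10 LR."""
    if math.isnan(log10_lr):
        raise ValueError("LR is not a number")
    direction = "PH" if log10_lr >= 0 else "DH"
    x = abs(log10_lr)
    if x <= _BAND_EDGES[0]:
        return NO_SUPPORT, direction
    if x < _BAND_EDGES[1]:
        return WEAK_MODERATE, direction
    if x <= _BAND_EDGES[2]:
        return STRONG, direction
    return EXTREMELY_STRONG, direction


def verbal_scale(lr: float) -> tuple[str, str]:
    """Verbal band for an LR on the natural scale.

    LR in [0.5, 2.0] gives 'no support'; (2, 1000) weak/moderate; [1000,
    1e6] strong; above 1e6 extremely strong — towards PH for LR > 1 and,
    via reciprocity, towards DH for LR < 1.
    """
    if lr <= 0:
        raise ValueError("LR must be positive")
    return verbal_scale_log10(math.log10(lr))


def het_excess_test(observed_het_count: int, n_loci: int, expected_het: float) -> float:
    """One-sided exact binomial P(X >= observed) for heterozygosity excess.

    An excess of heterozygous calls relative to the population expectation is
    the biallelic-panel signature of a DNA mixture/contamination.
    """
    if not 0.0 < expected_het < 1.0:
        raise ValueError("expected_het must be in (0, 1)")
    if not 0 <= observed_het_count <= n_loci:
        raise ValueError("observed count outside [0, n_loci]")
    return float(stats.binom.sf(observed_het_count - 1, n_loci, expected_het))


def _poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact Poisson-binomial pmf by dynamic programming."""
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
        pmf[0] *= 1.0 - p
    return pmf


def hwe_profile_test(profile: Profile, freqs: FrequencyTable) -> float:
    """Two-sided HWE-consistency test of one profile's heterozygote count.

    Under HWE each called locus is an independent Bernoulli(2pq) for
    heterozygosity; the observed heterozygote count is referred to the exact
    Poisson-binomial distribution (minimum-likelihood two-sided tail). A
    single profile has one genotype per locus, so the usual genotype-count
    chi-square is not applicable.
    """
    calls = profile.called_autosomal()
    if len(calls) < 10:
        raise ValueError("need at least 10 called autosomal loci")
    probs = []
    for locus_id in sorted(calls):
        fr = freqs.locus(locus_id)
        p = next(iter(fr.values()))
        probs.append(2.0 * p * (1.0 - p))
    k = sum(1 for c in calls.values() if c.is_het)
    pmf = _poisson_binomial_pmf(probs)
    return float(pmf[pmf <= pmf[k] * (1.0 + 1e-12)].sum())


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided comparison of two proportions.

    Pooled two-proportion z-test; falls back to Fisher's exact test when any
    expected cell count under the pooled proportion is below 5.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts outside [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    expected = [n * p for n in (n1, n2) for p in (pooled, 1.0 - pooled)]
    if min(expected) < 5:
        _, p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
        return float(p)
    from statsmodels.stats.proportion import proportions_ztest

    _, p = proportions_ztest([x1, x2], [n1, n2])
    return float(p)


@dataclass
class YComparison:
    matched: int
    dropins: int
    typed: int
    excluded_loci: tuple[str, ...] = ()


def y_haplotype_compare(test: Profile, reference: Profile) -> YComparison:
    """Compare a test Y haplotype against the reference haplotype.

    Over the test's called Y loci: matched counts identical calls; dropins
    counts differing calls plus annotated second alleles (each a spurious-
    haplotype contamination signal). Loci uncalled in the reference are
    excluded and reported.
    """
    test_y = test.called_y()
    ref_y = reference.called_y()
    if not test_y or not ref_y:
        raise ValueError("both profiles must contain called Y loci")
    matched = dropins = typed = 0
    excluded = []
    for locus_id, call in sorted(test_y.items()):
        ref = ref_y.get(locus_id)
        if ref is None:
            excluded.append(locus_id)
            continue
        typed += 1
        if call.genotype == ref.genotype:
            matched += 1
            if call.y_dropin_allele is not None and call.y_dropin_allele not in ref.genotype:
                dropins += 1
        else:
            dropins += 1
    return YComparison(matched, dropins, typed, tuple(excluded))


def pairwise_comparison_counts(n_profiles: int) -> tuple[int, int, int]:
    """(total, intra, inter) ordered comparison counts among n profiles."""
    if n_profiles < 1:
        raise ValueError("need at least one profile")
    return n_profiles * n_profiles, n_profiles, n_profiles * (n_profiles - 1)


def percent(x: int, n: int, decimals: int = 1) -> float:
    """A percentage recomputed from raw counts (never stored)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * x / n, decimals)


_BAND_ORDER = [EXTREMELY_STRONG, STRONG, WEAK_MODERATE, NO_SUPPORT]


def cohort_report(
    sample_rows: Sequence[Mapping],
    min_markers: int = 19,
) -> dict:
    """Aggregate per-sample results into a deterministic cohort report.

    Each row must carry sample_id, n_typed, and per-setting log10 LRs under
    keys like 'log10_LRd'. Percentages of LR > 1 per setting and the
    settings × verbal-band table are recomputed from the rows. Returns a
    JSON-stable dict; render_report() turns it into a text table.
    """
    if not sample_rows:
        raise ValueError("empty cohort")
    settings = sorted(
        {k[len("log10_"):] for row in sample_rows for k in row if k.startswith("log10_")}
    )
    rows = sorted(sample_rows, key=lambda r: r["sample_id"])
    retained = [r for r in rows if r["n_typed"] >= min_markers]
    report: dict = {
        "n_samples": len(rows),
        "n_retained": len(retained),
        "min_markers": min_markers,
        "samples": [dict(r) for r in rows],
        "lr_gt1_pct": {},
        "band_table": {},
    }
    for setting in settings:
        values = [r[f"log10_{setting}"] for r in retained if f"log10_{setting}" in r]
        if not values:
            continue
        gt1 = sum(1 for v in values if v > 0)
        report["lr_gt1_pct"][setting] = percent(gt1, len(values))
        bands: dict[str, int] = {}
        for v in values:
            label, direction = verbal_scale_log10(v)
            key = label if label == NO_SUPPORT else f"{label}_{direction}"
            bands[key] = bands.get(key, 0) + 1
        report["band_table"][setting] = dict(sorted(bands.items()))
    return report


def render_report(report: Mapping) -> str:
    """Plain-text rendering of a cohort report (settings × verbal bands)."""
    lines = [
        f"cohort: {report['n_samples']} samples, "
        f"{report['n_retained']} with >= {report['min_markers']} typed markers",
        "",
        "percentage of samples with LR > 1:",
    ]
    for setting, pct in report["lr_gt1_pct"].items():
        lines.append(f"  {setting:12s} {pct:5.1f}%")
    lines.append("")
    lines.append("verbal band counts per setting:")
    band_keys = sorted({k for t in report["band_table"].values() for k in t})
    for setting, table in report["band_table"].items():
        lines.append(f"  {setting}:")
        for key in band_keys:
            if key in table:
                lines.append(f"    {key:24s} {table[key]:3d}")
    return "\n".join(lines) + "\n"
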