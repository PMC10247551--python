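"""Semi-continuous LR model: θ-corrected genotype probabilities, the
drop-out/drop-in locus likelihood against an exhaustive enumeration oracle,
profile-level LRs, and drop-out estimation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bonesnp.core import CALLED, FrequencyTable, GenotypeCall, LRParams, Profile
from bonesnp.semicontinuous import (
    UNKNOWN,
    estimate_dropout,
    genotype_prob,
    locus_likelihood,
    lr_three_settings,
    profile_lr,
)

FREQS_AB = {"A": 0.3, "B": 0.7}


def enumeration_oracle(observed, contributor, d, c, locus_freqs):
    """Brute-force sum over every explicit drop-out/drop-in event combination.

    Each contributor allele copy independently survives (1-d) or drops (d);
    each non-carried allele independently drops in (c*p) or not. The evidence
    is the set of surviving plus dropped-in alleles.
    """
    observed = frozenset(observed)
    alleles = list(locus_freqs)
    copies = list(contributor)
    uncarried = [a for a in alleles if a not in contributor]
    total = 0.0
    for survival in itertools.product([0, 1], repeat=len(copies)):
        p_surv = 1.0
        seen = set()
        for allele, s in zip(copies, survival):
            p_surv *= (1.0 - d) if s else d
            if s:
                seen.add(allele)
        for dropins in itertools.product([0, 1], repeat=len(uncarried)):
            p_di = 1.0
            seen_di = set(seen)
            for allele, di in zip(uncarried, dropins):
                q = c * locus_freqs[allele]
                p_di *= q if di else (1.0 - q)
                if di:
                    seen_di.add(allele)
            if frozenset(seen_di) == observed:
                total += p_surv * p_di
    return total


def _genotype_profile(genotypes, sample_id="p"):
    calls = {
        locus: GenotypeCall(locus, CALLED, genotype=gt) for locus, gt in genotypes.items()
    }
    return Profile(sample_id, calls)


class TestGenotypeProb:
    def test_hwe_limit(self):
        assert genotype_prob(("A", "A"), FREQS_AB, theta=0.0) == pytest.approx(0.09)
        assert genotype_prob(("A", "B"), FREQS_AB, theta=0.0) == pytest.approx(0.42)

    def test_theta_conditioning_formula(self):
        """First sampled allele A given two prior A copies follows the
        Balding-Nichols sequential formula."""
        theta = 0.01
        p1 = (2 * theta + (1 - theta) * 0.3) / (1 + (2 - 1) * theta)
        assert p1 == pytest.approx(0.3138613861, abs=1e-9)
        p2 = (3 * theta + (1 - theta) * 0.3) / (1 + (3 - 1) * theta)
        expected_aa = p1 * p2
        got = genotype_prob(("A", "A"), FREQS_AB, theta=theta, conditioning=("A", "A"))
        assert got == pytest.approx(expected_aa, rel=1e-12)

    @given(
        theta=st.floats(0.0, 0.5),
        p=st.floats(0.05, 0.95),
        cond=st.sampled_from([(), ("A",), ("A", "B"), ("B", "B")]),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, theta, p, cond):
        freqs = {"A": p, "B": 1.0 - p}
        total = sum(
            genotype_prob(g, freqs, theta, cond)
            for g in (("A", "A"), ("A", "B"), ("B", "B"))
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_theta_domain(self):
        with pytest.raises(ValueError):
            genotype_prob(("A", "A"), FREQS_AB, theta=1.0)


class TestLocusLikelihood:
    def test_certain_match(self):
        assert locus_likelihood({"A", "B"}, ("A", "B"), 0.0, 0.0, FREQS_AB) == 1.0

    def test_double_dropout(self):
        assert locus_likelihood(set(), ("A", "A"), 0.1, 0.0, FREQS_AB) == pytest.approx(0.01)

    def test_dropin_on_homozygote(self):
        got = locus_likelihood({"A", "B"}, ("A", "A"), 0.1, 0.05, {"A": 0.5, "B": 0.5})
        assert got == pytest.approx((1 - 0.01) * 0.05 * 0.5, rel=1e-12)

    def test_matches_enumeration_oracle_everywhere(self):
        """All 3 genotypes x 4 evidence sets x a 5^3 (d, c, p) grid agree
        with explicit event enumeration to 1e-12."""
        grid = [0.0, 0.1, 0.3, 0.6, 0.9]
        pgrid = [0.05, 0.25, 0.5, 0.75, 0.95]
        evidences = [frozenset(), {"A"}, {"B"}, {"A", "B"}]
        for p in pgrid:
            freqs = {"A": p, "B": 1.0 - p}
            for contributor in [("A", "A"), ("A", "B"), ("B", "B")]:
                for d in grid:
                    for c in grid:
                        for ev in evidences:
                            got = locus_likelihood(ev, contributor, d, c, freqs)
                            want = enumeration_oracle(ev, contributor, d, c, freqs)
                            assert abs(got - want) < 1e-12

    @given(
        d=st.floats(0.0, 0.99), c=st.floats(0.0, 0.99), p=st.floats(0.05, 0.95),
        contributor=st.sampled_from([("A", "A"), ("A", "B"), ("B", "B"), UNKNOWN]),
        theta=st.floats(0.0, 0.3),
    )
    @settings(max_examples=150, deadline=None)
    def test_evidence_space_normalization(self, d, c, p, contributor, theta):
        """The model is a proper distribution over the 4 evidence sets."""
        freqs = {"A": p, "B": 1.0 - p}
        total = sum(
            locus_likelihood(ev, contributor, d, c, freqs, theta)
            for ev in [frozenset(), {"A"}, {"B"}, {"A", "B"}]
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_foreign_evidence_allele_rejected(self):
        with pytest.raises(ValueError):
            locus_likelihood({"T"}, ("A", "B"), 0.1, 0.05, FREQS_AB)


class TestProfileLR:
    def _freq_table(self, ps):
        return FrequencyTable(
            "pop", {f"l{i}": {"A": p, "B": 1 - p} for i, p in enumerate(ps)}
        )

    def test_inverse_match_probability_limit(self):
        """Evidence = reference, d=c=0, θ=0: LR is the inverse HWE random
        match probability, computed independently."""
        ps = [0.3, 0.5, 0.62, 0.18]
        gts = [("A", "A"), ("A", "B"), ("B", "B"), ("A", "B")]
        freqs = self._freq_table(ps)
        ref = _genotype_profile({f"l{i}": g for i, g in enumerate(gts)})
        params = LRParams(0.0, 0.0, 0.0, "custom")
        result = profile_lr(ref, ref, params, freqs)
        rmp = 1.0
        for p, g in zip(ps, gts):
            rmp *= p * p if g == ("A", "A") else ((1 - p) ** 2 if g == ("B", "B") else 2 * p * (1 - p))
        assert result.log10_lr == pytest.approx(-math.log10(rmp), rel=1e-9)

    def test_single_locus_hand_value(self):
        """Evidence {A}, reference AA, d=0.1, c=0.05, p_A=0.6, θ=0: numerator
        and denominator frozen from the enumeration oracle."""
        freqs = FrequencyTable("pop", {"l0": {"A": 0.6, "B": 0.4}})
        ev = _genotype_profile({"l0": ("A", "A")}, "ev")
        ref = _genotype_profile({"l0": ("A", "A")}, "ref")
        result = profile_lr(ev, ref, LRParams(0.1, 0.05, 0.0, "custom"), freqs)
        num, den = result.per_locus["l0"]
        assert num == pytest.approx(0.9702, rel=1e-12)
        oracle_den = sum(
            prob * enumeration_oracle({"A"}, g, 0.1, 0.05, {"A": 0.6, "B": 0.4})
            for g, prob in [(("A", "A"), 0.36), (("A", "B"), 0.48), (("B", "B"), 0.16)]
        )
        assert den == pytest.approx(oracle_den, rel=1e-12)
        assert result.log10_lr == pytest.approx(math.log10(num / oracle_den), rel=1e-9)

    def test_combined_equals_product_of_locus_ratios(self, panel, freqs, donor):
        ref = Profile("ref", donor.calls, True)
        result = profile_lr(ref, ref, LRParams.default(), freqs)
        manual = sum(
            math.log10(n) - math.log10(d) for n, d in result.per_locus.values()
        )
        assert result.log10_lr == pytest.approx(manual, rel=1e-6)

    def test_theta_monotonicity_on_full_match(self):
        """On a full matching profile with d=c=0, LR never increases with θ
        (match probabilities grow under substructure)."""
        ps = [0.3, 0.45, 0.7, 0.25, 0.6]
        freqs = self._freq_table(ps)
        gts = {f"l{i}": ("A", "B") if i % 2 else ("A", "A") for i in range(5)}
        ref = _genotype_profile(gts)
        values = [
            profile_lr(ref, ref, LRParams(0.0, 0.0, theta, "custom"), freqs).log10_lr
            for theta in (0.0, 0.01, 0.03, 0.1, 0.3)
        ]
        assert values == sorted(values, reverse=True)

    def test_no_shared_loci_error(self):
        freqs = FrequencyTable("pop", {"l0": {"A": 0.5, "B": 0.5}})
        ev = _genotype_profile({"l0": ("A", "A")})
        ref = Profile("ref", {}, False)
        with pytest.raises(ValueError):
            profile_lr(ev, ref, LRParams.default(), freqs)


class TestEstimateDropout:
    def _setup(self, n_loci=90, seed=0, p=None):
        rng = np.random.default_rng(seed)
        ps = p if p is not None else rng.uniform(0.2, 0.8, n_loci)
        freqs = FrequencyTable(
            "pop", {f"l{i}": {"A": float(q), "B": float(1 - q)} for i, q in enumerate(ps)}
        )
        gts = {}
        for i, q in enumerate(ps):
            draws = rng.uniform(size=2) < q
            gts[f"l{i}"] = tuple(sorted("A" if x else "B" for x in draws))
        return freqs, _genotype_profile(gts, "ref"), rng

    def _thin(self, ref, d, c, freqs, rng):
        """Per-copy Bernoulli drop-out plus c*p drop-in evidence profile."""
        calls = {}
        for locus, call in ref.calls.items():
            kept = {a for a in call.genotype if rng.uniform() >= d}
            for allele, p_a in freqs.locus(locus).items():
                if allele not in call.genotype and rng.uniform() < c * p_a:
                    kept.add(allele)
            if kept:
                gt = tuple(sorted(kept)) if len(kept) == 2 else (min(kept), min(kept))
                calls[locus] = GenotypeCall(locus, CALLED, genotype=gt)
            else:
                calls[locus] = GenotypeCall(locus, "no_call", no_call_reason="low_coverage")
        return Profile("ev", calls)

    def test_full_match_floors_at_minimum(self):
        freqs, ref, _ = self._setup()
        assert estimate_dropout(ref, ref, c=0.0, freqs=freqs) == pytest.approx(0.1)

    def test_recovers_true_dropout(self):
        """Per-copy drop-out 0.6 over 90 loci is recovered within ±0.1 in at
        least 90 of 100 replicates."""
        hits = 0
        for seed in range(100):
            freqs, ref, rng = self._setup(seed=seed)
            ev = self._thin(ref, d=0.6, c=0.05, freqs=freqs, rng=rng)
            d_hat = estimate_dropout(ev, ref, c=0.05, freqs=freqs)
            hits += abs(d_hat - 0.6) <= 0.1
        assert hits >= 90

    def test_tie_break_deterministic(self):
        freqs, ref, rng = self._setup(seed=3)
        ev = self._thin(ref, d=0.5, c=0.05, freqs=freqs, rng=rng)
        assert estimate_dropout(ev, ref, 0.05, freqs) == estimate_dropout(ev, ref, 0.05, freqs)


class TestThreeSettings:
    def test_reproducible_and_settings_labelled(self, panel, freqs, donor):
        ref = Profile("ref", donor.calls, True)
        res1 = lr_three_settings(ref, ref, freqs, actual_ado=0.0, actual_adi=0.0)
        res2 = lr_three_settings(ref, ref, freqs, actual_ado=0.0, actual_adi=0.0)
        assert res1["LRd"].log10_lr == res2["LRd"].log10_lr
        assert res1["LRe"].params.setting == "estimated"

    def test_actual_zero_rates_beat_defaults_on_perfect_match(self, panel, freqs, donor):
        """With evidence identical to the reference, removing the drop-out/
        drop-in penalties can only raise the LR."""
        ref = Profile("ref", donor.calls, True)
        res = lr_three_settings(ref, ref, freqs, actual_ado=0.0, actual_adi=0.0)
        assert res["LRa"].log10_lr >= res["LRd"].log10_lr

    def test_lra_requires_both_actuals(self, panel, freqs, donor):
        ref = Profile("ref", donor.calls, True)
        with pytest.raises(ValueError):
            lr_three_settings(ref, ref, freqs, actual_ado=0.2, actual_adi=None)

    def test_contamination_depresses_lra_relative_to_clean_samples(self, panel, freqs):
        """Contaminated samples tend to stay at LRa < 1 (supporting DH)
        while clean samples of the same quality reach LRa > 1 — the
        actual-parameter accounting separates the two groups."""
        from bonesnp.calling import call_profile
        from bonesnp.profiles import concordance_stats
        from bonesnp.simulate import SimulationConfig, sample_genotype, simulate_read_counts

        def lra(seed, cf):
            rng = np.random.default_rng(seed)
            donor = sample_genotype(freqs, panel, int(rng.integers(2**31)))
            cont = sample_genotype(freqs, panel, int(rng.integers(2**31)), sample_id="c")
            cfg = SimulationConfig(template_pg=20.0, contaminant_fraction=cf)
            counts, _ = simulate_read_counts(donor, cont, cfg, panel, int(rng.integers(2**31)))
            ev = call_profile(counts, panel)
            if ev.typed_autosomal() < 19:
                return None
            ref = Profile("ref", donor.calls, True)
            s = concordance_stats(ev, ref)
            res = lr_three_settings(
                ev, ref, freqs,
                actual_ado=min(s.ado_freq, 0.99), actual_adi=min(s.adi_freq, 0.99),
            )
            return res["LRa"].log10_lr

        contaminated = [x for s in range(25) if (x := lra(40_000 + s, 0.4)) is not None]
        clean = [x for s in range(25) if (x := lra(41_000 + s, 0.0)) is not None]
        assert np.median(contaminated) < np.median(clean)
        assert np.median(clean) > 0
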