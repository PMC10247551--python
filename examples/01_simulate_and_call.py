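"""Simulate a picogram-scale degraded bone library and call its genotypes.

Builds a 90+34-marker identity panel, draws a donor genotype under HWE,
simulates strand-split read counts at 6.8 pg of template (the median input
of very challenging skeletal extracts), and applies the 20x/10x-per-strand
calling rules with MAF flags.
"""

from bonesnp import (
    SimulationConfig,
    call_profile,
    make_panel,
    sample_frequencies,
    sample_genotype,
    simulate_read_counts,
)
from bonesnp.core import MAF_FLAG

panel = make_panel(90, 34, seed=1)
freqs = sample_frequencies(panel, seed=2)
donor = sample_genotype(freqs, panel, seed=3, sample_id="bone_01")

cfg = SimulationConfig(template_pg=6.8)  # ~2 haploid genome copies of input
counts, truth = simulate_read_counts(donor, None, cfg, panel, seed=4)
profile = call_profile(counts, panel)

typed = profile.typed_autosomal()
flagged = sum(1 for c in profile.calls.values() if MAF_FLAG in c.flags)
hets = sum(1 for c in profile.calls.values() if c.is_het)
print(f"typed autosomal markers : {typed}/90")
print(f"heterozygous calls      : {hets}")
print(f"MAF-flagged calls       : {flagged}")
print(f"called Y markers        : {len(profile.called_y())}/34")
# At ~2 template copies per locus, roughly a third of loci drop out entirely
# and surviving heterozygotes are often unbalanced enough to be flagged.
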