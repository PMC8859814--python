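"""In-silico digestion and capture-probe eligibility.

Builds a small synthetic genome with planted HindIII sites, digests it
into a restriction fragment map, and checks which fragments could carry a
120-mer capture probe under the promoter-capture design rules.
"""

import chicbench as cb
from chicbench.simulate import GenomeConfig, SimulationConfig, simulate_genome

config = SimulationConfig(
    seed=0,
    genome=GenomeConfig(n_chroms=1, chrom_length=100_000, mean_fragment_length=4_000),
)
genome, planted = simulate_genome(config)
fmap = cb.digest_genome(genome, cb.HINDIII)

print(f"chr1: {len(fmap)} HindIII fragments from {len(planted['chr1'])} cut sites")
print("first three fragments:", [(f.start, f.end) for f in list(fmap)[:3]])

rules = cb.BaitDesignRules()  # 120-mer, 25-65% GC, <=2 Ns, within 330 bp of a terminus
n_eligible = 0
for frag in fmap:
    seq = genome[frag.chrom][frag.start - 1 : frag.end]
    ok, probes = cb.bait_eligible(frag, seq, rules)
    n_eligible += ok
print(f"{n_eligible}/{len(fmap)} fragments admit a capture probe at a terminus")
# Fragments shorter than the probe, or with out-of-range GC near both
# termini, are the ones excluded — exactly the fragments a probe designer
# would have to skip.
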