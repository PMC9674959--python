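"""Minimum carrier-frequency estimates from LOF allele frequencies.

Pools the population allele frequencies of the study's LOF variants and
converts them to Hardy-Weinberg heterozygote (carrier) frequencies,
reported as 1:N.
"""

from octnvep import carrier_frequency_table, simulate_study

study = simulate_study(seed=7)
ch = study.characterized
lof = ch.index[ch["lof"]]
print(f"{len(lof)} LOF variants pooled per population\n")

cf = carrier_frequency_table(lof, study.af_table)
print(cf.round(6))
print()
print("q is the summed allele frequency of LOF variants observed in that")
print("population (absent entries contribute 0, so these are minimums);")
print("carrier_frequency = 2q(1-q), the expected heterozygote fraction.")
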