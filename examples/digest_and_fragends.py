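"""Digest a toy genome and build the 4C fragment-end map.

Builds a small random chromosome, digests it with DpnII, and derives the
fragment ends (with Csp6I blind-fragment flags) that 4C reads are counted on.
"""

from loop4c.digest import CSP6I, DPNII, build_fragends, digest_genome
from loop4c.simulate import random_genome

genome = random_genome(50_000, seed=1, chrom="chrToy")
fragmap = digest_genome(genome, DPNII)
fragends = build_fragends(fragmap, genome, CSP6I, L=36)

n_frags = len(fragmap)
n_blind = int(fragends["blind"].sum() // 2)
print(f"chromosome length : {len(genome['chrToy']):,} bp")
print(f"DpnII fragments   : {n_frags} (mean {len(genome['chrToy']) / n_frags:.0f} bp)")
print(f"fragment ends     : {len(fragends)} (two per fragment)")
print(f"blind fragments   : {n_blind} (no Csp6I site -> uninformative in 4C)")
print()
print(fragends.head(6).to_string(index=False))
print()
print(
    "Each fragment end carries the capture sequence a 4C read would start\n"
    "with; reads are assigned to fragends by exact lookup of those bases."
)
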