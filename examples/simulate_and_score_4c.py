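"""Simulate the enhancer-deletion study design and compute interaction scores.

Generates the paper-locus fixture (wild-type n=4, homozygous enhancer-cluster
deletion n=4, heterozygous alleles n=3/n=4), runs quantile normalization,
scores the gene-spanning region and both TAD regions, and prints the
condition comparisons -- the same statistics the 4C pipeline reports on real
count tables.
"""

import tempfile

from loop4c.pipeline import run_fourc
from loop4c.simulate import make_paper_locus_fixture

with tempfile.TemporaryDirectory() as workspace:
    make_paper_locus_fixture(seed=1, outdir=workspace)
    result = run_fourc(workspace)

print("condition comparisons vs wild type (two-tailed Welch t-test):\n")
print(
    result.comparisons[["region", "condition_b", "percent_change", "t", "p"]]
    .round({"percent_change": 1, "t": 2, "p": 4})
    .to_string(index=False)
)
print()
tad = result.tad_scores.groupby(["condition", "region"])["scaled_score"].mean().round(2)
print("TAD interaction scores (wild-type mean scaled to 1):")
print(tad.to_string())
print()
print("consensus bait-interacting region(s) across wild-type replicates:")
for start, end in result.consensus:
    print(f"  chrS:{start:,}-{end:,}")
print(
    "\nThe deletion allele loses ~a third of its contact with the planted\n"
    "gene-spanning peak (negative percent change, small p), leaks contacts\n"
    "into the downstream TAD (scaled score > 1), and leaves the intact\n"
    "allele of the heterozygote indistinguishable from wild type."
)
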