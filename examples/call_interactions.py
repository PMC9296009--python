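"""Call bait-interacting regions against a monotonic distance-decay background.

Simulates one wild-type 4C library with a planted interaction peak, fits the
robust isotonic background on each side of the bait, and reports the
intervals whose smoothed signal beats the background by the frozen
delta/rho thresholds.
"""

from loop4c.calling import call_interactions, consensus_regions, fit_background
from loop4c.reads import LibrarySpec
from loop4c.simulate import paper_locus_design, paper_locus_spec, build_locus, simulate_counts

locus = build_locus(paper_locus_spec())
fragends = locus.allele_fragends["wt"]
anchors = fragends["anchor_pos"].to_numpy()
wt_libraries = [lib for lib in paper_locus_design() if lib.condition == "WT"]

replicate_calls = []
for library, table in simulate_counts(locus, wt_libraries, seed=11):
    values = table["count"].to_numpy().astype(float)
    background = fit_background(values, anchors, locus.spec.bait_pos)
    calls = call_interactions(values, background, fragends)
    replicate_calls.append(calls)
    for c in calls:
        print(
            f"{library.sample_id}: {c.chrom}:{c.start:,}-{c.end:,} "
            f"({c.n_fragends} fragends, {c.enrichment:.1f}x background)"
        )

consensus = consensus_regions(replicate_calls)
print("\nconsensus (intersection across all replicates):")
for start, end in consensus:
    print(f"  chrS:{start:,}-{end:,}")
print(
    "\nThe planted gene-spanning peak (chrS:1,095,000-1,115,000) is recovered\n"
    "in every replicate; the consensus is the minimal region they all share."
)
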