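"""Probe-compatibility filtering for Infinium II single-bead assays.

Removes indels, tri-allelic sites and A/T / C/G transversions; SNPs with
another high-quality SNP within 50 bp; SNPs whose directly flanking 24-mer
occurs more than once in the genome (canonical, strand-collapsed count);
and SNPs scoring below 0.7 in the external design-score table.
"""

import arraysmith as ars

ds = ars.simulate(ars.SimulationSpec(seed=1))
q_survivors, _ = ars.apply_quality_stage(ds.records, ds.panel)

index = ars.build_kmer_index(ds.genome, 24)
print(f"24-mer index: {index.total_positions:,} genome windows, "
      f"{(index.counts > 1).sum():,} repeated canonical 24-mers")

survivors, stage = ars.apply_probe_stage(
    q_survivors, ds.genome, index, scores=ds.scores)
print(f"probe stage: {stage.input_count:,} -> {stage.survivor_count:,}")
for reason, n in sorted(stage.removals.items()):
    print(f"  removed {reason:12s} {n:5d}")
print("flank_repeat removals are exactly the variants whose upstream 24-mer")
print("was planted a second time elsewhere in the genome.")
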