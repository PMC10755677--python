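"""Simulate a toy transcriptome with a planted stalling motif and sample a
footprint library from it.

Prints the library composition and the planted ground truth: how many
Lys-Ile-Pro (KIP) sites were written into the proteome and the occupancy
multiplier attached to them.  Every downstream statistic can be checked
against this truth.
"""

from ribopause import SimConfig, simulate_footprints, simulate_transcriptome

cfg = SimConfig(
    seed=1,
    n_genes=20,
    cds_len_range=(600, 900),
    motif_multipliers={"KIP": 5.0},  # 5x ribosome occupancy when KIP spans E/P/A
    planted_sites=20,
    base_depth=2.0,  # mean reads per codon
    rna_depth=0.5,
    collision_prob=0.2,  # paused ribosomes sometimes yield disome reads
)

txome = simulate_transcriptome(cfg)
sim = simulate_footprints(txome, cfg, sample="treated")

n_kip = sum(g.protein.count("KIP") for g in txome)
print(f"transcriptome: {len(txome)} genes, {n_kip} KIP sites (>= 20 planted)")
print(f"library: {sim.n_molecules} unique molecules, by class: {sim.class_counts()}")
paused = sim.truth[sim.truth.multiplier > 1]
print(f"truth table: {len(paused)} codons carry multiplier "
      f"{paused.multiplier.unique().tolist()} (all other codons are 1.0)")
# the alignment table is the BED-like ground truth the aligner must recover
print(sim.alignments.head(3).to_string(index=False))
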