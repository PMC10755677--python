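"""Start-codon metagene and motif-aligned average-occupancy profile.

The metagene averages each gene's occupancy in a window around the start
codon (100 nt upstream, 300 nt in) after dividing by the window total, so
the profile is probability-like and sums to 1.  The motif metaprofile
averages gene-mean-normalized occupancy +/-50 nt around planted KIP sites:
the stall shows up as a peak at offset 0 of roughly the planted multiplier.
"""

import numpy as np

from ribopause import (
    AnalysisParams,
    SimConfig,
    build_track,
    enumerate_motif_sites,
    metagene,
    motif_metaprofile,
    simulate_footprints,
    simulate_transcriptome,
    size_select,
)

cfg = SimConfig(
    seed=12, n_genes=30, cds_len_range=(900, 1200),
    motif_multipliers={"KIP": 5.0}, planted_sites=60, base_depth=4.0,
)
params = AnalysisParams(min_motif_occurrences=1)
txome = simulate_transcriptome(cfg)
sim = simulate_footprints(txome, cfg, sample="s")
tracks = build_track(size_select(sim.alignments, "monosome", params), txome)

prof = metagene(tracks, txome, "start", params)
print(f"start metagene over {prof.n} genes: profile sum = {prof.mean.sum():.6f} "
      f"(per-gene windows are normalized to 1)")
in_orf = prof.mean[prof.offsets >= 30].mean()
upstream = prof.mean[prof.offsets < -10].mean()
print(f"mean occupancy in-ORF vs 5'UTR: {in_orf:.2e} vs {upstream:.2e} "
      "(footprints map to coding sequence only)")

sites = enumerate_motif_sites(txome, params)
kip = sites[(sites.motif == "KIP") & sites.eligible]
meta = motif_metaprofile(tracks, kip, txome, params)
peak_offset = meta.offsets[np.argmax(meta.mean)]
print(f"\nKIP metaprofile over {meta.n} sites: peak {meta.mean.max():.2f} at "
      f"offset {peak_offset} nt; baseline {np.median(meta.mean):.2f}")
print("  -> the planted 5x stall forms a 3 nt plateau centred on the readout "
      "position (offset 0 +/- 1 nt of 3'-end jitter)")
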