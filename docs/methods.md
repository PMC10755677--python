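# Methods

This note documents the statistical model, conventions and numerical choices
behind `ribopause`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and occupancy conventions

All coordinates are transcript-relative, 0-based, half-open; stored
sequences are spliced, sense-strand mRNAs.  A gene model is (5' UTR length,
CDS length, 3' UTR length); the stop codon belongs to the CDS but not to
the protein.

Ribosome footprints (monosome 25–34 nt, disome 57–63 nt) are reduced to the
transcript coordinate of their 3'-most base.  Fixed shifts map this
coordinate to ribosomal sites:

* **E-site readout** — the codon whose start is `3' end − 18 nt` is in the E
  site; equivalently, a motif whose E-site codon starts at position `x` is
  read out at track position `x + 18`.
* **P-site assignment** — for gene quantitation each footprint is assigned
  to position `3' end − 15 nt` (its P site).

The two shifts differ by one codon (E and P sites are adjacent); overriding
either so that this no longer holds triggers a warning, not an error.
RNA-seq reads (exactly 50 nt) use a coverage convention (+1 at every spanned
base) rather than 3'-end assignment.

Tracks are normalized to **rpm**: `count × 10⁶ / total mapped reads`, where
"total mapped" is the number of reads surviving deduplication and size
selection that aligned to the transcriptome for that sample.  The denominator
counts reads mapped anywhere on the transcript (UTRs included); a
CDS-restricted denominator would change every rpm by a near-constant factor
and cancel out of pause scores, which are scale-invariant.

## The pause score

For a tri-amino-acid motif occupying the E/P/A sites, with readout position
`p` on a 3'-end track `v`:

```
score = v[p] / mean(v[p − 50 … p + 50])
```

The window is the closed 101-position span and includes the motif position
itself (the plainest reading of "±50 nt"); excluding the centre is available
as an option (`include_motif_position_in_window=False`).  A site is
**eligible** when the whole window lies inside the ORF interior trimmed by
15 nt at both ends — the same trim used for quantitation — which unifies
edge handling and keeps initiation/termination peaks out of both numerator
and denominator.  Windows with zero mean yield an *ineligible* site with a
reason code, never a NaN score; ineligibility is data, not an error.

Motif averages are arithmetic means over eligible site scores; motifs
occurring fewer than `min_motif_occurrences` (default 100) times
transcriptome-wide are excluded.  Replicates are averaged at the
motif-average level by default (read-level pooling is possible by
concatenating alignment tables before track building).  Condition
comparisons use per-motif fold changes; the foreground is `fold ≥ 1.5` and
the background is the rest of the shared motif universe, so the two always
partition it.  Per-site score *ratios* between conditions are formed only
over sites eligible in both samples; sites lost in either are counted.

Disome tracks use the same 3'-end convention and, by default, the same
18 nt shift (leading-ribosome readout); the disome shift is a separate
parameter because the collided-ribosome geometry is less certain.

## Mann-Whitney U test

Shifts in site-level scores (or score ratios) between conditions are tested
with an independent two-group Mann-Whitney U test, two-sided by default.
For combined n ≤ 20 the null distribution is enumerated exactly over all
C(n, n₁) labelings of the pooled sample, computed from midranks so ties are
handled exactly; two-sided p doubles the smaller tail (capped at 1).  For
larger samples the tie-corrected normal approximation (scipy) is used; the
degenerate all-tied case returns p = 1.

## Metagenes, metaprofiles, quantitation

* **Metagene**: per gene, the occupancy window (start anchor: 100 nt
  upstream + 300 nt into the ORF; stop anchor: 300 nt of ORF + 100 nt
  downstream) is divided by its own total, so each per-gene vector and the
  across-gene average sum to exactly 1.  Excluded: genes flagged as
  ORF-overlapping, genes whose flanking feature is shorter than the window,
  and genes with no reads *in the window* (a gene with reads only elsewhere
  has an undefined normalized window).
* **Motif metaprofile**: each eligible site's ±50 nt window is divided by
  the gene's mean rpm over the ORF (full-transcript mean available via
  `gene_mean_region="transcript"`), then averaged across sites with sd.
* **Quantitation**: rpkm = (rpm sum over the region) / (region length in
  kb).  Footprint CDS quantitation shifts reads to the P site and trims
  15 nt from both ORF ends; the rpkm denominator is the trimmed length.
  RNA uses untrimmed, unshifted coverage.  UTR quantitation uses the 3'-end
  track without the P-site shift — shifting would move UTR-boundary signal
  across the CDS border.  A UTR of length 0 yields NaN (feature absent),
  not 0 (feature empty).  TE = ribo_rpkm / rna_rpkm, NaN where rna_rpkm = 0.
  Raw integer counts (same shift/trim rules) are exported for external
  differential-expression tools; the differential test itself is out of
  scope here.

## The synthetic footprint generator

The generator provides ground truth, not realism.  Its model:

* Random transcriptomes drawn codon-wise from the standard genetic code
  (uniform synonymous codon choice, uniform amino acids from a configurable
  alphabet, no internal stops by construction).  Requested motifs are
  planted at interior sites ≥ 17 codons from the ORF start, ≥ 28 from the
  end and ≥ 40 codons apart, so their pause windows are always eligible and
  never overlap.
* Ribosome count at the codon whose A site completes a configured motif is
  negative-binomial with mean `base_depth × m` and
  `Var = mean + mean²/dispersion`; all other codons have mean
  `base_depth`.  The pause is multiplicative at that single codon — matching
  how the pause score reads out one 3'-end position.
* Each monosome read's 3' end is placed at `E-site codon start + 18` plus a
  uniform jitter of ±1 nt (`end_jitter`), modelling RNase trimming
  heterogeneity; read length is uniform on 25–34 nt (5' end varies, 3' end
  stays tied to the decoded codon).  The jitter matters: with it the three
  jittered positions tile each codon, an unpaused track is flat in
  expectation, null pause scores are calibrated at 1, and a planted
  multiplier m reads out as `101m/(98+3m)` (≈ 4.47 for m = 5, within the
  ±20% recovery band).  With `end_jitter=0` (exact placement) reads occupy
  only every third nucleotide, the null score is ≈ 101/33 ≈ 3, and the
  statistic is no longer calibrated — so jitter is the default.
* A paused ribosome also yields a disome read with probability
  `collision_prob` (leading-ribosome 3'-end rule, 57–63 nt) — a
  simplification of collision kinetics sufficient to exercise the disome
  track conventions.  RNA reads are uniform over the transcript at 50 nt.
* Reads carry the library layout 2 nt RT-UMI + insert + 5 nt linker UMI +
  5 nt barcode; `duplication_factor` emits each molecule repeatedly to
  emulate PCR duplication.  UMIs are drawn uniformly but collision-free
  within each deduplication key group, so deduplication recovers the
  pre-duplication molecule count exactly.  Real libraries have occasional
  UMI collisions (and sequencing errors in UMIs); the simulator idealizes
  both away, so conservation tests are exact here but only approximate on
  real data.

Not emulated: ligation/sequence bias, initiation and termination peaks,
uORFs, rRNA contamination, mismatches/indels (the toy aligner is exact
matching), isoform structure, and stress-response regulation.  Passing
tests therefore validate the *conventions and arithmetic* of the analysis,
not its robustness to real-library artefacts.

## Deduplication

PCR duplicates are collapsed on the exact key (sample, gene, 3' position,
read length, 7 nt UMI); there is no UMI-distance clustering.  Whether the
original analyses keyed on read length as well is not determinable; the
exact-key choice is the simplest faithful reading and is idempotent.  The
2 nt RT-UMI's placement in the stored read is a library-specific detail;
here it is defined at the 5' end of the stored sequence, and parser and
simulator share the definition through `ReadLayout`.

## Study conditions used at desk scale

Simulated checks run at sizes a laptop handles in seconds, chosen to make
the statistics stable rather than to mimic sequencing depth:

* **Planted recovery**: 100 genes × 250–300 codons, m = 5 at 200 KIP
  sites, base_depth 2, dispersion 10, generator seed 7.  The fold ranking
  uses a 10-occurrence motif filter: in a random toy proteome only the
  planted motif can reach the genome-scale 100-occurrence threshold, which
  would reduce the ranking to a single motif.
* **Null calibration**: 50 genes × 200–300 codons over a 5-letter amino
  acid alphabet (125 motifs × ~100 sites each, so motif averages are
  stable), base_depth 10, dispersion 10, 30-occurrence filter; two
  independent null samples feed the foreground/background split, which must
  come out empty at the 1.5-fold cutoff.

## Residue enrichment

The simplified positional-logo statistic compares foreground and background
motif sets per position (E/P/A) and residue with a pseudocounted log-odds,
`log2(((c_fg + 0.5)/(n_fg + 1)) / ((c_bg + 0.5)/(n_bg + 1)))`, plus a
two-sided binomial p-value of the foreground count at the background
frequency.  This is a stand-in for external sequence-logo tools, not a
reimplementation of their statistics.

## Known limitations

* The exact-match aligner requires synthetic (error-free) reads; real data
  should be aligned externally and imported via the BED-like alignment
  table ("aligned" pipeline mode).
* Multi-isoform gene models and genome-coordinate liftover are out of
  scope; one transcript per gene.
* Pause-window eligibility couples to the 15 nt end trim; analyses wanting
  the untrimmed CDS interior can set `end_trim` accordingly, at the cost of
  initiation/termination contamination.
* TE's absolute scale mixes a 3'-end convention (numerator) with a coverage
  convention (denominator); only relative TE is interpretable.
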