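"""Analysis conventions gathered in one place.

Every fixed number of the occupancy/pause analysis lives here so that a run's
conventions are explicit and serializable: the 3'-end-to-ribosome-site shifts,
the pause window, the motif-occurrence filter, the foreground fold cutoff,
ORF end trimming, metagene windows, and the footprint size selections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field


@dataclass(frozen=True)
class AnalysisParams:
    """Numeric conventions of the pause/occupancy analysis.

    Attributes
    ----------
    e_site_shift:
        nt added to an E-site codon start to reach the footprint 3'-end track
        position it is read out from (monosome convention).
    p_site_shift:
        nt subtracted from a footprint 3' end to place its P site; used for
        gene-level quantitation.
    pause_window:
        Half-width (nt) of the pause-score background window: the window is
        the closed ``[pos - w, pos + w]`` span, 2w+1 positions, motif
        position included.
    min_motif_occurrences:
        Tri-amino-acid motifs occurring fewer times than this across the
        transcriptome are excluded from motif-average tables.
    fg_fold:
        Fold-change cutoff defining the foreground motif set in condition
        comparisons.
    end_trim:
        nt removed from both ends of each ORF before quantitation and before
        pause-site eligibility, to suppress initiation/termination signal.
    metagene_start_window / metagene_stop_window:
        (upstream nt, downstream nt) around the start codon / around the stop
        codon for metagene averaging.
    mono_len_range / disome_len_range:
        Inclusive footprint-length selections for monosome and disome reads.
    rna_len:
        Exact RNA-seq read length kept.
    disome_e_site_shift:
        3'-end shift used for disome tracks; defaults to the monosome value
        (leading-ribosome readout) and is exposed as a knob because the
        disome geometry is less certain.
    """

    e_site_shift: int = 18
    p_site_shift: int = 15
    pause_window: int = 50
    min_motif_occurrences: int = 100
    fg_fold: float = 1.5
    end_trim: int = 15
    metagene_start_window: tuple[int, int] = (100, 300)
    metagene_stop_window: tuple[int, int] = (300, 100)
    mono_len_range: tuple[int, int] = (25, 34)
    disome_len_range: tuple[int, int] = (57, 63)
    rna_len: int = 50
    disome_e_site_shift: int = 18
    include_motif_position_in_window: bool = True

    def __post_init__(self) -> None:
        for name in (
            "e_site_shift",
            "p_site_shift",
            "pause_window",
            "min_motif_occurrences",
            "end_trim",
            "rna_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fg_fold <= 0:
            raise ValueError("fg_fold must be positive")
        # One codon separates the E- and P-site readouts under the default
        # conventions; a user override is allowed but flagged.
        if self.e_site_shift - self.p_site_shift != 3:
            warnings.warn(
                "e_site_shift - p_site_shift != 3: E/P readouts are no longer "
                "one codon apart",
                stacklevel=2,
            )

    def length_range(self, cls: str) -> tuple[int, int]:
        """Inclusive read-length window for a footprint class."""
        if cls == "monosome":
            return self.mono_len_range
        if cls == "disome":
            return self.disome_len_range
        if cls == "rna":
            return (self.rna_len, self.rna_len)
        raise ValueError(f"unknown read class {cls!r}")

    def to_dict(self) -> dict:
        return asdict(self)
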