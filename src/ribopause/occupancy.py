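"""Per-nucleotide occupancy tracks in rpm units.

Footprint reads are reduced to one coordinate per ribosome — the transcript
position of the read's 3'-most base — and accumulated into per-gene tracks
spanning the full transcript (UTRs included).  RNA-seq reads instead use a
coverage convention (+1 at every spanned base).  Raw counts are normalized to
rpm: reads per million mapped reads of the sample,
``rpm = count * 1e6 / total_mapped``.

Fixed shifts map the 3'-end coordinate to ribosomal sites: the E-site codon
start sits ``e_site_shift`` (18) nt upstream of the 3' end, the P site
``p_site_shift`` (15) nt upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Transcriptome
from .params import AnalysisParams

__all__ = [
    "TrackSet",
    "build_track",
    "site_position",
    "p_site_position",
    "write_tracks",
    "read_tracks",
]

#: canonical column schema for aligned-read tables
ALIGN_COLUMNS = ["sample", "gene_id", "three_prime_pos", "read_len", "umi"]


@dataclass
class TrackSet:
    """Per-gene occupancy arrays for one sample under one convention.

    ``values[gene_id]`` is a float array over the full transcript in rpm.
    ``total_mapped`` is the normalization denominator, so raw counts are
    recoverable as ``values * total_mapped / 1e6``.
    """

    sample: str
    convention: str  # "three_prime_end" | "coverage"
    total_mapped: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def raw(self, gene_id: str) -> np.ndarray:
        return self.values[gene_id] * self.total_mapped / 1e6

    def total_rpm(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def gene_mean(self, gene_id: str, start: int | None = None, end: int | None = None) -> float:
        v = self.values[gene_id]
        return float(v[start:end].mean())

    def scaled(self, k: float) -> "TrackSet":
        """Return a copy with every value multiplied by ``k`` (testing aid)."""
        return TrackSet(
            self.sample,
            self.convention,
            self.total_mapped,
            {g: v * k for g, v in self.values.items()},
        )


def build_track(
    alignments: pd.DataFrame,
    txome: Transcriptome,
    convention: str = "three_prime_end",
    sample: str | None = None,
    total_mapped: int | None = None,
) -> TrackSet:
    """Accumulate size-selected, deduplicated alignments into rpm tracks.

    Parameters
    ----------
    alignments:
        Table with columns ``gene_id, three_prime_pos, read_len`` (and
        optionally ``sample``); should contain one footprint class only.
    convention:
        ``"three_prime_end"`` adds 1 at each read's 3'-end position;
        ``"coverage"`` adds 1 at every base the read spans.
    total_mapped:
        Normalization denominator; defaults to the number of alignments,
        i.e. all mapped reads of the sample are being placed.
    """
    if convention not in ("three_prime_end", "coverage"):
        raise ValueError(f"unknown convention {convention!r}")
    if sample is None:
        sample = (
            str(alignments["sample"].iloc[0])
            if "sample" in alignments.columns and len(alignments)
            else "sample"
        )
    n = len(alignments)
    total = int(total_mapped) if total_mapped is not None else n
    if total <= 0:
        raise ValueError(f"sample {sample!r}: zero mapped reads, cannot normalize to rpm")

    values = {g.gene_id: np.zeros(len(g)) for g in txome}
    for gid, sub in alignments.groupby("gene_id", sort=False):
        arr = values[str(gid)]
        pos = sub["three_prime_pos"].to_numpy(dtype=np.int64)
        if pos.min(initial=0) < 0 or (len(pos) and pos.max() >= len(arr)):
            raise ValueError(f"{gid}: 3' position outside transcript")
        if convention == "three_prime_end":
            np.add.at(arr, pos, 1.0)
        else:
            ln = sub["read_len"].to_numpy(dtype=np.int64)
            start = np.maximum(pos - ln + 1, 0)
            # difference-array trick: O(L) coverage accumulation
            diff = np.zeros(len(arr) + 1)
            np.add.at(diff, start, 1.0)
            np.add.at(diff, pos + 1, -1.0)
            arr += np.cumsum(diff[:-1])
    scale = 1e6 / total
    return TrackSet(sample, convention, total, {g: v * scale for g, v in values.items()})


def site_position(e_codon_start: int, params: AnalysisParams) -> int:
    """Track coordinate read out for a motif whose E-site codon starts here."""
    return e_codon_start + params.e_site_shift


def p_site_position(three_prime_pos: int, params: AnalysisParams) -> int:
    """P-site position of a footprint given its 3'-end coordinate."""
    return three_prime_pos - params.p_site_shift


# ---------------------------------------------------------------------------
# flat-file export/import: bedGraph-style per-gene rows, header in comments


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    """Write non-zero track positions as tab-separated (gene_id, pos, rpm)."""
    with open(path, "w") as fh:
        fh.write(f"# sample={tracks.sample}\n")
        fh.write(f"# convention={tracks.convention}\n")
        fh.write(f"# total_mapped={tracks.total_mapped}\n")
        for gid, v in tracks.values.items():
            (idx,) = np.nonzero(v)
            for i in idx:
                fh.write(f"{gid}\t{i}\t{v[i]:.10g}\n")


def write_wiggle(tracks: TrackSet, path: str | Path) -> None:
    """Wiggle-like flat export: one fixedStep block per gene, every position."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=wiggle_0 name="{tracks.sample}" '
            f"convention={tracks.convention} total_mapped={tracks.total_mapped}\n"
        )
        for gid, v in tracks.values.items():
            fh.write(f"fixedStep chrom={gid} start=1 step=1\n")
            for x in v:
                fh.write(f"{x:.10g}\n")


def read_wiggle(path: str | Path, txome: Transcriptome) -> TrackSet:
    """Inverse of :func:`write_wiggle`."""
    sample, convention, total = "sample", "three_prime_end", 0
    values = {g.gene_id: np.zeros(len(g)) for g in txome}
    gid, i = None, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("track"):
                fields = dict(
                    f.split("=", 1) for f in line.split() if "=" in f
                )
                sample = fields.get("name", sample).strip('"')
                convention = fields.get("convention", convention)
                total = int(fields.get("total_mapped", 0))
            elif line.startswith("fixedStep"):
                fields = dict(f.split("=", 1) for f in line.split() if "=" in f)
                gid, i = fields["chrom"], int(fields.get("start", 1)) - 1
            elif line:
                values[gid][i] = float(line)
                i += 1
    return TrackSet(sample, convention, total, values)


def read_tracks(path: str | Path, txome: Transcriptome) -> TrackSet:
    """Inverse of :func:`write_tracks` (needs the transcriptome for lengths)."""
    meta: dict[str, str] = {}
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line:
                gid, pos, rpm = line.split("\t")
                rows.append((gid, int(pos), float(rpm)))
    tracks = TrackSet(
        meta.get("sample", "sample"),
        meta.get("convention", "three_prime_end"),
        int(meta.get("total_mapped", 0) or 0),
        {g.gene_id: np.zeros(len(g)) for g in txome},
    )
    for gid, pos, rpm in rows:
        tracks.values[gid][pos] = rpm
    return tracks
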