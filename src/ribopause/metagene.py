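"""Metagenes, motif-aligned metaprofiles, and gene-level quantitation.

Metagene profiles average occupancy across genes aligned at the start or
stop codon; each gene's window is first divided by its own total reads in
that window, so every per-gene vector — and hence the averaged profile —
sums to 1.  Genes are excluded when their ORF overlaps another ORF, when the
flanking feature is smaller than the window, or when the window holds no
mapped reads.

Motif-aligned metaprofiles average the +/-50 nt neighbourhood of eligible
motif sites after dividing each window by the gene's mean rpm (ORF mean by
default), so a planted multiplicative pause appears as a peak of roughly
that height at offset 0.

Quantitation sums rpm over a region and divides by the region length in kb
(rpkm).  For ribosome footprints over the CDS, 3' ends are shifted by
``p_site_shift`` to the P site first and ``end_trim`` nt are dropped from
either ORF end; RNA-seq uses coverage tracks with no shift or trim.
Translation efficiency is the per-gene ratio ribo_rpkm / rna_rpkm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Transcriptome
from .occupancy import TrackSet
from .params import AnalysisParams

__all__ = [
    "MetageneProfile",
    "metagene_gene_windows",
    "metagene",
    "motif_metaprofile",
    "quantitate",
    "build_expression_table",
    "translation_efficiency",
    "export_raw_counts",
    "write_counts_mtx",
]


@dataclass
class MetageneProfile:
    """Averaged profile around a common anchor."""

    offsets: np.ndarray  # nt relative to the anchor
    mean: np.ndarray
    sd: np.ndarray
    n: int  # genes or sites averaged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean, "sd": self.sd})


def metagene_gene_windows(
    tracks: TrackSet,
    txome: Transcriptome,
    anchor: str,
    params: AnalysisParams,
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Per-gene normalized metagene windows plus an exclusion report.

    Returns ``(windows, excluded)`` where each window sums to 1 and
    ``excluded`` maps dropped gene ids to a reason
    (``orf_overlap`` / ``feature_too_small`` / ``no_reads_in_window``).
    """
    if anchor == "start":
        up, down = params.metagene_start_window
    elif anchor == "stop":
        up, down = params.metagene_stop_window
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    windows: dict[str, np.ndarray] = {}
    excluded: dict[str, str] = {}
    for g in txome:
        if txome.overlap_flags.get(g.gene_id, False):
            excluded[g.gene_id] = "orf_overlap"
            continue
        if anchor == "start":
            if g.utr5_len < up or g.cds_len < down:
                excluded[g.gene_id] = "feature_too_small"
                continue
            lo = g.cds_start - up
        else:
            if g.cds_len < up or g.utr3_len < down:
                excluded[g.gene_id] = "feature_too_small"
                continue
            lo = g.cds_end - up
        win = tracks.values[g.gene_id][lo : lo + up + down]
        total = win.sum()
        if total == 0:
            excluded[g.gene_id] = "no_reads_in_window"
            continue
        windows[g.gene_id] = win / total
    return windows, excluded


def metagene(
    tracks: TrackSet,
    txome: Transcriptome,
    anchor: str,
    params: AnalysisParams,
) -> MetageneProfile:
    """Start- or stop-anchored metagene profile (mean +/- sd across genes)."""
    windows, _ = metagene_gene_windows(tracks, txome, anchor, params)
    if not windows:
        raise ValueError(f"no genes survive the {anchor}-metagene exclusion rules")
    up = (params.metagene_start_window if anchor == "start" else params.metagene_stop_window)[0]
    mat = np.vstack(list(windows.values()))
    offsets = np.arange(-up, mat.shape[1] - up)
    return MetageneProfile(offsets, mat.mean(axis=0), mat.std(axis=0), len(windows))


def motif_metaprofile(
    tracks: TrackSet,
    sites: pd.DataFrame,
    txome: Transcriptome,
    params: AnalysisParams,
    gene_mean_region: str = "cds",
) -> MetageneProfile:
    """Average occupancy around eligible motif sites, gene-mean normalized.

    Each site's ``[track_pos - w, track_pos + w]`` window is divided by the
    gene's mean rpm (over the ORF by default, ``gene_mean_region='transcript'``
    for the full transcript) and the windows are averaged across sites.
    """
    w = params.pause_window
    ok = sites[sites["eligible"]]
    if ok.empty:
        raise ValueError("no eligible motif sites")
    rows = []
    for gid, sub in ok.groupby("gene_id", sort=False):
        g = txome[str(gid)]
        values = tracks.values[g.gene_id]
        if gene_mean_region == "cds":
            gmean = values[g.cds_start : g.cds_end].mean()
        elif gene_mean_region == "transcript":
            gmean = values.mean()
        else:
            raise ValueError(f"unknown gene_mean_region {gene_mean_region!r}")
        if gmean == 0:
            continue
        for pos in sub["track_pos"].to_numpy(dtype=np.int64):
            rows.append(values[pos - w : pos + w + 1] / gmean)
    if not rows:
        raise ValueError("no eligible motif sites with non-zero gene mean")
    mat = np.vstack(rows)
    offsets = np.arange(-w, w + 1)
    return MetageneProfile(offsets, mat.mean(axis=0), mat.std(axis=0), len(rows))


def quantitate(
    tracks: TrackSet,
    txome: Transcriptome,
    region: str,
    params: AnalysisParams,
    apply_p_site_shift: bool = True,
) -> pd.DataFrame:
    """Per-gene rpm sum and rpkm for one region (cds | utr5 | utr3).

    CDS quantitation of 3'-end (footprint) tracks shifts each read to its
    P site and trims ``end_trim`` nt from either ORF end before summing;
    coverage (RNA) tracks are summed over the untrimmed CDS.  UTR sums use
    the stored convention without shift or trim.  Genes whose region is
    absent (UTR length 0) or non-positive after trimming are flagged with
    NaN, not 0.
    """
    if region not in ("cds", "utr5", "utr3"):
        raise ValueError(f"unknown region {region!r}")
    shift = (
        params.p_site_shift
        if region == "cds"
        and apply_p_site_shift
        and tracks.convention == "three_prime_end"
        else 0
    )
    rows = []
    for g in txome:
        values = tracks.values[g.gene_id]
        if region == "cds":
            lo, hi = g.cds_start, g.cds_end
            if shift:
                lo, hi = lo + params.end_trim, hi - params.end_trim
            length = hi - lo
            if length <= 0:
                rows.append((g.gene_id, np.nan, np.nan, np.nan))
                continue
            # P site = 3' end - shift, so region [lo, hi) of P-site positions
            # reads track positions [lo + shift, hi + shift)
            span = values[lo + shift : hi + shift]
        elif region == "utr5":
            length = g.utr5_len
            if length <= 0:
                rows.append((g.gene_id, np.nan, np.nan, np.nan))
                continue
            span = values[: g.utr5_len]
        else:
            length = g.utr3_len
            if length <= 0:
                rows.append((g.gene_id, np.nan, np.nan, np.nan))
                continue
            span = values[g.cds_end :]
        rpm_sum = float(span.sum())
        rows.append((g.gene_id, rpm_sum, length / 1000.0, rpm_sum / (length / 1000.0)))
    return pd.DataFrame(rows, columns=["gene_id", "rpm_sum", "length_kb", "rpkm"])


def translation_efficiency(expr: pd.DataFrame) -> pd.Series:
    """TE = ribo_rpkm / rna_rpkm per gene; NaN where rna_rpkm is 0 or missing."""
    with np.errstate(divide="ignore", invalid="ignore"):
        te = expr["ribo_rpkm"] / expr["rna_rpkm"]
    return te.where(expr["rna_rpkm"] > 0)


def build_expression_table(
    ribo_tracks: TrackSet,
    rna_tracks: TrackSet,
    txome: Transcriptome,
    params: AnalysisParams,
) -> pd.DataFrame:
    """Assemble the per-gene expression table: rpkms, TE and UTR occupancy."""
    ribo = quantitate(ribo_tracks, txome, "cds", params).rename(
        columns={"rpkm": "ribo_rpkm"}
    )[["gene_id", "ribo_rpkm"]]
    rna = quantitate(rna_tracks, txome, "cds", params).rename(
        columns={"rpkm": "rna_rpkm"}
    )[["gene_id", "rna_rpkm"]]
    utr5 = quantitate(ribo_tracks, txome, "utr5", params).rename(
        columns={"rpkm": "utr5_rpkm"}
    )[["gene_id", "utr5_rpkm"]]
    utr3 = quantitate(ribo_tracks, txome, "utr3", params).rename(
        columns={"rpkm": "utr3_rpkm"}
    )[["gene_id", "utr3_rpkm"]]
    expr = ribo.merge(rna, on="gene_id").merge(utr5, on="gene_id").merge(utr3, on="gene_id")
    expr["te"] = translation_efficiency(expr)
    return expr


def export_raw_counts(
    alignments: pd.DataFrame, txome: Transcriptome, params: AnalysisParams
) -> pd.DataFrame:
    """Integer CDS-assigned counts per gene x sample (differential-expression
    input; the shift/trim rules match rpkm quantitation).

    Counts reads whose P site (3' end - p_site_shift) falls in the trimmed
    ORF interior.  Unaffected by rpm normalization by construction.
    """
    df = alignments.copy()
    df["p_site"] = df["three_prime_pos"] - params.p_site_shift
    rows = []
    for g in txome:
        lo, hi = g.cds_start + params.end_trim, g.cds_end - params.end_trim
        sub = df[df["gene_id"] == g.gene_id]
        in_region = sub[(sub["p_site"] >= lo) & (sub["p_site"] < hi)]
        counts = in_region.groupby("sample").size()
        rows.append((g.gene_id, counts))
    samples = sorted(df["sample"].unique()) if len(df) else []
    out = pd.DataFrame(
        {
            "gene_id": [gid for gid, _ in rows],
            **{
                s: [int(c.get(s, 0)) for _, c in rows]
                for s in samples
            },
        }
    )
    return out


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write the count matrix as MatrixMarket plus row/column name files."""
    from scipy import io as sio
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    samples = [c for c in counts.columns if c != "gene_id"]
    mat = csr_matrix(counts[samples].to_numpy(dtype=np.int64))
    sio.mmwrite(str(prefix.with_suffix(".mtx")), mat)
    counts["gene_id"].to_csv(prefix.with_suffix(".genes.tsv"), index=False, header=False)
    pd.Series(samples).to_csv(prefix.with_suffix(".samples.tsv"), index=False, header=False)
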