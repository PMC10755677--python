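"""Raw reads -> deduplicated per-transcript 3'-end alignments.

Library layout: each sequenced read is
``rt_umi (2 nt) + insert + linker_umi (5 nt) + sample barcode (5 nt)``.
Demultiplexing strips the linker side, routes reads by exact barcode match
(non-matching barcodes land in an ``unassigned`` bin rather than being
silently dropped) and attaches a 7 nt UMI = rt_umi + linker_umi.

PCR duplicates are collapsed on the exact key
(sample, gene, 3'-end position, read length, UMI); no UMI-distance
clustering is attempted.  Size selection keeps 25-34 nt monosome, 57-63 nt
disome, and exactly 50 nt RNA inserts.

``toy_align`` replaces a general aligner for synthetic data: exact, unique,
sense-strand substring matching against the transcriptome, with multi-mapping
reads dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO

from .annotation import Transcriptome
from .params import AnalysisParams

__all__ = [
    "ReadLayout",
    "InsertRead",
    "DemuxResult",
    "demultiplex_and_trim",
    "toy_align",
    "dedup_umis",
    "size_select",
    "filter_blocklist",
    "write_sam",
    "write_qc_report",
]

_UMI_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ReadLayout:
    """Linker/UMI/barcode geometry of the sequencing library."""

    barcode_map: dict[str, str] = field(default_factory=dict)  # barcode -> sample
    linker_umi_len: int = 5
    barcode_len: int = 5
    rt_umi_len: int = 2

    def __post_init__(self) -> None:
        if len(set(self.barcode_map.values())) != len(self.barcode_map):
            raise ValueError("sample names must be unique")
        for bc in self.barcode_map:
            if len(bc) != self.barcode_len:
                raise ValueError(f"barcode {bc!r} is not {self.barcode_len} nt")
            if any(ch not in _UMI_ALPHABET for ch in bc):
                raise ValueError(f"barcode {bc!r} has characters outside ACGTN")

    @property
    def tail_len(self) -> int:
        return self.linker_umi_len + self.barcode_len

    @property
    def min_read_len(self) -> int:
        # at least one insert base must survive trimming
        return self.rt_umi_len + self.tail_len + 1


class InsertRead(NamedTuple):
    name: str
    insert: str
    umi: str


@dataclass
class DemuxResult:
    samples: dict[str, list[InsertRead]]
    unassigned: list[InsertRead]
    counters: dict[str, int]


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        for rec in SeqIO.parse(str(reads), "fastq"):
            yield rec.id, str(rec.seq).upper()
    else:
        for item in reads:
            if isinstance(item, tuple):
                yield item[0], str(item[1]).upper()
            else:  # SeqRecord
                yield item.id, str(item.seq).upper()


def demultiplex_and_trim(reads, layout: ReadLayout) -> DemuxResult:
    """Split pooled reads by barcode, trim the linker, attach the 7 nt UMI.

    ``reads`` may be a FASTQ path, an iterable of Bio SeqRecords, or an
    iterable of ``(name, sequence)`` tuples.  Reads too short to contain one
    insert base are discarded and counted; counts conserve:
    assigned + unassigned + discarded == total.
    """
    samples: dict[str, list[InsertRead]] = {s: [] for s in layout.barcode_map.values()}
    unassigned: list[InsertRead] = []
    counters = {"total": 0, "assigned": 0, "unassigned": 0, "discarded_short": 0}
    b, u, r = layout.barcode_len, layout.linker_umi_len, layout.rt_umi_len
    for name, seq in _iter_reads(reads):
        counters["total"] += 1
        if len(seq) < layout.min_read_len:
            counters["discarded_short"] += 1
            continue
        barcode = seq[-b:]
        linker_umi = seq[-(b + u) : -b]
        rt_umi = seq[:r]
        insert = seq[r : -(b + u)]
        rec = InsertRead(name, insert, rt_umi + linker_umi)
        sample = layout.barcode_map.get(barcode)
        if sample is None:
            counters["unassigned"] += 1
            unassigned.append(rec)
        else:
            counters["assigned"] += 1
            samples[sample].append(rec)
    return DemuxResult(samples, unassigned, counters)


def _kmer_index(txome: Transcriptome, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for g in txome:
        seq = g.transcript_seq
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((g.gene_id, i))
    return index


def toy_align(
    inserts: Iterable[InsertRead],
    txome: Transcriptome,
    sample: str = "sample",
    seed_k: int = 15,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exact sense-strand substring alignment of synthetic inserts.

    A read must match at exactly one transcript position; multi-mapping reads
    are dropped and counted (uniqueness requirement), as are reads with no
    sense-strand match (which covers reverse-complement-only matches).
    Returns an aligned-read table (sample, gene_id, three_prime_pos,
    read_len, umi) plus stage counters.
    """
    index = _kmer_index(txome, seed_k)
    rows = []
    counters = {"input": 0, "aligned": 0, "multimapped": 0, "unaligned": 0}
    for rec in inserts:
        counters["input"] += 1
        ins = rec.insert
        hits: set[tuple[str, int]] = set()
        if len(ins) >= seed_k:
            for gid, pos in index.get(ins[:seed_k], ()):
                if txome[gid].transcript_seq[pos : pos + len(ins)] == ins:
                    hits.add((gid, pos))
        else:  # short inserts: exhaustive scan
            for g in txome:
                start = 0
                while True:
                    p = g.transcript_seq.find(ins, start)
                    if p == -1:
                        break
                    hits.add((g.gene_id, p))
                    start = p + 1
        if len(hits) == 1:
            gid, pos = next(iter(hits))
            rows.append(
                (sample, gid, pos + len(ins) - 1, len(ins), rec.umi)
            )
            counters["aligned"] += 1
        elif len(hits) > 1:
            counters["multimapped"] += 1
        else:
            counters["unaligned"] += 1
    df = pd.DataFrame(
        rows, columns=["sample", "gene_id", "three_prime_pos", "read_len", "umi"]
    )
    return df, counters


DEDUP_KEY = ["sample", "gene_id", "three_prime_pos", "read_len", "umi"]


def dedup_umis(alignments: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Collapse PCR duplicates: one read per exact dedup key.

    Idempotent; returns the deduplicated table and counters
    ``{input, retained, duplicates_removed}``.
    """
    out = alignments.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(
        drop=True
    )
    counters = {
        "input": len(alignments),
        "retained": len(out),
        "duplicates_removed": len(alignments) - len(out),
    }
    return out, counters


def size_select(
    alignments: pd.DataFrame, cls: str, params: AnalysisParams | None = None
) -> pd.DataFrame:
    """Keep reads within the class's footprint size selection (inclusive)."""
    params = params or AnalysisParams()
    lo, hi = params.length_range(cls)
    return alignments[alignments["read_len"].between(lo, hi)].reset_index(drop=True)


def filter_blocklist(
    alignments: pd.DataFrame, blocked_gene_ids: Iterable[str] = ()
) -> pd.DataFrame:
    """Contaminant (e.g. rRNA) subtraction hook; empty blocklist = pass-through."""
    blocked = set(blocked_gene_ids)
    if not blocked:
        return alignments
    return alignments[~alignments["gene_id"].isin(blocked)].reset_index(drop=True)


def write_sam(alignments: pd.DataFrame, txome: Transcriptome, path: str | Path) -> None:
    """Minimal SAM export (match-only CIGAR, mapped sense-strand reads)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g.gene_id, "LN": len(g)} for g in txome],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(alignments.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{row.sample}:{i:06d}:{row.umi}"
            a.flag = 0
            a.reference_name = row.gene_id
            a.reference_start = int(row.three_prime_pos) - int(row.read_len) + 1
            a.cigarstring = f"{int(row.read_len)}M"
            a.mapping_quality = 255
            g = txome[row.gene_id]
            a.query_sequence = g.transcript_seq[
                a.reference_start : a.reference_start + int(row.read_len)
            ]
            out.write(a)


def write_qc_report(stage_counters: dict[str, dict[str, int]], path: str | Path) -> None:
    """Tab-separated QC report: one row per (stage, counter)."""
    rows = [
        (stage, key, int(val))
        for stage, counters in stage_counters.items()
        for key, val in counters.items()
    ]
    pd.DataFrame(rows, columns=["stage", "counter", "count"]).to_csv(
        path, sep="\t", index=False
    )
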