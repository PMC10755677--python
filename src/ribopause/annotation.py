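"""Transcriptome annotation: gene models, sequences, and translations.

All coordinates in this package are transcript-relative, 0-based, half-open,
and every stored sequence is the sense (mRNA) strand.  A gene model is fully
described by its spliced transcript sequence plus the lengths of the 5' UTR,
CDS and 3' UTR; the CDS must start at ``utr5_len`` and end ``utr3_len``
nucleotides before the transcript end.  The stop codon belongs to the CDS but
is not part of the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("ribopause")

__all__ = [
    "GeneModel",
    "Transcriptome",
    "translate_cds",
    "load_transcriptome",
    "write_transcriptome",
    "load_gene_model_gff3",
]


class InternalStopError(ValueError):
    """CDS translation hit a stop codon before the final codon."""

    def __init__(self, gene_id: str, codon_index: int):
        self.gene_id = gene_id
        self.codon_index = codon_index
        super().__init__(
            f"{gene_id}: internal stop codon at codon index {codon_index}"
        )


def _translate(cds: str, gene_id: str = "?") -> str:
    """Translate a frame-checked CDS with the standard code, excluding the stop.

    Raises :class:`InternalStopError` if a stop codon occurs before the last
    codon, and ``ValueError`` if the terminal codon is not a stop.
    """
    aa = str(Seq(cds).translate(table=1))
    internal = aa[:-1].find("*")
    if internal != -1:
        raise InternalStopError(gene_id, internal)
    if not aa.endswith("*"):
        raise ValueError(f"{gene_id}: CDS does not end in a stop codon")
    return aa[:-1]


@dataclass
class GeneModel:
    """One transcript: sequence, UTR/CDS extents and the encoded protein."""

    gene_id: str
    transcript_seq: str
    utr5_len: int
    utr3_len: int
    protein: str = ""

    def __post_init__(self) -> None:
        self.transcript_seq = str(self.transcript_seq).upper()
        L = len(self.transcript_seq)
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: negative UTR length")
        cds_len = L - self.utr5_len - self.utr3_len
        if cds_len <= 0:
            raise ValueError(f"{self.gene_id}: non-positive CDS length {cds_len}")
        if cds_len % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {cds_len} not a multiple of 3"
            )
        if not self.protein:
            self.protein = translate_cds(self)
        if len(self.protein) != cds_len // 3 - 1:
            raise ValueError(f"{self.gene_id}: protein/CDS length mismatch")

    # -- derived coordinates ------------------------------------------------
    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return len(self.transcript_seq) - self.utr3_len

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def cds_seq(self) -> str:
        return self.transcript_seq[self.cds_start : self.cds_end]

    def __len__(self) -> int:
        return len(self.transcript_seq)

    def codon_interval(self, codon_index: int) -> tuple[int, int]:
        """Transcript nt interval [start, end) occupied by codon ``codon_index``."""
        start = self.cds_start + 3 * codon_index
        return start, start + 3

    def codon_at(self, position: int) -> int:
        """Inverse of :meth:`codon_interval` for any nt inside the CDS."""
        if not self.cds_start <= position < self.cds_end:
            raise ValueError(f"position {position} outside CDS")
        return (position - self.cds_start) // 3


def translate_cds(gene: GeneModel) -> str:
    """Standard-code translation of a gene's CDS, stop codon excluded."""
    return _translate(gene.cds_seq, gene.gene_id)


@dataclass
class Transcriptome:
    """Ordered collection of :class:`GeneModel` with per-gene overlap flags.

    ``overlap_flags[g]`` marks genes whose ORF overlaps another ORF; such
    genes are excluded from metagene averaging.  Synthetic transcriptomes are
    all-False by construction.
    """

    genes: dict[str, GeneModel] = field(default_factory=dict)
    overlap_flags: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, genes: Iterable[GeneModel]) -> "Transcriptome":
        out = cls()
        for g in genes:
            if g.gene_id in out.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            out.genes[g.gene_id] = g
            out.overlap_flags[g.gene_id] = False
        return out

    def set_overlap_flags(self, flags: Mapping[str, bool]) -> None:
        for gid, v in flags.items():
            if gid not in self.genes:
                raise KeyError(gid)
            self.overlap_flags[gid] = bool(v)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


def load_transcriptome(fasta_path: str | Path, model_path: str | Path) -> Transcriptome:
    """Read transcript FASTA + a 4-column gene model table into a Transcriptome.

    The model table is tab-separated with columns
    ``gene_id  utr5_len  cds_len  utr3_len`` (header optional, detected).
    Genes whose CDS fails the frame check, whose lengths do not add up to the
    sequence length, or whose CDS contains an internal stop are logged as
    warnings and dropped.  A model row without a FASTA record is a hard error.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    model = _read_model_table(model_path)

    genes: list[GeneModel] = []
    for row in model.itertuples(index=False):
        gid = str(row.gene_id)
        if gid not in seqs:
            raise ValueError(f"gene model row {gid!r} has no FASTA record")
        seq = seqs[gid]
        expected = int(row.utr5_len) + int(row.cds_len) + int(row.utr3_len)
        try:
            if expected != len(seq):
                raise ValueError(
                    f"{gid}: model lengths sum to {expected}, sequence is {len(seq)} nt"
                )
            genes.append(
                GeneModel(gid, seq, int(row.utr5_len), int(row.utr3_len))
            )
        except ValueError as exc:
            log.warning("dropping gene %s: %s", gid, exc)
    return Transcriptome.from_genes(genes)


def _read_model_table(model_path: str | Path) -> pd.DataFrame:
    cols = ["gene_id", "utr5_len", "cds_len", "utr3_len"]
    try:
        model = pd.read_csv(model_path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    if model.shape[1] < 4:
        raise ValueError("gene model table needs 4 columns: gene_id utr5 cds utr3")
    model = model.iloc[:, :4]
    model.columns = cols
    # tolerate a header row
    if not model.empty and not str(model.iloc[0, 1]).lstrip("-").isdigit():
        model = model.iloc[1:]
    for c in cols[1:]:
        model[c] = model[c].astype(int)
    return model


def write_transcriptome(
    txome: Transcriptome, fasta_path: str | Path, model_path: str | Path
) -> None:
    """Inverse of :func:`load_transcriptome` on valid inputs (round-trips)."""
    records = [
        SeqRecord(Seq(g.transcript_seq), id=g.gene_id, description="")
        for g in txome
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        (g.gene_id, g.utr5_len, g.cds_len, g.utr3_len) for g in txome
    ]
    pd.DataFrame(rows, columns=["gene_id", "utr5_len", "cds_len", "utr3_len"]).to_csv(
        model_path, sep="\t", header=False, index=False
    )


def load_gene_model_gff3(gff3_path: str | Path) -> pd.DataFrame:
    """GFF3 import shim: derive the 4-column gene model table from features.

    Sums the lengths of ``five_prime_UTR``, ``CDS`` and ``three_prime_UTR``
    features per parent transcript.  The caller still supplies the matching
    spliced transcript FASTA; this shim only maps feature extents to UTR/CDS
    lengths.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, dict[str, int]] = {}
    kinds = {"five_prime_UTR": "utr5_len", "CDS": "cds_len", "three_prime_UTR": "utr3_len"}
    for ftype, col in kinds.items():
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [feat.id])
            for parent in parents:
                rec = lengths.setdefault(
                    parent, {"utr5_len": 0, "cds_len": 0, "utr3_len": 0}
                )
                rec[col] += feat.end - feat.start + 1
    rows = [
        (gid, v["utr5_len"], v["cds_len"], v["utr3_len"])
        for gid, v in lengths.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "utr5_len", "cds_len", "utr3_len"])
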