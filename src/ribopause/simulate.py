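"""Synthetic transcriptomes and footprint libraries with known, planted pausing.

The simulator provides ground truth for every downstream statistic.  A toy
transcriptome is drawn codon-by-codon from the standard genetic code; chosen
tri-amino-acid motifs are planted at interior sites far enough from the ORF
ends that their pause windows are always eligible.  Footprints are then
sampled per decoded codon:

* the ribosome count at A-site codon ``c`` is negative-binomial with mean
  ``base_depth * m(c)`` and ``Var = mean + mean**2 / dispersion``, where
  ``m(c)`` is the planted multiplier when the E/P/A residue window ending at
  ``c`` matches a configured motif and 1 otherwise;
* each monosome read's 3' end falls at (E-site codon start + 18) nt plus a
  small uniform jitter of ``end_jitter`` nt modelling RNase trimming
  heterogeneity (with the default +/-1 nt the three jittered positions tile
  the codon, so an unpaused track is flat in expectation and site-level pause
  scores are calibrated around 1); the read length is uniform on the monosome
  size selection, so the 5' end varies while the 3' end stays tied to the
  decoded codon;
* a paused ribosome additionally yields a disome read with probability
  ``collision_prob`` (leading-ribosome 3'-end rule, 57-63 nt);
* RNA-seq reads are uniform over the transcript at fixed length.

Reads carry the library layout expected by :mod:`ribopause.readproc`:
2 nt RT UMI + insert + 5 nt linker UMI + 5 nt sample barcode.  UMIs are drawn
collision-free within each (gene, 3' position, length) group, so deduplicated
counts recover the pre-duplication molecule count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .annotation import GeneModel, Transcriptome

__all__ = ["SimConfig", "FootprintSim", "simulate_transcriptome", "simulate_footprints"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_UMI_LEN = 7
_UMI_SPACE = 4**_UMI_LEN


def _codon_tables() -> tuple[dict[str, list[str]], list[str]]:
    std = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(std.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa, sorted(std.stop_codons)


_CODONS_BY_AA, _STOP_CODONS = _codon_tables()


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    ``motif_multipliers`` maps a tri-amino-acid motif (E/P/A order) to its
    multiplicative pause strength m >= 1; ``planted_sites`` fixes how many
    sites of each such motif are written into the transcriptome (an int
    applies to every motif).  ``end_jitter=0`` recovers exact 3'-end
    placement at (E-site codon start + three_prime_offset).
    """

    seed: int = 0
    n_genes: int = 50
    cds_len_range: tuple[int, int] = (450, 900)  # nt incl. stop codon
    utr5_len: int = 100
    utr3_len: int = 100
    motif_multipliers: dict[str, float] = field(default_factory=dict)
    planted_sites: int | Mapping[str, int] = 2
    base_depth: float = 2.0
    dispersion: float = 10.0
    mono_len_range: tuple[int, int] = (25, 34)
    disome_len_range: tuple[int, int] = (57, 63)
    rna_read_len: int = 50
    rna_depth: float = 0.0  # mean RNA reads per codon; 0 disables RNA reads
    collision_prob: float = 0.0
    end_jitter: int = 1
    three_prime_offset: int = 18
    disome_three_prime_offset: int = 18
    aa_alphabet: str = _AA20
    duplication_factor: int = 1
    plant_margin_codons: tuple[int, int] = (17, 28)  # from start / from end
    plant_spacing_codons: int = 40

    def __post_init__(self) -> None:
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.collision_prob <= 1:
            raise ValueError("collision_prob must be in [0, 1]")
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")
        lo, hi = self.cds_len_range
        if lo < 90 or hi < lo:
            raise ValueError("cds_len_range must be >= 90 nt and ordered")
        if not (25 <= self.mono_len_range[0] <= self.mono_len_range[1] <= 34):
            raise ValueError("mono_len_range must lie within [25, 34]")
        if not (57 <= self.disome_len_range[0] <= self.disome_len_range[1] <= 63):
            raise ValueError("disome_len_range must lie within [57, 63]")
        if self.utr5_len < 50 or self.utr3_len < 20:
            raise ValueError("UTRs too short for footprint placement")
        for motif, m in self.motif_multipliers.items():
            if len(motif) != 3 or any(ch not in _AA20 for ch in motif):
                raise ValueError(f"invalid tri-amino-acid motif {motif!r}")
            if m < 1:
                raise ValueError(f"motif {motif!r}: multiplier {m} < 1")
        if any(ch not in _AA20 for ch in self.aa_alphabet) or not self.aa_alphabet:
            raise ValueError("aa_alphabet must be non-empty standard amino acids")

    def planted_count(self, motif: str) -> int:
        if isinstance(self.planted_sites, Mapping):
            return int(self.planted_sites.get(motif, 0))
        return int(self.planted_sites)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_sites"] = (
            dict(self.planted_sites)
            if isinstance(self.planted_sites, Mapping)
            else self.planted_sites
        )
        return d


def simulate_transcriptome(config: SimConfig) -> Transcriptome:
    """Draw a random transcriptome with the configured motifs planted.

    Planted sites sit at least ``plant_margin_codons`` from either ORF end and
    ``plant_spacing_codons`` apart, so their +/-50 nt pause windows are always
    eligible and do not overlap each other.  Raises if the requested site
    counts cannot be placed within ``cds_len_range``.
    """
    rng = np.random.default_rng(config.seed)
    lo_cod, hi_cod = config.cds_len_range[0] // 3, config.cds_len_range[1] // 3
    n_codons = rng.integers(lo_cod, hi_cod + 1, size=config.n_genes)
    prot_len = n_codons - 1

    alphabet = np.array(list(config.aa_alphabet))
    proteins = [
        "M" + "".join(rng.choice(alphabet, size=int(pl - 1)))
        for pl in prot_len
    ]

    # allocate disjoint planting slots round-robin over genes
    margin_lo, margin_hi = config.plant_margin_codons
    spacing = config.plant_spacing_codons
    slots: list[tuple[int, int]] = []
    for rnd in range(200):
        e = margin_lo + rnd * spacing
        added = False
        for gi in range(config.n_genes):
            if e + 3 <= prot_len[gi] - margin_hi:
                slots.append((gi, e))
                added = True
        if not added:
            break
    needed = sum(config.planted_count(m) for m in config.motif_multipliers)
    if needed > len(slots):
        raise ValueError(
            f"cannot plant {needed} motif sites: only {len(slots)} interior "
            f"slots available under cds_len_range={config.cds_len_range}"
        )
    chars = [list(p) for p in proteins]
    cursor = 0
    for motif in config.motif_multipliers:
        for _ in range(config.planted_count(motif)):
            gi, e = slots[cursor]
            cursor += 1
            chars[gi][e : e + 3] = list(motif)
    proteins = ["".join(c) for c in chars]

    nts = "ACGT"
    genes = []
    for gi, prot in enumerate(proteins):
        codons = [rng.choice(_CODONS_BY_AA[aa]) for aa in prot]
        codons.append(rng.choice(_STOP_CODONS))
        utr5 = "".join(rng.choice(list(nts), size=config.utr5_len))
        utr3 = "".join(rng.choice(list(nts), size=config.utr3_len))
        seq = utr5 + "".join(codons) + utr3
        genes.append(
            GeneModel(f"g{gi:04d}", seq, config.utr5_len, config.utr3_len, protein=prot)
        )
    return Transcriptome.from_genes(genes)


@dataclass
class FootprintSim:
    """Result bundle of one simulated sample.

    ``alignments`` is the pre-duplication molecule table (one row per unique
    molecule; the BED-like truth alignment); ``truth`` holds the expected
    relative occupancy multiplier per (gene, A-site codon), 1.0 everywhere a
    configured motif does not end.
    """

    sample: str
    barcode: str
    config: SimConfig
    txome: Transcriptome
    alignments: pd.DataFrame
    truth: pd.DataFrame

    @property
    def n_molecules(self) -> int:
        return len(self.alignments)

    def class_counts(self) -> dict[str, int]:
        return self.alignments["cls"].value_counts().to_dict()

    def write_alignment_table(self, path: str | Path) -> None:
        self.alignments.to_csv(path, sep="\t", index=False)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_fastq(self, path: str | Path, mode: str = "w") -> int:
        """Write reads (with linker UMI/barcode layout and PCR duplicates).

        Each molecule is emitted ``config.duplication_factor`` times.  Returns
        the number of records written.  Layout per read:
        ``rt_umi(2) + insert + linker_umi(5) + barcode(5)``.
        """
        d = self.config.duplication_factor
        n = 0
        with open(path, mode) as fh:
            for i, row in enumerate(self.alignments.itertuples(index=False)):
                seq3 = int(row.three_prime_pos)
                seq5 = seq3 - int(row.read_len) + 1
                insert = self.txome[row.gene_id].transcript_seq[seq5 : seq3 + 1]
                umi = row.umi
                read = umi[:2] + insert + umi[2:] + self.barcode
                qual = "I" * len(read)
                for k in range(d):
                    fh.write(f"@{self.sample}:{i:06d}:d{k}\n{read}\n+\n{qual}\n")
                    n += 1
        return n


def _umi_strings(codes: np.ndarray) -> list[str]:
    nts = np.array(list("ACGT"))
    out = np.empty((len(codes), _UMI_LEN), dtype="<U1")
    c = codes.copy()
    for j in range(_UMI_LEN - 1, -1, -1):
        out[:, j] = nts[c % 4]
        c //= 4
    return ["".join(row) for row in out]


def simulate_footprints(
    txome: Transcriptome,
    config: SimConfig,
    multipliers: Mapping[str, float] | None = None,
    sample: str = "sample1",
    barcode: str = "TGACT",
    seed: int | None = None,
) -> FootprintSim:
    """Sample a footprint library for one sample/condition.

    ``multipliers`` overrides ``config.motif_multipliers`` (pass ``{}`` for an
    untreated/null condition on the same transcriptome).  Determinism: the
    same transcriptome, config and seed yield byte-identical FASTQ output.
    """
    mult_map = dict(config.motif_multipliers if multipliers is None else multipliers)
    for motif, m in mult_map.items():
        if len(motif) != 3 or any(ch not in _AA20 for ch in motif) or m < 1:
            raise ValueError(f"invalid motif/multiplier {motif!r}: {m}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    gene_ids: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    classes: list[np.ndarray] = []
    truth_rows: list[pd.DataFrame] = []
    j = config.end_jitter
    disp = config.dispersion

    for g in txome:
        prot = g.protein
        n_prot = len(prot)
        a_idx = np.arange(2, n_prot)  # A-site codon indices with a full E/P/A window
        m = np.array([mult_map.get(prot[c - 2 : c + 1], 1.0) for c in a_idx])
        mean = config.base_depth * m
        k = rng.negative_binomial(disp, disp / (disp + mean))

        codon = np.repeat(a_idx, k)
        e_start = g.cds_start + 3 * (codon - 2)
        jit = rng.integers(-j, j + 1, size=len(codon)) if j > 0 else 0
        tp = e_start + config.three_prime_offset + jit
        ln = rng.integers(config.mono_len_range[0], config.mono_len_range[1] + 1, size=len(codon))
        ok = (tp - ln + 1 >= 0) & (tp < len(g))
        gene_ids.append(np.full(ok.sum(), g.gene_id, dtype=object))
        positions.append(tp[ok])
        lengths.append(ln[ok])
        classes.append(np.full(ok.sum(), "monosome", dtype=object))

        if config.collision_prob > 0:
            paused = m > 1
            k_dis = rng.binomial(k[paused], config.collision_prob)
            dcodon = np.repeat(a_idx[paused], k_dis)
            de = g.cds_start + 3 * (dcodon - 2)
            djit = rng.integers(-j, j + 1, size=len(dcodon)) if j > 0 else 0
            dtp = de + config.disome_three_prime_offset + djit
            dln = rng.integers(
                config.disome_len_range[0], config.disome_len_range[1] + 1, size=len(dcodon)
            )
            dok = (dtp - dln + 1 >= 0) & (dtp < len(g))
            gene_ids.append(np.full(dok.sum(), g.gene_id, dtype=object))
            positions.append(dtp[dok])
            lengths.append(dln[dok])
            classes.append(np.full(dok.sum(), "disome", dtype=object))

        if config.rna_depth > 0:
            n_rna = rng.poisson(config.rna_depth * n_prot)
            start = rng.integers(0, len(g) - config.rna_read_len + 1, size=n_rna)
            gene_ids.append(np.full(n_rna, g.gene_id, dtype=object))
            positions.append(start + config.rna_read_len - 1)
            lengths.append(np.full(n_rna, config.rna_read_len))
            classes.append(np.full(n_rna, "rna", dtype=object))

        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": g.gene_id,
                    "a_codon_index": a_idx,
                    "multiplier": m,
                }
            )
        )

    df = pd.DataFrame(
        {
            "sample": sample,
            "gene_id": np.concatenate(gene_ids) if gene_ids else [],
            "three_prime_pos": np.concatenate(positions).astype(np.int64)
            if positions
            else [],
            "read_len": np.concatenate(lengths).astype(np.int64) if lengths else [],
            "cls": np.concatenate(classes) if classes else [],
        }
    )

    # collision-free UMIs within each dedup key group
    codes = rng.integers(0, _UMI_SPACE, size=len(df))
    key = ["gene_id", "three_prime_pos", "read_len"]
    for _ in range(100):
        df["_code"] = codes
        dup = df.duplicated(subset=key + ["_code"], keep="first")
        if not dup.any():
            break
        codes[dup.to_numpy()] = rng.integers(0, _UMI_SPACE, size=int(dup.sum()))
    else:  # pragma: no cover - requires >16384 molecules at one position
        raise RuntimeError("UMI space exhausted at a single position")
    df = df.drop(columns="_code")
    df["umi"] = _umi_strings(codes)
    df = df[["sample", "gene_id", "three_prime_pos", "read_len", "umi", "cls"]]

    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else pd.DataFrame(
        columns=["gene_id", "a_codon_index", "multiplier"]
    )
    return FootprintSim(sample, barcode, config, txome, df, truth)
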