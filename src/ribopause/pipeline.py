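"""End-to-end orchestration: one config in, a bundle of result tables out.

Three modes:

* ``simulate`` — build a synthetic transcriptome, sample treated/untreated
  footprint libraries (the treated condition carries the configured motif
  multipliers), write pooled FASTQ, then run the full processing chain.
* ``fastq`` — start from a pooled FASTQ plus annotation and barcode map.
* ``aligned`` — start from pre-aligned BED-like tables per sample.

Every run writes a QC report with per-stage read-count conservation and a
``manifest.json`` recording parameters, input digests and stage counters, so
a run is reproducible from its manifest.  Reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import pause as ps
from .metagene import export_raw_counts, metagene as build_metagene, motif_metaprofile
from .annotation import Transcriptome, load_transcriptome, write_transcriptome
from .occupancy import build_track, write_tracks
from .params import AnalysisParams
from .readproc import (
    ReadLayout,
    demultiplex_and_trim,
    dedup_umis,
    size_select,
    toy_align,
    write_qc_report,
)
from .simulate import SimConfig, simulate_footprints, simulate_transcriptome

log = logging.getLogger("ribopause")

__all__ = ["RunConfig", "SampleSpec", "run"]


@dataclass
class SampleSpec:
    name: str
    cls: str  # monosome | disome | rna
    condition: str  # e.g. untreated | treated
    barcode: str = ""
    path: str = ""  # aligned mode: per-sample alignment table


@dataclass
class RunConfig:
    mode: str = "simulate"
    seed: int = 0
    fasta: str = ""
    model: str = ""
    fastq: str = ""
    samples: list[SampleSpec] = field(default_factory=list)
    compare: tuple[str, str] = ("treated", "untreated")
    params: AnalysisParams = field(default_factory=AnalysisParams)
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            mode=raw.get("mode", "simulate"),
            seed=int(raw.get("seed", 0)),
            fasta=raw.get("fasta", ""),
            model=raw.get("model", ""),
            fastq=raw.get("fastq", ""),
            compare=tuple(raw.get("compare", ("treated", "untreated"))),
            params=AnalysisParams(**_tupled(raw.get("params", {}))),
            sim=SimConfig(**_tupled(raw.get("sim", {}))),
        )
        cfg.samples = [SampleSpec(**s) for s in raw.get("samples", [])]
        names = [s.name for s in cfg.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        for attr in ("fasta", "model", "fastq"):
            p = getattr(cfg, attr)
            if p and cfg.mode != "simulate" and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        return cfg


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


_BARCODES = ["TGACT", "AACCG", "GTTAC", "CCGGA", "ATGCA", "TCAGT", "GACTG", "CTGAC"]


def run(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute a full run; returns a name -> path map of written artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counters: dict[str, dict[str, int]] = {}
    params = config.params

    # ---- stage: annotation / simulation -----------------------------------
    if config.mode == "simulate":
        txome = simulate_transcriptome(config.sim)
        fasta, model = out / "transcripts.fa", out / "gene_model.tsv"
        write_transcriptome(txome, fasta, model)
        artifacts["fasta"], artifacts["model"] = fasta, model

        conditions = [config.compare[1], config.compare[0]]  # untreated, treated
        sims = {}
        layout_map: dict[str, str] = {}
        fastq = out / "pooled.fastq"
        fastq.write_text("")
        n_truth = {}
        for i, cond in enumerate(conditions):
            mult = config.sim.motif_multipliers if cond == config.compare[0] else {}
            sim = simulate_footprints(
                txome,
                config.sim,
                multipliers=mult,
                sample=cond,
                barcode=_BARCODES[i],
                seed=(config.seed * 1000 + i) % (2**31),
            )
            sim.write_fastq(fastq, mode="a")
            sim.write_alignment_table(out / f"truth_alignments_{cond}.tsv")
            layout_map[_BARCODES[i]] = cond
            sims[cond] = sim
            n_truth[cond] = sim.n_molecules
        artifacts["fastq"] = fastq
        layout = ReadLayout(barcode_map=layout_map)
        sample_specs = [
            SampleSpec(name=c, cls="monosome", condition=c) for c in conditions
        ]
    elif config.mode in ("fastq", "aligned"):
        if not (config.fasta and config.model):
            raise FileNotFoundError("annotation stage: fasta/model paths required")
        txome = load_transcriptome(config.fasta, config.model)
        sample_specs = config.samples
        if config.mode == "fastq":
            layout = ReadLayout(
                barcode_map={s.barcode: s.name for s in sample_specs if s.barcode}
            )
            fastq = Path(config.fastq)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # ---- stage: read processing ------------------------------------------
    aligned: dict[str, pd.DataFrame] = {}
    if config.mode == "aligned":
        for spec in sample_specs:
            aligned[spec.name] = pd.read_csv(spec.path, sep="\t")
    else:
        demux = demultiplex_and_trim(fastq, layout)
        counters["demultiplex"] = demux.counters
        for spec in sample_specs:
            adf, align_counters = toy_align(
                demux.samples.get(spec.name, []), txome, sample=spec.name
            )
            counters[f"align:{spec.name}"] = align_counters
            dedup, dd_counters = dedup_umis(adf)
            counters[f"dedup:{spec.name}"] = dd_counters
            aligned[spec.name] = dedup

    # ---- stage: tracks, pause analysis -----------------------------------
    sites = ps.enumerate_motif_sites(txome, params)
    scored: dict[str, pd.DataFrame] = {}
    mono_tracks = {}
    for spec in sample_specs:
        if spec.cls != "monosome":
            continue
        sel = size_select(aligned[spec.name], "monosome", params)
        counters[f"size_select:{spec.name}"] = {
            "input": len(aligned[spec.name]),
            "retained": len(sel),
        }
        tracks = build_track(sel, txome, "three_prime_end", sample=spec.name)
        mono_tracks[spec.name] = tracks
        write_tracks(tracks, out / f"tracks_{spec.name}.tsv")
        sc = ps.score_sites(tracks, sites, params)
        scored[spec.name] = sc
        tbl = ps.average_pause_scores(sc, params)
        tbl.to_csv(out / f"pause_scores_{spec.name}.tsv", sep="\t", index=False)
        artifacts[f"pause_scores_{spec.name}"] = out / f"pause_scores_{spec.name}.tsv"

    cond_a, cond_b = config.compare
    if cond_a in scored and cond_b in scored:
        cmp_tbl = ps.compare_conditions(
            ps.average_pause_scores(scored[cond_a], params),
            ps.average_pause_scores(scored[cond_b], params),
            params,
        )
        cmp_tbl.to_csv(out / "pause_fold.tsv", sep="\t", index=False)
        artifacts["pause_fold"] = out / "pause_fold.tsv"

    # ---- stage: metagenes / metaprofiles ----------------------------------
    for name, tracks in mono_tracks.items():
        for anchor in ("start", "stop"):
            try:
                prof = build_metagene(tracks, txome, anchor, params)
            except ValueError as exc:
                log.warning("metagene %s/%s skipped: %s", name, anchor, exc)
                continue
            path = out / f"metagene_{anchor}_{name}.tsv"
            prof.to_frame().to_csv(path, sep="\t", index=False)
            artifacts[f"metagene_{anchor}_{name}"] = path
        motifs = set(config.sim.motif_multipliers) if config.mode == "simulate" else set()
        focus = sites[sites["motif"].isin(motifs)] if motifs else pd.DataFrame()
        if len(focus):
            prof = motif_metaprofile(tracks, focus, txome, params)
            path = out / f"motif_metaprofile_{name}.tsv"
            prof.to_frame().to_csv(path, sep="\t", index=False)
            artifacts[f"motif_metaprofile_{name}"] = path

    # ---- stage: expression / counts ---------------------------------------
    all_aligned = (
        pd.concat(list(aligned.values()), ignore_index=True) if aligned else pd.DataFrame()
    )
    if len(all_aligned):
        raw = export_raw_counts(
            size_select(all_aligned, "monosome", params)
            if "cls" not in all_aligned.columns
            else all_aligned,
            txome,
            params,
        )
        raw.to_csv(out / "raw_counts.tsv", sep="\t", index=False)
        artifacts["raw_counts"] = out / "raw_counts.tsv"

    # ---- QC + manifest -----------------------------------------------------
    write_qc_report(counters, out / "qc_report.tsv")
    artifacts["qc_report"] = out / "qc_report.tsv"
    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "params": params.to_dict(),
        "sim": config.sim.to_dict() if config.mode == "simulate" else None,
        "counters": counters,
        "inputs": {
            k: _digest(v) for k, v in artifacts.items() if k in ("fasta", "model", "fastq")
        },
    }
    if config.mode == "simulate":
        # conservation: demultiplexed+deduplicated reads recover the truth
        manifest["conservation"] = {
            c: {
                "truth_molecules": int(n_truth[c]),
                "retained_after_dedup": int(len(aligned[c])),
            }
            for c in aligned
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
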