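"""Tri-amino-acid pause scores and redox-pausing comparisons.

The central statistic: every overlapping 3-residue window of every protein
names the residues in the ribosomal E, P and A sites.  The ribosome decoding
that window is read out at a single 3'-end track coordinate,
``E-site codon start + e_site_shift`` (18 nt), and its pause score is

    score = rpm at the readout position
          / mean rpm over the closed +/- pause_window (50 nt) span

(101 positions, motif position included).  Scores are averaged per motif;
motifs occurring fewer than ``min_motif_occurrences`` times transcriptome-wide
are excluded.  Condition comparisons take per-motif fold changes and split
the universe into a foreground (fold >= fg_fold) and background.  Shifts of
site-level scores (or score ratios) between conditions/strains are tested
with a two-sided Mann-Whitney U test, exact by enumeration for small samples.

Site eligibility: the full score window must lie inside the ORF interior
after trimming ``end_trim`` (15) nt from either ORF end; windows crossing the
trimmed bounds, or with zero mean, yield an ineligible site (a reason code,
never a NaN-propagating score).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Transcriptome
from .occupancy import TrackSet, site_position
from .params import AnalysisParams

__all__ = [
    "enumerate_motif_sites",
    "pause_score",
    "score_sites",
    "average_pause_scores",
    "average_replicates",
    "compare_conditions",
    "site_score_ratios",
    "mann_whitney_u",
    "xip_score_shift_test",
    "residue_enrichment",
    "MannWhitneyResult",
]

SITE_COLUMNS = [
    "gene_id",
    "motif",
    "e_codon_index",
    "track_pos",
    "eligible",
    "reason",
    "motif_occurrences",
    "motif_retained",
]


def enumerate_motif_sites(txome: Transcriptome, params: AnalysisParams) -> pd.DataFrame:
    """All E/P/A tri-amino-acid motif sites with eligibility annotations.

    Emits one row per overlapping 3-residue protein window.  A site is
    eligible when its full pause window fits inside the trimmed ORF interior
    ``[cds_start + end_trim, cds_end - end_trim)``.  Per-motif occurrence
    counts (all sites, eligible or not) drive the ``motif_retained`` flag.
    """
    w = params.pause_window
    rows = []
    for g in txome:
        prot = g.protein
        lo = g.cds_start + params.end_trim
        hi = g.cds_end - params.end_trim - 1  # inclusive upper bound
        for e in range(len(prot) - 2):
            pos = site_position(g.cds_start + 3 * e, params)
            if pos >= len(g):
                eligible, reason = False, "outside_transcript"
            elif pos - w < lo or pos + w > hi:
                eligible, reason = False, "window_out_of_bounds"
            else:
                eligible, reason = True, "ok"
            rows.append((g.gene_id, prot[e : e + 3], e, pos, eligible, reason))
    sites = pd.DataFrame(
        rows,
        columns=["gene_id", "motif", "e_codon_index", "track_pos", "eligible", "reason"],
    )
    occ = sites["motif"].value_counts()
    sites["motif_occurrences"] = sites["motif"].map(occ).astype(int)
    sites["motif_retained"] = sites["motif_occurrences"] >= params.min_motif_occurrences
    return sites


def pause_score(values: np.ndarray, track_pos: int, params: AnalysisParams) -> float:
    """Pause score at one track position, or NaN if the window mean is zero
    or the window leaves the array."""
    w = params.pause_window
    lo, hi = track_pos - w, track_pos + w + 1
    if lo < 0 or hi > len(values):
        return float("nan")
    window = values[lo:hi]
    if not params.include_motif_position_in_window:
        window = np.delete(window, w)
    mean = window.mean()
    if mean == 0:
        return float("nan")
    return float(values[track_pos] / mean)


def score_sites(
    tracks: TrackSet, sites: pd.DataFrame, params: AnalysisParams
) -> pd.DataFrame:
    """Attach per-site pause scores for one sample's 3'-end tracks.

    Ineligible sites and zero-mean windows get score NaN and an updated
    reason code; the result carries a ``score`` column alongside the site
    annotations.
    """
    out = sites.copy().reset_index(drop=True)
    scores = np.full(len(out), np.nan)
    reasons = out["reason"].to_numpy(dtype=object).copy()
    w = params.pause_window
    span = 2 * w + 1
    for gid, sub in out.groupby("gene_id", sort=False):
        values = tracks.values[str(gid)]
        idx = sub.index[sub["eligible"].to_numpy()].to_numpy()
        if len(idx) == 0:
            continue
        pos = out.loc[idx, "track_pos"].to_numpy(dtype=np.int64)
        # windowed means over the eligible sites of one gene; the per-row
        # reduction is the same pairwise sum as the scalar definition, so
        # score_sites and pause_score agree bit for bit
        windows = np.lib.stride_tricks.sliding_window_view(values, span)
        wmean = windows[pos - w].mean(axis=1)
        if not params.include_motif_position_in_window:
            wmean = (wmean * span - values[pos]) / (span - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = values[pos] / wmean
        zero = wmean == 0
        s[zero] = np.nan
        scores[idx] = s
        reasons[idx[zero]] = "zero_window"
    out["score"] = scores
    out.loc[:, "reason"] = reasons
    return out


def average_pause_scores(
    scored_sites: pd.DataFrame, params: AnalysisParams
) -> pd.DataFrame:
    """Per-motif arithmetic mean of eligible site scores for one sample.

    Motifs below the occurrence threshold, or with zero scored sites, are
    excluded.  Columns: motif, n_sites, avg_score.
    """
    ok = scored_sites[
        scored_sites["motif_retained"] & scored_sites["score"].notna()
    ]
    tbl = (
        ok.groupby("motif")["score"]
        .agg(n_sites="count", avg_score="mean")
        .reset_index()
    )
    return tbl[tbl["n_sites"] >= 1].reset_index(drop=True)


def average_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-motif tables across replicates (motif-average level).

    Keeps motifs present in every replicate; ``n_sites`` reports the first
    replicate's site count.
    """
    if not tables:
        raise ValueError("no replicate tables")
    merged = tables[0][["motif", "n_sites", "avg_score"]].rename(
        columns={"avg_score": "avg_0"}
    )
    for i, t in enumerate(tables[1:], start=1):
        merged = merged.merge(
            t[["motif", "avg_score"]].rename(columns={"avg_score": f"avg_{i}"}),
            on="motif",
            how="inner",
        )
    cols = [c for c in merged.columns if c.startswith("avg_")]
    merged["avg_score"] = merged[cols].mean(axis=1)
    return merged[["motif", "n_sites", "avg_score"]]


def compare_conditions(
    table_a: pd.DataFrame, table_b: pd.DataFrame, params: AnalysisParams
) -> pd.DataFrame:
    """Per-motif fold table (A over B) with the foreground/background split.

    Motifs present in only one table are excluded from the universe (and
    reported via the returned frame's ``attrs['dropped_motifs']``).  The
    foreground is ``fold >= fg_fold``; the background is every other motif of
    the shared universe, so the two partition it.
    """
    a = table_a[["motif", "avg_score"]].rename(columns={"avg_score": "avg_a"})
    b = table_b[["motif", "avg_score"]].rename(columns={"avg_score": "avg_b"})
    merged = a.merge(b, on="motif", how="inner")
    dropped = sorted(
        set(a["motif"]).symmetric_difference(set(b["motif"]))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["fold"] = merged["avg_a"] / merged["avg_b"]
    merged["foreground"] = merged["fold"] >= params.fg_fold
    merged.attrs["dropped_motifs"] = dropped
    return merged


def site_score_ratios(
    scored_a: pd.DataFrame, scored_b: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Per-site pause-score ratios A/B over sites eligible in both samples.

    Sites ineligible (NaN score) in either sample are dropped; the dropped
    count is returned alongside the ratio table.
    """
    key = ["gene_id", "e_codon_index", "motif"]
    a = scored_a[key + ["score"]].rename(columns={"score": "score_a"})
    b = scored_b[key + ["score"]].rename(columns={"score": "score_b"})
    merged = a.merge(b, on=key, how="inner")
    ok = merged["score_a"].notna() & merged["score_b"].notna() & (merged["score_b"] > 0)
    dropped = int((~ok).sum())
    merged = merged[ok].reset_index(drop=True)
    merged["ratio"] = merged["score_a"] / merged["score_b"]
    return merged, dropped


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    pvalue: float
    method: str  # "exact" | "asymptotic"


def _rank_with_ties(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled)


def _exact_mwu(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact p-value by enumerating every assignment of the pooled values.

    Tie-capable: U is computed from midranks, and the null distribution is
    the multiset of U values over all C(n, n1) labelings of the pooled
    sample.  Feasible for combined n <= ~20 (C(20,10) = 184,756 labelings).
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _rank_with_ties(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    idx = np.array(list(combinations(range(n1 + n2), n1)), dtype=np.intp)
    u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2
    eps = 1e-9
    p_le = float(np.mean(u_all <= u_obs + eps))
    p_ge = float(np.mean(u_all >= u_obs - eps))
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(
    a: Iterable[float],
    b: Iterable[float],
    alternative: str = "two-sided",
    method: str = "auto",
    max_exact_n: int = 20,
) -> MannWhitneyResult:
    """Independent two-group Mann-Whitney U test.

    ``method='auto'`` enumerates the exact null distribution when the
    combined sample size is at most ``max_exact_n`` and otherwise uses the
    tie-corrected normal approximation (scipy).  The U statistic reported is
    that of the first sample.  Degenerate case: when the tie-corrected
    variance is zero (all pooled values identical) the p-value is 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    ranks = _rank_with_ties(np.concatenate([a, b]))
    u_obs = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)
    if method == "auto":
        method = "exact" if len(a) + len(b) <= max_exact_n else "asymptotic"
    if method == "exact":
        p = _exact_mwu(a, b, alternative)
        return MannWhitneyResult(u_obs, p, "exact")
    if np.ptp(np.concatenate([a, b])) == 0:
        return MannWhitneyResult(u_obs, 1.0, "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")


def xip_score_shift_test(
    scores_a: Iterable[float], scores_b: Iterable[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test for a shift in site-level pause scores
    (or score ratios) at motif sites between two conditions/strains."""
    return mann_whitney_u(scores_a, scores_b, alternative="two-sided")


# ---------------------------------------------------------------------------
# positional residue enrichment (simplified sequence-logo statistics)


def residue_enrichment(
    foreground: Iterable[str], background: Iterable[str]
) -> pd.DataFrame:
    """Per-position (E/P/A), per-residue log-odds of foreground vs background.

    For each of the 3 positions and 20 residues: pseudocounted log2 odds
    ``log2(((fg+0.5)/(fg_n+1)) / ((bg+0.5)/(bg_n+1)))`` plus a two-sided
    binomial p-value of the foreground count given the background frequency.
    Foreground and background must be disjoint motif sets.
    """
    fg = list(foreground)
    bg = list(background)
    if not fg:
        raise ValueError("empty foreground motif set")
    if set(fg) & set(bg):
        raise ValueError("foreground and background motif sets must be disjoint")
    residues = sorted("ACDEFGHIKLMNPQRSTVWY")
    positions = ["E", "P", "A"]
    rows = []
    for pi, pos_name in enumerate(positions):
        fg_counts = pd.Series([m[pi] for m in fg]).value_counts()
        bg_counts = pd.Series([m[pi] for m in bg]).value_counts()
        for res in residues:
            fc = int(fg_counts.get(res, 0))
            bc = int(bg_counts.get(res, 0))
            f_fg = (fc + 0.5) / (len(fg) + 1)
            f_bg = (bc + 0.5) / (len(bg) + 1)
            log2_odds = float(np.log2(f_fg / f_bg))
            p_bg = bc / len(bg) if bg else 0.0
            if 0 < p_bg < 1:
                pval = float(
                    stats.binomtest(fc, len(fg), p_bg, alternative="two-sided").pvalue
                )
            else:
                pval = float(
                    stats.binomtest(
                        fc, len(fg), min(max(f_bg, 1e-12), 1 - 1e-12)
                    ).pvalue
                )
            rows.append((pos_name, res, fc, bc, log2_odds, pval))
    return pd.DataFrame(
        rows,
        columns=["position", "residue", "fg_count", "bg_count", "log2_odds", "pvalue"],
    )
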