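"""Sliding-window DMR detection.

A DMR is a maximal genomic region in which enough same-direction DMPs
co-occur within some window of at most ``window_bp`` base pairs: at least
``k_lo`` DMPs with |delta beta| >= ``delta_lo``, or at least ``k_hi`` with
|delta beta| >= ``delta_hi``.  The window is conceptually slid along the
chromosome; every window that still satisfies a criterion extends the
region, and overlapping qualifying windows are merged into a single DMR.

Formally (the contract shared by :func:`call_dmrs` and its independent
oracle :func:`brute_force_dmrs`):

1. a window is any interval of length <= ``window_bp`` whose endpoints are
   DMP positions (inclusive span, ``max - min <= window_bp``);
2. a window *qualifies*, per direction, when it contains >= ``k_lo``
   same-direction DMPs at the low threshold or >= ``k_hi`` at the high one;
3. qualifying windows of one direction are merged transitively whenever
   they overlap (share at least one position, hence any shared DMP);
4. each merged component is one DMR whose reported span is the min/max
   position of its member DMPs (same-direction DMPs at the low threshold
   inside the component).

Opposite-direction DMRs may abut but never merge.

:func:`call_dmrs` avoids window enumeration: every qualifying window
contains a *core* of k consecutive qualifying DMPs spanning <= window_bp,
and the union of all windows containing a given core is the single interval
from the leftmost DMP position >= core_end - window_bp to the rightmost DMP
position <= core_start + window_bp.  Merging those reachable intervals is
equivalent to merging the windows themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WindowCriteria",
    "DMR",
    "call_dmrs",
    "brute_force_dmrs",
    "classify_and_tally",
    "annotate_relative_location",
    "dmrs_to_frame",
]


@dataclass(frozen=True)
class WindowCriteria:
    """Window qualification thresholds (defaults: 5 DMPs at |db|>=0.15 or
    3 DMPs at |db|>=0.25 within 1 kb, same direction required)."""

    window_bp: int = 1000
    k_lo: int = 5
    delta_lo: float = 0.15
    k_hi: int = 3
    delta_hi: float = 0.25
    require_same_direction: bool = True

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not self.delta_hi > self.delta_lo:
            raise ValueError("delta_hi must exceed delta_lo")
        if self.k_hi > self.k_lo:
            raise ValueError("k_hi must be <= k_lo")
        if self.k_lo < 1 or self.k_hi < 1:
            raise ValueError("window counts must be >= 1")


@dataclass
class DMR:
    """A merged region of qualifying windows of one direction."""

    chrom: str
    start: int
    end: int
    direction: str  # "hypo" | "hyper"
    n_lo: int
    n_hi: int
    mean_delta_beta: float
    rule: str  # "lo" | "hi" | "both"
    members: pd.DataFrame = field(repr=False, default=None)
    location: str | None = None

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.direction, self.n_lo, self.n_hi, self.rule)


def _check_dmp_frame(dmps: pd.DataFrame) -> None:
    for col in ("chrom", "pos", "delta_beta"):
        if col not in dmps.columns:
            raise ValueError(f"DMP table missing column {col!r}")
    pos = dmps["pos"].to_numpy()
    chrom = dmps["chrom"].to_numpy(dtype=object)
    if len(dmps) >= 2:
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] < pos[:-1])):
            raise ValueError("DMPs must be sorted by (chromosome, position)")


def _finish_regions(chrom_dmps: pd.DataFrame, direction: str, intervals, criteria: WindowCriteria):
    """Turn merged (left, right, rules) intervals into DMR records."""
    sign = -1.0 if direction == "hypo" else 1.0
    db = chrom_dmps["delta_beta"].to_numpy()
    pos = chrom_dmps["pos"].to_numpy()
    if criteria.require_same_direction:
        dir_ok = np.sign(db) == sign
    else:
        dir_ok = np.ones(len(db), dtype=bool)
    member_lo = dir_ok & (np.abs(db) >= criteria.delta_lo)
    out = []
    for left, right, rules in intervals:
        inside = member_lo & (pos >= left) & (pos <= right)
        members = chrom_dmps[inside]
        mpos = members["pos"].to_numpy()
        n_hi = int((members["delta_beta"].abs() >= criteria.delta_hi).sum())
        mean_db = float(members["delta_beta"].mean())
        if not criteria.require_same_direction:
            direction = "hypo" if mean_db < 0 else "hyper"
        out.append(
            DMR(
                chrom=str(chrom_dmps["chrom"].iloc[0]),
                start=int(mpos.min()),
                end=int(mpos.max()),
                direction=direction,
                n_lo=int(inside.sum()),
                n_hi=n_hi,
                mean_delta_beta=mean_db,
                rule="both" if rules == {"lo", "hi"} else next(iter(rules)),
                members=members.reset_index(drop=True),
            )
        )
    return out


def _merge_intervals(tagged):
    """Merge (left, right, rule) triples by inclusive-coordinate overlap."""
    if not tagged:
        return []
    tagged = sorted(tagged, key=lambda t: (t[0], t[1]))
    merged = []
    cl, cr, crules = tagged[0][0], tagged[0][1], {tagged[0][2]}
    for left, right, rule in tagged[1:]:
        if left <= cr:  # inclusive coordinates: touching at one position overlaps
            cr = max(cr, right)
            crules.add(rule)
        else:
            merged.append((cl, cr, crules))
            cl, cr, crules = left, right, {rule}
    merged.append((cl, cr, crules))
    return merged


def call_dmrs(dmps: pd.DataFrame, criteria: WindowCriteria = WindowCriteria()) -> list[DMR]:
    """Detect DMRs from a sorted DMP table (core-interval algorithm)."""
    _check_dmp_frame(dmps)
    if len(dmps) == 0:
        return []
    out: list[DMR] = []
    for chrom, chrom_dmps in dmps.groupby("chrom", sort=False):
        chrom_dmps = chrom_dmps.reset_index(drop=True)
        all_pos = chrom_dmps["pos"].to_numpy()
        db = chrom_dmps["delta_beta"].to_numpy()
        for direction, sign in (("hypo", -1.0), ("hyper", 1.0)):
            if criteria.require_same_direction:
                dir_ok = np.sign(db) == sign
            else:
                dir_ok = np.ones(len(db), dtype=bool)
            tagged = []
            for rule, k, delta in (("lo", criteria.k_lo, criteria.delta_lo), ("hi", criteria.k_hi, criteria.delta_hi)):
                mpos = all_pos[dir_ok & (np.abs(db) >= delta)]
                if len(mpos) < k:
                    continue
                c1 = mpos[: len(mpos) - k + 1]
                c2 = mpos[k - 1 :]
                ok = (c2 - c1) <= criteria.window_bp
                for a, b in zip(c1[ok], c2[ok]):
                    # union of all qualifying windows containing core [a, b]
                    left = all_pos[np.searchsorted(all_pos, b - criteria.window_bp, side="left")]
                    right = all_pos[np.searchsorted(all_pos, a + criteria.window_bp, side="right") - 1]
                    tagged.append((int(left), int(right), rule))
            out.extend(_finish_regions(chrom_dmps, direction, _merge_intervals(tagged), criteria))
            if not criteria.require_same_direction:
                break  # directions collapse to a single pass
    out.sort(key=lambda d: (d.chrom, d.start, d.end, d.direction))
    return out


def brute_force_dmrs(dmps: pd.DataFrame, criteria: WindowCriteria = WindowCriteria()) -> list[DMR]:
    """Reference oracle: exhaustively test every DMP-endpoint window.

    Same output contract as :func:`call_dmrs`; quadratic in the number of
    DMPs per chromosome, intended for small instances.
    """
    _check_dmp_frame(dmps)
    if len(dmps) == 0:
        return []
    out: list[DMR] = []
    for chrom, chrom_dmps in dmps.groupby("chrom", sort=False):
        chrom_dmps = chrom_dmps.reset_index(drop=True)
        pos = chrom_dmps["pos"].to_numpy()
        db = chrom_dmps["delta_beta"].to_numpy()
        n = len(pos)
        for direction, sign in (("hypo", -1.0), ("hyper", 1.0)):
            if criteria.require_same_direction:
                dir_ok = np.sign(db) == sign
            else:
                dir_ok = np.ones(n, dtype=bool)
            lo = dir_ok & (np.abs(db) >= criteria.delta_lo)
            hi = dir_ok & (np.abs(db) >= criteria.delta_hi)
            cum_lo = np.concatenate([[0], np.cumsum(lo)])
            cum_hi = np.concatenate([[0], np.cumsum(hi)])
            tagged = []
            for a in range(n):
                for b in range(a, n):
                    if pos[b] - pos[a] > criteria.window_bp:
                        break
                    if cum_lo[b + 1] - cum_lo[a] >= criteria.k_lo:
                        tagged.append((int(pos[a]), int(pos[b]), "lo"))
                    if cum_hi[b + 1] - cum_hi[a] >= criteria.k_hi:
                        tagged.append((int(pos[a]), int(pos[b]), "hi"))
            out.extend(_finish_regions(chrom_dmps, direction, _merge_intervals(tagged), criteria))
            if not criteria.require_same_direction:
                break
    out.sort(key=lambda d: (d.chrom, d.start, d.end, d.direction))
    return out


def classify_and_tally(dmrs: list[DMR]) -> tuple[int, int, float]:
    """Count hypo/hyper DMRs; the hypo fraction is NaN for an empty list."""
    n_hypo = sum(1 for d in dmrs if d.direction == "hypo")
    n_hyper = sum(1 for d in dmrs if d.direction == "hyper")
    total = n_hypo + n_hyper
    fraction = round(n_hypo / total, 3) if total else float("nan")
    return n_hypo, n_hyper, fraction


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Flatten DMRs into a summary table (one row per DMR)."""
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "direction": d.direction,
                "n_lo": d.n_lo,
                "n_hi": d.n_hi,
                "mean_delta_beta": d.mean_delta_beta,
                "rule": d.rule,
                "location": d.location,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "direction", "n_lo", "n_hi", "mean_delta_beta", "rule", "location"],
    )


def annotate_relative_location(
    dmrs: list[DMR], gene_model: pd.DataFrame | None, promoter_bp: int = 2000
) -> list[DMR]:
    """Label each DMR relative to a gene model.

    ``gene_model`` rows carry (chrom, start, end, strand, feature) with
    feature in {"transcript", "exon"}, 1-based inclusive.  Labels:
    ``promoter`` (within ``promoter_bp`` upstream of a transcription start),
    ``exon``, ``intron``, ``exon-intron`` (spans a boundary) or
    ``intergenic``; precedence promoter > exon-intron > exon > intron.
    Without a gene model every DMR is labeled ``unannotated``.
    """
    if gene_model is None or len(gene_model) == 0:
        for d in dmrs:
            d.location = "unannotated"
        return dmrs
    tx = gene_model[gene_model["feature"] == "transcript"]
    ex = gene_model[gene_model["feature"] == "exon"]
    for d in dmrs:
        label = "intergenic"
        ctx = tx[tx["chrom"] == d.chrom]
        cex = ex[ex["chrom"] == d.chrom]
        # promoter: window upstream of the TSS, strand aware
        promoter = False
        for _, t in ctx.iterrows():
            if str(t.get("strand", "+")) == "-":
                p_lo, p_hi = t["end"] + 1, t["end"] + promoter_bp
            else:
                p_lo, p_hi = t["start"] - promoter_bp, t["start"] - 1
            if d.end >= p_lo and d.start <= p_hi:
                promoter = True
                break
        inside_tx = ctx[(ctx["start"] <= d.end) & (ctx["end"] >= d.start)]
        in_exon = bool(len(cex[(cex["start"] <= d.end) & (cex["end"] >= d.start)]))
        fully_exonic = bool(
            len(cex[(cex["start"] <= d.start) & (cex["end"] >= d.end)])
        )
        if promoter:
            label = "promoter"
        elif len(inside_tx):
            if in_exon and not fully_exonic:
                label = "exon-intron"
            elif fully_exonic:
                label = "exon"
            else:
                label = "intron"
        d.location = label
    return dmrs
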