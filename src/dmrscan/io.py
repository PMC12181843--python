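"""Reading and writing standard methylation-call and interval formats.

Supported per-sample call formats (auto-detected):

* Bismark-style cytosine report: headerless TSV with columns
  ``chrom, pos, strand, count_methylated, count_unmethylated, context,
  trinucleotide``.
* methylKit-style TSV: headered ``chrBase, chr, base, strand, coverage,
  freqC, freqT`` with strand F/R and percent frequencies.

Internally coordinates are 1-based inclusive on the plus-strand cytosine;
the BED boundary is the only place 0-based half-open coordinates appear.
Readers reject malformed records rather than coercing them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MethylationCallMatrix, REQUIRED_SAMPLE_COLUMNS, validate_sample_table

logger = logging.getLogger(__name__)

_BISMARK_COLS = ["chrom", "pos", "strand", "count_m", "count_u", "context", "tri"]


def _parse_one_call_file(path) -> pd.DataFrame:
    """Parse one call file to plus-strand collapsed (chrom, pos, meth, coverage)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty call file")
    fields = first.rstrip("\n").split("\t")
    is_methylkit = "chrBase" in fields or "freqC" in fields
    if is_methylkit:
        raw = pd.read_csv(path, sep="\t", dtype=str)
        needed = {"chr", "base", "strand", "coverage", "freqC"}
        if not needed.issubset(raw.columns):
            raise ValueError(f"{path}: methylKit-style file missing columns {sorted(needed - set(raw.columns))}")
        strand = raw["strand"].map({"F": "+", "R": "-"})
        if strand.isna().any():
            line = int(raw.index[strand.isna()][0]) + 2
            raise ValueError(f"{path}, line {line}: unknown strand {raw['strand'][strand.isna()].iloc[0]!r}")
        cov = pd.to_numeric(raw["coverage"], errors="coerce")
        freq = pd.to_numeric(raw["freqC"], errors="coerce")
        pos = pd.to_numeric(raw["base"], errors="coerce")
        bad = cov.isna() | freq.isna() | pos.isna() | (cov % 1 != 0) | (pos % 1 != 0)
        if bad.any():
            line = int(raw.index[bad][0]) + 2
            raise ValueError(f"{path}, line {line}: malformed record")
        meth = np.rint(cov.to_numpy() * freq.to_numpy() / 100.0).astype(np.int64)
        frame = pd.DataFrame(
            {
                "chrom": raw["chr"].astype(str),
                "pos": pos.astype(np.int64),
                "strand": strand.to_numpy(dtype=object),
                "meth": meth,
                "coverage": cov.astype(np.int64),
            }
        )
        header_offset = 2
    else:
        raw = pd.read_csv(path, sep="\t", names=_BISMARK_COLS, dtype=str, header=None)
        if raw.shape[1] != 7:
            raise ValueError(f"{path}: expected 7 tab-separated columns in a cytosine report")
        strand_ok = raw["strand"].isin(["+", "-"])
        if not strand_ok.all():
            line = int(raw.index[~strand_ok][0]) + 1
            raise ValueError(f"{path}, line {line}: unknown strand {raw['strand'][~strand_ok].iloc[0]!r}")
        pos = pd.to_numeric(raw["pos"], errors="coerce")
        cm = pd.to_numeric(raw["count_m"], errors="coerce")
        cu = pd.to_numeric(raw["count_u"], errors="coerce")
        bad = pos.isna() | cm.isna() | cu.isna() | (pos % 1 != 0) | (cm % 1 != 0) | (cu % 1 != 0)
        if bad.any():
            line = int(raw.index[bad][0]) + 1
            raise ValueError(f"{path}, line {line}: non-integer counts or position")
        frame = pd.DataFrame(
            {
                "chrom": raw["chrom"].astype(str),
                "pos": pos.astype(np.int64),
                "strand": raw["strand"].to_numpy(dtype=object),
                "meth": cm.astype(np.int64),
                "coverage": (cm + cu).astype(np.int64),
            }
        )
        # keep CpG-context rows only
        frame = frame[raw["context"].fillna("CpG").isin(["CpG", "CG"])].reset_index(drop=True)
        header_offset = 1
    if (frame["meth"] < 0).any() or (frame["coverage"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    dup = frame.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        line = int(frame.index[dup][0]) + header_offset
        raise ValueError(f"{path}, line ~{line}: duplicate (chrom, pos, strand) record")
    # strand collapse: a minus-strand call at pos p belongs to the CpG whose
    # plus-strand C sits at p-1.  Already-collapsed (all '+') input is a
    # fixed point of this transform.
    minus = frame["strand"] == "-"
    frame.loc[minus, "pos"] = frame.loc[minus, "pos"] - 1
    if (frame["pos"] < 1).any():
        raise ValueError(f"{path}: minus-strand call at position 1 cannot be collapsed")
    out = (
        frame.groupby(["chrom", "pos"], as_index=False)[["meth", "coverage"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def read_cytosine_report(paths: Sequence, sample_ids: Sequence[str] | None = None) -> MethylationCallMatrix:
    """Read one call file per sample into a :class:`MethylationCallMatrix`.

    Plus/minus strand calls at the same CpG dinucleotide are summed onto the
    plus-strand cytosine position; the site list is the union across samples
    and missing cells get coverage 0.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    if sample_ids is None:
        sample_ids = [p.name.split(".")[0] for p in paths]
    sample_ids = [str(s) for s in sample_ids]
    if len(sample_ids) != len(paths):
        raise ValueError("sample_ids must match paths one-to-one")
    pieces = []
    for path, sid in zip(paths, sample_ids):
        one = _parse_one_call_file(path)
        one.insert(0, "sample_id", sid)
        pieces.append(one)
    long = pd.concat(pieces, ignore_index=True)
    return MethylationCallMatrix.from_long(long, sample_ids)


def write_cytosine_report(matrix: MethylationCallMatrix, sample_id: str, path) -> None:
    """Write one sample's calls as a Bismark-style cytosine report.

    Rows are plus-strand only (the matrix is already strand-collapsed);
    coverage-0 sites are omitted and round-trip back to "missing".
    """
    j = matrix.sample_index(sample_id)
    keep = matrix.coverage[:, j] > 0
    cov = matrix.coverage[keep, j]
    meth = matrix.meth[keep, j]
    frame = pd.DataFrame(
        {
            "chrom": matrix.chroms[keep],
            "pos": matrix.positions[keep],
            "strand": "+",
            "count_m": meth,
            "count_u": cov - meth,
            "context": "CpG",
            "tri": "CGN",
        }
    )
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_sample_table(sheet)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    validate_sample_table(samples)[list(REQUIRED_SAMPLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def filter_min_coverage(
    matrix: MethylationCallMatrix,
    min_cov: int = 10,
    mode: str = "all_samples",
    samples: pd.DataFrame | None = None,
) -> MethylationCallMatrix:
    """Keep sites meeting the minimum-coverage rule.

    ``mode="all_samples"`` (default) keeps a site only when every sample has
    coverage >= ``min_cov``; ``mode="per_group_all"`` applies the same rule
    within each of the CN/AD groups given by ``samples`` (samples outside
    either group are ignored).
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if mode == "all_samples":
        keep = (matrix.coverage >= min_cov).all(axis=1)
    elif mode == "per_group_all":
        if samples is None:
            raise ValueError("mode='per_group_all' requires a sample table")
        from .core import group_masks

        cn, ad = group_masks(samples, matrix.sample_ids)
        keep = (matrix.coverage[:, cn] >= min_cov).all(axis=1) & (matrix.coverage[:, ad] >= min_cov).all(axis=1)
    else:
        raise ValueError(f"unknown coverage filter mode {mode!r}")
    logger.info("coverage filter (>=%d, %s): retained %d / %d sites", min_cov, mode, int(keep.sum()), matrix.n_sites)
    return matrix.subset_sites(keep)


def _item_coords(items):
    """(chroms, starts, ends) arrays for a matrix, a coordinate frame or DMR list."""
    from .dmr import DMR  # local import to avoid a cycle

    if isinstance(items, MethylationCallMatrix):
        return items.chroms, items.positions, items.positions
    if isinstance(items, pd.DataFrame):
        chroms = items["chrom"].to_numpy(dtype=object)
        if "pos" in items.columns:
            pos = items["pos"].to_numpy()
            return chroms, pos, pos
        return chroms, items["start"].to_numpy(), items["end"].to_numpy()
    if isinstance(items, (list, tuple)) and all(isinstance(d, DMR) for d in items):
        chroms = np.array([d.chrom for d in items], dtype=object)
        return chroms, np.array([d.start for d in items]), np.array([d.end for d in items])
    raise TypeError(f"cannot extract coordinates from {type(items).__name__}")


def exclude_regions(items, regions: pd.DataFrame | None = None, chromosomes: Iterable[str] | None = None):
    """Drop items on the named chromosomes or overlapping the given regions.

    ``regions`` uses internal 1-based inclusive (chrom, start, end) records.
    Returns ``(filtered_items, n_removed)``.
    """
    chroms, starts, ends = _item_coords(items)
    drop = np.zeros(len(chroms), dtype=bool)
    if chromosomes is not None:
        drop |= np.isin(chroms.astype(str), list(chromosomes))
    if regions is not None and len(regions):
        for _, reg in regions.iterrows():
            drop |= (chroms.astype(str) == str(reg["chrom"])) & (ends >= reg["start"]) & (starts <= reg["end"])
    n_removed = int(drop.sum())
    keep = ~drop
    if isinstance(items, MethylationCallMatrix):
        return items.subset_sites(keep), n_removed
    if isinstance(items, pd.DataFrame):
        return items[keep].reset_index(drop=True), n_removed
    return [d for d, k in zip(items, keep) if k], n_removed


def write_bed(dmrs_or_regions, path) -> None:
    """Write DMRs or regions as BED6 (0-based half-open).

    Score is mean |delta beta| x 1000 capped at 1000 for DMRs, 0 otherwise.
    """
    from .dmr import DMR

    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    records = dmrs_or_regions
    if isinstance(records, pd.DataFrame):
        records = list(records.itertuples(index=False))
    for i, rec in enumerate(records):
        if isinstance(rec, DMR):
            chrom, start1, end1 = rec.chrom, rec.start, rec.end
            name = f"DMR_{i + 1}_{rec.direction}"
            score = min(1000, int(round(abs(rec.mean_delta_beta) * 1000)))
        else:
            chrom, start1, end1 = rec.chrom, rec.start, rec.end
            name = getattr(rec, "name", None) or f"region_{i + 1}"
            score = int(getattr(rec, "score", 0))
        if start1 - 1 < 0:
            raise ValueError(f"coordinate conversion produced negative start for {name}")
        lines.append(f"{chrom}\t{start1 - 1}\t{end1}\t{name}\t{score}\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into internal 1-based inclusive regions.

    Returns columns chrom, start, end (1-based inclusive), name, score.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}, line {lineno}: fewer than 3 BED columns")
        start0, end0 = int(parts[1]), int(parts[2])
        if start0 < 0 or end0 <= start0:
            raise ValueError(f"{path}, line {lineno}: invalid interval [{start0}, {end0})")
        rows.append(
            {
                "chrom": parts[0],
                "start": start0 + 1,
                "end": end0,
                "name": parts[3] if len(parts) > 3 else f"region_{len(rows) + 1}",
                "score": float(parts[4]) if len(parts) > 4 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
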