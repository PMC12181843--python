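"""Core in-memory containers for methylation call data.

The central object is :class:`MethylationCallMatrix`, a per-CpG x per-sample
pair of integer arrays (methylated count, total coverage) with genomic
coordinates.  Coordinates are 1-based inclusive and refer to the cytosine of
the CpG dinucleotide on the plus strand; minus-strand calls are collapsed
onto that position by the readers in :mod:`dmrscan.io`.  A missing site in a
sample is represented as coverage 0, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns a sample sheet must provide.
REQUIRED_SAMPLE_COLUMNS = ("sample_id", "group", "sex", "age", "apoe_e4", "cohort")

#: Phenotype labels: cognitively normal controls and Alzheimer's disease cases.
GROUPS = ("CN", "AD")


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and return it with normalized dtypes.

    Requires the columns in :data:`REQUIRED_SAMPLE_COLUMNS`; ``group`` must be
    CN/AD, ``apoe_e4`` an allele count in {0, 1, 2} and ``age`` positive.
    """
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    out = samples.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    bad_group = set(out["group"].unique()) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    out["age"] = out["age"].astype(float)
    if (out["age"] <= 0).any():
        raise ValueError("ages must be positive")
    out["apoe_e4"] = out["apoe_e4"].astype(int)
    if not out["apoe_e4"].isin([0, 1, 2]).all():
        raise ValueError("apoe_e4 must be an allele count in {0, 1, 2}")
    return out


def _check_sorted(chroms: np.ndarray, positions: np.ndarray) -> None:
    """Positions must be strictly increasing within each chromosome block."""
    if len(positions) < 2:
        return
    same = chroms[1:] == chroms[:-1]
    if np.any(same & (positions[1:] <= positions[:-1])):
        raise ValueError("site positions must be strictly increasing within a chromosome")
    # a chromosome may not appear in two separate blocks
    order = pd.unique(chroms)
    seen = set()
    prev = None
    for c in chroms:
        if c != prev:
            if c in seen:
                raise ValueError(f"chromosome {c!r} appears in non-contiguous blocks")
            seen.add(c)
            prev = c
    del order


@dataclass
class MethylationCallMatrix:
    """Multi-sample methylation call matrix.

    Parameters
    ----------
    chroms, positions
        Per-site chromosome name and 1-based plus-strand cytosine position,
        sorted by (chromosome block, position).
    meth, coverage
        ``(n_sites, n_samples)`` integer arrays with
        ``0 <= meth <= coverage`` elementwise.
    sample_ids
        Column labels, aligned with a sample sheet's ``sample_id``.
    """

    chroms: np.ndarray
    positions: np.ndarray
    meth: np.ndarray
    coverage: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.positions)
        if self.chroms.shape != (n,):
            raise ValueError("chroms and positions must have the same length")
        if self.meth.shape != (n, len(self.sample_ids)) or self.coverage.shape != self.meth.shape:
            raise ValueError("meth/coverage must be (n_sites, n_samples)")
        if (self.positions < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")
        if (self.coverage < 0).any() or (self.meth < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.meth > self.coverage).any():
            raise ValueError("methylated count exceeds coverage")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        _check_sorted(self.chroms, self.positions)

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "pos": self.positions})

    # -- derived quantities ---------------------------------------------
    def rates(self) -> np.ndarray:
        """Per-cell methylation rate meC/(meC+C); NaN where coverage is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.meth / self.coverage
        return np.where(self.coverage > 0, r, np.nan)

    # -- subsetting ------------------------------------------------------
    def subset_sites(self, mask: np.ndarray) -> "MethylationCallMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return MethylationCallMatrix(
            self.chroms[idx], self.positions[idx], self.meth[idx], self.coverage[idx], list(self.sample_ids)
        )

    def subset_samples(self, sample_ids) -> "MethylationCallMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [lookup[str(s)] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return MethylationCallMatrix(
            self.chroms, self.positions, self.meth[:, idx], self.coverage[:, idx], [str(s) for s in sample_ids]
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(str(sample_id))
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    # -- comparison ------------------------------------------------------
    def equals(self, other: "MethylationCallMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.meth, other.meth)
            and np.array_equal(self.coverage, other.coverage)
        )

    @classmethod
    def from_long(cls, frame: pd.DataFrame, sample_ids) -> "MethylationCallMatrix":
        """Assemble a matrix from long-format calls.

        ``frame`` columns: sample_id, chrom, pos, meth, coverage.  Sites are
        the union across samples; absent cells get coverage 0.
        """
        sample_ids = [str(s) for s in sample_ids]
        sites = (
            frame[["chrom", "pos"]]
            .drop_duplicates()
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        key = pd.MultiIndex.from_frame(sites)
        n = len(sites)
        meth = np.zeros((n, len(sample_ids)), dtype=np.int64)
        cov = np.zeros_like(meth)
        row_of = pd.Series(np.arange(n), index=key)
        for j, sid in enumerate(sample_ids):
            sub = frame[frame["sample_id"] == sid]
            rows = row_of.loc[pd.MultiIndex.from_frame(sub[["chrom", "pos"]])].to_numpy()
            meth[rows, j] = sub["meth"].to_numpy()
            cov[rows, j] = sub["coverage"].to_numpy()
        return cls(sites["chrom"].to_numpy(dtype=object), sites["pos"].to_numpy(), meth, cov, sample_ids)


def group_masks(samples: pd.DataFrame, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (CN, AD) masks over matrix columns, aligned by sample id."""
    samples = validate_sample_table(samples)
    by_id = samples.set_index("sample_id")["group"]
    missing = [s for s in sample_ids if s not in by_id.index]
    if missing:
        raise ValueError(f"samples absent from sample table: {missing}")
    groups = np.array([by_id[s] for s in sample_ids], dtype=object)
    return groups == "CN", groups == "AD"
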