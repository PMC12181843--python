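"""Synthetic methylation-count cohorts with implanted DMRs.

The generator emulates the statistical structure of two-group (CN vs AD)
targeted bisulfite data:

* per-CpG baseline methylation drawn from a low/intermediate/high beta
  mixture (most validated disease DMRs sit in intermediately methylated
  regions, so the intermediate band carries 40% of CpGs by default);
* per-cell counts ``meth ~ BetaBinomial(coverage, mu, rho)`` with
  between-sample overdispersion ``rho`` (``rho=0`` reduces to binomial);
* coverage negative-binomial around ~30x for capture-sequencing-like
  discovery cohorts and Poisson around ~1000x for amplicon-like validation
  cohorts;
* implanted DMRs: contiguous clusters of CpGs whose AD-sample means are
  shifted by a configurable signed delta-beta (additively on the beta scale
  with clipping by default; a logit-scale option exists);
* sample covariates (sex, age, APOE e4 allele count) drawn from
  configurable cohort demographics.

Identical config + seed reproduces byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .core import MethylationCallMatrix, validate_sample_table

__all__ = [
    "TrueDMRSpec",
    "DemographicParams",
    "BaselineMixture",
    "CoverageModel",
    "SyntheticConfig",
    "COHORT1",
    "COHORT2",
    "COHORT3",
    "sample_covariates",
    "simulate_cohort",
    "simulate_amplicon_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class TrueDMRSpec:
    """An implanted DMR: ``n_cpgs_affected`` CpGs evenly spaced across the
    1-based inclusive span, shifted by ``true_delta_beta`` (AD minus CN;
    negative = hypomethylated in AD) in AD samples only."""

    chrom: str
    start: int
    end: int
    n_cpgs_affected: int
    true_delta_beta: float

    def __post_init__(self) -> None:
        if self.n_cpgs_affected < 1:
            raise ValueError(f"DMR spec {self.chrom}:{self.start}-{self.end} contains zero CpGs")
        if self.end < self.start:
            raise ValueError("DMR span end < start")
        if self.n_cpgs_affected > 1 and (self.end - self.start) < 2 * (self.n_cpgs_affected - 1):
            raise ValueError(
                f"DMR spec {self.chrom}:{self.start}-{self.end} too short for "
                f"{self.n_cpgs_affected} CpGs (CpGs are >= 2 bp apart)"
            )
        if self.true_delta_beta == 0:
            raise ValueError("true_delta_beta must be nonzero")

    @property
    def direction(self) -> str:
        return "hypo" if self.true_delta_beta < 0 else "hyper"

    def positions(self) -> np.ndarray:
        pos = np.unique(np.round(np.linspace(self.start, self.end, self.n_cpgs_affected)).astype(np.int64))
        if len(pos) != self.n_cpgs_affected:
            raise ValueError(f"DMR spec {self.chrom}:{self.start}-{self.end}: positions collide")
        return pos


# Demographics follow the three study cohorts: per-group age mean/SD (years),
# male fraction, and APOE e4 genotype probabilities (homozygote,
# heterozygote, non-carrier).
@dataclass(frozen=True)
class DemographicParams:
    age_mean_cn: float = 70.3
    age_sd_cn: float = 2.4
    age_mean_ad: float = 71.2
    age_sd_ad: float = 4.0
    male_frac_cn: float = 0.5
    male_frac_ad: float = 0.5
    apoe_probs_cn: tuple = (1 / 48, 5 / 48, 42 / 48)
    apoe_probs_ad: tuple = (5 / 48, 30 / 48, 13 / 48)

    def __post_init__(self) -> None:
        for probs in (self.apoe_probs_cn, self.apoe_probs_ad):
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ValueError("APOE genotype probabilities must be 3 non-negative values")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("APOE genotype probabilities must sum to 1 (tolerance 1e-9)")
        for frac in (self.male_frac_cn, self.male_frac_ad):
            if not 0 <= frac <= 1:
                raise ValueError("male fraction must be in [0, 1]")


COHORT1 = DemographicParams(73.3, 3.2, 74.4, 6.4, 4 / 12, 2 / 12, (0.0, 1 / 12, 11 / 12), (2 / 12, 8 / 12, 2 / 12))
COHORT2 = DemographicParams()
COHORT3 = DemographicParams(69.8, 3.0, 71.8, 2.6, 0.5, 0.5, (1 / 48, 10 / 48, 37 / 48), (6 / 48, 19 / 48, 23 / 48))


@dataclass(frozen=True)
class BaselineMixture:
    """Low / intermediate / high baseline methylation mixture."""

    weights: tuple = (0.3, 0.4, 0.3)
    low: tuple = (2.0, 38.0)     # Beta params, mean ~0.05
    mid: tuple = (8.0, 8.0)      # intermediate band around 0.5
    high: tuple = (38.0, 2.0)    # mean ~0.95

    def __post_init__(self) -> None:
        if len(self.weights) != 3 or any(w < 0 for w in self.weights) or abs(sum(self.weights) - 1) > 1e-9:
            raise ValueError("mixture weights must be 3 non-negative values summing to 1")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        comp = rng.choice(3, size=size, p=list(self.weights))
        params = np.array([self.low, self.mid, self.high])
        return rng.beta(params[comp, 0], params[comp, 1])


@dataclass(frozen=True)
class CoverageModel:
    """Per-cell sequencing depth: ``nb`` (mean + dispersion, variance
    mean + dispersion*mean^2), ``poisson`` or ``fixed``."""

    kind: str = "nb"
    mean: float = 30.0
    dispersion: float = 0.3

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(shape, int(round(self.mean)), dtype=np.int64)
        if self.kind == "poisson":
            return rng.poisson(self.mean, size=shape).astype(np.int64)
        if self.kind == "nb":
            size_param = 1.0 / self.dispersion
            p = size_param / (size_param + self.mean)
            return rng.negative_binomial(size_param, p, size=shape).astype(np.int64)
        raise ValueError(f"unknown coverage model {self.kind!r}")


DISCOVERY_COVERAGE = CoverageModel("nb", 30.0, 0.3)
AMPLICON_COVERAGE = CoverageModel("poisson", 1000.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort; ``seed`` is mandatory."""

    n_cn: int
    n_ad: int
    n_cpgs: int
    seed: int
    chrom_layout: tuple = (("chr1", 150.0), ("chr2", 150.0))
    baseline: BaselineMixture = BaselineMixture()
    rho: float = 0.02
    coverage: CoverageModel = DISCOVERY_COVERAGE
    dmr_specs: tuple = ()
    age_effect: float = 0.0
    demographics: DemographicParams = COHORT2
    sex_chrom_fraction: float = 0.0
    logit_scale_effects: bool = False
    cohort: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_cn < 0 or self.n_ad < 0 or self.n_cpgs < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.rho < 1:
            raise ValueError("dispersion rho must be in [0, 1)")
        if not 0 <= self.sex_chrom_fraction < 1:
            raise ValueError("sex_chrom_fraction must be in [0, 1)")
        spans = sorted((s.chrom, s.start, s.end) for s in self.dmr_specs)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            if c1 == c2 and s2 <= e1:
                raise ValueError("DMR spans must not overlap")


def sample_covariates(
    n_cn: int,
    n_ad: int,
    params: DemographicParams = COHORT2,
    seed: int = 0,
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Draw a sample sheet (id, group, sex, age, apoe_e4, cohort).

    Ages are normal per group (floored at 1 year), sex Bernoulli at the
    per-group male fraction, and the APOE e4 allele count is drawn from the
    per-group genotype probabilities (homozygote=2, heterozygote=1,
    non-carrier=0).
    """
    if n_cn < 0 or n_ad < 0:
        raise ValueError("sample counts must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, age_mean, age_sd, male_frac, apoe_probs in (
        ("CN", n_cn, params.age_mean_cn, params.age_sd_cn, params.male_frac_cn, params.apoe_probs_cn),
        ("AD", n_ad, params.age_mean_ad, params.age_sd_ad, params.male_frac_ad, params.apoe_probs_ad),
    ):
        ages = np.maximum(rng.normal(age_mean, age_sd, size=n), 1.0)
        sexes = np.where(rng.random(n) < male_frac, "male", "female")
        apoe = rng.choice([2, 1, 0], size=n, p=list(apoe_probs))
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{cohort}_{group}_{i + 1:03d}",
                    "group": group,
                    "sex": sexes[i],
                    "age": round(float(ages[i]), 1),
                    "apoe_e4": int(apoe[i]),
                    "cohort": cohort,
                }
            )
    table = pd.DataFrame(rows, columns=["sample_id", "group", "sex", "age", "apoe_e4", "cohort"])
    return validate_sample_table(table) if len(table) else table


def _layout_positions(config: SyntheticConfig, rng: np.random.Generator):
    """Background CpG positions per chromosome, avoiding DMR spans."""
    layout = list(config.chrom_layout)
    fractions = [(1.0 - config.sex_chrom_fraction) / len(layout)] * len(layout)
    if config.sex_chrom_fraction > 0:
        layout += [("chrX", layout[0][1]), ("chrY", layout[0][1])]
        fractions += [config.sex_chrom_fraction * 0.8, config.sex_chrom_fraction * 0.2]
    chroms, positions = [], []
    for (chrom, spacing), frac in zip(layout, fractions):
        n = int(round(config.n_cpgs * frac))
        gaps = np.maximum(np.round(rng.exponential(max(spacing - 2.0, 0.0), size=n)), 0).astype(np.int64) + 2
        pos = 10_000 + np.cumsum(gaps)
        spans = [(s.start, s.end) for s in config.dmr_specs if s.chrom == chrom]
        for lo, hi in spans:
            pos = pos[(pos < lo) | (pos > hi)]
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
    return layout, chroms, positions


def _betabinom_counts(rng: np.random.Generator, coverage: np.ndarray, mu: np.ndarray, rho: float) -> np.ndarray:
    if rho == 0:
        return rng.binomial(coverage, mu)
    s = (1.0 - rho) / rho
    interior = (mu > 0) & (mu < 1)
    p = np.where(interior, mu, 0.5)
    p = rng.beta(np.maximum(p * s, 1e-12), np.maximum((1.0 - p) * s, 1e-12))
    p = np.where(interior, p, mu)
    return rng.binomial(coverage, p)


def _simulate_counts(config: SyntheticConfig, chroms, positions, samples, rng):
    """Shared generative core: coverage, mu per cell, beta-binomial counts."""
    chroms = np.concatenate(chroms) if isinstance(chroms, list) else chroms
    positions = np.concatenate(positions) if isinstance(positions, list) else positions
    n_sites, n_samples = len(positions), len(samples)
    pi = config.baseline.draw(rng, n_sites)
    delta = np.zeros(n_sites)
    for spec in config.dmr_specs:
        inside = (chroms == spec.chrom) & (positions >= spec.start) & (positions <= spec.end)
        delta[inside] = spec.true_delta_beta
    is_ad = (samples["group"] == "AD").to_numpy()
    ages = samples["age"].to_numpy(dtype=float)
    age_dev = ages - ages.mean() if n_samples else ages
    if config.logit_scale_effects:
        eta = special.logit(np.clip(pi, 1e-6, 1 - 1e-6))[:, None] + np.outer(delta, is_ad.astype(float)) * 4.0
        mu = special.expit(eta + config.age_effect * age_dev[None, :] * 4.0)
    else:
        mu = pi[:, None] + np.outer(delta, is_ad.astype(float)) + config.age_effect * age_dev[None, :]
        mu = np.clip(mu, 0.0, 1.0)
    coverage = config.coverage.draw(rng, (n_sites, n_samples))
    meth = _betabinom_counts(rng, coverage, mu, config.rho)
    return MethylationCallMatrix(chroms, positions, meth, coverage, list(samples["sample_id"]))


def simulate_cohort(config: SyntheticConfig):
    """Simulate a discovery-style cohort.

    Returns ``(matrix, sample_table, truth)`` where ``truth`` is the list of
    implanted :class:`TrueDMRSpec` (exactly ``config.dmr_specs``).  CpGs
    inside each spec span are the spec's evenly spaced positions; background
    CpGs never fall inside a span.
    """
    rng = np.random.default_rng(config.seed)
    samples = sample_covariates(
        config.n_cn, config.n_ad, config.demographics, seed=int(rng.integers(2**31 - 1)), cohort=config.cohort
    )
    layout, chroms, positions = _layout_positions(config, rng)
    layout_chroms = {c for c, _ in layout}
    for spec in config.dmr_specs:
        if spec.chrom not in layout_chroms:
            raise ValueError(f"DMR spec on {spec.chrom} but layout has no such chromosome")
        chroms.append(np.full(spec.n_cpgs_affected, spec.chrom, dtype=object))
        positions.append(spec.positions())
    order_frame = pd.DataFrame({"chrom": np.concatenate(chroms), "pos": np.concatenate(positions)})
    order_frame = order_frame.drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")
    matrix = _simulate_counts(
        config,
        order_frame["chrom"].to_numpy(dtype=object),
        order_frame["pos"].to_numpy(),
        samples,
        rng,
    )
    return matrix, samples, list(config.dmr_specs)


def simulate_amplicon_cohort(config: SyntheticConfig, regions: pd.DataFrame, seed: int | None = None):
    """Simulate an amplicon-style validation cohort restricted to regions.

    ``regions`` rows carry 1-based inclusive (chrom, start, end) and
    optionally ``n_cpgs`` (CpGs evenly spaced across the region; default
    derived from the region length at ~1 CpG / 20 bp, minimum 1).  The
    generative model is identical to :func:`simulate_cohort`; effects come
    from ``config.dmr_specs`` overlapping the regions.
    """
    if regions is None or len(regions) == 0:
        raise ValueError("regions list must be nonempty")
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    samples = sample_covariates(
        cfg.n_cn, cfg.n_ad, cfg.demographics, seed=int(rng.integers(2**31 - 1)), cohort=cfg.cohort
    )
    chroms, positions = [], []
    for _, reg in regions.iterrows():
        n = int(reg["n_cpgs"]) if "n_cpgs" in regions.columns and not pd.isna(reg.get("n_cpgs")) else max(
            1, int((reg["end"] - reg["start"] + 1) // 20)
        )
        if n < 1:
            raise ValueError(f"region {reg['chrom']}:{reg['start']}-{reg['end']} contains no CpGs")
        pos = np.unique(np.round(np.linspace(reg["start"], reg["end"], n)).astype(np.int64))
        if len(pos) != n:
            raise ValueError(f"region {reg['chrom']}:{reg['start']}-{reg['end']} too short for {n} CpGs")
        chroms.append(np.full(n, str(reg["chrom"]), dtype=object))
        positions.append(pos)
    frame = pd.DataFrame({"chrom": np.concatenate(chroms), "pos": np.concatenate(positions)})
    frame = frame.drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")
    matrix = _simulate_counts(
        cfg, frame["chrom"].to_numpy(dtype=object), frame["pos"].to_numpy(), samples, rng
    )
    return matrix, samples


def write_cohort(outdir, matrix: MethylationCallMatrix, samples: pd.DataFrame, truth=()) -> dict:
    """Write a cohort in the formats the readers consume.

    One Bismark-style cytosine report per sample, a TSV sample sheet, and a
    BED of implanted DMR spans.  Returns the written paths.
    """
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    call_paths = []
    for sid in matrix.sample_ids:
        path = outdir / f"{sid}.cov.txt"
        mio.write_cytosine_report(matrix, sid, path)
        call_paths.append(path)
    sheet_path = outdir / "samples.tsv"
    mio.write_sample_sheet(samples, sheet_path)
    truth_path = None
    if truth:
        truth_path = outdir / "truth_dmrs.bed"
        truth_frame = pd.DataFrame(
            [
                {"chrom": s.chrom, "start": s.start, "end": s.end, "name": f"true_{i+1}_{s.direction}", "score": 0}
                for i, s in enumerate(truth)
            ]
        )
        mio.write_bed(truth_frame, truth_path)
    return {"calls": call_paths, "samples": sheet_path, "truth": truth_path}
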