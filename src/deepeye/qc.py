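"""Site-level variant quality control.

Reproduces a bcftools-style hard-filtering stage for multi-sample variant
calls: mapping-quality rules, missingness, excess heterozygosity, strand
bias, allele balance in heterozygotes, and a per-site *depth deviation*
score that targets collapsed duplications (sites where read depth is
systematically elevated across samples).  Strand-bias and excess-het
statistics are consumed as precomputed per-site INFO fields; recomputing
them would require raw alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthMatrix",
    "SiteFilterConfig",
    "SiteQCReport",
    "depth_deviation",
    "allele_balance_test",
    "apply_site_filters",
    "normalized_region_coverage",
]


@dataclass
class DepthMatrix:
    """Read depth per sample (rows) x site (columns).

    ``sample_mean`` / ``sample_sd`` are the *genome-wide* per-sample moments
    used to standardize the focal-site depth; by default they are computed
    from the matrix itself but they may be supplied (e.g. from a larger
    callset than the sites carried here).
    """

    depths: np.ndarray
    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    sample_mean: np.ndarray | None = None
    sample_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.depths.ndim != 2 or self.depths.shape[0] != len(self.samples):
            raise ValueError("depths must be (n_samples, n_sites)")
        if self.depths.shape[1] != self.pos.size:
            raise ValueError("one position per site column required")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")
        if self.sample_mean is None:
            self.sample_mean = self.depths.mean(axis=1)
        else:
            self.sample_mean = np.asarray(self.sample_mean, dtype=float)
        if self.sample_sd is None:
            self.sample_sd = self.depths.std(axis=1, ddof=0)
        else:
            self.sample_sd = np.asarray(self.sample_sd, dtype=float)

    @property
    def n_sites(self) -> int:
        return self.depths.shape[1]


@dataclass
class SiteFilterConfig:
    """Thresholds of the seven site filters (defaults as used in practice
    for cichlid whole-genome callsets).

    A site FAILS a rule when:
      mq        : MQ < mq_min
      mq0f      : MQ0F > mq0f_max
      missing   : fraction missing genotypes > missing_max
      exchet    : excess-het statistic < exchet_min
      strandbias: strand-bias P < strandbias_p
      ab        : pooled heterozygote allele-balance P < ab_p
      dd        : depth deviation > dd_max (strict)
    """

    mq_min: float = 50.0
    mq0f_max: float = 0.10
    missing_max: float = 0.20
    exchet_min: float = 0.2
    strandbias_p: float = 0.001
    ab_p: float = 0.01
    dd_max: float = 1.5
    dd_absolute: bool = False  # use |z| instead of signed mean z
    on_missing_info: str = "skip"  # or "error"


@dataclass
class SiteQCReport:
    """Per-site pass/fail bookkeeping for one filtering run."""

    passed: np.ndarray  # bool per site
    failing_rules: list[list[str]]  # per site, names of failed rules
    rule_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.passed.sum())

    @property
    def n_failed(self) -> int:
        return int((~self.passed).sum())


def depth_deviation(
    depths: DepthMatrix, site: int | None = None, absolute: bool = False
) -> float | np.ndarray:
    """Depth-deviation score: mean across samples of the per-sample z-score
    of the focal-site depth against that sample's genome-wide depth.

    Signed by default (positive = excess depth, the duplication signature);
    ``absolute=True`` averages |z| instead.

    Parameters
    ----------
    site
        Column index; when None, scores for all sites are returned.
    """
    sd = depths.sample_sd
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(
            f"zero depth standard deviation for sample(s) "
            f"{[depths.samples[i] for i in bad]}"
        )
    d = depths.depths if site is None else depths.depths[:, [site]]
    z = (d - depths.sample_mean[:, None]) / sd[:, None]
    if absolute:
        z = np.abs(z)
    score = z.mean(axis=0)
    return float(score[0]) if site is not None else score


def allele_balance_test(het_allele_depths) -> float:
    """Exact two-sided binomial test of pooled ref/alt read counts across
    heterozygous calls against an expectation of 0.5.

    Returns NaN (rule skipped) when there are no heterozygotes or no reads.
    """
    pairs = np.atleast_2d(np.asarray(het_allele_depths, dtype=np.int64))
    if pairs.size == 0:
        return float("nan")
    ref = int(pairs[:, 0].sum())
    alt = int(pairs[:, 1].sum())
    n = ref + alt
    if n == 0:
        return float("nan")
    return float(stats.binomtest(ref, n, 0.5, alternative="two-sided").pvalue)


#: rule evaluation order; report counts are keyed by these names
RULES = ("biallelic", "mq", "mq0f", "missing", "exchet", "strandbias", "ab", "dd")


def apply_site_filters(
    sites: pd.DataFrame,
    depths: DepthMatrix | None,
    config: SiteFilterConfig | None = None,
) -> tuple[pd.DataFrame, SiteQCReport]:
    """Apply the seven site filters plus the biallelic-SNP requirement.

    Parameters
    ----------
    sites
        One row per site with columns among: ``chrom, pos, n_alleles,
        mq, mq0f, missing_frac, exchet, strandbias_p, ab_p``.  ``ab_p`` may
        be NaN (no heterozygotes: rule skipped for that site).
    depths
        Aligned DepthMatrix (same site order) for the depth-deviation rule;
        None skips the rule (if configured to skip).

    Returns
    -------
    (retained sites DataFrame, SiteQCReport)
    """
    config = config or SiteFilterConfig()
    n = len(sites)
    failing: list[list[str]] = [[] for _ in range(n)]

    def _col(name):
        if name in sites.columns:
            return sites[name].to_numpy(dtype=float)
        if config.on_missing_info == "error":
            raise KeyError(f"required INFO field '{name}' missing")
        warnings.warn(f"INFO field '{name}' missing; rule skipped")
        return None

    def _mark(rule: str, fails: np.ndarray) -> None:
        for i in np.flatnonzero(fails):
            failing[i].append(rule)

    if "n_alleles" in sites.columns:
        _mark("biallelic", sites["n_alleles"].to_numpy() != 2)

    mq = _col("mq")
    if mq is not None:
        _mark("mq", mq < config.mq_min)
    mq0f = _col("mq0f")
    if mq0f is not None:
        _mark("mq0f", mq0f > config.mq0f_max)
    miss = _col("missing_frac")
    if miss is not None:
        _mark("missing", miss > config.missing_max)
    exchet = _col("exchet")
    if exchet is not None:
        _mark("exchet", exchet < config.exchet_min)
    sbp = _col("strandbias_p")
    if sbp is not None:
        _mark("strandbias", sbp < config.strandbias_p)
    abp = _col("ab_p")
    if abp is not None:
        with np.errstate(invalid="ignore"):
            _mark("ab", abp < config.ab_p)  # NaN compares False: rule skipped

    if depths is not None:
        dd = depth_deviation(depths, absolute=config.dd_absolute)
        _mark("dd", np.asarray(dd) > config.dd_max)

    passed = np.array([len(f) == 0 for f in failing])
    counts = {r: sum(r in f for f in failing) for r in RULES}
    report = SiteQCReport(passed=passed, failing_rules=failing, rule_counts=counts)
    return sites.loc[passed].reset_index(drop=True), report


def normalized_region_coverage(
    depths: DepthMatrix, chrom: str, start: int, end: int, flag_ratio: float = 1.5
) -> pd.DataFrame:
    """Per-sample ratio of median in-region depth to median genome-wide depth.

    Used to screen a locus for an unresolved duplication: samples with
    ratio > ``flag_ratio`` are flagged as duplication-suspect (reporting
    only, nothing is filtered).
    """
    in_region = (depths.chrom == chrom) & (depths.pos >= start) & (depths.pos <= end)
    if not in_region.any():
        raise ValueError(f"region {chrom}:{start}-{end} overlaps no site with depth data")
    region_med = np.median(depths.depths[:, in_region], axis=1)
    genome_med = np.median(depths.depths, axis=1)
    if np.any(genome_med == 0):
        raise ValueError("a sample has zero median genome-wide depth")
    ratio = region_med / genome_med
    return pd.DataFrame(
        {
            "sample": depths.samples,
            "region_median": region_med,
            "genome_median": genome_med,
            "ratio": ratio,
            "duplication_suspect": ratio > flag_ratio,
        }
    )
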