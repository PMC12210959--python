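"""Haplotype-based selection statistics: EHH, iHH, iHS, site-EHH/iES and
XP-EHH, plus an empirical null built from randomly placed genomic windows.

Definitions
-----------
EHH(x) for a core allele is the probability that two randomly drawn
carrier haplotypes are identical over all markers between the core and
distance x:

    EHH(x) = sum_k n_k (n_k - 1) / (n_c (n_c - 1))

over the distinct extended haplotypes k among the n_c carriers.  iHH is
the trapezoidal integral of EHH over physical distance, both sides summed,
truncated where EHH falls below ``limehh``; raw iHS = ln(iHH_A / iHH_D)
is standardized within derived-allele frequency bins.  Negative iHS marks
unusually long derived haplotypes (recent partial sweeps).

For cross-population comparison the site statistic EHHS uses ALL
haplotypes, with groups seeded by the core-site partition and the curve
normalized to 1 at the core; its integral iES per population gives
raw XP-EHH = ln(iES_A / iES_B), standardized genome-wide.  Positive
XP-EHH means longer haplotypes (candidate selection) in population A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EHHConfig",
    "WindowNull",
    "ehh_decay",
    "integrated_ehh",
    "site_ehh_decay",
    "ihs_scan",
    "xpehh_scan",
    "window_empirical_null",
    "rank_candidate_windows",
]


@dataclass
class EHHConfig:
    """Truncation and standardization constants (the defaults of the
    standard EHH tooling, applied as-is)."""

    limehh: float = 0.05
    limhaplo: int = 2
    discard_integration_at_border: bool = True
    freq_bin_width: float = 0.025
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.limehh < 1:
            raise ValueError("limehh must be in (0, 1)")


def _ehh_side(
    haps: np.ndarray, rows: np.ndarray, core: int, step: int, stop_below: float | None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EHH values marker-by-marker on one side of the core.

    ``step`` is +1 (right) or -1 (left).  Haplotype groups are refined at
    each successive marker; the walk stops when EHH < ``stop_below`` (if
    given) or EHH reaches 0 or the chromosome border.  Returns (marker
    column indices, EHH at each, border_hit) where border_hit is True when
    the walk exhausted the chromosome while EHH was still >= stop_below.
    """
    n_sites = haps.shape[1]
    n_c = rows.size
    denom = n_c * (n_c - 1)
    ids = np.zeros(n_c, dtype=np.int64)
    cols, vals = [], []
    j = core + step
    ehh = 1.0
    since_relabel = 0
    while 0 <= j < n_sites:
        ids = ids * 2 + haps[rows, j]
        since_relabel += 1
        if since_relabel >= 48:  # relabel before the packed ids overflow
            ids = np.unique(ids, return_inverse=True)[1]
            since_relabel = 0
        s = np.sort(ids)
        edges = np.flatnonzero(np.diff(s)) + 1  # run boundaries of distinct extended haplotypes
        counts = np.diff(np.concatenate(([0], edges, [n_c])))
        ehh = float((counts * (counts - 1)).sum() / denom)
        cols.append(j)
        vals.append(ehh)
        if ehh == 0.0 or (stop_below is not None and ehh < stop_below):
            return np.array(cols), np.array(vals), False
        j += step
    border = stop_below is not None and ehh >= stop_below
    return np.array(cols, dtype=int), np.array(vals), border


def ehh_decay(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    core_allele: int,
    limhaplo: int = 2,
    stop_below: float | None = None,
) -> dict | None:
    """EHH decay curves on both sides of a core site for one core allele.

    ``haps`` is a (haplotypes x sites) 0/1 matrix for ONE chromosome with
    ``positions`` sorted ascending.  Returns
    ``{"left"/"right": (positions, ehh, border_hit)}`` (positions ordered
    outward from the core, EHH(0) = 1 implicit at the core itself), or
    None when fewer than ``limhaplo`` haplotypes carry the core allele.
    """
    rows = np.flatnonzero(haps[:, core] == core_allele)
    if rows.size < limhaplo:
        return None
    out = {}
    for name, step in (("left", -1), ("right", +1)):
        cols, vals, border = _ehh_side(haps, rows, core, step, stop_below)
        out[name] = (positions[cols], vals, border)
    return out


def integrated_ehh(
    curves: dict, core_pos: int, config: EHHConfig | None = None
) -> float:
    """Trapezoidal iHH from two-sided EHH curves (bp x EHH units).

    Each side integrates outward from the core (EHH = 1 there) until the
    first marker with EHH < ``limehh``, including that final trapezoid.  If
    a side hits the chromosome border while still above the threshold and
    ``discard_integration_at_border`` is set, the whole site is missing
    (NaN)."""
    config = config or EHHConfig()
    total = 0.0
    for side in ("left", "right"):
        pos, vals, border = curves[side]
        if border and config.discard_integration_at_border:
            return float("nan")
        prev_pos, prev_ehh = core_pos, 1.0
        for p, e in zip(pos, vals):
            total += 0.5 * (prev_ehh + e) * abs(int(p) - int(prev_pos))
            if e < config.limehh:
                break
            prev_pos, prev_ehh = p, e
    return total


def site_ehh_decay(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    limhaplo: int = 2,
    stop_below: float | None = None,
) -> dict | None:
    """Site-EHH (EHHS) decay over ALL haplotypes, normalized to 1 at the core.

    Groups are seeded with the core-site allele partition; the unnormalized
    homozygosity h(x) = sum_k n_k (n_k - 1) / (n (n - 1)) is divided by its
    core value h(0)."""
    n = haps.shape[0]
    if n < limhaplo:
        return None
    denom = n * (n - 1)

    def _h(ids):
        s = np.sort(ids)
        edges = np.flatnonzero(np.diff(s)) + 1
        counts = np.diff(np.concatenate(([0], edges, [ids.size])))
        return (counts * (counts - 1)).sum() / denom

    h0 = _h(haps[:, core].astype(np.int64))
    if h0 == 0:
        return None
    out = {}
    n_sites = haps.shape[1]
    stop_raw = None if stop_below is None else stop_below * h0
    for name, step in (("left", -1), ("right", +1)):
        ids = haps[:, core].astype(np.int64)
        cols, vals = [], []
        j = core + step
        h = h0
        border = False
        since_relabel = 0
        while 0 <= j < n_sites:
            ids = ids * 2 + haps[:, j]
            since_relabel += 1
            if since_relabel >= 48:
                ids = np.unique(ids, return_inverse=True)[1]
                since_relabel = 0
            h = _h(ids)
            cols.append(j)
            vals.append(h / h0)
            if h == 0.0 or (stop_raw is not None and h < stop_raw):
                break
            j += step
        else:
            border = stop_below is not None and h / h0 >= stop_below
        out[name] = (positions[np.array(cols, dtype=int)], np.array(vals), border)
    return out


def _standardize_in_bins(raw: np.ndarray, freq: np.ndarray, width: float) -> np.ndarray:
    """Subtract bin mean and divide by bin SD within frequency bins."""
    std = np.full_like(raw, np.nan)
    bins = np.floor(freq / width).astype(int)
    for b in np.unique(bins):
        sel = (bins == b) & np.isfinite(raw)
        if sel.sum() < 2:
            continue
        mu = raw[sel].mean()
        sd = raw[sel].std()
        if sd > 0:
            std[sel] = (raw[sel] - mu) / sd
    return std


def _per_chromosome(panel):
    for c in pd.unique(panel.chrom):
        cols = np.flatnonzero(panel.chrom == c)
        yield str(c), cols, panel.haplotypes[:, cols], panel.pos[cols]


def ihs_scan(panel, config: EHHConfig | None = None) -> pd.DataFrame:
    """Integrated haplotype score along the genome of one population panel.

    Core sites are those with derived frequency in
    [maf_min, 1 - maf_min].  Raw iHS = ln(iHH_A / iHH_D); standardized
    within derived-frequency bins of width ``freq_bin_width``.
    """
    config = config or EHHConfig()
    recs = []
    for chrom_name, cols, haps, pos in _per_chromosome(panel):
        freqs = haps.mean(axis=0)
        for local in range(haps.shape[1]):
            f = freqs[local]
            if f < config.maf_min or f > 1 - config.maf_min:
                continue
            row = {"chrom": chrom_name, "pos": int(pos[local]), "freq_derived": float(f)}
            ihh = {}
            for allele, key in ((0, "ihh_a"), (1, "ihh_d")):
                curves = ehh_decay(
                    haps, pos, local, allele, config.limhaplo, stop_below=config.limehh
                )
                ihh[key] = (
                    float("nan")
                    if curves is None
                    else integrated_ehh(curves, int(pos[local]), config)
                )
            row.update(ihh)
            if (
                np.isfinite(row["ihh_a"])
                and np.isfinite(row["ihh_d"])
                and row["ihh_a"] > 0
                and row["ihh_d"] > 0
            ):
                row["ihs_raw"] = float(np.log(row["ihh_a"] / row["ihh_d"]))
            else:
                row["ihs_raw"] = float("nan")
            recs.append(row)
    out = pd.DataFrame(recs)
    if out.empty:
        return out
    out["ihs_std"] = _standardize_in_bins(
        out["ihs_raw"].to_numpy(), out["freq_derived"].to_numpy(), config.freq_bin_width
    )
    return out


def _ies_track(panel, config: EHHConfig) -> pd.DataFrame:
    recs = []
    for chrom_name, cols, haps, pos in _per_chromosome(panel):
        for local in range(haps.shape[1]):
            curves = site_ehh_decay(
                haps, pos, local, config.limhaplo, stop_below=config.limehh
            )
            ies = (
                float("nan")
                if curves is None
                else integrated_ehh(curves, int(pos[local]), config)
            )
            recs.append({"chrom": chrom_name, "pos": int(pos[local]), "ies": ies})
    return pd.DataFrame(recs)


def xpehh_scan(panel_a, panel_b, config: EHHConfig | None = None) -> pd.DataFrame:
    """Cross-population XP-EHH over the shared site set of two panels.

    Positive scores: longer haplotype homozygosity (candidate selection)
    in panel A.  Raw scores are antisymmetric under the population swap;
    standardization is genome-wide (mean 0, SD 1 over scored sites).
    """
    config = config or EHHConfig()
    if not (
        np.array_equal(panel_a.chrom, panel_b.chrom)
        and np.array_equal(panel_a.pos, panel_b.pos)
    ):
        raise ValueError("panels must be phased over identical sites")
    ta = _ies_track(panel_a, config).rename(columns={"ies": "ies_a"})
    tb = _ies_track(panel_b, config).rename(columns={"ies": "ies_b"})
    out = ta.merge(tb, on=["chrom", "pos"])
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log(out["ies_a"].to_numpy() / out["ies_b"].to_numpy())
    raw[~np.isfinite(raw)] = np.nan
    out["xpehh_raw"] = raw
    ok = np.isfinite(raw)
    if ok.sum() >= 2 and np.nanstd(raw) > 0:
        out["xpehh_std"] = (raw - np.nanmean(raw)) / np.nanstd(raw)
    else:
        out["xpehh_std"] = np.nan
    return out


@dataclass
class WindowNull:
    """Empirical distribution of window-extreme scores from randomly
    placed fixed-width genomic windows."""

    width: int
    max_scores: np.ndarray
    min_scores: np.ndarray
    n_requested: int
    n_dropped: int
    seed: int


def window_empirical_null(
    scores: pd.DataFrame,
    chrom_lengths: dict[str, int],
    score_col: str = "xpehh_std",
    width: int = 30_000,
    n_windows: int = 10_000,
    seed: int = 0,
) -> WindowNull:
    """Null distribution of per-window max and min scores.

    Windows are placed with replacement: chromosome chosen proportional to
    its (length - width + 1), start uniform so the window lies fully inside
    the chromosome.  Windows containing no scored site are dropped (and
    counted)."""
    chroms = [c for c, L in chrom_lengths.items() if L >= width]
    if not chroms:
        raise ValueError("no chromosome at least as long as the window width")
    weights = np.array([chrom_lengths[c] - width + 1 for c in chroms], dtype=float)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(chroms), size=n_windows, p=weights / weights.sum())

    pos_by, val_by = {}, {}
    for c in chroms:
        sub = scores[(scores["chrom"] == c) & np.isfinite(scores[score_col])]
        order = np.argsort(sub["pos"].to_numpy())
        pos_by[c] = sub["pos"].to_numpy()[order]
        val_by[c] = sub[score_col].to_numpy()[order]

    maxs, mins = [], []
    dropped = 0
    for ci in pick:
        c = chroms[ci]
        start = int(rng.integers(1, chrom_lengths[c] - width + 2))
        lo = np.searchsorted(pos_by[c], start, side="left")
        hi = np.searchsorted(pos_by[c], start + width - 1, side="right")
        if hi <= lo:
            dropped += 1
            continue
        vals = val_by[c][lo:hi]
        maxs.append(vals.max())
        mins.append(vals.min())
    return WindowNull(
        width=width,
        max_scores=np.array(maxs),
        min_scores=np.array(mins),
        n_requested=n_windows,
        n_dropped=dropped,
        seed=seed,
    )


def rank_candidate_windows(
    scores: pd.DataFrame,
    candidates: pd.DataFrame,
    null: WindowNull,
    score_col: str = "xpehh_std",
    upper_q: float = 0.95,
    lower_q: float = 0.05,
) -> pd.DataFrame:
    """Rank candidate windows (width ``null.width`` centered on each
    candidate position) against the window null.

    quantile_max = fraction of null window maxima <= the candidate window
    maximum (ties count); quantile_min analogously on minima.  A candidate
    is flagged when quantile_max > ``upper_q`` (long-haplotype tail) or
    quantile_min < ``lower_q``."""
    half = null.width // 2
    rows = []
    for _, cand in candidates.iterrows():
        c, p = cand["chrom"], int(cand["pos"])
        sub = scores[
            (scores["chrom"] == c)
            & (scores["pos"] >= p - half)
            & (scores["pos"] <= p + half)
            & np.isfinite(scores[score_col])
        ]
        row = {"chrom": c, "pos": p}
        if sub.empty:
            row.update(
                {"max_score": np.nan, "min_score": np.nan, "quantile_max": np.nan,
                 "quantile_min": np.nan, "flagged": False, "evaluable": False}
            )
        else:
            mx = float(sub[score_col].max())
            mn = float(sub[score_col].min())
            qmax = float((null.max_scores <= mx).mean())
            qmin = float((null.min_scores <= mn).mean())
            row.update(
                {
                    "max_score": mx,
                    "min_score": mn,
                    "quantile_max": qmax,
                    "quantile_min": qmin,
                    "flagged": bool(qmax > upper_q or qmin < lower_q),
                    "evaluable": True,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
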