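"""100-bp tiling and differential-methylation-tile (DMT) calling.

The analysis walks the genome in step-wise tiling windows (default 100 bp,
non-overlapping), keeps tiles with >= 2 CpGs and >= 10x summed CpG coverage
in every sample of the contrast, and tests each treated diet group against
control.  With replicates in both groups the test is a binomial logistic
regression of (methylated, unmethylated) counts on group membership,
evaluated by likelihood-ratio test — with a single group factor this
reduces exactly to the G-test on the pooled 2x2 count table, which is
computed in closed form.  When either group has exactly one sample,
Fisher's exact test on pooled counts is used instead.  P-values are
adjusted by Benjamini–Hochberg step-up FDR; a tile is a DMT when
q < 0.01 and |delta| > 10 percentage points (strict inequalities).

Two methylation summaries are carried per tile: the per-sample unweighted
mean of CpG-level fractions (the tile methylation level), and the
coverage-weighted pooled group proportion, from which ``delta`` — the
quantity gating DMT calls — is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rrbs_io import SampleMethylome

__all__ = [
    "TileSet", "aggregate_tiles", "test_tile", "logistic_lrt_p", "adjust_fdr",
    "test_contrast", "call_dmts", "summarize_dmts", "MAGNITUDE_BINS",
]

#: |delta| bins (percentage points): (10, 15], (15, 20], (20, inf)
MAGNITUDE_BINS = ("10-15", "15-20", ">20")


@dataclass
class TileSet:
    """Per-tile, per-sample aggregated counts on a fixed tile grid.

    Arrays are (n_tiles, n_samples); ``frac_mean`` is the unweighted mean
    of CpG-level methylation fractions per sample (NaN when the sample
    covers no CpG in the tile); ``n_cpgs`` counts distinct covered CpG
    positions per tile across all samples.
    """

    tiles: pd.DataFrame          # chrom, start, end, n_cpgs
    samples: pd.DataFrame        # sample_id, tissue, diet, sex
    coverage: np.ndarray
    meth: np.ndarray
    frac_mean: np.ndarray

    def __len__(self):
        return len(self.tiles)

    def sample_mask(self, tissue: Optional[str] = None, diet: Optional[str] = None) -> np.ndarray:
        m = np.ones(len(self.samples), dtype=bool)
        if tissue is not None:
            m &= (self.samples["tissue"] == tissue).to_numpy()
        if diet is not None:
            m &= (self.samples["diet"] == diet).to_numpy()
        return m


def aggregate_tiles(samples: Sequence[SampleMethylome], tile_size: int = 100,
                    step: Optional[int] = None) -> TileSet:
    """Assign every CpG to its tiling window(s) and aggregate counts.

    With ``step`` equal to ``tile_size`` (the default) windows are disjoint
    and each CpG lands in exactly one tile; a smaller ``step`` (must divide
    ``tile_size``) produces overlapping sliding windows.  1-based CpG
    positions are converted to the 0-based half-open tile grid here.
    """
    if not samples:
        return TileSet(pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs"]),
                       pd.DataFrame(columns=["sample_id", "tissue", "diet", "sex"]),
                       np.zeros((0, 0)), np.zeros((0, 0)), np.zeros((0, 0)))
    step = tile_size if step is None else step
    if step <= 0 or tile_size % step:
        raise ValueError("step must be a positive divisor of tile_size")

    frames = []
    for si, s in enumerate(samples):
        rec = s.records
        if not rec["pos"].is_monotonic_increasing and not (
                rec.sort_values(["chrom", "pos"]).index == rec.index).all():
            warnings.warn(f"records of {s.sample_id} not sorted; sorting internally")
            rec = rec.sort_values(["chrom", "pos"])
        pos0 = rec["pos"].to_numpy() - 1  # to 0-based
        cov = (rec["count_meth"] + rec["count_unmeth"]).to_numpy()
        frac = rec["count_meth"].to_numpy() / cov
        for offset in range(0, tile_size, step):
            in_grid = pos0 >= offset
            tstart = offset + ((pos0[in_grid] - offset) // tile_size) * tile_size
            frames.append(pd.DataFrame({
                "chrom": rec["chrom"].to_numpy()[in_grid], "start": tstart,
                "sidx": si, "pos": pos0[in_grid],
                "count_meth": rec["count_meth"].to_numpy()[in_grid],
                "cov": cov[in_grid], "frac": frac[in_grid]}))
    long = pd.concat(frames, ignore_index=True)

    per = long.groupby(["chrom", "start", "sidx"], sort=True).agg(
        meth=("count_meth", "sum"), cov=("cov", "sum"), frac=("frac", "mean"))
    n_cpgs = long.groupby(["chrom", "start"], sort=True)["pos"].nunique()

    tiles = n_cpgs.reset_index().rename(columns={"pos": "n_cpgs"})
    tiles["end"] = tiles["start"] + tile_size
    tiles = tiles[["chrom", "start", "end", "n_cpgs"]]
    tile_key = pd.MultiIndex.from_frame(tiles[["chrom", "start"]])
    tile_pos = pd.Series(np.arange(len(tiles)), index=tile_key)

    n_t, n_s = len(tiles), len(samples)
    coverage = np.zeros((n_t, n_s), dtype=np.int64)
    meth = np.zeros((n_t, n_s), dtype=np.int64)
    frac_mean = np.full((n_t, n_s), np.nan)
    idx = per.index.to_frame(index=False)
    ti = tile_pos.loc[pd.MultiIndex.from_frame(idx[["chrom", "start"]])].to_numpy()
    si = idx["sidx"].to_numpy()
    coverage[ti, si] = per["cov"].to_numpy()
    meth[ti, si] = per["meth"].to_numpy()
    frac_mean[ti, si] = per["frac"].to_numpy()

    meta = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "tissue": [s.tissue for s in samples],
        "diet": [s.diet for s in samples],
        "sex": [s.sex for s in samples]})
    return TileSet(tiles.reset_index(drop=True), meta, coverage, meth, frac_mean)


# ---------------------------------------------------------------------------
# Per-tile tests

def logistic_lrt_p(meth_a, cov_a, meth_b, cov_b, dispersion=None):
    """Likelihood-ratio p for group effect in a binomial logistic model.

    Vectorized over tiles.  Inputs are pooled group counts (methylated and
    total coverage).  With a single binary covariate the logistic MLE fits
    each group's pooled proportion, so the LR statistic is the 2x2 G
    statistic; p from chi-square with 1 df.  ``dispersion``, if given,
    scales the statistic down (quasi-binomial correction).
    """
    meth_a, cov_a = np.asarray(meth_a, float), np.asarray(cov_a, float)
    meth_b, cov_b = np.asarray(meth_b, float), np.asarray(cov_b, float)
    o = np.stack([meth_a, cov_a - meth_a, meth_b, cov_b - meth_b], axis=-1)
    n = cov_a + cov_b
    p_pool = (meth_a + meth_b) / np.where(n > 0, n, 1)
    e = np.stack([cov_a * p_pool, cov_a * (1 - p_pool),
                  cov_b * p_pool, cov_b * (1 - p_pool)], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / np.where(e > 0, e, 1)), 0.0)
    g = 2.0 * terms.sum(axis=-1)
    g = np.maximum(g, 0.0)
    if dispersion is not None:
        g = g / np.maximum(np.asarray(dispersion, float), 1.0)
    p = stats.chi2.sf(g, df=1)
    return np.where(n > 0, p, np.nan)


def _fisher_p(meth_a, cov_a, meth_b, cov_b) -> float:
    table = [[int(meth_a), int(cov_a - meth_a)], [int(meth_b), int(cov_b - meth_b)]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def test_tile(meth_a: np.ndarray, cov_a: np.ndarray,
              meth_b: np.ndarray, cov_b: np.ndarray,
              overdispersion_correction: bool = False) -> float:
    """P-value for one tile from per-sample counts of the two groups.

    Logistic likelihood-ratio test when both groups have >= 2 samples;
    Fisher's exact test on pooled counts when either group has exactly one
    sample.  Zero total coverage is undefined (returns NaN; such tiles are
    skipped upstream).
    """
    meth_a, cov_a = np.atleast_1d(meth_a), np.atleast_1d(cov_a)
    meth_b, cov_b = np.atleast_1d(meth_b), np.atleast_1d(cov_b)
    if cov_a.sum() == 0 or cov_b.sum() == 0:
        return float("nan")
    if len(meth_a) < 2 or len(meth_b) < 2:
        return _fisher_p(meth_a.sum(), cov_a.sum(), meth_b.sum(), cov_b.sum())
    disp = None
    if overdispersion_correction:
        disp = _tile_dispersion(meth_a[None, :], cov_a[None, :],
                                meth_b[None, :], cov_b[None, :])[0]
    return float(logistic_lrt_p(meth_a.sum(), cov_a.sum(),
                                meth_b.sum(), cov_b.sum(), dispersion=disp))


def _tile_dispersion(meth_a, cov_a, meth_b, cov_b):
    """Per-tile Pearson dispersion of the group-fitted binomial model."""
    def chi(meth, cov, p):
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (meth - cov * p[:, None]) ** 2 / np.where(
                cov * p[:, None] * (1 - p[:, None]) > 0,
                cov * p[:, None] * (1 - p[:, None]), 1.0)
        return np.where(cov > 0, r2, 0.0).sum(axis=1)

    pa = meth_a.sum(axis=1) / np.maximum(cov_a.sum(axis=1), 1)
    pb = meth_b.sum(axis=1) / np.maximum(cov_b.sum(axis=1), 1)
    df = (cov_a > 0).sum(axis=1) + (cov_b > 0).sum(axis=1) - 2
    phi = (chi(meth_a, cov_a, pa) + chi(meth_b, cov_b, pb)) / np.maximum(df, 1)
    return np.maximum(phi, 1.0)


# ---------------------------------------------------------------------------
# FDR

def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at
    1, mapped back to input order.  NaN entries are excluded from m and
    reported as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# Contrast testing and DMT calling

def test_contrast(ts: TileSet, tissue: str, treatment: str, control: str = "Ctrl",
                  min_cpgs: int = 2, min_coverage: int = 10,
                  overdispersion_correction: bool = False) -> pd.DataFrame:
    """Test every testable tile of one tissue x (treatment vs control).

    Returns one row per testable tile: chrom, start, end, n_cpgs,
    meth_ctrl, meth_treat, delta (coverage-weighted pooled, percentage
    points), meth_ctrl_mean, meth_treat_mean (means over per-sample tile
    levels), p_value and q_value (BH over this contrast's tiles).

    A tile is testable when it has >= ``min_cpgs`` distinct CpGs and
    summed CpG coverage >= ``min_coverage`` in every sample of the
    contrast.
    """
    mask_c = ts.sample_mask(tissue=tissue, diet=control)
    mask_t = ts.sample_mask(tissue=tissue, diet=treatment)
    if mask_c.sum() < 1 or mask_t.sum() < 1:
        raise ValueError(f"need >=1 sample per group for {tissue} {treatment} vs {control}")

    cov_c, meth_c = ts.coverage[:, mask_c], ts.meth[:, mask_c]
    cov_t, meth_t = ts.coverage[:, mask_t], ts.meth[:, mask_t]
    testable = (
        (ts.tiles["n_cpgs"].to_numpy() >= min_cpgs)
        & (cov_c >= min_coverage).all(axis=1)
        & (cov_t >= min_coverage).all(axis=1)
    )

    res = ts.tiles.loc[testable, ["chrom", "start", "end", "n_cpgs"]].reset_index(drop=True)
    mc, cc = meth_c[testable], cov_c[testable]
    mt, ct = meth_t[testable], cov_t[testable]
    pooled_c = 100.0 * mc.sum(axis=1) / cc.sum(axis=1)
    pooled_t = 100.0 * mt.sum(axis=1) / ct.sum(axis=1)
    res["meth_ctrl"] = pooled_c
    res["meth_treat"] = pooled_t
    res["delta"] = pooled_t - pooled_c
    t_idx = testable.nonzero()[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res["meth_ctrl_mean"] = 100.0 * np.nanmean(
            ts.frac_mean[np.ix_(t_idx, mask_c.nonzero()[0])], axis=1)
        res["meth_treat_mean"] = 100.0 * np.nanmean(
            ts.frac_mean[np.ix_(t_idx, mask_t.nonzero()[0])], axis=1)

    if mask_c.sum() >= 2 and mask_t.sum() >= 2:
        disp = _tile_dispersion(mc, cc, mt, ct) if overdispersion_correction else None
        p = logistic_lrt_p(mc.sum(axis=1), cc.sum(axis=1),
                           mt.sum(axis=1), ct.sum(axis=1), dispersion=disp)
    else:
        p = np.array([_fisher_p(a.sum(), b.sum(), c.sum(), d.sum())
                      for a, b, c, d in zip(mc, cc, mt, ct)])
    res["p_value"] = p
    res["q_value"] = adjust_fdr(p)
    res["tissue"] = tissue
    res["treatment"] = treatment
    res["control"] = control
    return res


def magnitude_bin(abs_delta) -> np.ndarray:
    """Bin |delta| into 10-15 / 15-20 / >20 (boundaries at 15 and 20)."""
    a = np.asarray(abs_delta, dtype=float)
    return np.select([a > 20, a > 15], [MAGNITUDE_BINS[2], MAGNITUDE_BINS[1]],
                     default=MAGNITUDE_BINS[0])


def call_dmts(results: pd.DataFrame, q_threshold: float = 0.01,
              min_delta: float = 10.0) -> pd.DataFrame:
    """Designate DMTs: q strictly below threshold AND |delta| strictly above
    ``min_delta`` percentage points; ties are not DMTs.  Adds direction
    (hyper/hypo) and magnitude bin."""
    sel = (results["q_value"] < q_threshold) & (results["delta"].abs() > min_delta)
    dmts = results[sel].copy().reset_index(drop=True)
    dmts["direction"] = np.where(dmts["delta"] > 0, "hyper", "hypo")
    dmts["magnitude_bin"] = magnitude_bin(dmts["delta"].abs())
    return dmts


def summarize_dmts(dmts: pd.DataFrame) -> dict:
    """Counts and fractions by direction and magnitude bin."""
    n = len(dmts)
    out = {"n_dmts": n, "n_hyper": 0, "n_hypo": 0,
           "bin_counts": {b: 0 for b in MAGNITUDE_BINS}}
    if n == 0:
        return out
    out["n_hyper"] = int((dmts["direction"] == "hyper").sum())
    out["n_hypo"] = n - out["n_hyper"]
    out["hyper_fraction"] = out["n_hyper"] / n
    out["hypo_fraction"] = out["n_hypo"] / n
    for b in MAGNITUDE_BINS:
        out["bin_counts"][b] = int((dmts["magnitude_bin"] == b).sum())
    return out
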