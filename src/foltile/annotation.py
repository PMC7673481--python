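"""Genomic-feature annotation of tiles, enrichment tests and cross-tissue
DMT intersection.

Each tile gets exactly one feature from {promoter, exon, intron,
intergenic}: the feature with maximal overlap wins, ties resolved by the
precedence promoter > exon > intron, tiles overlapping nothing are
intergenic.  Enrichment of a category among DMTs relative to all testable
(background) tiles is a two-sided Fisher's exact test on the 2x2 table
(category vs not) x (DMT vs background).  DMT lists from the two tissues
are intersected by exact tile coordinates; a conserved tile is concordant
when the deltas share a sign and high-magnitude when at least one tissue
changes by more than 20 percentage points.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .rrbs_io import GeneModel, INTERGENIC, resolve_feature

__all__ = ["annotate_tiles", "feature_fractions", "enrichment_test", "intersect_tissues"]

FEATURE_CATEGORIES = ("promoter", "exon", "intron", INTERGENIC)


def annotate_tiles(tiles: pd.DataFrame, gene_model: GeneModel) -> pd.DataFrame:
    """Assign one feature and (optionally) a gene id to every tile.

    ``tiles`` needs chrom/start/end columns; returns a copy with
    ``feature`` and ``gene_id`` columns added.  Chromosomes absent from
    the gene model are annotated intergenic with a warning.
    """
    missing = set(tiles["chrom"].unique()) - gene_model.chroms()
    if missing:
        warnings.warn(f"chromosomes absent from gene model, treated as intergenic: {sorted(missing)}")
    features, genes = [], []
    for row in tiles.itertuples(index=False):
        hits = gene_model.overlaps(row.chrom, int(row.start), int(row.end))
        f, g = resolve_feature(hits)
        features.append(f)
        genes.append(g)
    out = tiles.copy()
    out["feature"] = features
    out["gene_id"] = genes
    return out


def feature_fractions(annotated: pd.DataFrame) -> pd.Series:
    """Fraction of tiles per feature category (sums to 1 over nonempty input)."""
    counts = annotated["feature"].value_counts()
    counts = counts.reindex(FEATURE_CATEGORIES, fill_value=0)
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def enrichment_test(dmt_features: pd.Series, background_features: pd.Series,
                    category: str = INTERGENIC):
    """Odds ratio and two-sided Fisher p for category enrichment in DMTs.

    Inputs are feature labels per tile (DMT set and background set).  The
    2x2 table is [[DMT in category, DMT not], [background in category,
    background not]].  A zero margin leaves the odds ratio undefined
    (returned as NaN, p = 1).
    """
    a = int((dmt_features == category).sum())
    b = int(len(dmt_features) - a)
    c = int((background_features == category).sum())
    d = int(len(background_features) - c)
    if len(dmt_features) == 0 or len(background_features) == 0:
        raise ValueError("both tile sets must be non-empty")
    if (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def intersect_tissues(dmts_a: pd.DataFrame, dmts_b: pd.DataFrame,
                      high_magnitude_delta: float = 20.0):
    """Intersect two DMT tables by exact tile coordinates.

    Returns ``(conserved, counts)`` where ``conserved`` has one row per
    shared tile with delta_a, delta_b, ``concordant`` (same sign of
    change) and ``high_magnitude`` (at least one |delta| strictly above
    ``high_magnitude_delta`` pp), and ``counts`` totals the conserved /
    concordant / high-magnitude-concordant tiles.
    """
    key = ["chrom", "start", "end"]
    merged = dmts_a[key + ["delta"]].merge(
        dmts_b[key + ["delta"]], on=key, suffixes=("_a", "_b"))
    merged["concordant"] = np.sign(merged["delta_a"]) == np.sign(merged["delta_b"])
    merged["high_magnitude"] = (
        np.maximum(merged["delta_a"].abs(), merged["delta_b"].abs()) > high_magnitude_delta)
    counts = {
        "n_conserved": int(len(merged)),
        "n_concordant": int(merged["concordant"].sum()),
        "n_high_magnitude_concordant": int((merged["concordant"] & merged["high_magnitude"]).sum()),
    }
    return merged, counts
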