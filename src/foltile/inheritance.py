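"""Maternal-allele methylation inheritance: region selection and DMT
classification.

Loci that normally inherit their methylation from the oocyte are found by
combining three 100-bp reference tracks: sperm (paternal germline), GVO
(germinal-vesicle oocyte, the maternal germline state) and ICMm (maternal
allele of the inner-cell-mass, the post-fertilization state).  A region is
maternally inherited when sperm methylation is low (<= 10%) while both GVO
and ICMm are at least 25%.  Its GVO -> ICM dynamic is classified as gain
(ICM - GVO >= +10 pp), loss (GVO - ICM >= +10 pp) or stable; regions with
GVO methylation >= 75% are flagged ``gvo_high``.  DMT lists are then
intersected with these regions by exact tile coordinates and tabulated as
(dynamic class) x (hyper/hypo direction) counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["select_maternal_regions", "intersect_with_dmts"]

DYNAMIC_CLASSES = ("gain", "stable", "loss")


def classify_dynamics(gvo, icm, delta_threshold: float = 10.0) -> np.ndarray:
    """Gain/stable/loss of methylation from GVO to ICM (>= threshold, inclusive)."""
    gvo = np.asarray(gvo, float)
    icm = np.asarray(icm, float)
    return np.select(
        [icm - gvo >= delta_threshold, gvo - icm >= delta_threshold],
        ["gain", "loss"], default="stable")


def select_maternal_regions(sperm: pd.DataFrame, gvo: pd.DataFrame, icm: pd.DataFrame,
                            sperm_max: float = 10.0, gvo_icm_min: float = 25.0,
                            dynamic_delta: float = 10.0,
                            gvo_high_min: float = 75.0,
                            require_both: bool = True) -> pd.DataFrame:
    """Select maternally-inherited regions from the three reference tracks.

    Tracks are (chrom, start, end, meth_percent) tables on a shared 100-bp
    grid; regions missing from any track are dropped.  Retained regions
    satisfy sperm <= ``sperm_max`` and — with ``require_both`` (default) —
    BOTH GVO and ICMm >= ``gvo_icm_min`` (with ``require_both=False``
    either track suffices).  Each retained region carries its dynamic
    class and the ``gvo_high`` flag.
    """
    key = ["chrom", "start", "end"]
    for name, tr in (("sperm", sperm), ("GVO", gvo), ("ICMm", icm)):
        if (tr["start"] % 100).any() or ((tr["end"] - tr["start"]) != 100).any():
            raise ValueError(f"{name} track not on the 100-bp grid")
    m = (sperm[key + ["meth_percent"]].rename(columns={"meth_percent": "sperm_meth"})
         .merge(gvo[key + ["meth_percent"]].rename(columns={"meth_percent": "gvo_meth"}), on=key)
         .merge(icm[key + ["meth_percent"]].rename(columns={"meth_percent": "icm_meth"}), on=key))
    if require_both:
        gate = (m["gvo_meth"] >= gvo_icm_min) & (m["icm_meth"] >= gvo_icm_min)
    else:
        gate = (m["gvo_meth"] >= gvo_icm_min) | (m["icm_meth"] >= gvo_icm_min)
    keep = (m["sperm_meth"] <= sperm_max) & gate
    out = m[keep].reset_index(drop=True)
    out["dynamic_class"] = classify_dynamics(out["gvo_meth"], out["icm_meth"], dynamic_delta)
    out["gvo_high"] = out["gvo_meth"] >= gvo_high_min
    return out


def intersect_with_dmts(maternal: pd.DataFrame, dmts: pd.DataFrame):
    """Cross DMTs with maternally-inherited regions and tabulate.

    Returns ``(table, intersected)``: ``table`` counts DMTs by dynamic
    class (gain/stable/loss rows plus a total row) x direction
    (hyper/hypo/all columns) and carries the fraction of intersected DMTs
    at ``gvo_high`` regions in ``table.attrs['gvo_high_fraction']``;
    ``intersected`` lists the matched DMTs with their region attributes.
    """
    key = ["chrom", "start", "end"]
    inter = dmts.merge(maternal, on=key, how="inner")
    rows = []
    for cls in DYNAMIC_CLASSES:
        sub = inter[inter["dynamic_class"] == cls]
        hyper = int((sub["direction"] == "hyper").sum())
        hypo = int((sub["direction"] == "hypo").sum())
        rows.append((cls, hyper, hypo, hyper + hypo))
    total_hyper = sum(r[1] for r in rows)
    total_hypo = sum(r[2] for r in rows)
    rows.append(("total", total_hyper, total_hypo, total_hyper + total_hypo))
    table = pd.DataFrame(rows, columns=["dynamic_class", "hyper", "hypo", "all_dmts"])
    table.attrs["gvo_high_fraction"] = (
        float(inter["gvo_high"].mean()) if len(inter) else float("nan"))
    return table, inter
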