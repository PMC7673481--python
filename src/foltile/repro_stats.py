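"""Litter- and embryo-level reproductive-outcome statistics.

Dam-level outcomes derive from counts made at necropsy: corpora lutea (CL,
ovulations), implantation sites, and resorption sites.  Pre-implantation
loss is CL minus implantation sites; post-implantation loss is, by
default, the resorption count (the number of conceptuses lost after
implanting) — a ``literal`` mode returning implantation sites minus
resorptions (the viable count) is also provided since that subtraction is
sometimes quoted as the definition.  Embryos are growth-classified against
the control group: restricted below, and enhanced above, two standard
deviations of the distribution of control litter-mean weights.  A litter
with more than one abnormal outcome (resorption, growth restriction or
growth enhancement, counted additively) is flagged, and flagged-litter
proportions are compared between control and the pooled treated diets by
Fisher's exact test.  Continuous per-litter outcomes are compared to
control by ANOVA followed by Dunnett's multiple-comparison test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "preimplantation_loss", "postimplantation_loss", "classify_growth",
    "abnormal_litter_test", "dunnett_vs_control", "litter_outcome_table",
]

GROWTH_CLASSES = ("normal", "restricted", "enhanced")


def preimplantation_loss(corpora_lutea, implantation_sites):
    """Pre-implantation loss per dam: CL - implantation sites, floored at 0.

    An implantation count exceeding CL is biologically a miscount; it is
    floored with a warning rather than rejected.  Missing CL yields NaN
    (excluded from group statistics).
    """
    cl = np.asarray(corpora_lutea, dtype=float)
    imp = np.asarray(implantation_sites, dtype=float)
    loss = cl - imp
    if np.any(loss < 0):
        warnings.warn("implantation sites exceed corpora lutea; flooring loss at 0")
        loss = np.maximum(loss, 0.0)
    return float(loss) if loss.ndim == 0 else loss


def postimplantation_loss(implantation_sites, resorptions, mode: str = "resorptions"):
    """Post-implantation loss per dam.

    ``mode='resorptions'`` (default) returns the resorption count — the
    number of implanted conceptuses that died.  ``mode='literal'`` returns
    implantation sites minus resorptions, the difference sometimes quoted
    as the definition (it equals the viable-embryo count).
    """
    imp = np.asarray(implantation_sites, dtype=float)
    res = np.asarray(resorptions, dtype=float)
    if mode == "resorptions":
        out = res
    elif mode == "literal":
        out = imp - res
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def classify_growth(embryos: pd.DataFrame, litters: pd.DataFrame,
                    control_diet: str = "Ctrl", sd_multiplier: float = 2.0) -> pd.Series:
    """Growth class per embryo from the control litter-mean distribution.

    Each control litter contributes its mean embryo weight; mu and sigma
    are the mean and SD of those litter means.  An embryo is ``restricted``
    when its weight is strictly below mu - k*sigma and ``enhanced`` when
    strictly above mu + k*sigma (k = ``sd_multiplier``); boundary weights
    are ``normal``.
    """
    ctrl_dams = litters.loc[litters["diet"] == control_diet, "dam_id"]
    ctrl_embryos = embryos[embryos["dam_id"].isin(ctrl_dams)]
    litter_means = ctrl_embryos.groupby("dam_id")["weight"].mean()
    if len(litter_means) < 2:
        raise ValueError("need >= 2 control litters with embryos to define growth thresholds")
    mu = float(litter_means.mean())
    sigma = float(litter_means.std(ddof=1))
    lo, hi = mu - sd_multiplier * sigma, mu + sd_multiplier * sigma
    cls = np.select([embryos["weight"] < lo, embryos["weight"] > hi],
                    ["restricted", "enhanced"], default="normal")
    return pd.Series(cls, index=embryos.index, name="growth_class")


def _abnormal_flags(litters: pd.DataFrame, embryos: pd.DataFrame,
                    control_diet: str, sd_multiplier: float) -> pd.DataFrame:
    growth = classify_growth(embryos, litters, control_diet, sd_multiplier)
    emb = embryos.assign(growth_class=growth)
    per_dam = emb.groupby("dam_id")["growth_class"].agg(
        restricted=lambda s: int((s == "restricted").sum()),
        enhanced=lambda s: int((s == "enhanced").sum()))
    lit = litters.merge(per_dam, left_on="dam_id", right_index=True, how="left")
    lit[["restricted", "enhanced"]] = lit[["restricted", "enhanced"]].fillna(0).astype(int)
    lit["n_abnormal"] = lit["resorptions"] + lit["restricted"] + lit["enhanced"]
    lit["flagged"] = lit["n_abnormal"] > 1
    return lit


def abnormal_litter_test(litters: pd.DataFrame, embryos: pd.DataFrame,
                         control_diet: str = "Ctrl", sd_multiplier: float = 2.0,
                         pool_treated: bool = True, alternative: str = "two-sided"):
    """Fisher's exact test on flagged-litter proportions, control vs treated.

    A litter is flagged when resorptions + growth-restricted + growth-
    enhanced embryos exceed 1.  With ``pool_treated`` all non-control diets
    form one column of the 2x2 table.  Returns ``(table, p)`` where
    ``table`` is [[ctrl_flagged, ctrl_not], [treated_flagged, treated_not]].
    ``alternative`` follows the usual Fisher conventions; the two-sided p
    sums hypergeometric point probabilities <= that of the observed table.
    """
    lit = _abnormal_flags(litters, embryos, control_diet, sd_multiplier)
    ctrl = lit[lit["diet"] == control_diet]
    treated = lit[lit["diet"] != control_diet]
    if len(ctrl) == 0 or len(treated) == 0:
        raise ValueError("both control and treated litters are required")
    if not pool_treated:
        out = {}
        for diet, sub in treated.groupby("diet"):
            tab = [[int(ctrl["flagged"].sum()), int((~ctrl["flagged"]).sum())],
                   [int(sub["flagged"].sum()), int((~sub["flagged"]).sum())]]
            out[diet] = (tab, float(stats.fisher_exact(tab, alternative=alternative)[1]))
        return out
    table = [[int(ctrl["flagged"].sum()), int((~ctrl["flagged"]).sum())],
             [int(treated["flagged"].sum()), int((~treated["flagged"]).sum())]]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    return table, p


def dunnett_vs_control(values, groups, control: str = "Ctrl") -> pd.DataFrame:
    """Dunnett-adjusted two-sided p per non-control group.

    ANOVA-style many-to-one comparison against the control group; the
    adjustment integrates the joint multivariate-t distribution of the
    contrast statistics, so each adjusted p is at least the raw p.  All
    groups need >= 2 observations.  Identical constant data across groups
    returns p = 1 for every contrast.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    names = [g for g in pd.unique(groups) if g != control]
    ctrl_vals = values[groups == control]
    treat_vals = [values[groups == g] for g in names]
    if len(ctrl_vals) < 2 or any(len(v) < 2 for v in treat_vals):
        raise ValueError("every group needs >= 2 non-missing observations")
    if np.ptp(values) == 0:
        return pd.DataFrame({"group": names, "statistic": 0.0, "p_adjusted": 1.0})
    # multivariate-t integration is quasi-random; pin it for reproducibility
    res = stats.dunnett(*treat_vals, control=ctrl_vals, alternative="two-sided",
                        random_state=np.random.default_rng(1234))
    return pd.DataFrame({"group": names,
                         "statistic": np.asarray(res.statistic, float),
                         "p_adjusted": np.asarray(res.pvalue, float)})


def litter_outcome_table(litters: pd.DataFrame, embryos: pd.DataFrame,
                         control_diet: str = "Ctrl",
                         postimp_mode: str = "resorptions") -> pd.DataFrame:
    """Per-litter derived outcomes ready for group statistics.

    Adds litter size (viable embryos), pre-/post-implantation loss, mean
    embryo and placenta weights and the embryo/placenta weight ratio.
    """
    lit = litters.copy()
    lit["litter_size"] = lit["implantation_sites"] - lit["resorptions"]
    lit["preimplantation_loss"] = preimplantation_loss(
        lit["corpora_lutea"], lit["implantation_sites"])
    lit["postimplantation_loss"] = postimplantation_loss(
        lit["implantation_sites"], lit["resorptions"], mode=postimp_mode)
    emb = embryos.assign(ep_ratio=embryos["weight"] / embryos["placenta_weight"])
    per_dam = emb.groupby("dam_id").agg(
        mean_embryo_weight=("weight", "mean"),
        mean_placenta_weight=("placenta_weight", "mean"),
        mean_ep_ratio=("ep_ratio", "mean"))
    return lit.merge(per_dam, left_on="dam_id", right_index=True, how="left")
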