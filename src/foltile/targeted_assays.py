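"""Targeted methylation assays: LUMA global methylation and imprinted-gene
pyrosequencing summaries.

LUMA estimates global CpG methylation from restriction digests: HpaII
(methylation-sensitive) and MspI (methylation-insensitive) cut the same
CCGG site, each normalized by an EcoRI internal control, so

    % methylation = 100 * (1 - (HpaII/EcoRI) / (MspI/EcoRI))

with duplicate digestions averaged before the formula.  Pyrosequencing
yields per-CpG percent methylation at imprinted germline DMRs (H19, Snrpn,
Kcnq1ot1, Peg1, Peg3); somatic tissues are expected near 50% (one
methylated allele).  Group comparisons use one-way ANOVA across the four
diets; sex differences use a two-sample t-test (Welch by default), and the
sexes are pooled for the diet comparison when that test is non-significant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["luma_percent", "group_anova", "sex_ttest", "pyro_gene_summary", "pool_sexes_if_ns"]

IMPRINTED_GENES = ("H19", "Snrpn", "Kcnq1ot1", "Peg1", "Peg3")


def luma_percent(ratio_hpaii_ecori, ratio_mspi_ecori) -> float:
    """Percent global methylation from duplicate-averaged LUMA peak ratios.

    Values outside [0, 100] (possible with noisy peak ratios) are clipped
    with a warning.  Non-positive MspI/EcoRI ratios are invalid.
    """
    h = np.asarray(ratio_hpaii_ecori, dtype=float)
    m = np.asarray(ratio_mspi_ecori, dtype=float)
    if np.any(m <= 0):
        raise ValueError("MspI/EcoRI ratio must be positive")
    if np.any(h < 0):
        raise ValueError("HpaII/EcoRI ratio must be non-negative")
    pct = 100.0 * (1.0 - h / m)
    if np.any((pct < 0) | (pct > 100)):
        warnings.warn("LUMA percent outside [0, 100]; clipping")
        pct = np.clip(pct, 0.0, 100.0)
    return float(pct) if pct.ndim == 0 else pct


def group_anova(values, groups):
    """Classical one-way ANOVA (F, p) across diet groups.

    Degenerate input with zero variance everywhere and equal means returns
    (0, 1) rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    arrays = [values[groups == g] for g in pd.unique(groups)]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp([a[0] for a in arrays]) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def sex_ttest(values, sex_labels, equal_var: bool = False):
    """Two-sided two-sample t-test between sexes (Welch by default)."""
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex_labels)
    males = values[sex == "M"]
    females = values[sex == "F"]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both sexes must be present")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(males, females, equal_var=equal_var)
    return float(t), float(p)


def pool_sexes_if_ns(values, sex_labels, alpha: float = 0.05):
    """Decide whether sexes may be pooled for the diet comparison.

    Returns ``(pooled, t, p)``: ``pooled`` is True when the sex t-test is
    non-significant at ``alpha``, mirroring the practice of combining
    males and females downstream when no sex effect is detected.
    """
    t, p = sex_ttest(values, sex_labels)
    return p >= alpha, t, p


def pyro_gene_summary(pyro: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary of pyrosequencing methylation with diet ANOVA.

    Input is the table from :func:`foltile.rrbs_io.read_pyro_table`
    (sample_id, gene, diet, sex, cpg columns, mean_percent).  Output has
    one row per gene: per-diet means, overall mean, ANOVA F and p, and
    the sex t-test p (NaN when only one sex present).
    """
    rows = []
    for gene, sub in pyro.groupby("gene"):
        entry = {"gene": gene, "overall_mean": float(sub["mean_percent"].mean())}
        for diet, dsub in sub.groupby("diet"):
            entry[f"mean_{diet}"] = float(dsub["mean_percent"].mean())
        try:
            f, p = group_anova(sub["mean_percent"], sub["diet"])
            entry["anova_F"], entry["anova_p"] = f, p
        except ValueError:
            entry["anova_F"] = entry["anova_p"] = float("nan")
        try:
            _, sp = sex_ttest(sub["mean_percent"], sub["sex"])
            entry["sex_ttest_p"] = sp
        except ValueError:
            entry["sex_ttest_p"] = float("nan")
        rows.append(entry)
    return pd.DataFrame(rows)
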