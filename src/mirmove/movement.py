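"""Tissue-pair movement quantification and qPCR relative expression.

Band-intensity tables (emitter vs recipient tissue, e.g. vasculature vs
epidermis of peeled leaves, or scion vs rootstock of grafts) are loading-
normalized, expressed relative to a reference genotype, converted into
recipient/emitter ratios per replicate, and summarized as a percent reduction
in movement between a test and a reference genotype. Crossing-point (Cp)
tables from stem-loop RT-qPCR are converted to relative expression via
2^-dCp against the per-sample mean of reference targets, normalized to a
control condition.

Group comparisons follow a fixed decision tree: Shapiro-Wilk normality
checks (reported as warnings, not gates), an F test of variance equality at
alpha = 0.05 selecting Student's t versus Welch's t for two groups, and
one-way ANOVA followed by Tukey HSD for more than two groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

VARIANCE_ALPHA = 0.05  # F-test threshold for switching to Welch's correction

INTENSITY_COLUMNS = [
    "sample_id", "genotype", "tissue", "replicate",
    "target_intensity", "loading_intensity",
]
CP_COLUMNS = ["sample_id", "target", "condition", "Cp", "is_reference"]


# ---------------------------------------------------------------------------
# intensity normalization and ratios
# ---------------------------------------------------------------------------

def normalize_and_relativize(
    records: pd.DataFrame, reference_genotype: str
) -> pd.DataFrame:
    """Loading-normalize intensities and express them relative to the
    reference genotype.

    Adds ``normalized = target_intensity / loading_intensity`` and
    ``relative`` = normalized divided by the mean normalized value of
    ``reference_genotype`` within the same tissue. Records with
    non-positive loading intensity are dropped with a logged warning; an
    empty reference group (overall or within a tissue present in the data)
    raises ``ValueError``.
    """
    missing = set(INTENSITY_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    df = records.copy()
    bad = df["loading_intensity"] <= 0
    if bad.any():
        logger.warning(
            "dropping %d record(s) with non-positive loading intensity", int(bad.sum())
        )
        df = df.loc[~bad].copy()
    if not (df["genotype"] == reference_genotype).any():
        raise ValueError(f"reference genotype {reference_genotype!r} absent from table")
    df["normalized"] = df["target_intensity"] / df["loading_intensity"]

    ref_means = (
        df.loc[df["genotype"] == reference_genotype]
        .groupby("tissue")["normalized"]
        .mean()
    )
    missing_tissues = set(df["tissue"]) - set(ref_means.index)
    if missing_tissues:
        raise ValueError(
            f"reference genotype has no records in tissue(s): {sorted(missing_tissues)}"
        )
    df["relative"] = df["normalized"] / df["tissue"].map(ref_means)
    return df


def tissue_ratio(
    normalized: pd.DataFrame,
    pairing: str = "by_replicate",
    recipient: str = "recipient",
    emitter: str = "emitter",
) -> pd.DataFrame:
    """Recipient/emitter ratio of loading-normalized levels.

    ``pairing="by_replicate"`` pairs the two tissues within each
    (genotype, replicate); replicates missing either tissue are skipped with
    a warning. ``pairing="unpaired"`` returns one row per genotype with the
    ratio of tissue means.
    """
    if "normalized" not in normalized.columns:
        raise ValueError("run normalize_and_relativize first ('normalized' column)")
    if pairing == "unpaired":
        means = normalized.pivot_table(
            index="genotype", columns="tissue", values="normalized", aggfunc="mean"
        )
        out = (means[recipient] / means[emitter]).rename("ratio").reset_index()
        out["replicate"] = pd.NA
        return out[["genotype", "replicate", "ratio"]]
    if pairing != "by_replicate":
        raise ValueError(f"unknown pairing mode {pairing!r}")
    rows = []
    for (genotype, rep), grp in normalized.groupby(["genotype", "replicate"]):
        by_tissue = grp.set_index("tissue")["normalized"]
        if recipient not in by_tissue.index or emitter not in by_tissue.index:
            logger.warning("skipping unpaired replicate %s/%s", genotype, rep)
            continue
        rec = by_tissue.loc[recipient]
        emi = by_tissue.loc[emitter]
        rec = rec.mean() if isinstance(rec, pd.Series) else rec
        emi = emi.mean() if isinstance(emi, pd.Series) else emi
        rows.append({"genotype": genotype, "replicate": rep, "ratio": rec / emi})
    return pd.DataFrame(rows, columns=["genotype", "replicate", "ratio"])


# ---------------------------------------------------------------------------
# group comparison decision tree
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    normality_p: dict[str, float] = field(default_factory=dict)
    variance_p: float | None = None
    pairwise: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def _f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test of variance equality (Fisher's test on two samples)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    return float(2 * min(cdf, 1 - cdf))


def compare_groups(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Compare group means following the package's statistical decision tree.

    Two groups: Shapiro-Wilk per group (warning only), F test of variances at
    alpha = 0.05, then Student's t (equal variances) or Welch's t (unequal).
    More than two groups: one-way ANOVA, then Tukey HSD for all pairwise
    comparisons. Any group with n < 2 raises ``ValueError`` naming it.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n={arr.size} < 2")

    normality: dict[str, float] = {}
    warnings: list[str] = []
    for name, arr in arrays.items():
        if arr.size >= 3 and np.ptp(arr) > 0:
            p = float(stats.shapiro(arr).pvalue)
            normality[name] = p
            if p < 0.05:
                warnings.append(f"group {name!r} fails Shapiro-Wilk (p={p:.3g})")
        else:
            normality[name] = math.nan

    if len(arrays) == 2:
        (na, a), (nb, b) = arrays.items()
        var_p = _f_test(a, b)
        if var_p < VARIANCE_ALPHA:
            res = stats.ttest_ind(a, b, equal_var=False)
            name = "Welch-t"
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            name = "t"
        return TestResult(
            name, float(res.statistic), float(res.pvalue),
            normality_p=normality, variance_p=var_p, warnings=warnings,
        )

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate(
        [np.repeat(name, arr.size) for name, arr in arrays.items()]
    )
    anova = stats.f_oneway(*arrays.values())
    tukey = pairwise_tukeyhsd(values, labels, alpha=0.05)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return TestResult(
        "ANOVA+Tukey", float(anova.statistic), float(anova.pvalue),
        normality_p=normality, pairwise=pairwise, warnings=warnings,
    )


# ---------------------------------------------------------------------------
# movement estimate
# ---------------------------------------------------------------------------

@dataclass
class MovementEstimate:
    """Percent reduction in movement of a test relative to a reference
    genotype, from recipient/emitter ratio sets."""

    percent_reduction: float  # headline: 100 * (1 - mean(test) / mean(ref))
    percent_reduction_gmean: float  # geometric-mean variant
    reference_genotype: str
    test_genotype: str
    test_name: str
    p_value: float
    mean_test: float
    sd_test: float
    mean_reference: float
    sd_reference: float
    n_test: int
    n_reference: int


def percent_reduction(
    ratios_test: Sequence[float],
    ratios_reference: Sequence[float],
    test_genotype: str = "test",
    reference_genotype: str = "reference",
) -> MovementEstimate:
    """Estimate the reduction in movement from two sets of tissue ratios.

    Headline estimate is the ratio of arithmetic means:
    ``100 * (1 - mean(test) / mean(reference))``; a geometric-mean variant is
    reported alongside. Negative values (test moving more than reference) are
    allowed. The p-value comes from the two-group comparison decision tree.
    """
    t = np.asarray(ratios_test, dtype=float)
    r = np.asarray(ratios_reference, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("both ratio groups must be non-empty")
    if r.mean() == 0:
        raise ValueError("reference ratio mean is zero")
    pct = 100.0 * (1.0 - t.mean() / r.mean())
    pct_g = 100.0 * (1.0 - stats.gmean(t) / stats.gmean(r)) if (
        np.all(t > 0) and np.all(r > 0)
    ) else math.nan
    if pct < 0:
        logger.warning(
            "test genotype %r moves more than reference (%.1f%% increase)",
            test_genotype, -pct,
        )
    if t.size >= 2 and r.size >= 2:
        res = compare_groups({test_genotype: t, reference_genotype: r})
        test_name, p = res.test_name, res.p_value
    else:
        test_name, p = "none", math.nan
    return MovementEstimate(
        percent_reduction=float(pct),
        percent_reduction_gmean=float(pct_g),
        reference_genotype=reference_genotype,
        test_genotype=test_genotype,
        test_name=test_name,
        p_value=float(p),
        mean_test=float(t.mean()),
        sd_test=float(t.std(ddof=1)) if t.size > 1 else math.nan,
        mean_reference=float(r.mean()),
        sd_reference=float(r.std(ddof=1)) if r.size > 1 else math.nan,
        n_test=int(t.size),
        n_reference=int(r.size),
    )


def movement_estimates(
    ratios: pd.DataFrame, reference_genotype: str
) -> pd.DataFrame:
    """Percent-reduction estimates for every non-reference genotype in a
    ratio table (columns genotype, replicate, ratio)."""
    ref = ratios.loc[ratios["genotype"] == reference_genotype, "ratio"]
    if ref.empty:
        raise ValueError(f"reference genotype {reference_genotype!r} absent")
    rows = []
    for genotype, grp in ratios.groupby("genotype"):
        if genotype == reference_genotype:
            continue
        est = percent_reduction(
            grp["ratio"].to_numpy(), ref.to_numpy(),
            test_genotype=str(genotype), reference_genotype=reference_genotype,
        )
        rows.append(
            {
                "genotype": genotype,
                "percent_reduction": est.percent_reduction,
                "percent_reduction_gmean": est.percent_reduction_gmean,
                "mean_ratio": est.mean_test,
                "sd_ratio": est.sd_test,
                "reference_mean_ratio": est.mean_reference,
                "test_name": est.test_name,
                "p_value": est.p_value,
                "n": est.n_test,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def relative_expression(
    cp_table: pd.DataFrame,
    control_condition: str,
    reference_targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """2^-dCp relative expression from crossing-point values.

    For each sample, ``dCp = Cp(target) - mean(Cp of reference targets in the
    same sample)`` and the pre-normalization value is ``2^-dCp``
    (``value_vs_reference``). Values are then divided, per target, by the
    mean value of the control condition (``expression``). Reference-target
    rows are used only for the per-sample reference mean. A sample missing a
    declared reference target raises ``ValueError``.
    """
    missing = set(CP_COLUMNS) - set(cp_table.columns)
    if missing:
        raise ValueError(f"Cp table missing columns: {sorted(missing)}")
    df = cp_table.copy()
    df["is_reference"] = df["is_reference"].astype(bool)
    if reference_targets is None:
        reference_targets = sorted(df.loc[df["is_reference"], "target"].unique())
    if not reference_targets:
        raise ValueError("no reference targets declared")

    ref_rows = df[df["target"].isin(reference_targets)]
    ref_means = {}
    for sample_id, grp in df.groupby("sample_id"):
        present = set(grp["target"]) & set(reference_targets)
        absent = set(reference_targets) - present
        if absent:
            raise ValueError(
                f"sample {sample_id!r} missing reference target(s): {sorted(absent)}"
            )
        ref_means[sample_id] = ref_rows.loc[
            ref_rows["sample_id"] == sample_id, "Cp"
        ].mean()

    out = df.loc[~df["target"].isin(reference_targets)].copy()
    out["dCp"] = out["Cp"] - out["sample_id"].map(ref_means)
    out["value_vs_reference"] = 2.0 ** (-out["dCp"])

    control = out.loc[out["condition"] == control_condition]
    if control.empty:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    control_means = control.groupby("target")["value_vs_reference"].mean()
    missing_targets = set(out["target"]) - set(control_means.index)
    if missing_targets:
        raise ValueError(
            f"target(s) absent from control condition: {sorted(missing_targets)}"
        )
    out["expression"] = out["value_vs_reference"] / out["target"].map(control_means)
    return out[
        ["sample_id", "target", "condition", "Cp", "dCp",
         "value_vs_reference", "expression"]
    ].reset_index(drop=True)
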