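"""Relative quantification of qPCR expression by the 2^(-ddCt) method.

Implements the Livak & Schmittgen workflow: technical replicates are
averaged on the Ct scale, each target gene is normalised to the reference
gene within its biological replicate (dCt), expressed relative to the mean
dCt of a calibrator group (ddCt, default: the same genotype's control
treatment), and converted to a fold change 2^(-ddCt). Group summaries
report the arithmetic mean +/- SD of per-replicate fold changes across
biological replicates.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "average_technical_reps",
    "delta_ct",
    "fold_change",
    "summarize_expression",
    "quantify",
    "DeltaDeltaCtQuantifier",
]

CELL_KEYS = ["genotype", "treatment", "bio_rep"]


def _validate_ct(ct_table: pd.DataFrame, ct_window: tuple[float, float]) -> pd.DataFrame:
    required = set(CELL_KEYS + ["tech_rep", "gene", "ct"])
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    df = ct_table.copy()
    n_missing = df["ct"].isna().sum()
    if n_missing:
        warnings.warn(f"dropping {n_missing} technical replicates with missing Ct")
        before = df.groupby(CELL_KEYS)["gene"].agg(set)
        df = df.dropna(subset=["ct"])
        after = df.groupby(CELL_KEYS)["gene"].agg(set)
        for cell, genes in before.items():
            lost = genes - after.get(cell, set())
            if lost:
                raise ValueError(
                    f"cell {cell} lost all technical replicates for {sorted(lost)}"
                )
    bad = ~np.isfinite(df["ct"]) | (df["ct"] < ct_window[0]) | (df["ct"] > ct_window[1])
    if bad.any():
        rows = df.loc[bad, ["genotype", "treatment", "bio_rep", "gene", "ct"]]
        raise ValueError(
            f"{bad.sum()} Ct values outside the plausible window {ct_window}:\n"
            f"{rows.head().to_string(index=False)}"
        )
    return df


def average_technical_reps(
    ct_table: pd.DataFrame, ct_window: tuple[float, float] = (5.0, 40.0)
) -> pd.DataFrame:
    """Average Ct over technical replicates.

    Returns one row per (genotype, treatment, bio_rep, gene) with the
    arithmetic mean Ct and the number of technical replicates retained
    (``n_tech``) for audit. Missing Ct values are dropped with a warning;
    a gene whose technical replicates are all missing in a cell raises.
    """
    df = _validate_ct(ct_table, ct_window)
    if df.empty:
        raise ValueError("no Ct observations left after filtering")
    return (
        df.groupby(CELL_KEYS + ["gene"], sort=False, as_index=False)
        .agg(ct=("ct", "mean"), n_tech=("ct", "size"))
    )


def delta_ct(
    ct_means: pd.DataFrame,
    reference_gene: str,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Compute dCt = Ct_target - Ct_reference per biological replicate.

    ``targets`` defaults to every gene except the reference. Requesting the
    reference gene as a target, or a biological replicate lacking the
    reference gene, is an error (replicates missing the reference are
    excluded with a warning only when other replicates remain).
    """
    if targets is not None and reference_gene in targets:
        raise ValueError("the reference gene cannot be quantified against itself")
    genes = ct_means["gene"].unique()
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} not present in the Ct table")
    wide_ref = ct_means[ct_means["gene"] == reference_gene].set_index(CELL_KEYS)["ct"]
    tgt = ct_means[ct_means["gene"] != reference_gene]
    if targets is not None:
        tgt = tgt[tgt["gene"].isin(targets)]
    tgt = tgt.copy()
    idx = pd.MultiIndex.from_frame(tgt[CELL_KEYS])
    ref_ct = wide_ref.reindex(idx)
    if ref_ct.isna().any():
        cells = idx[ref_ct.isna().to_numpy()].unique()
        warnings.warn(
            f"excluding {len(cells)} biological replicates missing the reference gene: "
            f"{list(cells)[:4]}"
        )
        keep = ~ref_ct.isna().to_numpy()
        tgt = tgt[keep]
        ref_ct = ref_ct[keep]
        if tgt.empty:
            raise ValueError("no biological replicate contains the reference gene")
    tgt["delta_ct"] = tgt["ct"].to_numpy() - ref_ct.to_numpy()
    return tgt[CELL_KEYS + ["gene", "delta_ct"]].reset_index(drop=True)


def fold_change(
    delta_ct_table: pd.DataFrame, calibrator_treatment: str = "control"
) -> pd.DataFrame:
    """Express each replicate relative to its genotype's calibrator group.

    ddCt = dCt - mean(dCt over the calibrator replicates of the same
    genotype and gene); fold_change = 2^(-ddCt). Within the calibrator
    group the ddCt values are centred, so their fold changes have geometric
    mean exactly 1.
    """
    cal = delta_ct_table[delta_ct_table["treatment"] == calibrator_treatment]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_treatment!r} is empty")
    cal_mean = cal.groupby(["genotype", "gene"])["delta_ct"].mean()
    key = pd.MultiIndex.from_frame(delta_ct_table[["genotype", "gene"]])
    base = cal_mean.reindex(key).to_numpy()
    if np.isnan(base).any():
        missing = key[np.isnan(base)].unique()
        raise ValueError(f"no calibrator replicates for: {list(missing)[:4]}")
    out = delta_ct_table.copy()
    out["delta_delta_ct"] = out["delta_ct"].to_numpy() - base
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def summarize_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of fold change per genotype x treatment x gene.

    SD is the sample standard deviation (n-1 denominator) across biological
    replicates; a single-replicate group reports SD 0 and is flagged.
    """
    if expression.empty:
        raise ValueError("empty expression table")
    g = expression.groupby(["genotype", "treatment", "gene"], sort=False)["fold_change"]
    out = g.agg(mean_fold_change="mean", sd_fold_change="std", n="size").reset_index()
    single = out["n"] == 1
    if single.any():
        warnings.warn(f"{single.sum()} groups have a single biological replicate; SD set to 0")
    out["single_replicate"] = single
    out.loc[single, "sd_fold_change"] = 0.0
    return out


def quantify(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_treatment: str = "control",
    ct_window: tuple[float, float] = (5.0, 40.0),
) -> pd.DataFrame:
    """Full 2^(-ddCt) pipeline: tech-rep averaging -> dCt -> fold change."""
    means = average_technical_reps(ct_table, ct_window=ct_window)
    dct = delta_ct(means, reference_gene)
    return fold_change(dct, calibrator_treatment=calibrator_treatment)


class DeltaDeltaCtQuantifier(BaseEstimator, TransformerMixin):
    """Relative-quantification transformer over long-format Ct tables.

    Parameters
    ----------
    reference_gene : str
        Housekeeping gene used for dCt normalisation.
    calibrator_treatment : str
        Treatment whose same-genotype mean dCt anchors ddCt (default
        "control", so fold changes read "relative to that genotype's
        unstressed plants").
    ct_window : (low, high)
        Plausibility window for raw Ct values; values outside raise.

    After :meth:`fit`, ``calibrator_delta_ct_`` holds the per
    (genotype, gene) calibrator mean dCt and :meth:`transform` expresses
    any compatible Ct table relative to it.
    """

    def __init__(
        self,
        reference_gene: str = "Actin-7",
        calibrator_treatment: str = "control",
        ct_window: tuple[float, float] = (5.0, 40.0),
    ):
        self.reference_gene = reference_gene
        self.calibrator_treatment = calibrator_treatment
        self.ct_window = ct_window

    def fit(self, ct_table: pd.DataFrame, y=None):
        means = average_technical_reps(ct_table, ct_window=self.ct_window)
        dct = delta_ct(means, self.reference_gene)
        cal = dct[dct["treatment"] == self.calibrator_treatment]
        if cal.empty:
            raise ValueError(f"calibrator group {self.calibrator_treatment!r} is empty")
        self.calibrator_delta_ct_ = cal.groupby(["genotype", "gene"])["delta_ct"].mean()
        self.genes_ = tuple(dct["gene"].unique())
        return self

    def transform(self, ct_table: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "calibrator_delta_ct_"):
            raise ValueError("DeltaDeltaCtQuantifier is not fitted")
        means = average_technical_reps(ct_table, ct_window=self.ct_window)
        dct = delta_ct(means, self.reference_gene)
        key = pd.MultiIndex.from_frame(dct[["genotype", "gene"]])
        base = self.calibrator_delta_ct_.reindex(key).to_numpy()
        if np.isnan(base).any():
            missing = key[np.isnan(base)].unique()
            raise ValueError(f"no fitted calibrator for: {list(missing)[:4]}")
        out = dct.copy()
        out["delta_delta_ct"] = out["delta_ct"].to_numpy() - base
        out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
        return out

    def summarize(self, expression: pd.DataFrame) -> pd.DataFrame:
        return summarize_expression(expression)
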