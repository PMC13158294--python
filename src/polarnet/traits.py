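"""Phenotypic trait statistics: summaries, two-way ANOVA, Tukey letters.

The factorial analysis mirrors common practice for balanced genotype x
treatment field trials: cell means +/- SD, a classical fixed-effects
two-way ANOVA (Type-I sums of squares, which coincide with Types II/III on
balanced data), all-pairs Tukey HSD on the cell means using the
studentized-range distribution with the pooled error term, and a compact
letter display built by the insert-and-absorb algorithm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

__all__ = [
    "summarize_traits",
    "two_way_anova",
    "tukey_cld",
    "percent_change",
    "compact_letter_display",
]


def _check_columns(traits: pd.DataFrame) -> None:
    required = {"genotype", "treatment", "bio_rep", "trait", "value"}
    missing = required - set(traits.columns)
    if missing:
        raise ValueError(f"trait table is missing columns: {sorted(missing)}")


def summarize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) per genotype x treatment x trait."""
    _check_columns(traits)
    if traits.empty:
        raise ValueError("empty trait table")
    if traits["value"].isna().any() or not np.isfinite(traits["value"]).all():
        raise ValueError("trait values must be finite")
    g = traits.groupby(["genotype", "treatment", "trait"], sort=False)["value"]
    out = g.agg(mean="mean", sd="std", n="size").reset_index()
    single = out["n"] == 1
    if single.any():
        warnings.warn(f"{single.sum()} trait cells have a single replicate; SD set to 0")
    out["single_replicate"] = single
    out.loc[single, "sd"] = 0.0
    if "unit" in traits.columns:
        units = traits.groupby("trait")["unit"].agg(lambda u: u.iloc[0])
        nuniq = traits.groupby("trait")["unit"].nunique()
        if (nuniq > 1).any():
            raise ValueError(f"inconsistent units for traits: {list(nuniq[nuniq > 1].index)}")
        out["unit"] = out["trait"].map(units)
    return out


def _one_trait(traits: pd.DataFrame, trait: str) -> pd.DataFrame:
    _check_columns(traits)
    df = traits[traits["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} not present in the table")
    counts = df.groupby(["genotype", "treatment"]).size()
    n_geno = df["genotype"].nunique()
    n_trt = df["treatment"].nunique()
    if len(counts) < n_geno * n_trt or (counts == 0).any():
        raise ValueError(f"trait {trait!r} has empty genotype x treatment cells")
    if counts.nunique() > 1:
        raise ValueError(
            f"unbalanced design for trait {trait!r} (replicates per cell: "
            f"{dict(counts)}); rebalance the data or analyse cells directly — "
            "Type-I/II/III sums of squares differ on unbalanced data"
        )
    return df


def two_way_anova(traits: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Classical two-way fixed-effects ANOVA for one trait.

    Returns a table with one row per effect (genotype, treatment,
    genotype:treatment, residual): sum of squares, degrees of freedom, mean
    square, F and p. Requires a balanced design with replicated cells; on
    balanced data least-squares means equal cell means. With zero residual
    variance F is undefined and reported as NaN.
    """
    df = _one_trait(traits, trait)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.ols("value ~ C(genotype) * C(treatment)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        index={
            "C(genotype)": "genotype",
            "C(treatment)": "treatment",
            "C(genotype):C(treatment)": "genotype:treatment",
            "Residual": "residual",
        },
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p_value"},
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    # numerically-zero residual variance (e.g. constant data): F is undefined
    eps = 1e-12 * max(1.0, float((df["value"] ** 2).mean()))
    if table.loc["residual", "mean_sq"] <= eps:
        table.loc[table.index != "residual", ["F", "p_value"]] = np.nan
    table.loc[~np.isfinite(table["F"]), ["F", "p_value"]] = np.nan
    return table[["sum_sq", "df", "mean_sq", "F", "p_value"]]


@dataclass
class _PairwiseResult:
    cells: list[tuple[str, str]]
    means: np.ndarray
    significant: np.ndarray  # boolean matrix, True = means differ


def _tukey_pairwise(
    df: pd.DataFrame, cells: list[tuple[str, str]], mse: float, df_error: float, alpha: float
) -> _PairwiseResult:
    means = np.array(
        [df[(df["genotype"] == g) & (df["treatment"] == t)]["value"].mean() for g, t in cells]
    )
    ns = np.array(
        [len(df[(df["genotype"] == g) & (df["treatment"] == t)]) for g, t in cells]
    )
    k = len(cells)
    sig = np.zeros((k, k), dtype=bool)
    if k < 2:
        return _PairwiseResult(cells, means, sig)
    q_crit = studentized_range.ppf(1 - alpha, k, df_error)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            stat = abs(means[i] - means[j]) / se if se > 0 else np.inf
            if se == 0 and means[i] == means[j]:
                stat = 0.0
            sig[i, j] = sig[j, i] = stat > q_crit
    return _PairwiseResult(cells, means, sig)


def compact_letter_display(
    labels: list, means: np.ndarray, significant: np.ndarray
) -> dict:
    """Insert-and-absorb compact letter display.

    Starts from one letter column covering all groups; every significant
    pair splits the columns containing both members; redundant columns are
    absorbed. Letters are assigned in descending-mean order, so the group
    with the largest mean carries "a". Groups sharing a letter are not
    significantly different.
    """
    k = len(labels)
    columns: list[set[int]] = [set(range(k))]
    order = sorted(range(k), key=lambda i: (-means[i], labels[i]))
    for a in range(k):
        for b in range(a + 1, k):
            if not significant[a, b]:
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                for drop in (a, b):
                    new = col - {drop}
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
    # absorb: drop columns contained in others (can arise across splits)
    columns = [c for c in columns if not any(c < other for other in columns)]
    # deterministic letter order: sort columns by the rank of their best member
    rank = {idx: pos for pos, idx in enumerate(order)}
    columns.sort(key=lambda c: min(rank[i] for i in c))
    letters = {lab: "" for lab in labels}
    for pos, col in enumerate(columns):
        ch = chr(ord("a") + pos)
        for i in sorted(col, key=lambda i: rank[i]):
            letters[labels[i]] += ch
    return letters


def tukey_cld(
    traits: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    mode: str = "within_genotype",
) -> pd.DataFrame:
    """All-pairs Tukey HSD with compact letter display for one trait.

    ``mode="within_genotype"`` (default) compares the two treatment cells
    separately inside each genotype, matching figure legends of the form
    "significantly different between treatments (per genotype)"; letters
    are independent between genotypes. ``mode="all_cells"`` compares all
    four genotype x treatment cells jointly. Both modes use the pooled
    error term of the full two-way model.
    """
    if mode not in ("within_genotype", "all_cells"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _one_trait(traits, trait)
    anova = two_way_anova(traits, trait)
    df_error = float(anova.loc["residual", "df"])
    if df_error <= 0:
        raise ValueError("zero error degrees of freedom; Tukey's test is undefined")
    mse = float(anova.loc["residual", "mean_sq"])

    frames = []
    if mode == "all_cells":
        cells = sorted(
            (g, t) for g in df["genotype"].unique() for t in df["treatment"].unique()
        )
        res = _tukey_pairwise(df, cells, mse, df_error, alpha)
        letters = compact_letter_display(res.cells, res.means, res.significant)
        frames.append(
            pd.DataFrame(
                {
                    "genotype": [c[0] for c in cells],
                    "treatment": [c[1] for c in cells],
                    "mean": res.means,
                    "letters": [letters[c] for c in cells],
                }
            )
        )
    else:
        for g in df["genotype"].unique():
            cells = sorted((g, t) for t in df["treatment"].unique())
            res = _tukey_pairwise(df, cells, mse, df_error, alpha)
            letters = compact_letter_display(res.cells, res.means, res.significant)
            frames.append(
                pd.DataFrame(
                    {
                        "genotype": g,
                        "treatment": [c[1] for c in cells],
                        "mean": res.means,
                        "letters": [letters[c] for c in cells],
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "trait", trait)
    return out


def pairwise_significance(
    traits: pd.DataFrame, trait: str, alpha: float = 0.05
) -> _PairwiseResult:
    """All-cells Tukey pairwise significance matrix (for CLD verification)."""
    df = _one_trait(traits, trait)
    anova = two_way_anova(traits, trait)
    df_error = float(anova.loc["residual", "df"])
    if df_error <= 0:
        raise ValueError("zero error degrees of freedom")
    mse = float(anova.loc["residual", "mean_sq"])
    cells = sorted((g, t) for g in df["genotype"].unique() for t in df["treatment"].unique())
    return _tukey_pairwise(df, cells, mse, df_error, alpha)


def percent_change(control_mean: float, stress_mean: float) -> tuple[float, int]:
    """Percent reduction from control to stress: 100*(c - s)/c.

    Returns the full-precision percentage and its half-away-from-zero
    integer rounding (the headline form). Negative values mean an increase
    under stress. The control mean must be positive.
    """
    if not control_mean > 0:
        raise ValueError("control mean must be positive")
    pct = 100.0 * (control_mean - stress_mean) / control_mean
    rounded = int(np.sign(pct) * np.floor(abs(pct) + 0.5))
    return pct, rounded
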