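"""Genotype-specific correlation networks and polarity-reversal analysis.

The central question: which genes rewire between a heat-tolerant and a
heat-susceptible genotype? Per genotype, pairwise Pearson correlations
among per-replicate gene expression values (fold changes pooled across
both treatments) define a network whose edges carry a sign (positive /
negative) and a strength tier (strong |r| >= 0.75, medium 0.25 <= |r| <
0.75, weak |r| < 0.25). Comparing the two networks edge by edge yields
polarity reversals (sign flips) and tier transitions; per-node statistics
then classify genes into

- **hubs**: many incident reversals, high connectivity, and up-regulated
  in the tolerant genotype;
- **phenotypic switchers**: non-hub genes whose correlations with the
  measured traits all reverse sign between genotypes;
- **contextual responders**: the remainder (stable internal co-regulation,
  limited polarity shifts).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CorrelationMatrix",
    "EdgeClass",
    "EdgeComparison",
    "NodeProfile",
    "correlation_matrix",
    "classify_edge",
    "gene_trait_correlations",
    "compare_networks",
    "node_reversal_counts",
    "classify_roles",
    "expression_matrix",
    "upregulated_genes",
    "export_network",
    "DifferentialNetwork",
    "DEFAULT_TIER_THRESHOLDS",
]

DEFAULT_TIER_THRESHOLDS = (0.25, 0.75)
ROLES = ("hub", "phenotypic_switcher", "contextual_responder")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with its sample basis."""

    labels: tuple[str, ...]
    values: np.ndarray
    genotype: str = ""
    n: int = 0
    basis: str = "replicates"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    def r(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class EdgeClass:
    """Sign and strength tier of one correlation."""

    pair: tuple[str, str]
    r: float
    sign: str  # "positive" | "negative"
    tier: str  # "strong" | "medium" | "weak"
    zero_flagged: bool = False


@dataclass(frozen=True)
class EdgeComparison:
    """One edge compared across the two genotype networks."""

    pair: tuple[str, str]
    a: EdgeClass
    b: EdgeClass
    polarity_reversed: bool
    robust: bool
    tier_transition: tuple[str, str]


@dataclass
class NodeProfile:
    """Per-gene network metrics and assigned role."""

    gene: str
    connectivity: dict[str, int]
    reversal_count: int
    trait_reversal_fraction: float
    tier_downgrade_count: int
    upregulated_tolerant: bool
    role: str = "contextual_responder"


def correlation_matrix(
    data: pd.DataFrame,
    min_n: int = 3,
    genotype: str = "",
    basis: str = "replicates",
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over the rows of ``data``.

    ``data`` is observations x variables with no missing entries. Zero
    variance in any column raises (naming the variable), as does having
    fewer than ``min_n`` complete rows.
    """
    if data.isna().any().any():
        raise ValueError("correlation input contains missing values")
    if len(data) < min_n:
        raise ValueError(f"need at least {min_n} complete rows, got {len(data)}")
    sd = data.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance variables: {dead}")
    values = np.corrcoef(np.asarray(data, dtype=float), rowvar=False)
    return CorrelationMatrix(
        labels=tuple(data.columns), values=values, genotype=genotype, n=len(data), basis=basis
    )


def classify_edge(
    r: float,
    thresholds: tuple[float, float] = DEFAULT_TIER_THRESHOLDS,
    pair: tuple[str, str] = ("", ""),
) -> EdgeClass:
    """Classify one correlation into sign and tier.

    Tiers partition |r| with half-open boundaries: strong iff |r| >= the
    upper threshold, medium iff lower <= |r| < upper, weak iff |r| < lower.
    The sign is the sign of r; r exactly 0 is assigned "positive" by
    convention and flagged (flagged edges never count as reversals).
    """
    low, high = thresholds
    if not 0 < low < high <= 1:
        raise ValueError("tier thresholds must satisfy 0 < low < high <= 1")
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise ValueError(f"correlation out of range: {r}")
    a = min(abs(r), 1.0)
    tier = "strong" if a >= high else ("medium" if a >= low else "weak")
    return EdgeClass(
        pair=pair,
        r=float(r),
        sign="negative" if r < 0 else "positive",
        tier=tier,
        zero_flagged=(r == 0),
    )


def expression_matrix(
    expression: pd.DataFrame,
    genotype: str,
    scale: str = "fold",
    basis: str = "replicates",
) -> pd.DataFrame:
    """Wide per-genotype expression matrix entering the networks.

    Rows are biological replicates pooled across both treatments (default)
    or treatment means; columns are genes. Values are per-replicate fold
    changes 2^(-ddCt) (``scale="fold"``) or -ddCt (``scale="log"``).
    """
    if scale not in ("fold", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    if basis not in ("replicates", "treatment_means"):
        raise ValueError(f"unknown basis {basis!r}")
    e = expression[expression["genotype"] == genotype]
    if e.empty:
        raise ValueError(f"expression table does not cover genotype {genotype!r}")
    e = e.copy()
    if scale == "fold":
        e["_value"] = e["fold_change"]
    else:
        e["_value"] = (
            -e["delta_delta_ct"] if "delta_delta_ct" in e else np.log2(e["fold_change"])
        )
    wide = e.pivot_table(index=["treatment", "bio_rep"], columns="gene", values="_value")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"incomplete replicates for genes: {bad}")
    if basis == "treatment_means":
        wide = wide.groupby(level="treatment").mean()
    return wide


def gene_trait_correlations(
    expression: pd.DataFrame,
    traits: pd.DataFrame,
    genotype: str,
    trait_list: tuple[str, ...] | None = None,
    scale: str = "fold",
    min_n: int = 3,
) -> pd.DataFrame:
    """Genes x traits Pearson correlation block over the same sample basis."""
    genes = expression_matrix(expression, genotype, scale=scale)
    t = traits[traits["genotype"] == genotype]
    if t.empty:
        raise ValueError(f"trait table does not cover genotype {genotype!r}")
    if trait_list is None:
        trait_list = tuple(t["trait"].unique())
    tw = t[t["trait"].isin(trait_list)].pivot_table(
        index=["treatment", "bio_rep"], columns="trait", values="value"
    )[list(trait_list)]
    if not genes.index.equals(tw.index):
        raise ValueError("replicate mismatch between expression and trait tables")
    both = pd.concat([genes, tw], axis=1)
    corr = correlation_matrix(both, min_n=min_n, genotype=genotype)
    frame = corr.to_frame()
    return frame.loc[list(genes.columns), list(trait_list)]


def compare_networks(
    net_a: CorrelationMatrix,
    net_b: CorrelationMatrix,
    thresholds: tuple[float, float] = DEFAULT_TIER_THRESHOLDS,
) -> list[EdgeComparison]:
    """Edge-wise comparison of two networks over identical variable sets.

    One comparison per unordered pair. ``polarity_reversed`` means the
    signs differ (never true when either correlation is exactly 0);
    ``robust`` requires both tiers to be at least medium;
    ``tier_transition`` is ordered (tier in A, tier in B).
    """
    if net_a.labels != net_b.labels:
        raise ValueError(
            f"variable sets differ: {net_a.labels} vs {net_b.labels}"
        )
    out = []
    labels = net_a.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = (labels[i], labels[j])
            ea = classify_edge(net_a.values[i, j], thresholds, pair)
            eb = classify_edge(net_b.values[i, j], thresholds, pair)
            reversed_ = (
                ea.sign != eb.sign and not ea.zero_flagged and not eb.zero_flagged
            )
            out.append(
                EdgeComparison(
                    pair=pair,
                    a=ea,
                    b=eb,
                    polarity_reversed=reversed_,
                    robust=(ea.tier != "weak" and eb.tier != "weak"),
                    tier_transition=(ea.tier, eb.tier),
                )
            )
    return out


def node_reversal_counts(comparisons: list[EdgeComparison]) -> dict[str, int]:
    """Per gene, the number of incident polarity-reversed gene-gene edges."""
    counts: dict[str, int] = {}
    for c in comparisons:
        for g in c.pair:
            counts.setdefault(g, 0)
            if c.polarity_reversed:
                counts[g] += 1
    return counts


def robust_reversal_counts(comparisons: list[EdgeComparison]) -> dict[str, int]:
    """Reversal counts restricted to edges at least medium in both networks."""
    counts: dict[str, int] = {}
    for c in comparisons:
        for g in c.pair:
            counts.setdefault(g, 0)
            if c.polarity_reversed and c.robust:
                counts[g] += 1
    return counts


def _connectivity(comparisons: list[EdgeComparison]) -> tuple[dict[str, int], dict[str, int]]:
    conn_a: dict[str, int] = {}
    conn_b: dict[str, int] = {}
    for c in comparisons:
        for g in c.pair:
            conn_a.setdefault(g, 0)
            conn_b.setdefault(g, 0)
            if c.a.tier != "weak":
                conn_a[g] += 1
            if c.b.tier != "weak":
                conn_b[g] += 1
    return conn_a, conn_b


def _tier_downgrades(comparisons: list[EdgeComparison]) -> dict[str, int]:
    down: dict[str, int] = {}
    for c in comparisons:
        for g in c.pair:
            down.setdefault(g, 0)
            if c.tier_transition == ("strong", "medium"):
                down[g] += 1
    return down


def upregulated_genes(
    expression: pd.DataFrame,
    genotype: str,
    stress_treatment: str = "stress",
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Genes significantly up-regulated under stress in one genotype.

    One-sided one-sample t-test of the stress replicates' log2 fold changes
    (-ddCt) against 0 at level ``alpha``. With a single replicate the test
    is undefined and the gene counts as up-regulated iff its log2 fold
    change exceeds 0 (flagged with a warning).
    """
    e = expression[
        (expression["genotype"] == genotype) & (expression["treatment"] == stress_treatment)
    ]
    if e.empty:
        raise ValueError(f"no stress replicates for genotype {genotype!r}")
    out: dict[str, bool] = {}
    for gene, grp in e.groupby("gene", sort=False):
        lfc = (
            -grp["delta_delta_ct"].to_numpy()
            if "delta_delta_ct" in grp
            else np.log2(grp["fold_change"].to_numpy())
        )
        if len(lfc) < 2 or np.allclose(lfc, lfc[0]):
            warnings.warn(f"{gene}: too few replicates for a t-test; using the sign of the mean")
            out[gene] = bool(lfc.mean() > 0)
            continue
        res = stats.ttest_1samp(lfc, 0.0, alternative="greater")
        out[gene] = bool(res.pvalue < alpha)
    return out


def trait_reversal_fractions(
    gt_a: pd.DataFrame, gt_b: pd.DataFrame
) -> dict[str, float]:
    """Fraction of gene-trait correlations whose sign flips between genotypes.

    Correlations that are exactly zero in either genotype never count as
    flipped (same convention as gene-gene edges).
    """
    if not (gt_a.index.equals(gt_b.index) and gt_a.columns.equals(gt_b.columns)):
        raise ValueError("gene-trait blocks are not aligned")
    a = gt_a.to_numpy()
    b = gt_b.to_numpy()
    flipped = (np.sign(a) * np.sign(b)) < 0
    return {g: float(flipped[i].mean()) for i, g in enumerate(gt_a.index)}


def classify_roles(
    comparisons: list[EdgeComparison],
    upregulated_tolerant: dict[str, bool],
    trait_reversal_fraction: dict[str, float] | None = None,
    theta_rev: int = 3,
    theta_conn: float | str = "median",
    theta_switch: float = 1.0,
    gene_order: tuple[str, ...] | None = None,
) -> list[NodeProfile]:
    """Deterministic role cascade over the compared networks.

    1. **hub** — reversal_count >= ``theta_rev`` AND tolerant-network
       connectivity >= ``theta_conn`` (default: the median connectivity)
       AND significantly up-regulated in the tolerant genotype;
    2. **phenotypic_switcher** (among non-hubs) — trait_reversal_fraction
       >= ``theta_switch`` (default 1.0: every measured trait flips);
    3. **contextual_responder** — the remainder.

    Genes are emitted in ``gene_order`` (default: first-appearance order in
    the comparisons), which also fixes any tie-breaking.
    """
    counts = node_reversal_counts(comparisons)
    conn_a, conn_b = _connectivity(comparisons)
    downs = _tier_downgrades(comparisons)
    genes = gene_order or tuple(counts)
    missing = set(genes) - set(upregulated_tolerant)
    if missing:
        raise ValueError(f"missing up-regulation flags for: {sorted(missing)}")
    if trait_reversal_fraction is None:
        trait_reversal_fraction = {g: 0.0 for g in genes}
    missing = set(genes) - set(trait_reversal_fraction)
    if missing:
        raise ValueError(f"missing trait-reversal fractions for: {sorted(missing)}")
    if theta_conn == "median":
        theta_conn_val = float(np.median([conn_a[g] for g in genes])) if genes else 0.0
    else:
        theta_conn_val = float(theta_conn)

    profiles = []
    for g in genes:
        profile = NodeProfile(
            gene=g,
            connectivity={"tolerant": conn_a[g], "susceptible": conn_b[g]},
            reversal_count=counts[g],
            trait_reversal_fraction=trait_reversal_fraction[g],
            tier_downgrade_count=downs[g],
            upregulated_tolerant=upregulated_tolerant[g],
        )
        if (
            profile.reversal_count >= theta_rev
            and conn_a[g] >= theta_conn_val
            and profile.upregulated_tolerant
        ):
            profile.role = "hub"
        elif profile.trait_reversal_fraction >= theta_switch:
            profile.role = "phenotypic_switcher"
        else:
            profile.role = "contextual_responder"
        profiles.append(profile)
    return profiles


class DifferentialNetwork(BaseEstimator):
    """Two-genotype differential correlation-network estimator.

    Parameters
    ----------
    genotype_tolerant, genotype_susceptible : str
        Labels of the two genotypes to compare (network A is the tolerant
        one; reversal counts are symmetric in the pair).
    thresholds : (low, high)
        Tier boundaries on |r|.
    theta_rev, theta_conn, theta_switch : role-rule thresholds.
    basis : "replicates" | "treatment_means"
        Sample basis of the correlations (default: biological replicates
        pooled across both treatments, n = 2 x n_bio).
    scale : "fold" | "log"
        Expression values entering the networks: per-replicate fold
        changes (default) or -ddCt.
    alpha_up : significance level of the up-regulation t-test.

    Fitted attributes: ``correlations_`` (dict genotype -> CorrelationMatrix),
    ``gene_trait_`` (dict genotype -> genes x traits DataFrame),
    ``comparisons_`` (list of EdgeComparison), ``node_profiles_`` (list of
    NodeProfile), ``roles_`` (dict gene -> role), ``thresholds_used_``.
    """

    def __init__(
        self,
        genotype_tolerant: str = "Misr2",
        genotype_susceptible: str = "Line4",
        thresholds: tuple[float, float] = DEFAULT_TIER_THRESHOLDS,
        theta_rev: int = 3,
        theta_conn: float | str = "median",
        theta_switch: float = 1.0,
        basis: str = "replicates",
        scale: str = "fold",
        min_n: int = 3,
        alpha_up: float = 0.05,
        stress_treatment: str = "stress",
    ):
        self.genotype_tolerant = genotype_tolerant
        self.genotype_susceptible = genotype_susceptible
        self.thresholds = thresholds
        self.theta_rev = theta_rev
        self.theta_conn = theta_conn
        self.theta_switch = theta_switch
        self.basis = basis
        self.scale = scale
        self.min_n = min_n
        self.alpha_up = alpha_up
        self.stress_treatment = stress_treatment

    def fit(self, expression: pd.DataFrame, traits: pd.DataFrame | None = None):
        self.correlations_ = {}
        gene_order: tuple[str, ...] | None = None
        for g in (self.genotype_tolerant, self.genotype_susceptible):
            wide = expression_matrix(expression, g, scale=self.scale, basis=self.basis)
            if gene_order is None:
                gene_order = tuple(wide.columns)
            else:
                wide = wide[list(gene_order)]
            self.correlations_[g] = correlation_matrix(
                wide, min_n=self.min_n, genotype=g, basis=self.basis
            )
        self.gene_order_ = gene_order
        self.comparisons_ = compare_networks(
            self.correlations_[self.genotype_tolerant],
            self.correlations_[self.genotype_susceptible],
            self.thresholds,
        )
        self.gene_trait_ = {}
        frac = None
        if traits is not None:
            for g in (self.genotype_tolerant, self.genotype_susceptible):
                self.gene_trait_[g] = gene_trait_correlations(
                    expression, traits, g, scale=self.scale, min_n=self.min_n
                )
            frac = trait_reversal_fractions(
                self.gene_trait_[self.genotype_tolerant],
                self.gene_trait_[self.genotype_susceptible],
            )
        up = upregulated_genes(
            expression,
            self.genotype_tolerant,
            stress_treatment=self.stress_treatment,
            alpha=self.alpha_up,
        )
        self.node_profiles_ = classify_roles(
            self.comparisons_,
            upregulated_tolerant=up,
            trait_reversal_fraction=frac,
            theta_rev=self.theta_rev,
            theta_conn=self.theta_conn,
            theta_switch=self.theta_switch,
            gene_order=gene_order,
        )
        self.roles_ = {p.gene: p.role for p in self.node_profiles_}
        self.reversal_counts_ = node_reversal_counts(self.comparisons_)
        self.thresholds_used_ = {
            "tier_thresholds": self.thresholds,
            "theta_rev": self.theta_rev,
            "theta_conn": self.theta_conn,
            "theta_switch": self.theta_switch,
            "alpha_up": self.alpha_up,
            "basis": self.basis,
            "scale": self.scale,
        }
        return self

    def edge_table(self) -> pd.DataFrame:
        """Edge-wise comparison as a flat table."""
        if not hasattr(self, "comparisons_"):
            raise ValueError("DifferentialNetwork is not fitted")
        rows = [
            {
                "gene_a": c.pair[0],
                "gene_b": c.pair[1],
                "r_tolerant": c.a.r,
                "r_susceptible": c.b.r,
                "sign_tolerant": c.a.sign,
                "sign_susceptible": c.b.sign,
                "tier_tolerant": c.a.tier,
                "tier_susceptible": c.b.tier,
                "polarity_reversed": c.polarity_reversed,
                "robust": c.robust,
            }
            for c in self.comparisons_
        ]
        return pd.DataFrame(rows)

    def node_table(self) -> pd.DataFrame:
        if not hasattr(self, "node_profiles_"):
            raise ValueError("DifferentialNetwork is not fitted")
        return pd.DataFrame(
            [
                {
                    "gene": p.gene,
                    "connectivity_tolerant": p.connectivity["tolerant"],
                    "connectivity_susceptible": p.connectivity["susceptible"],
                    "reversal_count": p.reversal_count,
                    "trait_reversal_fraction": p.trait_reversal_fraction,
                    "tier_downgrade_count": p.tier_downgrade_count,
                    "upregulated_tolerant": p.upregulated_tolerant,
                    "role": p.role,
                }
                for p in self.node_profiles_
            ]
        )


_DOT_STYLE = {"strong": "bold", "medium": "solid", "weak": "dashed"}
_DOT_EDGE_COLOR = {"positive": "green", "negative": "red"}
_DOT_NODE_COLOR = {
    "hub": "red",
    "phenotypic_switcher": "green",
    "contextual_responder": "orange",
}


def _to_dot(
    corr: CorrelationMatrix,
    roles: dict[str, str],
    thresholds: tuple[float, float],
) -> str:
    """DOT rendering of one genotype network (line style = tier, edge color
    = sign, node color = role)."""
    lines = [f'graph "{corr.genotype}" {{']
    for g in corr.labels:
        color = _DOT_NODE_COLOR[roles[g]]
        lines.append(f'  "{g}" [style=filled, fillcolor={color}];')
    for i in range(len(corr.labels)):
        for j in range(i + 1, len(corr.labels)):
            e = classify_edge(corr.values[i, j], thresholds)
            lines.append(
                f'  "{corr.labels[i]}" -- "{corr.labels[j]}" '
                f'[style={_DOT_STYLE[e.tier]}, color={_DOT_EDGE_COLOR[e.sign]}, '
                f'label="{e.r:.2f}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_network(
    model: DifferentialNetwork,
    directory: str | Path,
    formats: tuple[str, ...] = ("tsv", "graphml", "dot"),
) -> list[Path]:
    """Serialize a fitted differential network.

    Writes an edge-comparison TSV, a GraphML graph with node/edge
    attributes, and per-genotype DOT files using the figure-legend visual
    encoding (double/bold line = strong, solid = medium, dashed = weak;
    green = positive, red = negative; node color = role).
    """
    known = {"tsv", "graphml", "dot"}
    unknown = set(formats) - known
    if unknown:
        raise ValueError(f"unknown formats: {sorted(unknown)} (choose from {sorted(known)})")
    if not hasattr(model, "comparisons_"):
        raise ValueError("DifferentialNetwork is not fitted")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    if "tsv" in formats:
        p = directory / "edges_compared.tsv"
        model.edge_table().to_csv(p, sep="\t", index=False)
        paths.append(p)
    if "graphml" in formats:
        G = nx.Graph()
        for prof in model.node_profiles_:
            G.add_node(
                prof.gene,
                role=prof.role,
                reversal_count=prof.reversal_count,
                connectivity_tolerant=prof.connectivity["tolerant"],
                connectivity_susceptible=prof.connectivity["susceptible"],
            )
        for c in model.comparisons_:
            G.add_edge(
                c.pair[0],
                c.pair[1],
                r_tolerant=c.a.r,
                r_susceptible=c.b.r,
                sign_tolerant=c.a.sign,
                sign_susceptible=c.b.sign,
                tier_tolerant=c.a.tier,
                tier_susceptible=c.b.tier,
                polarity_reversed=c.polarity_reversed,
            )
        p = directory / "network.graphml"
        nx.write_graphml(G, p)
        paths.append(p)
    if "dot" in formats:
        for g, corr in model.correlations_.items():
            p = directory / f"network_{g}.dot"
            p.write_text(_to_dot(corr, model.roles_, model.thresholds))
            paths.append(p)
    return paths
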