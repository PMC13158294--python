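"""Synthetic study generator with plantable ground truth.

Generates cycle-threshold (Ct) and trait tables for a two-genotype,
two-treatment factorial design so that every downstream stage — relative
quantification, trait statistics, PCA, and differential correlation
networks — can be exercised against a known answer.

Generative model
----------------
Per genotype, the latent log2 expression of gene *i* in replicate *r* is

    x_ir = sum_k  L_ik * f_kr  (+ biological noise, SD ``noise_sd_bio``)

where the factor scores ``f_kr`` are *fixed* orthonormal contrasts over the
2 x n_bio replicates: the treatment contrast first, then polynomial
replicate contrasts and their treatment interactions. Because the scores
are deterministic, the noiseless pooled-replicate correlation structure of
the study is fully determined by the loading matrix ``L``: the treatment
column of ``L`` sets each gene's stress log2 fold change, and the remaining
columns sculpt the correlation signs and magnitudes. Sign flips of loadings
between genotypes implement correlation polarity reversals.

Ct values are reference-anchored: ``Ct = baseline - x`` for targets and a
fixed baseline (default 20) for the reference gene, plus additive Gaussian
technical noise on the Ct scale, so the downstream 2^(-ddCt) computation
inverts the construction exactly when noise is zero.

Traits respond to the treatment contrast only (control mean + stress
effect + noise), which ties every gene-trait correlation sign to the sign
of the gene's treatment loading.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import PAPER_GENES, PAPER_TRAITS, StudyDesign, build_design

__all__ = [
    "GroundTruth",
    "TruthRecord",
    "factor_scores",
    "paper_like_truth",
    "generate_study",
    "write_fixtures",
    "load_paper_like",
    "PAPER_LIKE_SEED",
]

#: Seed used to build the packaged ``paper_like`` fixture.
PAPER_LIKE_SEED = 7

#: Planted stress log2 fold changes, tolerant genotype (canonical gene order).
#: TaHSP70 rises ~4.5-fold and TaPEX11.4 ~5.5-fold under stress; the five
#: peripheral genes are down-regulated.
_LFC_TOLERANT = (
    2.169925001442312,  # TaHSP70 = log2(4.5)
    -0.8,               # TaHSP90
    -1.0,               # TaSOD
    1.5,                # TaCAT1
    -1.2,               # TaPEX11.3
    2.4594316186372973,  # TaPEX11.4 = log2(5.5)
    -1.0,               # TaFIS1A
    -1.2,               # TaDRP5B
)

#: Planted stress log2 fold changes, susceptible genotype. TaSOD and TaDRP5B
#: switch direction (up-regulated here, down in the tolerant background);
#: TaHSP70 and TaPEX11.4 barely move.
_LFC_SUSCEPTIBLE = (0.2, -0.9, 1.0, 1.3, -1.1, 0.1, -0.9, 1.0)

#: Frozen loading matrix of the susceptible genotype (genes x 5 factors).
#: Column 0 realises the fold changes above; columns 1-4 realise the
#: sign-frustrated correlation topology (three distinct per-hub reversal
#: counts force a multi-factor structure; see docs/methods.md). The numbers
#: come from a one-time constrained construction maximising sign margins on
#: the fold-change scale subject to the planted sign and tier pattern.
_LOADINGS_SUSCEPTIBLE = (
    (0.10954451150103323, 0.3950982939114046, -1.2541175197824397, -1.1508399310688895, -0.10779561157513495),
    (-0.49295030175464954, 0.7876318299613326, 0.5230628815720141, -0.7767411326933725, 0.7417861994810672),
    (0.5477225575051661, -0.16632947888543076, 0.03248964288445457, -1.0776604412589343, 0.7958304496884919),
    (0.7120393247567159, -1.4993100742533225, -0.22480885765967043, -0.830198279165392, -0.3942762745509245),
    (-0.6024948132556828, 0.14461847907525127, -0.5515066979006078, -1.0020526083412638, 0.6575294956816138),
    (0.05477225575051661, 0.6131264233453605, -1.265915654710597, 0.25500399531214535, 0.23562317560302112),
    (-0.4929503017546495, -0.21210550394099714, -0.15061072060109534, -1.7122930693198672, -0.6845724530705215),
    (0.5477225575051661, -0.4856312148427705, -0.09620047884966354, -1.250408061412382, -0.3960796658804072),
)

#: Plausible qPCR Ct baselines (cycles at control-mean expression).
_BASELINE_CT = (24.0, 23.0, 25.0, 24.5, 26.0, 27.0, 25.5, 26.5)

#: trait -> (control mean tolerant, stress mean tolerant,
#:           control mean susceptible, stress mean susceptible, noise SD)
_TRAIT_PARAMS = {
    "grain_yield": (770.33, 389.79, 633.45, 273.25, 20.0),
    "h2o2": (2.0, 4.6, 2.2, 5.2, 0.12),
    "tss": (25.0, 45.0, 24.0, 35.0, 0.8),
    "proline": (2.0, 6.0, 2.2, 4.0, 0.12),
    "mda": (10.0, 18.0, 11.0, 22.0, 0.5),
    "chl_a": (1.80, 1.68, 1.78, 1.64, 0.01),
    "chl_b": (0.80, 0.74, 0.79, 0.72, 0.005),
    "carotenoids": (0.50, 0.46, 0.50, 0.45, 0.003),
    "sod_activity": (8.0, 14.0, 8.2, 9.0, 0.1),
    "pox_activity": (5.0, 9.5, 5.2, 8.0, 0.2),
    "cat_activity": (12.0, 18.0, 12.5, 17.0, 0.4),
    "peroxisome_abundance": (1000.0, 1600.0, 450.0, 800.0, 25.0),
}

CT_COLUMNS = ["sample_id", "genotype", "treatment", "bio_rep", "tech_rep", "gene", "ct"]
TRAIT_COLUMNS = ["genotype", "treatment", "bio_rep", "trait", "value", "unit"]


def factor_scores(n_bio: int) -> np.ndarray:
    """Fixed orthonormal factor scores for a 2 x ``n_bio`` replicate layout.

    Rows are ordered control replicates then stress replicates. Columns:
    the treatment contrast, then polynomial contrasts of the replicate
    index (degree 1..n_bio-1) tiled over both treatments, then the same
    contrasts multiplied by the treatment sign (+1 control, -1 stress).
    Every column has mean 0 and unit sample SD (ddof=1), and columns are
    mutually orthogonal, so the sample covariance of ``F @ L.T`` is exactly
    ``L @ L.T``.
    """
    if n_bio < 2:
        raise ValueError("factor scores need at least two biological replicates")
    n = 2 * n_bio
    tind = np.repeat([-1.0, 1.0], n_bio)

    # orthogonal polynomial contrasts over the replicate index
    idx = np.arange(n_bio, dtype=float)
    basis = [np.ones(n_bio)]
    polys = []
    for degree in range(1, n_bio):
        v = idx**degree
        for b in basis:
            v = v - (v @ b) / (b @ b) * b
        basis.append(v)
        polys.append(v)

    cols = [tind]
    for p in polys:
        cols.append(np.tile(p, 2))
    sgn = np.repeat([1.0, -1.0], n_bio)
    for p in polys:
        cols.append(np.tile(p, 2) * sgn)

    F = np.column_stack(cols)
    F = F - F.mean(axis=0)
    F = F / F.std(axis=0, ddof=1)
    return F


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic study.

    ``loadings`` maps genotype label -> (n_genes x K) latent-factor loading
    matrix (column 0 is the treatment axis; the planted stress log2 fold
    change of gene *i* equals ``2c * loadings[g][i, 0]`` with
    ``c = sqrt((n-1)/n)`` the treatment-contrast amplitude). The realised
    latent covariance is ``L @ L.T`` and therefore positive semidefinite by
    construction.
    """

    genes: tuple[str, ...]
    loadings: dict[str, np.ndarray]
    baseline_ct: dict[str, np.ndarray]
    trait_labels: tuple[str, ...]
    trait_control_mean: dict[str, np.ndarray]
    trait_stress_effect: dict[str, np.ndarray]
    trait_noise_sd: np.ndarray
    reference_ct: float = 20.0
    noise_sd_bio: float = 0.1
    noise_sd_tech: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd_bio < 0 or self.noise_sd_tech < 0:
            raise ValueError("noise SDs must be non-negative")
        n_genes = len(self.genes)
        for g, L in self.loadings.items():
            L = np.asarray(L, dtype=float)
            self.loadings[g] = L
            if L.shape[0] != n_genes:
                raise ValueError(f"loadings for {g!r} have {L.shape[0]} rows, expected {n_genes}")
        for g, b in self.baseline_ct.items():
            b = np.asarray(b, dtype=float)
            self.baseline_ct[g] = b
            if b.shape != (n_genes,):
                raise ValueError(f"baseline_ct for {g!r} has wrong shape")
        nt = len(self.trait_labels)
        for d in (self.trait_control_mean, self.trait_stress_effect):
            for g, v in d.items():
                d[g] = np.asarray(v, dtype=float)
                if d[g].shape != (nt,):
                    raise ValueError(f"trait parameter vector for {g!r} has wrong shape")
        self.trait_noise_sd = np.asarray(self.trait_noise_sd, dtype=float)
        if np.any(self.trait_noise_sd < 0):
            raise ValueError("trait noise SDs must be non-negative")

    def planted_lfc(self, genotype: str, n_bio: int) -> np.ndarray:
        """Planted stress log2 fold change per gene for the given genotype."""
        n = 2 * n_bio
        c = np.sqrt((n - 1) / n)
        return 2 * c * self.loadings[genotype][:, 0]

    def with_noise(self, sd_bio: float, sd_tech: float) -> "GroundTruth":
        """Copy of this truth with different noise levels."""
        return GroundTruth(
            genes=self.genes,
            loadings={g: L.copy() for g, L in self.loadings.items()},
            baseline_ct={g: b.copy() for g, b in self.baseline_ct.items()},
            trait_labels=self.trait_labels,
            trait_control_mean={g: v.copy() for g, v in self.trait_control_mean.items()},
            trait_stress_effect={g: v.copy() for g, v in self.trait_stress_effect.items()},
            trait_noise_sd=self.trait_noise_sd.copy(),
            reference_ct=self.reference_ct,
            noise_sd_bio=sd_bio,
            noise_sd_tech=sd_tech,
        )


def paper_like_truth(design: StudyDesign | None = None) -> GroundTruth:
    """Default ground truth reproducing the study's qualitative topology.

    The tolerant genotype has a pure single-factor (treatment-driven)
    structure: every gene-gene correlation is +/-1 before noise, and the
    planted fold changes include the 4.5-fold TaHSP70 and 5.5-fold
    TaPEX11.4 inductions. The susceptible genotype uses the frozen
    five-factor loadings, which plant polarity reversals on 6 of TaCAT1's,
    5 of TaHSP70's and 3 of TaPEX11.4's gene-gene edges, four strong-to-
    medium tier downgrades for TaPEX11.4, full trait-sign reversals for
    TaSOD and TaDRP5B, and stable co-regulation among the five peripheral
    genes.
    """
    design = design or StudyDesign()
    if design.genes != PAPER_GENES or design.trait_labels != tuple(t.label for t in PAPER_TRAITS):
        raise ValueError("paper_like_truth requires the default gene and trait lists")
    if design.n_bio != 3:
        raise ValueError("paper_like_truth is calibrated for n_bio=3")
    tol, sus = design.tolerant, design.susceptible
    c = np.sqrt(5.0 / 6.0)
    L_tol = np.zeros((8, 5))
    L_tol[:, 0] = np.asarray(_LFC_TOLERANT) / (2 * c)
    L_sus = np.array(_LOADINGS_SUSCEPTIBLE)
    base = np.asarray(_BASELINE_CT)
    params = {t: _TRAIT_PARAMS[t] for t in design.trait_labels}
    ctrl_tol = np.array([p[0] for p in params.values()])
    eff_tol = np.array([p[1] - p[0] for p in params.values()])
    ctrl_sus = np.array([p[2] for p in params.values()])
    eff_sus = np.array([p[3] - p[2] for p in params.values()])
    sd = np.array([p[4] for p in params.values()])
    return GroundTruth(
        genes=design.genes,
        loadings={tol: L_tol, sus: L_sus},
        baseline_ct={tol: base.copy(), sus: base.copy()},
        trait_labels=design.trait_labels,
        trait_control_mean={tol: ctrl_tol, sus: ctrl_sus},
        trait_stress_effect={tol: eff_tol, sus: eff_sus},
        trait_noise_sd=sd,
    )


@dataclass
class TruthRecord:
    """Everything needed to check that the pipeline recovers the plant.

    All quantities are computed from the noiseless forward pass of the
    generator (deterministic given the ground truth), on the same scale the
    pipeline reports: fold changes are arithmetic means of per-replicate
    2^(-ddCt) values, and correlations are Pearson r of per-replicate fold
    changes pooled across both treatments.
    """

    seed: int
    genes: tuple[str, ...]
    trait_labels: tuple[str, ...]
    genotypes: tuple[str, ...]
    planted_lfc: dict[str, np.ndarray]
    expected_fold_change: dict[str, np.ndarray]
    gene_corr: dict[str, np.ndarray]
    gene_trait_corr: dict[str, np.ndarray]
    noise_sd_bio: float
    noise_sd_tech: float

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "genes": list(self.genes),
            "trait_labels": list(self.trait_labels),
            "genotypes": list(self.genotypes),
            "planted_lfc": {g: v.tolist() for g, v in self.planted_lfc.items()},
            "expected_fold_change": {g: v.tolist() for g, v in self.expected_fold_change.items()},
            "gene_corr": {g: v.tolist() for g, v in self.gene_corr.items()},
            "gene_trait_corr": {g: v.tolist() for g, v in self.gene_trait_corr.items()},
            "noise_sd_bio": self.noise_sd_bio,
            "noise_sd_tech": self.noise_sd_tech,
        }


def _noiseless_profiles(design: StudyDesign, truth: GroundTruth, genotype: str):
    """Deterministic per-replicate fold-change and trait profiles."""
    F = factor_scores(design.n_bio)
    L = truth.loadings[genotype]
    X = F[:, : L.shape[1]] @ L.T  # (n, genes), log2 deviations
    ctrl = X[: design.n_bio].mean(axis=0)
    fc = 2.0 ** (X - ctrl)
    t_ind = np.repeat([0.0, 1.0], design.n_bio)
    traits = (
        truth.trait_control_mean[genotype][None, :]
        + t_ind[:, None] * truth.trait_stress_effect[genotype][None, :]
    )
    return fc, traits


def _safe_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation between blocks, NaN for zero variance."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a**2).sum(axis=0))
    sb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a.T @ b) / np.outer(sa, sb)
    return r


def build_truth_record(design: StudyDesign, truth: GroundTruth, seed: int) -> TruthRecord:
    planted_lfc, expected_fc, gcorr, gtcorr = {}, {}, {}, {}
    for g in design.genotype_labels:
        fc, traits = _noiseless_profiles(design, truth, g)
        planted_lfc[g] = truth.planted_lfc(g, design.n_bio)
        expected_fc[g] = fc[design.n_bio :].mean(axis=0)
        gcorr[g] = _safe_corr(fc, fc)
        gtcorr[g] = _safe_corr(fc, traits)
    return TruthRecord(
        seed=seed,
        genes=design.genes,
        trait_labels=design.trait_labels,
        genotypes=design.genotype_labels,
        planted_lfc=planted_lfc,
        expected_fold_change=expected_fc,
        gene_corr=gcorr,
        gene_trait_corr=gtcorr,
        noise_sd_bio=truth.noise_sd_bio,
        noise_sd_tech=truth.noise_sd_tech,
    )


def generate_study(
    design: StudyDesign, truth: GroundTruth, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate one study: long Ct table, long trait table, truth record.

    The master seed is split into deterministic per-genotype substreams
    (NumPy ``SeedSequence.spawn`` over PCG64), so adding genotypes or
    re-ordering downstream consumers never perturbs existing draws.
    Identical seeds give identical tables.
    """
    genotypes = design.genotype_labels
    for g in genotypes:
        if g not in truth.loadings:
            raise ValueError(f"ground truth has no loadings for genotype {g!r}")
        K = truth.loadings[g].shape[1]
        if K > 2 * design.n_bio - 1:
            raise ValueError(
                f"{K} latent factors cannot be realised over {2 * design.n_bio} replicates"
            )
    if len(truth.genes) != len(design.genes):
        raise ValueError("ground truth gene dimension does not match the design")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(genotypes))
    expr_rngs = {g: np.random.default_rng(children[i]) for i, g in enumerate(genotypes)}
    trait_rngs = {
        g: np.random.default_rng(children[len(genotypes) + i]) for i, g in enumerate(genotypes)
    }

    F = factor_scores(design.n_bio)
    n = 2 * design.n_bio
    units = design.trait_units

    ct_rows, trait_rows = [], []
    for g in genotypes:
        L = truth.loadings[g]
        rng = expr_rngs[g]
        X = F[:, : L.shape[1]] @ L.T
        if truth.noise_sd_bio > 0:
            X = X + rng.normal(0.0, truth.noise_sd_bio, X.shape)
        for r in range(n):
            treatment = design.treatments[0] if r < design.n_bio else design.treatments[1]
            bio = (r % design.n_bio) + 1
            sample = f"{g}_{treatment}_b{bio}"
            for t in range(1, design.n_tech + 1):
                for j, gene in enumerate(design.genes):
                    ct = truth.baseline_ct[g][j] - X[r, j]
                    if truth.noise_sd_tech > 0:
                        ct += rng.normal(0.0, truth.noise_sd_tech)
                    ct_rows.append((sample, g, treatment, bio, t, gene, ct))
                ct_ref = truth.reference_ct
                if truth.noise_sd_tech > 0:
                    ct_ref += rng.normal(0.0, truth.noise_sd_tech)
                ct_rows.append((sample, g, treatment, bio, t, design.reference_gene, ct_ref))

        trng = trait_rngs[g]
        for r in range(n):
            treatment = design.treatments[0] if r < design.n_bio else design.treatments[1]
            bio = (r % design.n_bio) + 1
            stress = 0.0 if r < design.n_bio else 1.0
            for k, trait in enumerate(design.trait_labels):
                value = (
                    truth.trait_control_mean[g][k]
                    + stress * truth.trait_stress_effect[g][k]
                )
                if truth.trait_noise_sd[k] > 0:
                    value += trng.normal(0.0, truth.trait_noise_sd[k])
                trait_rows.append((g, treatment, bio, trait, value, units[trait]))

    ct_table = pd.DataFrame(ct_rows, columns=CT_COLUMNS)
    trait_table = pd.DataFrame(trait_rows, columns=TRAIT_COLUMNS)
    record = build_truth_record(design, truth, seed)
    return ct_table, trait_table, record


def write_fixtures(
    ct_table: pd.DataFrame,
    trait_table: pd.DataFrame,
    directory: str | Path,
    truth_record: TruthRecord | None = None,
) -> list[Path]:
    """Write study tables (and optionally the truth record) as CSV/JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("ct_table.csv", ct_table), ("trait_table.csv", trait_table)):
        p = directory / name
        df.to_csv(p, index=False, float_format="%.6f")
        paths.append(p)
    if truth_record is not None:
        p = directory / "truth.json"
        p.write_text(json.dumps(truth_record.to_jsonable(), indent=1))
        paths.append(p)
    return paths


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trait table is missing columns: {sorted(missing)}")
    return df


def load_paper_like() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the packaged paper-like fixture (Ct table, trait table).

    The fixture is one realisation of the default design and ground truth at
    seed ``PAPER_LIKE_SEED``; its planted structure reproduces the study's
    qualitative network topology.
    """
    root = resources.files("polarnet").joinpath("data/paper_like")
    with resources.as_file(root.joinpath("ct_table.csv")) as p:
        ct = read_ct_table(p)
    with resources.as_file(root.joinpath("trait_table.csv")) as p:
        traits = read_trait_table(p)
    return ct, traits
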