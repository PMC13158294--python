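"""Relative quantification: Livak algebra, replicate handling, invariants."""
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polarnet as pn
from polarnet import qpcr


def _ct_table(rows):
    """rows: (genotype, treatment, bio_rep, tech_rep, gene, ct)"""
    df = pd.DataFrame(rows, columns=["genotype", "treatment", "bio_rep", "tech_rep", "gene", "ct"])
    df.insert(0, "sample_id", df["genotype"] + "_" + df["treatment"] + "_b" + df["bio_rep"].astype(str))
    return df


def _simple_study(ct_by_cell):
    """ct_by_cell: {(treatment, bio_rep): target_ct}; reference fixed at 20."""
    rows = []
    for (trt, b), ct in ct_by_cell.items():
        rows.append(("G", trt, b, 1, "gene1", ct))
        rows.append(("G", trt, b, 1, "Ref", 20.0))
    return _ct_table(rows)


@pytest.mark.parametrize(
    "reps, expected",
    [([20.0, 20.2, 19.8], 20.0), ([21.5], 21.5), ([18.0, 19.0, 23.0], 20.0)],
)
def test_technical_replicates_average_on_ct_scale(reps, expected):
    rows = [("G", "control", 1, i + 1, "gene1", ct) for i, ct in enumerate(reps)]
    rows += [("G", "control", 1, i + 1, "Ref", 20.0) for i in range(len(reps))]
    out = qpcr.average_technical_reps(_ct_table(rows))
    row = out[out["gene"] == "gene1"].iloc[0]
    assert row["ct"] == pytest.approx(expected)
    assert row["n_tech"] == len(reps)


def test_missing_tech_reps_dropped_with_warning_all_missing_raises():
    rows = [
        ("G", "control", 1, 1, "gene1", 20.0),
        ("G", "control", 1, 2, "gene1", np.nan),
        ("G", "control", 1, 1, "Ref", 20.0),
    ]
    with pytest.warns(UserWarning, match="dropping"):
        out = qpcr.average_technical_reps(_ct_table(rows))
    assert out[out["gene"] == "gene1"]["n_tech"].iloc[0] == 1

    rows = [
        ("G", "control", 1, 1, "gene1", np.nan),
        ("G", "control", 1, 1, "Ref", 20.0),
        ("G", "control", 2, 1, "gene1", 21.0),
        ("G", "control", 2, 1, "Ref", 20.0),
    ]
    with pytest.raises(ValueError, match="lost all technical replicates"):
        with pytest.warns(UserWarning):
            qpcr.average_technical_reps(_ct_table(rows))


def test_ct_window_enforced():
    rows = [("G", "control", 1, 1, "gene1", 47.0), ("G", "control", 1, 1, "Ref", 20.0)]
    with pytest.raises(ValueError, match="window"):
        qpcr.average_technical_reps(_ct_table(rows))


def test_delta_ct_is_target_minus_reference():
    rows = [("G", "control", 1, 1, "gene1", 25.0), ("G", "control", 1, 1, "Ref", 20.0)]
    out = qpcr.delta_ct(qpcr.average_technical_reps(_ct_table(rows)), "Ref")
    assert out["delta_ct"].iloc[0] == pytest.approx(5.0)


def test_reference_cannot_be_its_own_target():
    rows = [("G", "control", 1, 1, "gene1", 25.0), ("G", "control", 1, 1, "Ref", 20.0)]
    means = qpcr.average_technical_reps(_ct_table(rows))
    with pytest.raises(ValueError, match="against itself"):
        qpcr.delta_ct(means, "Ref", targets=["Ref"])


def test_full_study_yields_complete_delta_ct_grid(study, design):
    """8 genes x (2 genotypes x 2 treatments x 3 reps) = 96 values, none missing."""
    ct, _, _ = study
    means = qpcr.average_technical_reps(ct)
    dct = qpcr.delta_ct(means, design.reference_gene)
    assert len(dct) == 8 * 12
    assert dct["delta_ct"].notna().all()


@pytest.mark.parametrize("ddct, expected", [(0.0, 1.0), (-2.0, 4.0), (1.0, 0.5)])
def test_fold_change_is_two_to_minus_ddct(ddct, expected):
    table = pd.DataFrame(
        {
            "genotype": ["G", "G"],
            "treatment": ["control", "stress"],
            "bio_rep": [1, 1],
            "gene": ["gene1", "gene1"],
            "delta_ct": [0.0, ddct],
        }
    )
    out = qpcr.fold_change(table)
    assert out[out["treatment"] == "stress"]["fold_change"].iloc[0] == pytest.approx(expected)


def test_fold_change_hand_oracle():
    """control dCt {2.0, 2.2, 1.8}, stress dCt {0.0, 0.2, -0.2}: calibrator
    mean 2.0, stress fold changes {4.00, 3.48, 4.59}, mean ~= 4.03."""
    table = pd.DataFrame(
        {
            "genotype": "G",
            "treatment": ["control"] * 3 + ["stress"] * 3,
            "bio_rep": [1, 2, 3, 1, 2, 3],
            "gene": "gene1",
            "delta_ct": [2.0, 2.2, 1.8, 0.0, 0.2, -0.2],
        }
    )
    out = qpcr.fold_change(table)
    stress = out[out["treatment"] == "stress"]["fold_change"].to_numpy()
    np.testing.assert_allclose(sorted(stress), [2**1.8, 2**2.0, 2**2.2], rtol=1e-12)
    assert stress.mean() == pytest.approx((2**1.8 + 4.0 + 2**2.2) / 3, rel=1e-12)
    assert stress.mean() == pytest.approx(4.02, abs=0.01)


def test_empty_calibrator_raises():
    table = pd.DataFrame(
        {"genotype": ["G"], "treatment": ["stress"], "bio_rep": [1], "gene": ["g"], "delta_ct": [1.0]}
    )
    with pytest.raises(ValueError, match="calibrator"):
        qpcr.fold_change(table)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    dcts=st.lists(
        st.tuples(
            st.floats(min_value=-5, max_value=10),
            st.floats(min_value=-5, max_value=10),
        ),
        min_size=2,
        max_size=8,
    )
)
def test_calibrator_geometric_mean_is_one_and_folds_positive(dcts):
    """Invariant: within the calibrator group, fold changes have geometric
    mean 1 (to 1e-9) and every fold change is positive."""
    table = pd.DataFrame(
        {
            "genotype": "G",
            "treatment": ["control"] * len(dcts) + ["stress"] * len(dcts),
            "bio_rep": list(range(len(dcts))) * 2,
            "gene": "gene1",
            "delta_ct": [a for a, _ in dcts] + [b for _, b in dcts],
        }
    )
    out = qpcr.fold_change(table)
    assert (out["fold_change"] > 0).all()
    cal = out[out["treatment"] == "control"]["fold_change"]
    gmean = np.exp(np.log(cal).mean())
    assert gmean == pytest.approx(1.0, abs=1e-9)
    # monotone: larger ddCt => smaller fold change
    srt = out.sort_values("delta_delta_ct")["fold_change"].to_numpy()
    assert (np.diff(srt) <= 1e-12).all()


@settings(deadline=None, derandomize=True, max_examples=20)
@given(offset=st.floats(min_value=-3, max_value=3))
def test_pipeline_equivariant_to_global_ct_offset(offset):
    """Shifting every Ct (targets and reference alike) leaves dCt unchanged."""
    cells = {("control", 1): 24.0, ("control", 2): 24.4, ("stress", 1): 22.0, ("stress", 2): 21.6}
    base = _simple_study(cells)
    shifted = base.copy()
    shifted["ct"] = shifted["ct"] + offset
    d0 = qpcr.delta_ct(qpcr.average_technical_reps(base), "Ref")
    d1 = qpcr.delta_ct(qpcr.average_technical_reps(shifted), "Ref")
    np.testing.assert_allclose(d0["delta_ct"], d1["delta_ct"], atol=1e-12)


def test_replicate_missing_reference_excluded_with_warning():
    rows = [
        ("G", "control", 1, 1, "gene1", 25.0),
        ("G", "control", 1, 1, "Ref", 20.0),
        ("G", "control", 2, 1, "gene1", 25.5),  # no reference in rep 2
    ]
    means = qpcr.average_technical_reps(_ct_table(rows))
    with pytest.warns(UserWarning, match="missing the reference"):
        out = qpcr.delta_ct(means, "Ref")
    assert len(out) == 1 and out["bio_rep"].iloc[0] == 1


def test_summary_single_replicate_flagged():
    expr = pd.DataFrame(
        {
            "genotype": ["G"],
            "treatment": ["stress"],
            "bio_rep": [1],
            "gene": ["gene1"],
            "fold_change": [3.0],
        }
    )
    with pytest.warns(UserWarning, match="single"):
        out = qpcr.summarize_expression(expr)
    assert out["sd_fold_change"].iloc[0] == 0.0
    assert bool(out["single_replicate"].iloc[0])


def test_quantifier_estimator_matches_functional_path(study, design):
    ct, _, _ = study
    est = pn.DeltaDeltaCtQuantifier(reference_gene=design.reference_gene)
    expr_est = est.fit(ct).transform(ct)
    expr_fn = pn.quantify(ct, design.reference_gene)
    np.testing.assert_allclose(
        expr_est.sort_values(["genotype", "treatment", "bio_rep", "gene"])["fold_change"],
        expr_fn.sort_values(["genotype", "treatment", "bio_rep", "gene"])["fold_change"],
        rtol=1e-12,
    )
    # sklearn param plumbing
    assert est.get_params()["reference_gene"] == design.reference_gene
    from sklearn.base import clone

    est2 = clone(est)
    assert est2.get_params() == est.get_params()


def test_group_summary_recovers_planted_induction(expression):
    """The 4.5-fold planted induction is recovered within the noise envelope."""
    summary = pn.summarize_expression(expression)
    row = summary[
        (summary["genotype"] == "Misr2")
        & (summary["treatment"] == "stress")
        & (summary["gene"] == "TaHSP70")
    ].iloc[0]
    assert row["mean_fold_change"] == pytest.approx(4.5, rel=0.25)
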