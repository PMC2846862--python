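"""Transcript-pool dissection and standard-curve qPCR quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ncf1cnv import (
    CopyNumberTrio,
    ExpressionModel,
    cdna_gt_ratio,
    dissect_contributions,
    fit_standard_curve,
    normalized_fold_change,
    per_copy_activity,
    quantify,
    simulate_expression,
)
from ncf1cnv.errors import AssayInconsistencyError, DomainError, FitError
from ncf1cnv.expression import StandardCurve


@pytest.mark.parametrize(
    "f_gtgt, f_g, expected",
    [
        # monocyte (pre-differentiation) pool: 32.9% B / 52.7% N / 14.4% C
        (0.527, 0.144, (0.329, 0.527, 0.144)),
        # macrophage (post-differentiation) pool: 8.3% / 80.4% / 11.3%
        (0.804, 0.113, (0.083, 0.804, 0.113)),
        (1.0, 0.0, (0.0, 1.0, 0.0)),
    ],
)
def test_dissection_worked_examples(f_gtgt, f_g, expected):
    c = dissect_contributions(f_gtgt, f_g)
    assert c.as_tuple() == pytest.approx(expected, abs=1e-12)


def test_dissection_clips_small_negative_residue():
    c = dissect_contributions(0.60, 0.41, tol=0.02)  # implied p_B = -0.01
    assert c.p_b == 0.0
    assert c.p_n + c.p_c == pytest.approx(1.0)
    assert c.p_n / c.p_c == pytest.approx(0.60 / 0.41)


def test_dissection_rejects_inconsistent_assays():
    with pytest.raises(AssayInconsistencyError, match="0.6"):
        dissect_contributions(0.60, 0.45, tol=0.02)


@given(f_gtgt=st.floats(0, 1), f_g=st.floats(0, 1))
@settings(derandomize=True, max_examples=200)
def test_dissection_always_sums_to_one(f_gtgt, f_g):
    try:
        c = dissect_contributions(f_gtgt, f_g)
    except AssayInconsistencyError:
        return
    assert sum(c.as_tuple()) == pytest.approx(1.0, abs=1e-9)
    assert min(c.as_tuple()) >= 0


@pytest.mark.parametrize(
    "shares, ratio",
    [
        ((1 / 6, 2 / 3, 1 / 6), 0.5),  # individual-6 pattern: 0.5:1 in cDNA
        ((0.0, 1.0, 0.0), 0.0),
        ((0.329, 0.527, 0.144), 0.897),
    ],
)
def test_cdna_gt_ratio(shares, ratio):
    from ncf1cnv.expression import TranscriptContributions

    c = TranscriptContributions(*shares)
    assert cdna_gt_ratio(c) == pytest.approx(ratio, abs=1e-3)


def test_cdna_ratio_undefined_without_ncf1_share():
    from ncf1cnv.expression import TranscriptContributions

    with pytest.raises(DomainError):
        cdna_gt_ratio(TranscriptContributions(0.5, 0.0, 0.5))


def test_per_copy_activity_individual_six():
    """4 pseudogene copies carrying 1/3 of the pool vs 2 NCF1 copies carrying
    2/3: each pseudogene copy works at a quarter of an NCF1 copy's rate."""
    from ncf1cnv.expression import TranscriptContributions

    c = TranscriptContributions(1 / 6, 2 / 3, 1 / 6)
    act = per_copy_activity(c, CopyNumberTrio(2, 2, 2))
    assert act["n"] == pytest.approx(1.0)
    assert act["b"] == pytest.approx(0.25)
    assert act["c"] == pytest.approx(0.25)
    # combined pseudogene pool activity: (1/3 over 4 copies) vs (2/3 over 2)
    combined = ((c.p_b + c.p_c) / 4) / (c.p_n / 2)
    assert combined == pytest.approx(0.25)


def test_per_copy_activity_uniform_and_silent():
    from ncf1cnv.expression import TranscriptContributions

    uniform = per_copy_activity(
        TranscriptContributions(1 / 3, 1 / 3, 1 / 3), CopyNumberTrio(2, 2, 2)
    )
    assert all(v == pytest.approx(1.0) for v in uniform.values())
    silent = per_copy_activity(
        TranscriptContributions(0.0, 1.0, 0.0), CopyNumberTrio(2, 2, 2)
    )
    assert silent["b"] == silent["c"] == 0.0


def test_activity_impossible_with_share_but_no_copies():
    from ncf1cnv.expression import TranscriptContributions

    with pytest.raises(DomainError, match="0 copies"):
        per_copy_activity(
            TranscriptContributions(0.2, 0.6, 0.2), CopyNumberTrio(0, 2, 2)
        )


def test_standard_curve_two_point_exact():
    """(1, 30) and (10, 26.6781) give slope -3.3219, i.e. efficiency 1."""
    curve = fit_standard_curve([(1.0, 30.0), (10.0, 26.6781)])
    assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
    assert curve.intercept == pytest.approx(30.0, abs=1e-9)
    assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
    assert curve.r_squared == pytest.approx(1.0)


def test_standard_curve_requires_two_distinct_quantities():
    with pytest.raises(FitError):
        fit_standard_curve([(1.0, 30.0)])
    with pytest.raises(FitError):
        fit_standard_curve([(1.0, 30.0), (1.0, 29.5)])


def test_positive_slope_flagged_invalid():
    curve = fit_standard_curve([(1.0, 26.0), (10.0, 30.0)])
    assert not curve.valid


def test_quantify_interpolation():
    curve = StandardCurve(slope=-3.3219, intercept=30.0, r_squared=1.0)
    assert quantify(30.0, curve) == pytest.approx(1.0)
    # one cycle earlier at efficiency 1 means twice the template
    assert quantify(29.0, curve) / quantify(30.0, curve) == pytest.approx(2.0, abs=1e-3)
    assert quantify(30.0 - 3.3219, curve) == pytest.approx(10.0, abs=1e-3)


def test_quantify_round_trips_collinear_calibration_points():
    pts = [(1.0, 30.0), (0.1, 33.3219), (0.01, 36.6438)]
    curve = fit_standard_curve(pts)
    for q, ct in pts:
        assert quantify(ct, curve) == pytest.approx(q, rel=1e-4)


def _qpcr_frames(model, conditions, seed, n_replicates=5):
    _, qpcr, _ = simulate_expression(
        {"s": CopyNumberTrio(2, 2, 2)}, model, conditions,
        n_replicates=n_replicates, seed=seed,
    )
    return (qpcr[qpcr.gene == "NCF1_total"], qpcr[qpcr.gene == "reference"])


_PERFECT_TARGET = StandardCurve(-3.3219280948873623, 30.0, 1.0)
_PERFECT_REF = StandardCurve(-3.3219280948873623, 25.0, 1.0)


def test_fold_change_identical_conditions_is_one():
    model = ExpressionModel(ct_noise_sd=0.0,
                            condition_multipliers={"a": 1.0, "b": 1.0})
    tgt, ref = _qpcr_frames(model, ["a", "b"], seed=0)
    fc = normalized_fold_change(tgt, ref, _PERFECT_TARGET, _PERFECT_REF, "a", "b")
    assert fc.fold == pytest.approx(1.0, abs=1e-9)


def test_fold_change_one_cycle_shift_doubles():
    """Target down one Ct with reference unchanged at efficiency 1 -> fold 2."""
    model = ExpressionModel(ct_noise_sd=0.0,
                            condition_multipliers={"base": 1.0, "up": 2.0})
    tgt, ref = _qpcr_frames(model, ["base", "up"], seed=0)
    d_ct = tgt[tgt.condition == "up"].ct.mean() - tgt[tgt.condition == "base"].ct.mean()
    assert d_ct == pytest.approx(-1.0, abs=1e-9)
    fc = normalized_fold_change(tgt, ref, _PERFECT_TARGET, _PERFECT_REF, "base", "up")
    assert fc.fold == pytest.approx(2.0, abs=1e-9)


def test_fold_change_recovers_simulated_upregulation():
    """A true 1.34-fold induction is recovered within the replicate CI."""
    model = ExpressionModel(condition_multipliers={"mono": 1.0, "macro": 1.34},
                            ct_noise_sd=0.1)
    folds = []
    for seed in range(10):
        tgt, ref = _qpcr_frames(model, ["mono", "macro"], seed=seed)
        fc = normalized_fold_change(
            tgt, ref, _PERFECT_TARGET, _PERFECT_REF, "mono", "macro"
        )
        folds.append(fc.fold)
    mean_fold = np.mean(folds)
    se = np.std(folds, ddof=1) / np.sqrt(len(folds))
    assert abs(mean_fold - 1.34) < 3 * se + 0.02


def test_fold_change_invariant_to_plate_offset():
    """Adding a constant Ct to every well cancels in the normalisation."""
    model = ExpressionModel(ct_noise_sd=0.0,
                            condition_multipliers={"a": 1.0, "b": 1.6})
    tgt, ref = _qpcr_frames(model, ["a", "b"], seed=0)
    base = normalized_fold_change(tgt, ref, _PERFECT_TARGET, _PERFECT_REF, "a", "b")
    tgt2, ref2 = tgt.copy(), ref.copy()
    tgt2["ct"] += 1.7
    ref2["ct"] += 1.7
    shifted = normalized_fold_change(tgt2, ref2, _PERFECT_TARGET, _PERFECT_REF, "a", "b")
    assert shifted.fold == pytest.approx(base.fold, rel=1e-9)


def test_fold_change_needs_baseline_and_replicates():
    from ncf1cnv.errors import InputError

    model = ExpressionModel(ct_noise_sd=0.0)
    tgt, ref = _qpcr_frames(model, ["baseline"], seed=0)
    with pytest.raises(InputError, match="missing"):
        normalized_fold_change(tgt, ref, _PERFECT_TARGET, _PERFECT_REF,
                               "baseline", "treated")
    tgt1, ref1 = _qpcr_frames(
        ExpressionModel(ct_noise_sd=0.0, condition_multipliers={"a": 1, "b": 1}),
        ["a", "b"], seed=0, n_replicates=1,
    )
    with pytest.raises(InputError, match="replicates"):
        normalized_fold_change(tgt1, ref1, _PERFECT_TARGET, _PERFECT_REF, "a", "b")
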