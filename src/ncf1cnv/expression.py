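"""Transcript-pool dissection and standard-curve RT-qPCR quantification.

The exon-2 cDNA assay sees only transcripts that retain the (mutant GT or
wild-type GTGT) exon 2 — the "GT-containing pool".  Within that pool the two
PSV fractions identify each paralog's contribution directly:

* the GTGT fraction of the exon-2 cDNA assay is NCF1's share ``p_N``;
* the G fraction of the exon-9 cDNA assay is NCF1C's share ``p_C``;
* NCF1B's share is the remainder ``p_B = 1 - p_N - p_C``.

Because ``p_B`` is obtained by subtraction it inherits both assays' errors;
small negative values within a tolerance are clipped and the shares
renormalised, larger ones raise.

qPCR quantification follows the standard-curve method: a least-squares line
of Ct on log10(quantity) over serial dilutions defines slope, intercept and
amplification efficiency E = 10^(-1/slope) - 1; unknowns are interpolated
as Q = 10^((Ct - intercept)/slope).  Fold changes are computed on
replicate-level reference-normalised quantities so a t-test across
replicates is well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayInconsistencyError, DomainError, FitError, InputError
from .popstats import TTestMethod, TTestResult, two_sample_t
from .psv_model import CopyNumberTrio

__all__ = [
    "TranscriptContributions",
    "StandardCurve",
    "dissect_contributions",
    "cdna_gt_ratio",
    "per_copy_activity",
    "fit_standard_curve",
    "quantify",
    "normalized_fold_change",
    "FoldChangeResult",
]


@dataclass(frozen=True)
class TranscriptContributions:
    """Shares of the GT/GTGT-containing transcript pool per paralog."""

    p_b: float
    p_n: float
    p_c: float

    def __post_init__(self) -> None:
        s = self.p_b + self.p_n + self.p_c
        if abs(s - 1.0) > 1e-9:
            raise InputError(f"contributions must sum to 1, got {s}")
        if min(self.p_b, self.p_n, self.p_c) < -1e-12:
            raise InputError("contributions must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_b, self.p_n, self.p_c)


@dataclass(frozen=True)
class StandardCurve:
    """Ct = slope * log10(quantity) + intercept, with derived efficiency."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 = perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


def dissect_contributions(
    f_gtgt_cdna: float, f_g_cdna: float, tol: float = 0.02
) -> TranscriptContributions:
    """Per-paralog shares of the GT-containing pool from the two cDNA assays.

    ``f_gtgt_cdna`` — GTGT fraction at exon 2; ``f_g_cdna`` — G fraction at
    exon 9.  A subtraction residue p_B in [-tol, 0) is clipped to zero and
    the shares renormalised; below -tol the assays are declared inconsistent.
    """
    for name, v in (("f_gtgt_cdna", f_gtgt_cdna), ("f_g_cdna", f_g_cdna)):
        if not 0.0 <= v <= 1.0:
            raise InputError(f"{name}={v} outside [0, 1]")
    p_n, p_c = f_gtgt_cdna, f_g_cdna
    p_b = 1.0 - p_n - p_c
    if p_b < -tol:
        raise AssayInconsistencyError(
            f"implied NCF1B share {p_b:.4f} < -tol with f_GTGT={f_gtgt_cdna}, "
            f"f_G={f_g_cdna}: assays inconsistent"
        )
    if p_b < 0:
        total = p_n + p_c
        p_b, p_n, p_c = 0.0, p_n / total, p_c / total
    return TranscriptContributions(p_b, p_n, p_c)


def cdna_gt_ratio(contributions: TranscriptContributions) -> float:
    """Pseudogene:NCF1 ratio in cDNA, (p_B + p_C) / p_N."""
    if contributions.p_n == 0:
        raise DomainError("cDNA GT ratio undefined when the NCF1 share is zero")
    return (contributions.p_b + contributions.p_c) / contributions.p_n


def per_copy_activity(
    contributions: TranscriptContributions, trio: CopyNumberTrio
) -> dict[str, float]:
    """Per-copy transcriptional activity of each paralog, NCF1 = 1.

    a_i = (p_i / g_i) / (p_N / n): transcript share per gene copy, relative
    to the functional gene.  A paralog with zero copies but a positive share
    is impossible and raises.
    """
    shares = dict(zip(("b", "n", "c"), contributions.as_tuple()))
    copies = {"b": trio.b, "n": trio.n, "c": trio.c}
    if trio.n == 0 or contributions.p_n == 0:
        raise DomainError("activity normalisation needs NCF1 copies and share > 0")
    for p in ("b", "c"):
        if shares[p] > 0 and copies[p] == 0:
            raise DomainError(
                f"paralog {p.upper()} has transcript share {shares[p]} but 0 copies"
            )
    ref = contributions.p_n / trio.n
    return {
        p: (shares[p] / copies[p]) / ref if copies[p] > 0 else 0.0
        for p in ("b", "n", "c")
    }


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares Ct-on-log10(quantity) line over serial-dilution points."""
    if len(points) < 2:
        raise FitError("standard curve needs at least 2 points")
    q = np.array([p[0] for p in points], dtype=float)
    ct = np.array([p[1] for p in points], dtype=float)
    if (q <= 0).any():
        raise FitError("standard-curve quantities must be > 0")
    x = np.log10(q)
    if len(np.unique(x)) < 2:
        raise FitError("standard curve needs >= 2 distinct quantities")
    res = stats.linregress(x, ct)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return StandardCurve(float(res.slope), float(res.intercept), r2)


def quantify(ct: float, curve: StandardCurve) -> float:
    """Interpolate a quantity from a Ct value: Q = 10^((Ct - intercept)/slope)."""
    if curve.slope == 0:
        raise FitError("cannot quantify on a flat standard curve")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    p: float
    ttest: TTestResult
    n_treated: int
    n_baseline: int


def _normalized_quantities(
    target: pd.DataFrame,
    reference: pd.DataFrame,
    target_curve: StandardCurve,
    reference_curve: StandardCurve,
    condition: str,
) -> np.ndarray:
    t = target[target["condition"] == condition].set_index("replicate")["ct"]
    r = reference[reference["condition"] == condition].set_index("replicate")["ct"]
    common = t.index.intersection(r.index)
    if len(common) == 0:
        raise InputError(f"no paired target/reference replicates for {condition!r}")
    qt = np.array([quantify(t[i], target_curve) for i in common])
    qr = np.array([quantify(r[i], reference_curve) for i in common])
    if (qr <= 0).any():
        raise InputError(f"zero reference quantity in condition {condition!r}")
    return qt / qr


def normalized_fold_change(
    target: pd.DataFrame,
    reference: pd.DataFrame,
    target_curve: StandardCurve,
    reference_curve: StandardCurve,
    baseline: str,
    treated: str,
    method: TTestMethod = TTestMethod.student_pooled,
) -> FoldChangeResult:
    """Reference-normalised fold change of ``treated`` over ``baseline``.

    ``target``/``reference`` are frames with columns condition, replicate, ct.
    Each replicate's target quantity is divided by its reference quantity
    (same replicate, via the genes' standard curves) before averaging, so
    the two conditions' normalised quantities support a replicate-level
    t-test; needs >= 2 replicates per condition for the p-value.
    """
    for cond in (baseline, treated):
        if not (target["condition"] == cond).any():
            raise InputError(f"condition {cond!r} missing from target measurements")
    nb = _normalized_quantities(target, reference, target_curve, reference_curve, baseline)
    nt = _normalized_quantities(target, reference, target_curve, reference_curve, treated)
    if len(nb) < 2 or len(nt) < 2:
        raise InputError("need >= 2 replicates per condition for the t-test")
    res = two_sample_t(nt, nb, method)
    return FoldChangeResult(
        fold=float(nt.mean() / nb.mean()),
        p=res.p,
        ttest=res,
        n_treated=len(nt),
        n_baseline=len(nb),
    )
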