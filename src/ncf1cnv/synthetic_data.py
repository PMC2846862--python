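"""Synthetic data with the statistical structure the NCF1 CNV analysis assumes.

Diploid genomes are formed by drawing two haplotypes (per-chromosome
duplicon-count arms) independently from a population pool; pyrosequencing
read-outs are the forward-model fractions plus truncated Gaussian noise in
fraction space (approximately homoscedastic there; the default sigma of
0.015 back-translates through the delta method, dr/df = (1-f)^-2 = 9 at the
4:2 class, to a ratio-scale SD of ~0.14, matching the spread observed in
blood-DNA panels).  Pedigrees are gene-dropped: founders drawn from the
pool, children inheriting one uniformly chosen haplotype per parent.
Expression tables assume each paralog copy transcribes at a per-copy rate,
with only a fraction rho of pseudogene transcripts retaining the (defective)
exon 2 — the rest splice around it and are invisible to the exon-2 assay.
qPCR Cts come from a log-linear standard curve plus Gaussian cycle noise.

Population presets are *conventions, not estimates*: true haplotype
frequencies are unknown, and no pool under random mating can reproduce an
arbitrary diploid ratio-class spectrum (the heterozygote class frequency is
bounded by 2*sqrt(P_hom1 * P_hom2)).  Each preset matches its population's
published mean NCF1B and NCF1C copy numbers exactly and the ratio-class
spectrum as closely as Hardy–Weinberg pairing permits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .pedigree import Haplotype, HaploGenotype, Individual, Pedigree
from .psv_model import CopyNumberTrio, expected_fractions

__all__ = [
    "HaplotypePool",
    "NoiseModel",
    "ExpressionModel",
    "POPULATION_POOLS",
    "ceph_like_structure",
    "simulate_population",
    "simulate_pedigree",
    "simulate_expression",
    "simulate_standards",
]


@dataclass(frozen=True)
class HaplotypePool:
    """Haplotypes with sampling frequencies (must sum to 1)."""

    haplotypes: tuple[Haplotype, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) == 0:
            raise ConfigurationError("empty haplotype pool")
        if len(self.haplotypes) != len(self.frequencies):
            raise ConfigurationError("haplotypes and frequencies differ in length")
        if min(self.frequencies) < 0:
            raise ConfigurationError("negative haplotype frequency")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"haplotype frequencies sum to {sum(self.frequencies)}, not 1"
            )

    @classmethod
    def from_dict(cls, d: Mapping[tuple[int, int, int] | Haplotype, float]) -> "HaplotypePool":
        haps = tuple(Haplotype(*h) for h in d)
        return cls(haps, tuple(float(v) for v in d.values()))

    def draw(self, rng: np.random.Generator, size: int) -> list[Haplotype]:
        idx = rng.choice(len(self.haplotypes), size=size, p=self.frequencies)
        return [self.haplotypes[i] for i in idx]

    def diploid_class_probabilities(self) -> dict[str, float]:
        """Ratio-class spectrum implied by two independent draws."""
        probs: dict[str, float] = {}
        for h1, f1 in zip(self.haplotypes, self.frequencies):
            for h2, f2 in zip(self.haplotypes, self.frequencies):
                trio = h1 + h2
                probs[trio.class_label] = probs.get(trio.class_label, 0.0) + f1 * f2
        return probs

    def mean_trio(self) -> tuple[float, float, float]:
        """Expected diploid (b, n, c) copy numbers."""
        eb = sum(f * h.b for h, f in zip(self.haplotypes, self.frequencies))
        en = sum(f * h.n for h, f in zip(self.haplotypes, self.frequencies))
        ec = sum(f * h.c for h, f in zip(self.haplotypes, self.frequencies))
        return (2 * eb, 2 * en, 2 * ec)


#: Population presets: least-squares pools calibrated to the published
#: per-individual statistics — mean ± SD copy numbers (AA NCF1B 1.4±0.8,
#: NCF1C 2.3±0.6; Cau 1.8±0.7, 1.9±0.4; Mex 1.6±0.6, 1.0±0.4) and the
#: diploid ratio-class spectra — as closely as random mating over integer
#: haplotypes allows.  Caucasian statistics are matched exactly, African-
#: American nearly so (4:2 class 0.64 vs 0.72 published); the Mexican
#: published values are jointly unattainable under Hardy-Weinberg pairing
#: (a 50% heterozygote 3:2 class exceeds the 2*sqrt(P_2:2 * P_4:2) bound,
#: and an NCF1C SD of 0.4 around a mean of 1.0 is below the 0.707 minimum
#: for independent integer arm draws), so means are matched exactly and
#: spread approaches its lower bound.  NCF1 is fixed at one copy per arm:
#: the published population means (2.1) slightly exceed 2, but the
#: per-individual evidence for three-copy NCF1 genomes is not published.
POPULATION_POOLS: dict[str, HaplotypePool] = {
    "african_american": HaplotypePool.from_dict(
        {(0, 1, 1): 0.1769, (0, 1, 2): 0.1769, (1, 1, 1): 0.5923,
         (2, 1, 0): 0.0269, (2, 1, 1): 0.0270}
    ),
    "caucasian": HaplotypePool.from_dict(
        {(0, 1, 0): 0.0586, (0, 1, 1): 0.1189, (1, 1, 0): 0.0077,
         (1, 1, 1): 0.7373, (2, 1, 1): 0.0613, (2, 1, 2): 0.0162}
    ),
    "mexican": HaplotypePool.from_dict(
        {(0, 1, 0): 0.0267, (0, 1, 1): 0.1833, (1, 1, 0): 0.4632,
         (1, 1, 1): 0.3168, (2, 1, 0): 0.0100}
    ),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: fraction-scale Gaussian SD and peak-height CV."""

    sigma_f: float = 0.015
    peak_cv: float = 0.05
    peak_scale: float = 100.0  # mean pyrogram peak height per template unit

    def __post_init__(self) -> None:
        if self.sigma_f < 0 or self.peak_cv < 0:
            raise ConfigurationError("noise parameters must be >= 0")

    def noisy_fraction(self, f: float, rng: np.random.Generator) -> float:
        return float(np.clip(f + rng.normal(0.0, self.sigma_f), 0.0, 1.0)) \
            if self.sigma_f > 0 else f


@dataclass(frozen=True)
class ExpressionModel:
    """Per-copy transcription and splice retention driving cDNA read-outs.

    ``rate_*`` — transcripts produced per gene copy (arbitrary units);
    ``rho_*`` — fraction of each pseudogene's transcripts retaining the
    defective exon 2 (NCF1 retains GTGT with probability 1).  The default
    rho of 0.25 makes a 2:2:2 genome's pseudogene pool contribute half as
    much GT-containing transcript as one NCF1 copy pool (cDNA ratio 0.5:1).
    ``condition_multipliers`` scale output per condition, either a scalar
    (all paralogs) or a per-paralog triple (m_b, m_n, m_c); baseline is 1.
    """

    rate_b: float = 1.0
    rate_n: float = 1.0
    rate_c: float = 1.0
    rho_b: float = 0.25
    rho_c: float = 0.25
    condition_multipliers: Mapping[str, float | tuple[float, float, float]] = field(
        default_factory=lambda: {"baseline": 1.0}
    )
    curve_slope: float = -3.3219280948873623  # -1/log10(2): perfect doubling
    curve_intercept: float = 30.0
    reference_intercept: float = 25.0
    ct_noise_sd: float = 0.1
    cdna_sigma_f: float = 0.015

    def __post_init__(self) -> None:
        if min(self.rate_b, self.rate_n, self.rate_c) < 0:
            raise ConfigurationError("transcription rates must be >= 0")
        if not (0 <= self.rho_b <= 1 and 0 <= self.rho_c <= 1):
            raise ConfigurationError("splice-retention fractions must lie in [0, 1]")

    def _weights(
        self, trio: CopyNumberTrio, condition: str | None = None
    ) -> tuple[float, float, float]:
        mult = self.condition_multipliers.get(condition, 1.0) if condition else 1.0
        mb, mn, mc = (mult, mult, mult) if np.isscalar(mult) else mult
        return (
            trio.b * self.rate_b * self.rho_b * mb,
            trio.n * self.rate_n * mn,
            trio.c * self.rate_c * self.rho_c * mc,
        )

    def gt_pool_shares(
        self, trio: CopyNumberTrio, condition: str | None = None
    ) -> tuple[float, float, float]:
        """True (p_B, p_N, p_C) shares of the GT-containing transcript pool."""
        wb, wn, wc = self._weights(trio, condition)
        total = wb + wn + wc
        if total == 0:
            raise ConfigurationError("all-zero expression: no GT-containing transcripts")
        return (wb / total, wn / total, wc / total)

    def gt_pool_total(self, trio: CopyNumberTrio, condition: str | None = None) -> float:
        return sum(self._weights(trio, condition))


def _profile_row(
    trio: CopyNumberTrio, noise: NoiseModel, rng: np.random.Generator
) -> dict[str, float]:
    exp = expected_fractions(trio)
    f_gt = noise.noisy_fraction(exp.f_gt, rng)
    f_a = noise.noisy_fraction(exp.f_a, rng)
    # raw peak heights consistent with the noisy fractions; overall pyrogram
    # intensity varies per assay run, bounded away from zero
    def _scale() -> float:
        if noise.peak_cv == 0:
            return noise.peak_scale
        return noise.peak_scale * max(0.1, 1.0 + rng.normal(0, noise.peak_cv))

    scale2, scale9 = _scale(), _scale()
    return {
        "f_GT": f_gt,
        "f_A": f_a,
        "h_GT": f_gt * scale2,
        "h_GTGT": (1 - f_gt) * scale2,
        "h_A": f_a * scale9,
        "h_G": (1 - f_a) * scale9,
    }


def simulate_population(
    pool: HaplotypePool,
    n: int,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
    population: str = "pop",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n`` diploid individuals from a haplotype pool.

    Returns ``(samples, truth)``: a sample sheet with noisy fractions and
    peak heights, and a truth table with the underlying trios and
    haplotypes.  Reproducible under a fixed seed.
    """
    if n < 1:
        raise InputError(f"need n >= 1 individuals, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h1s = pool.draw(rng, n)
    h2s = pool.draw(rng, n)
    samples, truth = [], []
    for i, (h1, h2) in enumerate(zip(h1s, h2s)):
        trio = h1 + h2
        sid = f"{population}_{i:04d}"
        samples.append({"sample_id": sid, "population": population,
                        **_profile_row(trio, noise, rng)})
        truth.append({"sample_id": sid, "population": population,
                      "b": trio.b, "n": trio.n, "c": trio.c,
                      "class": trio.class_label,
                      "hap1": f"{h1.b},{h1.n},{h1.c}",
                      "hap2": f"{h2.b},{h2.n},{h2.c}"})
    return pd.DataFrame(samples), pd.DataFrame(truth)


def ceph_like_structure(n_children: int = 6, family: str = "FAM1") -> list[Individual]:
    """Three-generation structure: four grandparents, two parents, children."""
    inds = [
        Individual("pgf", None, None, "1", family),
        Individual("pgm", None, None, "2", family),
        Individual("mgf", None, None, "1", family),
        Individual("mgm", None, None, "2", family),
        Individual("father", "pgf", "pgm", "1", family),
        Individual("mother", "mgf", "mgm", "2", family),
    ]
    inds += [
        Individual(f"child{i + 1}", "father", "mother", "1" if i % 2 == 0 else "2", family)
        for i in range(n_children)
    ]
    return inds


def simulate_pedigree(
    pool: HaplotypePool,
    structure: Sequence[Individual] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
) -> tuple[Pedigree, dict[str, HaploGenotype], dict[str, CopyNumberTrio], pd.DataFrame]:
    """Gene-drop haplotypes through a pedigree.

    Founders draw two pool haplotypes; each child inherits one uniformly
    chosen haplotype from each parent.  Returns the pedigree, the true
    haplogenotypes and trios, and a noisy sample sheet.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ped = Pedigree(structure if structure is not None else ceph_like_structure())
    genos: dict[str, tuple[Haplotype, Haplotype]] = {}
    for iid in ped.order:
        ind = ped.members[iid]
        if ind.father is None:
            h1, h2 = pool.draw(rng, 2)
        else:
            h1 = genos[ind.father][int(rng.integers(2))]
            h2 = genos[ind.mother][int(rng.integers(2))]
        genos[iid] = (h1, h2)
    haplogenotypes = {i: tuple(sorted(g)) for i, g in genos.items()}
    trios = {i: g[0] + g[1] for i, g in genos.items()}
    rows = [{"sample_id": i, **_profile_row(trios[i], noise, rng)} for i in ped.order]
    return ped, haplogenotypes, trios, pd.DataFrame(rows)


def simulate_standards(
    model: ExpressionModel,
    gene: str,
    dilutions: Iterable[float] = (1.0, 0.1, 0.01, 0.001),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Serial-dilution standards table (gene, quantity, ct) from the true curve."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intercept = model.reference_intercept if gene.startswith("ref") else model.curve_intercept
    rows = []
    for q in dilutions:
        ct = model.curve_slope * np.log10(q) + intercept
        if model.ct_noise_sd > 0:
            ct += rng.normal(0, model.ct_noise_sd)
        rows.append({"gene": gene, "quantity": q, "ct": float(ct)})
    return pd.DataFrame(rows)


def simulate_expression(
    trios: Mapping[str, CopyNumberTrio],
    model: ExpressionModel = ExpressionModel(),
    conditions: Sequence[str] = ("baseline",),
    n_replicates: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """cDNA fraction and qPCR Ct tables for samples with known trios.

    Returns ``(cdna, qpcr, truth)``.  ``cdna`` holds the noisy exon-2 GTGT
    and exon-9 G cDNA fractions per sample and condition; ``qpcr`` holds
    target and reference Cts per replicate, the target quantity scaled by
    the condition multiplier; ``truth`` records the true shares and totals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cdna_rows, qpcr_rows = [], []
    truth: dict = {"shares": {}, "totals": {}, "multipliers": dict(model.condition_multipliers)}
    for sid, trio in trios.items():
        truth["shares"][sid] = {}
        truth["totals"][sid] = {}
        for cond in conditions:
            p_b, p_n, p_c = model.gt_pool_shares(trio, cond)
            truth["shares"][sid][cond] = (p_b, p_n, p_c)
            truth["totals"][sid][cond] = model.gt_pool_total(trio, cond)
            f_gtgt = float(np.clip(p_n + rng.normal(0, model.cdna_sigma_f), 0, 1)) \
                if model.cdna_sigma_f > 0 else p_n
            f_g = float(np.clip(p_c + rng.normal(0, model.cdna_sigma_f), 0, 1)) \
                if model.cdna_sigma_f > 0 else p_c
            cdna_rows.append({"sample_id": sid, "condition": cond,
                              "f_GTGT": f_gtgt, "f_G": f_g})
            q_target = model.gt_pool_total(trio, cond)
            for rep in range(1, n_replicates + 1):
                for gene, q, intercept in (
                    ("NCF1_total", q_target, model.curve_intercept),
                    ("reference", 1.0, model.reference_intercept),
                ):
                    ct = model.curve_slope * np.log10(q) + intercept
                    if model.ct_noise_sd > 0:
                        ct += rng.normal(0, model.ct_noise_sd)
                    qpcr_rows.append({"sample_id": sid, "condition": cond,
                                      "gene": gene, "ct": float(ct), "replicate": rep})
    return pd.DataFrame(cdna_rows), pd.DataFrame(qpcr_rows), truth
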