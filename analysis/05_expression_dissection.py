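#!/usr/bin/env python
"""Dissect transcript pools and recover a simulated qPCR induction.

Three parts: (1) dissect the published monocyte/macrophage cDNA fractions
into per-paralog contributions and per-copy activities; (2) reproduce the
individual-6 pattern (4 pseudogene copies contributing half of one NCF1
copy's transcripts) from a simulated genome; (3) simulate a 1.34-fold
PMA induction measured by standard-curve RT-qPCR with a reference gene
and recover the fold change with a replicate-level t-test.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ncf1cnv import (
    CopyNumberTrio,
    ExpressionModel,
    cdna_gt_ratio,
    dissect_contributions,
    fit_standard_curve,
    normalized_fold_change,
    per_copy_activity,
    simulate_expression,
)
from ncf1cnv.io import write_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    # 1. published cDNA fractions -> contributions (THP-1 is 2:2:2)
    states = {"monocyte": (0.527, 0.144), "macrophage": (0.804, 0.113)}
    rows = []
    for cond, (f_gtgt, f_g) in states.items():
        c = dissect_contributions(f_gtgt, f_g)
        act = per_copy_activity(c, CopyNumberTrio(2, 2, 2))
        rows.append({"condition": cond,
                     "p_NCF1B": c.p_b, "p_NCF1": c.p_n, "p_NCF1C": c.p_c,
                     "cdna_ratio": cdna_gt_ratio(c),
                     "act_NCF1B": act["b"], "act_NCF1C": act["c"]})
        print(f"{cond}: NCF1B {c.p_b:.1%}, NCF1 {c.p_n:.1%}, NCF1C {c.p_c:.1%} "
              f"of the GT-containing pool; per-copy activity vs NCF1: "
              f"B {act['b']:.2f}, C {act['c']:.2f}")
    write_tsv(pd.DataFrame(rows), args.results_dir / "transcript_contributions.tsv")

    # 2. individual-6 pattern from the generative model (rho = 0.25 default)
    model0 = ExpressionModel(cdna_sigma_f=0.0, ct_noise_sd=0.0)
    cdna, _, _ = simulate_expression({"ind6": CopyNumberTrio(2, 2, 2)}, model0)
    c6 = dissect_contributions(cdna.iloc[0]["f_GTGT"], cdna.iloc[0]["f_G"])
    print(f"\nsimulated 4:2 genome with 25% exon-2 retention: cDNA "
          f"pseudogene:NCF1 ratio = {cdna_gt_ratio(c6):.2f} (expected 0.50)")

    # 3. fold-change recovery
    model = ExpressionModel(condition_multipliers={"monocyte": 1.0, "macrophage": 1.34})
    slope = 3.3219280948873623
    target_curve = fit_standard_curve([(10.0 ** -k, 30.0 + slope * k) for k in range(4)])
    ref_curve = fit_standard_curve([(10.0 ** -k, 25.0 + slope * k) for k in range(4)])
    folds, ps = [], []
    rng = np.random.default_rng(args.seed)
    for _ in range(10):
        _, qpcr, _ = simulate_expression(
            {"thp1": CopyNumberTrio(2, 2, 2)}, model,
            ["monocyte", "macrophage"], n_replicates=5,
            seed=int(rng.integers(2**31 - 1)),
        )
        fc = normalized_fold_change(
            qpcr[qpcr.gene == "NCF1_total"], qpcr[qpcr.gene == "reference"],
            target_curve, ref_curve, "monocyte", "macrophage",
        )
        folds.append(fc.fold)
        ps.append(fc.p)
    print(f"simulated 1.34-fold induction: recovered "
          f"{np.mean(folds):.3f} ± {np.std(folds, ddof=1):.3f} "
          f"(10 runs of 5 replicates); median p = {np.median(ps):.3g}")
    write_tsv(pd.DataFrame({"fold": folds, "p": ps}),
              args.results_dir / "fold_change_recovery.tsv")


if __name__ == "__main__":
    main()
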