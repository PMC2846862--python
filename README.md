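# ncf1cnv

Copy-number and expression analysis of the human **NCF1** segmental
duplication from paralog-specific-variant (PSV) allele ratios.

## The problem

NCF1 (p47phox, a subunit of the phagocyte NADPH oxidase; its loss causes
chronic granulomatous disease) lies at 7q11.23 inside a ~106-kb block that is
present in three near-identical copies per chromosome arm. Two of the copies,
the pseudogenes **NCF1B** and **NCF1C**, carry a signature 2-bp GT deletion
in exon 2 and the block copy numbers vary between people. Because the blocks
are >99.5% identical, per-paralog copy numbers cannot be read from unique
alignments or probes. They can, however, be inferred from quantitative
pyrosequencing of two PSVs amplified from *all* copies at once:

* **exon-2 GT/GTGT indel** — NCF1 carries GTGT; NCF1B and NCF1C carry GT;
* **exon-9 A/G substitution** — NCF1B and NCF1 carry A; NCF1C carries G.

For a diploid genome with copy numbers `(b, n, c)` of (NCF1B, NCF1, NCF1C)
and total `T = b + n + c`, the expected allele fractions are

```
f_GT = (b + c) / T        f_A = (b + n) / T
```

and the ΔGT/GTGT ratio is `r = (b + c) / n` (pseudogene : NCF1 copies, e.g.
4:2 ≡ 2:1). The two fractions determine `(b, n, c)` up to an overall scale
factor; the caller breaks that degeneracy by fixing `n = 2` (default) or by a
minimum-total-copies tie-break over a free grid.

This package implements, as a tested library with analysis drivers:

* the forward PSV model and pyrogram peak-height → fraction conversion
  (`ncf1cnv.psv_model`);
* integer copy-number calling by constrained grid search and ΔGT/GTGT
  ratio-class assignment (`ncf1cnv.copy_caller`);
* per-chromosome haplotype (arm) deduction and Mendelian-consistency checking
  across pedigrees by constraint propagation + backtracking
  (`ncf1cnv.pedigree`);
* population summaries and pooled/Welch two-sample t-tests
  (`ncf1cnv.popstats`);
* transcript-pool dissection from cDNA pyrosequencing and standard-curve
  RT-qPCR quantification with replicate-level fold changes
  (`ncf1cnv.expression`);
* a calibrated synthetic-data generator — haplotype-pool populations,
  gene-dropped pedigrees, expression/Ct tables — so every stage is testable
  end to end (`ncf1cnv.synthetic_data`);
* TSV/PED I/O and a `ncf1cnv` command line with `simulate`, `call`,
  `pedigree`, `popstats` and `expression` subcommands (`ncf1cnv.io`,
  `ncf1cnv.cli`).

## Worked example

```python
from ncf1cnv import (AlleleFractionProfile, CallConstraints, call_trio,
                     classify_ratio, default_ratio_classes,
                     dissect_contributions)

# genomic DNA: measured fractions f_GT = 2/3 (exon 2), f_A = 1/2 (exon 9)
call = call_trio(AlleleFractionProfile(2/3, 0.5), CallConstraints())
print(call.trio, call.class_label)
# -> CopyNumberTrio(b=1, n=2, c=3) 4:2

# a measured ΔGT/GTGT ratio of 1.97 lands in the 4:2 (2:1) class
print(classify_ratio(1.97, default_ratio_classes()).label)   # -> 4:2

# cDNA: GTGT fraction 0.527 (exon 2) and G fraction 0.144 (exon 9)
c = dissect_contributions(0.527, 0.144)
print(f"{c.p_b:.1%} {c.p_n:.1%} {c.p_c:.1%}")  # -> 32.9% 52.7% 14.4%
```

The called trio `(1, 2, 3)` means one NCF1B, two NCF1 and three NCF1C
copies — a 4:2 pseudogene:NCF1 genome. The cDNA dissection says NCF1B
contributes 32.9% of the GT/GTGT-containing transcript pool, NCF1 52.7% and
NCF1C 14.4%: the four pseudogene copies together transcribe less than the
two functional copies.

The numbered scripts under `analysis/` run the full pipeline on synthetic
cohorts (simulate → call → score → compare populations → pedigree check →
expression dissection) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_call_copy_numbers.py
python analysis/03_pedigree_transmission.py --seed 1
python analysis/04_population_comparison.py
python analysis/05_expression_dissection.py --seed 1
```

With seed 1 this reports, among other things, 98.8% exact trio recovery over
86 noisy samples, Mendelian consistency of both simulated families, and a
recovered qPCR induction of 1.356 ± 0.086 for a true 1.34-fold effect.

## Documentation

See `docs/methods.md` for the model, its assumptions, the calibration of the
synthetic-data generator, numerical choices and known limitations.
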