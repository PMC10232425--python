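# hedscape

Immunogenetic analysis of leukemia relapse after allogeneic hematopoietic cell
transplantation (allo-HCT). After transplant, donor immune effectors exert a
graft-versus-leukemia effect through HLA-restricted antigen presentation;
relapse is often an immune-escape event. `hedscape` quantifies two sides of
that escape:

* **Germline**: the *HLA evolutionary divergence* (HED) of a recipient's
  genotype — how physicochemically different the two alleles at each locus are
  across the peptide-binding domain — and its association with relapse and
  survival under competing risks.
* **Somatic**: the landscape of acquired HLA lesions (mutations and allelic
  losses) in relapse specimens, including donor-type breakdowns, early/late
  relapse splits and myeloid driver co-mutation enrichment.

It is written for transplant immunogenetics and outcomes researchers who work
from HLA genotype tables, allele sequence dictionaries (IPD-IMGT/HLA-style
FASTA), time-to-event tables and pre-called somatic lesion tables.

## The score and the models

For residues *i, j*, the Grantham distance combines composition *c*,
polarity *p* and volume *v*:

```
D(i, j) = rho * sqrt( alpha*(c_i - c_j)^2 + beta*(p_i - p_j)^2 + gamma*(v_i - v_j)^2 )
```

with `alpha = 1.833`, `beta = 0.1018`, `gamma = 0.000399` and `rho = 50.723`
scaling the mean inter-residue distance to 100. HED at a locus is the mean
`D` per aligned position between the binding-domain sequences of the two
alleles (exons 2+3 for class I, exon 2 for class II); class I/II scores
average the three loci of each class (A, B, C and DRB1, DQB1, DPB1) and the
global score averages all six. Scores are dichotomized high/low at the 50th
percentile of a healthy-control reference, slot by slot (ties are low).

Outcomes are modeled in a competing-risk setting: relapse cumulative
incidence by the Aalen–Johansen estimator with death as the competing event,
group contrasts by the log-rank test, and hazard ratios by cause-specific Cox
regression (Efron ties; competing events censored at their time). HLA-C
alleles are additionally classified into KIR-ligand groups C1/C2 by allele
supertype.

Because the motivating clinical cohort is access-controlled, the package
ships a seeded synthetic-cohort generator (`hedscape.synthetic`) producing
genotypes, sequences, outcome tables and lesion tables with the statistical
structure the analysis assumes, calibrated to the published effect sizes.

## Worked example

```sh
python examples/04_competing_risks.py
```

simulates 2,000 subjects whose relapse hazard carries a class II HED effect
of hazard ratio 0.65 and prints:

```
relapse cumulative incidence at 12 months: 0.111
relapse cumulative incidence at 36 months: 0.286
event-free probability at 36 months:       0.516
log-rank high vs low class II HED: chi2 = 6.0, p = 1.42e-02
cause-specific Cox: HR 0.70 (95% CI 0.59-0.82, p = 2.5e-05); configured truth 0.65
```

Reading: by three years 28.6% of subjects have relapsed (death treated as a
competing event, not censoring); subjects with high class II divergence
relapse less, and the cause-specific Cox fit recovers the configured
protective hazard ratio within sampling error. The other scripts in
`examples/` cover divergence scoring, control-based dichotomization,
KIR-ligand status, the somatic lesion landscape, and the end-to-end pipeline
(`hedscape run` on files).

A thin CLI mirrors the library:

```sh
hedscape simulate --outdir demo --seed 1 --n 300
hedscape hed compute --genotypes demo/genotypes.tsv \
    --sequences demo/sequences.fasta --controls demo/controls.tsv --out hed.tsv
hedscape lesions tabulate --lesions demo/lesions.tsv --patients demo/patients.tsv
```

## Layout

```
src/hedscape/
  hla.py        nomenclature parsing, genotype tables, sequence dictionaries
  grantham.py   amino-acid distance model (packaged integer matrix)
  hed.py        divergence scores, control cutoffs, dichotomization
  kir.py        HLA-C KIR-ligand C1/C2 classification
  outcomes.py   Kaplan-Meier, log-rank, Aalen-Johansen, cause-specific Cox
  lesions.py    somatic lesion tabulation, early/late split, co-mutation tests
  synthetic.py  seeded cohort generator and deterministic fixtures
  pipeline.py   end-to-end orchestration with manifest + logging
  cli.py        thin click front end (`hedscape ...`)
```

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
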