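# heartperm

Scoring and permutation inference for cardiac cell-division defects in the
*Drosophila* embryonic heart tube.

## The problem

The stage-16 *Drosophila* dorsal vessel is a chain of bilaterally paired
hemisegments along abdominal segments A2–A8 (14 per embryo), each normally
containing 2 Svp cardiac cells (CCs), 2 Svp pericardial cells (PCs) and
4 Tin CCs. Because these censuses arise from stereotyped progenitor
divisions — the Tin superprogenitor divides symmetrically twice (1 → 4 CCs),
the Svp superprogenitor divides symmetrically once and each daughter divides
asymmetrically into one CC and one PC — a deviant count pinpoints which
division failed. Geneticists score hemisegment cell counts from confocal
z-stacks and ask whether a mutant genotype raises the defect frequency, and
whether two mutations interact *synergistically* (the double heterozygote
exceeding the additive sum of the two single-heterozygote frequencies).

`heartperm` provides, for people doing this kind of quantitative
developmental genetics:

1. a deterministic decision table converting hemisegment counts into three
   defect categories — `tin_symmetric` (tin_cc ≠ 4), `svp_earlier`
   ((svp_cc, svp_pc) ∈ {(1,1), (3,3)}), `svp_asymmetric`
   ({(1,3), (3,1)} or the karyokinesis signature (2,1)) — plus an
   antibody-assay mode in which Svp PCs are invisible and the two Svp
   categories collapse into `svp_combined` (svp_cc ≠ 2);
2. a synthetic-cohort generator with within-embryo correlated defect
   probabilities (logit-normal embryo effects), genotype main effects and a
   configurable interaction effect;
3. permutation inference on per-embryo defect proportions.

## The statistics

Hemisegments of one embryo are correlated in their defect propensity, so
hemisegment-level contingency tests (Fisher's exact) are invalid. The unit
of analysis is the per-embryo defect proportion Y_j.

**Two-group comparison.** Fit Y_j = β₀ + β₁·I_j + ε_j, with I_j = 1 for the
mutant group. β₁ is the difference in group means; its null distribution is
obtained by shuffling genotype labels among embryos. The p-value is
p = (n+1)/(N+1), with n the number of permuted β₁ estimates exceeding the
observed one out of N permutations; samples with few embryos switch
automatically to exhaustive enumeration of all C(n₀+n₁, n₁) label
arrangements.

**Synergy (interaction) test.** Fit the intercept-free model
Y_j = β₁·Ip_j + β₂·Iq_j + β₃·Ip_j·Iq_j + ε_j on the two single-heterozygote
groups and the double heterozygote, so that
β₃ = ȳ_double − ȳ_singleP − ȳ_singleQ — exactly the departure from the
additive expectation. H₀: β₃ = 0 is tested with the Smith procedure:
orthogonalize the interaction column g against the main-effect columns Z,
then permute the entries of g⊥ across embryos, recomputing
stat(π) = π(g⊥)·M_Z y / ‖g⊥‖². A result is called *synergistic* iff β₃ > 0
and p ≤ α.

## Worked example

Simulate a synergistic interaction cohort (15 embryos per genotype, marginal
Tin-defect rates 5% / 5% / 25% for the two single heterozygotes and the
double heterozygote — a 15-point synergy on top of the 10% additive
expectation — with embryo-level dispersion 0.3), then run the full pipeline:

```
heartperm --seed 7 --permutations 9999 --tie-rule geq --out out \
    report counts.csv \
    --roles "P_het=single_het_1,Q_het=single_het_2,PQ_het=double_het"
```

prints

```
tin_symmetric: coefficient=0.142857 p=0.0013 -> synergistic
svp_earlier: coefficient=-0.004762 p=0.7223 -> not_synergistic
svp_asymmetric: coefficient=-0.023810 p=0.9986 -> not_synergistic
report written to out/genotype_report.csv
```

The coefficient is β̂₃ on the proportion scale: the double heterozygote's
Tin-defect proportion sits 14.3 points above the sum of the two single-het
proportions, and only 12 of 9999 permutations reached it (p = 0.0013), so
the Tin category is called synergistic at α = 0.05. The background Svp
categories, simulated without any genotype effect, stay at their additive
expectation. `out/genotype_report.csv` holds the per-genotype pooled
percentages in figure-legend style, e.g. the double-het row
`PQ_het,tin_symmetric,15,210,49,...,23.3,0.0013,9.05`: 49 of 210
hemisegments defective (23.3%) against an additive expectation of 9.0%.

The same pipeline ingests real scored count tables: a CSV with columns
`embryo_id, genotype, segment, side, tin_cc, svp_cc, svp_pc,
enlarged_svp_nucleus, assay` (empty cell = missing; `svp_pc` must be empty
in `SVP_ANTIBODY` mode and present in `SVP_LACZ` mode).

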