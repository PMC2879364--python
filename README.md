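# stromix

Allele-specific copy-number calling from SNP-array data, built for tumor
samples contaminated with normal (stromal) cells.

Genotyping arrays report two signals per SNP: the **log R ratio** (LRR,
total-intensity log ratio, ≈0 at two copies) and the **B-allele frequency**
(BAF, allelic intensity proportion in [0,1]). `stromix` decodes these with
a hidden Markov model whose states are chromosomal configurations of the
two parental homologs F and M — 'O' (homozygous deletion) plus every
distinguishable word F^a M^b up to copy number 7, 20 states in all. Each
state carries a copy number CN = #F + #M and an allelic imbalance
AI = 1/2 − #M/CN, so the caller separates events that total-signal methods
conflate: copy-neutral and high-copy LOH ('FF', 'FFF', …), balanced
('FFMM') versus imbalanced ('FFFM') amplification, and copy numbers up to 7.

Biopsies are rarely pure. Given a stromal proportion w — supplied or
estimated from the BAF band structure — `stromix` updates every state's
emission distributions for a mixture of w normal ('FM') DNA and 1 − w
tumor DNA (lognormal moment matching for LRR, copy-weighted band mixing
for BAF) and decodes the tumor states directly from the contaminated
signal. A simulator that samples from the same emission model and a
recovery-rate/FDR scorer complete the validation loop.

## Worked example

Simulate a 40%-contaminated sample (one region per state on two
chromosomes), call CNVs with the matching purity, and score the calls:

```sh
$ stromix simulate --region-len 50 --n-chrom 2 -w 0.4 --seed 7 -o sim
simulated 2000 SNPs on 2 chromosome(s) (seed=7, w=0.4)

$ stromix detect sim/sim.snps.tsv -w 0.4 -o det
wrote 39 region(s) to det/sample.regions.tsv

$ stromix evaluate sim/sim.truth_regions.tsv det/sample.regions.tsv sim/sim.snps.tsv
class   n_snps_true  n_snps_detected  recovery_cn  recovery_ai  fdr
0n      100          100              1.000000     1.000000     0.000000
1n      100          100              1.000000     1.000000     0.000000
FF      100          100              1.000000     1.000000     0.000000
FM      100          100              1.000000     1.000000     0.000000
3n      200          200              1.000000     1.000000     0.000000
>=4n    1400         1400             0.950000     0.981429     0.000000
overall 2000         2000             0.965000     0.987000     0.000000
```

`recovery_cn`/`recovery_ai` are the proportions of SNPs whose decoded copy
number / allelic imbalance exactly match the simulated truth, per collapsed
class and overall; `fdr` is the fraction of SNPs detected as a class whose
truth is a different class. Despite 40% contamination, every deletion, LOH
and 3-copy region is recovered perfectly; the residual errors sit at
borders between high-copy states, whose mixed distributions are closest.

If the purity is unknown, annotate the contamination band of a deletion
region and invert it — a BAF band at 0.25 for the 'A' genotype of a
one-copy ('F') region implies

```sh
$ stromix estimate-purity --band-baf 0.25
0.3333
```

i.e. w = b/(1 − b) = 0.33. `stromix mix-model -w 0.5` prints every state's
contamination-adjusted band positions (at w = 0.5, 'FFM' and 'FFFM'-at-0.75
become indistinguishable — see `docs/methods.md` for this identifiability
limit). `detect` writes BED-like region calls (0-based half-open), SGR
tracks of BAF/LRR and WIG tracks of CN/AI for genome browsers, and
optionally per-SNP genotype calls ('AAB' rather than a generic 'AB' in a
three-copy region).

Inputs are tab-delimited BeadStudio-style exports (columns `Name`, `Chr`,
`Position`, `B Allele Freq`, `Log R Ratio`; remappable); autosomes only by
default. The 20-state model ships as an editable text file
(`stromix dump-model my.hmm`) holding, per state, the stationary
probability, mean region length, LRR Gaussian and g3-class BAF Gaussian.

## Limitations

Raw-intensity normalization (tQN, GC-wave correction) must happen
upstream; sex chromosomes are excluded by default; a single global w is
assumed (one dominant clone — multi-clone mixtures are not deconvolved).
See `docs/methods.md` for the model, defaults, and design rationale.
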