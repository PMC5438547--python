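# tstv

Do transversions perturb regulatory DNA more than transitions?

Single-nucleotide substitutions come in two chemical flavours: transitions
(Ts; A↔G, C↔T) keep the ring count of the base, transversions (Tv;
purine↔pyrimidine) change it. Their different consequences in
protein-coding sequence are classical; `tstv` quantifies their differential
impact on *non-coding regulatory* DNA along four independent lines of
evidence, each implemented as a tested, reusable analysis arm:

1. **DNA shape** (`tstv.shape`) — a pentamer-lookup model predicts minor
   groove width (MGW), propeller twist (ProT), roll, and helical twist
   (HelT) across a sequence. Random sequences are mutated at their middle
   base to all alternatives and the effect of each substitution pair is the
   summed |Δ| of each shape profile, compared between classes with the
   originating sequence absorbed as a fixed effect.
2. **TF binding motifs** (`tstv.motif`) — JASPAR-format position frequency
   matrices become log2-odds PSSMs (pseudocount 0.1, uniform background);
   every possible single-base change at every motif position is scored as
   |Δ PSSM score| in bits and Tv vs Ts magnitudes are compared within bins
   of normalized motif position and information content (Welch t-tests).
3. **Allele-specific binding** (`tstv.asb`) — the Tv fraction among SNPs
   showing allele-specific ChIP-seq binding is compared with the Tv
   fraction among all SNPs tested by a pooled-variance two-proportion
   Z-test, z = (p₁−p₀)/√(p̂(1−p̂)(1/n₁+1/n₀)), with redundant variants
   collapsed across TFs/cell lines.
4. **Regulatory activity** (`tstv.haplo`, `tstv.satmut`) — reporter-assay
   haplotypes are contrasted against a per-amplicon reference haplotype and
   |Δlog2 effect| is regressed on Ts/Tv presence or counts (amplicon as a
   categorical covariate); saturation-mutagenesis enhancer data are
   re-analysed with a one-sided test of the transversion coefficient.

`tstv.synthetic` generates every input format with *planted* effect
structure (known Ts/Tv coefficients, enrichment fractions, and noise), so
the full pipeline is testable and calibratable offline. See
`docs/methods.md` for models, parameter defaults, and limitations.

## Worked example

Simulate inputs for every arm, then run three of the arms:

```sh
tstv simulate --seed 7 --out demo --n-amplicons 40 --haplotypes-per-amplicon 6 \
     --n-motifs 30 --n-tested 5000 --n-asb 500 --n-elements 2 --element-length 60
tstv haplo-reg --effects demo/haplotype_effects.tsv --sequences demo/haplotypes.fasta \
     --amplicons demo/amplicons.bed --dhs demo/dhs.bed --seed 1 --out demo/haplo
tstv asb-test  --snps demo/asb_snps.tsv  --out demo/asb
tstv satmut-reg --table demo/satmut.tsv --out demo/sat
```

which prints:

```
count: n_ts: beta=0.1324+/-0.1648 p=0.423, n_tv: beta=0.2052+/-0.0999 p=0.0418
Tv fraction ASB 0.3780 vs tested 0.3532 (z = 0.920, p = 0.358)
pooled: beta_tv=0.1250 one-sided p=6.25e-06
```

Reading the output: in the haplotype count model, each additional
transversion difference between a haplotype and its amplicon's reference
shifts |Δlog2 activity| by β = 0.21 ± 0.10 (p = 0.04), while the
transition term is indistinguishable from zero — the planted Tv > Ts
structure is detected even at this small scale with a randomly chosen
reference haplotype. The ASB arm reports the Tv fraction among
allele-specific SNPs (37.8%) vs all tested SNPs (35.3%); at n₁ = 500 the
planted enrichment is in the right direction but not yet significant
(z = 0.92). The saturation arm detects the planted 1.5× transversion
scaling (β_TV = 0.125, one-sided p ≈ 6×10⁻⁶). Results are also written
as JSON/TSV artifacts stamped with version, seed, and a config digest.

The library surface mirrors the CLI, e.g.:

```python
from tstv import shape, synthetic

table = synthetic.gen_shape_table(seed=1)           # or shape.load_shape_table(path)
effects = shape.run_shape_experiment(1000, 503, seed=1, table=table)
comparison = shape.compare_shape_effects(effects)
print(comparison["summary"][["parameter", "mean_ts", "mean_tv", "ratio_tv_ts", "p"]])
```

Directional shape conclusions (Tv > Ts for MGW and roll) require the
empirically derived Monte-Carlo pentamer table, supplied as an external
TSV via `shape.load_shape_table`; the shipped synthetic table exercises
the machinery without encoding any class asymmetry.

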