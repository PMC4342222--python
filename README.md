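# poex — parent-of-origin expression analysis for hybrid seed RNA-seq

`poex` is a tested re-implementation of a classic SNP-based imprinting
analysis for plant seeds.  Given RNA-seq pileups of two parental genotypes
and of their hybrid seed, it

1. **discovers parent-diagnostic SNPs**: transcript positions where ≥ 95% of
   one parent's reads carry the same non-reference base at ≥ 5-read coverage,
   with same-start read deduplication, removal of positions sharing the SNP
   base between parents, and removal of reference-parent self-SNPs;
2. **quantifies allelic expression** per gene in the hybrid: the paternal
   allelic fraction *P<sub>p</sub>* (unweighted mean over informative SNP
   positions), mean coverage *C*, and approximate parental read counts
   *N<sub>m</sub> = C·P<sub>m</sub>/100*, *N<sub>p</sub> = C·P<sub>p</sub>/100*;
3. **classifies genes** as maternally expressed (MEG: *P<sub>m</sub>* > 66%,
   the point beyond which the 2m:1p endosperm genome dose cannot explain the
   bias), paternally expressed (PEG: *P<sub>p</sub>* > 50%) or biparental,
   gated by a Pearson chi-square goodness-of-fit against the class's null
   ratio (+1 pseudocount per parental count) with Benjamini–Hochberg FDR
   control at α = 0.05;
4. **compares crosses** (2×2 chi-square per gene, coverage-downsampled
   variant, Wilcoxon signed-rank and OLS correlation of paternal bias,
   Venn-style call-set overlaps) and **annotates calls against literature**
   imprinted genes (confirmed / reverted-to-maternal / de-novo PEG);
5. **scores endosperm specificity** from a seed-compartment (LCM-style)
   expression matrix via the floored log-ratio of maxima
   log₁₀((max<sub>endo</sub> − 2.3)/(max<sub>non-endo</sub> − 2.3)), a
   log-sum ≥ 1.8 expression filter and the upper Tukey fence
   (Q3 + 1.5·IQR), and tests **gene-set overlaps** with an exact log-space
   hypergeometric upper tail.

Because the original deposited libraries are not required, the package ships
a **synthetic-data generator** (`poex.simulate`) that emulates the full data
generating process — parental divergence (~0.5% within species, ~5% between),
heterozygosity of the outcrossing parent, seed-tissue mixtures (maternal
sporophyte + endosperm at 2m:1p + embryo at 1:1), per-gene imprinting classes
including hybrid-specific PEG reversion, reference-mapping bias calibrated so
a true 50:50 mix reads ~60:40, negative-binomial read depth and sequencing
error — with truth tables beside every output, so every stage is verifiable.

## Worked example

Run the bundled four-cross synthetic design (two reciprocal intraspecific
controls, two interspecific hybrids sharing the outcrossing pollen parent):

```bash
poex run --seed 7 --out out/
```

which prints the per-cross classification summary (200-gene design):

```
 cross_id      class  n_genes   percent
  b_x_out   maternal       23 12.849162
  b_x_out biparental      147 82.122905
  b_x_out   paternal        9  5.027933
  b_x_ref   maternal       19 12.101911
  b_x_ref biparental      123 78.343949
  b_x_ref   paternal       15  9.554140
  ...
```

Reading the numbers: in the intraspecific control (`ref_x_b`, ~9.5% paternal)
the planted PEGs *and* the planted reverted-PEGs are paternally expressed; in
the interspecific hybrid (`ref_x_out`, ~5% paternal) the reverted class has
switched to maternal expression, so only the stable PEGs remain — the
hybrid-specific loss of paternal expression the classifier is built to
detect.  `out/reports/` contains the per-gene calls, between-cross
chi-squares, bias statistics (Wilcoxon, R²), call-set overlaps and the
literature annotation; `out/manifest.json` records seeds and thresholds, and
reruns are byte-identical.

A single enrichment test from the command line:

```bash
poex overlap --k 13 --n 40 --big-k 940 --big-n 15352
# expected = 2.449
# p_upper = 4e-07
```

i.e. 13 observed overlaps where 2.449 are expected by chance — strong
enrichment of endosperm-specific genes among the candidate PEGs.

## Layout

- `poex.pileup` — pileup TSV I/O, mpileup import, replicate pooling,
  read-start dedup, library-size normalization
- `poex.simulate` — the synthetic generator and its models
- `poex.snps` — diagnostic SNP discovery and per-gene summaries
- `poex.quantify` — hybrid genotyping, allelic profiles, pseudocounts,
  mapping-bias QC
- `poex.classify` — chi-square tests, BH, MEG/PEG calls, comparisons,
  literature annotation
- `poex.endosperm` — endosperm-specificity scoring
- `poex.overlap` — hypergeometric overlap testing
- `poex.pipeline` / `poex.cli` — orchestration and the `poex` command

See `docs/methods.md` for the statistical model, parameter choices and known
limitations.
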