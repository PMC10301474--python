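# cyp2d6dup

Resolve which *CYP2D6* star allele is duplicated — directly from real-time
PCR endpoint genotyping signals and three-probe copy-number data — and
translate the resolved diplotype to a CPIC/DPWG activity score and
metabolizer phenotype.

## The problem

*CYP2D6* metabolizes roughly a fifth of commonly prescribed drugs, and
full-gene duplications are common. When a patient carries three gene
copies and two alleles with *different* activity values (say `*1` and
`*4`), the phenotype depends on **which** allele is duplicated:
`*1×2/*4` is a normal metabolizer (activity score 2) while `*1/*4×2` is
intermediate (score 1). The gold standard — long-range PCR to isolate the
duplicated copy followed by Sanger sequencing — is slow, expensive, and
not feasible on all specimen types, so many laboratories simply report
"indeterminate".

This package implements the alternative: the duplication is visible in
the *routine* data already collected. On an allelic-discrimination
(TaqMan VIC/FAM) plot a balanced heterozygote sits in the middle of the
heterozygous cluster; a three-copy heterozygote carries its alleles 2:1
and is *shifted* toward the axis of the duplicated allele. Formally, with
variant-signal fraction f = FAM/(VIC+FAM), the shift statistic at each
informative (heterozygous) assay is

    z = (mean replicate fraction − het cluster center) / robust cluster spread

where the cluster model is fitted (median/MAD) from 2-copy control and
concurrent samples on the same run. Each confident shift (both replicates
on the same side, both |z| ≥ z_min = 3) votes for the haplotype that
gained a copy; unanimous votes of at least `min_votes = 2` together with a
clean 3-copy CNV result name the duplicated allele, and anything
ambiguous — a single informative SNV, discordant replicates, conflicting
votes (the allelic-dropout signature), or an inconsistent copy-number
result — defers to reflex sequencing. The three CNV probes (promoter,
intron 6, exon 9, normalized to *RPPH1*) additionally resolve hybrid
*CYP2D6–CYP2D7* structures: a probe triple (p, i, e) is decomposed into
nonnegative counts of full copies and *68-like (1,0,0), *36-like (1,1,0)
and *13-like (0,1,1) hybrids, and a half-integer plateau on all three
probes (e.g. "2.5 copies") is recognized as the fingerprint of a variant
under a control-gene probe rather than a duplication.

A seeded simulator generates the full study conditions — 2-copy control
clusters, 3-copy shifted heterozygotes, allelic dropout, lot-to-lot signal
scaling and control-gene interference — including the packaged 73-case
(main), 11-case (hybrid/multicopy) and 3-case (ambiguous CNV) cohorts.

## Worked example

Simulate a run of the packaged main cohort and call it:

```sh
cyp2d6dup simulate --seed 11 --out demo
cyp2d6dup call --genotyper demo/genotyper.tsv --cnv demo/cnv.tsv --format text
```

The first case prints:

```
Sample:         M001
Status:         reported
Diplotype:      *17/*4×2
Activity score: 0.5
Phenotype:      Intermediate
Votes:
  c.100C>T: *4 (z=11.195)
  c.320C>T: *4 (z=-10.843)
  c.506-1G>A: *4 (z=11.853)
  c.886C>T: *4 (z=-13.455)
```

Four informative assays all vote for `*4`: at the `*4`-tagging sites
(c.100C>T, c.506-1G>A) the signal shifts toward the variant axis
(positive z), and at the `*17`-tagging sites (c.320C>T, c.886C>T) it
shifts toward the reference axis (negative z) — both directions are
evidence that the `*4` haplotype gained the extra copy. With a 3-copy CNV
result the case is reported as `*4×2/*17` (score 0.5, intermediate
metabolizer) without sequencing. Cases with a single informative SNV or
conflicting votes come back as `Status: reflex_sequencing` with explicit
defer reasons.

Other entry points:

```sh
cyp2d6dup score "*1×2/*41"         # activity score: 2.5 / Ultrarapid
cyp2d6dup interpret-cnv 4 3 3      # 3 full + 1 *68-like
cyp2d6dup evaluate --calls reports.json --truth demo/truth.tsv
```

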