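# rflpkit

In-silico simulation and interpretation of a multiplex PCR-RFLP genotyping
assay for three clinically relevant *CYP3A4* variants: *CYP3A4\*4*
(rs55951658 A>G), *CYP3A4\*18B* (rs2242480 G>A) and *CYP3A4\*22*
(rs35599367 C>T). These alleles modulate CYP3A4 activity and with it the
metabolism of many drugs (tamoxifen, cyclosporine, statins, midazolam), so
cheap gel-based genotyping of all three at once is attractive for
pharmacogenetic screening.

The package is for people who design, debug or teach PCR-RFLP assays: it
predicts what the gel *should* look like for every genotype, calls genotypes
back from observed band sizes, and validates whether a multiplex design can
distinguish all genotypes at all.

## The method

PCR-RFLP reads a SNP from fragment sizes: a restriction enzyme's recognition
site is created or destroyed by the variant base, so digesting the PCR
product yields allele-specific fragments. In the multiplex design modelled
here, one PCR co-amplifies three products — 244 bp (*4), 331 bp (*18B) and
793 bp (*22) — which are then split into three digestion tubes:

| tube | enzyme | recognition / cut | diagnostic for | wild-type fragments | variant |
|------|--------|-------------------|----------------|--------------------|---------|
| 1 | BsmAI | GTCTC(1/5), type IIS offset cutter | *4 (A>G creates a site) | 14, 89, 141 | 14, 47, 89, 94 |
| 2 | RsaI | GT↓AC, blunt | *18B (G>A destroys the site) | 115, 216 | 331 (uncut) |
| 3 | BseYI | C↓CCAGC, staggered | *22 (C>T destroys the site) | 219, 574 | 793 (uncut) |

Because the 793 bp *22 product is long, it is unavoidably cross-digested:
BsmAI also cuts it into 56/59/153/525 and RsaI into 112/681. These appear
as constant background bands in tubes 1 and 2; the caller knows to explain
them away. A heterozygote shows the union of both alleles' fragments.

A simple gel model decides what is actually seen on a 4 % agarose gel:
fragments under 75 bp are invisible, bands closer than 5 % in size
co-migrate, and observed sizes match predictions within 5 %.

Since real patient DNA cannot ship with a package, `rflpkit.templates`
generates synthetic amplicons and loci that embed the assay's printed
primers and exactly the restriction sites the design requires, with seeded
random sequence elsewhere (spurious sites are repaired away). Digests of
these templates reproduce the published fragment tables by construction.

## Worked example

```bash
$ rflpkit make-fixtures --out fixtures --seed 7
$ rflpkit digest --fasta fixtures/amplicon_CYP3A4_22_wild.fa \
    --enzymes BsmAI,RsaI,BseYI --out digest.tsv
$ cat digest.tsv
template	enzyme	n_fragments	fragments_bp
CYP3A4_22_wild_amplicon	BsmAI	4	153,56,59,525
CYP3A4_22_wild_amplicon	RsaI	2	112,681
CYP3A4_22_wild_amplicon	BseYI	2	219,574
```

The wild-type *22 amplicon digests to 219 + 574 bp under its diagnostic
enzyme BseYI, and shows the expected cross-digestion patterns under BsmAI
and RsaI. Calling a genotype from observed bands:

```bash
$ printf 'sample\ttube\tband_bp\nS1\tRsaI\t115\nS1\tRsaI\t216\nS1\tRsaI\t331\n' > bands.tsv
$ rflpkit call --bands bands.tsv --out calls.tsv
$ cut -f1-4 calls.tsv
sample	snp	call	tube
S1	CYP3A4*4	fail	BsmAI
S1	CYP3A4*18B	heterozygous	RsaI
S1	CYP3A4*22	fail	BseYI
```

The RsaI tube shows both the cut (115 + 216) and uncut (331) *18B species —
a heterozygote. The other two SNPs fail loudly because their tubes contain
no observed bands. The same logic is available as a library
(`rflpkit.call_genotype`, `rflpkit.predict_patterns`,
`rflpkit.validate_multiplex`), and `rflpkit predict --render` draws a text
gel of any genotype's expected lanes.

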