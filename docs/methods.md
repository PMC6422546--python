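# Methods

## Scope and model

`rflpkit` simulates a three-SNP multiplex PCR-RFLP genotyping workflow
in silico: exact-match primer binding and amplification, complete
restriction digestion with explicit double-strand cut geometry, a
visibility/co-migration model of agarose gel electrophoresis, genotype
calling by exhaustive pattern comparison, and design validation
(cross-digestion and distinguishability). Wet-lab chemistry — cycling
conditions, enzyme units, incubation times, partial digestion, methylation
sensitivity and band intensity — is deliberately out of scope; incubation
metadata is carried as annotation only.

## Restriction-cut geometry

Coordinates are 1-based and inclusive; "cut after x" means cleavage between
template positions x and x+1. An enzyme is `(recognition, cut_top,
cut_bottom)`: for a top-strand match starting at s, the top strand is cut
after s + cut_top − 1 and the bottom strand after s + cut_bottom − 1. A
bottom-strand match spanning [start, end] applies the same geometry read
along the bottom strand, which maps to top-strand cuts after end −
cut_bottom and end − cut_top. The three assay enzymes are shipped as data
(`data/enzymes.json`):

* BsmAI — GTCTC(1/5): `cut_top=6`, `cut_bottom=10` (type IIS, cuts
  downstream of the motif, 4 nt 5' overhang);
* RsaI — GT↓AC: `cut_top=cut_bottom=2` (blunt, palindromic; each physical
  site is reported once);
* BseYI — C↓CCAGC: `cut_top=1`, `cut_bottom=5`.

Fragment lengths are spans between consecutive distinct **top-strand** cut
coordinates plus the molecule ends. Staggered overhangs are invisible on a
gel, so they are not modelled as separate species; consequently digesting
the reverse complement can shift each staggered boundary by the overhang
length (asserted as a property test). Cuts that would fall at or beyond a
molecule end are dropped with a logged warning — the enzyme binds but
cannot productively cleave. Complete digestion is assumed; coincident cut
coordinates collapse to one boundary. These conventions agree with
Biopython's REBASE-derived `Bio.Restriction` fragment sets on random
templates, which the test suite uses as an independent cross-check (the
implementation itself is self-contained).

## Known deviation: the wild *4 5'-proximal fragments

The printed *4 forward primer (CACATTTTCTACAACCATGGAGACC) contains GAGAC —
a bottom-strand BsmAI recognition — at primer positions 20–24. Under the
GTCTC(1/5) convention its top-strand cut falls after amplicon coordinate
14, so the wild *4 amplicon digests to {14, 89, 141} where the assay's
published table prints {15, 88, 141}. The one-base discrepancy cannot be
resolved from the published material (it is consistent with either a
different counting convention or a genomic site one base away); the
diagnostic quantities — the 141 bp wild fragment, the 47/94 bp variant
fragments and the site counts — are unaffected, and the genotype caller
never keys on the 14/15 or 88/89 values (14 is below gel visibility and
88/89 are within sizing tolerance of each other).

## Primer metrics

Melting temperature uses the Wallace rule, Tm = 2(A+T) + 4(G+C) °C, the
standard estimate for short oligos; GC% is rounded half-up to one decimal,
matching how primer tables are printed. Primer QC flags length outside
18–30 nt, GC outside 40–60 %, and annotations inconsistent with the
sequence (annotated Tm > 2 °C from the Wallace value, or annotated GC%
different from the recomputed one). The shipped *22_F primer annotation
(GC 47.8 %, Tm 70 °C) is inconsistent with its printed 24-mer sequence
(12 G+C → 50.0 %, 72 °C — the annotations fit a 23-mer); QC surfaces this
as a warning, and nothing downstream relies on that row's annotations.

## In-silico PCR

Primer binding is exact full-length string matching on both strands; the
assay's primers were genome-BLASTed for specificity by design, so a
mismatch-tolerant annealing model would add free parameters without adding
realism (a `max_mismatches` hook exists but only 0 is implemented).
A product is any forward/reverse hit combination in amplifiable orientation
with span ≤ 5,000 bp (a generous bound over the largest 793 bp product);
its sequence is reported canonical to the forward primer's strand. Multiple
products per pair and cross-pair chimeras are reported as design warnings,
never silently suppressed.

## Synthetic templates

The generator emulates only what the assay logic can observe: primers at
the amplicon ends, recognition sites at designed positions, the SNP base
coupling (A>G at *4 position 145 completes a GTCTC; G>A at *18B position
114 destroys its GTAC; C>T at *22 position 219 destroys its CCCAGC), and
uniform-random ACGT elsewhere. Fragment order along an amplicon is not
observable on a gel, so the orders were fixed for convenience of placement
(*4: 14|89|141; *22 BsmAI: 153|56|59|525, avoiding collisions with the
RsaI site at 111–114 and the BseYI site at 219–224). It does **not**
emulate the true genomic context (flanking sequence, GC content,
neighbouring polymorphisms), polymerase behaviour, or partial digestion —
so passing tests show the assay *logic* is coherent, not that the primers
would behave on real DNA.

Generation is deterministic given (layout, seed); the default seed is
20180830 and is recorded in FASTA headers. After stamping the fixed
features, both alleles are scanned with all configured enzymes and all six
assay primers; any recognition site or primer match that touches a
randomly filled position is removed by re-randomising those positions (up
to 1,000 repair rounds, after which the layout is declared infeasible — a
fixed, unrepairable off-target match fails immediately). Loci embed the
amplicon in flanks that are kept entirely free of enzyme sites and primer
matches, which is stronger than the minimum needed for correct PCR.

## Gel model and genotype calling

`GelModel` has three parameters, all overridable on the CLI:

* `min_visible_bp = 75` — on the published 4 % gel, 88 and 112 bp bands are
  visible while 15/56/59 bp are annotated "not shown"; 75 separates the two
  groups.
* `comigration_rel = 0.05` — bands whose pairwise relative size difference
  is below 5 % merge into one band at their mean (greedy clustering in
  ascending size order).
* `sizing_tolerance_rel = 0.05` — an observed band matches a predicted one
  within 5 % relative error, appropriate to high-resolution agarose run
  against a 50 bp ladder.

For each SNP the caller compares the observed bands of its diagnostic tube
against the three genotype patterns (wild / het / hom, het being the union
of both alleles' fragments) after the gel model. A candidate matches when
every predicted diagnostic band is observed and every observed band is
explained by a diagnostic or background prediction; background bands
(cross-digestion fragments of the other two amplicons, which in this design
are identical for both alleles) are optional, so a weak background band
that falls below detection — the 112 bp *22/RsaI band does this in
practice — never degrades a call. Exactly one matching genotype is
reported; several matches yield `ambiguous` with all candidates listed
(never tie-broken), none yields `fail` with the mismatch evidence. An empty
tube fails with reason "no bands".

Under the default parameters the full round trip — predict, gel-filter,
call — recovers all 27 genotype combinations with no ambiguity, which is
the package's statement that the published design is fully resolvable.

## Design validation

`validate_multiplex` reports (a) the enzyme × amplicon × allele
cross-digestion matrix (cut/ND) — for this design: BsmAI cuts *4 and *22
but not *18B, RsaI cuts wild *18B and *22 but not *4, BseYI cuts wild *22
only; (b) pairwise distinguishability of the three genotype patterns per
tube after the gel model, with collisions listed; (c) primer QC summaries.

## Numerical and I/O choices

GC% rounding is half-up (`decimal`), not banker's. Co-migration merging
uses the relative difference against the pairwise mean. Tabular outputs are
tab-separated UTF-8 with header rows; configs and reports are JSON; FASTA
is 60-column wrapped with `key=value` header metadata. Logging goes to
stderr, results to files/stdout; CLI exit codes are 0 (success), 1 (user
error), 2 (internal error).

## Problem sizes

The property tests use randomised templates up to 500 bp: length
conservation and scanner-vs-brute-force equivalence run over 1,000 random
500 bp templates, and cross-checks against `Bio.Restriction` use 50–200
random templates of 400–500 bp; the genotype round trip enumerates all 27
genotype combinations on the full-size synthetic amplicons (244/331/793
bp). These sizes comfortably exercise every code path of a method whose
real inputs are single amplicons under 800 bp.

## Limitations

* Heterozygotes are modelled as pure band-set unions; real gels carry
  dosage information in band intensity that the caller does not use.
* Complete digestion is assumed; a partial digest would produce extra
  bands that the caller would report as `fail` rather than recognise.
* Exact-match primer binding cannot flag primers that would mis-anneal on
  real genomic DNA.
* The synthetic templates satisfy the assay's constraints but are not the
  CYP3A4 gene; results on them validate the method's logic, not its
  wet-lab performance.
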