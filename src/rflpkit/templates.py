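"""Seeded synthetic amplicons and loci for the CYP3A4*4/*18B/*22 assay.

Real patient DNA is obviously not shippable, so these generators build
stand-in sequences that encode exactly the constraints the assay depends
on: the printed primers stamped at the amplicon ends, restriction sites
placed so each enzyme's digest reproduces the published per-allele fragment
sizes, a single SNP position that creates or destroys the diagnostic site,
and seeded random sequence everywhere else.  Any *spurious* recognition
site or off-target primer match introduced by the random fill is repaired
by re-randomising the offending window, so digestion results are exact by
construction and independent of the seed.

The three default layouts (see :func:`default_layouts`):

* CYP3A4*4 (244 bp, rs55951658 A>G, read with BsmAI): a top-strand GTCTC
  at 98-102 cuts after 103; the printed forward primer itself carries a
  bottom-strand BsmAI site (GAGAC at primer positions 20-24) cutting after
  14.  Wild digest {14, 89, 141}.  The variant base A>G at 145 completes a
  third site (GTCTC at 145-149, cut after 150), splitting the 141 bp
  terminal fragment into 47 + 94.
* CYP3A4*18B (331 bp, rs2242480 G>A, read with RsaI): GTAC at 114-117 cuts
  after 115 -> {115, 216}; the variant A at 114 destroys the site
  (undigested 331).
* CYP3A4*22 (793 bp, rs35599367 C>T, read with BseYI): CCCAGC at 219-224
  cuts after 219 -> {219, 574}; the variant T at 219 destroys it.  The
  long product is unavoidably cross-digested: three top-strand GTCTC sites
  (148, 204, 263) give the BsmAI pattern {153, 56, 59, 525} and a GTAC at
  111-114 gives the RsaI pattern {112, 681}.

Where the published tables print 15/88 for the wild *4 5'-proximal
fragments, the GTCTC(1/5) offset convention applied to the primer-embedded
site yields 14/89; the diagnostic fragments (141 wild, 47/94 variant) are
unaffected.  See docs/methods.md.

Fragment order along an amplicon is invisible on a gel; the orders fixed
here were chosen so that placements do not collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzymes import RestrictionEnzyme, default_enzymes, find_sites
from .pcr import PrimerPair
from .sequences import DnaSequence, PrimerRecord, reverse_complement
from .io import default_primers

__all__ = [
    "Placement",
    "SnpSpec",
    "TemplateLayout",
    "default_layouts",
    "default_pairs",
    "build_amplicon",
    "build_allele_pair",
    "build_locus",
    "DEFAULT_SEED",
    "SNPS",
    "ALLELES",
]

# Default generator seed; recorded in FASTA headers for provenance.
DEFAULT_SEED = 20180830
MAX_REPAIR_ROUNDS = 1000

SNPS = ("CYP3A4*4", "CYP3A4*18B", "CYP3A4*22")
ALLELES = ("wild", "variant")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Placement:
    """A fixed subsequence stamped at a 1-based position (top strand)."""

    motif: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.motif) - 1


@dataclass(frozen=True)
class SnpSpec:
    position: int  # 1-based on the amplicon
    wild_base: str
    variant_base: str


@dataclass(frozen=True)
class TemplateLayout:
    """Declarative description of one synthetic amplicon (both alleles)."""

    name: str  # SNP name, e.g. CYP3A4*4
    length: int
    primer_f: PrimerRecord
    primer_r: PrimerRecord
    placements: tuple[Placement, ...]
    snp: SnpSpec
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        regions = [(1, self.primer_f.length_nt, str(self.primer_f.sequence))]
        r_start = self.length - self.primer_r.length_nt + 1
        regions.append((r_start, self.length, str(reverse_complement(self.primer_r.sequence))))
        for p in self.placements:
            regions.append((p.start, p.end, p.motif))
        for i, (a1, b1, _) in enumerate(regions):
            if a1 < 1 or b1 > self.length:
                raise ValueError(f"{self.name}: placement [{a1},{b1}] outside amplicon")
            for a2, b2, _ in regions[i + 1:]:
                if a1 <= b2 and a2 <= b1:
                    raise ValueError(
                        f"{self.name}: placements [{a1},{b1}] and [{a2},{b2}] overlap"
                    )
        if not (1 <= self.snp.position <= self.length):
            raise ValueError(f"{self.name}: SNP position outside amplicon")

    def fixed_positions(self) -> dict[int, str | None]:
        """1-based position -> fixed base (None marks the SNP slot)."""
        fixed: dict[int, str | None] = {}
        for i, ch in enumerate(str(self.primer_f.sequence)):
            fixed[1 + i] = ch
        rc_r = str(reverse_complement(self.primer_r.sequence))
        r_start = self.length - self.primer_r.length_nt + 1
        for i, ch in enumerate(rc_r):
            fixed[r_start + i] = ch
        for p in self.placements:
            for i, ch in enumerate(p.motif):
                fixed[p.start + i] = ch
        if self.snp.position in fixed:
            raise ValueError(f"{self.name}: SNP position collides with a placement/primer")
        fixed[self.snp.position] = None
        return fixed


def default_layouts(seed: int = DEFAULT_SEED) -> dict[str, TemplateLayout]:
    """The three canonical layouts, keyed by SNP name."""
    primers = default_primers()
    return {
        "CYP3A4*4": TemplateLayout(
            name="CYP3A4*4",
            length=244,
            primer_f=primers["*4_F"],
            primer_r=primers["*4_R"],
            placements=(
                Placement("GTCTC", 98),  # constitutive site, cut after 103
                Placement("TCTC", 146),  # variant SNP G at 145 completes GTCTC
            ),
            snp=SnpSpec(position=145, wild_base="A", variant_base="G"),
            seed=seed,
        ),
        "CYP3A4*18B": TemplateLayout(
            name="CYP3A4*18B",
            length=331,
            primer_f=primers["*18B_F"],
            primer_r=primers["*18B_R"],
            placements=(
                Placement("TAC", 115),  # wild SNP G at 114 completes GTAC
            ),
            snp=SnpSpec(position=114, wild_base="G", variant_base="A"),
            seed=seed,
        ),
        "CYP3A4*22": TemplateLayout(
            name="CYP3A4*22",
            length=793,
            primer_f=primers["*22_F"],
            primer_r=primers["*22_R"],
            placements=(
                Placement("GTAC", 111),   # RsaI cross-digestion, cut after 112
                Placement("GTCTC", 148),  # BsmAI, cut after 153
                Placement("GTCTC", 204),  # BsmAI, cut after 209
                Placement("CCAGC", 220),  # wild SNP C at 219 completes CCCAGC
                Placement("GTCTC", 263),  # BsmAI, cut after 268
            ),
            snp=SnpSpec(position=219, wild_base="C", variant_base="T"),
            seed=seed,
        ),
    }


def default_pairs() -> dict[str, PrimerPair]:
    """The three assay primer pairs with their expected product sizes."""
    primers = default_primers()
    sizes = {"CYP3A4*4": 244, "CYP3A4*18B": 331, "CYP3A4*22": 793}
    tags = {"CYP3A4*4": "*4", "CYP3A4*18B": "*18B", "CYP3A4*22": "*22"}
    return {
        snp: PrimerPair(
            name=snp,
            forward=primers[f"{tags[snp]}_F"],
            reverse=primers[f"{tags[snp]}_R"],
            expected_size=sizes[snp],
        )
        for snp in SNPS
    }


class LayoutInfeasibleError(RuntimeError):
    """Raised when the repair budget is exhausted or a conflict is unfixable."""


def _spurious_free_positions(
    seq: list[str],
    free: set[int],  # 0-based indices open to re-randomisation
    enzymes: list[RestrictionEnzyme],
    primers: list[PrimerRecord],
    expected_primer_hits: set[tuple[str, str, int]],  # (primer, strand, 1-based start)
) -> set[int]:
    """0-based free positions inside unintended site/primer windows.

    A recognition-site window lying entirely on fixed sequence is considered
    intentional (stamped placements and primer-embedded sites); any window
    touching a free position is spurious.  Raises if an unintended window is
    fully fixed and therefore unrepairable.
    """
    text = DnaSequence("".join(seq))
    offending: set[int] = set()
    for enz in enzymes:
        for site in find_sites(text, enz):
            window = set(range(site.start - 1, site.end))
            hit = window & free
            if hit:
                offending.update(hit)
    for primer in primers:
        needles = {
            "top": str(primer.sequence),
            "bottom": str(reverse_complement(primer.sequence)),
        }
        for strand, needle in needles.items():
            pos = text.find(needle)
            while pos != -1:
                key = (primer.name, strand, pos + 1)
                if key not in expected_primer_hits:
                    window = set(range(pos, pos + len(needle)))
                    hit = window & free
                    if not hit:
                        raise LayoutInfeasibleError(
                            f"off-target {primer.name} match at {pos + 1} lies entirely "
                            "on fixed sequence"
                        )
                    offending.update(hit)
                pos = text.find(needle, pos + 1)
    return offending


def _repair_fill(
    seq: list[str],
    free: set[int],
    rng: np.random.Generator,
    scan_variants: list[list[str]],
    enzymes: list[RestrictionEnzyme],
    primers: list[PrimerRecord],
    expected_hits: set[tuple[str, str, int]],
    what: str,
) -> None:
    """Re-randomise free positions until no scanned variant has spurious hits.

    ``scan_variants`` share the mutable ``seq`` storage at free positions via
    explicit re-sync each round (variants differ only at fixed slots such as
    the SNP base).
    """
    for _ in range(MAX_REPAIR_ROUNDS):
        offending: set[int] = set()
        for variant in scan_variants:
            for i in free:
                variant[i] = seq[i]
            offending |= _spurious_free_positions(
                variant, free, enzymes, primers, expected_hits
            )
        if not offending:
            return
        for i in sorted(offending):
            seq[i] = str(rng.choice(_BASES))
    raise LayoutInfeasibleError(f"{what}: repair budget exhausted ({MAX_REPAIR_ROUNDS} rounds)")


def _scan_primer_set(primers: dict[str, PrimerRecord] | None) -> list[PrimerRecord]:
    if primers is None:
        return list(default_primers().values())
    return list(primers.values())


def build_allele_pair(
    layout: TemplateLayout,
    seed: int | None = None,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
    primers: dict[str, PrimerRecord] | None = None,
) -> dict[str, DnaSequence]:
    """Build both alleles of one layout; they differ only at the SNP base.

    Both alleles are screened for spurious sites in the same repair loop so
    that the shared random fill is clean for either SNP base.  Deterministic
    given (layout, seed).
    """
    enz_list = list((enzymes or default_enzymes()).values())
    primer_list = _scan_primer_set(primers)
    rng = np.random.default_rng(layout.seed if seed is None else seed)
    n = layout.length

    fixed = layout.fixed_positions()
    seq = [str(rng.choice(_BASES)) for _ in range(n)]
    for pos, base in fixed.items():
        if base is not None:
            seq[pos - 1] = base
    free = {i for i in range(n) if (i + 1) not in fixed}

    expected_hits = {
        (layout.primer_f.name, "top", 1),
        (layout.primer_r.name, "bottom", n - layout.primer_r.length_nt + 1),
    }
    snp0 = layout.snp.position - 1
    variants = []
    for base in (layout.snp.wild_base, layout.snp.variant_base):
        v = list(seq)
        v[snp0] = base
        variants.append(v)
    _repair_fill(seq, free, rng, variants, enz_list, primer_list, expected_hits,
                 what=f"amplicon {layout.name}")

    out = {}
    for allele, base in (("wild", layout.snp.wild_base), ("variant", layout.snp.variant_base)):
        v = list(seq)
        v[snp0] = base
        out[allele] = DnaSequence("".join(v))
    return out


def build_amplicon(
    layout: TemplateLayout,
    allele: str,
    seed: int | None = None,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
    primers: dict[str, PrimerRecord] | None = None,
) -> DnaSequence:
    """One allele's synthetic amplicon (see :func:`build_allele_pair`)."""
    if allele not in ALLELES:
        raise ValueError(f"allele must be one of {ALLELES}, got {allele!r}")
    return build_allele_pair(layout, seed=seed, enzymes=enzymes, primers=primers)[allele]


def build_locus(
    layout: TemplateLayout,
    allele: str,
    flank_bp: int,
    seed: int | None = None,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
    primers: dict[str, PrimerRecord] | None = None,
) -> DnaSequence:
    """Amplicon embedded in seeded random flanks free of sites and primer hits.

    The flanks carry no match of any assay primer and no recognition site of
    any configured enzyme (anywhere in the flank, which is stronger than the
    minimum needed near the junctions), so in-silico PCR on the locus yields
    exactly the designed product.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    base_seed = layout.seed if seed is None else seed
    amplicon = build_amplicon(layout, allele, seed=base_seed, enzymes=enzymes, primers=primers)
    if flank_bp == 0:
        return amplicon

    enz_list = list((enzymes or default_enzymes()).values())
    primer_list = _scan_primer_set(primers)
    allele_code = ALLELES.index(allele)
    rng = np.random.default_rng([base_seed, flank_bp, allele_code])

    n = flank_bp * 2 + layout.length
    seq = [str(rng.choice(_BASES)) for _ in range(n)]
    seq[flank_bp:flank_bp + layout.length] = list(str(amplicon))
    free = set(range(flank_bp)) | set(range(flank_bp + layout.length, n))

    expected_hits = {
        (layout.primer_f.name, "top", flank_bp + 1),
        (layout.primer_r.name, "bottom", flank_bp + layout.length - layout.primer_r.length_nt + 1),
    }
    _repair_fill(seq, free, rng, [list(seq)], enz_list, primer_list, expected_hits,
                 what=f"locus {layout.name} ({allele})")
    return DnaSequence("".join(seq))
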