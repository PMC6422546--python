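"""In-silico PCR: primer binding, amplification, multiplexing.

Binding is exact full-length matching — the assay's primers were designed
and specificity-checked against the genome, so mismatch-tolerant annealing
would add parameters without adding realism here.  A hook for 3'-anchored
mismatches exists (``max_mismatches``, default 0) but only 0 is currently
implemented.

The product of a primer pair is the inclusive span between the two primer
5' ends; its sequence is reported on the strand of the forward primer, so
every amplicon starts with the forward primer and ends with the reverse
complement of the reverse primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequences import DnaSequence, PrimerRecord, reverse_complement

__all__ = [
    "PrimerPair",
    "Amplicon",
    "MultiplexResult",
    "find_binding_sites",
    "amplify",
    "multiplex_amplify",
]

MAX_PRODUCT_SIZE = 5000  # generous bound over the largest expected product


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: PrimerRecord
    reverse: PrimerRecord
    expected_size: int | None = None

    def __post_init__(self) -> None:
        if self.expected_size is not None and self.expected_size < (
            self.forward.length_nt + self.reverse.length_nt
        ):
            raise ValueError(
                f"{self.name}: expected size {self.expected_size} smaller than "
                "combined primer lengths"
            )


@dataclass(frozen=True)
class Amplicon:
    pair: str
    sequence: DnaSequence
    start: int  # 1-based inclusive, on the source template
    end: int
    template: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MultiplexResult:
    amplicons: list[Amplicon] = field(default_factory=list)
    nonspecific: list[str] = field(default_factory=list)  # pairs with >1 product
    chimera_warnings: list[str] = field(default_factory=list)


def find_binding_sites(
    template: str, primer: PrimerRecord, max_mismatches: int = 0
) -> list[tuple[str, int]]:
    """Exact full-length primer matches: ``(strand, start)`` 1-based, sorted.

    A "bottom" hit means the primer anneals to the bottom strand, i.e. its
    reverse complement appears on the top strand starting at ``start``.
    """
    if max_mismatches != 0:
        raise NotImplementedError("mismatch-tolerant binding is not implemented")
    tpl = DnaSequence(template)
    fwd = str(primer.sequence)
    rev = str(reverse_complement(primer.sequence))
    hits: list[tuple[str, int]] = []
    for strand, needle in (("top", fwd), ("bottom", rev)):
        pos = tpl.find(needle)
        while pos != -1:
            hits.append((strand, pos + 1))
            pos = tpl.find(needle, pos + 1)
    return sorted(hits, key=lambda h: (h[1], h[0]))


def amplify(
    template: str,
    pair: PrimerPair,
    max_size: int = MAX_PRODUCT_SIZE,
    template_name: str = "",
) -> list[Amplicon]:
    """All products of one primer pair on one template.

    A product requires a top-strand forward hit upstream of a bottom-strand
    reverse hit, with total span <= max_size.  Multiple products are all
    returned — non-specificity is a design signal, not an error.
    """
    if max_size <= 0:
        raise ValueError("max_size must be positive")
    tpl = DnaSequence(template)
    f_len = pair.forward.length_nt
    r_len = pair.reverse.length_nt
    f_sites = find_binding_sites(tpl, pair.forward)
    r_sites = find_binding_sites(tpl, pair.reverse)
    products: list[Amplicon] = []
    # forward on the top strand, reverse on the bottom strand
    for f_start in (s for strand, s in f_sites if strand == "top"):
        for r_start in (s for strand, s in r_sites if strand == "bottom"):
            r_5prime = r_start + r_len - 1  # reverse primer 5' end (top coords)
            span = r_5prime - f_start + 1
            if span < max(f_len, r_len) or span > max_size:
                continue
            seq = DnaSequence(tpl[f_start - 1:r_5prime])
            products.append(Amplicon(
                pair=pair.name, sequence=seq, start=f_start, end=r_5prime,
                template=template_name,
            ))
    # flipped orientation: the product is read off the bottom strand so its
    # sequence stays canonical to the forward primer
    for f_start in (s for strand, s in f_sites if strand == "bottom"):
        f_5prime = f_start + f_len - 1
        for r_start in (s for strand, s in r_sites if strand == "top"):
            span = f_5prime - r_start + 1
            if span < max(f_len, r_len) or span > max_size:
                continue
            seq = reverse_complement(tpl[r_start - 1:f_5prime])
            products.append(Amplicon(
                pair=pair.name, sequence=seq, start=r_start, end=f_5prime,
                template=template_name,
            ))
    return products


def multiplex_amplify(
    templates: list[str] | dict[str, str],
    pairs: list[PrimerPair],
    max_size: int = MAX_PRODUCT_SIZE,
) -> MultiplexResult:
    """Co-amplification of all primer pairs over all templates.

    Besides the per-pair products, cross-pair chimeras (forward primer of
    one pair with the reverse of another) are searched for and reported as
    design warnings.
    """
    if not pairs:
        raise ValueError("at least one primer pair required")
    if isinstance(templates, dict):
        items = list(templates.items())
    else:
        items = [(f"template_{i + 1}", t) for i, t in enumerate(templates)]
    if not items:
        raise ValueError("at least one template required")

    result = MultiplexResult()
    for name, tpl in items:
        for pair in pairs:
            prods = amplify(tpl, pair, max_size=max_size, template_name=name)
            result.amplicons.extend(prods)
            if len(prods) > 1:
                result.nonspecific.append(
                    f"{pair.name} on {name}: {len(prods)} products"
                )
        for pa in pairs:
            for pb in pairs:
                if pa.name == pb.name:
                    continue
                chimera = PrimerPair(
                    name=f"{pa.name}_F+{pb.name}_R",
                    forward=pa.forward,
                    reverse=pb.reverse,
                )
                for prod in amplify(tpl, chimera, max_size=max_size, template_name=name):
                    result.chimera_warnings.append(
                        f"chimeric product {prod.length} bp on {name}: "
                        f"{pa.name} forward x {pb.name} reverse"
                    )
    return result
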