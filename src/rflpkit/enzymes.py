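"""Restriction-enzyme model: site finding, cut geometry, linear digestion.

Cut geometry convention
-----------------------
Coordinates are 1-based and inclusive; "cut after x" means cleavage of the
phosphodiester bond between template positions x and x+1.  An enzyme is
defined by its top-strand recognition motif plus two offsets, ``cut_top``
(t) and ``cut_bottom`` (b), both counted from the first base of a top-strand
match: the top strand is cleaved after coordinate start+t-1 and the bottom
strand after start+b-1.  This covers within-site cutters (RsaI: GT^AC,
t=b=2), asymmetric within-site cutters (BseYI: C^CCAGC, t=1, b=5) and
type IIS offset cutters that cleave downstream of the motif (BsmAI:
GTCTC(1/5), t=6, b=10).

A match on the bottom strand (the window equals the reverse complement of
the recognition motif) cuts with the same geometry read along the bottom
strand: for a window spanning [start, end] on top-strand coordinates the
top strand is cleaved after end-b and the bottom strand after end-t.

Fragment sizes are computed from TOP-strand cut coordinates only: the 4-nt
staggered overhangs BsmAI and BseYI leave are invisible on an agarose gel,
so a single length per fragment is what a gel (and a fragment table)
reports.  Complete digestion is assumed.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .sequences import IUPAC_SETS, DnaSequence, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "RestrictionEnzyme",
    "SiteMatch",
    "CutEvent",
    "FragmentSet",
    "load_enzymes",
    "default_enzymes",
    "find_sites",
    "cut_positions",
    "digest_linear",
    "site_count",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition motif plus top/bottom cut offsets (see module docstring)."""

    name: str
    recognition: DnaSequence
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", DnaSequence(self.recognition))
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition motif shorter than 4 nt")
        if self.cut_top < 1 or self.cut_bottom < 1:
            raise ValueError(f"{self.name}: cut offsets must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)

    @property
    def is_blunt(self) -> bool:
        return self.cut_top == self.cut_bottom

    @property
    def overhang(self) -> int:
        """Signed overhang length (bottom minus top cut offset)."""
        return self.cut_bottom - self.cut_top


@dataclass(frozen=True)
class SiteMatch:
    """One physical recognition site, located on top-strand coordinates."""

    enzyme: str
    strand: str  # "top" | "bottom"
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive


@dataclass(frozen=True)
class CutEvent:
    site: SiteMatch
    top_cut_after: int
    bottom_cut_after: int | None  # None when it falls off the molecule


class FragmentSet:
    """Digestion fragments of a linear molecule, ordered 5'->3' (top strand)."""

    def __init__(self, fragments: Sequence[int], template_length: int):
        self.fragments = list(fragments)
        self.template_length = template_length
        if any(f < 1 for f in self.fragments):
            raise ValueError("zero/negative fragment length")
        if sum(self.fragments) != template_length:
            raise ValueError(
                f"fragments sum to {sum(self.fragments)} != template length {template_length}"
            )

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __eq__(self, other) -> bool:
        if isinstance(other, FragmentSet):
            return self.multiset == other.multiset
        return NotImplemented

    @property
    def multiset(self) -> Counter:
        return Counter(self.fragments)

    @property
    def sorted(self) -> list[int]:
        return sorted(self.fragments)

    def __repr__(self) -> str:
        return f"FragmentSet({self.fragments})"


def load_enzymes(path=None) -> dict[str, RestrictionEnzyme]:
    """Load enzyme definitions from a JSON config (name -> enzyme).

    The packaged default carries BsmAI, RsaI and BseYI; further enzymes can
    be added as data without code changes.
    """
    if path is None:
        text = resources.files("rflpkit.data").joinpath("enzymes.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed enzyme config: {exc}") from exc
    if not isinstance(raw, list):
        raise ValueError("enzyme config must be a JSON array")
    enzymes: dict[str, RestrictionEnzyme] = {}
    for i, entry in enumerate(raw):
        missing = {"name", "recognition", "cut_top", "cut_bottom"} - set(entry)
        if missing:
            raise ValueError(f"enzyme entry {i}: missing fields {sorted(missing)}")
        enz = RestrictionEnzyme(
            name=entry["name"],
            recognition=DnaSequence(entry["recognition"]),
            cut_top=int(entry["cut_top"]),
            cut_bottom=int(entry["cut_bottom"]),
        )
        enzymes[enz.name] = enz
    return enzymes


def default_enzymes() -> dict[str, RestrictionEnzyme]:
    return load_enzymes()


def find_sites(template: str, enzyme: RestrictionEnzyme) -> list[SiteMatch]:
    """All recognition sites on both strands, sorted by start coordinate.

    Palindromic motifs match identically on both strands, so each physical
    site is reported once (as a top-strand match).
    """
    tpl = DnaSequence(template)
    motif = enzyme.recognition
    rc_motif = reverse_complement(motif)
    # degeneracy sets precomputed once; windows are compared as plain chars
    top_sets = [IUPAC_SETS[c] for c in motif]
    bottom_sets = [IUPAC_SETS[c] for c in rc_motif]
    L = len(motif)
    n = len(tpl)
    text = str(tpl)
    palindromic = enzyme.is_palindromic
    sites: list[SiteMatch] = []
    for start0 in range(n - L + 1):
        window = text[start0:start0 + L]
        if all(w in s for s, w in zip(top_sets, window)):
            sites.append(SiteMatch(enzyme.name, "top", start0 + 1, start0 + L))
            if palindromic:
                continue  # same physical site; do not double-report
        if not palindromic and all(w in s for s, w in zip(bottom_sets, window)):
            sites.append(SiteMatch(enzyme.name, "bottom", start0 + 1, start0 + L))
    return sites


def cut_positions(template: str, enzyme: RestrictionEnzyme) -> list[CutEvent]:
    """Cut events for every in-bounds site.

    Events whose top-strand cut would fall at or beyond either molecule end
    (<= 0 or >= length) produce no cleavage and are dropped with a warning.
    """
    tpl = DnaSequence(template)
    n = len(tpl)
    t, b = enzyme.cut_top, enzyme.cut_bottom
    events: list[CutEvent] = []
    for site in find_sites(tpl, enzyme):
        if site.strand == "top":
            top_cut = site.start + t - 1
            bottom_cut = site.start + b - 1
        else:
            top_cut = site.end - b
            bottom_cut = site.end - t
        if top_cut < 1 or top_cut >= n:
            logger.warning(
                "%s site at %d-%d (%s strand): top cut after %d falls outside "
                "the molecule (length %d); dropped",
                enzyme.name, site.start, site.end, site.strand, top_cut, n,
            )
            continue
        events.append(CutEvent(
            site=site,
            top_cut_after=top_cut,
            bottom_cut_after=bottom_cut if 1 <= bottom_cut < n else None,
        ))
    return sorted(events, key=lambda e: e.top_cut_after)


def digest_linear(
    template: str, enzymes: Iterable[RestrictionEnzyme]
) -> FragmentSet:
    """Complete digestion of a linear molecule by one or more enzymes.

    Fragment lengths are spans between consecutive distinct top-strand cut
    coordinates plus the molecule ends; coincident cuts collapse.  An empty
    enzyme list returns the full-length molecule.
    """
    tpl = DnaSequence(template)
    n = len(tpl)
    cuts: set[int] = set()
    for enzyme in enzymes:
        cuts.update(e.top_cut_after for e in cut_positions(tpl, enzyme))
    boundaries = [0] + sorted(cuts) + [n]
    fragments = [b - a for a, b in zip(boundaries, boundaries[1:])]
    return FragmentSet(fragments, n)


def site_count(template: str, enzyme: RestrictionEnzyme) -> int:
    """Number of recognition sites (both strands)."""
    return len(find_sites(template, enzyme))
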