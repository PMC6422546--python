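"""Nucleotide-sequence primitives.

Everything downstream (site scanning, digestion, in-silico PCR) operates on
plain validated DNA strings.  Templates must be unambiguous A/C/G/T; motifs
(enzyme recognition sequences) may use the full IUPAC degenerate alphabet.

The melting temperature implemented here is the Wallace rule,
Tm = 2(A+T) + 4(G+C) °C, the standard back-of-the-envelope estimate for
short oligonucleotides (< ~30 nt).  It is deliberately crude: primer QC
flags primers whose annotated Tm deviates from it rather than trying to
model salt or nearest-neighbour thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

__all__ = [
    "DnaSequence",
    "PrimerRecord",
    "QCCheck",
    "QCReport",
    "reverse_complement",
    "gc_percent",
    "wallace_tm",
    "iupac_match",
    "primer_qc",
]

# IUPAC degeneracy sets (DNA only; U is rejected on ingest).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMP_TABLE = str.maketrans(IUPAC_COMPLEMENT)
UNAMBIGUOUS = frozenset("ACGT")


class DnaSequence(str):
    """A validated uppercase DNA string (IUPAC alphabet).

    Lower-case input is accepted and upper-cased; ``U`` is rejected.
    Instances are plain ``str`` subclasses, so all slicing/scanning code can
    treat them as text.
    """

    def __new__(cls, bases: str) -> "DnaSequence":
        s = str(bases).upper()
        if not s:
            raise ValueError("empty sequence")
        for i, ch in enumerate(s):
            if ch not in IUPAC_SETS:
                raise ValueError(
                    f"invalid nucleotide {ch!r} at position {i + 1} (1-based)"
                )
        return super().__new__(cls, s)

    @property
    def is_unambiguous(self) -> bool:
        return all(c in UNAMBIGUOUS for c in self)

    def reverse_complement(self) -> "DnaSequence":
        return DnaSequence(self.translate(_COMP_TABLE)[::-1])


def reverse_complement(s: str) -> DnaSequence:
    """IUPAC-aware reverse complement (R<->Y, S<->S, W<->W, K<->M, N<->N)."""
    return DnaSequence(s).reverse_complement()


def _require_unambiguous(s: DnaSequence, what: str) -> None:
    for i, ch in enumerate(s):
        if ch not in UNAMBIGUOUS:
            raise ValueError(
                f"{what} undefined for ambiguous base {ch!r} at position {i + 1}"
            )


def gc_percent(s: str) -> float:
    """G+C content as a percentage, rounded half-up to one decimal."""
    seq = DnaSequence(s)
    _require_unambiguous(seq, "GC%")
    gc = seq.count("G") + seq.count("C")
    pct = Decimal(100 * gc) / Decimal(len(seq))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def wallace_tm(s: str) -> int:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C), in °C."""
    seq = DnaSequence(s)
    _require_unambiguous(seq, "Tm")
    gc = seq.count("G") + seq.count("C")
    at = len(seq) - gc
    return 2 * at + 4 * gc


def iupac_match(motif: str, window: str) -> bool:
    """True iff each window base lies in the degeneracy set of the motif base.

    The match is one-directional: the motif may be degenerate, the window is
    expected to be concrete template sequence.  Lengths must agree.
    """
    m = DnaSequence(motif)
    w = DnaSequence(window)
    if len(m) != len(w):
        raise ValueError(f"length mismatch: motif {len(m)} vs window {len(w)}")
    return all(wb in IUPAC_SETS[mb] for mb, wb in zip(m, w))


@dataclass(frozen=True)
class PrimerRecord:
    """A primer with its annotated metrics (as a vendor table would print them).

    ``tm_c`` and ``gc_pct`` are the *annotated* values; QC recomputes them
    from the sequence and flags inconsistencies.
    """

    name: str
    sequence: DnaSequence
    length_nt: int
    tm_c: int
    gc_pct: float

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "PrimerRecord":
        seq = DnaSequence(sequence)
        return cls(
            name=name,
            sequence=seq,
            length_nt=len(seq),
            tm_c=wallace_tm(seq),
            gc_pct=gc_percent(seq),
        )


@dataclass(frozen=True)
class QCCheck:
    rule: str
    status: str  # "pass" | "warn"
    message: str


@dataclass
class QCReport:
    primer: str
    checks: list[QCCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.status == "pass" for c in self.checks)

    @property
    def warnings(self) -> list[QCCheck]:
        return [c for c in self.checks if c.status == "warn"]


# Consensus design rules for PCR primers: 18-30 nt, 40-60% GC.
PRIMER_LEN_RANGE = (18, 30)
PRIMER_GC_RANGE = (40.0, 60.0)
TM_CONSISTENCY_C = 2


def primer_qc(p: PrimerRecord) -> QCReport:
    """Rule-based primer QC: length, GC window, and annotation consistency.

    Always returns a report; nothing here raises on a bad primer.
    """
    report = QCReport(primer=p.name)
    checks = report.checks

    lo, hi = PRIMER_LEN_RANGE
    if lo <= len(p.sequence) <= hi:
        checks.append(QCCheck("length", "pass", f"{len(p.sequence)} nt within {lo}-{hi}"))
    else:
        checks.append(QCCheck("length", "warn", f"{len(p.sequence)} nt outside {lo}-{hi}"))

    gc = gc_percent(p.sequence)
    glo, ghi = PRIMER_GC_RANGE
    if glo <= gc <= ghi:
        checks.append(QCCheck("gc_range", "pass", f"GC {gc}% within {glo}-{ghi}%"))
    else:
        checks.append(QCCheck("gc_range", "warn", f"GC {gc}% outside {glo}-{ghi}%"))

    if abs(p.gc_pct - gc) > 0.05:
        checks.append(QCCheck(
            "gc_consistency", "warn",
            f"annotated GC {p.gc_pct}% != computed {gc}%",
        ))
    else:
        checks.append(QCCheck("gc_consistency", "pass", f"annotated GC matches computed {gc}%"))

    tm = wallace_tm(p.sequence)
    if abs(p.tm_c - tm) > TM_CONSISTENCY_C:
        checks.append(QCCheck(
            "tm_consistency", "warn",
            f"annotated Tm {p.tm_c} °C deviates >{TM_CONSISTENCY_C} °C from Wallace {tm} °C",
        ))
    else:
        checks.append(QCCheck("tm_consistency", "pass", f"annotated Tm consistent with Wallace {tm} °C"))

    if p.length_nt != len(p.sequence):
        checks.append(QCCheck(
            "length_consistency", "warn",
            f"annotated length {p.length_nt} != sequence length {len(p.sequence)}",
        ))
    else:
        checks.append(QCCheck("length_consistency", "pass", "annotated length matches sequence"))

    return report
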