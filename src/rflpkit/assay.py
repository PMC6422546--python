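"""RFLP assay logic: band prediction, gel model, genotype calls, validation.

The multiplex product pool is split into one tube per SNP, each digested by
that SNP's diagnostic enzyme.  Every tube therefore contains the fragments
of *all three* amplicons under that enzyme — the diagnostic fragments of
one SNP plus cross-digestion background from the other two.  A heterozygote
contributes the union of both alleles' fragment sets (no dosage/intensity
modelling).

The gel model captures what a stained high-percentage agarose gel can
resolve: fragments below ``min_visible_bp`` are not seen, near-identical
sizes co-migrate into one band, and observed sizes match predictions only
within a relative tolerance.  Genotypes are called by exhaustive comparison
against the three predicted patterns; if more than one genotype explains
the visible bands the call is reported ambiguous — never tie-broken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .enzymes import RestrictionEnzyme, cut_positions, default_enzymes, digest_linear
from .sequences import DnaSequence, PrimerRecord, QCReport, primer_qc

__all__ = [
    "SnpDef",
    "TubeSpec",
    "AssayDefinition",
    "GelModel",
    "BandPattern",
    "GenotypeCall",
    "load_assay",
    "default_assay",
    "predict_patterns",
    "apply_gel_model",
    "call_genotype",
    "validate_multiplex",
    "GENOTYPES",
]

GENOTYPES = ("wild", "het", "hom")
_GENOTYPE_ALLELES = {
    "wild": ("wild",),
    "het": ("wild", "variant"),
    "hom": ("variant",),
}


@dataclass(frozen=True)
class SnpDef:
    name: str
    wild_allele: str  # nucleotide, e.g. "A"
    variant_allele: str


@dataclass(frozen=True)
class TubeSpec:
    enzyme: str
    diagnostic_snp: str
    incubation: str = ""  # informational only


@dataclass
class AssayDefinition:
    snps: list[SnpDef]
    tubes: list[TubeSpec]
    amplicon_sizes: dict[str, int]

    def __post_init__(self) -> None:
        snp_names = [s.name for s in self.snps]
        diagnosed = [t.diagnostic_snp for t in self.tubes]
        if sorted(snp_names) != sorted(diagnosed):
            raise ValueError(
                "each SNP must be assigned exactly one diagnostic tube "
                f"(snps={snp_names}, tubes diagnose {diagnosed})"
            )

    def tube_for(self, snp: str) -> TubeSpec:
        for tube in self.tubes:
            if tube.diagnostic_snp == snp:
                return tube
        raise KeyError(snp)


@dataclass(frozen=True)
class GelModel:
    """Visibility and sizing behaviour of the gel.

    Defaults reflect a 4% high-resolution agarose gel: the smallest bands
    the published figures annotate as visible are 88/112 bp while 15/56/59
    bp are "not shown", so 75 bp separates them; 5% relative co-migration
    and sizing tolerances suit a high-percentage gel run against a 50 bp
    ladder.
    """

    min_visible_bp: float = 75.0
    comigration_rel: float = 0.05
    sizing_tolerance_rel: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_visible_bp, self.comigration_rel, self.sizing_tolerance_rel) <= 0:
            raise ValueError("all gel-model parameters must be > 0")


@dataclass
class BandPattern:
    tube: str
    bands: list[float]  # every fragment present in the tube
    visible_bands: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands)
        self.visible_bands = sorted(self.visible_bands)


@dataclass
class GenotypeCall:
    snp: str
    call: str  # wild | heterozygous | homozygous_variant | ambiguous | fail
    evidence: dict = field(default_factory=dict)


_CALL_NAME = {
    "wild": "wild",
    "het": "heterozygous",
    "hom": "homozygous_variant",
}


def load_assay(path=None) -> AssayDefinition:
    """Load an assay definition from JSON (packaged default: the 3-SNP design)."""
    if path is None:
        text = resources.files("rflpkit.data").joinpath("assay.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed assay config: {exc}") from exc
    for key in ("snps", "tubes", "amplicon_sizes"):
        if key not in raw:
            raise ValueError(f"assay config missing {key!r}")
    return AssayDefinition(
        snps=[SnpDef(s["name"], s["wild_allele"], s["variant_allele"]) for s in raw["snps"]],
        tubes=[TubeSpec(t["enzyme"], t["diagnostic_snp"], t.get("incubation", "")) for t in raw["tubes"]],
        amplicon_sizes={k: int(v) for k, v in raw["amplicon_sizes"].items()},
    )


def default_assay() -> AssayDefinition:
    return load_assay()


def _digest_sizes(seq: DnaSequence, enzyme: RestrictionEnzyme) -> list[int]:
    return list(digest_linear(seq, [enzyme]))


def predict_patterns(
    assay: AssayDefinition,
    genotypes: dict[str, str],
    amplicon_seqs: dict[str, dict[str, DnaSequence]],
    enzymes: dict[str, RestrictionEnzyme] | None = None,
) -> dict[str, BandPattern]:
    """Per-tube band multisets for a full diploid genotype assignment.

    ``amplicon_seqs`` maps SNP -> allele ("wild"/"variant") -> sequence.
    Heterozygotes contribute both alleles' fragment sets; homozygotes one.
    """
    enzymes = enzymes or default_enzymes()
    patterns: dict[str, BandPattern] = {}
    for tube in assay.tubes:
        enzyme = enzymes[tube.enzyme]
        bands: list[float] = []
        for snp in assay.snps:
            g = genotypes.get(snp.name)
            if g not in GENOTYPES:
                raise ValueError(f"genotype for {snp.name} must be one of {GENOTYPES}, got {g!r}")
            for allele in _GENOTYPE_ALLELES[g]:
                try:
                    seq = amplicon_seqs[snp.name][allele]
                except KeyError:
                    raise ValueError(
                        f"missing amplicon sequence for {snp.name} allele {allele!r}"
                    ) from None
                bands.extend(_digest_sizes(seq, enzyme))
        patterns[tube.enzyme] = BandPattern(tube=tube.enzyme, bands=bands)
    return patterns


def _merge_comigrating(sizes: list[float], rel: float) -> list[float]:
    """Greedy left-to-right clustering of sizes within ``rel`` of the cluster mean."""
    merged: list[float] = []
    cluster: list[float] = []
    for bp in sorted(sizes):
        if cluster and abs(bp - cluster[-1]) / ((bp + cluster[-1]) / 2) < rel:
            cluster.append(bp)
        else:
            if cluster:
                merged.append(sum(cluster) / len(cluster))
            cluster = [bp]
    if cluster:
        merged.append(sum(cluster) / len(cluster))
    return merged


def apply_gel_model(pattern: BandPattern, gel: GelModel) -> BandPattern:
    """Visible bands: drop sub-threshold fragments, merge co-migrating ones."""
    visible = [bp for bp in pattern.bands if bp >= gel.min_visible_bp]
    visible = _merge_comigrating(visible, gel.comigration_rel)
    return BandPattern(tube=pattern.tube, bands=list(pattern.bands), visible_bands=visible)


def _matches(observed: float, predicted: float, rel: float) -> bool:
    return abs(observed - predicted) / predicted <= rel


def _pattern_match(
    observed: list[float],
    diagnostic: list[float],
    background: list[float],
    rel: float,
) -> tuple[bool, dict]:
    """Does a candidate genotype explain the observed tube?

    Every predicted diagnostic band must be observed; every observed band
    must be explained by a diagnostic or background prediction.  Background
    bands are optional (their absence never degrades the call — e.g. a weak
    cross-digestion band may fall below detection in one lane).
    """
    missing = [
        pb for pb in diagnostic
        if not any(_matches(ob, pb, rel) for ob in observed)
    ]
    unexplained = [
        ob for ob in observed
        if not any(_matches(ob, pb, rel) for pb in diagnostic + background)
    ]
    matched = [
        ob for ob in observed
        if any(_matches(ob, pb, rel) for pb in diagnostic)
    ]
    return (not missing and not unexplained), {
        "matched": matched,
        "missing": missing,
        "unexplained": unexplained,
    }


def _candidate_patterns(
    assay: AssayDefinition,
    snp: SnpDef,
    tube: TubeSpec,
    amplicon_seqs: dict[str, dict[str, DnaSequence]],
    enzymes: dict[str, RestrictionEnzyme],
    gel: GelModel,
) -> tuple[dict[str, list[float]], list[float]]:
    """(per-genotype visible diagnostic bands, visible background bands)."""
    enzyme = enzymes[tube.enzyme]
    diag: dict[str, list[float]] = {}
    for g in GENOTYPES:
        bands: list[float] = []
        for allele in _GENOTYPE_ALLELES[g]:
            bands.extend(_digest_sizes(amplicon_seqs[snp.name][allele], enzyme))
        diag[g] = apply_gel_model(BandPattern(tube.enzyme, bands), gel).visible_bands
    background: list[float] = []
    for other in assay.snps:
        if other.name == snp.name:
            continue
        for allele in ("wild", "variant"):
            bands = _digest_sizes(amplicon_seqs[other.name][allele], enzymes[tube.enzyme])
            background.extend(
                apply_gel_model(BandPattern(tube.enzyme, bands), gel).visible_bands
            )
    return diag, background


def call_genotype(
    observed: dict[str, list[float]],
    assay: AssayDefinition,
    gel: GelModel | None = None,
    amplicon_seqs: dict[str, dict[str, DnaSequence]] | None = None,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
) -> list[GenotypeCall]:
    """Call each SNP's genotype from the observed bands of its diagnostic tube.

    ``observed`` maps tube (enzyme name) -> list of observed band sizes.
    A unique matching genotype is reported; multiple matches -> ambiguous;
    none (or an empty tube) -> fail, with the evidence recorded.
    """
    gel = gel or GelModel()
    enzymes = enzymes or default_enzymes()
    if amplicon_seqs is None:
        amplicon_seqs = default_amplicon_seqs()
    calls: list[GenotypeCall] = []
    for snp in assay.snps:
        tube = assay.tube_for(snp.name)
        obs = sorted(observed.get(tube.enzyme, []))
        if not obs:
            calls.append(GenotypeCall(snp.name, "fail", {"reason": "no bands", "tube": tube.enzyme}))
            continue
        diag, background = _candidate_patterns(assay, snp, tube, amplicon_seqs, enzymes, gel)
        matches: dict[str, dict] = {}
        evidence_all: dict[str, dict] = {}
        for g in GENOTYPES:
            ok, ev = _pattern_match(obs, diag[g], background, gel.sizing_tolerance_rel)
            evidence_all[g] = ev
            if ok:
                matches[g] = ev
        if len(matches) == 1:
            g = next(iter(matches))
            calls.append(GenotypeCall(snp.name, _CALL_NAME[g], {
                "tube": tube.enzyme, "genotype": g, **matches[g],
            }))
        elif len(matches) > 1:
            calls.append(GenotypeCall(snp.name, "ambiguous", {
                "tube": tube.enzyme,
                "candidates": sorted(matches),
                "evidence": {g: matches[g] for g in matches},
            }))
        else:
            calls.append(GenotypeCall(snp.name, "fail", {
                "tube": tube.enzyme,
                "reason": "no genotype explains the observed bands",
                "evidence": evidence_all,
            }))
    return calls


def default_amplicon_seqs(seed: int | None = None) -> dict[str, dict[str, DnaSequence]]:
    """Synthetic amplicons for all SNPs and alleles from the default layouts."""
    from .templates import build_allele_pair, default_layouts

    layouts = default_layouts()
    return {name: build_allele_pair(layout, seed=seed) for name, layout in layouts.items()}


def _patterns_indistinguishable(a: list[float], b: list[float], rel: float) -> bool:
    """True if every band of each pattern matches some band of the other."""
    return all(any(_matches(x, y, rel) for y in b) for x in a) and all(
        any(_matches(y, x, rel) for x in a) for y in b
    )


def validate_multiplex(
    assay: AssayDefinition,
    amplicon_seqs: dict[str, dict[str, DnaSequence]],
    gel: GelModel | None = None,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
    primers: dict[str, PrimerRecord] | None = None,
) -> dict:
    """Design validation report for a multiplex PCR-RFLP assay.

    Contains (a) the enzyme x amplicon cross-digestion matrix ("cut"/"ND"
    per allele), (b) per-tube pairwise distinguishability of the three
    genotype patterns after the gel model, and (c) a primer QC summary.
    """
    gel = gel or GelModel()
    enzymes = enzymes or default_enzymes()

    cross: dict[str, dict[str, dict[str, str]]] = {}
    for enz_name, enzyme in enzymes.items():
        cross[enz_name] = {}
        for snp in assay.snps:
            cross[enz_name][snp.name] = {}
            for allele in ("wild", "variant"):
                seq = amplicon_seqs[snp.name][allele]
                cut = len(cut_positions(seq, enzyme)) > 0
                cross[enz_name][snp.name][allele] = "cut" if cut else "ND"

    collisions: list[dict] = []
    for snp in assay.snps:
        tube = assay.tube_for(snp.name)
        diag, _ = _candidate_patterns(assay, snp, tube, amplicon_seqs, enzymes, gel)
        for i, g1 in enumerate(GENOTYPES):
            for g2 in GENOTYPES[i + 1:]:
                if _patterns_indistinguishable(diag[g1], diag[g2], gel.sizing_tolerance_rel):
                    collisions.append({
                        "snp": snp.name,
                        "tube": tube.enzyme,
                        "genotypes": [g1, g2],
                        "patterns": {g1: diag[g1], g2: diag[g2]},
                    })

    qc_reports: dict[str, QCReport] = {}
    if primers:
        qc_reports = {name: primer_qc(rec) for name, rec in primers.items()}

    return {
        "cross_digestion": cross,
        "distinguishability_collisions": collisions,
        "distinguishable": not collisions,
        "primer_qc": {
            name: {
                "passed": rep.passed,
                "warnings": [c.message for c in rep.warnings],
            }
            for name, rep in qc_reports.items()
        },
    }
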