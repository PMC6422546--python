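import itertools

import pytest

from rflpkit.assay import (
    GENOTYPES,
    AssayDefinition,
    BandPattern,
    GelModel,
    SnpDef,
    TubeSpec,
    apply_gel_model,
    call_genotype,
    load_assay,
    predict_patterns,
    validate_multiplex,
)

CALL_NAME = {"wild": "wild", "het": "heterozygous", "hom": "homozygous_variant"}


def visible(assay, genotypes, seqs, gel):
    patterns = predict_patterns(assay, genotypes, seqs)
    return {t: apply_gel_model(p, gel).visible_bands for t, p in patterns.items()}


class TestAssayDefinition:
    def test_default_assay(self, assay):
        assert [t.enzyme for t in assay.tubes] == ["BsmAI", "RsaI", "BseYI"]
        assert assay.tube_for("CYP3A4*18B").enzyme == "RsaI"
        assert assay.amplicon_sizes == {
            "CYP3A4*4": 244, "CYP3A4*18B": 331, "CYP3A4*22": 793,
        }

    def test_each_snp_one_tube(self):
        with pytest.raises(ValueError, match="exactly one diagnostic tube"):
            AssayDefinition(
                snps=[SnpDef("a", "A", "G"), SnpDef("b", "C", "T")],
                tubes=[TubeSpec("RsaI", "a")],
                amplicon_sizes={},
            )

    def test_bad_config_rejected(self, tmp_path):
        p = tmp_path / "assay.json"
        p.write_text('{"snps": []}')
        with pytest.raises(ValueError, match="missing"):
            load_assay(p)


class TestPredictPatterns:
    def test_all_wild_bsmai_tube(self, assay, amplicon_seqs):
        genotypes = {s.name: "wild" for s in assay.snps}
        patterns = predict_patterns(assay, genotypes, amplicon_seqs)
        # *4 fragments + undigested *18B + *22 cross-digestion
        assert patterns["BsmAI"].bands == sorted([14, 89, 141, 331, 56, 59, 153, 525])

    def test_all_wild_rsai_tube(self, assay, amplicon_seqs):
        genotypes = {s.name: "wild" for s in assay.snps}
        patterns = predict_patterns(assay, genotypes, amplicon_seqs)
        assert patterns["RsaI"].bands == sorted([115, 216, 244, 112, 681])

    def test_18b_hom_rsai_tube(self, assay, amplicon_seqs):
        genotypes = {"CYP3A4*4": "wild", "CYP3A4*18B": "hom", "CYP3A4*22": "wild"}
        patterns = predict_patterns(assay, genotypes, amplicon_seqs)
        assert patterns["RsaI"].bands == sorted([331, 244, 112, 681])

    def test_het_contributes_both_alleles(self, assay, amplicon_seqs):
        genotypes = {"CYP3A4*4": "het", "CYP3A4*18B": "wild", "CYP3A4*22": "wild"}
        patterns = predict_patterns(assay, genotypes, amplicon_seqs)
        assert patterns["BsmAI"].bands == sorted(
            [14, 89, 141] + [14, 47, 89, 94] + [331] + [56, 59, 153, 525]
        )

    def test_het_is_union_of_wild_and_hom(self, assay, amplicon_seqs):
        """Allele-union semantics: in every tube, the het pattern plus the
        shared background equals the wild plus hom patterns (as multisets)."""
        from collections import Counter

        from rflpkit.enzymes import digest_linear
        from rflpkit.assay import default_enzymes

        enzymes = default_enzymes()
        base = {s.name: "wild" for s in assay.snps}
        for s in assay.snps:
            pats = {
                g: predict_patterns(assay, {**base, s.name: g}, amplicon_seqs)
                for g in GENOTYPES
            }
            for tube in pats["wild"]:
                background = Counter()
                for other in assay.snps:
                    if other.name != s.name:
                        background += Counter(
                            digest_linear(amplicon_seqs[other.name]["wild"],
                                          [enzymes[tube]])
                        )
                w = Counter(pats["wild"][tube].bands)
                h = Counter(pats["hom"][tube].bands)
                het = Counter(pats["het"][tube].bands)
                assert het + background == w + h, (s.name, tube)

    def test_missing_allele_sequence_errors(self, assay, amplicon_seqs):
        seqs = {k: dict(v) for k, v in amplicon_seqs.items()}
        del seqs["CYP3A4*18B"]["variant"]
        genotypes = {"CYP3A4*4": "wild", "CYP3A4*18B": "het", "CYP3A4*22": "wild"}
        with pytest.raises(ValueError, match=r"CYP3A4\*18B.*variant"):
            predict_patterns(assay, genotypes, seqs)

    def test_unknown_genotype_errors(self, assay, amplicon_seqs):
        genotypes = {"CYP3A4*4": "wild", "CYP3A4*18B": "xx", "CYP3A4*22": "wild"}
        with pytest.raises(ValueError, match="genotype"):
            predict_patterns(assay, genotypes, amplicon_seqs)


class TestGelModel:
    @pytest.mark.parametrize("bands,expected", [
        ([15, 88, 141], [88, 141]),       # 15 bp runs off / is not shown
        ([56, 59, 153, 525], [153, 525]),  # 56/59 below visibility
        ([], []),
    ])
    def test_visibility_threshold(self, gel, bands, expected):
        pattern = apply_gel_model(BandPattern("t", bands), gel)
        assert pattern.visible_bands == expected

    def test_comigration_merges_to_mean(self, gel):
        pattern = apply_gel_model(BandPattern("t", [100, 104, 300]), gel)
        assert pattern.visible_bands == [102.0, 300]

    def test_bands_preserved(self, gel):
        pattern = apply_gel_model(BandPattern("t", [15, 88, 141]), gel)
        assert pattern.bands == [15, 88, 141]

    def test_parameters_validated(self):
        with pytest.raises(ValueError):
            GelModel(min_visible_bp=0)


class TestCallGenotype:
    def test_18b_heterozygous_from_full_tube(self, assay, gel, amplicon_seqs):
        observed = {"RsaI": [115, 216, 331, 244, 112, 681]}
        calls = call_genotype(observed, assay, gel, amplicon_seqs)
        by_snp = {c.snp: c for c in calls}
        assert by_snp["CYP3A4*18B"].call == "heterozygous"

    def test_22_wild_from_bseyi_tube(self, assay, gel, amplicon_seqs):
        observed = {"BseYI": [219, 574, 244, 331]}
        calls = {c.snp: c for c in call_genotype(observed, assay, gel, amplicon_seqs)}
        assert calls["CYP3A4*22"].call == "wild"

    def test_4_heterozygous_both_diagnostic_sets(self, assay, gel, amplicon_seqs):
        genotypes = {"CYP3A4*4": "het", "CYP3A4*18B": "wild", "CYP3A4*22": "wild"}
        observed = visible(assay, genotypes, amplicon_seqs, gel)
        calls = {c.snp: c for c in call_genotype(observed, assay, gel, amplicon_seqs)}
        assert calls["CYP3A4*4"].call == "heterozygous"

    def test_empty_tube_fails(self, assay, gel, amplicon_seqs):
        calls = {c.snp: c for c in call_genotype({}, assay, gel, amplicon_seqs)}
        for c in calls.values():
            assert c.call == "fail"
            assert c.evidence["reason"] == "no bands"

    def test_unexplained_band_fails(self, assay, gel, amplicon_seqs):
        observed = {"RsaI": [115, 216, 999]}
        calls = {c.snp: c for c in call_genotype(observed, assay, gel, amplicon_seqs)}
        assert calls["CYP3A4*18B"].call == "fail"

    def test_missing_background_band_tolerated(self, assay, gel, amplicon_seqs):
        # the 112 bp *22 cross-digestion band straddles the visibility
        # threshold in practice; its absence must not degrade an *18B call
        observed = {"RsaI": [115, 216, 681]}
        calls = {c.snp: c for c in call_genotype(observed, assay, gel, amplicon_seqs)}
        assert calls["CYP3A4*18B"].call == "wild"

    def test_ambiguity_reported_not_tiebroken(self, assay, amplicon_seqs):
        sloppy = GelModel(min_visible_bp=75, comigration_rel=0.05,
                          sizing_tolerance_rel=0.9)
        observed = {"RsaI": [115, 216, 244, 112, 681]}
        calls = {c.snp: c for c in call_genotype(observed, assay, sloppy, amplicon_seqs)}
        call = calls["CYP3A4*18B"]
        assert call.call == "ambiguous"
        assert len(call.evidence["candidates"]) > 1

    def test_round_trip_all_27_genotypes(self, assay, gel, amplicon_seqs):
        """predict -> gel-filter -> call recovers every diploid genotype
        combination with no ambiguity."""
        names = [s.name for s in assay.snps]
        for combo in itertools.product(GENOTYPES, repeat=3):
            genotypes = dict(zip(names, combo))
            observed = visible(assay, genotypes, amplicon_seqs, gel)
            calls = call_genotype(observed, assay, gel, amplicon_seqs)
            assert len(calls) == 3
            for c in calls:
                assert c.call == CALL_NAME[genotypes[c.snp]], (genotypes, c)


class TestValidateMultiplex:
    def test_cross_digestion_matrix(self, assay, gel, amplicon_seqs):
        report = validate_multiplex(assay, amplicon_seqs, gel)
        cross = report["cross_digestion"]
        assert cross["BsmAI"]["CYP3A4*4"] == {"wild": "cut", "variant": "cut"}
        assert cross["BsmAI"]["CYP3A4*18B"] == {"wild": "ND", "variant": "ND"}
        assert cross["BsmAI"]["CYP3A4*22"] == {"wild": "cut", "variant": "cut"}
        assert cross["RsaI"]["CYP3A4*4"] == {"wild": "ND", "variant": "ND"}
        assert cross["RsaI"]["CYP3A4*18B"] == {"wild": "cut", "variant": "ND"}
        assert cross["RsaI"]["CYP3A4*22"] == {"wild": "cut", "variant": "cut"}
        assert cross["BseYI"]["CYP3A4*4"] == {"wild": "ND", "variant": "ND"}
        assert cross["BseYI"]["CYP3A4*18B"] == {"wild": "ND", "variant": "ND"}
        assert cross["BseYI"]["CYP3A4*22"] == {"wild": "cut", "variant": "ND"}

    def test_default_design_distinguishable(self, assay, gel, amplicon_seqs):
        report = validate_multiplex(assay, amplicon_seqs, gel)
        assert report["distinguishable"]
        assert report["distinguishability_collisions"] == []

    def test_degenerate_gel_flags_collisions(self, assay, amplicon_seqs):
        """A gel that cannot see any band makes all genotype patterns
        coincide; the validator must flag that."""
        blind = GelModel(min_visible_bp=10000)
        report = validate_multiplex(assay, amplicon_seqs, blind)
        assert not report["distinguishable"]
        assert report["distinguishability_collisions"]

    def test_primer_qc_summary(self, assay, gel, amplicon_seqs, primers):
        report = validate_multiplex(assay, amplicon_seqs, gel, primers=primers)
        assert set(report["primer_qc"]) == set(primers)
        assert all(entry["passed"] for entry in report["primer_qc"].values())
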