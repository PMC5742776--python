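"""Digestion engine: site finding, exhaustive digestion, resistance, oracle."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oatpep import (
    CleavageRuleSet,
    PositionalRule,
    digest,
    digest_many,
    find_cleavage_sites,
    is_resistant,
    load_enzyme,
    oracle_digest,
    random_protein,
)

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80)


def ruleset(*rules, name="test", exceptions=()):
    return CleavageRuleSet(
        enzyme_name=name,
        rules=tuple(PositionalRule({k: frozenset(v) for k, v in r.items()})
                    for r in rules),
        exceptions=tuple(PositionalRule({k: frozenset(v) for k, v in e.items()})
                         for e in exceptions),
    )


class TestFindCleavageSites:
    def test_no_sites_without_matching_residue(self, trypsin):
        assert find_cleavage_sites("GGGG", trypsin) == []

    def test_trypsin_cuts_after_lysine(self, trypsin):
        assert find_cleavage_sites("AKAG", trypsin) == [1]

    def test_lysine_proline_bond_is_spared(self, trypsin):
        assert find_cleavage_sites("AKPG", trypsin) == []

    def test_keil_tryptophan_exception_restores_kp_cleavage(self, trypsin):
        # W-K|P is the documented positive exception to the K|P block
        assert find_cleavage_sites("AWKPG", trypsin) == [2]

    def test_undetermined_residue_matches_no_set(self, trypsin):
        assert find_cleavage_sites("AKXG", trypsin) == []
        assert find_cleavage_sites("AXKAG", trypsin) == [2]

    def test_unknown_residue_rejected(self, trypsin):
        with pytest.raises(ValueError):
            find_cleavage_sites("AKZ", trypsin)
        with pytest.raises(ValueError):
            find_cleavage_sites("", trypsin)

    def test_rule_with_out_of_range_context_does_not_match(self):
        rs = ruleset({"P2": "A", "P1": "K"})
        # bond 0 has no P2 position, so only bond 2 (A at P2) is cut
        assert find_cleavage_sites("KAKA", rs) == [2]


class TestDigest:
    def test_zero_sites_release_whole_substrate(self, trypsin):
        result = digest("GGGG", trypsin)
        assert [p.sequence for p in result.peptides] == ["GGGG"]

    def test_fragments_from_site_list(self, trypsin):
        result = digest("AKAG", trypsin)
        assert [p.sequence for p in result.peptides] == ["AK", "AG"]
        assert [(p.start, p.end) for p in result.peptides] == [(0, 2), (2, 4)]

    def test_papain_releases_cpa_and_wcy_from_11s_globulin(self, oat_proteins, papain):
        eleven_s = next(p for p in oat_proteins if p.id == "globulin_11S")
        released = {p.sequence for p in digest(eleven_s, papain).peptides}
        assert {"CPA", "WCY"} <= released

    @settings(max_examples=40, derandomize=True)
    @given(sequences)
    def test_reconstruction_and_count(self, seq):
        rs = ruleset({"P1": "KR", "P1'": "ACDEFGHIKLMNQRSTVWY"}, {"P1": "G"})
        result = digest(seq, rs)
        assert "".join(p.sequence for p in result.peptides) == seq
        assert len(result.peptides) == len(result.cut_sites) + 1
        assert all(0 <= b <= len(seq) - 2 for b in result.cut_sites)

    def test_reconstruction_on_fixtures(self, oat_proteins, all_enzymes):
        for record in oat_proteins:
            for enzyme in all_enzymes:
                result = digest(record, enzyme)
                assert "".join(p.sequence for p in result.peptides) == record.sequence
                assert len(result.peptides) == len(result.cut_sites) + 1


class TestDigestMany:
    def test_singleton_union_matches_digest(self, oat_proteins, papain):
        record = oat_proteins[0]
        pooled = digest_many([record], [papain])
        assert set(pooled) == {p.sequence for p in digest(record, papain).peptides}

    def test_products_are_substrings_of_sources(self, oat_proteins, papain, ficin):
        by_id = {p.id: p.sequence for p in oat_proteins}
        pooled = digest_many(oat_proteins, [papain, ficin])
        for seq, provenance in pooled.items():
            for pep in provenance:
                assert by_id[pep.source_id][pep.start:pep.end] == seq

    def test_duplicate_records_do_not_add_sequences(self, oat_proteins, papain):
        record = oat_proteins[0]
        once = digest_many([record], [papain])
        twice = digest_many([record, record], [papain])
        assert set(once) == set(twice)

    def test_order_is_deterministic(self, oat_proteins, papain, ficin):
        a = digest_many(oat_proteins, [papain, ficin])
        b = digest_many(reversed(oat_proteins), [ficin, papain])
        assert list(a) == sorted(a)
        assert list(a) == list(b)

    def test_empty_inputs_rejected(self, papain):
        with pytest.raises(ValueError):
            digest_many([], [papain])


class TestResistance:
    def test_single_residue_has_no_internal_bond(self, panel):
        assert is_resistant("A", panel).resistant

    def test_cpa_survives_the_gi_panel(self, panel):
        report = is_resistant("CPA", panel)
        assert report.resistant
        assert all(sites == () for sites in report.sites_by_enzyme.values())

    def test_ffg_is_cleaved(self, panel):
        report = is_resistant("FFG", panel)
        assert not report.resistant
        assert any(report.sites_by_enzyme.values())

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            is_resistant("CPA", [])


class TestOracleEquivalence:
    def test_oracle_hand_example(self, trypsin):
        assert oracle_digest("AKAG", trypsin) == ["AK", "AG"]

    def test_oracle_rejects_empty_sequence(self, trypsin):
        with pytest.raises(ValueError):
            oracle_digest("", trypsin)

    def test_engine_matches_oracle_on_all_fixtures(self, oat_proteins, all_enzymes):
        for record in oat_proteins:
            for enzyme in all_enzymes:
                engine = [p.sequence for p in digest(record, enzyme).peptides]
                assert engine == oracle_digest(record.sequence, enzyme)

    def test_engine_matches_oracle_on_seeded_random_proteins(self, all_enzymes):
        for seed in range(50):
            seq = random_protein(60, seed=seed).sequence
            for enzyme in all_enzymes:
                engine = [p.sequence for p in digest(seq, enzyme).peptides]
                assert engine == oracle_digest(seq, enzyme)


class TestPyteomicsCrossCheck:
    """The packaged trypsin/chymotrypsin tables encode the PeptideCutter
    conventions; pyteomics ships the same conventions as regexes and serves
    as an implementation-independent check on the X-free fixtures."""

    CASES = {
        "trypsin": "trypsin",
        "chymotrypsin_high": "chymotrypsin high specificity",
        "chymotrypsin_low": "chymotrypsin low specificity",
    }

    @pytest.mark.parametrize("enzyme_name", sorted(CASES))
    def test_fragments_match_pyteomics(self, oat_proteins, enzyme_name):
        parser = pytest.importorskip("pyteomics.parser")
        regex = parser.expasy_rules[self.CASES[enzyme_name]]
        enzyme = load_enzyme(enzyme_name)
        for record in oat_proteins:
            if "X" in record.sequence:  # regexes have no X convention
                continue
            sites = [m.start() for m in re.finditer(regex, record.sequence)]
            assert find_cleavage_sites(record.sequence, enzyme) == sites


class TestRuleSetAlgebra:
    @settings(max_examples=30, derandomize=True)
    @given(sequences, st.sets(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                              min_size=1, max_size=5))
    def test_adding_a_rule_never_removes_sites(self, seq, extra_p1):
        base = ruleset({"P1": "KR"})
        wider = ruleset({"P1": "KR"}, {"P1": "".join(extra_p1)})
        assert set(find_cleavage_sites(seq, base)) <= set(find_cleavage_sites(seq, wider))

    @settings(max_examples=30, derandomize=True)
    @given(sequences, st.sets(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                              min_size=1, max_size=5))
    def test_adding_an_exception_never_adds_sites(self, seq, blocked_p1p):
        base = ruleset({"P1": "KR"})
        narrower = ruleset({"P1": "KR"},
                           exceptions=[{"P1": "KR", "P1'": "".join(blocked_p1p)}])
        assert set(find_cleavage_sites(seq, narrower)) <= set(find_cleavage_sites(seq, base))

    @settings(max_examples=30, derandomize=True)
    @given(sequences)
    def test_exhaustive_digestion_is_idempotent_for_p1_p1p_rules(self, seq):
        # Holds only when no constrained label reaches beyond P1/P1', so
        # fragment termini see the same context the parent did.
        rs = ruleset({"P1": "FY", "P1'": "ACDEFGHIKLMNQRSTVWY"}, {"P1": "K"})
        for pep in digest(seq, rs).peptides:
            again = digest(pep.sequence, rs)
            assert [p.sequence for p in again.peptides] == [pep.sequence]

    def test_rule_must_anchor_the_scissile_bond(self):
        with pytest.raises(ValueError):
            PositionalRule({"P2": frozenset("A")})
        with pytest.raises(ValueError):
            PositionalRule({"P1": frozenset()})
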