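"""Six-branch decision scheme: rule firing, severities, determinism."""

import pytest

from mutexplain.config import RunConfig
from mutexplain.decision_engine import (
    BRANCHES,
    InputError,
    MutationRequest,
    load_rules,
    load_sentences,
    run_scheme,
)
from tests.conftest import record, store_with

SEQ = "MCTAYIAKQRQISFVKSHFSRQLEERLGLIEVQA"  # C at 2, S at 17/20, L at 27


def _request(position, wild, mutant):
    return MutationRequest(seq_id="P1", position=position, wild_type=wild,
                           mutant=mutant)


def _by_branch(findings, branch):
    return [f for f in findings if f.branch == branch]


class TestRequestValidation:
    def test_wild_type_mismatch_names_both(self):
        store = store_with(SEQ, [])
        with pytest.raises(InputError, match="expected wild-type L.*has M"):
            run_scheme(_request(1, "L", "P"), store)

    def test_identity_substitution_rejected(self):
        store = store_with(SEQ, [])
        with pytest.raises(InputError, match="identical"):
            run_scheme(_request(1, "M", "M"), store)

    def test_position_out_of_range(self):
        store = store_with(SEQ, [])
        with pytest.raises(InputError, match="outside"):
            run_scheme(_request(99, "L", "P"), store)


class TestScenarios:
    def test_disulfide_loss_is_severe(self):
        store = store_with(SEQ, [
            record(tier="STRUCTURE", category="CONTACT", ftype="DISULFID",
                   begin=2, end=2, partner="25", description="disulfide bridge"),
        ])
        findings = run_scheme(_request(2, "C", "S"), store)
        contacts = _by_branch(findings, "CONTACTS")
        assert len(contacts) == 1
        assert contacts[0].severity == "SEVERE"
        assert contacts[0].sentence_key == "disulfide_lost"
        assert "disulfide bond" in contacts[0].rendered_text

    def test_salt_bridge_charge_flip_is_severe(self):
        store = store_with(SEQ, [
            record(tier="STRUCTURE", category="CONTACT", ftype="SALT_BRIDGE",
                   begin=8, end=8, partner="24", description="salt bridge"),
        ])
        findings = run_scheme(_request(8, "K", "E"), store)
        contacts = _by_branch(findings, "CONTACTS")
        assert contacts and contacts[0].severity == "SEVERE"
        assert contacts[0].sentence_key == "salt_bridge_broken"

    def test_proline_in_helix_is_severe(self):
        store = store_with(SEQ, [
            record(tier="STRUCTURE", category="FIXED",
                   ftype="SECONDARY_STRUCTURE", begin=22, end=30,
                   description="alpha-helix"),
        ])
        findings = run_scheme(_request(27, "L", "P"), store)
        domain = _by_branch(findings, "DOMAIN")
        assert domain and domain[0].severity == "SEVERE"
        assert domain[0].sentence_key == "helix_breaker"

    def test_buried_hydrophobicity_loss_canonical_sentence(self):
        store = store_with(SEQ, [
            record(tier="STRUCTURE", category="VARIABLE", ftype="ACCESSIBILITY",
                   begin=27, end=27, value=0.01),
        ])
        findings = run_scheme(_request(27, "L", "S"), store)
        props = _by_branch(findings, "PROPERTIES")
        assert props[0].severity == "SEVERE"
        assert props[0].sentence_key == "core_destabilization"
        assert (
            "the mutation introduces a less hydrophobic residue in the core "
            "of the protein which can destabilize the structure"
        ) in props[0].rendered_text.lower()

    def test_phospho_site_loss_and_retention(self):
        store = store_with(SEQ, [
            record(tier="CURATED", category="FIXED", ftype="PHOSPHO_SITE",
                   begin=17, end=17, description="kinase target"),
        ])
        lost = _by_branch(run_scheme(_request(17, "S", "A"), store), "MODIFICATION")
        kept = _by_branch(run_scheme(_request(17, "S", "T"), store), "MODIFICATION")
        assert lost[0].severity == "SEVERE"
        assert lost[0].sentence_key == "phospho_lost"
        assert kept[0].severity == "MODERATE"
        assert kept[0].sentence_key == "phospho_kept"

    def test_prediction_only_evidence_downgrades_severity(self):
        curated = store_with(SEQ, [
            record(tier="CURATED", category="FIXED", ftype="PHOSPHO_SITE",
                   begin=17, end=17)])
        predicted = store_with(SEQ, [
            record(tier="PREDICTED", category="FIXED", ftype="PHOSPHO_SITE",
                   begin=17, end=17)])
        strong = _by_branch(run_scheme(_request(17, "S", "A"), curated),
                            "MODIFICATION")
        weak = _by_branch(run_scheme(_request(17, "S", "A"), predicted),
                          "MODIFICATION")
        assert strong[0].severity == "SEVERE"
        assert weak[0].severity == "MODERATE"

    def test_empty_information_fallback(self):
        store = store_with(SEQ, [])
        findings = run_scheme(_request(27, "L", "P"), store)
        assert [f.branch for f in findings] == ["PROPERTIES"]
        assert findings[0].sentence_key == "property_summary"
        assert "leucine" in findings[0].rendered_text
        assert "proline" in findings[0].rendered_text

    def test_transmem_plus_ligand_gives_two_paragraphs(self):
        """One aspect paragraph per branch, even when both apply."""
        store = store_with(SEQ, [
            record(tier="CURATED", category="FIXED", ftype="TRANSMEM",
                   begin=1, end=15, description="membrane helix"),
            record(tier="STRUCTURE", category="CONTACT", ftype="METAL_CONTACT",
                   begin=5, end=5, partner="ZN", description="zinc contact"),
        ])
        findings = run_scheme(_request(5, "Y", "D"), store)
        assert _by_branch(findings, "CONTACTS")
        assert _by_branch(findings, "DOMAIN")

    def test_known_variant_reported_as_info(self):
        store = store_with(SEQ, [
            record(tier="CURATED", category="VARIANT", ftype="VARIANT",
                   begin=27, end=27, partner="P", description="L->P disease X"),
            record(tier="CURATED", category="VARIANT", ftype="MUTAGEN",
                   begin=27, end=27, partner="A", description="loss of activity"),
        ])
        findings = _by_branch(run_scheme(_request(27, "L", "P"), store), "VARIANT")
        keys = {f.sentence_key for f in findings}
        assert keys == {"variant_same", "variant_other"}
        assert all(f.severity == "INFO" for f in findings)

    def test_conservation_branch_severities(self):
        from mutexplain.conservation import ConservationVerdict

        store = store_with(SEQ, [])
        severe = run_scheme(
            _request(27, "L", "P"), store,
            ConservationVerdict(verdict="INVARIANT", wild_frequency=1.0,
                                mutant_frequency=0.0, mutant_observed=False))
        info = run_scheme(
            _request(27, "L", "P"), store,
            ConservationVerdict(verdict="VARIABLE", wild_frequency=0.4,
                                mutant_frequency=0.3, mutant_observed=True))
        silent = run_scheme(_request(27, "L", "P"), store,
                            ConservationVerdict(verdict="NO_DATA"))
        assert _by_branch(severe, "CONSERVATION")[0].severity == "SEVERE"
        assert _by_branch(info, "CONSERVATION")[0].severity == "INFO"
        assert _by_branch(silent, "CONSERVATION") == []


class TestSchemeContracts:
    def test_branch_order_is_fixed(self):
        store = store_with(SEQ, [
            record(tier="STRUCTURE", category="CONTACT", ftype="DISULFID",
                   begin=2, end=2, partner="25"),
            record(tier="CURATED", category="FIXED", ftype="TRANSMEM",
                   begin=1, end=15),
        ])
        findings = run_scheme(_request(2, "C", "S"), store)
        seen = [f.branch for f in findings]
        assert seen == sorted(seen, key=BRANCHES.index)
        assert seen.index("CONTACTS") < seen.index("DOMAIN") < seen.index("PROPERTIES")

    def test_output_is_deterministic(self):
        store = store_with(SEQ, [
            record(tier="CURATED", category="FIXED", ftype="TRANSMEM",
                   begin=1, end=15)])
        a = run_scheme(_request(5, "Y", "D"), store)
        b = run_scheme(_request(5, "Y", "D"), store)
        assert [f.to_dict() for f in a] == [f.to_dict() for f in b]

    def test_properties_always_contributes(self):
        store = store_with(SEQ, [])
        for wild, pos, mutant in (("M", 1, "A"), ("L", 27, "I"), ("Y", 5, "F")):
            findings = run_scheme(_request(pos, wild, mutant), store)
            assert _by_branch(findings, "PROPERTIES")

    def test_every_rule_has_a_sentence(self):
        sentences = load_sentences()
        for rule in (dict(r) for r in load_rules()):
            assert rule["sentence"] in sentences

    def test_evidence_is_traceable(self):
        records = [
            record(tier="STRUCTURE", category="CONTACT", ftype="DISULFID",
                   begin=2, end=2, partner="25", description="disulfide bridge"),
            record(tier="CURATED", category="FIXED", ftype="TRANSMEM",
                   begin=1, end=15, description="membrane helix"),
        ]
        store = store_with(SEQ, records)
        stored = {(r.feature_type, r.begin, r.end) for r in store.records}
        for f in run_scheme(_request(2, "C", "S"), store):
            for ev in f.evidence:
                if ev["kind"] == "record":
                    assert (ev["feature_type"], ev["begin"], ev["end"]) in stored
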