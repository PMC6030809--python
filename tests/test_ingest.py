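import random

import pytest
from lxml import etree

from sbmlpatterns.errors import DataError, FormatError
from sbmlpatterns.ingest import (
    combined_networks,
    extract_sbo_term,
    ingest_directory,
    ingest_model,
    normalize_sbo_term,
    parse_sbml_model,
)
from sbmlpatterns.synth import SynthConfig, generate_corpus, write_sbml

L2_NS = "http://www.sbml.org/sbml/level2/version4"

SIMPLE_L2 = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{L2_NS}" level="2" version="4">
 <model id="toy" name="toy model">
  <listOfSpecies>
   <species id="S1" sboTerm="SBO:0000247"/>
   <species id="S2"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" sboTerm="216">
    <listOfReactants><speciesReference species="S1" stoichiometry="2"/></listOfReactants>
    <listOfProducts><speciesReference species="S2"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""

RULES_ONLY = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{L2_NS}" level="2" version="4">
 <model id="rules">
  <listOfSpecies><species id="S1"/><species id="S2"/></listOfSpecies>
  <listOfRules>
   <assignmentRule variable="S2"><math/></assignmentRule>
  </listOfRules>
 </model>
</sbml>
"""


class TestParseSbml:
    def test_one_reaction_maps_to_role_tuples(self, tmp_path):
        path = tmp_path / "toy.xml"
        path.write_text(SIMPLE_L2)
        record, tuples, annotations = parse_sbml_model(path)
        assert record.model_id == "toy" and record.model_name == "toy model"
        assert tuples == {("R1", "HAS_REACTANT", "S1"), ("R1", "HAS_PRODUCT", "S2")}
        terms = {a.element_id: a.term for a in annotations}
        # bare-integer sboTerm normalised to the accession form
        assert terms == {"S1": "SBO:0000247", "R1": "SBO:0000216"}

    def test_rules_only_model_yields_no_tuples(self, tmp_path):
        path = tmp_path / "rules.xml"
        path.write_text(RULES_ONLY)
        _, tuples, _ = parse_sbml_model(path)
        assert tuples == set()
        model = ingest_model(path)
        assert len(model.networks) == 0
        assert model.species_ids == {"S1", "S2"}

    def test_duplicate_species_reference_collapses(self, tmp_path):
        xml = SIMPLE_L2.replace(
            '<speciesReference species="S1" stoichiometry="2"/>',
            '<speciesReference species="S1"/><speciesReference species="S1"/>',
        )
        path = tmp_path / "dup.xml"
        path.write_text(xml)
        _, tuples, _ = parse_sbml_model(path)
        assert tuples == {("R1", "HAS_REACTANT", "S1"), ("R1", "HAS_PRODUCT", "S2")}

    def test_species_as_reactant_and_product_keeps_both_roles(self, tmp_path):
        xml = SIMPLE_L2.replace(
            '<listOfProducts><speciesReference species="S2"/></listOfProducts>',
            '<listOfProducts><speciesReference species="S1"/></listOfProducts>',
        )
        path = tmp_path / "both.xml"
        path.write_text(xml)
        _, tuples, _ = parse_sbml_model(path)
        assert tuples == {("R1", "HAS_REACTANT", "S1"), ("R1", "HAS_PRODUCT", "S1")}

    def test_unparseable_file_is_format_error_naming_file(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<sbml><model>")
        with pytest.raises(FormatError, match="broken.xml"):
            parse_sbml_model(path)

    def test_non_sbml_root_rejected(self, tmp_path):
        path = tmp_path / "notsbml.xml"
        path.write_text("<foo/>")
        with pytest.raises(FormatError):
            parse_sbml_model(path)

    def test_tuple_count_equals_distinct_participations(self, tmp_path):
        path = tmp_path / "toy.xml"
        path.write_text(SIMPLE_L2)
        _, tuples, _ = parse_sbml_model(path)
        assert len(tuples) == 2  # 1 distinct reactant + 0 modifiers + 1 product


class TestSboTerm:
    def test_accession_and_integer_forms_normalise(self):
        assert normalize_sbo_term("SBO:0000247") == "SBO:0000247"
        assert normalize_sbo_term("216") == "SBO:0000216"

    def test_malformed_term_is_data_error(self):
        with pytest.raises(DataError):
            normalize_sbo_term("not-a-term")

    def test_unset_attribute_returns_absent(self):
        element = etree.fromstring('<species id="S9"/>')
        assert extract_sbo_term(element) is None


class TestSynthRoundTrip:
    def test_generated_sbml_reproduces_ledger_edge_lists(self, tmp_path):
        """Write/parse round trip over 100 random model configurations."""
        rng = random.Random(1234)
        for trial in range(10):
            config = SynthConfig(
                n_models=10,
                species_range=(1, rng.randint(2, 8)),
                reactions_range=(1, rng.randint(2, 8)),
                participants_range=(1, 2),
                seed=rng.randrange(2**31),
            )
            models, ledger = generate_corpus(config)
            for m in models:
                path = tmp_path / f"{trial}_{m.record.model_id}.xml"
                write_sbml(m, path)
                _, tuples, _ = parse_sbml_model(path)
                assert tuples == ledger.edge_lists[m.record.model_id]

    def test_sbo_terms_survive_round_trip(self, tmp_path):
        from sbmlpatterns.graphs import REACTION, SPECIES

        vocab = [("SBO:0000247", SPECIES, 1.0), ("SBO:0000176", REACTION, 1.0)]
        models, ledger = generate_corpus(
            SynthConfig(n_models=5, sbo_vocabulary=vocab, seed=7)
        )
        for m in models:
            path = tmp_path / f"{m.record.model_id}.xml"
            write_sbml(m, path)
            _, _, annotations = parse_sbml_model(path)
            assert {a.element_id: a.term for a in annotations} == ledger.sbo_terms[
                m.record.model_id
            ]


class TestDirectoryIngest:
    def test_sbo_mode_keeps_only_fully_annotated_models(self, tmp_path):
        from sbmlpatterns.graphs import REACTION, SPECIES

        vocab = [("SBO:0000247", SPECIES, 1.0), ("SBO:0000176", REACTION, 1.0)]
        annotated, _ = generate_corpus(
            SynthConfig(n_models=3, sbo_vocabulary=vocab, seed=1, id_prefix="ANN")
        )
        plain, _ = generate_corpus(SynthConfig(n_models=2, seed=2, id_prefix="PLN"))
        for i, m in enumerate(annotated + plain):
            write_sbml(m, tmp_path / f"m{i}_{m.record.model_id}.xml")
        structural = ingest_directory(tmp_path)
        sbo_only = ingest_directory(tmp_path, sbo_mode=True)
        assert len(structural) == 5
        assert len(sbo_only) == 3
        for m in sbo_only:
            for net in m.networks:
                assert all(lab.sbo_term for lab in net.graph.nodes.values())

    def test_combined_networks_concatenates_provenance(self, tmp_path):
        models, _ = generate_corpus(SynthConfig(n_models=4, seed=3))
        nets = combined_networks(models)
        assert set(nets.model_ids()) == {m.record.model_id for m in models}
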