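"""Synonym indexing, mention linking, and SMILES insertion."""

from __future__ import annotations

import numpy as np
import pytest

from kvreader.linking import (MoleculeRecord, build_mixed_corpus,
                              build_synonym_index, default_stoplist,
                              insert_smiles, link_mentions, split_sentences,
                              strip_smiles_spans)
from kvreader.synthetic import default_grammar, gen_corpus, gen_pairs


def record(mol_id, name, synonyms, smiles="CCO"):
    return MoleculeRecord(id=mol_id, name=name, synonyms=synonyms,
                          smiles=smiles)


class TestSynonymIndex:
    def test_synonyms_become_keys(self):
        idx = build_synonym_index([record("M1", "aspirin", ["aspirin"])],
                                  stoplist={"success", "dogs"})
        assert idx.lookup("aspirin") == "M1"
        assert idx.lookup("Aspirin") == "M1"   # case folded

    def test_stoplisted_common_words_are_excluded(self):
        idx = build_synonym_index(
            [record("M1", "drugX", ["success", "drugX"])],
            stoplist={"success"})
        assert idx.lookup("success") is None
        assert idx.lookup("drugx") == "M1"

    def test_ambiguous_synonyms_dropped(self):
        idx = build_synonym_index([
            record("M1", "a1", ["acid A", "onlyA"]),
            record("M2", "a2", ["acid A"]),
        ])
        assert idx.lookup("acid a") is None
        assert "acid a" in idx.ambiguous
        assert idx.lookup("onlya") == "M1"

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            build_synonym_index([])

    def test_default_stoplist_takes_top_corpus_words(self):
        sents = ["the cat and the dog", "the dog barked"]
        stop = default_stoplist(sents, top_k=2, extra=["manual"])
        assert "the" in stop and "dog" in stop and "manual" in stop
        assert "barked" not in stop


class TestLinkMentions:
    def test_exact_case_insensitive_match(self):
        idx = build_synonym_index([record("M1", "aspirin", ["aspirin"])])
        doc = link_mentions(["Aspirin reduces fever."], idx)
        assert len(doc.mentions) == 1
        m = doc.mentions[0]
        assert (m.sentence, m.molecule_id) == (0, "M1")
        assert doc.sentences[0][m.start:m.end] == "Aspirin"

    def test_longest_match_wins_over_nested_synonym(self):
        idx = build_synonym_index([
            record("M2", "salicylic acid", ["salicylic acid"]),
            record("M3", "acid", ["acid"]),
        ])
        doc = link_mentions(["salicylic acid is produced"], idx)
        assert [m.molecule_id for m in doc.mentions] == ["M2"]

    def test_stoplisted_mention_not_linked(self):
        idx = build_synonym_index(
            [record("M1", "success", ["success"])], stoplist={"success"})
        doc = link_mentions(["Success was reported."], idx)
        assert doc.mentions == []

    def test_removing_synonym_never_increases_mentions(self):
        sents = ["aspirin and salicylic acid were compared",
                 "then aspirin won"]
        full = build_synonym_index([
            record("M1", "aspirin", ["aspirin"]),
            record("M2", "salicylic acid", ["salicylic acid"]),
        ])
        reduced = build_synonym_index([
            record("M2", "salicylic acid", ["salicylic acid"]),
        ])
        n_full = len(link_mentions(sents, full).mentions)
        n_reduced = len(link_mentions(sents, reduced).mentions)
        assert n_reduced <= n_full


class TestInsertSmiles:
    def test_span_appended_after_mention(self):
        records = {"M1": record("M1", "Aspirin", ["Aspirin"],
                                smiles="CC(=O)Oc1ccccc1C(=O)O")}
        idx = build_synonym_index(records.values())
        doc = link_mentions(["Aspirin reduces fever."], idx)
        out = insert_smiles(doc, records)
        assert out == ["Aspirin [SMI] CC=OOccccccC=OO [/SMI] reduces fever."]

    def test_replace_mode_substitutes_the_mention(self):
        records = {"M1": record("M1", "Aspirin", ["Aspirin"], smiles="CCO")}
        idx = build_synonym_index(records.values())
        doc = link_mentions(["Aspirin reduces fever."], idx)
        out = insert_smiles(doc, records, replace=True)
        assert out == ["[SMI] CCO [/SMI] reduces fever."]

    def test_document_without_mentions_returned_verbatim(self):
        records = {"M1": record("M1", "x", ["x"])}
        idx = build_synonym_index(records.values())
        doc = link_mentions(["Nothing of note here."], idx)
        assert insert_smiles(doc, records) == ["Nothing of note here."]

    def test_two_mentions_in_one_sentence_keep_order(self):
        records = {"M1": record("M1", "alphaol", ["alphaol"], smiles="CCO"),
                   "M2": record("M2", "betaol", ["betaol"], smiles="CCN")}
        idx = build_synonym_index(records.values())
        sent = "alphaol reacts with betaol slowly."
        out = insert_smiles(link_mentions([sent], idx), records)
        assert out == ["alphaol [SMI] CCO [/SMI] reacts with "
                       "betaol [SMI] CCN [/SMI] slowly."]

    def test_unresolvable_molecule_id_raises(self):
        records = {"M1": record("M1", "alphaol", ["alphaol"])}
        idx = build_synonym_index([record("M9", "betaol", ["betaol"])])
        doc = link_mentions(["betaol was tested."], idx)
        with pytest.raises(KeyError, match="M9"):
            insert_smiles(doc, records)

    def test_deleting_spans_restores_original_bytes(self):
        records = {"M1": record("M1", "alphaol", ["alphaol"], smiles="CCO")}
        idx = build_synonym_index(records.values())
        sents = ["alphaol dissolved.", "Then alphaol crystallized, slowly."]
        out = insert_smiles(link_mentions(sents, idx), records)
        assert [strip_smiles_spans(s) for s in out] == sents


@pytest.fixture(scope="module")
def planted():
    grammar = default_grammar(n_fragments=8, seed=3)
    pairs, records, log = gen_pairs(grammar, 40, seed=3)
    docs, plants = gen_corpus(records, grammar, n_docs=40,
                              mentions_per_doc=2, log=log, seed=4)
    return records, docs, plants


class TestPlantedCorpus:
    """Round trips through the generator's recorded ground truth."""

    def test_full_dictionary_gives_perfect_precision_and_recall(self, planted):
        records, docs, plants = planted
        idx = build_synonym_index(records.values())
        found = set()
        for d, doc in enumerate(docs):
            for m in link_mentions(doc["sentences"], idx).mentions:
                found.add((d, m.sentence, m.start, m.end, m.molecule_id))
        expected = {(p.doc, p.sentence, p.start, p.end, p.molecule_id)
                    for p in plants}
        assert found == expected   # precision 1.0 and recall 1.0

    def test_stoplisting_a_synonym_reduces_recall_by_its_planted_share(
            self, planted):
        records, docs, plants = planted
        stopped = plants[0].synonym
        idx = build_synonym_index(records.values(), stoplist=[stopped])
        n_found = sum(
            len(link_mentions(doc["sentences"], idx).mentions)
            for doc in docs)
        n_stopped = sum(p.synonym.casefold() == stopped.casefold()
                        for p in plants)
        assert n_found == len(plants) - n_stopped
        assert n_stopped > 0

    def test_mixed_corpus_round_trip_restores_sentences(self, planted):
        records, docs, plants = planted
        idx = build_synonym_index(records.values())
        mixed = build_mixed_corpus(docs, records, idx)
        for doc, mix in zip(docs, mixed):
            assert [strip_smiles_spans(s) for s in mix["sentences"]] == \
                doc["sentences"]


def test_sentence_splitter_splits_on_terminator_then_capital():
    text = "First one. Second here! Third? yes, still third."
    assert split_sentences(text) == [
        "First one.", "Second here!", "Third? yes, still third."]
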