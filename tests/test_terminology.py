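"""Vocabulary loading, refinement filters and lexicon construction."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litriage.terminology import (
    Lexicon,
    RefinementPolicy,
    SynonymRecord,
    TermEntry,
    Vocabulary,
    build_lexicon,
    default_stopwords,
    load_vocabulary,
    vocab_stats,
)
from litriage.text import normalize_surface

from conftest import GO_BP_STANZA


class TestLoadObo:
    def test_go_stanza_parses_with_axis_and_synonyms(self, go_obo):
        vocab = load_vocabulary(go_obo, format="obo")
        assert len(vocab) == 1
        entry = vocab.entries["GO:0030318"]
        assert entry.preferred_name == "melanocyte differentiation"
        assert entry.axis == "GO_BP"
        assert len(entry.synonyms) == 2
        assert all(s.syn_type == "EXACT" for s in entry.synonyms)
        assert {s.surface for s in entry.synonyms} == {
            "melanocyte cell differentiation",
            "melanophore differentiation",
        }

    def test_header_only_file_yields_empty_vocabulary(self, tmp_path):
        path = tmp_path / "empty.obo"
        path.write_text("format-version: 1.2\nontology: empty\n", encoding="utf-8")
        assert len(load_vocabulary(path, format="obo")) == 0

    def test_namespace_filter_matches_independent_line_scan(self, tmp_path):
        stanzas = []
        namespaces = ["biological_process"] * 3 + ["molecular_function"] * 2
        for i, ns in enumerate(namespaces):
            stanzas.append(f"[Term]\nid: GO:{i:07d}\nname: term {i}\nnamespace: {ns}\n")
        text = "format-version: 1.2\n\n" + "\n".join(stanzas)
        path = tmp_path / "mixed.obo"
        path.write_text(text, encoding="utf-8")
        # independent oracle: count namespace lines directly
        expected = sum(1 for line in text.splitlines() if line == "namespace: biological_process")
        vocab = load_vocabulary(path, format="obo", axis_filter="GO_BP")
        assert len(vocab) == expected == 3
        assert all(e.axis == "GO_BP" for e in vocab)

    def test_obsolete_terms_are_skipped(self, tmp_path):
        text = GO_BP_STANZA + "\n[Term]\nid: GO:0000001\nname: gone\nnamespace: biological_process\nis_obsolete: true\n"
        path = tmp_path / "obs.obo"
        path.write_text(text, encoding="utf-8")
        vocab = load_vocabulary(path, format="obo")
        assert "GO:0000001" not in vocab.entries
        assert "GO:0030318" in vocab.entries

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            load_vocabulary(tmp_path / "nope.obo", format="obo")


class TestLoadTabular:
    def test_rows_group_into_terms(self, tmp_path):
        path = tmp_path / "ncit.tsv"
        path.write_text(
            "term_id\tpreferred_name\tsynonym\tsyn_type\n"
            "C38145\tChronic Allograft Nephropathy\tCAN\tABBREVIATION\n"
            "C38145\tChronic Allograft Nephropathy\tchronic rejection of renal transplant\tEXACT\n"
            "C9134\tPapillary Breast Cancer\t\t\n",
            encoding="utf-8",
        )
        vocab = load_vocabulary(path, format="tabular", axis="DISEASES")
        assert len(vocab) == 2
        assert len(vocab.entries["C38145"].synonyms) == 2
        assert vocab.entries["C9134"].synonyms == ()

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "term_id\tpreferred_name\tsynonym\tsyn_type\nC1\tname only two fields\n",
            encoding="utf-8",
        )
        with pytest.raises(ValueError, match=r":2:"):
            load_vocabulary(path, format="tabular", axis="DISEASES")


class TestBuildLexicon:
    def test_preferred_name_and_exact_synonyms_share_term_id(self, go_obo, permissive_policy):
        vocab = load_vocabulary(go_obo, format="obo")
        lex = build_lexicon(vocab, permissive_policy)
        assert len(lex.surface_map) == 3
        assert all(ids == {"GO:0030318"} for ids in lex.surface_map.values())

    def test_short_abbreviation_dropped_longer_synonyms_kept(self):
        vocab = Vocabulary(name="ncit", axis="DISEASES")
        vocab.add(
            TermEntry(
                term_id="C38145",
                preferred_name="Chronic Allograft Nephropathy",
                synonyms=(SynonymRecord("CAN", "ABBREVIATION"),),
                axis="DISEASES",
            )
        )
        lex = build_lexicon(vocab, RefinementPolicy(stopword_list=frozenset(), min_surface_length=4))
        assert "can" not in lex.surface_map
        assert "chronic allograft nephropathy" in lex.surface_map

    def test_stopword_surfaces_dropped_case_insensitively(self):
        vocab = Vocabulary(name="v", axis="DISEASES")
        vocab.add(TermEntry(term_id="C1", preferred_name="About", axis="DISEASES"))
        lex = build_lexicon(vocab, RefinementPolicy(stopword_list=frozenset({"about"})))
        assert lex.surface_map == {}

    def test_empty_vocabulary_yields_empty_lexicon(self, permissive_policy):
        lex = build_lexicon(Vocabulary(name="none", axis="DISEASES"), permissive_policy)
        assert lex.surface_map == {}
        assert vocab_stats(lex) == (0, 0)

    def test_no_retained_surface_violates_policy(self):
        policy = RefinementPolicy(stopword_list=default_stopwords(), min_surface_length=4)
        vocab = Vocabulary(name="v", axis="DISEASES")
        for i, name in enumerate(["the", "CAN", "melanoma", "with"]):
            vocab.add(TermEntry(term_id=f"C{i}", preferred_name=name, axis="DISEASES"))
        lex = build_lexicon(vocab, policy)
        for key in lex.surface_map:
            provs = lex.provenance[key]
            assert all(len(p.original_surface) >= 4 for p in provs)
            assert all(p.original_surface.lower() not in policy.stopword_list for p in provs)
        assert set(lex.surface_map) == {"melanoma"}

    def test_rebuild_is_idempotent(self, go_obo, permissive_policy):
        vocab = load_vocabulary(go_obo, format="obo")
        first = build_lexicon(vocab, permissive_policy)
        second = build_lexicon(vocab, permissive_policy)
        assert first.surface_map == second.surface_map

    def test_more_synonym_types_never_fewer_surfaces(self):
        vocab = Vocabulary(name="v", axis="DISEASES")
        vocab.add(
            TermEntry(
                term_id="C1",
                preferred_name="alpha syndrome",
                synonyms=(
                    SynonymRecord("beta syndrome", "EXACT"),
                    SynonymRecord("gamma syndrome", "NARROW"),
                    SynonymRecord("delta syndrome", "BROAD"),
                ),
                axis="DISEASES",
            )
        )
        sizes = []
        included: frozenset[str] = frozenset()
        for syn_type in ("EXACT", "NARROW", "BROAD"):
            included = included | {syn_type}
            policy = RefinementPolicy(stopword_list=frozenset(), included_syn_types=included)
            sizes.append(len(build_lexicon(vocab, policy).surface_map))
        assert sizes == sorted(sizes)

    def test_save_load_round_trip(self, go_obo, permissive_policy, tmp_path):
        vocab = load_vocabulary(go_obo, format="obo")
        lex = build_lexicon(vocab, permissive_policy)
        path = tmp_path / "lex.json"
        lex.save(path)
        loaded = Lexicon.load(path)
        assert loaded.surface_map == lex.surface_map
        assert loaded.provenance == lex.provenance
        assert loaded.axis == lex.axis


class TestVocabStats:
    def test_counts_surfaces_once_terms_per_id(self):
        vocab = Vocabulary(name="v", axis="DISEASES")
        vocab.add(TermEntry(term_id="C1", preferred_name="shared name", axis="DISEASES"))
        vocab.add(TermEntry(term_id="C2", preferred_name="shared name", axis="DISEASES"))
        lex = build_lexicon(vocab, RefinementPolicy(stopword_list=frozenset()))
        assert vocab_stats(lex) == (1, 2)

    def test_three_surface_single_term(self, go_obo, permissive_policy):
        lex = build_lexicon(load_vocabulary(go_obo, format="obo"), permissive_policy)
        assert vocab_stats(lex) == (3, 1)


@settings(derandomize=True, max_examples=50)
@given(st.text(min_size=0, max_size=60))
def test_surface_normalization_is_idempotent(surface):
    once = normalize_surface(surface)
    assert normalize_surface(once) == once


def test_policy_rejects_degenerate_min_length():
    with pytest.raises(ValueError):
        RefinementPolicy(stopword_list=frozenset(), min_surface_length=0)


def test_default_stopwords_are_lowercase_and_plentiful():
    words = default_stopwords()
    assert len(words) > 300
    assert all(w == w.lower() for w in words)
    assert "the" in words
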