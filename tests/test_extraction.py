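"""Matching, longest-match resolution, and co-occurrence assignment."""

import random

import pytest

from helpers import brute_force_longest, random_match_set
from ppio.dictionary import SurfaceEntry, TermDictionary, compile_dictionary
from ppio.extraction import (
    Match,
    PPIMention,
    Sentence,
    annotate_corpus,
    assign_annotations,
    find_matches,
    normalize_with_offsets,
    read_annotations_tsv,
    resolve_longest,
    write_annotations_tsv,
)
from ppio.evaluation import predicted_tuples
from ppio.model import Category
from ppio.synthetic import PlantSpec, gen_corpus

IT = Category.INTERACTION_TYPE
SCL = Category.SUBCELLULAR_LOCATION
BP = Category.BIOLOGICAL_PROCESS


def make_dict(surfaces_by_cat):
    d = TermDictionary()
    for i, (surface, cat) in enumerate(surfaces_by_cat):
        entry = d.entries.setdefault(surface, SurfaceEntry(surface=surface))
        tid = f"T:{i}"
        entry.term_ids.add(tid)
        entry.category_per_term[tid] = cat
    return d


class TestNormalizeWithOffsets:
    def test_offsets_point_back_into_original_text(self):
        text = "  The   NUCLEUS  matters "
        norm, offsets = normalize_with_offsets(text)
        assert norm == "the nucleus matters"
        start = norm.index("nucleus")
        span = (offsets[start], offsets[start + len("nucleus") - 1] + 1)
        assert text[span[0]:span[1]] == "NUCLEUS"

    def test_exhaustive_scan_oracle_on_random_strings(self):
        rng = random.Random(0)
        alphabet = "aB c\t\nDe"
        for _ in range(50):
            text = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 30)))
            norm, offsets = normalize_with_offsets(text)
            assert len(norm) == len(offsets)
            # Independent oracle: join-split lowering
            assert norm == " ".join(text.lower().split())
            for i, ch in enumerate(norm):
                if ch != " ":
                    assert text[offsets[i]].lower() == ch


class TestFindMatches:
    def test_no_dictionary_surface_in_sentence_gives_no_match(self):
        d = make_dict([("phosphorylation", IT)])
        assert find_matches(Sentence("s1", "nothing relevant here"), d) == []

    def test_offsets_of_two_matches(self):
        d = make_dict([("phosphorylation", IT), ("nucleus", SCL)])
        text = "A phosphorylates B via Phosphorylation in the nucleus"
        matches = find_matches(Sentence("s1", text), d)
        found = {(text[m.span[0]:m.span[1]].lower(), m.category) for m in matches}
        assert found == {("phosphorylation", IT), ("nucleus", SCL)}
        # independent substring-scan oracle for the count
        assert len(matches) == 2

    def test_word_boundary_blocks_embedded_match(self):
        d = make_dict([("binding", IT)])
        assert find_matches(Sentence("s1", "Unbinding occurred"), d) == []
        assert len(find_matches(Sentence("s1", "Unbinding occurred"), d, boundaries=False)) == 1

    def test_nested_and_overlapping_occurrences_all_reported(self):
        d = make_dict([("regulation", BP), ("regulation of transcription", BP)])
        text = "strong regulation of transcription was seen"
        matches = find_matches(Sentence("s1", text), d)
        assert len(matches) == 2

    def test_ambiguous_surface_emits_one_match_per_category(self):
        d = make_dict([("binding", IT), ("binding", BP)])
        matches = find_matches(Sentence("s1", "binding observed"), d)
        assert {m.category for m in matches} == {IT, BP}

    def test_whitespace_and_case_insensitive_matching(self):
        d = make_dict([("regulation of transcription", BP)])
        text = "Regulation   OF\ttranscription happens"
        matches = find_matches(Sentence("s1", text), d)
        assert len(matches) == 1
        s, e = matches[0].span
        assert text[s:e] == "Regulation   OF\ttranscription"

    def test_empty_dictionary_is_an_error(self):
        with pytest.raises(ValueError):
            find_matches(Sentence("s1", "text"), TermDictionary())

    def test_stemmed_mode_matches_plural_inflection(self):
        d = make_dict([("protein kinase", IT)])
        d.stemmed = True
        matches = find_matches(Sentence("s1", "two protein kinases were assayed"), d)
        assert len(matches) == 1


class TestResolveLongest:
    def test_nested_match_yields_only_the_longest(self):
        inner = Match((7, 17), "regulation", frozenset({"T:1"}), BP)
        outer = Match((7, 33), "regulation of transcription", frozenset({"T:2"}), BP)
        assert resolve_longest([inner, outer]) == [outer]

    def test_disjoint_matches_both_kept(self):
        a = Match((0, 5), "alpha", frozenset({"T:1"}), BP)
        b = Match((10, 15), "gamma", frozenset({"T:2"}), BP)
        assert resolve_longest([a, b]) == [a, b]

    def test_equal_length_overlap_keeps_leftmost(self):
        a = Match((0, 6), "abcdef", frozenset({"T:1"}), BP)
        b = Match((3, 9), "defghi", frozenset({"T:2"}), BP)
        assert resolve_longest([a, b]) == [a]

    def test_cross_category_overlaps_survive_per_category_mode(self):
        a = Match((0, 10), "long match", frozenset({"T:1"}), BP)
        b = Match((2, 8), "short", frozenset({"T:2"}), SCL)
        assert set(resolve_longest([a, b])) == {a, b}
        assert resolve_longest([a, b], per_category=False) == [a]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_enumeration(self, seed):
        matches = random_match_set(random.Random(seed))
        got = resolve_longest(matches)
        expected = brute_force_longest(matches)
        assert got == expected
        # no surviving proper sub-span of a surviving same-category match
        for m in got:
            for other in got:
                if m is other or m.category is not other.category:
                    continue
                assert not (
                    other.span[0] <= m.span[0] and m.span[1] <= other.span[1] and m.span != other.span
                )


class TestAssignAnnotations:
    def _sentence(self):
        return Sentence("s1", "PROTA binds PROTB during phosphorylation .")

    def test_one_match_lands_on_every_ppi(self):
        sent = self._sentence()
        ppis = [
            PPIMention("s1", "PROTA", "PROTB", (0, 5), (12, 17)),
            PPIMention("s1", "PROTA", "PROTC"),
        ]
        m = Match((25, 40), "phosphorylation", frozenset({"T:1"}), IT)
        out = assign_annotations(sent, ppis, [m])
        assert len(out) == 2
        for ap in out:
            assert ap.annotations[IT] == {("T:1", "phosphorylation")}

    def test_no_matches_gives_empty_category_sets(self):
        out = assign_annotations(self._sentence(), [PPIMention("s1", "A", "B")], [])
        assert all(not v for v in out[0].annotations.values())

    def test_match_overlapping_protein_span_is_excluded_for_that_ppi(self):
        sent = self._sentence()
        with_span = PPIMention("s1", "PROTA", "PROTB", (0, 5), (12, 17))
        without_span = PPIMention("s1", "PROTA", "PROTB")
        m = Match((0, 5), "prota", frozenset({"T:9"}), IT)
        out = assign_annotations(sent, [with_span, without_span], [m])
        assert out[0].annotations[IT] == set()
        assert out[1].annotations[IT] == {("T:9", "prota")}

    def test_sentence_id_mismatch_is_an_input_error(self):
        with pytest.raises(ValueError):
            assign_annotations(self._sentence(), [PPIMention("s2", "A", "B")], [])


class TestAnnotateCorpus:
    def test_empty_corpus_gives_empty_output(self, toy_dictionary):
        assert annotate_corpus([], [], toy_dictionary) == []

    def test_nested_match_corpus_keeps_longest_only(self):
        d = make_dict([("regulation", BP), ("regulation of transcription", BP)])
        sents = [Sentence("s1", "PROTA binds PROTB via regulation of transcription .")]
        ppis = [PPIMention("s1", "PROTA", "PROTB")]
        out = annotate_corpus(sents, ppis, d)
        surfaces = {s for _tid, s in out[0].annotations[BP]}
        assert surfaces == {"regulation of transcription"}

    def test_planted_corpus_recovers_exactly_the_gold(self, toy_ontology, toy_dictionary, small_corpus):
        sentences, ppis, gold = small_corpus
        out = annotate_corpus(sentences, ppis, toy_dictionary)
        assert predicted_tuples(out) == {(g.sentence_id, g.category, g.term_surface) for g in gold}

    def test_sentence_order_invariance_and_determinism(self, toy_dictionary, small_corpus):
        sentences, ppis, _ = small_corpus
        a = annotate_corpus(sentences, ppis, toy_dictionary)
        b = annotate_corpus(list(reversed(sentences)), ppis, toy_dictionary)
        key = lambda ap: (ap.ppi.sentence_id, ap.ppi.protein_a, ap.ppi.protein_b)
        assert sorted(a, key=key) == sorted(b, key=key)
        assert annotate_corpus(sentences, ppis, toy_dictionary) == a

    def test_total_assignment_count_identity(self, toy_dictionary, small_corpus):
        """Assigned tuples per PPI = kept matches not overlapping its proteins."""
        from ppio.extraction import find_matches, resolve_longest, _spans_overlap

        sentences, ppis, _ = small_corpus
        out = annotate_corpus(sentences, ppis, toy_dictionary)
        by_sid = {s.sentence_id: s for s in sentences}
        for ap in out:
            kept = resolve_longest(find_matches(by_sid[ap.ppi.sentence_id], toy_dictionary))
            spans = [s for s in (ap.ppi.span_a, ap.ppi.span_b) if s]
            eligible = [m for m in kept if not any(_spans_overlap(m.span, ps) for ps in spans)]
            n_assigned = sum(len(v) for v in ap.annotations.values())
            n_expected = sum(len(m.term_ids) for m in eligible)
            assert n_assigned == n_expected

    def test_annotation_tsv_round_trip(self, toy_dictionary, small_corpus, tmp_path):
        sentences, ppis, _ = small_corpus
        out = annotate_corpus(sentences, ppis, toy_dictionary)
        p = tmp_path / "ann.tsv"
        write_annotations_tsv(out, p, header_lines=["test run"])
        back = read_annotations_tsv(p)
        assert predicted_tuples(back) == predicted_tuples(out)
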