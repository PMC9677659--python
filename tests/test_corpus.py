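"""BIO corpus I/O, label schemes, splitting, encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from convner import (TaggedSentence, Vocab, build_label_scheme, decode_labels,
                     encode_sentence, read_bio_corpus, split_corpus,
                     write_bio_corpus)
from convner.corpus import SchemeViolation, cap_sentence_length


class TestLabelScheme:
    @pytest.mark.parametrize("types,n_labels", [
        (["disease", "position", "LabCheck", "check", "drug", "method"], 13),
        (["disease", "symptom", "age", "history", "check", "method", "drug"], 15),
        (["x"], 3),
    ])
    def test_label_inventory_size(self, types, n_labels):
        s = build_label_scheme(types)
        assert s.n_labels == n_labels == 2 * len(types) + 1
        assert s.labels[0] == "O"
        assert sorted(s.label_to_index.values()) == list(range(n_labels))

    def test_label_order_follows_type_order(self):
        s = build_label_scheme(["a", "b"])
        assert s.labels == ("O", "B-a", "I-a", "B-b", "I-b")

    def test_duplicate_and_empty_names_rejected(self):
        with pytest.raises(ValueError):
            build_label_scheme(["a", "a"])
        with pytest.raises(ValueError):
            build_label_scheme([])

    def test_bio_legality_predicate(self, scheme):
        assert scheme.is_legal_transition("B-disease", "I-disease")
        assert scheme.is_legal_transition("I-disease", "I-disease")
        assert not scheme.is_legal_transition("O", "I-disease")
        assert not scheme.is_legal_transition(None, "I-disease")
        assert not scheme.is_legal_transition("B-drug", "I-disease")
        # everything else is legal
        assert scheme.is_legal_transition("I-disease", "B-drug")
        assert scheme.is_legal_transition("O", "B-check")

    def test_validate_rejects_orphan_continuation(self, scheme):
        with pytest.raises(SchemeViolation):
            scheme.validate_labels(["O", "I-disease"])
        with pytest.raises(SchemeViolation):
            scheme.validate_labels(["B-drug", "I-disease"])
        scheme.validate_labels(["B-disease", "I-disease", "O"])


class TestReadWrite:
    def test_parse_single_sentence(self, tmp_path, scheme):
        p = tmp_path / "c.bio"
        p.write_text("头 B-position\n痛 I-position\n。 O\n", encoding="utf-8")
        sents = read_bio_corpus(p, scheme)
        assert len(sents) == 1
        assert sents[0].chars == ("头", "痛", "。")
        assert sents[0].labels == ("B-position", "I-position", "O")

    def test_empty_file(self, tmp_path, scheme):
        p = tmp_path / "e.bio"
        p.write_text("", encoding="utf-8")
        assert read_bio_corpus(p, scheme) == []

    def test_unknown_label_reports_line(self, tmp_path, scheme):
        p = tmp_path / "bad.bio"
        p.write_text("头 B-bogus\n", encoding="utf-8")
        with pytest.raises(SchemeViolation, match="1"):
            read_bio_corpus(p, scheme)

    def test_roundtrip(self, tmp_path, scheme, tiny_sentences):
        p = tmp_path / "rt.bio"
        write_bio_corpus(tiny_sentences, p)
        assert read_bio_corpus(p, scheme) == tiny_sentences
        # byte-identical on rewrite
        first = p.read_bytes()
        write_bio_corpus(read_bio_corpus(p, scheme), p)
        assert p.read_bytes() == first

    def test_empty_corpus_writes_empty_file(self, tmp_path):
        p = tmp_path / "empty.bio"
        write_bio_corpus([], p)
        assert p.read_text() == ""

    def test_separator_char_rejected(self, tmp_path):
        s = TaggedSentence((" ",), ("O",))
        with pytest.raises(ValueError, match="separator"):
            write_bio_corpus([s], tmp_path / "sep.bio")

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_roundtrip_property(self, data, tmp_path_factory, scheme):
        """read(write(corpus)) is the identity on arbitrary valid corpora."""
        alphabet = st.characters(codec="utf-8", categories=("Lo", "Lu", "Ll"),
                                 exclude_characters=" \n\r\t")
        sentences = []
        for _ in range(data.draw(st.integers(1, 4))):
            chars, labels = [], []
            for _ in range(data.draw(st.integers(1, 6))):
                t = data.draw(st.sampled_from(scheme.entity_types))
                if data.draw(st.booleans()):
                    chars.append(data.draw(alphabet))
                    labels.append("O")
                else:
                    n = data.draw(st.integers(1, 3))
                    chars.extend(data.draw(alphabet) for _ in range(n))
                    labels.extend([f"B-{t}"] + [f"I-{t}"] * (n - 1))
            sentences.append(TaggedSentence(tuple(chars), tuple(labels)))
        p = tmp_path_factory.mktemp("rt") / "c.bio"
        write_bio_corpus(sentences, p)
        assert read_bio_corpus(p, scheme) == sentences

    def test_generated_corpora_validate(self, small_corpus, scheme):
        for s in small_corpus:
            scheme.validate_labels(list(s.labels))


class TestSplit:
    def test_sizes_and_determinism(self, tiny_sentences):
        sents = tiny_sentences * 4  # 12 sentences
        a = split_corpus(sents, (0.6, 0.2, 0.2), seed=42)
        b = split_corpus(sents, (0.6, 0.2, 0.2), seed=42)
        assert (len(a.train), len(a.validation), len(a.test)) == (7, 2, 3)
        assert a.train == b.train and a.validation == b.validation and a.test == b.test

    def test_ratio_622_on_1000(self, scheme, lexicon):
        from convner import GeneratorConfig, generate_corpus
        corpus = generate_corpus(lexicon, GeneratorConfig(scheme=scheme,
                                                          n_sentences=1000, seed=1))
        sp = split_corpus(corpus, (0.6, 0.2, 0.2), seed=0)
        assert (len(sp.train), len(sp.validation), len(sp.test)) == (600, 200, 200)
        # disjoint and exhaustive
        ids = [id(s) for s in sp.train + sp.validation + sp.test]
        assert len(ids) == 1000 and len(set(ids)) == 1000

    def test_too_few_sentences(self, tiny_sentences):
        with pytest.raises(ValueError):
            split_corpus(tiny_sentences[:2], (0.6, 0.2, 0.2), seed=0)


class TestEncoding:
    def test_encode_decode_roundtrip(self, scheme, tiny_sentences):
        vocab = Vocab.from_sentences(tiny_sentences)
        for s in tiny_sentences:
            ci, li = encode_sentence(s, scheme, vocab)
            assert len(ci) == len(li) == len(s)
            assert decode_labels(li, scheme) == list(s.labels)

    def test_oov_maps_to_unknown(self, scheme, tiny_sentences):
        vocab = Vocab.from_sentences(tiny_sentences)
        s = TaggedSentence(("猫",), ("O",))
        ci, _ = encode_sentence(s, scheme, vocab)
        assert ci[0] == Vocab.UNK


class TestLengthCap:
    def test_long_sentence_split_at_last_o(self, scheme):
        chars = tuple("a" * 10)
        labels = ("O",) * 4 + ("B-disease", "I-disease") + ("O",) * 4
        out = cap_sentence_length([TaggedSentence(chars, labels)], max_len=5)
        assert all(len(s) <= 5 for s in out)
        assert sum(len(s) for s in out) == 10
        for s in out:
            scheme.validate_labels(list(s.labels))

    def test_short_sentences_untouched(self, tiny_sentences):
        assert cap_sentence_length(tiny_sentences, max_len=256) == tiny_sentences
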