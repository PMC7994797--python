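import numpy as np
import pytest

from petweak.nn import Tensor
from petweak.report_labeler import (
    MASKED,
    LabeledSentence,
    ReportModelConfig,
    TokenClassifierHead,
    TokenLabelSequence,
    WordpieceVocab,
    build_wordpiece_vocab,
    label_tokens,
    make_labeled_sentence,
    masked_token_loss,
    predict_mention_probability,
    rule_based_label,
    tokenize,
    train_report_model,
)
from petweak.report_labeler.model import SequenceEncoder
from petweak.synthetic import cohort_labeled_sentences, demo_ontology, generate_cohort
from petweak.tagging import Mention, parse_report, tag_report

# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------


class TestBuildVocab:
    def test_dominant_word_merges_fully(self):
        vocab = build_wordpiece_vocab(["lymph"] * 50, target_size=30)
        assert "lymph" in vocab
        assert tokenize("lymph", vocab).tokens == ["lymph"]

    def test_rare_word_splits_into_frequent_parts(self):
        corpus = ["sub total"] * 30 + ["carinal mass"] * 30 + ["subcarinal"]
        chars = len({c for text in corpus for c in text.lower() if not c.isspace()})
        vocab = build_wordpiece_vocab(corpus, target_size=chars + 1 + 8)
        tokens = tokenize("subcarinal", vocab).tokens
        assert len(tokens) >= 2

    def test_greedy_steps_match_exhaustive_search(self):
        # oracle: recount the token reduction of every candidate merge from
        # scratch and check each greedy step attains the maximum
        corpus = ["abc"] * 5 + ["abd"] * 3 + ["xyz"] * 2 + ["xyw", "pqr"]
        chars = sorted({c for w in corpus for c in w})
        n_merges = 2
        vocab = build_wordpiece_vocab(corpus, target_size=1 + len(chars) + n_merges)
        merged = [p for p in vocab.pieces if len(p) > 1 and p != "<unk>"]
        assert len(merged) == n_merges

        def total_tokens(pieces):
            v = WordpieceVocab(pieces=list(pieces))
            return sum(len(tokenize(w, v)) for w in corpus)

        state = ["<unk>"] + chars
        for step_piece in merged:
            # candidate merges: adjacent piece pairs in the current
            # decomposition of every corpus word
            candidates = {}
            v = WordpieceVocab(pieces=list(state))
            for word in corpus:
                toks = tokenize(word, v).tokens
                for left, right in zip(toks, toks[1:]):
                    piece = left + right
                    if piece not in state:
                        candidates[piece] = total_tokens(state) - total_tokens(
                            state + [piece]
                        )
            best = max(candidates.values())
            assert candidates[step_piece] == best
            state.append(step_piece)

    def test_target_too_small_raises(self):
        with pytest.raises(ValueError):
            build_wordpiece_vocab(["abcdefgh"], target_size=3)

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            build_wordpiece_vocab([], target_size=100)


class TestTokenize:
    def test_two_known_words(self):
        vocab = WordpieceVocab(pieces=sorted(set("lymphnodes")) + ["lymph", "nodes"])
        assert tokenize("lymph nodes", vocab).tokens == ["lymph", "nodes"]

    def test_empty_sentence(self):
        vocab = WordpieceVocab(pieces=["a"])
        seq = tokenize("", vocab)
        assert seq.tokens == [] and seq.char_spans == []

    def test_greedy_longest_match(self):
        vocab = WordpieceVocab(pieces=sorted(set("subcarinal")) + ["sub", "carinal"])
        assert tokenize("subcarinal", vocab).tokens == ["sub", "carinal"]

    def test_unknown_char_maps_to_unk(self):
        vocab = WordpieceVocab(pieces=["a", "b"])
        assert "<unk>" in tokenize("axb", vocab).tokens

    def test_roundtrip_on_generator_sentences(self):
        ontology = demo_ontology()
        cohort = generate_cohort(
            ontology, 10, {r: 0.4 for r in ontology.leaves()},
            volume_shape=(8, 8, 4), neutral_sentence_rate=0.3, seed=5,
        )
        corpus = [s for ex in cohort for _, s in ex.report.sentences]
        vocab = build_wordpiece_vocab(corpus, target_size=120)
        for sentence in corpus:
            seq = tokenize(sentence, vocab)
            assert seq.detokenize() == " ".join(sentence.lower().split())


# ---------------------------------------------------------------------------
# token labels
# ---------------------------------------------------------------------------


def word_vocab(sentence):
    """Vocab in which every word of `sentence` is a single piece."""
    words = sentence.lower().split()
    chars = sorted({c for w in words for c in w})
    return WordpieceVocab(pieces=chars + sorted(set(words), key=len))


class TestLabelTokens:
    def test_paper_worked_example(self):
        sentence = "Abnormal FDG uptake in the left lung"
        vocab = word_vocab(sentence)
        tokens = tokenize(sentence, vocab)
        assert tokens.tokens == ["abnormal", "fdg", "uptake", "in", "the", "left", "lung"]
        start = sentence.index("left lung")
        mention = Mention("left_lung", "findings", 0, (start, start + len("left lung")))
        labels = label_tokens(tokens, [mention], {0: 1})
        assert labels.labels == [MASKED, MASKED, MASKED, MASKED, MASKED, 1, 1]

    def test_no_mentions_all_masked(self):
        vocab = word_vocab("the liver is clear")
        labels = label_tokens(tokenize("the liver is clear", vocab), [], {})
        assert all(lab is MASKED for lab in labels.labels)

    def test_two_mentions_two_states(self):
        sentence = "left lung clear but liver abnormal"
        vocab = word_vocab(sentence)
        tokens = tokenize(sentence, vocab)
        m1 = Mention("left_lung", "findings", 0, (0, 9))
        liver_start = sentence.index("liver")
        m2 = Mention("liver", "findings", 0, (liver_start, liver_start + 5))
        labels = label_tokens(tokens, [m1, m2], {0: 0, 1: 1})
        assert labels.labels == [0, 0, MASKED, MASKED, 1, MASKED]

    def test_conflicting_overlap_raises(self):
        sentence = "left lung"
        vocab = word_vocab(sentence)
        tokens = tokenize(sentence, vocab)
        m1 = Mention("left_lung", "findings", 0, (0, 9))
        m2 = Mention("lungs", "findings", 0, (5, 9))
        with pytest.raises(ValueError, match="conflicting"):
            label_tokens(tokens, [m1, m2], {0: 1, 1: 0})


# ---------------------------------------------------------------------------
# masked loss
# ---------------------------------------------------------------------------


class TestMaskedLoss:
    def test_masked_positions_do_not_affect_loss(self, rng):
        labels = TokenLabelSequence(labels=[MASKED, 1, MASKED, 0, MASKED])
        base = rng.uniform(0.05, 0.95, size=5)
        loss1 = masked_token_loss(Tensor(base), labels).item()
        perturbed = base.copy()
        perturbed[[0, 2, 4]] = rng.uniform(0.05, 0.95, size=3)
        loss2 = masked_token_loss(Tensor(perturbed), labels).item()
        assert loss1 == pytest.approx(loss2, abs=1e-15)

    def test_normalized_by_sentence_length(self):
        labels = TokenLabelSequence(labels=[1, MASKED])
        p = 0.5
        loss = masked_token_loss(Tensor(np.array([p, p])), labels).item()
        assert loss == pytest.approx(-np.log(p) / 2)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_report_model():
    ontology = demo_ontology()
    cohort = generate_cohort(
        ontology, 60, {r: 0.4 for r in ontology.leaves()},
        volume_shape=(8, 8, 4), neutral_sentence_rate=0.5, seed=0,
    )
    corpus = [s for ex in cohort for _, s in ex.report.sentences]
    vocab = build_wordpiece_vocab(corpus, target_size=150)
    items = cohort_labeled_sentences(cohort, vocab)
    train, val = items[:200], items[200:260]
    config = ReportModelConfig(epochs=12, lr=3e-3, seed=0)
    result = train_report_model(train, val, vocab, config)
    return result, vocab, train, val


class TestTrainReportModel:
    def test_validation_auroc_high(self, trained_report_model):
        result, *_ = trained_report_model
        assert max(h["val_auroc"] for h in result.history) > 0.95

    def test_loss_decreases_to_best_epoch(self, trained_report_model):
        result, *_ = trained_report_model
        assert result.history[0]["loss"] > result.history[result.best_epoch]["loss"]

    def test_single_class_labels_raise(self, trained_report_model):
        _, vocab, train, val = trained_report_model
        positives = [
            item for item in train if any(lab == 1 for lab in item.labels.labels)
        ][:5]
        with pytest.raises(ValueError, match="single class"):
            train_report_model(positives, val, vocab, ReportModelConfig(epochs=1))

    def test_empty_validation_raises(self, trained_report_model):
        _, vocab, train, _ = trained_report_model
        with pytest.raises(ValueError, match="validation"):
            train_report_model(train, [], vocab, ReportModelConfig(epochs=1))

    def test_reproducible_for_fixed_seed(self, trained_report_model):
        _, vocab, train, val = trained_report_model
        config = ReportModelConfig(epochs=2, lr=3e-3, seed=123)
        r1 = train_report_model(train[:40], val[:20], vocab, config)
        r2 = train_report_model(train[:40], val[:20], vocab, config)
        assert r1.history == r2.history


# ---------------------------------------------------------------------------
# mention probability reduction
# ---------------------------------------------------------------------------


class _StubEncoder(SequenceEncoder):
    """Returns fixed hidden vectors so head outputs are known exactly."""

    def __init__(self, values):
        self.hidden_size = 1
        self._values = np.asarray(values, dtype=float)

    def __call__(self, token_ids):
        return Tensor(self._values[: len(token_ids)].reshape(-1, 1))


def _identity_head():
    head = TokenClassifierHead(hidden_size=1, seed=0)
    head.linear.weight.data[:] = 1.0
    head.linear.bias.data[:] = 0.0
    return head


def _logit(p):
    return float(np.log(p / (1 - p)))


class TestPredictMentionProbability:
    def _run(self, sentence, char_span, token_probs):
        vocab = word_vocab(sentence)
        encoder = _StubEncoder([_logit(p) for p in token_probs])
        mention = Mention("r", "findings", 0, char_span)
        ontology = None  # unused
        scored = predict_mention_probability(
            sentence, [mention], encoder, _identity_head(), vocab
        )
        return scored[0]

    def test_mean_of_two_tokens(self):
        m = self._run("left lung", (0, 9), [0.8, 0.6])
        assert m.probability == pytest.approx(0.7, abs=1e-9)
        assert m.token_span == (0, 2)

    def test_single_token_mention(self):
        m = self._run("liver clear", (0, 5), [0.8, 0.1])
        assert m.probability == pytest.approx(0.8, abs=1e-9)

    def test_three_token_mean(self):
        m = self._run("left lung base", (0, 14), [0.9, 0.3, 0.3])
        assert m.probability == pytest.approx(0.5, abs=1e-9)

    def test_zero_token_span_raises(self):
        vocab = word_vocab("liver clear")
        mention = Mention("r", "findings", 0, (100, 105))
        with pytest.raises(ValueError, match="zero tokens"):
            predict_mention_probability(
                "liver clear", [mention], _StubEncoder([0.0, 0.0]), _identity_head(), vocab
            )


# ---------------------------------------------------------------------------
# rule-based baseline
# ---------------------------------------------------------------------------


class TestRuleBasedLabel:
    def test_physiologic_is_neutral(self, ontology):
        doc = parse_report("Findings: intense physiologic uptake in the liver.")
        mentions = tag_report(doc, ontology)
        states = dict(rule_based_label(doc.sentences[0][1], mentions, ontology))
        assert states["liver"] == 0

    def test_abnormal_assigns_ancestors(self, ontology):
        doc = parse_report("Findings: Abnormal FDG uptake in the left lung.")
        mentions = tag_report(doc, ontology)
        states = dict(rule_based_label(doc.sentences[0][1], mentions, ontology))
        assert states["left_lung"] == 1
        assert states["lungs"] == 1
        assert states["chest"] == 1
        assert states["body"] == 1

    def test_explicit_negative(self, ontology):
        sentence = (
            "no pathologically enlarged or hypermetabolic axillary lymph nodes on the current study"
        )
        doc = parse_report(f"Findings: {sentence}.")
        mentions = tag_report(doc, ontology)
        states = dict(rule_based_label(doc.sentences[0][1], mentions, ontology))
        assert all(v == 0 for v in states.values())

    def test_no_mentions_empty(self, ontology):
        assert rule_based_label("Nothing here.", [], ontology) == []

    def test_keyword_needs_word_boundary(self, ontology):
        # "nodes"/"nodule" must not trigger the "no"/"not" keywords
        doc = parse_report("Findings: hypermetabolic nodule in the liver.")
        mentions = tag_report(doc, ontology)
        states = dict(rule_based_label(doc.sentences[0][1], mentions, ontology))
        assert states["liver"] == 1


class TestTrainedBeatsRuleBaseline:
    def test_mention_f1_direction(self, trained_report_model, ontology):
        # hard neutral templates carry no negative keyword: the rule baseline
        # false-positives on them while the trained labeler uses context
        result, vocab, *_ = trained_report_model
        cohort = generate_cohort(
            ontology, 40, {r: 0.4 for r in ontology.leaves()},
            volume_shape=(8, 8, 4), neutral_sentence_rate=0.6, seed=99,
        )
        truth, rule_pred, model_pred = [], [], []
        for exam in cohort:
            for planted in exam.planted:
                mention = Mention(
                    planted.region_id, planted.section, 0, planted.char_span
                )
                truth.append(planted.state)
                states = dict(
                    rule_based_label(planted.sentence, [mention], ontology)
                )
                rule_pred.append(states[planted.region_id])
                scored = predict_mention_probability(
                    planted.sentence, [mention], result.encoder, result.head, vocab
                )
                model_pred.append(int(scored[0].probability >= 0.5))

        def f1(y, p):
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
            return 2 * tp / (2 * tp + fp + fn)

        assert f1(truth, model_pred) > f1(truth, rule_pred)
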