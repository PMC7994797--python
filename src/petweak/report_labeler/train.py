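"""Training of the token classifier and mention-level probability prediction.

The objective is masked cross-entropy: each sentence contributes the mean
over its n tokens of 1[y_i != MASKED] * CE(y_i, p_i), so predictions on
masked tokens never influence the loss. Optimization follows the Adam
schedule with the learning rate annealed by half on a fixed epoch period,
a per-epoch sample of mentions drawn with replacement, and early stopping
on validation token AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from ..nn import Adam, Tensor, halved_lr, no_grad
from ..tagging import Mention
from .labels import MASKED, TokenLabelSequence, char_span_to_token_span, label_tokens
from .model import SequenceEncoder, TinySelfAttentionEncoder, TokenClassifierHead
from .vocab import TokenSequence, WordpieceVocab, tokenize

__all__ = [
    "LabeledSentence",
    "ReportModelConfig",
    "TrainedReportModel",
    "make_labeled_sentence",
    "masked_token_loss",
    "train_report_model",
    "predict_mention_probability",
]

_EPS = 1e-7


@dataclass
class LabeledSentence:
    sentence: str
    tokens: TokenSequence
    labels: TokenLabelSequence
    n_mentions: int = 1

    def __post_init__(self):
        if len(self.tokens) != len(self.labels):
            raise ValueError("token and label sequences differ in length")


def make_labeled_sentence(
    sentence: str,
    mentions: Sequence[Mention],
    states: Sequence[int],
    vocab: WordpieceVocab,
) -> LabeledSentence:
    tokens = tokenize(sentence, vocab)
    labels = label_tokens(tokens, mentions, dict(enumerate(states)))
    return LabeledSentence(
        sentence=sentence, tokens=tokens, labels=labels, n_mentions=max(len(mentions), 1)
    )


@dataclass
class ReportModelConfig:
    epochs: int = 85
    mentions_per_epoch: int = 100
    batch_size: int = 16
    lr: float = 1e-4
    anneal_every: int = 20
    hidden: int = 32
    ffn: int = 64
    n_blocks: int = 1
    max_len: int = 128
    seed: int = 0


@dataclass
class TrainedReportModel:
    encoder: SequenceEncoder
    head: TokenClassifierHead
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def __iter__(self):  # allow  encoder, head = train_report_model(...)
        return iter((self.encoder, self.head))


def masked_token_loss(probs: Tensor, labels: TokenLabelSequence) -> Tensor:
    """Eq-style masked cross-entropy, normalized by sentence length n."""
    n = len(labels)
    if n != probs.shape[0]:
        raise ValueError("probability/label length mismatch")
    mask = np.array([0.0 if lab is MASKED else 1.0 for lab in labels.labels])
    y = np.array([0.0 if lab is MASKED else float(lab) for lab in labels.labels])
    p = probs.clip(_EPS, 1.0 - _EPS)
    ce = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    return (ce * Tensor(mask)).sum() * (1.0 / n)


def _labeled_arrays(items: Sequence[LabeledSentence]) -> tuple[np.ndarray, np.ndarray]:
    ys, sentence_ids = [], []
    for idx, item in enumerate(items):
        for lab in item.labels.labels:
            if lab is not MASKED:
                ys.append(lab)
                sentence_ids.append(idx)
    return np.array(ys), np.array(sentence_ids)


def _validation_auroc(
    items: Sequence[LabeledSentence],
    encoder: SequenceEncoder,
    head: TokenClassifierHead,
    vocab: WordpieceVocab,
) -> float:
    ys, ps = [], []
    with no_grad():
        for item in items:
            probs = head(encoder(item.tokens.ids(vocab))).data
            for lab, p in zip(item.labels.labels, probs):
                if lab is not MASKED:
                    ys.append(lab)
                    ps.append(p)
    return float(roc_auc_score(ys, ps))


def train_report_model(
    train: Sequence[LabeledSentence],
    val: Sequence[LabeledSentence],
    vocab: WordpieceVocab,
    config: Optional[ReportModelConfig] = None,
) -> TrainedReportModel:
    """Train encoder + head with masked cross-entropy; fully seeded.

    Returns the parameters from the epoch with the highest validation token
    AUROC.
    """
    config = config or ReportModelConfig()
    if not val:
        raise ValueError("empty validation set")
    train_y, _ = _labeled_arrays(train)
    if train_y.size == 0:
        raise ValueError("no labeled (non-masked) tokens in the training set")
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain a single class")
    val_y, _ = _labeled_arrays(val)
    if val_y.size == 0 or len(np.unique(val_y)) < 2:
        raise ValueError("validation set must contain labeled tokens of both classes")

    rng = np.random.default_rng(config.seed)
    encoder = TinySelfAttentionEncoder(
        vocab_size=len(vocab),
        hidden=config.hidden,
        ffn=config.ffn,
        n_blocks=config.n_blocks,
        max_len=config.max_len,
        seed=config.seed,
    )
    head = TokenClassifierHead(hidden_size=config.hidden, seed=config.seed + 1)
    params = encoder.parameters() + head.parameters()
    optimizer = Adam(params, lr=config.lr)

    # sampling unit: one mention occurrence, mapped to its sentence
    units = np.array(
        [idx for idx, item in enumerate(train) for _ in range(item.n_mentions)]
    )
    token_ids = [item.tokens.ids(vocab) for item in train]

    history: list[dict] = []
    best = (-np.inf, -1, None)
    for epoch in range(config.epochs):
        optimizer.lr = halved_lr(config.lr, epoch, config.anneal_every)
        sampled = rng.choice(units, size=config.mentions_per_epoch, replace=True)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(sampled), config.batch_size):
            batch = sampled[start : start + config.batch_size]
            optimizer.zero_grad()
            total = None
            for idx in batch:
                probs = head(encoder(token_ids[idx]))
                loss = masked_token_loss(probs, train[idx].labels)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(batch))
            total.backward()
            optimizer.step()
            epoch_loss += total.item()
            n_batches += 1
        val_auroc = _validation_auroc(val, encoder, head, vocab)
        history.append(
            {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "val_auroc": val_auroc}
        )
        if val_auroc > best[0]:
            best = (val_auroc, epoch, [p.data.copy() for p in params])

    if best[2] is not None:
        for p, data in zip(params, best[2]):
            p.data = data
    return TrainedReportModel(encoder=encoder, head=head, history=history, best_epoch=best[1])


def predict_mention_probability(
    sentence: str,
    mentions: Sequence[Mention],
    encoder: SequenceEncoder,
    head: TokenClassifierHead,
    vocab: WordpieceVocab,
) -> list[Mention]:
    """Score each mention as the mean token probability over its span."""
    tokens = tokenize(sentence, vocab)
    with no_grad():
        probs = head(encoder(tokens.ids(vocab))).data
    scored = []
    for mention in mentions:
        t_start, t_end = char_span_to_token_span(tokens, mention.char_span)
        p = float(np.mean(probs[t_start:t_end]))
        scored.append(replace(mention, token_span=(t_start, t_end), probability=p))
    return scored
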