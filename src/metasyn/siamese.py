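"""Siamese recurrent synonymy classifier.

Two weight-sharing LSTM encoders read the token sequences of a pair of
terms (padded or truncated to 30 positions) and the pair is scored with
the Manhattan-distance similarity ``exp(-||h_A - h_B||_1)`` in [0, 1],
where ``h`` is the final hidden state (50 units by default).  Training
minimizes the mean squared error between the similarity score and the 0/1
synonymy label with adaptive-moment gradient descent.

The network is implemented directly in numpy, including backpropagation
through time, so runs are exactly reproducible from the configured seed.
Embeddings are either loaded from a word2vec-text file (e.g. biomedical
pre-trained vectors) or randomly initialized and trained; the padding
embedding is fixed at zero and masked timesteps leave the recurrent state
unchanged, so trailing padding never alters the encoding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from metasyn.metrics import confusion_at, prf1
from metasyn.pairgen import SplitDataset
from metasyn.vocab import normalize_embed

__all__ = [
    "NetConfig",
    "Vocabulary",
    "EncodedPair",
    "SiameseLSTM",
    "encode_pair",
    "manhattan_similarity",
    "train_model",
    "predict_pairs",
    "load_word2vec_text",
]

PAD = 0
UNK = 1


@dataclass(frozen=True)
class NetConfig:
    """Network and training hyperparameters.

    ``seed`` is mandatory; all weight initialization and batch shuffling
    derive from it.  ``embedding_path`` points to an optional word2vec
    text file — when given, its dimensionality overrides
    ``embedding_dim``.  ``early_stopping_patience`` stops training when
    the validation loss has not improved for that many epochs (the best
    weights are restored); ``None`` trains for the full epoch budget.
    """

    seed: int
    embedding_dim: int = 200
    hidden_units: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    epochs: int = 100
    max_len: int = 30
    bidirectional: bool = False
    embedding_path: str | None = None
    early_stopping_patience: int | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "hidden_units", "batch_size", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


class Vocabulary:
    """Token-to-index mapping with reserved padding and unknown indices."""

    def __init__(self, tokens: Sequence[str]):
        self._index = {"<pad>": PAD, "<unk>": UNK}
        for tok in tokens:
            if tok not in self._index:
                self._index[tok] = len(self._index)

    @classmethod
    def from_texts(cls, texts: Iterable[str]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for text in texts:
            for tok in normalize_embed(text):
                seen.setdefault(tok, None)
        return cls(list(seen))

    def index_of(self, token: str) -> int:
        return self._index.get(token, UNK)

    @property
    def tokens(self) -> list[str]:
        return list(self._index)

    def __len__(self) -> int:
        return len(self._index)


EncodedPair = tuple[np.ndarray, np.ndarray]


def encode(text: str, vocab: Vocabulary, max_len: int = 30) -> np.ndarray:
    """Token-index sequence of exactly ``max_len`` positions.

    Truncation keeps the leading tokens; shorter sequences are padded at
    the end.  Out-of-vocabulary tokens map to the unknown index.  A
    punctuation-only string yields an all-padding sequence.
    """
    ids = [vocab.index_of(t) for t in normalize_embed(text)][:max_len]
    return np.array(ids + [PAD] * (max_len - len(ids)), dtype=np.int64)


def encode_pair(
    str_a: str, str_b: str, vocab: Vocabulary, max_len: int = 30
) -> EncodedPair:
    """Encode both members of a pair (deterministic)."""
    return encode(str_a, vocab, max_len), encode(str_b, vocab, max_len)


def manhattan_similarity(h_a: np.ndarray, h_b: np.ndarray) -> np.ndarray:
    """exp(-L1 distance): 1 iff the encodings coincide, always > 0."""
    return np.exp(-np.abs(np.asarray(h_a) - np.asarray(h_b)).sum(axis=-1))


def load_word2vec_text(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a word2vec text-format embedding file (header ``n dim``)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        words: list[str] = []
        vecs = np.empty((n, dim), dtype=np.float64)
        for i in range(n):
            fields = fh.readline().rstrip("\n").split(" ")
            words.append(fields[0])
            vecs[i] = [float(x) for x in fields[1 : dim + 1]]
    return words, vecs


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SiameseLSTM:
    """Twin LSTM encoders with shared weights and exp(-L1) output."""

    def __init__(self, vocab: Vocabulary, cfg: NetConfig):
        self.vocab = vocab
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 91]))
        dim = cfg.embedding_dim
        pretrained: dict[str, np.ndarray] = {}
        if cfg.embedding_path is not None:
            words, vecs = load_word2vec_text(cfg.embedding_path)
            pretrained = dict(zip(words, vecs))
            dim = vecs.shape[1]
        self.dim = dim
        H = cfg.hidden_units
        V = len(vocab)
        E = rng.normal(0.0, 0.1, size=(V, dim))
        for i, tok in enumerate(vocab.tokens):
            if tok in pretrained:
                E[i] = pretrained[tok]
        E[PAD] = 0.0
        self.params: dict[str, np.ndarray] = {"E": E}
        self._dirs = ["fwd", "bwd"] if cfg.bidirectional else ["fwd"]
        for d in self._dirs:
            sx = np.sqrt(6.0 / (dim + 4 * H))
            sh = np.sqrt(6.0 / (H + 4 * H))
            self.params[f"Wx_{d}"] = rng.uniform(-sx, sx, size=(dim, 4 * H))
            self.params[f"Wh_{d}"] = rng.uniform(-sh, sh, size=(H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b_{d}"] = b
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------

    def _run_direction(self, X: np.ndarray, d: str, need_cache: bool):
        H = self.cfg.hidden_units
        E = self.params["E"]
        Wx, Wh, b = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"]
        B, T = X.shape
        mask = X != PAD
        t_eff = int(mask.any(axis=0).nonzero()[0].max()) + 1 if mask.any() else 0
        order = range(t_eff - 1, -1, -1) if d == "bwd" else range(t_eff)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in order:
            x = E[X[:, t]]
            m = mask[:, t][:, None].astype(float)
            z = x @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            if need_cache:
                cache.append((t, m, h, c, i, f, g, o, c_new))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
        return h, cache

    def encode_batch(self, X: np.ndarray, need_cache: bool = False):
        """Final hidden state for a batch of index sequences."""
        states, caches = [], []
        for d in self._dirs:
            h, cache = self._run_direction(X, d, need_cache)
            states.append(h)
            caches.append((d, cache))
        return np.concatenate(states, axis=1), caches

    def _backward_direction(
        self,
        X: np.ndarray,
        dh_final: np.ndarray,
        cache,
        d: str,
        grads: dict[str, np.ndarray],
    ) -> None:
        H = self.cfg.hidden_units
        E = self.params["E"]
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        dh = dh_final
        dc = np.zeros_like(dh)
        for (t, m, h_prev, c_prev, i, f, g, o, c_new) in reversed(cache):
            dh_new = dh * m
            dh_skip = dh * (1.0 - m)
            dc_skip = dc * (1.0 - m)
            tanh_c = np.tanh(c_new)
            dc_new = dc * m + dh_new * o * (1.0 - tanh_c**2)
            do = dh_new * tanh_c
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            x = E[X[:, t]]
            grads[f"Wx_{d}"] += x.T @ dz
            grads[f"Wh_{d}"] += h_prev.T @ dz
            grads[f"b_{d}"] += dz.sum(axis=0)
            np.add.at(grads["E"], X[:, t], dz @ Wx.T)
            dh = dz @ Wh.T + dh_skip
            dc = dc_new * f + dc_skip

    def _train_batch(self, XA: np.ndarray, XB: np.ndarray, y: np.ndarray):
        """One gradient step; returns (loss, scores before the update)."""
        hA, cachesA = self.encode_batch(XA, need_cache=True)
        hB, cachesB = self.encode_batch(XB, need_cache=True)
        diff = hA - hB
        scores = np.exp(-np.abs(diff).sum(axis=1))
        err = scores - y
        loss = float(np.mean(err**2))
        B = len(y)
        dscore = 2.0 * err / B
        dhA = (dscore * -scores)[:, None] * np.sign(diff)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        H = self.cfg.hidden_units
        for j, (d, cache) in enumerate(cachesA):
            self._backward_direction(XA, dhA[:, j * H : (j + 1) * H], cache, d, grads)
        for j, (d, cache) in enumerate(cachesB):
            self._backward_direction(XB, -dhA[:, j * H : (j + 1) * H], cache, d, grads)
        grads["E"][PAD] = 0.0
        self._adam_step(grads)
        return loss, scores

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        lr = self.cfg.learning_rate
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- inference ---------------------------------------------------------

    def score_encoded(self, XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
        """Similarity scores for pre-encoded pairs, batched."""
        out = np.empty(len(XA))
        bs = self.cfg.batch_size
        for start in range(0, len(XA), bs):
            sl = slice(start, start + bs)
            hA, _ = self.encode_batch(XA[sl])
            hB, _ = self.encode_batch(XB[sl])
            out[sl] = manhattan_similarity(hA, hB)
        return out

    def score_texts(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        if len(pairs) == 0:
            return np.empty(0)
        XA = np.stack([encode(a, self.vocab, self.cfg.max_len) for a, _ in pairs])
        XB = np.stack([encode(b, self.vocab, self.cfg.max_len) for _, b in pairs])
        return self.score_encoded(XA, XB)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.cfg)
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))
        (directory / "vocab.txt").write_text("\n".join(self.vocab.tokens) + "\n")
        np.savez(directory / "weights.npz", **self.params)

    @classmethod
    def load(cls, directory: str | Path) -> "SiameseLSTM":
        directory = Path(directory)
        cfg = NetConfig(**json.loads((directory / "config.json").read_text()))
        tokens = (directory / "vocab.txt").read_text().splitlines()
        vocab = Vocabulary(tokens[2:])  # first two lines are <pad>/<unk>
        model = cls(vocab, cfg)
        weights = np.load(directory / "weights.npz")
        for k in model.params:
            model.params[k] = weights[k]
        return model


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def _encode_side(
    pairs, texts_by_aui: Mapping[str, str], vocab: Vocabulary, max_len: int
):
    XA = np.stack([encode(texts_by_aui[p.aui_a], vocab, max_len) for p in pairs])
    XB = np.stack([encode(texts_by_aui[p.aui_b], vocab, max_len) for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return XA, XB, y


def train_model(
    dataset: SplitDataset,
    texts_by_aui: Mapping[str, str],
    cfg: NetConfig,
) -> tuple[SiameseLSTM, list[dict]]:
    """Train on the learning side of a split dataset.

    The vocabulary is built from the learning-side term strings.  Each
    history entry records the epoch's mean training loss, validation loss
    and accuracy/precision/recall/F1 on both sides at the configured
    threshold (training metrics use the pre-update batch predictions, the
    conventional running estimate).  With ``epochs=0`` the untrained model
    is returned with an empty history.
    """
    train_pairs, val_pairs = dataset.training, dataset.validation
    if not train_pairs:
        raise ValueError("training set is empty")
    labels = {p.label for p in train_pairs}
    if labels != {0, 1}:
        raise ValueError(f"training set needs both classes, found labels {sorted(labels)}")

    corpus = [texts_by_aui[p.aui_a] for p in train_pairs + val_pairs]
    corpus += [texts_by_aui[p.aui_b] for p in train_pairs + val_pairs]
    vocab = Vocabulary.from_texts(corpus)
    model = SiameseLSTM(vocab, cfg)
    if cfg.epochs == 0:
        return model, []

    XA, XB, y = _encode_side(train_pairs, texts_by_aui, vocab, cfg.max_len)
    has_val = len(val_pairs) > 0
    if has_val:
        VA, VB, vy = _encode_side(val_pairs, texts_by_aui, vocab, cfg.max_len)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    history: list[dict] = []
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(len(y))
        losses = []
        train_scores = np.empty(len(y))
        for start in range(0, len(y), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            loss, scores = model._train_batch(XA[idx], XB[idx], y[idx])
            losses.append(loss * len(idx))
            train_scores[idx] = scores
        entry = {"epoch": epoch, "loss": float(np.sum(losses) / len(y))}
        tr = prf1(confusion_at(train_scores, y.astype(int), cfg.threshold))
        entry.update(
            {"acc": tr.accuracy, "precision": tr.precision, "recall": tr.recall, "f1": tr.f1}
        )
        if has_val:
            val_scores = model.score_encoded(VA, VB)
            entry["val_loss"] = float(np.mean((val_scores - vy) ** 2))
            vr = prf1(confusion_at(val_scores, vy.astype(int), cfg.threshold))
            entry.update(
                {
                    "val_acc": vr.accuracy,
                    "val_precision": vr.precision,
                    "val_recall": vr.recall,
                    "val_f1": vr.f1,
                }
            )
        history.append(entry)
        if cfg.early_stopping_patience is not None and has_val:
            if entry["val_loss"] < best_val - 1e-6:
                best_val = entry["val_loss"]
                best_params = {k: v.copy() for k, v in model.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stopping_patience:
                    break
    if best_params is not None:
        model.params.update(best_params)
    return model, history


def predict_pairs(
    model: SiameseLSTM, pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Similarity scores for (strA, strB) pairs, order-preserving.

    Scores are symmetric up to floating-point tolerance because the twin
    encoders share all weights.
    """
    return model.score_texts(pairs)
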