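"""Predictor backends behind a single PredictorScores contract.

The pipeline never talks to external binaries directly: any backend that
returns PredictorScores per (peptide, allele) plugs in.  Shipped backends:

* ``MockPredictor`` — deterministic hash-seeded scores, optionally overlaid
  with a fixture table; the default for all tests.
* ``SurrogateModel`` — a small presentation classifier (one-hot peptide +
  learned per-allele embedding, two dense layers) trained at desk scale on
  synthetic labels.  It demonstrates the architecture; it makes no claim of
  real pMHC accuracy.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .models import AMINO_ACIDS, PredictorScores

MAX_PEP_LEN = 11
EMBED_DIM = 74
HIDDEN1 = 256
HIDDEN2 = 74


def _hash_unit(*parts: object) -> float:
    """Deterministic float in [0, 1) from a blake2b digest of the parts."""
    h = hashlib.blake2b("|".join(str(p) for p in parts).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") / 2**64


def mock_predict(peptide: str, allele: str, seed: int = 0) -> PredictorScores:
    """Pure hash-seeded scores: log-uniform affinity in [1, 50000] nM,
    cleavage in [0, 1], TAP in [-3, 3], and a presentation call."""
    u_aff = _hash_unit("aff", peptide, allele, seed)
    u_cle = _hash_unit("cle", peptide, allele, seed)
    u_tap = _hash_unit("tap", peptide, allele, seed)
    u_dl = _hash_unit("dl", peptide, allele, seed)
    affinity = float(10 ** (u_aff * (np.log10(50000.0) - 0.0)))  # 1..50000 nM
    identified = u_dl > 0.5
    rank = int(1 + u_dl * 49) if identified else None
    return PredictorScores(
        affinity_nM=affinity,
        cleavage=u_cle,
        tap=u_tap * 6.0 - 3.0,
        dl_identified=identified,
        dl_rank=rank,
    ).validate()


@dataclass
class MockPredictor:
    """Hash-seeded backend with fixture-table injection.

    Entries in ``fixture`` win over generated scores; everything else is a
    pure function of (peptide, allele, seed).
    """

    seed: int = 0
    fixture: dict[tuple[str, str], PredictorScores] = field(default_factory=dict)

    def predict(self, peptide: str, allele: str) -> PredictorScores:
        key = (peptide, allele)
        if key in self.fixture:
            return self.fixture[key]
        return mock_predict(peptide, allele, self.seed)

    def predict_many(self, pairs):
        return {pair: self.predict(*pair) for pair in pairs}


@dataclass
class PoorBinderFallback:
    """Backend where non-fixture pairs are guaranteed weak binders (> 500 nM).

    Used by the synthetic generator so that only designated peptides survive
    the affinity filter.
    """

    seed: int = 0
    fixture: dict[tuple[str, str], PredictorScores] = field(default_factory=dict)

    def predict(self, peptide: str, allele: str) -> PredictorScores:
        key = (peptide, allele)
        if key in self.fixture:
            return self.fixture[key]
        u = _hash_unit("weak", peptide, allele, self.seed)
        return PredictorScores(
            affinity_nM=5000.0 + 25000.0 * u,
            cleavage=_hash_unit("wcle", peptide, allele, self.seed),
            tap=_hash_unit("wtap", peptide, allele, self.seed) * 6.0 - 3.0,
            dl_identified=False,
            dl_rank=None,
        )

    def predict_many(self, pairs):
        return {pair: self.predict(*pair) for pair in pairs}


def encode_peptide(peptide: str) -> np.ndarray:
    """One-hot encode an 8-11-mer, right-padded with zeros to 11 positions."""
    if not 8 <= len(peptide) <= MAX_PEP_LEN:
        raise ValueError(f"peptide length {len(peptide)} outside 8-11")
    x = np.zeros((MAX_PEP_LEN, len(AMINO_ACIDS)))
    for i, aa in enumerate(peptide):
        j = AMINO_ACIDS.find(aa)
        if j < 0:
            raise ValueError(f"non-standard residue {aa!r} in {peptide}")
        x[i, j] = 1.0
    return x.ravel()


class SurrogateModel:
    """Dense presentation classifier gated by a per-allele embedding.

    Forward pass: h1 = relu(W1 x + b1) (256 units); h2 = relu(W2 h1 + b2)
    (74 units); logit = h2 . e(allele) + b0; output = sigmoid(logit).
    The allele embedding (length 74) modulates the dense output per HLA type.
    """

    def __init__(self, alleles: list[str], seed: int = 0):
        rng = np.random.default_rng(seed)
        in_dim = MAX_PEP_LEN * len(AMINO_ACIDS)
        self.alleles = sorted(set(alleles))
        self.allele_index = {a: i for i, a in enumerate(self.alleles)}
        scale1 = np.sqrt(2.0 / in_dim)
        scale2 = np.sqrt(2.0 / HIDDEN1)
        self.W1 = rng.normal(0, scale1, size=(HIDDEN1, in_dim))
        self.b1 = np.zeros(HIDDEN1)
        self.W2 = rng.normal(0, scale2, size=(HIDDEN2, HIDDEN1))
        self.b2 = np.zeros(HIDDEN2)
        self.embed = rng.normal(0, 1.0, size=(len(self.alleles), EMBED_DIM))
        self.b0 = 0.0
        self.history: list[tuple[float, float]] = []  # (train_loss, val_loss)

    def _forward(self, X: np.ndarray, aidx: np.ndarray):
        A1 = X @ self.W1.T + self.b1
        H1 = np.maximum(A1, 0.0)
        A2 = H1 @ self.W2.T + self.b2
        H2 = np.maximum(A2, 0.0)
        E = self.embed[aidx]
        logit = np.sum(H2 * E, axis=1) + self.b0
        prob = 1.0 / (1.0 + np.exp(-logit))
        return A1, H1, A2, H2, E, prob

    def predict_proba(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        X = np.stack([encode_peptide(p) for p, _ in pairs])
        aidx = np.array([self.allele_index[a] for _, a in pairs])
        prob = self._forward(X, aidx)[-1]
        # keep strictly inside (0, 1) per the sigmoid contract
        return np.clip(prob, 1e-12, 1.0 - 1e-12)

    def fit(
        self,
        pairs: list[tuple[str, str]],
        labels: np.ndarray,
        epochs: int = 200,
        lr: float = 0.3,
        val_fraction: float = 0.1,
        patience: int = 20,
        seed: int = 0,
    ) -> "SurrogateModel":
        rng = np.random.default_rng(seed)
        X = np.stack([encode_peptide(p) for p, _ in pairs])
        aidx = np.array([self.allele_index[a] for _, a in pairs])
        y = np.asarray(labels, dtype=float)
        n = len(y)
        order = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val, tr = order[:n_val], order[n_val:]
        best_val = np.inf
        stall = 0
        for _ in range(epochs):
            self._step(X[tr], aidx[tr], y[tr], lr)
            train_loss = self._loss(X[tr], aidx[tr], y[tr])
            val_loss = self._loss(X[val], aidx[val], y[val])
            self.history.append((train_loss, val_loss))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                stall = 0
            else:
                stall += 1
                if stall >= patience:  # validation loss stopped decreasing
                    break
        return self

    def _loss(self, X, aidx, y) -> float:
        prob = np.clip(self._forward(X, aidx)[-1], 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))

    def _step(self, X, aidx, y, lr):
        n = len(y)
        A1, H1, A2, H2, E, prob = self._forward(X, aidx)
        dlogit = (prob - y) / n  # d(BCE)/d(logit)
        dH2 = dlogit[:, None] * E
        dE = dlogit[:, None] * H2
        dA2 = dH2 * (A2 > 0)
        dW2 = dA2.T @ H1
        db2 = dA2.sum(axis=0)
        dH1 = dA2 @ self.W2
        dA1 = dH1 * (A1 > 0)
        dW1 = dA1.T @ X
        db1 = dA1.sum(axis=0)
        self.W1 -= lr * dW1
        self.b1 -= lr * db1
        self.W2 -= lr * dW2
        self.b2 -= lr * db2
        self.b0 -= lr * float(dlogit.sum())
        np.add.at(self.embed, aidx, -lr * dE)


def train_surrogate(
    positives: list[tuple[str, str]],
    negatives: list[tuple[str, str]],
    epochs: int = 200,
    seed: int = 0,
) -> SurrogateModel:
    """Train the surrogate on labelled (peptide, allele) pairs.

    10% of the data is held out for validation; training stops when the
    validation loss stops decreasing.  Desk scale only (<= 5000 examples).
    """
    if not positives or not negatives:
        raise ValueError("both positives and negatives must be non-empty")
    pairs = list(positives) + list(negatives)
    if len(pairs) > 5000:
        raise ValueError("surrogate training is desk-scale only (<= 5000 examples)")
    labels = np.array([1.0] * len(positives) + [0.0] * len(negatives))
    alleles = [a for _, a in pairs]
    model = SurrogateModel(alleles, seed=seed)
    return model.fit(pairs, labels, epochs=epochs, seed=seed)


def surrogate_rank(
    model: SurrogateModel,
    candidates: list[tuple[str, str]],
    cutoff: float = 0.5,
) -> dict[tuple[str, str], tuple[bool, int]]:
    """Score candidates, assign 1-based descending-score ranks.

    Ties break by lexicographic (peptide, allele) so ranking is stable and
    reproducible.
    """
    if not candidates:
        return {}
    probs = model.predict_proba(candidates)
    order = sorted(range(len(candidates)), key=lambda i: (-probs[i], candidates[i]))
    out: dict[tuple[str, str], tuple[bool, int]] = {}
    for rank, i in enumerate(order, start=1):
        out[candidates[i]] = (bool(probs[i] > cutoff), rank)
    return out
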