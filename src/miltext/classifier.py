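"""Three-stage MIL classifier cascade and its evaluation utilities.

Each stage is a binary classifier over stacked block-level encoder
features: the per-block classification-token vectors form an ``L x d``
matrix, a bank of convolution filters with several window sizes slides
over the block axis, each feature map is max-pooled to a scalar, the
pooled features are concatenated, and a dense softmax layer produces class
probabilities. Model 1 gates MIL relevance; Models 2 and 3 rate
search-for-meaning (SFM) and presence-of-meaning (POM) level on related
posts only, yielding a POM x SFM quadrant per related post.

The trainer optimizes the convolutional head with Adam under a
class-weighted cross-entropy loss, early stopping on a validation split,
and k-fold cross-validation over the non-test data; the encoder is a
frozen feature extractor behind the adapter boundary (a production
adapter may fine-tune internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

RELATED, NOT_RELATED = "RELATED", "NOT_RELATED"
HIGH, LOW = "HIGH", "LOW"


@dataclass
class ClassifierConfig:
    """Architecture of the convolutional head.

    ``L`` and ``d`` must match the encoder adapter; production defaults
    mirror a 12-block encoder with 768-dimensional vectors, window sizes
    (3, 4, 5) and 128 filters per window; ``max_len`` is the token
    truncation/padding length (default 164).
    """

    L: int = 12
    d: int = 768
    windows: tuple[int, ...] = (3, 4, 5)
    m: int = 128
    n_classes: int = 2
    max_len: int = 164

    def __post_init__(self) -> None:
        if max(self.windows) > self.L:
            raise ValueError("largest window exceeds number of blocks L")
        if self.m < 1 or self.max_len < 1:
            raise ValueError("m and max_len must be >= 1")


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 2e-5
    patience_steps: int = 1000
    max_steps: int = 20000
    folds: int = 10
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    class_weights: dict[str, float] | None = None  # None -> n/(K*n_c)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience_steps < 1:
            raise ValueError("patience_steps must be >= 1")


@dataclass
class CascadeResult:
    """Cascade prediction for one post. SFM/POM present iff RELATED."""

    post_id: str
    relevance: str
    relevance_prob: float
    sfm: str | None = None
    sfm_prob: float | None = None
    pom: str | None = None
    pom_prob: float | None = None

    def __post_init__(self) -> None:
        has_levels = self.sfm is not None or self.pom is not None
        if has_levels and self.relevance != RELATED:
            raise ValueError("SFM/POM labels on a post gated NOT_RELATED")

    @property
    def quadrant(self) -> str | None:
        """Subgroup key, e.g. 'S1P0' for high SFM / low POM."""
        if self.relevance != RELATED:
            return None
        return f"S{int(self.sfm == HIGH)}P{int(self.pom == HIGH)}"


def stack_cls(encoder, tokens: Sequence[int], max_len: int | None = None) -> np.ndarray:
    """Stack per-block summary vectors into an ``L x d`` matrix."""
    max_len = max_len if max_len is not None else getattr(encoder, "max_len", 164)
    mat = np.asarray(encoder.encode(tokens, max_len), dtype=float)
    expected = (encoder.n_blocks, encoder.dim)
    if mat.shape != expected:
        raise ValueError(f"encoder returned shape {mat.shape}, expected {expected}")
    return mat


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _init_params(cfg: ClassifierConfig, rng: np.random.Generator) -> dict:
    params: dict = {"W_out": rng.normal(0, 0.05, (cfg.n_classes, len(cfg.windows) * cfg.m)),
                    "b_out": np.zeros(cfg.n_classes)}
    for w in cfg.windows:
        params[f"F{w}"] = rng.normal(0, 0.1, (cfg.m, w, cfg.d))
        params[f"b{w}"] = np.zeros(cfg.m)
    return params


def _sliding(X: np.ndarray, w: int) -> np.ndarray:
    """(B, L, d) -> (B, L-w+1, w, d) view of window slices."""
    B, L, d = X.shape
    return np.stack([X[:, t : t + w, :] for t in range(L - w + 1)], axis=1)


def _forward(X: np.ndarray, params: dict, cfg: ClassifierConfig, cache: bool = False):
    """Batch forward pass. X: (B, L, d) -> probabilities (B, n_classes)."""
    pooled, caches = [], []
    for w in cfg.windows:
        Xs = _sliding(X, w)                              # (B, T, w, d)
        Z = np.einsum("btwd,fwd->btf", Xs, params[f"F{w}"]) + params[f"b{w}"]
        A = np.maximum(Z, 0.0)                           # (B, T, m)
        t_star = A.argmax(axis=1)                        # (B, m)
        P = A.max(axis=1)                                # (B, m)
        pooled.append(P)
        if cache:
            caches.append((Xs, Z, t_star))
    V = np.concatenate(pooled, axis=1)                   # (B, |windows|*m)
    logits = V @ params["W_out"].T + params["b_out"]
    probs = _softmax(logits)
    if cache:
        return probs, (V, caches)
    return probs


def conv_head_forward(matrix: np.ndarray, params: dict, cfg: ClassifierConfig) -> np.ndarray:
    """Class probabilities for a single ``L x d`` matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (cfg.L, cfg.d):
        raise ValueError(f"matrix shape {matrix.shape} != ({cfg.L}, {cfg.d})")
    return _forward(matrix[None], params, cfg)[0]


def _backward(X, y_onehot, sample_w, params, cfg):
    """Gradient of the weighted mean cross-entropy w.r.t. head parameters."""
    B = X.shape[0]
    probs, (V, caches) = _forward(X, params, cfg, cache=True)
    dlogits = (probs - y_onehot) * sample_w[:, None] / B      # (B, C)
    grads = {
        "W_out": dlogits.T @ V,
        "b_out": dlogits.sum(axis=0),
    }
    dV = dlogits @ params["W_out"]                            # (B, Wm)
    loss = float(-(sample_w * np.log(probs[np.arange(B), y_onehot.argmax(1)] + 1e-12)).mean())
    for k, w in enumerate(cfg.windows):
        Xs, Z, t_star = caches[k]
        dP = dV[:, k * cfg.m : (k + 1) * cfg.m]               # (B, m)
        dZ = np.zeros_like(Z)
        b_idx = np.repeat(np.arange(B), cfg.m)
        f_idx = np.tile(np.arange(cfg.m), B)
        dZ[b_idx, t_star.ravel(), f_idx] = dP.ravel()
        dZ *= Z > 0
        grads[f"F{w}"] = np.einsum("btf,btwd->fwd", dZ, Xs)
        grads[f"b{w}"] = dZ.sum(axis=(0, 1))
    return loss, grads


class _Adam:
    """Adaptive-moment optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def class_weight_rule(labels: Sequence[str]) -> dict[str, float]:
    """Balanced weights w_c = n / (K * n_c)."""
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    K = len(classes)
    return {c: n / (K * cnt) for c, cnt in zip(classes, counts)}


@dataclass
class FoldMetrics:
    fold: int
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class TrainResult:
    fold_metrics: list[FoldMetrics]
    test_metrics: dict[str, float]
    cv_mean_accuracy: float
    n_train: int
    n_val: int
    n_test: int


class MILClassifier:
    """One binary stage of the cascade (sklearn-style fit/predict).

    Parameters
    ----------
    encoder :
        An encoder adapter (see :mod:`miltext.encoder`).
    config :
        Head architecture; ``L``/``d`` must match the encoder.
    positive_label, negative_label :
        The two class labels; a tie at probability 0.5 resolves to the
        positive class (and is logged).
    """

    def __init__(self, encoder, config: ClassifierConfig,
                 positive_label: str = RELATED, negative_label: str = NOT_RELATED):
        if (config.L, config.d) != (encoder.n_blocks, encoder.dim):
            raise ValueError("config (L, d) must match encoder (n_blocks, dim)")
        self.encoder = encoder
        self.config = config
        self.positive_label = positive_label
        self.negative_label = negative_label
        self.params: dict | None = None

    # -- features ---------------------------------------------------------
    def features(self, texts: Sequence[str]) -> np.ndarray:
        mats = [
            stack_cls(self.encoder, self.encoder.tokenize(t), self.config.max_len)
            for t in texts
        ]
        return np.stack(mats) if mats else np.empty((0, self.config.L, self.config.d))

    # -- training ---------------------------------------------------------
    def _encode_y(self, labels: Sequence[str]) -> np.ndarray:
        y = np.zeros((len(labels), 2))
        for i, lab in enumerate(labels):
            if lab == self.positive_label:
                y[i, 1] = 1.0
            elif lab == self.negative_label:
                y[i, 0] = 1.0
            else:
                raise ValueError(f"unknown label {lab!r}")
        return y

    def _train_head(self, Xtr, ytr, wtr, Xval, yval, tcfg: TrainConfig,
                    rng: np.random.Generator) -> dict:
        params = _init_params(self.config, rng)
        opt = _Adam(params, tcfg.learning_rate)
        best = {k: v.copy() for k, v in params.items()}
        best_val, since_best = -np.inf, 0
        n = Xtr.shape[0]
        order = rng.permutation(n)
        pos = 0
        for step in range(tcfg.max_steps):
            if pos + tcfg.batch_size > n:
                order = rng.permutation(n)
                pos = 0
            idx = order[pos : pos + tcfg.batch_size]
            pos += tcfg.batch_size
            _, grads = _backward(Xtr[idx], ytr[idx], wtr[idx], params, self.config)
            opt.step(params, grads)
            if Xval.shape[0]:
                val_acc = accuracy_score(
                    yval.argmax(1), _forward(Xval, params, self.config).argmax(1)
                )
            else:
                val_acc = accuracy_score(
                    ytr.argmax(1), _forward(Xtr, params, self.config).argmax(1)
                )
            if val_acc > best_val:
                best_val, since_best = val_acc, 0
                best = {k: v.copy() for k, v in params.items()}
            else:
                since_best += 1
                if since_best >= tcfg.patience_steps:
                    break
        return best

    def fit(self, texts: Sequence[str], labels: Sequence[str],
            tcfg: TrainConfig | None = None) -> TrainResult:
        """Train the head with held-out test split and k-fold CV.

        The data is split train:validation:test per ``tcfg.split`` (test
        held out once); k-fold cross-validation runs over the non-test
        portion, then a final head is trained on the train split with the
        validation split driving early stopping, and test metrics are
        reported from that final head. Seeded runs are reproducible.
        """
        tcfg = tcfg or TrainConfig()
        labels = list(labels)
        if len(set(labels)) < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(tcfg.seed)
        X = self.features(texts)
        y = self._encode_y(labels)
        weights = tcfg.class_weights or class_weight_rule(labels)
        w = np.array([weights[lab] for lab in labels])

        n = len(labels)
        perm = rng.permutation(n)
        n_test = int(round(tcfg.split[2] * n))
        n_val = int(round(tcfg.split[1] * n))
        test_idx = perm[:n_test]
        val_idx = perm[n_test : n_test + n_val]
        train_idx = perm[n_test + n_val :]
        dev_idx = perm[n_test:]  # CV pool = train + val (the non-test 90%)

        fold_metrics: list[FoldMetrics] = []
        n_folds = min(tcfg.folds, len(dev_idx))
        if n_folds >= 2:
            kf = KFold(n_splits=n_folds, shuffle=True, random_state=tcfg.seed)
            for f, (tr, va) in enumerate(kf.split(dev_idx)):
                tr_i, va_i = dev_idx[tr], dev_idx[va]
                params = self._train_head(X[tr_i], y[tr_i], w[tr_i],
                                          X[va_i], y[va_i], tcfg, rng)
                pred = _forward(X[va_i], params, self.config).argmax(1)
                acc = accuracy_score(y[va_i].argmax(1), pred)
                pr, rc, f1, _ = precision_recall_fscore_support(
                    y[va_i].argmax(1), pred, average="binary", zero_division=0
                )
                fold_metrics.append(FoldMetrics(f, acc, pr, rc, f1))

        self.params = self._train_head(
            X[train_idx], y[train_idx], w[train_idx], X[val_idx], y[val_idx],
            tcfg, rng,
        )
        if len(test_idx):
            pred = _forward(X[test_idx], self.params, self.config).argmax(1)
            acc = accuracy_score(y[test_idx].argmax(1), pred)
            pr, rc, f1, _ = precision_recall_fscore_support(
                y[test_idx].argmax(1), pred, average="binary", zero_division=0
            )
            test_metrics = {"accuracy": acc, "precision": pr, "recall": rc, "f1": f1}
        else:
            test_metrics = {}
        cv_mean = float(np.mean([fm.accuracy for fm in fold_metrics])) if fold_metrics else float("nan")
        return TrainResult(
            fold_metrics=fold_metrics,
            test_metrics=test_metrics,
            cv_mean_accuracy=cv_mean,
            n_train=len(train_idx), n_val=len(val_idx), n_test=len(test_idx),
        )

    # -- inference --------------------------------------------------------
    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        """Probability of (negative, positive) per post."""
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        X = self.features(texts)
        if not len(texts):
            return np.empty((0, 2))
        return _forward(X, self.params, self.config)

    def predict(self, texts: Sequence[str]) -> list[tuple[str, float]]:
        """(label, probability-of-positive) per post; tie 0.5 -> positive."""
        probs = self.predict_proba(texts)[:, 1]
        out = []
        for p in probs:
            if p == 0.5:
                logger.info("tie at probability 0.5 resolved to positive class")
            label = self.positive_label if p >= 0.5 else self.negative_label
            out.append((label, float(p)))
        return out


def train_model(texts: Sequence[str], labels: Sequence[str], encoder,
                ccfg: ClassifierConfig, tcfg: TrainConfig | None = None,
                positive_label: str = RELATED,
                negative_label: str = NOT_RELATED) -> tuple[MILClassifier, TrainResult]:
    """Convenience wrapper: build one cascade stage and fit it."""
    clf = MILClassifier(encoder, ccfg, positive_label, negative_label)
    result = clf.fit(texts, labels, tcfg)
    return clf, result


def predict_cascade(posts, model1: MILClassifier, model2: MILClassifier,
                    model3: MILClassifier) -> list[CascadeResult]:
    """Run the three-stage cascade.

    Model 1 gates relevance on every post; Models 2 (SFM) and 3 (POM) run
    only on posts gated RELATED. Output order and ids match the input.
    """
    fps = {getattr(m.encoder, "fingerprint", lambda: id(m.encoder))()
           for m in (model1, model2, model3)}
    if len(fps) > 1:
        raise ValueError("cascade models must share the same encoder adapter")
    posts = list(posts)
    texts = [p.text for p in posts]
    rel = model1.predict(texts)
    related_ix = [i for i, (lab, _) in enumerate(rel) if lab == RELATED]
    rel_texts = [texts[i] for i in related_ix]
    sfm = model2.predict(rel_texts) if related_ix else []
    pom = model3.predict(rel_texts) if related_ix else []
    sfm_map = dict(zip(related_ix, sfm))
    pom_map = dict(zip(related_ix, pom))
    out = []
    for i, p in enumerate(posts):
        lab, prob = rel[i]
        if i in sfm_map:
            out.append(CascadeResult(
                post_id=p.post_id, relevance=lab, relevance_prob=prob,
                sfm=sfm_map[i][0], sfm_prob=sfm_map[i][1],
                pom=pom_map[i][0], pom_prob=pom_map[i][1],
            ))
        else:
            out.append(CascadeResult(post_id=p.post_id, relevance=lab,
                                     relevance_prob=prob))
    return out


def stratified_sample(results: Sequence[CascadeResult], frac: float,
                      min_per_stratum: int = 100,
                      rng: np.random.Generator | int | None = None
                      ) -> list[CascadeResult]:
    """Stratified validation sample over the four POM x SFM quadrants.

    Per quadrant the draw size is ``max(min_per_stratum, round(frac * N_q))``
    without replacement; a quadrant smaller than ``min_per_stratum`` is an
    error (it cannot satisfy the floor).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    strata: dict[str, list[CascadeResult]] = {}
    for r in results:
        q = r.quadrant
        if q is None:
            continue
        strata.setdefault(q, []).append(r)
    sample: list[CascadeResult] = []
    for q in sorted(strata):
        members = strata[q]
        if len(members) < min_per_stratum:
            raise ValueError(
                f"quadrant {q} has {len(members)} items, fewer than the "
                f"minimum {min_per_stratum}"
            )
        k = max(min_per_stratum, int(round(frac * len(members))))
        idx = rng.choice(len(members), size=min(k, len(members)), replace=False)
        sample.extend(members[i] for i in sorted(idx.tolist()))
    return sample


def joint_accuracy(predictions: Sequence[CascadeResult],
                   gold: Mapping[str, tuple[str, str]]) -> float:
    """Fraction of posts whose SFM and POM are simultaneously correct."""
    preds = {r.post_id: (r.sfm, r.pom) for r in predictions}
    if set(preds) != set(gold):
        raise ValueError("prediction and gold post ids do not match")
    hits = sum(preds[pid] == tuple(gold[pid]) for pid in preds)
    return hits / len(preds) if preds else float("nan")


def user_mil_proportion(results: Sequence[CascadeResult],
                        user_of: Mapping[str, str]) -> dict[str, float]:
    """Per-user proportion of MIL-related posts."""
    totals: dict[str, int] = {}
    related: dict[str, int] = {}
    for r in results:
        u = user_of[r.post_id]
        totals[u] = totals.get(u, 0) + 1
        related[u] = related.get(u, 0) + (r.relevance == RELATED)
    return {u: related[u] / totals[u] for u in totals}


def correlate(proportions: Sequence[float], scores: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (two-sided p) between proportions and survey scores."""
    if len(proportions) != len(scores):
        raise ValueError("length mismatch")
    if len(proportions) < 3:
        raise ValueError("need at least 3 users")
    if np.ptp(proportions) == 0 or np.ptp(scores) == 0:
        raise ValueError("zero-variance input")
    r, p = pearsonr(proportions, scores)
    return float(r), float(p)
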