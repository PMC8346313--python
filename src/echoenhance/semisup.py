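"""Semi-supervised discriminator losses.

A discriminator scores each input over ``K`` real classes plus one
generated/"fake" class.  The fake-class logit is pinned to 0 (the standard
over-parameterization removal), so with ``t = LSE`` over the real-class
logits the fake-class probability is ``1 / (1 + e^t)`` and the three loss
terms reduce to the closed forms implemented here:

* labeled:   ``-l_y + LSE(l)``           (real-class cross-entropy)
* unlabeled: ``-t + softplus(t)``        (encourage "this is real")
* fake:      ``softplus(t)``             (encourage "this is generated")

The total discriminator objective is ``L_label + v * (L_unlabel + L_fake) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscriminatorLogits",
    "SemiSupReport",
    "lse",
    "softplus",
    "loss_label",
    "loss_unlabel",
    "loss_fake",
    "total_discriminator_loss",
    "semisup_report",
    "FeatureDiscriminator",
    "make_training_hook",
]


@dataclass(frozen=True)
class DiscriminatorLogits:
    """Scores over ``K`` real classes plus the final generated-class entry.

    Entry ``K+1`` (the last) is the fake-class slot; by the pinned-logit
    convention the losses only read the real-class entries, so the stored
    fake score is informational.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("scores must be a 1-D vector of length >= 2 (K real + 1 fake)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("scores must be finite")
        arr.setflags(write=False)
        object.__setattr__(self, "scores", arr)

    @property
    def class_count(self) -> int:
        """Number of real classes K."""
        return self.scores.size - 1

    @property
    def real_scores(self) -> np.ndarray:
        return self.scores[:-1]

    @classmethod
    def from_real_scores(cls, real: np.ndarray) -> "DiscriminatorLogits":
        """Build logits from real-class scores with the fake slot pinned at 0."""
        real = np.asarray(real, dtype=np.float64)
        return cls(np.concatenate([real, [0.0]]))


def lse(l: np.ndarray) -> float:
    """Numerically stable log-sum-exp: ``max(l) + log(sum(exp(l - max(l))))``."""
    arr = np.asarray(l, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("lse of an empty vector is undefined")
    m = float(arr.max())
    return m + float(np.log(np.sum(np.exp(arr - m))))


def softplus(t: float) -> float:
    """``log(1 + e^t)`` computed without overflow."""
    t = float(t)
    return max(t, 0.0) + float(np.log1p(np.exp(-abs(t))))


def loss_label(logits: DiscriminatorLogits, y: int) -> float:
    """Cross-entropy of the real-class softmax at true class ``y`` (1-based)."""
    if not 1 <= y <= logits.class_count:
        raise ValueError(f"class index y={y} outside 1..{logits.class_count}")
    l = logits.real_scores
    return -float(l[y - 1]) + lse(l)


def loss_unlabel(logits: DiscriminatorLogits) -> float:
    """Unlabeled-data term: ``-t + softplus(t)`` with ``t = LSE`` over real classes."""
    t = lse(logits.real_scores)
    return -t + softplus(t)


def loss_fake(logits: DiscriminatorLogits) -> float:
    """Generated-data term: ``softplus(t)`` with ``t = LSE`` over real classes."""
    return softplus(lse(logits.real_scores))


def total_discriminator_loss(
    L_label: float, L_unlabel: float, L_fake: float, v: float
) -> float:
    """Weighted total ``L_label + v * (L_unlabel + L_fake) / 2``."""
    if v < 0:
        raise ValueError(f"weight v must be >= 0, got {v}")
    return float(L_label) + v * (float(L_unlabel) + float(L_fake)) / 2.0


@dataclass(frozen=True)
class SemiSupReport:
    """One evaluation of the three loss terms and their weighted total."""

    L_label: float
    L_unlabel: float
    L_fake: float
    L_D: float
    v: float

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("weight v must be >= 0")
        expected = total_discriminator_loss(self.L_label, self.L_unlabel, self.L_fake, self.v)
        if self.L_D != expected:
            raise ValueError(f"inconsistent total: L_D={self.L_D} != {expected}")


class FeatureDiscriminator:
    """Tiny linear discriminator over summary image features.

    This backs the optional semi-supervised training mode: clean phantoms
    act as labeled real data (one class per phantom "view", here a single
    class), degraded inputs as unlabeled data, and enhancer outputs as
    generated data.  It produces :class:`DiscriminatorLogits` with the fake
    slot pinned at 0 and is updated by plain gradient descent on the total
    loss.  It observes the enhancer but never feeds a gradient back into it.
    """

    def __init__(self, class_count: int = 1, seed: int = 0, lr: float = 0.05):
        rng = np.random.default_rng(seed)
        self.n_features = 3  # mean, std, mean |gradient|
        self.weights = 0.01 * rng.standard_normal((class_count, self.n_features))
        self.bias = np.zeros(class_count)
        self.lr = lr

    @staticmethod
    def features(pixels: np.ndarray) -> np.ndarray:
        gy, gx = np.gradient(np.asarray(pixels, dtype=np.float64))
        return np.array(
            [pixels.mean(), pixels.std(), np.mean(np.abs(gx) + np.abs(gy))]
        )

    def logits(self, pixels: np.ndarray) -> DiscriminatorLogits:
        f = self.features(pixels)
        return DiscriminatorLogits.from_real_scores(self.weights @ f + self.bias)

    def _numeric_grad(self, images, fn, eps: float = 1e-6):
        """Central-difference gradient of a scalar objective; the net is tiny."""
        gw = np.zeros_like(self.weights)
        gb = np.zeros_like(self.bias)
        for idx in np.ndindex(self.weights.shape):
            self.weights[idx] += eps
            hi = fn()
            self.weights[idx] -= 2 * eps
            lo = fn()
            self.weights[idx] += eps
            gw[idx] = (hi - lo) / (2 * eps)
        for i in range(self.bias.size):
            self.bias[i] += eps
            hi = fn()
            self.bias[i] -= 2 * eps
            lo = fn()
            self.bias[i] += eps
            gb[i] = (hi - lo) / (2 * eps)
        return gw, gb

    def update(
        self,
        real: list[np.ndarray],
        unlabeled: list[np.ndarray],
        generated: list[np.ndarray],
        v: float,
    ) -> SemiSupReport:
        """One descent step on the total discriminator loss; returns the report."""

        def objective() -> float:
            rep = self._report(real, unlabeled, generated, v)
            return rep.L_D

        gw, gb = self._numeric_grad(real, objective)
        self.weights -= self.lr * gw
        self.bias -= self.lr * gb
        return self._report(real, unlabeled, generated, v)

    def _report(self, real, unlabeled, generated, v) -> SemiSupReport:
        labeled = [(self.logits(px), 1) for px in real]
        unl = [self.logits(px) for px in unlabeled]
        gen = [self.logits(px) for px in generated]
        return semisup_report(labeled, unl, gen, v)


def make_training_hook(v: float = 0.5, seed: int = 0):
    """Build a per-epoch hook for :func:`echoenhance.enhancer.train`.

    Returns ``(hook, reports)``; each epoch appends one :class:`SemiSupReport`
    computed from clean phantoms (real), degraded inputs (unlabeled) and the
    current enhancer outputs (generated).
    """
    from .enhancer import forward  # local import to avoid a cycle

    disc = FeatureDiscriminator(seed=seed)
    reports: list[SemiSupReport] = []

    def hook(net, pairs, epoch) -> None:
        real = [clean.pixels for clean, _ in pairs]
        unlabeled = [noisy.pixels for _, noisy in pairs]
        generated = [forward(net, noisy).pixels for _, noisy in pairs]
        reports.append(disc.update(real, unlabeled, generated, v))

    return hook, reports


def semisup_report(
    labeled: list[tuple[DiscriminatorLogits, int]],
    unlabeled: list[DiscriminatorLogits],
    generated: list[DiscriminatorLogits],
    v: float = 0.5,
) -> SemiSupReport:
    """Average the three loss terms over their batches and combine them.

    Empty batches contribute 0 to their term.
    """
    L_lab = float(np.mean([loss_label(lg, y) for lg, y in labeled])) if labeled else 0.0
    L_unl = float(np.mean([loss_unlabel(lg) for lg in unlabeled])) if unlabeled else 0.0
    L_fak = float(np.mean([loss_fake(lg) for lg in generated])) if generated else 0.0
    return SemiSupReport(
        L_label=L_lab,
        L_unlabel=L_unl,
        L_fake=L_fak,
        L_D=total_discriminator_loss(L_lab, L_unl, L_fak, v),
        v=v,
    )
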