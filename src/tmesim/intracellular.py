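"""Macrophage differentiation: mechanistic stand-in, M1/M2 score, surrogate.

A macrophage reads the IL-4 and IFN-g levels in its local environment (plus
the current PI3K activity, the handle for re-education therapy) and commits
to the M1 or M2 phenotype.  The decision pipeline is:

1. A mechanistic model maps (IL-4, IFN-g, PI3K) to normalized expression of
   five M1 markers (iNOS, TNF-a, CXCL9, CXCL10, IL-12) and three M2 markers
   (IL-10, Arg-1, VEGF).  The intracellular signaling ODE system this stands
   in for is external; the packaged stand-in is a saturating algebraic model
   with the same input/output contract, exposed as a plug-in so a full
   time-course model can be substituted.
2. The M1/M2 score is the product of the M1 marker levels divided by the
   product of the M2 marker levels, averaged over a 24-hour window.  Score
   > 1 commits to M1, otherwise M2.
3. A small neural network (one hidden layer, four sigmoid neurons) is
   trained on Monte-Carlo samples labeled by (1)+(2) and replaces the
   mechanistic call inside the simulator for speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

M1_MARKERS = ("iNOS", "TNFa", "CXCL9", "CXCL10", "IL12")
M2_MARKERS = ("IL10", "Arg1", "VEGF")

M1, M2 = "M1", "M2"


@dataclass(frozen=True)
class StandInConstants:
    """Constants of the algebraic differentiation stand-in.

    Each M1 marker responds to IFN-g as ``1 + alpha_j * H(ifng; K_ifng)`` and
    each M2 marker to IL-4 as ``1 + beta_j * pi3k * H(il4; K_il4)`` with the
    Hill function ``H(x; K) = x / (x + K)``.  Marker gains are staggered so
    the M1/M2 decision boundary is a nontrivial curve across the cytokine
    ranges the simulator realizes; the half-saturation constants sit in the
    middle of those ranges.
    """

    alpha: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.2)
    beta: tuple[float, ...] = (1.5, 2.0, 2.5)
    k_ifng: float = 20.0
    k_il4: float = 20.0


#: cytokine/PI3K ranges realized in the simulator; also the Monte-Carlo
#: sampling box for surrogate training (per-site molecule counts).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "il4": (0.0, 100.0),
    "ifng": (0.0, 100.0),
    "pi3k": (0.0, 1.0),
}


def standin_mechanistic(
    il4: float, ifng: float, pi3k: float = 1.0,
    constants: StandInConstants = StandInConstants(),
) -> dict[str, float]:
    """Steady-state marker levels, normalized to 1 at baseline (no cytokines).

    M1 markers rise saturably with IFN-g; M2 markers rise saturably with
    IL-4, scaled by PI3K activity (pi3k = 0 abolishes the M2 drive).
    """
    if il4 < 0 or ifng < 0 or pi3k < 0:
        raise ValueError("cytokine and PI3K inputs must be non-negative")
    h_i = ifng / (ifng + constants.k_ifng) if ifng > 0 else 0.0
    h_4 = il4 / (il4 + constants.k_il4) if il4 > 0 else 0.0
    out = {m: 1.0 + a * h_i for m, a in zip(M1_MARKERS, constants.alpha)}
    out.update({m: 1.0 + b * pi3k * h_4 for m, b in zip(M2_MARKERS, constants.beta)})
    return out


def m1m2_score(channels: dict[str, float]) -> tuple[float, str]:
    """Product of M1 marker levels over product of M2 marker levels.

    For a time-course model the ratio is averaged over the 24-h evaluation
    window; the algebraic stand-in is at steady state so the average equals
    the instantaneous value.  Score strictly greater than 1 labels M1; the
    tie at exactly 1 (the baseline state) falls to M2, the environment's
    default attractor.
    """
    for m in M1_MARKERS + M2_MARKERS:
        if channels[m] <= 0:
            raise ValueError(f"marker {m} must be positive, got {channels[m]}")
    num = np.prod([channels[m] for m in M1_MARKERS])
    den = np.prod([channels[m] for m in M2_MARKERS])
    score = float(num / den)
    return score, (M1 if score > 1.0 else M2)


def mechanistic_label(
    il4: float, ifng: float, pi3k: float = 1.0,
    constants: StandInConstants = StandInConstants(),
) -> str:
    """Convenience composition: stand-in model -> score -> phenotype label."""
    return m1m2_score(standin_mechanistic(il4, ifng, pi3k, constants))[1]


def generate_training_set(
    n_samples: int = 100_000,
    ranges: dict[str, tuple[float, float]] | None = None,
    rng_seed: int = 0,
    constants: StandInConstants = StandInConstants(),
    oracle: Callable[[float, float, float], str] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo labeled dataset for surrogate training.

    Uniformly samples (il4, ifng, pi3k) over ``ranges`` and labels each row
    with the mechanistic pipeline (or a caller-supplied ``oracle``).
    Reproducible under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ranges = dict(ranges or DEFAULT_RANGES)
    for k in ("il4", "ifng", "pi3k"):
        lo, hi = ranges[k]
        if hi < lo:
            raise ValueError(f"empty range for {k}: {(lo, hi)}")
    rng = np.random.default_rng(rng_seed)
    cols = {k: rng.uniform(*ranges[k], size=n_samples) for k in ("il4", "ifng", "pi3k")}
    if oracle is None:
        oracle = lambda a, g, p: mechanistic_label(a, g, p, constants)
    labels = [oracle(a, g, p) for a, g, p in zip(cols["il4"], cols["ifng"], cols["pi3k"])]
    return pd.DataFrame({**cols, "label": labels})


@dataclass
class SurrogateModel:
    """Tiny feed-forward network standing in for the mechanistic call.

    One hidden layer of four sigmoid neurons, three inputs (IL-4, IFN-g,
    PI3K activity) normalized to [0, 1], one sigmoid output thresholded at
    0.5.  Weights are stored explicitly so prediction is a pure numpy
    forward pass, deterministic and serializable to JSON.
    """

    w1: np.ndarray  # (3, 4)
    b1: np.ndarray  # (4,)
    w2: np.ndarray  # (4,)
    b2: float
    ranges: dict[str, tuple[float, float]]
    held_out_accuracy: float
    single_class_warning: bool = False
    clamped_queries: int = field(default=0, compare=False)

    _ORDER = ("il4", "ifng", "pi3k")

    def _normalize(self, il4: float, ifng: float, pi3k: float) -> np.ndarray:
        x = np.empty(3)
        for i, (name, v) in enumerate(zip(self._ORDER, (il4, ifng, pi3k))):
            lo, hi = self.ranges[name]
            span = hi - lo if hi > lo else 1.0
            z = (v - lo) / span
            if z < 0.0 or z > 1.0:
                self.clamped_queries += 1
                z = min(1.0, max(0.0, z))
            x[i] = z
        return x

    def decision_value(self, il4: float, ifng: float, pi3k: float = 1.0) -> float:
        x = self._normalize(il4, ifng, pi3k)
        h = 1.0 / (1.0 + np.exp(-(x @ self.w1 + self.b1)))
        z = float(h @ self.w2 + self.b2)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, il4: float, ifng: float, pi3k: float = 1.0) -> str:
        """Phenotype label; out-of-range inputs are clamped to the box edges."""
        return M1 if self.decision_value(il4, ifng, pi3k) > 0.5 else M2

    # -- persistence -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "held_out_accuracy": self.held_out_accuracy,
            "single_class_warning": self.single_class_warning,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            ranges={k: tuple(v) for k, v in d["ranges"].items()},
            held_out_accuracy=float(d["held_out_accuracy"]),
            single_class_warning=bool(d["single_class_warning"]),
        )


def train_surrogate(
    dataset: pd.DataFrame,
    split_fraction: float = 0.2,
    rng_seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
    max_iter: int = 500,
) -> SurrogateModel:
    """Fit the 4-neuron sigmoid network on a labeled Monte-Carlo dataset.

    The dataset is randomly split into training and held-out sets; the
    held-out accuracy is recorded on the model.  A single-class dataset
    trains (trivially) but sets ``single_class_warning``.
    """
    ranges = dict(ranges or DEFAULT_RANGES)
    X = dataset[["il4", "ifng", "pi3k"]].to_numpy(dtype=float).copy()
    for i, name in enumerate(("il4", "ifng", "pi3k")):
        lo, hi = ranges[name]
        span = hi - lo if hi > lo else 1.0
        X[:, i] = np.clip((X[:, i] - lo) / span, 0.0, 1.0)
    y = (dataset["label"].to_numpy() == M1).astype(int)

    single_class = len(np.unique(y)) < 2
    if single_class:
        X_tr, X_te, y_tr, y_te = X, X, y, y
    else:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=split_fraction, random_state=rng_seed, stratify=y
        )

    clf = MLPClassifier(
        hidden_layer_sizes=(4,),
        activation="logistic",
        solver="adam",
        learning_rate_init=0.05,
        max_iter=max_iter,
        early_stopping=not single_class,
        n_iter_no_change=15,
        random_state=rng_seed,
    )
    if single_class:
        # MLPClassifier cannot fit one class; emit a constant-output model.
        const = 10.0 if y[0] == 1 else -10.0
        model = SurrogateModel(
            w1=np.zeros((3, 4)), b1=np.zeros(4), w2=np.zeros(4), b2=const,
            ranges=ranges, held_out_accuracy=1.0, single_class_warning=True,
        )
        return model
    clf.fit(X_tr, y_tr)
    acc = float(clf.score(X_te, y_te))
    return SurrogateModel(
        w1=np.asarray(clf.coefs_[0], dtype=float),
        b1=np.asarray(clf.intercepts_[0], dtype=float),
        w2=np.asarray(clf.coefs_[1], dtype=float).ravel(),
        b2=float(np.asarray(clf.intercepts_[1]).ravel()[0]),
        ranges=ranges,
        held_out_accuracy=acc,
    )


def grid_agreement(
    model: SurrogateModel,
    n_il4: int = 50,
    n_ifng: int = 50,
    pi3k_values: tuple[float, ...] = (0.0, 0.5, 1.0),
    ranges: dict[str, tuple[float, float]] | None = None,
    constants: StandInConstants = StandInConstants(),
) -> float:
    """Fraction of a regular input grid where surrogate and oracle agree."""
    ranges = dict(ranges or DEFAULT_RANGES)
    il4s = np.linspace(*ranges["il4"], n_il4)
    ifngs = np.linspace(*ranges["ifng"], n_ifng)
    hits = total = 0
    for p in pi3k_values:
        for a in il4s:
            for g in ifngs:
                total += 1
                if model.predict(a, g, p) == mechanistic_label(a, g, p, constants):
                    hits += 1
    return hits / total
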