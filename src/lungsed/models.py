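"""The RNN-variant detector zoo: build, train, predict, cross-validate.

Twelve variants are supported: {LSTM, GRU} x {uni, bi} x {plain, CNN
front}, plus the four "SIMP" bidirectional variants whose recurrent
width is halved so their parameter budget is comparable to the
unidirectional models.

The common backbone, reconstructed from the published trainable-
parameter counts, is two stacked recurrent layers followed by a
time-distributed Dense(32, ReLU) and a Dense(1) output head:

* unidirectional: 128 units per layer;
* bidirectional: 128 units per direction per layer (256 total);
* SIMP bidirectional: 64 per direction (128 total);
* CNN-fronted variants first halve the time axis 938 -> 469 and
  re-embed each frame (see :class:`lungsed.nn.ConvFront`).

With TensorFlow/Keras weight conventions this backbone reproduces the
published counts exactly for the eight non-CNN entries (e.g. LSTM
300,609; GRU 227,265; SIMP BiGRU 178,113).  The CNN front itself is
underdetermined by the published totals, so CNN-model counts are
advisory (see docs/methods.md).

One detector is trained per task (I, E, CAS, DAS); recordings are
assigned to cross-validation folds by their subject/day group so that
no acquisition session spans two folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import Manifest
from .features import FRAME_STEP_S, N_FEATURES, N_FRAMES, FeatureMatrix
from .nn import Bidirectional, ConvFront, Dense, GRU, LSTM, SequenceModel
from .nn.training import TrainConfig, TrainingHistory, fit  # noqa: F401  (re-export)

FULL_UNITS = 128       # per direction
SIMP_UNITS = 64        # per direction, simplified bidirectional variants
HEAD_UNITS = 32
CNN_OUTPUT_FRAMES = 469


@dataclass(frozen=True)
class ModelSpec:
    """Which of the twelve detector variants to build."""

    cell: str = "GRU"               # "LSTM" or "GRU"
    bidirectional: bool = False
    cnn_front: bool = False
    simplified: bool = False

    def __post_init__(self) -> None:
        if self.cell not in ("LSTM", "GRU"):
            raise ValueError(f"cell must be LSTM or GRU, got {self.cell!r}")
        if self.simplified and not self.bidirectional:
            raise ValueError("simplified variants are bidirectional only")

    @property
    def rnn_units(self) -> int:
        """Recurrent units per direction per layer."""
        return SIMP_UNITS if self.simplified else FULL_UNITS

    @property
    def output_length(self) -> int:
        return CNN_OUTPUT_FRAMES if self.cnn_front else N_FRAMES

    @property
    def name(self) -> str:
        base = ("Bi" if self.bidirectional else "") + self.cell
        if self.cnn_front:
            base = "CNN-" + base
        if self.simplified:
            base = "SIMP " + base
        return base


#: the twelve benchmark variants in table order
ALL_SPECS = [
    ModelSpec("LSTM"),
    ModelSpec("GRU"),
    ModelSpec("LSTM", bidirectional=True),
    ModelSpec("GRU", bidirectional=True),
    ModelSpec("LSTM", bidirectional=True, simplified=True),
    ModelSpec("GRU", bidirectional=True, simplified=True),
    ModelSpec("LSTM", cnn_front=True),
    ModelSpec("GRU", cnn_front=True),
    ModelSpec("LSTM", bidirectional=True, cnn_front=True),
    ModelSpec("GRU", bidirectional=True, cnn_front=True),
    ModelSpec("LSTM", bidirectional=True, cnn_front=True, simplified=True),
    ModelSpec("GRU", bidirectional=True, cnn_front=True, simplified=True),
]


@dataclass
class PredictionSequence:
    """Per-frame detection scores in [0, 1] for one recording and task."""

    scores: np.ndarray
    task: str
    frame_times: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        if self.frame_times is None:
            # center of the pooled frame group on the 0.016-s base grid
            factor = N_FRAMES / len(self.scores)
            self.frame_times = (np.arange(len(self.scores)) * factor
                                + (factor - 1) / 2.0) * FRAME_STEP_S
        self.frame_times = np.asarray(self.frame_times, dtype=float)

    def __len__(self) -> int:
        return len(self.scores)


def _rnn_layer(cell: str, n_in: int, units: int, bidirectional: bool,
               rng: np.random.Generator):
    cls = LSTM if cell == "LSTM" else GRU
    if bidirectional:
        return Bidirectional(cls(n_in, units, rng), cls(n_in, units, rng))
    return cls(n_in, units, rng)


def build_model(spec: ModelSpec, n_features: int = N_FEATURES,
                seed: int = 0) -> SequenceModel:
    """Construct an initialized (untrained) detector for ``spec``."""
    rng = np.random.default_rng(seed)
    layers = []
    d = n_features
    if spec.cnn_front:
        front = ConvFront(n_features, rng)
        layers.append(front)
        d = front.n_out
    units = spec.rnn_units
    ndir = 2 if spec.bidirectional else 1
    layers.append(_rnn_layer(spec.cell, d, units, spec.bidirectional, rng))
    layers.append(_rnn_layer(spec.cell, units * ndir, units, spec.bidirectional, rng))
    layers.append(Dense(units * ndir, HEAD_UNITS, activation="relu", rng=rng))
    layers.append(Dense(HEAD_UNITS, 1, activation="linear", rng=rng))
    meta = {"spec": spec.__dict__ | {"name": spec.name},
            "n_features": n_features, "seed": seed}
    return SequenceModel(layers, meta=meta)


def parameter_count(spec: ModelSpec, n_features: int = N_FEATURES) -> int:
    """Trainable-parameter count of the built model (counted, not tabulated)."""
    return build_model(spec, n_features).n_params


def predict(model: SequenceModel, features: FeatureMatrix | np.ndarray,
            task: str = "I") -> PredictionSequence:
    """Run one recording through a detector; scores are sigmoid outputs."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if x.ndim != 2:
        raise ValueError("expected a single (frames x features) matrix")
    if x.shape[1] != model.meta.get("n_features", x.shape[1]):
        raise ValueError(
            f"feature width {x.shape[1]} does not match model "
            f"({model.meta.get('n_features')})")
    scores = model.scores(x[None])[0]
    return PredictionSequence(scores=scores, task=task)


def make_folds(manifest: Manifest | pd.DataFrame, k: int = 5,
               seed: int = 0) -> np.ndarray:
    """Assign each manifest row to one of ``k`` folds, whole groups intact.

    Groups (subject/day keys) are shuffled under ``seed``, then greedily
    placed into the currently smallest fold, largest groups first, so
    fold sizes are as balanced as the grouping permits.  Returns an
    integer fold id per manifest row.
    """
    frame = manifest.frame if isinstance(manifest, Manifest) else manifest
    groups = frame["group"].to_numpy()
    unique, counts = np.unique(groups, return_counts=True)
    if len(unique) < k:
        raise ValueError(
            f"insufficient groups: {len(unique)} groups for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    # stable sort by descending size, ties broken by the shuffled order
    by_size = sorted(order, key=lambda i: -counts[i])
    fold_sizes = np.zeros(k, dtype=int)
    group_fold: dict[str, int] = {}
    for i in by_size:
        f = int(np.argmin(fold_sizes))
        group_fold[unique[i]] = f
        fold_sizes[f] += counts[i]
    return np.array([group_fold[g] for g in groups], dtype=int)
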