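"""Pathologic-finding classification and longitudinal disease activity.

The finding classifier here is a deliberately small convolutional model
trained on tomogram phantoms: it exists to make the pipeline end-to-end
testable and to define the pluggable interface (any object with a
``predict(crop) -> FindingResult`` method drops in).  Clinical-grade finding
detection is out of scope.

Disease activity compares consecutive visits of one (patient, laterality)
series.  The first visit is always "not applicable".  Later visits are
labeled by the relative change of central macular thickness (CMT):
improvement when CMT falls by at least the threshold fraction, worsening
when it rises by at least the threshold or a finding newly appears, and
stationary otherwise.  A finding that merely resolves does not, by itself,
label the visit an improvement.  The default threshold of 0.25 is the
midpoint of the interval consistent with the published example course
(a −31% drop labeled improvement; −13%, +8%, +1% and −20.6% changes all
labeled stationary), i.e. θ ∈ (0.206, 0.310].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import _nn
from ._nn import Parameter, Tensor, softmax_cross_entropy
from .area_explorer import ContentClass, detect_content_class
from .synthetic import render_tomogram_phantom

__all__ = [
    "FINDING_VOCABULARY",
    "ActivityLabel",
    "ACTIVITY_DISPLAY",
    "FindingResult",
    "VisitObservation",
    "FindingModel",
    "train_finding_classifier",
    "classify_finding",
    "derive_activity",
    "DEFAULT_ACTIVITY_THRESHOLD",
    "save_finding_model",
    "load_finding_model",
]

logger = logging.getLogger("octreport.finding_activity")

FINDING_VOCABULARY = ("subretinal_fluid", "macular_edema")
DEFAULT_ACTIVITY_THRESHOLD = 0.25


class ActivityLabel:
    NOT_APPLICABLE = "not_applicable"
    IMPROVEMENT = "improvement"
    WORSENING = "worsening"
    STATIONARY = "stationary"


ACTIVITY_DISPLAY = {
    ActivityLabel.NOT_APPLICABLE: "N/A",
    ActivityLabel.IMPROVEMENT: "Improvement",
    ActivityLabel.WORSENING: "Worsening",
    ActivityLabel.STATIONARY: "Stationary",
}


@dataclass(frozen=True)
class FindingResult:
    labels: dict[str, bool]
    probabilities: dict[str, float]

    @staticmethod
    def from_probabilities(probs: dict[str, float]) -> "FindingResult":
        return FindingResult(labels={k: p >= 0.5 for k, p in probs.items()},
                             probabilities=dict(probs))


@dataclass(frozen=True)
class VisitObservation:
    """One visit of a (patient, laterality) series, time-ordered by date."""

    visit_date: str  # ISO date
    cmt: float | None  # central macular thickness, µm (None = missing)
    findings: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# baseline convolutional finding classifier

_INPUT = 48


class FindingModel:
    """Small conv net over resized tomogram crops; one 2-way head per finding."""

    def __init__(self, vocabulary: tuple[str, ...] = FINDING_VOCABULARY, seed: int = 0):
        self.vocabulary = tuple(vocabulary)
        rng = np.random.default_rng(seed)
        c1, c2, fc = 8, 16, 32
        flat = c2 * (_INPUT // 4) * (_INPUT // 4)
        n_out = 2 * len(self.vocabulary)
        self.params = {
            "c1w": Parameter(rng.normal(0, np.sqrt(2 / 9), (c1, 9))),
            "c1b": Parameter(np.zeros(c1)),
            "c2w": Parameter(rng.normal(0, np.sqrt(2 / (c1 * 9)), (c2, c1 * 9))),
            "c2b": Parameter(np.zeros(c2)),
            "f1w": Parameter(rng.normal(0, np.sqrt(2 / flat), (flat, fc))),
            "f1b": Parameter(np.zeros(fc)),
            "f2w": Parameter(rng.normal(0, np.sqrt(1 / fc), (fc, n_out))),
            "f2b": Parameter(np.zeros(n_out)),
        }

    def parameters(self):
        return list(self.params.values())

    @staticmethod
    def _prepare(crop: np.ndarray) -> np.ndarray:
        arr = np.asarray(crop)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        img = Image.fromarray(arr.astype(np.uint8)).resize((_INPUT, _INPUT),
                                                           Image.BILINEAR)
        x = np.asarray(img, dtype=np.float32)
        return (x - x.mean()) / (x.std() + 1e-3)

    def _logits(self, batch: np.ndarray) -> Tensor:
        p = self.params
        t = Tensor(batch)
        t = t.conv2d(p["c1w"], p["c1b"]).relu().maxpool2()
        t = t.conv2d(p["c2w"], p["c2b"]).relu().maxpool2()
        B = t.shape[0]
        t = t.reshape(B, -1)
        t = (t @ p["f1w"] + p["f1b"]).relu()
        return t @ p["f2w"] + p["f2b"]

    def predict_batch(self, crops: list[np.ndarray]) -> list[FindingResult]:
        x = np.stack([self._prepare(c) for c in crops])[:, None, :, :]
        logits = self._logits(x).data
        out = []
        for b in range(len(crops)):
            probs = {}
            for i, name in enumerate(self.vocabulary):
                z = logits[b, 2 * i:2 * i + 2]
                z = z - z.max()
                e = np.exp(z)
                probs[name] = float(e[1] / e.sum())
            out.append(FindingResult.from_probabilities(probs))
        return out

    def predict(self, crop: np.ndarray) -> FindingResult:
        return self.predict_batch([crop])[0]

    def state(self):
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state):
        for k, v in state.items():
            self.params[k].data = v.astype(np.float32).copy()


def train_finding_classifier(n_train: int = 240, seed: int = 0,
                             vocabulary: tuple[str, ...] = FINDING_VOCABULARY,
                             iterations: int = 300, batch_size: int = 16,
                             size: tuple[int, int] = (440, 170)) -> FindingModel:
    """Train the baseline classifier on randomly flagged phantoms."""
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for _ in range(n_train):
        flags = {name: bool(rng.random() < 0.5) for name in vocabulary}
        crops.append(render_tomogram_phantom(flags, int(rng.integers(0, 2**31 - 1)),
                                             size=size))
        labels.append(flags)
    model = FindingModel(vocabulary, seed=int(rng.integers(0, 2**31 - 1)))
    prepared = np.stack([model._prepare(c) for c in crops])[:, None, :, :]
    y = np.array([[int(l[name]) for name in vocabulary] for l in labels])
    opt = _nn.AdaDelta(model.parameters())
    ones = np.ones(batch_size, dtype=np.float32)
    for _ in range(iterations):
        take = rng.integers(0, n_train, size=batch_size)
        logits = model._logits(prepared[take])
        loss = None
        for i in range(len(vocabulary)):
            part = softmax_cross_entropy(logits[:, 2 * i:2 * i + 2], y[take, i], ones)
            loss = part if loss is None else loss + part
        opt.zero_grad()
        loss.backward()
        _nn.clip_global_norm(model.parameters())
        opt.step()
    return model


def classify_finding(crop: np.ndarray, model: FindingModel) -> FindingResult:
    """Per-finding probabilities for a tomogram crop (deterministic)."""
    cls = detect_content_class(crop)
    if cls != ContentClass.TOMOGRAM:
        raise ValueError(f"classify_finding requires a tomogram crop, got {cls}")
    return model.predict(crop)


def save_finding_model(model: FindingModel, path) -> None:
    _nn.save_params(path, model.params, {"vocabulary": list(model.vocabulary)})


def load_finding_model(path) -> FindingModel:
    arrays, meta = _nn.load_params(path)
    model = FindingModel(tuple(meta["vocabulary"]))
    model.load_state(arrays)
    return model


# ---------------------------------------------------------------------------
# disease activity

def derive_activity(series: list[VisitObservation],
                    threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> list[str | None]:
    """Label each visit of a time-ordered series.

    Visit 1 is always not_applicable.  Visit k>1 is improvement when relative
    CMT change <= -threshold; worsening when relative change >= +threshold or
    any finding newly appears; else stationary.  A label depends only on
    visits k-1 and k.  Visits with a missing CMT (or a missing previous CMT)
    are skipped with a warning (label None).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dates = [v.visit_date for v in series]
    if dates != sorted(dates):
        raise ValueError("series must be sorted by visit date")
    labels: list[str | None] = []
    for k, visit in enumerate(series):
        if k == 0:
            labels.append(ActivityLabel.NOT_APPLICABLE)
            continue
        prev = series[k - 1]
        if visit.cmt is None or prev.cmt is None:
            logger.warning("visit %s: missing CMT, activity label skipped",
                           visit.visit_date)
            labels.append(None)
            continue
        rel = (visit.cmt - prev.cmt) / prev.cmt
        newly = any(visit.findings.get(name, False) and not prev.findings.get(name, False)
                    for name in visit.findings)
        if rel <= -threshold:
            labels.append(ActivityLabel.IMPROVEMENT)
        elif rel >= threshold or newly:
            labels.append(ActivityLabel.WORSENING)
        else:
            labels.append(ActivityLabel.STATIONARY)
    return labels
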