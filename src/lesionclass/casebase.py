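"""Case-based-reasoning layer: store case representations, retrieve the
nearest cases for a query, and orchestrate the full image pipeline.

A case couples the network embedding (the default retrieval
representation), the 12-feature descriptor, the class label, and a
free-text recommendation.  Retrieval is exact k-nearest-neighbour search
under Euclidean distance with deterministic ties (by case id); the
predicted class of a query is the majority label among the retrieved
cases.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import classify, cnn, features, segment
from .errors import (DimensionError, ParameterError, StageError)
from .synthgen import BENIGN, MALIGNANT


@dataclass
class CaseRecord:
    case_id: str
    embedding: np.ndarray
    feature_vector: np.ndarray | None
    label: str
    image_path: str = ""
    recommendation_text: str = ""


class CaseBase:
    """An in-memory, persistable collection of :class:`CaseRecord`.

    All embeddings (and feature vectors, when present) must share one
    dimension; mismatching records are rejected.
    """

    def __init__(self, provenance: dict | None = None):
        self.records: list[CaseRecord] = []
        self.provenance = provenance or {}

    def __len__(self) -> int:
        return len(self.records)

    def add_case(self, record: CaseRecord) -> "CaseBase":
        emb = np.asarray(record.embedding, dtype=float).ravel()
        if self.records and emb.shape[0] != self.records[0].embedding.shape[0]:
            raise DimensionError(
                f"embedding dim {emb.shape[0]} != base dim "
                f"{self.records[0].embedding.shape[0]}")
        if record.feature_vector is not None:
            fv = np.asarray(record.feature_vector, dtype=float).ravel()
            if fv.shape[0] != features.N_FEATURES:
                raise DimensionError("feature vector must have 12 entries")
            record.feature_vector = fv
        record.embedding = emb
        self.records.append(record)
        return self

    def retrieve(self, query_embedding: np.ndarray, k: int = 5,
                 representation: str = "embedding"
                 ) -> list[tuple[CaseRecord, float]]:
        """The k nearest cases (ascending distance), ties by case_id."""
        if not self.records:
            raise ParameterError("cannot retrieve from an empty case base")
        if k < 1:
            raise ParameterError("k must be >= 1")
        q = np.asarray(query_embedding, dtype=float).ravel()
        if representation == "embedding":
            M = np.stack([r.embedding for r in self.records])
        elif representation == "features":
            M = np.stack([r.feature_vector for r in self.records])
        else:
            raise ParameterError(f"unknown representation {representation!r}")
        if q.shape[0] != M.shape[1]:
            raise DimensionError(
                f"query dim {q.shape[0]} != base dim {M.shape[1]}")
        d = np.linalg.norm(M - q, axis=1)
        order = sorted(range(len(d)),
                       key=lambda i: (d[i], self.records[i].case_id))
        return [(self.records[i], float(d[i])) for i in order[:k]]

    def predict(self, query_embedding: np.ndarray, k: int = 5,
                representation: str = "embedding") -> tuple[str, float]:
        """Majority label among the k nearest; score = malignant fraction."""
        top = self.retrieve(query_embedding, k, representation)
        votes = [r.label == MALIGNANT for r, _ in top]
        score = float(np.mean(votes))
        if score > 0.5:
            label = MALIGNANT
        elif score < 0.5:
            label = BENIGN
        else:
            label = top[0][0].label
        return label, score

    # -- persistence --------------------------------------------------------

    def save(self, directory: str) -> None:
        """JSON manifest + binary embedding matrix (.npy)."""
        os.makedirs(directory, exist_ok=True)
        emb = np.stack([r.embedding for r in self.records]) if self.records \
            else np.zeros((0, 0))
        np.save(os.path.join(directory, "embeddings.npy"), emb)
        manifest = {
            "provenance": self.provenance,
            "records": [{
                "case_id": r.case_id,
                "label": r.label,
                "image_path": r.image_path,
                "recommendation_text": r.recommendation_text,
                "feature_vector": None if r.feature_vector is None
                else list(r.feature_vector),
            } for r in self.records],
        }
        with open(os.path.join(directory, "casebase.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory: str) -> "CaseBase":
        with open(os.path.join(directory, "casebase.json")) as fh:
            manifest = json.load(fh)
        emb = np.load(os.path.join(directory, "embeddings.npy"))
        base = cls(provenance=manifest.get("provenance", {}))
        for i, rec in enumerate(manifest["records"]):
            fv = rec.get("feature_vector")
            base.add_case(CaseRecord(
                case_id=rec["case_id"], embedding=emb[i],
                feature_vector=None if fv is None else np.asarray(fv),
                label=rec["label"], image_path=rec.get("image_path", ""),
                recommendation_text=rec.get("recommendation_text", "")))
        return base


def provenance_hash(obj) -> str:
    """Short stable hash for provenance bookkeeping."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """Everything :func:`classify_image` needs to run end to end."""

    seg_config: segment.SegmentationConfig = field(
        default_factory=segment.SegmentationConfig)
    normalization: "features.NormalizationParams | None" = None
    classical_model: "classify.TrainedModel | None" = None
    network: "cnn.Network | None" = None
    case_base: CaseBase | None = None
    retrieval_k: int = 5
    input_size: tuple[int, int] | None = None  # network input (h, w)


def classify_image(config: PipelineConfig, image: np.ndarray,
                   poi: list[tuple[int, int]] | None) -> dict:
    """Run segment -> features -> classifier and/or CNN -> retrieval.

    Returns a consolidated report; any stage failure is re-raised as
    :class:`StageError` carrying the stage name.
    """
    report: dict = {}
    mask = None
    if config.classical_model is not None:
        if not poi:
            raise StageError("segment", ParameterError(
                "segmentation requires at least one POI"))
        try:
            mask = segment.segment_lesion(image, poi, config.seg_config)
        except Exception as e:  # noqa: BLE001 - stage identity wrapper
            raise StageError("segment", e) from e
        try:
            fv = features.extract_features(image, mask)
        except Exception as e:  # noqa: BLE001
            raise StageError("features", e) from e
        try:
            label, score = classify.predict(config.classical_model, fv)
        except Exception as e:  # noqa: BLE001
            raise StageError("classify", e) from e
        report.update({"label": label, "score": score,
                       "mask_area": int(mask.sum()),
                       "feature_vector": fv})
    if config.network is not None:
        try:
            x = cnn.images_to_tensor([image], size=config.input_size)
            emb = config.network.embed(x)[0]
        except Exception as e:  # noqa: BLE001
            raise StageError("cnn", e) from e
        report["embedding"] = emb
        probs = config.network.predict_proba(x)[0]
        report["cnn_probabilities"] = probs
        report.setdefault("score", float(probs[1]))
        report.setdefault("label", (BENIGN, MALIGNANT)[int(probs.argmax())])
        if config.case_base is not None:
            try:
                top = config.case_base.retrieve(emb, config.retrieval_k)
                label, score = config.case_base.predict(emb, config.retrieval_k)
            except Exception as e:  # noqa: BLE001
                raise StageError("retrieve", e) from e
            report["top_cases"] = [
                {"case_id": r.case_id, "label": r.label, "distance": d,
                 "recommendation_text": r.recommendation_text}
                for r, d in top]
            report["label"] = label
            report["score"] = score
    if not report:
        raise ParameterError("pipeline config names no classifier")
    return report
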