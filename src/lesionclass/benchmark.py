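"""The reference end-to-end synthetic benchmark.

One fixed experiment definition shared by the test suite, the acceptance
script and the README example: 150 training and 50 test images per class
at 64x64 (mirroring the 300-train / 100-test first-round split of the
study conditions), with

* the handcrafted route: segmentation -> 12 features -> min-max
  normalization -> k-NN (k=5) and RBF-SVM;
* the deep route: the 16-layer network at width multiplier 0.25 with the
  ``reference`` filler profile, trained 12 epochs with momentum SGD
  (lr 0.001, momentum 0.9, batch 25);
* case-based retrieval over the trained network's FC7 embeddings.

Everything is a pure function of the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import casebase, classify, cnn, evaluate, features, segment, synthgen

N_TRAIN_PER_CLASS = 150
N_TEST_PER_CLASS = 50
IMAGE_SIZE = (64, 64)
WIDTH_MULT = 0.25
CNN_EPOCHS = 12


@dataclass
class BenchmarkData:
    train_cases: list
    test_cases: list
    X_train: np.ndarray
    X_test: np.ndarray
    y_train: list[str]
    y_test: list[str]
    mean_jaccard: float


def _labels_int(cases) -> np.ndarray:
    return np.array([0 if c.label == synthgen.BENIGN else 1 for c in cases])


def prepare_data(seed: int, n_train: int = N_TRAIN_PER_CLASS,
                 n_test: int = N_TEST_PER_CLASS) -> BenchmarkData:
    """Generate both splits and run segmentation + feature extraction."""
    presets = synthgen.default_presets(image_size=IMAGE_SIZE)
    train = synthgen.generate_dataset(n_train, presets, seed=seed)
    test = synthgen.generate_dataset(n_test, presets, seed=seed + 1)
    jac = []

    def featurize(cases):
        rows = []
        for c in cases:
            mask = segment.segment_lesion(c.image, c.poi)
            jac.append(segment.jaccard(mask, c.truth_mask))
            rows.append(features.extract_features(c.image, mask))
        return np.array(rows)

    X_train = featurize(train)
    X_test = featurize(test)
    return BenchmarkData(train_cases=train, test_cases=test,
                         X_train=X_train, X_test=X_test,
                         y_train=[c.label for c in train],
                         y_test=[c.label for c in test],
                         mean_jaccard=float(np.mean(jac)))


def classical_results(data: BenchmarkData, seed: int) -> dict:
    """Accuracy + AUC of k-NN and SVM on the handcrafted features."""
    norm = features.fit_normalizer(data.X_train)
    out = {}
    models = {
        "knn": classify.knn_fit(data.X_train, data.y_train, k=5,
                                normalization=norm),
        "svm": classify.svm_fit(data.X_train, data.y_train,
                                normalization=norm, seed=seed),
    }
    for name, model in models.items():
        preds, scores = classify.predict_batch(model, data.X_test)
        counts = evaluate.confusion_from_predictions(data.y_test, preds)
        rep = evaluate.metrics(counts)
        curves = evaluate.roc_pr_curves(data.y_test, scores)
        out[name] = {"accuracy": rep.accuracy,
                     "f_measure": rep.f_measure,
                     "auc_roc": curves["auc_roc"],
                     "model": model, "counts": counts}
    out["normalization"] = norm
    return out


def cnn_results(data: BenchmarkData, seed: int,
                epochs: int = CNN_EPOCHS) -> dict:
    """Train the reduced-width network and evaluate on the test split."""
    Xtr = cnn.images_to_tensor([c.image for c in data.train_cases])
    Xte = cnn.images_to_tensor([c.image for c in data.test_cases])
    ytr = _labels_int(data.train_cases)
    yte = _labels_int(data.test_cases)
    spec = cnn.build_lesion_net((*IMAGE_SIZE, 3), K=2,
                                width_mult=WIDTH_MULT,
                                filler_profile="reference")
    config = cnn.TrainConfig(epochs=epochs, seed=seed)
    net, history = cnn.train(spec, Xtr, ytr, config)
    probs = net.predict_proba(Xte)
    preds = [synthgen.BENIGN if p == 0 else synthgen.MALIGNANT
             for p in probs.argmax(axis=1)]
    counts = evaluate.confusion_from_predictions(data.y_test, preds)
    rep = evaluate.metrics(counts)
    curves = evaluate.roc_pr_curves(data.y_test, probs[:, 1])
    return {"network": net, "loss_history": history,
            "accuracy": rep.accuracy, "f_measure": rep.f_measure,
            "auc_roc": curves["auc_roc"], "counts": counts,
            "train_tensor": Xtr, "test_tensor": Xte,
            "probs": probs}


def retrieval_results(data: BenchmarkData, cnn_out: dict, k: int = 5) -> dict:
    """Build a case base from training embeddings; classify test queries."""
    net = cnn_out["network"]
    emb_train = net.embed(cnn_out["train_tensor"])
    emb_test = net.embed(cnn_out["test_tensor"])
    base = casebase.CaseBase(provenance={
        "network": casebase.provenance_hash(net.spec)})
    for i, case in enumerate(data.train_cases):
        base.add_case(casebase.CaseRecord(
            case_id=f"train_{i:04d}", embedding=emb_train[i],
            feature_vector=data.X_train[i], label=case.label))
    preds, scores = [], []
    for q in emb_test:
        label, score = base.predict(q, k=k)
        preds.append(label)
        scores.append(score)
    counts = evaluate.confusion_from_predictions(data.y_test, preds)
    rep = evaluate.metrics(counts)
    return {"case_base": base, "accuracy": rep.accuracy, "counts": counts,
            "scores": np.array(scores)}
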