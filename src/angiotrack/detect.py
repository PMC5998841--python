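"""CNN-based sliding-window cell detection.

Labeled 100x100 templates (cell-centred vs background) are augmented by
rotation, flipping and additive Gaussian noise, used to train the patch
classifier with five-fold cross-validation, and the trained classifier
is slid over each registered frame; connected clusters of positive
windows yield one detection at the cluster centroid.  Candidates
outside the (dilated) vessel mask are discarded, since the cells remain
within the vessel.

The detector is pluggable: the tracker equally accepts detection tables
from CSV, so tracking is testable independently of training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.model_selection import KFold

from .cnn import CnnArchitecture, PatchCNN
from .vessel import VesselModel


@dataclass
class Detection:
    """One cell candidate: frame index, position, classifier score."""

    frame: int
    x: float
    y: float
    score: float


def augment_templates(patches, labels, rng_seed=0, noise_sigma=0.02):
    """Twelve variants per template.

    Each base patch yields {original, three 90-degree rotations, a
    horizontal and a vertical flip} plus a Gaussian-noise copy of each
    of those six.  Labels propagate; the output is deterministic under
    ``rng_seed``.
    """
    patches = np.asarray(patches, dtype=np.float32)
    if patches.ndim != 3 or patches.shape[1] != patches.shape[2]:
        raise ValueError("patches must be (n, size, size)")
    rng = np.random.default_rng(rng_seed)
    labels = np.asarray(labels)
    out, out_labels = [], []
    for patch, lab in zip(patches, labels):
        geo = [patch,
               np.rot90(patch, 1), np.rot90(patch, 2), np.rot90(patch, 3),
               patch[:, ::-1], patch[::-1, :]]
        for g in geo:
            out.append(np.ascontiguousarray(g))
            out_labels.append(lab)
        for g in geo:
            out.append(g + rng.normal(0.0, noise_sigma,
                                      g.shape).astype(np.float32))
            out_labels.append(lab)
    return np.stack(out), np.asarray(out_labels)


def train_classifier(patches, labels, arch: CnnArchitecture | None = None,
                     folds: int = 5, rng_seed: int = 0, epochs: int = 6,
                     lr: float = 0.003, batch_size: int = 32,
                     momentum: float = 0.9, cross_validate: bool = True):
    """Train the patch CNN; optionally report k-fold CV accuracy.

    The bank is randomly partitioned into ``folds`` equal-sized
    subsamples; each fold in turn serves as validation for a model
    trained on the rest, and the mean held-out accuracy is returned
    alongside a final model trained on all data.
    """
    patches = np.asarray(patches, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training bank must contain both classes")
    if len(patches) < folds:
        raise ValueError("bank smaller than the number of folds")
    cv_accuracy = float("nan")
    if cross_validate:
        accs = []
        kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        for i, (tr, va) in enumerate(kf.split(patches)):
            model = PatchCNN(arch, rng=rng_seed + 10 + i)
            model.fit(patches[tr], labels[tr], epochs=epochs, lr=lr,
                      batch_size=batch_size, momentum=momentum,
                      rng=rng_seed + 20 + i)
            accs.append(float(np.mean(model.predict(patches[va])
                                      == labels[va])))
        cv_accuracy = float(np.mean(accs))
    model = PatchCNN(arch, rng=rng_seed)
    model.fit(patches, labels, epochs=epochs, lr=lr, batch_size=batch_size,
              momentum=momentum, rng=rng_seed + 1)
    return model, cv_accuracy


def _patch_scores(image, model: PatchCNN, stride: int):
    """Naive stride-grid patch scoring (any stride)."""
    size = model.arch.input_size
    h, w = image.shape
    rows = np.arange(0, h - size + 1, stride)
    cols = np.arange(0, w - size + 1, stride)
    scores = np.zeros((len(rows), len(cols)), dtype=np.float32)
    batch, index = [], []
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            batch.append(image[r:r + size, c:c + size])
            index.append((i, j))
            if len(batch) == 64:
                p = model.predict_proba(np.stack(batch))[:, 1]
                for (ii, jj), v in zip(index, p):
                    scores[ii, jj] = v
                batch, index = [], []
    if batch:
        p = model.predict_proba(np.stack(batch))[:, 1]
        for (ii, jj), v in zip(index, p):
            scores[ii, jj] = v
    return scores


def sliding_window_detect(image, model: PatchCNN,
                          vessel: VesselModel | None = None,
                          stride: int = 4, score_threshold: float = 0.5,
                          min_cluster: int = 4, vessel_dilation: int = 10,
                          frame: int = 0) -> pd.DataFrame:
    """Detect cell candidates in one registered frame.

    Windows are scored on a ``stride`` grid (the default stride of 4
    uses the fast convolutional evaluation, which is exact for this
    architecture); pixels with score >= ``score_threshold`` are grouped
    into 8-connected clusters, clusters smaller than ``min_cluster``
    windows are dropped as speckle, and each remaining cluster emits
    one detection at its centroid.  Candidates outside the vessel mask
    dilated by ``vessel_dilation`` px are discarded.
    """
    image = np.asarray(image, dtype=float)
    if stride == model.arch.pool ** 2:
        probs, stride_eff, offset = model.score_map(image)
    else:
        probs = _patch_scores(image, model, stride)
        stride_eff, offset = stride, model.arch.input_size // 2
    positive = probs >= score_threshold
    lab, n = ndi.label(positive, structure=np.ones((3, 3)))
    rows = []
    if n:
        sizes = ndi.sum_labels(positive, lab, index=np.arange(1, n + 1))
        coms = ndi.center_of_mass(probs, lab, index=np.arange(1, n + 1))
        maxs = ndi.maximum(probs, lab, index=np.arange(1, n + 1))
        for size, (ci, cj), smax in zip(sizes, coms, maxs):
            if size < min_cluster:
                continue
            x = cj * stride_eff + offset
            y = ci * stride_eff + offset
            rows.append((frame, float(x), float(y), float(smax)))
    det = pd.DataFrame(rows, columns=["frame", "x", "y", "score"])
    if vessel is not None and len(det):
        dil = ndi.binary_dilation(vessel.mask, iterations=vessel_dilation)
        keep = []
        h, w = dil.shape
        for _, row in det.iterrows():
            r, c = int(round(row.y)), int(round(row.x))
            keep.append(0 <= r < h and 0 <= c < w and bool(dil[r, c]))
        det = det[np.array(keep, dtype=bool)].reset_index(drop=True)
    return det


def detections_from_csv(path) -> list:
    """Load per-frame detection tables from a single CSV."""
    df = pd.read_csv(path)
    frames = sorted(df["frame"].unique())
    return [df[df["frame"] == k].reset_index(drop=True) for k in frames]
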