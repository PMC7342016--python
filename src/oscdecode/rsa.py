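"""Representational similarity analysis between neural and model geometries.

Neural RDMs reuse pairwise cross-decoding accuracies as dissimilarities (the
easier two objects are to classify, the more dissimilar their patterns);
model RDMs are 1 - Pearson correlations of per-object feature vectors, or a
binary +1/-1 code for superordinate category membership.  RDMs are compared
with Spearman rank correlation over the 66 lower-triangle entries of the
12 x 12 matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

#: the study's 12 objects in their 4 superordinate categories
DEFAULT_CATEGORIES: dict[str, str] = {
    "butterfly": "animal", "chicken": "animal", "sheep": "animal",
    "ear": "body_part", "eye": "body_part", "hand": "body_part",
    "apple": "plant", "carrot": "plant", "rose": "plant",
    "car": "man_made", "chair": "man_made", "violin": "man_made",
}


@dataclass
class RDM:
    """Symmetric condition x condition representational dissimilarity matrix."""

    matrix: np.ndarray
    labels: list[str]
    source: str = "model"  # {"neural_cross", "neural_within", "model"}
    dissimilarity_kind: str = "1-pearson"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.matrix[off], self.matrix.T[off], equal_nan=True):
            raise ValueError("RDM must be symmetric off the diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        """The n*(n-1)/2 below-diagonal entries (66 for 12 objects)."""
        il = np.tril_indices(self.n, k=-1)
        return self.matrix[il]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(matrix=df.to_numpy(), labels=list(df.index), **kwargs)


def neural_rdm_from_cluster(
    per_pair: np.ndarray,
    cluster_mask: np.ndarray,
    labels: list[str],
    source: str = "neural_cross",
) -> RDM:
    """Average the pairwise-accuracy slices over the cells of a cluster.

    ``per_pair``: (..., n_obj, n_obj) with leading map axes matching
    ``cluster_mask`` (time, or train-time x test-time); diagonal may be NaN.
    """
    per_pair = np.asarray(per_pair)
    mask = np.asarray(cluster_mask, dtype=bool)
    if per_pair.shape[: mask.ndim] != mask.shape:
        raise ValueError("cluster mask shape does not match per-pair map")
    if not mask.any():
        raise ValueError("empty cluster mask")
    mat = per_pair[mask].mean(axis=0)
    mat = np.array(mat, dtype=float)
    np.fill_diagonal(mat, 0.0)
    return RDM(matrix=mat, labels=labels, source=source,
               dissimilarity_kind="decoding accuracy")


# within_task_rdm is the same cluster-averaging contract applied to the 1-D
# within-task time course (mask over time points)
def within_task_rdm(
    per_pair: np.ndarray, cluster_mask: np.ndarray, labels: list[str]
) -> RDM:
    return neural_rdm_from_cluster(
        per_pair, cluster_mask, labels, source="neural_within"
    )


def model_rdm(
    features: np.ndarray, labels: list[str], stage_name: str = "model"
) -> RDM:
    """1 - Pearson correlation between per-object feature rows."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("features must be (n_objects, n_features)")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 feature columns for a correlation")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("zero-variance feature row")
    mat = 1.0 - np.corrcoef(X)
    np.fill_diagonal(mat, 0.0)
    return RDM(matrix=mat, labels=list(labels), source="model",
               dissimilarity_kind="1-pearson")


def category_rdm(
    category_assignment: dict[str, str] | None = None,
    labels: list[str] | None = None,
) -> RDM:
    """Binary category model: same category -> -1, different -> +1."""
    assignment = category_assignment or DEFAULT_CATEGORIES
    labels = labels or list(assignment)
    missing = [o for o in labels if o not in assignment]
    if missing:
        raise ValueError(f"objects without category: {missing}")
    cats = np.array([assignment[o] for o in labels], dtype=object)
    mat = np.where(cats[:, None] == cats[None, :], -1.0, 1.0)
    np.fill_diagonal(mat, 0.0)
    return RDM(matrix=mat, labels=list(labels), source="model",
               dissimilarity_kind="binary +-1")


#: convolutional-block grouping of the 19 VGG-19 layers: conv layers between
#: successive max-pooling stages are averaged, fully connected layers kept
VGG_GROUPS: tuple[tuple[int, ...], ...] = (
    (0, 1), (2, 3), (4, 5, 6, 7), (8, 9, 10, 11), (12, 13, 14, 15),
    (16,), (17,), (18,),
)


def aggregate_vgg_rdms(layer_rdms: list[RDM]) -> list[RDM]:
    """Aggregate 19 layer RDMs into 8 block RDMs (5 conv blocks + 3 FC)."""
    if len(layer_rdms) != 19:
        raise ValueError(f"expected 19 layer RDMs, got {len(layer_rdms)}")
    labels = layer_rdms[0].labels
    out = []
    for gi, group in enumerate(VGG_GROUPS, start=1):
        mats = [layer_rdms[k].matrix for k in group]
        out.append(
            RDM(matrix=np.mean(mats, axis=0), labels=labels, source="model",
                dissimilarity_kind=layer_rdms[group[0]].dissimilarity_kind)
        )
    return out


#: auditory model architecture: 2 spectrotemporal stages; 11 DNN layers =
#: 3 shared conv + (2 conv + 2 FC) per branch x 2 branches
AUDITORY_SPECTROTEMPORAL_STAGES = ("auditory_spectrogram", "cortical_features")
AUDITORY_DNN_LAYERS = tuple(
    ["shared_conv1", "shared_conv2", "shared_conv3"]
    + [f"{branch}_{layer}" for branch in ("genre", "word")
       for layer in ("conv1", "conv2", "fc1", "fc2")]
)


def auditory_model_rdms(
    stage_features: dict[str, np.ndarray], labels: list[str]
) -> dict[str, RDM]:
    """One 1-Pearson RDM per auditory model stage (2 + 11 = 13 total)."""
    expected = AUDITORY_SPECTROTEMPORAL_STAGES + AUDITORY_DNN_LAYERS
    missing = [s for s in expected if s not in stage_features]
    extra = [s for s in stage_features if s not in expected]
    if missing or extra:
        raise ValueError(
            f"auditory stage mismatch: missing {missing}, unexpected {extra}"
        )
    return {
        stage: model_rdm(stage_features[stage], labels, stage_name=stage)
        for stage in expected
    }


def compare_rdms(neural_rdms: list[RDM], model: RDM) -> np.ndarray:
    """Spearman R between each participant's neural RDM and one model RDM.

    Correlations use only the 66 lower-triangle entries; ties (e.g. the
    binary category model) get average ranks.  Returns one R per participant,
    ready for a group sign-permutation test against 0.
    """
    out = np.empty(len(neural_rdms))
    mv = model.lower_triangle()
    for k, neural in enumerate(neural_rdms):
        if neural.labels != model.labels:
            raise ValueError("RDM labels do not match")
        out[k] = spearmanr(neural.lower_triangle(), mv).statistic
    return out


@dataclass
class ModelFeatureSet:
    """External per-stage feature matrix (n_objects x n_features)."""

    stage_name: str
    features: np.ndarray
    model_family: str  # {visual_dnn, category, auditory_spectrotemporal, auditory_dnn}

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ValueError("features must be a 2-D object x feature matrix")


def load_feature_manifest(path: str | Path) -> list[ModelFeatureSet]:
    """Read a JSON manifest listing model stages and their feature CSVs.

    Manifest format: ``{"stages": [{"name": ..., "family": ..., "csv": ...},
    ...]}`` with CSV paths relative to the manifest; each CSV has one row per
    object (first column = object name).
    """
    import json

    path = Path(path)
    spec = json.loads(path.read_text())
    out = []
    for entry in spec["stages"]:
        df = pd.read_csv(path.parent / entry["csv"], index_col=0)
        out.append(
            ModelFeatureSet(
                stage_name=entry["name"],
                features=df.to_numpy(),
                model_family=entry["family"],
            )
        )
    return out
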