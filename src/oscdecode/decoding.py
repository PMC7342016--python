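"""Pairwise SVM decoding of oscillatory response patterns.

The decoding scheme follows the multivariate EEG/MEG decoding tradition:
single trials are averaged into four pseudo-trials per condition (25% random
shares, redrawn on every repeat), all 66 unordered pairs of the 12 objects
are discriminated with linear C-SVC classifiers (cost 1), and accuracies are
averaged over pairs, repeats and — for the cross-task analysis — both
train/test directions, with the direction average aligned on a fixed
perception-time x imagery-time grid.  Within-task decoding uses a
leave-one-pseudo-trial-out scheme with yoked training/testing times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .epochs import EpochSet
from .timefreq import (
    BandSpec,
    FrequencyGrid,
    TFEpochs,
    band_vectors,
    baseline_normalize,
    downsample,
    morlet_power,
)
from . import montage

try:  # fast path: the libsvm solver without per-call estimator overhead
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LOWLEVEL = True
except Exception:  # pragma: no cover - exercised only on other sklearn builds
    _HAVE_LOWLEVEL = False


# --------------------------------------------------------------------------
# linear pair classifier


@dataclass
class PairClassifier:
    """Binary linear maximum-margin classifier for one object pair.

    ``decision_function(x) > 0`` predicts the first class (``class_a``).
    """

    weights: np.ndarray
    bias: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict_a(self, X: np.ndarray) -> np.ndarray:
        """Boolean array: True where the first class is predicted."""
        return self.decision_function(X) > 0


def _fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Fit libsvm C-SVC (linear kernel); decision > 0 -> first label in y."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if _HAVE_LOWLEVEL:
        out = _libsvm.fit(X, y, svm_type=0, kernel="linear", C=C, tol=1e-3)
        support_vectors, sv_coef, intercept = out[1], out[3], out[4]
        w = sv_coef[0] @ support_vectors
        return w, float(intercept[0])
    from sklearn.svm import SVC  # pragma: no cover - fallback path

    m = SVC(kernel="linear", C=C).fit(X, y)
    sign = -1.0 if m.classes_[0] == y[0] else 1.0
    return sign * m.coef_[0], float(sign * m.intercept_[0])


def train_pair_classifier(
    class_a: np.ndarray, class_b: np.ndarray, C: float = 1.0
) -> PairClassifier:
    """Train a linear C-SVC on two exemplar sets (rows = exemplars)."""
    class_a = np.atleast_2d(class_a)
    class_b = np.atleast_2d(class_b)
    if class_a.shape[0] < 1 or class_b.shape[0] < 1:
        raise ValueError("need at least one exemplar per class")
    X = np.vstack([class_a, class_b])
    y = np.concatenate([np.zeros(len(class_a)), np.ones(len(class_b))])
    w, b = _fit_linear_svm(X, y, C)
    return PairClassifier(weights=w, bias=b)


# --------------------------------------------------------------------------
# pseudo-trials


@dataclass
class PseudoTrialSet:
    """Condition x pseudo-trial x ... averages of disjoint random trial shares."""

    vectors: np.ndarray  # (n_conditions, n_pseudo, ...)
    conditions: np.ndarray  # sorted condition labels
    n_pseudo: int


def make_pseudotrials(
    X: np.ndarray,
    conditions: np.ndarray,
    n_pseudo: int = 4,
    rng: np.random.Generator | None = None,
) -> PseudoTrialSet:
    """Average each condition's trials into ``n_pseudo`` disjoint random shares.

    With 4 pseudo-trials each is the mean of 25% of the available trials.
    Trials that do not divide evenly are dropped at random.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X)
    conditions = np.asarray(conditions)
    labels = np.unique(conditions)
    out = None
    for ci, label in enumerate(labels):
        idx = np.flatnonzero(conditions == label)
        if len(idx) < n_pseudo:
            raise ValueError(
                f"condition {label!r} has {len(idx)} trials < n_pseudo={n_pseudo}"
            )
        share = len(idx) // n_pseudo
        perm = rng.permutation(idx)[: share * n_pseudo].reshape(n_pseudo, share)
        means = X[perm].mean(axis=1)
        if out is None:
            out = np.empty((len(labels),) + means.shape, dtype=X.dtype)
        out[ci] = means
    return PseudoTrialSet(vectors=out, conditions=labels, n_pseudo=n_pseudo)


# --------------------------------------------------------------------------
# result containers


@dataclass
class TimeGenMatrix:
    """Cross-task time-generalization accuracies (percent).

    Axes are always perception-time x imagery-time, whichever task was used
    for training; ``per_pair`` stores the unaveraged 12 x 12 pairwise slices
    (symmetric, diagonal NaN).
    """

    accuracy: np.ndarray  # (n_tp, n_ti)
    per_pair: np.ndarray  # (n_tp, n_ti, n_obj, n_obj)
    perception_times: np.ndarray
    imagery_times: np.ndarray
    band: str
    n_repeats: int


@dataclass
class WithinTaskTimecourse:
    """Within-task leave-one-pseudo-trial-out accuracies (percent)."""

    accuracy: np.ndarray  # (n_times,)
    per_pair: np.ndarray  # (n_times, n_obj, n_obj)
    times: np.ndarray
    task: str
    band: str
    n_repeats: int


def _pair_scores(
    clf_w: np.ndarray,
    clf_b: float,
    test_a: np.ndarray,
    test_b: np.ndarray,
) -> np.ndarray:
    """Accuracy per test time; each test pseudo-trial scored individually.

    ``test_a``/``test_b``: (n_pseudo, n_features, n_test_times).  A decision
    value of exactly 0 earns half credit (unbiased for degenerate classifiers).
    """
    sa = np.einsum("pft,f->pt", test_a, clf_w) + clf_b
    sb = np.einsum("pft,f->pt", test_b, clf_w) + clf_b
    correct = (
        (sa > 0).sum(axis=0) + 0.5 * (sa == 0).sum(axis=0)
        + (sb < 0).sum(axis=0) + 0.5 * (sb == 0).sum(axis=0)
    )
    return correct / (test_a.shape[0] + test_b.shape[0])


class CrossTaskTimeGeneralizer(BaseEstimator):
    """Cross-task time-generalization decoder.

    Parameters
    ----------
    n_pseudo : int
        Pseudo-trials per condition (default 4; each averages 25% of trials).
    n_repeats : int
        Repeats with fresh pseudo-trial assignments (default 100).
    C : float
        SVM cost parameter (default 1).
    directions : {"both", "train_perception", "train_imagery"}
        Which train/test directions to run; "both" averages the two onto the
        same perception-time x imagery-time cell.
    random_state : int or None
        Seed for pseudo-trial assignment.

    Attributes
    ----------
    accuracy_ : ndarray (n_perception_times, n_imagery_times), percent.
    per_pair_ : ndarray (..., n_obj, n_obj), pairwise accuracies, percent.
    """

    def __init__(
        self,
        n_pseudo: int = 4,
        n_repeats: int = 100,
        C: float = 1.0,
        directions: str = "both",
        random_state: int | None = None,
    ):
        self.n_pseudo = n_pseudo
        self.n_repeats = n_repeats
        self.C = C
        self.directions = directions
        self.random_state = random_state

    def fit(
        self,
        X_perception: np.ndarray,
        y_perception: np.ndarray,
        X_imagery: np.ndarray,
        y_imagery: np.ndarray,
    ) -> "CrossTaskTimeGeneralizer":
        """Decode all (perception time, imagery time) combinations.

        ``X_*``: (n_trials, n_features, n_times) band pattern vectors.
        """
        Xp = np.asarray(X_perception, dtype=np.float64)
        Xi = np.asarray(X_imagery, dtype=np.float64)
        if Xp.shape[1] != Xi.shape[1]:
            raise ValueError("tasks must share the feature dimension")
        labels = np.unique(y_perception)
        if not np.array_equal(labels, np.unique(y_imagery)):
            raise ValueError("tasks must share condition labels")
        n_obj = len(labels)
        n_tp, n_ti = Xp.shape[2], Xi.shape[2]
        rng = np.random.default_rng(self.random_state)
        pairs = list(itertools.combinations(range(n_obj), 2))
        if self.directions not in ("both", "train_perception", "train_imagery"):
            raise ValueError(f"unknown directions {self.directions!r}")

        acc = np.zeros((n_tp, n_ti, n_obj, n_obj))
        pair_i = np.array([i for i, _ in pairs])
        pair_j = np.array([j for _, j in pairs])
        n_feat = Xp.shape[1]
        n_acc = 0
        for _ in range(self.n_repeats):
            pp = make_pseudotrials(Xp, y_perception, self.n_pseudo, rng).vectors
            pi = make_pseudotrials(Xi, y_imagery, self.n_pseudo, rng).vectors
            runs = []
            if self.directions in ("both", "train_perception"):
                runs.append(("P", pp, pi))
            if self.directions in ("both", "train_imagery"):
                runs.append(("I", pi, pp))
            for tag, train, test in runs:
                n_train_t = train.shape[-1]
                W = np.empty((len(pairs), n_feat))
                B = np.empty(len(pairs))
                test_i = np.ascontiguousarray(test[pair_i])  # (n_pairs, n_pseudo, f, n_te)
                test_j = np.ascontiguousarray(test[pair_j])
                for t in range(n_train_t):
                    for k, (i, j) in enumerate(pairs):
                        clf = train_pair_classifier(
                            train[i, :, :, t], train[j, :, :, t], C=self.C
                        )
                        W[k] = clf.weights
                        B[k] = clf.bias
                    # score each pair's two test sets at all test times at once
                    bias = B[:, None, None]
                    si = np.einsum("kpft,kf->kpt", test_i, W, optimize=True) + bias
                    sj = np.einsum("kpft,kf->kpt", test_j, W, optimize=True) + bias
                    a = 0.5 * (
                        (si > 0).mean(axis=1) + 0.5 * (si == 0).mean(axis=1)
                        + (sj < 0).mean(axis=1) + 0.5 * (sj == 0).mean(axis=1)
                    )  # (n_pairs, n_test_times)
                    # advanced indexing: [t, :, ii, jj] -> (n_pairs, n_te),
                    # [:, t, ii, jj] -> (n_tp, n_pairs)
                    for ii, jj in ((pair_i, pair_j), (pair_j, pair_i)):
                        if tag == "P":
                            acc[t, :, ii, jj] += a
                        else:
                            acc[:, t, ii, jj] += a.T
            n_acc += len(runs)
        acc /= n_acc * 1.0
        acc *= 100.0
        iu = np.triu_indices(n_obj, k=1)
        self.accuracy_ = acc[:, :, iu[0], iu[1]].mean(axis=-1)
        acc[:, :, np.arange(n_obj), np.arange(n_obj)] = np.nan
        self.per_pair_ = acc
        self.conditions_ = labels
        return self


class WithinTaskDecoder(BaseEstimator):
    """Within-task pairwise decoding with leave-one-pseudo-trial-out CV.

    Training and testing times are yoked; every repeat rotates the held-out
    pseudo-trial over all ``n_pseudo`` folds.
    """

    def __init__(
        self,
        n_pseudo: int = 4,
        n_repeats: int = 100,
        C: float = 1.0,
        random_state: int | None = None,
    ):
        self.n_pseudo = n_pseudo
        self.n_repeats = n_repeats
        self.C = C
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WithinTaskDecoder":
        X = np.asarray(X, dtype=np.float64)
        labels = np.unique(y)
        n_obj = len(labels)
        n_t = X.shape[2]
        rng = np.random.default_rng(self.random_state)
        pairs = list(itertools.combinations(range(n_obj), 2))
        acc = np.zeros((n_t, n_obj, n_obj))
        for _ in range(self.n_repeats):
            ps = make_pseudotrials(X, y, self.n_pseudo, rng).vectors
            for fold in range(self.n_pseudo):
                train_idx = [k for k in range(self.n_pseudo) if k != fold]
                for t in range(n_t):
                    for i, j in pairs:
                        clf = train_pair_classifier(
                            ps[i, train_idx, :, t], ps[j, train_idx, :, t], C=self.C
                        )
                        a = _pair_scores(
                            clf.weights,
                            clf.bias,
                            ps[i, fold : fold + 1, :, t : t + 1],
                            ps[j, fold : fold + 1, :, t : t + 1],
                        )[0]
                        acc[t, i, j] += a
                        acc[t, j, i] += a
        acc /= self.n_repeats * self.n_pseudo
        acc *= 100.0
        iu = np.triu_indices(n_obj, k=1)
        self.accuracy_ = acc[:, iu[0], iu[1]].mean(axis=-1)
        acc[:, np.arange(n_obj), np.arange(n_obj)] = np.nan
        self.per_pair_ = acc
        self.conditions_ = labels
        return self


# --------------------------------------------------------------------------
# configured wrappers


@dataclass
class DecodingConfig:
    """Windows, strides and repeat counts for the decoding analyses.

    Analysis windows are half-open ms intervals on the 50 Hz time grid;
    strides subsample the decoded time points (1 = every 20 ms bin).
    """

    n_pseudo: int = 4
    n_repeats: int = 100
    C: float = 1.0
    perception_window: tuple[float, float] = (0.0, 800.0)
    imagery_window: tuple[float, float] = (0.0, 2500.0)
    perception_stride: int = 1
    imagery_stride: int = 1
    mode: str = "average"
    seed: int = 0


def _windowed_features(
    tf: TFEpochs, band: BandSpec, window: tuple[float, float], stride: int, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    if lo < tf.times[0] or hi > tf.times[-1] + 1000.0 / tf.sampling_rate:
        raise ValueError("analysis window outside decomposed epoch")
    mask = (tf.times >= lo) & (tf.times < hi)
    feats = band_vectors(tf, band, mode=mode)[..., mask][..., ::stride]
    times = tf.times[mask][::stride]
    return feats, times


def cross_task_timegen(
    tf_perception: TFEpochs,
    tf_imagery: TFEpochs,
    band: BandSpec,
    config: DecodingConfig | None = None,
    directions: str = "both",
) -> TimeGenMatrix:
    """Cross-task time-generalization decoding for one frequency band."""
    cfg = config or DecodingConfig()
    Xp, tp = _windowed_features(
        tf_perception, band, cfg.perception_window, cfg.perception_stride, cfg.mode
    )
    Xi, ti = _windowed_features(
        tf_imagery, band, cfg.imagery_window, cfg.imagery_stride, cfg.mode
    )
    est = CrossTaskTimeGeneralizer(
        n_pseudo=cfg.n_pseudo,
        n_repeats=cfg.n_repeats,
        C=cfg.C,
        directions=directions,
        random_state=cfg.seed,
    ).fit(Xp, tf_perception.object_id, Xi, tf_imagery.object_id)
    return TimeGenMatrix(
        accuracy=est.accuracy_,
        per_pair=est.per_pair_,
        perception_times=tp,
        imagery_times=ti,
        band=band.name,
        n_repeats=cfg.n_repeats,
    )


def within_task_cv(
    tf: TFEpochs,
    band: BandSpec,
    config: DecodingConfig | None = None,
    task: str | None = None,
) -> WithinTaskTimecourse:
    """Within-task decoding time course for one frequency band."""
    cfg = config or DecodingConfig()
    task = task or str(tf.task[0])
    window = cfg.perception_window if task == "perception" else cfg.imagery_window
    stride = cfg.perception_stride if task == "perception" else cfg.imagery_stride
    X, times = _windowed_features(tf, band, window, stride, cfg.mode)
    est = WithinTaskDecoder(
        n_pseudo=cfg.n_pseudo,
        n_repeats=cfg.n_repeats,
        C=cfg.C,
        random_state=cfg.seed,
    ).fit(X, tf.object_id)
    return WithinTaskTimecourse(
        accuracy=est.accuracy_,
        per_pair=est.per_pair_,
        times=times,
        task=task,
        band=band.name,
        n_repeats=cfg.n_repeats,
    )


def electrode_subset(data: EpochSet | TFEpochs, subset: str):
    """Restrict epochs or TF data to the anterior or posterior electrode half."""
    if subset not in ("anterior", "posterior"):
        raise ValueError("subset must be 'anterior' or 'posterior'")
    halves = montage.electrode_halves(data.channels)
    return data.select_channels(halves[subset])


def peak_alpha_band(
    perception_epochs: EpochSet,
    config: DecodingConfig | None = None,
    baseline_window: tuple[float, float] = (-500.0, -300.0),
    target_rate: float = 50.0,
) -> dict:
    """Participant-specific peak alpha frequency from within-task decoding.

    A 1 Hz-resolution Morlet decomposition on the integer grid 7-14 Hz feeds
    within-task perception decoding of each 3-bin band {f-1, f, f+1} for
    f = 8..13; the peak is the frequency with the highest time-averaged
    accuracy (ties break to the lowest frequency) and the returned band is
    the peak and its two neighbors.
    """
    cfg = config or DecodingConfig()
    grid = FrequencyGrid(tuple(float(f) for f in range(7, 15)))
    tf = morlet_power(perception_epochs, grid)
    tf = baseline_normalize(tf, baseline_window)
    tf = downsample(tf, target_rate)
    accs = {}
    for f in range(8, 14):
        band = BandSpec(
            name=f"alpha_{f}", nominal_range=(f - 1, f + 1),
            member_bins=(f - 8, f - 7, f - 6),
        )
        tc = within_task_cv(tf, band, cfg, task="perception")
        accs[f] = float(tc.accuracy.mean())
    peak = min((f for f in accs), key=lambda f: (-accs[f], f))
    return {
        "peak_freq": peak,
        "band_range": (peak - 1, peak + 1),
        "band": BandSpec(
            name="individual_alpha",
            nominal_range=(peak - 1, peak + 1),
            member_bins=(peak - 8, peak - 7, peak - 6),
        ),
        "grid": grid,
        "accuracies": accs,
    }


def alpha_power_split(
    tf_perception: TFEpochs,
    alpha_band: BandSpec,
    window: tuple[float, float] = (0.0, 800.0),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split perception trials by net alpha power change and equalize counts.

    Trials whose mean baseline-normalized alpha power (over channels and the
    post-stimulus window) is > 0 dB count as enhanced, the rest as
    suppressed; the larger class is randomly subsampled to the smaller one.
    Returns (enhanced_idx, suppressed_idx).
    """
    if not tf_perception.normalized:
        raise ValueError("alpha power split needs baseline-normalized data")
    if rng is None:
        rng = np.random.default_rng()
    mask = (tf_perception.times >= window[0]) & (tf_perception.times < window[1])
    alpha = tf_perception.power[:, :, list(alpha_band.member_bins), :][..., mask]
    stat = alpha.mean(axis=(1, 2, 3))
    enhanced = np.flatnonzero(stat > 0)
    suppressed = np.flatnonzero(stat <= 0)
    if len(enhanced) == 0 or len(suppressed) == 0:
        raise ValueError(
            f"degenerate alpha split: {len(enhanced)} enhanced / "
            f"{len(suppressed)} suppressed trials"
        )
    n = min(len(enhanced), len(suppressed))
    if len(enhanced) > n:
        enhanced = np.sort(rng.choice(enhanced, size=n, replace=False))
    if len(suppressed) > n:
        suppressed = np.sort(rng.choice(suppressed, size=n, replace=False))
    return enhanced, suppressed


def broadband_timegen(
    perception: EpochSet,
    imagery: EpochSet,
    config: DecodingConfig | None = None,
    baseline_window: tuple[float, float] = (-600.0, 0.0),
    directions: str = "both",
) -> TimeGenMatrix:
    """Cross-task time generalization on raw (baseline-corrected) voltages.

    The identical pseudo-trial and classification machinery is applied to
    electrode voltage patterns at the acquisition resolution, without any
    frequency decomposition.
    """
    cfg = config or DecodingConfig()
    out = []
    for eps, window, stride in (
        (perception, cfg.perception_window, cfg.perception_stride),
        (imagery, cfg.imagery_window, cfg.imagery_stride),
    ):
        eps = eps.baseline_correct(baseline_window)
        eps = eps.crop(*window)
        out.append((eps.data[..., ::stride], eps.times[::stride], eps.object_id))
    (Xp, tp, yp), (Xi, ti, yi) = out
    est = CrossTaskTimeGeneralizer(
        n_pseudo=cfg.n_pseudo,
        n_repeats=cfg.n_repeats,
        C=cfg.C,
        directions=directions,
        random_state=cfg.seed,
    ).fit(Xp, yp, Xi, yi)
    return TimeGenMatrix(
        accuracy=est.accuracy_,
        per_pair=est.per_pair_,
        perception_times=tp,
        imagery_times=ti,
        band="broadband",
        n_repeats=cfg.n_repeats,
    )


def broadband_within(
    epochs: EpochSet,
    config: DecodingConfig | None = None,
    baseline_window: tuple[float, float] = (-600.0, 0.0),
) -> WithinTaskTimecourse:
    """Within-task decoding on raw voltage patterns (yoked times)."""
    cfg = config or DecodingConfig()
    task = str(epochs.task[0])
    window = cfg.perception_window if task == "perception" else cfg.imagery_window
    stride = cfg.perception_stride if task == "perception" else cfg.imagery_stride
    eps = epochs.baseline_correct(baseline_window).crop(*window)
    X, times = eps.data[..., ::stride], eps.times[::stride]
    est = WithinTaskDecoder(
        n_pseudo=cfg.n_pseudo, n_repeats=cfg.n_repeats, C=cfg.C, random_state=cfg.seed
    ).fit(X, eps.object_id)
    return WithinTaskTimecourse(
        accuracy=est.accuracy_,
        per_pair=est.per_pair_,
        times=times,
        task=task,
        band="broadband",
        n_repeats=cfg.n_repeats,
    )
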