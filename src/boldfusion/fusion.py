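"""Feature fusion, the fully-connected classifier, and the two-stage cascade.

The feature fusion module (FFM) concatenates, per signal and in fixed
order, the LSTM branch features ``fL`` (100), the scalogram-CNN branch
features ``fR`` (2048) and the frequency-domain block ``fF`` (607) into a
2755-vector, reduces it to 512 MRMR-selected features, and classifies with
a two-layer fully-connected network.

Stage I labels the task (emotion / memory / motor / resting). Stage II
re-runs the FFM on sub-phase segments with presets adapted to the shorter
200-sample inputs: emotion runs are cut into three equal thirds (high /
medium / low support), memory runs into their design-defined encode and
recall blocks. Two separate Stage II heads (3-class and 2-class) are the
default; a combined 5-class head is available for parity with treating all
sub-phases as one problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .lstm import STAGE1_PRESET, STAGE2_PRESET, LstmFeaturizer, lstm_encode
from .mrmr import MrmrSelector
from .resnet import FEATURE_DIM, ResNet50Features
from .signals import (
    BoldSignal,
    SignalPool,
    extract_design_segments,
    pad_to_length,
    split_into_phases,
    zero_mean_detrend,
)
from .spectral import cwt_scalogram, render_scalogram_image, spectral_block

__all__ = [
    "FeatureBundle",
    "CascadePrediction",
    "fuse_features",
    "compute_spectral_features",
    "compute_cnn_features",
    "FcnClassifier",
    "FfmClassifier",
    "CascadeClassifier",
    "stage1_classify",
    "stage2_classify",
    "run_cascade",
    "STAGE1_FFM",
    "STAGE2_FFM",
]

#: Branch dimensions of the Stage I "paper preset" (600-sample inputs).
STAGE1_FFM = {"fL": 100, "fR": FEATURE_DIM, "fF": 607, "fused": 2755,
              "n_selected": 512, "dwt_levels": 8, "input_length": 600}
#: Stage II preset for 200-sample sub-phase segments: 6 DWT levels keep the
#: periodized decomposition valid, and the MRMR target scales down to 256.
STAGE2_FFM = {"fL": 100, "fR": FEATURE_DIM, "fF": 207, "fused": 2355,
              "n_selected": 256, "dwt_levels": 6, "input_length": 200}

EMOTION_PHASES = ("high", "medium", "low")
MEMORY_PHASES = ("encode", "recall")


@dataclass
class FeatureBundle:
    """Per-signal branch features and their fusion, in fixed L-R-F order."""

    fL: np.ndarray
    fR: np.ndarray
    fF: np.ndarray
    fused: np.ndarray
    selected: np.ndarray | None = None
    signal_id: str = ""


@dataclass
class CascadePrediction:
    """Stage I task prediction plus optional Stage II sub-phase predictions."""

    signal_id: str
    stage1_label: str
    stage1_scores: dict[str, float]
    stage2: list[tuple[int, str, dict[str, float]]] = field(default_factory=list)


def fuse_features(fL=None, fR=None, fF=None, expected: dict | None = None) -> np.ndarray:
    """Concatenate enabled branch features in the fixed order L, R, F.

    Disabled (None) branches are skipped, supporting ablation runs. When
    ``expected`` (a preset dict) is given, present branch lengths are
    validated against it.
    """
    parts = []
    for name, vec in (("fL", fL), ("fR", fR), ("fF", fF)):
        if vec is None:
            continue
        vec = np.asarray(vec)
        if expected is not None and vec.shape[-1] != expected[name]:
            raise ValueError(
                f"{name} has length {vec.shape[-1]}, preset expects {expected[name]}"
            )
        parts.append(vec)
    if not parts:
        raise ValueError("at least one branch must be enabled")
    return np.concatenate(parts, axis=-1)


def compute_spectral_features(X, tr_seconds: float = 1.0, wavelet: str = "haar",
                              levels: int = 8) -> np.ndarray:
    """Frequency-domain block ``fF`` for each row of (n, T) signals."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return np.stack(
        [spectral_block(row, tr_seconds, wavelet, levels).combined for row in X]
    )


def compute_cnn_features(X, encoder: ResNet50Features, n_scales: int = 64,
                         cwt_wavelet: str = "cmor1.5-1.0") -> np.ndarray:
    """Scalogram-CNN branch ``fR`` for each row of (n, T) signals.

    Renders each signal's CWT scalogram to a 224x224 image and encodes it
    with the fixed-weight residual CNN.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    images = np.stack(
        [
            render_scalogram_image(cwt_scalogram(row, n_scales=n_scales, wavelet=cwt_wavelet))
            for row in X
        ]
    )
    return encoder.transform(images)


class FcnClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer fully-connected softmax classifier over selected features.

    One ReLU hidden layer (default width 128) followed by a softmax output
    over the classes, trained with Adam on cross-entropy; features are
    standardised internally since the fused branches live on very different
    scales. Deterministic under ``random_state``.
    """

    def __init__(self, hidden: int = 128, lr: float = 1e-3, max_iter: int = 300,
                 batch_size: int = 256, alpha: float = 1e-4, random_state: int = 0):
        self.hidden = hidden
        self.lr = lr
        self.max_iter = max_iter
        self.batch_size = batch_size
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training labels are degenerate (single class)")
        self.scaler_ = StandardScaler().fit(X)
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(self.hidden,),
            activation="relu",
            solver="adam",
            learning_rate_init=self.lr,
            max_iter=self.max_iter,
            batch_size=min(self.batch_size, X.shape[0]),
            alpha=self.alpha,
            random_state=self.random_state,
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.net_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict(self.scaler_.transform(np.asarray(X)))

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self.scaler_.transform(np.asarray(X)))


class FfmClassifier(BaseEstimator, ClassifierMixin):
    """Feature-fusion classifier: branch features -> MRMR -> FCN.

    Operates on conditioned, uniformly padded signals, shape (n, T). The
    branch extractors follow the Stage I preset by default (T=600: fL 100,
    fR 2048, fF 607, fused 2755, 512 selected); ``preset=STAGE2_FFM``
    adapts the spectral levels and selection size to 200-sample segments.
    Branches can be disabled individually for ablation studies.
    """

    def __init__(
        self,
        preset: dict | None = None,
        use_lstm: bool = True,
        use_cnn: bool = True,
        use_spectral: bool = True,
        lstm_hidden=STAGE1_PRESET["hidden_sizes"],
        lstm_dropout=STAGE1_PRESET["dropout"],
        lstm_lr: float = 1e-3,
        lstm_epochs: int = 30,
        lstm_batch_size: int = 256,
        cnn_seed: int = 0,
        n_scales: int = 64,
        cwt_wavelet: str = "cmor1.5-1.0",
        dwt_wavelet: str = "haar",
        tr_seconds: float = 1.0,
        n_selected: int | None = None,
        mrmr_criterion: str = "MID",
        mrmr_bins: int = 8,
        fcn_hidden: int = 128,
        fcn_lr: float = 1e-3,
        fcn_max_iter: int = 300,
        random_state: int = 0,
    ):
        self.preset = preset
        self.use_lstm = use_lstm
        self.use_cnn = use_cnn
        self.use_spectral = use_spectral
        self.lstm_hidden = lstm_hidden
        self.lstm_dropout = lstm_dropout
        self.lstm_lr = lstm_lr
        self.lstm_epochs = lstm_epochs
        self.lstm_batch_size = lstm_batch_size
        self.cnn_seed = cnn_seed
        self.n_scales = n_scales
        self.cwt_wavelet = cwt_wavelet
        self.dwt_wavelet = dwt_wavelet
        self.tr_seconds = tr_seconds
        self.n_selected = n_selected
        self.mrmr_criterion = mrmr_criterion
        self.mrmr_bins = mrmr_bins
        self.fcn_hidden = fcn_hidden
        self.fcn_lr = fcn_lr
        self.fcn_max_iter = fcn_max_iter
        self.random_state = random_state

    def _preset(self) -> dict:
        return self.preset if self.preset is not None else STAGE1_FFM

    def _branch_features(self, X, cnn_features=None, spectral_features=None):
        """Per-branch feature matrices (None for disabled branches)."""
        X = np.asarray(X, dtype=np.float64)
        fL = fR = fF = None
        if self.use_lstm:
            check_is_fitted(self, "lstm_")
            fL = lstm_encode(X, self.lstm_.params_)
        if self.use_cnn:
            fR = (
                np.asarray(cnn_features)
                if cnn_features is not None
                else compute_cnn_features(X, self.cnn_, self.n_scales, self.cwt_wavelet)
            )
        if self.use_spectral:
            fF = (
                np.asarray(spectral_features)
                if spectral_features is not None
                else compute_spectral_features(
                    X, self.tr_seconds, self.dwt_wavelet, self._preset()["dwt_levels"]
                )
            )
        return fL, fR, fF

    def featurize(self, X, cnn_features=None, spectral_features=None) -> np.ndarray:
        """Fused (pre-selection) feature matrix for conditioned signals."""
        fL, fR, fF = self._branch_features(X, cnn_features, spectral_features)
        return fuse_features(fL, fR, fF)

    def fit(self, X, y, cnn_features=None, spectral_features=None):
        """Fit branches, MRMR selection and the FCN on training signals only.

        ``cnn_features`` / ``spectral_features`` allow passing precomputed
        branch matrices (these extractors are unfitted deterministic
        transforms, so sharing them across folds leaks nothing).
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        expected_t = self._preset()["input_length"]
        if X.ndim != 2 or X.shape[1] != expected_t:
            raise ValueError(
                f"expected conditioned signals of length {expected_t}, got {X.shape}"
            )
        if self.use_lstm:
            self.lstm_ = LstmFeaturizer(
                hidden_sizes=tuple(self.lstm_hidden),
                dropout=tuple(self.lstm_dropout),
                lr=self.lstm_lr,
                epochs=self.lstm_epochs,
                batch_size=self.lstm_batch_size,
                random_state=self.random_state,
            ).fit(X, y)
        if self.use_cnn:
            self.cnn_ = ResNet50Features(seed=self.cnn_seed)
        fused = self.featurize(X, cnn_features, spectral_features)
        m = self.n_selected if self.n_selected is not None else self._preset()["n_selected"]
        self.selector_ = MrmrSelector(
            n_features_to_select=min(m, fused.shape[1]),
            criterion=self.mrmr_criterion,
            bins=self.mrmr_bins,
        ).fit(fused, y)
        self.fcn_ = FcnClassifier(
            hidden=self.fcn_hidden,
            lr=self.fcn_lr,
            max_iter=self.fcn_max_iter,
            random_state=self.random_state,
        ).fit(self.selector_.transform(fused), y)
        self.classes_ = self.fcn_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_features(self, X, cnn_features=None, spectral_features=None):
        check_is_fitted(self, "selector_")
        return self.selector_.transform(
            self.featurize(X, cnn_features, spectral_features)
        )

    def predict(self, X, cnn_features=None, spectral_features=None):
        return self.fcn_.predict(self.decision_features(X, cnn_features, spectral_features))

    def predict_proba(self, X, cnn_features=None, spectral_features=None):
        return self.fcn_.predict_proba(
            self.decision_features(X, cnn_features, spectral_features)
        )

    def bundles(self, X, cnn_features=None, spectral_features=None,
                signal_ids=None) -> list[FeatureBundle]:
        """Per-signal :class:`FeatureBundle` views (for inspection/export)."""
        fL, fR, fF = self._branch_features(X, cnn_features, spectral_features)
        fused = fuse_features(fL, fR, fF)
        sel = self.selector_.transform(fused) if hasattr(self, "selector_") else None
        n = fused.shape[0]
        ids = signal_ids if signal_ids is not None else [f"{i:05d}" for i in range(n)]
        out = []
        for i in range(n):
            out.append(
                FeatureBundle(
                    fL=fL[i] if fL is not None else None,
                    fR=fR[i] if fR is not None else None,
                    fF=fF[i] if fF is not None else None,
                    fused=fused[i],
                    selected=sel[i] if sel is not None else None,
                    signal_id=str(ids[i]),
                )
            )
        return out


def _condition_segment(seg: BoldSignal, target: int) -> np.ndarray:
    return pad_to_length(zero_mean_detrend(seg), target).values


def _emotion_segments(signal: BoldSignal, n_segments: int, target: int):
    """Equal-thirds segments of a conditioned emotion run, conditioned again."""
    return [
        _condition_segment(seg, target) for seg in split_into_phases(signal, n_segments)
    ]


class CascadeClassifier(BaseEstimator):
    """Two-stage task and sub-phase classifier over a signal pool.

    Stage I assigns one of the four task labels to every conditioned,
    padded signal. Signals labelled emotion or memory are routed to Stage
    II, where their sub-phase segments are re-featurised with the Stage II
    FFM preset and classified into high/medium/low support (emotion,
    equal thirds) or encode/recall (memory, design blocks).

    ``stage2_mode='split'`` trains separate 3-class and 2-class heads;
    ``'combined'`` trains one 5-class head over all sub-phase segments.
    """

    def __init__(
        self,
        stage1_params: dict | None = None,
        stage2_params: dict | None = None,
        stage2_mode: str = "split",
        n_segments_emotion: int = 3,
        random_state: int = 0,
    ):
        self.stage1_params = stage1_params
        self.stage2_params = stage2_params
        self.stage2_mode = stage2_mode
        self.n_segments_emotion = n_segments_emotion
        self.random_state = random_state

    def _make_stage1(self) -> FfmClassifier:
        kwargs = dict(self.stage1_params or {})
        kwargs.setdefault("random_state", self.random_state)
        return FfmClassifier(preset=STAGE1_FFM, **kwargs)

    def _make_stage2(self) -> FfmClassifier:
        kwargs = dict(self.stage2_params or {})
        kwargs.setdefault("random_state", self.random_state)
        kwargs.setdefault("lstm_hidden", STAGE2_PRESET["hidden_sizes"])
        kwargs.setdefault("lstm_dropout", STAGE2_PRESET["dropout"])
        return FfmClassifier(preset=STAGE2_FFM, **kwargs)

    # -- training -----------------------------------------------------------

    def _collect_stage2_training(self, conditioned: SignalPool):
        em_X, em_y, mem_X, mem_y = [], [], [], []
        t2 = STAGE2_FFM["input_length"]
        for sig in conditioned:
            if sig.task_label == "emotion":
                segs = _emotion_segments(sig, self.n_segments_emotion, t2)
                labels = sig.subphase_labels
                if len(labels) != len(segs):
                    continue  # no usable phase labels for this run
                em_X.extend(segs)
                em_y.extend(labels)
            elif sig.task_label == "memory":
                for seg, label in extract_design_segments(sig):
                    mem_X.append(_condition_segment(seg, t2))
                    mem_y.append(label)
        return (np.asarray(em_X), np.asarray(em_y), np.asarray(mem_X), np.asarray(mem_y))

    def fit(self, pool: SignalPool):
        if self.stage2_mode not in ("split", "combined"):
            raise ValueError("stage2_mode must be 'split' or 'combined'")
        conditioned = pool.conditioned()
        X = conditioned.to_matrix()
        y = conditioned.task_labels()
        self.stage1_ = self._make_stage1().fit(X, y)
        em_X, em_y, mem_X, mem_y = self._collect_stage2_training(conditioned)
        if self.stage2_mode == "split":
            self.stage2_emotion_ = (
                self._make_stage2().fit(em_X, em_y) if len(em_X) else None
            )
            self.stage2_memory_ = (
                self._make_stage2().fit(mem_X, mem_y) if len(mem_X) else None
            )
        else:
            all_X = np.concatenate([em_X, mem_X]) if len(mem_X) else em_X
            all_y = np.concatenate([em_y, mem_y]) if len(mem_X) else em_y
            self.stage2_combined_ = (
                self._make_stage2().fit(all_X, all_y) if len(all_X) else None
            )
        self.target_length_ = conditioned.target_length
        return self

    # -- prediction ---------------------------------------------------------

    def _stage2_head(self, task: str) -> FfmClassifier | None:
        if self.stage2_mode == "combined":
            return getattr(self, "stage2_combined_", None)
        return (
            getattr(self, "stage2_emotion_", None)
            if task == "emotion"
            else getattr(self, "stage2_memory_", None)
        )

    def _predict_segments(self, head: FfmClassifier, segments) -> list:
        if head is None or not len(segments):
            return []
        proba = head.predict_proba(np.asarray(segments))
        out = []
        for i, p in enumerate(proba):
            j = int(np.argmax(p))
            scores = {c: float(v) for c, v in zip(head.classes_, p)}
            out.append((i, str(head.classes_[j]), scores))
        return out

    def stage2_for_signal(self, signal: BoldSignal, stage1_label: str) -> list:
        """Sub-phase predictions for one conditioned signal given its task."""
        if stage1_label not in ("emotion", "memory"):
            raise ValueError(
                f"stage 2 applies only to emotion/memory signals, got {stage1_label!r}"
            )
        t2 = STAGE2_FFM["input_length"]
        if stage1_label == "emotion":
            segs = _emotion_segments(signal, self.n_segments_emotion, t2)
        else:
            # memory sub-phases live on the design grid; without design
            # metadata (e.g. a misrouted signal) there is nothing to segment
            if signal.design is None:
                return []
            segs = [
                _condition_segment(seg, t2)
                for seg, _ in extract_design_segments(signal)
            ]
        return self._predict_segments(self._stage2_head(stage1_label), segs)

    def predict(self, pool: SignalPool) -> list[CascadePrediction]:
        """Run the full cascade over a pool; deterministic once fitted."""
        check_is_fitted(self, "stage1_")
        conditioned = pool.conditioned()
        X = conditioned.to_matrix()
        proba = self.stage1_.predict_proba(X)
        out = []
        for i, (sig, p) in enumerate(zip(conditioned, proba)):
            j = int(np.argmax(p))
            label = str(self.stage1_.classes_[j])
            scores = {c: float(v) for c, v in zip(self.stage1_.classes_, p)}
            pred = CascadePrediction(
                signal_id=f"{i:05d}", stage1_label=label, stage1_scores=scores
            )
            if label in ("emotion", "memory"):
                pred.stage2 = self.stage2_for_signal(sig, label)
            out.append(pred)
        return out


def stage1_classify(signal: BoldSignal, system: CascadeClassifier):
    """Task label and class scores for one conditioned, padded signal."""
    check_is_fitted(system, "stage1_")
    if len(signal) != system.target_length_:
        raise ValueError(
            f"signal length {len(signal)} != padded length {system.target_length_}; "
            "condition the pool first"
        )
    proba = system.stage1_.predict_proba(signal.values[None, :])[0]
    j = int(np.argmax(proba))
    return str(system.stage1_.classes_[j]), {
        c: float(v) for c, v in zip(system.stage1_.classes_, proba)
    }


def stage2_classify(signal: BoldSignal, stage1_label: str, system: CascadeClassifier):
    """Sub-phase predictions for one conditioned signal routed to Stage II."""
    check_is_fitted(system, "stage1_")
    return system.stage2_for_signal(signal, stage1_label)


def run_cascade(pool: SignalPool, system: CascadeClassifier) -> list[CascadePrediction]:
    """Stage I + conditional Stage II predictions for every pooled signal."""
    return system.predict(pool)
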