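"""Feature assembly, cancer-detection models, and tissue-of-origin classifier.

The per-sample feature vector has 1,029 named entries drawn from three
fragmentomic categories:

* fragmentation profile — Spearman correlation to the median
  healthy-control profile (1), count of new peaks (1), and per-window
  positive area, negative area and Euclidean distance (3 x 255);
* fragment size — the sample median fragment size (1);
* 5' end motif — the four genome-normalized end-base preferences (4), the
  256 4-mer motif proportions, and the motif diversity score (1).

Detection models are random forests (500 trees, 6 features per split)
trained MT-vs-control for each control group (HC, INF or BT); the forest's
malignancy probability is the MEFI score.  Training performance is
estimated by stratified tenfold cross-validation, and the classification
cutoff is fixed on the training scores by Youden's index.  The
tissue-of-origin classifier is a 6-class forest with the same parameters,
trained on MT samples passing the HC-control model at 99.5% specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .end_features import duplex_composition, motif_diversity_score, motif_spectrum
from .fragments import FragmentSet, motif_string
from .fsd import SiteProfile, compute_profile, profile_correlation
from .peaks import call_peaks, new_peaks, window_areas, window_distances, windows
from .reference import MtReference
from .end_features import end_base_preference, end_base_proportion

logger = logging.getLogger(__name__)

N_WINDOWS = 255
N_FEATURES = 1 + 1 + 3 * N_WINDOWS + 1 + 4 + 256 + 1  # = 1029

RF_N_TREES = 500
RF_FEATURES_PER_SPLIT = 6


def feature_names(n_windows: int = N_WINDOWS) -> list[str]:
    names = ["profile_correlation", "new_peak_count"]
    names += [f"pos_area_{k:03d}" for k in range(1, n_windows + 1)]
    names += [f"neg_area_{k:03d}" for k in range(1, n_windows + 1)]
    names += [f"euclid_{k:03d}" for k in range(1, n_windows + 1)]
    names += ["median_fragment_size"]
    names += [f"pref_{b}" for b in "ACGT"]
    names += [f"motif_{motif_string(i)}" for i in range(256)]
    names += ["mds"]
    return names


def assemble_features(
    profile_corr: float,
    new_peak_count: int,
    pos_area: np.ndarray,
    neg_area: np.ndarray,
    euclid: np.ndarray,
    median_fragment_size: float,
    end_preference: dict[str, float],
    motif_proportions: np.ndarray,
    mds: float,
    include_end_preference: bool = True,
) -> pd.Series:
    """Assemble the named 1,029-feature vector (order fixed).

    ``include_end_preference=False`` zeroes the four preference entries for
    the alternative reading in which base preference is excluded from the
    model input; the vector length and ordering are unchanged.
    """
    for arr, n in ((pos_area, N_WINDOWS), (neg_area, N_WINDOWS), (euclid, N_WINDOWS)):
        if len(arr) != n:
            raise ValueError(f"expected {n} window features, got {len(arr)}")
    if len(motif_proportions) != 256:
        raise ValueError("expected 256 motif proportions")
    pref = [end_preference[b] if include_end_preference else 0.0 for b in "ACGT"]
    values = np.concatenate(
        [
            [profile_corr, new_peak_count],
            pos_area,
            neg_area,
            euclid,
            [median_fragment_size],
            pref,
            motif_proportions,
            [mds],
        ]
    )
    vec = pd.Series(values, index=feature_names())
    if vec.isna().any():
        raise ValueError("feature vector contains missing values")
    return vec


def extract_features(
    fs: FragmentSet,
    ref: MtReference,
    gc_track: np.ndarray,
    reference_profile_z: np.ndarray,
    reference_peaks=None,
    include_end_preference: bool = True,
) -> pd.Series:
    """Full per-sample pipeline from fragments to the 1,029-feature vector."""
    prof = compute_profile(fs, gc_track)
    win = windows(ref.length, N_WINDOWS)
    if reference_peaks is None:
        reference_peaks = call_peaks(reference_profile_z)
    sample_peaks = call_peaks(prof.fsd_z)
    _, n_new = new_peaks(sample_peaks, reference_peaks, ref.length)
    pos, neg = window_areas(prof.fsd_z, win)
    euclid = window_distances(prof.fsd_z, reference_profile_z, win)
    corr = profile_correlation(prof.fsd_z, reference_profile_z)
    comp = duplex_composition(ref)
    prop = end_base_proportion(fs, ref)
    pref = end_base_preference(prop, comp)
    spec = motif_spectrum(fs, ref)
    return assemble_features(
        corr,
        n_new,
        pos,
        neg,
        euclid,
        prof.median_fragment_size,
        pref,
        spec.proportions,
        motif_diversity_score(spec),
        include_end_preference=include_end_preference,
    )


# ---------------------------------------------------------------------------
# Detection model
# ---------------------------------------------------------------------------

@dataclass
class DetectionModel:
    control_group: str
    forest: RandomForestClassifier
    youden_cutoff: float
    cv_scores: pd.Series  # out-of-fold MEFI scores on the training cohort
    cv_labels: pd.Series
    seed: int

    @property
    def cv_auc(self) -> float:
        return float(roc_auc_score((self.cv_labels == "MT").astype(int), self.cv_scores))


def _new_forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=RF_N_TREES,
        max_features=RF_FEATURES_PER_SPLIT,
        random_state=seed,
        n_jobs=1,
    )


def train_detection(
    features: pd.DataFrame,
    labels: pd.Series,
    control_group: str = "HC",
    seed: int = 0,
    n_folds: int = 10,
) -> DetectionModel:
    """Train an MT-vs-control random forest with tenfold CV scoring.

    Out-of-fold MEFI scores estimate training-cohort performance; the Youden
    cutoff is fixed on those scores.  The returned forest is refit on the
    full training cohort and is what scores validation samples.
    """
    mask = labels.isin(["MT", control_group])
    X = features.loc[mask]
    y = labels.loc[mask]
    if y.nunique() < 2:
        raise ValueError("need both MT and control samples to train")
    y_bin = (y == "MT").astype(int).to_numpy()

    min_class = int(np.bincount(y_bin).min())
    if min_class < n_folds:
        logger.warning("reducing CV folds from %d to %d (small class)", n_folds, min_class)
        n_folds = min_class
    cv_scores = pd.Series(index=X.index, dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y_bin):
        forest = _new_forest(seed)
        forest.fit(X.iloc[train_idx], y_bin[train_idx])
        cv_scores.iloc[test_idx] = forest.predict_proba(X.iloc[test_idx])[:, 1]

    cutoff = youden_cutoff(cv_scores.to_numpy(), y_bin)
    final = _new_forest(seed)
    final.fit(X, y_bin)
    return DetectionModel(
        control_group=control_group,
        forest=final,
        youden_cutoff=cutoff,
        cv_scores=cv_scores,
        cv_labels=y,
        seed=seed,
    )


def mefi_score(model: DetectionModel, features: pd.DataFrame) -> np.ndarray:
    """Malignancy probability from the trained forest, in [0, 1]."""
    want = list(model.forest.feature_names_in_)
    if list(features.columns) != want:
        if set(features.columns) != set(want):
            raise ValueError("feature names do not match the trained model")
        features = features[want]
    return model.forest.predict_proba(features)[:, 1]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    confusion: np.ndarray  # rows: true (control, case); cols: predicted


def youden_cutoff(scores: np.ndarray, y_bin: np.ndarray) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the higher cutoff (higher specificity), the
    conservative choice for a screening test.
    """
    fpr, tpr, thresholds = roc_curve(y_bin, scores)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    return float(thresholds[best].max())


def _delong_auc_ci(scores, y_bin, level=0.95):
    """DeLong variance of the empirical AUC via midrank placements."""
    pos = np.asarray(scores)[y_bin == 1]
    neg = np.asarray(scores)[y_bin == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        return (np.nan, np.nan)
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n  # placement of each case among controls
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    if n == 0:
        return (np.nan, np.nan)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return (float(ci.low), float(ci.high))


def evaluate(
    scores: np.ndarray, labels: np.ndarray, cutoff: float | str = "youden"
) -> EvalReport:
    """ROC AUC (with DeLong CI), Youden or fixed cutoff, and sens/spec with
    Clopper-Pearson CIs.  ``labels`` are binary (1 = case) or 'MT'/control
    strings."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == "MT").astype(int) if labels.dtype.kind in "UO" else labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for evaluation")
    auc = float(roc_auc_score(y, scores))
    if cutoff == "youden":
        cutoff = youden_cutoff(scores, y)
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    return EvalReport(
        auc=auc,
        auc_ci=_delong_auc_ci(scores, y),
        cutoff=float(cutoff),
        sensitivity=tp / (tp + fn),
        sensitivity_ci=_clopper_pearson(tp, tp + fn),
        specificity=tn / (tn + fp),
        specificity_ci=_clopper_pearson(tn, tn + fp),
        confusion=np.array([[tn, fp], [fn, tp]]),
    )


# ---------------------------------------------------------------------------
# Tissue of origin
# ---------------------------------------------------------------------------

def too_gate(
    scores: np.ndarray,
    labels: np.ndarray,
    target_specificity: float = 0.995,
) -> tuple[float, np.ndarray]:
    """Threshold achieving >= ``target_specificity`` on control scores and the
    mask of MT samples scoring above it.

    The threshold is the smallest control score such that the fraction of
    controls strictly above it stays within 1 - target_specificity.  An
    unreachable target falls back to the maximum control score (logged).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_mt = labels == "MT"
    controls = np.sort(scores[~is_mt])
    if controls.size == 0:
        raise ValueError("no control scores to set the threshold")
    allowed = int(np.floor((1 - target_specificity) * controls.size))
    if allowed >= controls.size:
        logger.warning("specificity target unreachable; using max control score")
        thr = float(controls[-1])
    else:
        thr = float(controls[controls.size - allowed - 1])
    selected = is_mt & (scores > thr)
    return thr, selected


@dataclass
class TooModel:
    forest: RandomForestClassifier
    classes: np.ndarray
    seed: int


def train_too(
    features: pd.DataFrame, cancer_types: pd.Series, seed: int = 0
) -> TooModel:
    """Multiclass random forest over cancer types (same forest parameters)."""
    counts = cancer_types.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"classes with <2 samples: {list(small.index)}")
    if counts.size < 2:
        raise ValueError("need at least two cancer types")
    forest = _new_forest(seed)
    forest.fit(features, cancer_types)
    return TooModel(forest=forest, classes=forest.classes_, seed=seed)


def predict_too(
    model: TooModel, features: pd.DataFrame, cancer_types: pd.Series | None = None
):
    """Class probabilities plus, when truth is given, confusion matrix and
    top-1/top-2 accuracy (true class within the two highest probabilities)."""
    proba = model.forest.predict_proba(features)
    result = {"proba": pd.DataFrame(proba, columns=model.classes, index=features.index)}
    if cancer_types is not None:
        truth = np.asarray(cancer_types)
        order = np.argsort(-proba, axis=1)
        top1 = model.classes[order[:, 0]]
        top2 = model.classes[order[:, :2]]
        result["top1_accuracy"] = float(np.mean(top1 == truth))
        result["top2_accuracy"] = float(
            np.mean([t in row for t, row in zip(truth, top2)])
        )
        result["confusion"] = pd.DataFrame(
            _sk_confusion_matrix(truth, top1, labels=model.classes),
            index=model.classes,
            columns=model.classes,
        )
    return result


# ---------------------------------------------------------------------------
# Leave one batch out
# ---------------------------------------------------------------------------

def leave_one_batch_out(
    features: pd.DataFrame,
    labels: pd.Series,
    batch_ids: pd.Series,
    control_group: str = "HC",
    seed: int = 0,
) -> dict[str, EvalReport | None]:
    """Train on all batches but one, evaluate on the held-out batch.

    Batches containing a single class get a None report (scores cannot form
    an ROC; logged).  Detects batch-confounded labels: if labels track
    batches, held-out AUC collapses toward chance.
    """
    batches = pd.unique(batch_ids)
    if len(batches) < 2:
        raise ValueError("need at least two batches")
    mask_all = labels.isin(["MT", control_group])
    out: dict[str, EvalReport | None] = {}
    for b in batches:
        held = (batch_ids == b) & mask_all
        train = (~(batch_ids == b)) & mask_all
        y_train = labels[train]
        if y_train.nunique() < 2:
            logger.warning("training split for batch %s has one class; skipped", b)
            out[str(b)] = None
            continue
        forest = _new_forest(seed)
        forest.fit(features[train], (y_train == "MT").astype(int))
        y_held = labels[held]
        scores = forest.predict_proba(features[held])[:, 1]
        if y_held.nunique() < 2:
            logger.warning("held-out batch %s has one class; AUC skipped", b)
            out[str(b)] = None
            continue
        out[str(b)] = evaluate(scores, y_held.to_numpy())
    return out
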