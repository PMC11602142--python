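"""Train, calibrate and apply the sequence-only fragility classifier.

Two classifier kinds are supported: an L2-penalised logistic model and
gradient-boosted trees (LightGBM). Hyperparameters are tuned by seeded
random search over fixed ranges (regularization strength 1e-2..1,
tolerance 1e-6..1e-3, iterations 100..1000 for the logistic model;
alpha/lambda 1e-8..10 log-scale, leaves 2..100, learning rate
0.001..0.1, estimators 1000..10000, feature/bagging fraction 0.1..1.0
for the trees), maximising cross-validated AUROC inside a 70/30
stratified train/test partition.

Downstream analyses: probability thresholds calibrated to target false
positive rates (step-function inversion, no interpolation, so the
empirical FPR never exceeds the target on the calibration set); sliding
genome scans; hot/cold fragility zones (top/bottom 5% of binned
predicted break density); and before/after delta fragility of
structural variants over a 1,960-base context.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_auc_score, roc_curve
from sklearn.model_selection import ParameterSampler, StratifiedKFold, train_test_split

from .feature_engineering import FeatureExtractor
from .genomic_io import GenomeSequence

SV_CONTEXT = 1960  # bases of sequence context centred on an SV (980 per side)

LOGISTIC_SPACE = {
    "C": loguniform(1e-2, 1.0),
    "tol": loguniform(1e-6, 1e-3),
    "max_iter": randint(100, 1001),
}

GBM_SPACE = {
    "reg_alpha": loguniform(1e-8, 10.0),
    "reg_lambda": loguniform(1e-8, 10.0),
    "num_leaves": randint(2, 101),
    "learning_rate": uniform(0.001, 0.099),
    "n_estimators": randint(1000, 10001),
    "colsample_bytree": uniform(0.1, 0.9),
    "subsample": uniform(0.1, 0.9),
}


def _split_matrix(matrix: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    if "label" not in matrix.columns:
        raise ValueError("feature matrix must carry a 'label' column")
    feats = [c for c in matrix.columns if c != "label"]
    X = matrix[feats].to_numpy(dtype=np.float64)
    y = matrix["label"].to_numpy(dtype=np.int64)
    return X, y, feats


def _make_estimator(kind: str, params: Dict, seed: int):
    if kind == "logistic":
        return LogisticRegression(penalty="l2", random_state=seed, **params)
    if kind == "gbm":
        import lightgbm as lgb

        return lgb.LGBMClassifier(
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            subsample_freq=1,
            n_jobs=1,
            verbose=-1,
            importance_type="gain",
            **params,
        )
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class FragilityModel:
    kind: str
    estimator: object
    feature_names: List[str]
    seed: int
    hyperparams: Dict
    thresholds: List[Tuple[float, float]] = field(default_factory=list)  # (target_fpr, cutoff)
    test_index: Optional[np.ndarray] = None
    extractor: Optional[FeatureExtractor] = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (break) class."""
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        return np.asarray(self.estimator.predict(X))  # raw Booster

    def check_manifest(self, columns: Sequence[str]) -> None:
        cols = [c for c in columns if c != "label"]
        if cols != self.feature_names:
            for got, want in zip(cols, self.feature_names):
                if got != want:
                    raise ValueError(f"feature manifest mismatch at column {got!r} (expected {want!r})")
            raise ValueError("feature manifest mismatch: differing column count")

    def cutoff_for(self, threshold_id: Optional[float]) -> float:
        """Look up a calibrated cutoff by target FPR; None -> 0.5."""
        if threshold_id is None:
            return 0.5
        for target, cutoff in self.thresholds:
            if abs(target - threshold_id) < 1e-12:
                return cutoff
        raise KeyError(f"no calibrated threshold for target FPR {threshold_id}")


def train_classifier(
    matrix: pd.DataFrame,
    kind: str = "gbm",
    search_budget: int = 20,
    cv_folds: int = 3,
    seed: int = 0,
    extractor: Optional[FeatureExtractor] = None,
    test_fraction: float = 0.3,
    param_space: Optional[Dict] = None,
) -> FragilityModel:
    """Random hyperparameter search maximising cross-validated AUROC on
    a stratified 70/30 train/test partition; the best configuration is
    refit on the full training split. The held-out test rows are
    recorded in ``model.test_index`` for evaluation and calibration."""
    X, y, feats = _split_matrix(matrix)
    if np.unique(y).size < 2:
        raise ValueError("feature matrix must contain both classes")
    idx = np.arange(X.shape[0])
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    Xtr, ytr = X[train_idx], y[train_idx]
    space = param_space if param_space is not None else (
        LOGISTIC_SPACE if kind == "logistic" else GBM_SPACE
    )
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    sampler = ParameterSampler(space, n_iter=search_budget, random_state=seed)
    best_params, best_score = None, -np.inf
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for params in sampler:
        scores = []
        converged = True
        for tr, va in skf.split(Xtr, ytr):
            est = _make_estimator(kind, params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xtr[tr], ytr[tr])
            p = est.predict_proba(Xtr[va])[:, 1]
            scores.append(roc_auc_score(ytr[va], p))
        score = float(np.mean(scores))
        if converged and score > best_score:
            best_score, best_params = score, params
    est = _make_estimator(kind, best_params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xtr, ytr)
    return FragilityModel(
        kind=kind,
        estimator=est,
        feature_names=feats,
        seed=seed,
        hyperparams=dict(best_params),
        test_index=test_idx,
        extractor=extractor,
    )


def feature_importances(model: FragilityModel) -> pd.Series:
    """Relative feature importance: split gain for the trees, absolute
    coefficient magnitude for the logistic model; normalised to sum 1."""
    if model.kind == "gbm":
        imp = np.asarray(model.estimator.feature_importances_, dtype=np.float64)
    else:
        imp = np.abs(np.asarray(model.estimator.coef_).ravel())
    total = imp.sum()
    return pd.Series(imp / total if total > 0 else imp, index=model.feature_names)


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float  # TP / (TP + FN)
    fpr: float  # FP / (FP + TN)
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auroc: float
    accuracy: float


def evaluate(model: FragilityModel, matrix: pd.DataFrame) -> EvaluationReport:
    """Full ROC, AUROC and the confusion matrix at the default 0.5
    probability threshold (probability >= 0.5 calls positive)."""
    model.check_manifest(list(matrix.columns))
    X, y, _ = _split_matrix(matrix)
    p = model.predict_proba(X)
    fpr_arr, tpr_arr, _ = roc_curve(y, p)
    auroc = float(auc(fpr_arr, tpr_arr))
    calls = p >= 0.5
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    tn = int(np.sum(~calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    accuracy = (tp + tn) / y.size
    return EvaluationReport(tp, fp, tn, fn, tpr, fpr, fpr_arr, tpr_arr, auroc, accuracy)


def thresholds_from_fpr(
    model: FragilityModel, matrix: pd.DataFrame, targets: Sequence[float]
) -> List[Tuple[float, float]]:
    """Smallest probability cutoff whose empirical FPR does not exceed
    each target (step-function inversion of the negative-score
    distribution; calls are probability >= cutoff). Guarantees FPR <=
    target on the calibration data; lower targets never yield lower
    cutoffs. The result is stored on the model."""
    targets = list(targets)
    if any(not (0.0 < t <= 1.0) for t in targets):
        raise ValueError("targets must lie in (0, 1]")
    model.check_manifest(list(matrix.columns))
    X, y, _ = _split_matrix(matrix)
    neg = np.sort(model.predict_proba(X)[y == 0])[::-1]
    if neg.size == 0:
        raise ValueError("no negatives to calibrate on")
    out: List[Tuple[float, float]] = []
    for t in sorted(targets):
        m = int(np.floor(t * neg.size))
        if m >= neg.size:
            cutoff = 0.0
        else:
            if m == 0:
                warnings.warn(f"target FPR {t} below 1/{neg.size} resolution")
            cutoff = float(np.nextafter(neg[m], 1.0))
        out.append((float(t), cutoff))
    model.thresholds = out
    return out


@dataclass
class ScanResult:
    positions: np.ndarray  # bond positions in input-sequence coordinates
    probabilities: np.ndarray
    calls: np.ndarray
    cutoff: float


def scan_sequence(
    model: FragilityModel,
    seq: str,
    stride: int = 1,
    threshold_id: Optional[float] = None,
) -> ScanResult:
    """Predicted break probability at interior bonds of a sequence.

    The sequence is N-padded so edge bonds have a full long-range
    window (N-containing k-mers follow the usual skip rules). Bonds
    start at max(1, stride // 2) and advance by ``stride``; stride = 1
    evaluates every interior bond, stride = len(seq) gives one central
    evaluation."""
    if model.extractor is None:
        raise ValueError("model carries no feature extractor; cannot scan")
    L = len(seq)
    if L < 2:
        raise ValueError("sequence too short to scan")
    ctx = model.extractor.context_required
    padded = "N" * ctx + seq.upper() + "N" * ctx
    positions = np.arange(max(1, stride // 2), L, stride, dtype=np.int64)
    X = model.extractor.features_for_bonds(padded, positions + ctx)
    if model.feature_names != model.extractor.columns:
        raise ValueError("extractor columns do not match model manifest")
    p = model.predict_proba(X)
    cutoff = model.cutoff_for(threshold_id)
    return ScanResult(positions, p, p >= cutoff, cutoff)


@dataclass
class FragilityZones:
    """Genome bins labelled by predicted break density: the top 5% are
    'high', the bottom 5% 'low', the rest 'medium'; ties resolved
    deterministically by (density, chrom, start)."""

    bins: pd.DataFrame  # chrom, start, end, density, label
    bin_size: int


def fragility_zones(
    scans: Mapping[str, ScanResult],
    lengths: Mapping[str, int],
    bin_size: int = 20000,
) -> FragilityZones:
    rows = []
    for chrom in sorted(scans):
        res = scans[chrom]
        L = lengths[chrom]
        for start in range(0, L, bin_size):
            end = min(start + bin_size, L)
            in_bin = (res.positions >= start) & (res.positions < end)
            density = float(res.calls[in_bin].sum()) / (end - start)
            rows.append((chrom, start, end, density))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "density"])
    n = len(df)
    if n < 20:
        raise ValueError("fewer than 20 bins; 5% percentile labels unstable")
    n_tail = int(round(0.05 * n))
    order = df.sort_values(["density", "chrom", "start"], kind="stable").index
    labels = pd.Series("medium", index=df.index)
    labels.loc[order[:n_tail]] = "low"
    labels.loc[order[-n_tail:]] = "high"
    df["label"] = labels
    return FragilityZones(df, bin_size)


def zone_control_fractions(
    zones: FragilityZones, n_draws: int, seed: int
) -> Dict[str, float]:
    """Fraction of uniformly random control bonds landing in each zone
    class; under uniform sampling this tracks each class's share of the
    binned bases."""
    rng = np.random.default_rng(seed)
    df = zones.bins
    sizes = (df["end"] - df["start"]).to_numpy(dtype=np.float64)
    picks = rng.choice(len(df), size=n_draws, replace=True, p=sizes / sizes.sum())
    counts = df["label"].iloc[picks].value_counts()
    return {lab: float(counts.get(lab, 0)) / n_draws for lab in ("low", "medium", "high")}


@dataclass(frozen=True)
class SVRecord:
    chrom: str
    pos: int  # 0-based start of REF on the chromosome
    ref: str
    alt: str
    svtype: str = ""  # insertion / deletion / duplication / inversion / SNV


def _window_call_count(
    model: FragilityModel, seq: str, center: int, cutoff: float
) -> int:
    """Predicted break calls at every bond of the SV_CONTEXT window
    centred on ``center`` of ``seq``; out-of-sequence context is
    N-padded."""
    ctx = model.extractor.context_required
    half = SV_CONTEXT // 2
    lo, hi = center - half, center + half  # bonds lo+1 .. hi-1? use [lo, hi)
    rs, re_ = lo - ctx, hi + ctx
    left_pad = max(0, -rs)
    right_pad = max(0, re_ - len(seq))
    local = "N" * left_pad + seq[max(0, rs) : min(len(seq), re_)] + "N" * right_pad
    bonds = np.arange(lo, hi, dtype=np.int64) - rs
    X = model.extractor.features_for_bonds(local, bonds)
    p = model.predict_proba(X)
    return int(np.sum(p >= cutoff))


def sv_delta_fragility(
    model: FragilityModel,
    genome: GenomeSequence,
    sv: SVRecord,
    threshold_id: Optional[float] = None,
) -> Tuple[float, float, float]:
    """(before, after, delta) predicted break-call counts over the
    1,960-base context centred on the SV, in the reference and in the
    rearranged sequence (re-centred on the replacement). Point variants
    (1-base REF and ALT) get a single centred evaluation instead."""
    if model.extractor is None:
        raise ValueError("model carries no feature extractor")
    cutoff = model.cutoff_for(threshold_id)
    seq = genome.sequences[sv.chrom]
    ref, alt = sv.ref.upper(), sv.alt.upper()
    if seq[sv.pos : sv.pos + len(ref)] != ref:
        raise ValueError("REF does not match the genome at the given position")
    alt_seq = seq[: sv.pos] + alt + seq[sv.pos + len(ref) :]
    if len(ref) == 1 and len(alt) == 1:
        ctx = model.extractor.context_required

        def _single(s: str, centre: int) -> float:
            padded = "N" * ctx + s + "N" * ctx
            X = model.extractor.features_for_bonds(padded, np.array([centre + ctx]))
            return float(model.predict_proba(X)[0] >= cutoff)

        before = _single(seq, sv.pos)
        after = _single(alt_seq, sv.pos)
        return before, after, after - before
    center_ref = sv.pos + len(ref) // 2
    center_alt = sv.pos + len(alt) // 2
    before = _window_call_count(model, seq, center_ref, cutoff)
    after = _window_call_count(model, alt_seq, center_alt, cutoff)
    return float(before), float(after), float(after - before)


def probability_per_base(call_count: float, annotation_length: int) -> float:
    """Predicted strand-break calls divided by annotation length."""
    if annotation_length <= 0:
        raise ValueError("annotation length must be positive")
    return call_count / annotation_length


def relative_fragility(probabilities: Mapping[str, float]) -> Dict[str, float]:
    """Each feature's per-base break probability divided by the maximum
    over the compared features."""
    mx = max(probabilities.values())
    if mx <= 0:
        return {k: 0.0 for k in probabilities}
    return {k: v / mx for k, v in probabilities.items()}


def save_model(model: FragilityModel, prefix: str) -> None:
    """Versioned JSON manifest plus a native text model blob; the
    feature-name checksum guards against manifest drift."""
    manifest = {
        "format_version": 1,
        "kind": model.kind,
        "feature_names": model.feature_names,
        "feature_checksum": hashlib.sha256("\n".join(model.feature_names).encode()).hexdigest(),
        "thresholds": model.thresholds,
        "seed": model.seed,
        "hyperparams": {k: (v.item() if hasattr(v, "item") else v) for k, v in model.hyperparams.items()},
    }
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if model.kind == "gbm":
        model.estimator.booster_.save_model(f"{prefix}.model.txt")
    else:
        blob = {
            "coef": model.estimator.coef_.tolist(),
            "intercept": model.estimator.intercept_.tolist(),
            "classes": model.estimator.classes_.tolist(),
        }
        with open(f"{prefix}.model.txt", "w") as fh:
            json.dump(blob, fh)


def load_model(prefix: str, extractor: Optional[FeatureExtractor] = None) -> FragilityModel:
    with open(f"{prefix}.manifest.json") as fh:
        manifest = json.load(fh)
    checksum = hashlib.sha256("\n".join(manifest["feature_names"]).encode()).hexdigest()
    if checksum != manifest["feature_checksum"]:
        raise ValueError("feature-name checksum mismatch")
    if manifest["kind"] == "gbm":
        import lightgbm as lgb

        class _BoosterWrapper:
            def __init__(self, booster):
                self.booster = booster

            def predict_proba(self, X):
                p = self.booster.predict(X)
                return np.column_stack([1 - p, p])

        est = _BoosterWrapper(lgb.Booster(model_file=f"{prefix}.model.txt"))
    else:
        with open(f"{prefix}.model.txt") as fh:
            blob = json.load(fh)
        est = LogisticRegression()
        est.coef_ = np.asarray(blob["coef"])
        est.intercept_ = np.asarray(blob["intercept"])
        est.classes_ = np.asarray(blob["classes"])
    return FragilityModel(
        kind=manifest["kind"],
        estimator=est,
        feature_names=list(manifest["feature_names"]),
        seed=int(manifest["seed"]),
        hyperparams=dict(manifest["hyperparams"]),
        thresholds=[tuple(t) for t in manifest["thresholds"]],
        extractor=extractor,
    )
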