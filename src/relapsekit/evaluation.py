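"""Experiment protocol: splits, normalization, pooling, metrics, runners,
severity analysis and decision-level fusion.

The detection protocol is 5-fold cross-validation over *normal* data groups
(days or interview sessions): each fold trains on 60% of the normal groups,
keeps 20% for validation (internally halved into val1 for early stopping and
val2 for the error distribution), and tests on the remaining 20% merged with
the anomalous groups. Group atomicity is preserved throughout - all
instances of one day/session share a fold role - and anomalous instances
never influence training or normalization statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import average_precision_score, roc_auc_score

from .detection import (
    TrainSpec,
    anomaly_score,
    error_vectors,
    fit_error_distribution,
    mahalanobis,
    recon_score,
    train,
)
from .features import DETECTION_FEATURES
from .models import ModelConfig, build_model
from .synthetic import SEVERITY_LEVELS

__all__ = [
    "SplitPlan",
    "PoolingSpec",
    "EvalResult",
    "DayRecord",
    "make_splits",
    "normalize",
    "pool",
    "day_average",
    "evaluate",
    "evaluate_folds",
    "run_experiment",
    "severity_analysis",
    "fuse",
    "compare_model_variants",
]

TRIG_COLUMNS = tuple(DETECTION_FEATURES.index(c) for c in ("sin_t", "cos_t"))


@dataclass
class SplitPlan:
    fold: int
    train: list
    val1: list
    val2: list
    test: list

    def roles(self) -> dict:
        out = {}
        for role in ("train", "val1", "val2", "test"):
            for gid in getattr(self, role):
                out.setdefault(gid, role)
        return out


@dataclass(frozen=True)
class PoolingSpec:
    method: str = "AP"          # AP | MP | NP
    p: float = 10.0

    def __post_init__(self):
        if self.method not in ("AP", "MP", "NP"):
            raise ValueError("pooling method must be AP, MP or NP")
        if self.p < 1:
            raise ValueError("norm-pooling exponent must be >= 1")


@dataclass
class EvalResult:
    roc_auc: list
    pr_auc: list
    skipped: int = 0

    @property
    def roc_median(self) -> float:
        return float(np.median(self.roc_auc)) if self.roc_auc else float("nan")

    @property
    def pr_median(self) -> float:
        return float(np.median(self.pr_auc)) if self.pr_auc else float("nan")


@dataclass
class DayRecord:
    patient_id: str
    day: int
    tensor: np.ndarray          # (288, n_features) in DETECTION_FEATURES order
    label: str                  # normal | near_relapse | relapse
    severity: str | None = None
    m_eff: float = 0.0


def make_splits(normal_groups, anomalous_groups, k: int = 5, seed: int = 0,
                anomalous_mode: str = "duplicate") -> list:
    """Rotate normal groups through the test role across k folds.

    60% of normal groups train, 20% validate (split into two equal halves),
    20% test; anomalous groups are appended to every fold's test set
    (``anomalous_mode="partition"`` distributes them across folds instead).
    """
    normal_groups = list(normal_groups)
    anomalous_groups = list(anomalous_groups)
    if len(normal_groups) < k:
        raise ValueError(f"need at least {k} normal groups, got {len(normal_groups)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(31,)))
    order = [normal_groups[i] for i in rng.permutation(len(normal_groups))]
    folds = [order[i::k] for i in range(k)]
    anom_folds = [anomalous_groups[i::k] for i in range(k)] \
        if anomalous_mode == "partition" else [anomalous_groups] * k
    plans = []
    for i in range(k):
        test = list(folds[i])
        rest = [g for j, f in enumerate(folds) if j != i for g in f]
        n_val = max(2, round(len(rest) * 0.25)) if len(rest) >= 4 else max(1, len(rest) // 4)
        val = rest[:n_val]
        train_groups = rest[n_val:]
        half = (len(val) + 1) // 2
        plans.append(SplitPlan(
            fold=i, train=train_groups, val1=val[:half], val2=val[half:],
            test=test + list(anom_folds[i]),
        ))
    return plans


def normalize(data: np.ndarray, fit_mask: np.ndarray,
              mode: str = "global", patient_ids=None,
              trig_columns: tuple = TRIG_COLUMNS):
    """Min-max scale features into [0, 1] using statistics of the fit
    partition only; sin/cos time encodings pass through; values outside the
    fit range are clipped.

    ``data`` is (N, ..., F). With ``mode="per_patient"`` statistics are
    computed per patient (patients absent from the fit partition fall back
    to the global statistics). Constant features map to 0.5. Returns
    ``(scaled, transform_record)``.
    """
    x = np.asarray(data, dtype=float)
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if not fit_mask.any():
        raise ValueError("empty fit partition")
    f = x.shape[-1]
    feat_axis_flat = lambda arr: arr.reshape(-1, f)

    def fit_minmax(subset):
        flat = feat_axis_flat(subset)
        return np.nanmin(flat, axis=0), np.nanmax(flat, axis=0)

    def apply(arr, lo, hi):
        out = arr.astype(float).copy()
        span = hi - lo
        for j in range(f):
            if j in trig_columns:
                continue
            if span[j] <= 0:
                out[..., j] = 0.5
            else:
                out[..., j] = np.clip((arr[..., j] - lo[j]) / span[j], 0.0, 1.0)
        return out

    record = {"mode": mode}
    out = np.empty_like(x)
    if mode == "global":
        lo, hi = fit_minmax(x[fit_mask])
        record["lo"], record["hi"] = lo, hi
        out = apply(x, lo, hi)
    elif mode == "per_patient":
        if patient_ids is None:
            raise ValueError("per_patient normalization needs patient_ids")
        patient_ids = np.asarray(patient_ids)
        glo, ghi = fit_minmax(x[fit_mask])
        record["per_patient"] = {}
        for pid in np.unique(patient_ids):
            sel = patient_ids == pid
            fit_sel = sel & fit_mask
            lo, hi = fit_minmax(x[fit_sel]) if fit_sel.any() else (glo, ghi)
            record["per_patient"][pid] = (lo, hi)
            out[sel] = apply(x[sel], lo, hi)
    else:
        raise ValueError("mode must be 'global' or 'per_patient'")
    return out, record


def pool(scores, spec: PoolingSpec = PoolingSpec()) -> float:
    """Temporal pooling of per-instance scores into one session score."""
    s = np.asarray(scores, dtype=float)
    if len(s) == 0:
        raise ValueError("cannot pool an empty score set")
    if spec.method == "AP":
        return float(s.mean())
    if spec.method == "MP":
        return float(s.max())
    if np.any(s < 0):
        raise ValueError("norm pooling requires non-negative scores")
    return float(np.mean(s**spec.p) ** (1.0 / spec.p))


def day_average(scores, day_ids) -> dict:
    """Arithmetic mean of per-point scores per subject-local day."""
    s = np.asarray(scores, dtype=float)
    out, counts = {}, {}
    for value, day in zip(s, day_ids):
        out[day] = out.get(day, 0.0) + value
        counts[day] = counts.get(day, 0) + 1
    return {day: out[day] / counts[day] for day in out}


def evaluate(scores, labels) -> tuple:
    """(ROC-AUC, PR-AUC) with relapse as the positive class.

    ROC-AUC through the Mann-Whitney statistic relation; PR-AUC by
    step-function integration (average precision). Raises on a single-class
    test set.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def evaluate_folds(fold_results) -> EvalResult:
    """Median-over-folds evaluation; single-class folds are skipped with a
    count."""
    res = EvalResult(roc_auc=[], pr_auc=[])
    for scores, labels in fold_results:
        try:
            roc, pr = evaluate(scores, labels)
        except ValueError:
            res.skipped += 1
            continue
        res.roc_auc.append(roc)
        res.pr_auc.append(pr)
    return res


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------

def _subsequences(tensor: np.ndarray, slots: int) -> np.ndarray:
    n = tensor.shape[0] // slots
    return tensor[: n * slots].reshape(n, slots, tensor.shape[1])


def _fold_scores(day_records, plan, architecture, probe, seed, input_hours,
                 model_config, train_spec, norm_mode="global"):
    """Train on one fold and return (per-day scores, labels, baseline scores).

    ``day_records`` maps group id (patient, day) -> DayRecord.
    """
    slots = int(input_hours * 12)
    roles = plan.roles()
    gids = list(roles)
    X = np.stack([day_records[g].tensor for g in gids])
    fit_mask = np.array([roles[g] == "train" for g in gids])
    pids = np.array([day_records[g].patient_id for g in gids])
    Xn, _ = normalize(X, fit_mask, mode=norm_mode, patient_ids=pids)

    def seqs(role):
        sel = [i for i, g in enumerate(gids) if roles[g] == role]
        chunks, owners = [], []
        for i in sel:
            sub = _subsequences(Xn[i], slots)
            chunks.append(sub)
            owners.extend([gids[i]] * len(sub))
        data = np.concatenate(chunks) if chunks else np.empty((0, slots, X.shape[2]))
        return data, owners

    train_X, _ = seqs("train")
    val1_X, _ = seqs("val1")
    val2_X, _ = seqs("val2")
    test_X, test_owner = seqs("test")

    spec = train_spec if train_spec is not None else TrainSpec.for_architecture(architecture)
    spec = TrainSpec(**{**spec.__dict__, "architecture": architecture, "seed": seed})
    model = build_model(architecture, (slots, X.shape[2]), model_config, seed=seed)
    model, _ = train(model, train_X, val1_X, spec)

    point_owner = [o for o in test_owner for _ in range(slots)]
    if probe == "mahalanobis":
        dist = fit_error_distribution(error_vectors(model, val2_X, spec))
        point_scores = anomaly_score(model, dist, test_X, spec)
        owner_per_point = point_owner
    elif probe == "recon":
        point_scores = recon_score(model, test_X, spec)
        owner_per_point = list(test_owner)
    else:
        raise ValueError("probe must be 'mahalanobis' or 'recon'")
    scores_by_day = day_average(point_scores, owner_per_point)

    # model-free baseline on the raw (normalized) feature points
    val_feats = np.concatenate([val1_X, val2_X]).reshape(-1, X.shape[2])
    test_feats = test_X.reshape(-1, X.shape[2])
    base_points = random_baseline_scores(val_feats, test_feats)
    base_by_day = day_average(base_points, point_owner)

    days = sorted(scores_by_day)
    labels = [1 if day_records[d].label == "relapse" else 0 for d in days]
    return (np.array([scores_by_day[d] for d in days]), np.array(labels),
            np.array([base_by_day[d] for d in days]), days)


def random_baseline_scores(val_features, test_features):
    dist = fit_error_distribution(np.asarray(val_features))
    return mahalanobis(np.asarray(test_features), dist)


def _splitable(days):
    normal = [(d.patient_id, d.day) for d in days if d.label == "normal"]
    anomalous = [(d.patient_id, d.day) for d in days if d.label == "relapse"]
    return normal, anomalous


def run_experiment(days, scheme: str = "personalized", architecture: str = "cnn",
                   probe: str = "mahalanobis", k: int = 5, seed: int = 0,
                   input_hours: float = 4.0,
                   model_config: ModelConfig = ModelConfig(),
                   train_spec: TrainSpec | None = None,
                   norm_mode: str | None = None) -> pd.DataFrame:
    """Run the detection protocol over a cohort of day tensors.

    Near-relapse days are discarded; normal days rotate through the 5-fold
    test role while relapse days join every test set. Returns a results
    table with per-patient rows (personalized / global_eval_individual) or a
    pooled row (global), each carrying the median ROC/PR AUC over folds and
    the model-free baseline column; a final median row summarizes
    per-patient schemes. Patients without relapse days are excluded with a
    record row (AUC undefined).
    """
    days = [d for d in days if d.label != "near_relapse"]
    records = {(d.patient_id, d.day): d for d in days}
    rows = []
    if scheme == "personalized":
        for pid in sorted({d.patient_id for d in days}):
            pdays = [d for d in days if d.patient_id == pid]
            normal, anomalous = _splitable(pdays)
            if not anomalous or len(normal) < k:
                rows.append({"patient_id": pid, "roc_auc": np.nan, "pr_auc": np.nan,
                             "baseline_roc_auc": np.nan, "n_folds": 0,
                             "note": "no relapse days" if not anomalous else "too few normal days"})
                continue
            plans = make_splits(normal, anomalous, k=k, seed=seed)
            fold_res, base_res = [], []
            for plan in plans:
                s, y, b, _ = _fold_scores(records, plan, architecture, probe,
                                          seed + plan.fold, input_hours,
                                          model_config, train_spec)
                fold_res.append((s, y))
                base_res.append((b, y))
            ev, bev = evaluate_folds(fold_res), evaluate_folds(base_res)
            rows.append({"patient_id": pid, "roc_auc": ev.roc_median,
                         "pr_auc": ev.pr_median,
                         "baseline_roc_auc": bev.roc_median,
                         "n_folds": len(ev.roc_auc), "note": ""})
        valid = [r for r in rows if np.isfinite(r["roc_auc"])]
        rows.append({"patient_id": "MEDIAN",
                     "roc_auc": float(np.median([r["roc_auc"] for r in valid])) if valid else np.nan,
                     "pr_auc": float(np.median([r["pr_auc"] for r in valid])) if valid else np.nan,
                     "baseline_roc_auc": float(np.median([r["baseline_roc_auc"] for r in valid])) if valid else np.nan,
                     "n_folds": sum(r["n_folds"] for r in valid), "note": "median over patients"})
        return pd.DataFrame(rows)

    if scheme in ("global", "global_eval_individual"):
        normal, anomalous = _splitable(days)
        nm = norm_mode or ("per_patient" if scheme == "global_eval_individual" else "global")
        plans = make_splits(normal, anomalous, k=k, seed=seed)
        per_fold = []
        for plan in plans:
            s, y, b, day_ids = _fold_scores(records, plan, architecture, probe,
                                            seed + plan.fold, input_hours,
                                            model_config, train_spec, norm_mode=nm)
            per_fold.append((s, y, b, day_ids))
        if scheme == "global":
            ev = evaluate_folds([(s, y) for s, y, _, _ in per_fold])
            bev = evaluate_folds([(b, y) for _, y, b, _ in per_fold])
            return pd.DataFrame([{"patient_id": "GLOBAL", "roc_auc": ev.roc_median,
                                  "pr_auc": ev.pr_median,
                                  "baseline_roc_auc": bev.roc_median,
                                  "n_folds": len(ev.roc_auc), "note": "pooled"}])
        rows = []
        for pid in sorted({d.patient_id for d in days}):
            folds = []
            for s, y, _, day_ids in per_fold:
                sel = [i for i, d in enumerate(day_ids) if d[0] == pid]
                folds.append((s[sel], y[sel]))
            ev = evaluate_folds(folds)
            if ev.roc_auc:
                rows.append({"patient_id": pid, "roc_auc": ev.roc_median,
                             "pr_auc": ev.pr_median, "baseline_roc_auc": np.nan,
                             "n_folds": len(ev.roc_auc), "note": ""})
        med = float(np.median([r["roc_auc"] for r in rows])) if rows else np.nan
        med_pr = float(np.median([r["pr_auc"] for r in rows])) if rows else np.nan
        rows.append({"patient_id": "MEDIAN", "roc_auc": med, "pr_auc": med_pr,
                     "baseline_roc_auc": np.nan,
                     "n_folds": sum(r["n_folds"] for r in rows), "note": "median over patients"})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# severity and fusion
# ---------------------------------------------------------------------------

def severity_analysis(day_scores: pd.DataFrame, n_boot: int = 500,
                      seed: int = 0) -> pd.DataFrame:
    """Mean anomaly score per relapse severity with bootstrap CIs.

    ``day_scores`` has columns (score, severity); rows without severity are
    ignored. Rows are ordered low < moderate < severe.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(41,)))
    rows = []
    present = [s for s in SEVERITY_LEVELS
               if s in set(day_scores["severity"].dropna())]
    for sev in present:
        vals = day_scores.loc[day_scores["severity"] == sev, "score"].to_numpy(float)
        boots = np.array([
            rng.choice(vals, size=len(vals), replace=True).mean()
            for _ in range(n_boot)
        ])
        rows.append({"severity": sev, "n_days": len(vals),
                     "mean_score": float(vals.mean()),
                     "ci_low": float(np.percentile(boots, 2.5)),
                     "ci_high": float(np.percentile(boots, 97.5))})
    return pd.DataFrame(rows)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def fuse(sessions: pd.DataFrame, day_scores: pd.DataFrame,
         method: str = "additive") -> pd.DataFrame:
    """Decision-level fusion of session-pooled audio scores with the
    physiological score of the same calendar day.

    Each session row (patient_id, day, score, label) must pair with a
    (patient_id, day, score) day row; unpaired sessions are rejected
    (dropped with a ``paired`` flag). Both modalities are min-max
    standardized over the paired evaluation set, then summed or multiplied.
    """
    if method not in ("additive", "multiplicative"):
        raise ValueError("method must be 'additive' or 'multiplicative'")
    merged = sessions.merge(
        day_scores.rename(columns={"score": "physio_score"}),
        on=["patient_id", "day"], how="left", validate="many_to_one")
    merged["paired"] = merged["physio_score"].notna()
    paired = merged[merged["paired"]].copy()
    if len(paired) == 0:
        raise ValueError("no session could be paired with a physiological day score")
    a = _minmax(paired["score"].to_numpy(float))
    b = _minmax(paired["physio_score"].to_numpy(float))
    paired["fused_score"] = a + b if method == "additive" else a * b
    return paired


def compare_model_variants(auc_a, auc_b, n_comparisons: int = 1) -> dict:
    """Bonferroni-corrected Mann-Whitney comparison of two AUC samples
    (repetitions x folds)."""
    res = sstats.mannwhitneyu(auc_a, auc_b, alternative="two-sided")
    return {"U": float(res.statistic), "p_raw": float(res.pvalue),
            "p_bonferroni": float(min(1.0, res.pvalue * n_comparisons)),
            "significant_05": bool(res.pvalue * n_comparisons < 0.05)}
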