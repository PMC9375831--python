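"""Stress-recognition pipeline: labeling, screening, ANOVA/Tukey, SMOTE,
and the four-classifier benchmark.

Each cohort row is one (subject, task) recording with its HRV feature vector.
Binary stress labels follow the protocol's rule: the resting task T1 is
always non-stress; the activity tasks T2/T3 are stress for subjects in the
high-difficulty ``test`` group and non-stress for the ``ctrl`` group.
Candidate features are screened for normality (Shapiro-Wilk, features kept
when p > 0.05), compared across groups with a classic one-way ANOVA and
Tukey HSD post-hoc comparisons, balanced with SMOTE minority oversampling,
and fed to four classifiers (random forest with 20 trees, linear-kernel SVM,
5-nearest-neighbors, LightGBM) evaluated with the standard confusion-matrix
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

from .errors import InsufficientData, InvalidArgument, InvalidLabel, InvalidSplit
from .quality import ConfusionCounts, classification_metrics

__all__ = [
    "AnovaResult",
    "assign_stress_labels",
    "normality_screen",
    "oneway_anova",
    "tukey_pairwise",
    "smote_balance",
    "fit_eval_classifiers",
    "STRESS",
    "NON_STRESS",
]

TASKS = ("T1", "T2", "T3")
GROUPS = ("test", "ctrl")
STRESS = "stress"
NON_STRESS = "non_stress"


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome for a single feature."""

    feature: str
    F: float
    df_between: int
    df_within: int
    p: float

    def __post_init__(self) -> None:
        if self.F < 0 or not (0 <= self.p <= 1):
            raise InvalidArgument("require F >= 0 and p in [0, 1]")


def assign_stress_labels(manifest: pd.DataFrame) -> pd.DataFrame:
    """Add a ``stress_label`` column per the labeling rule.

    T1 rows are non-stress; T2/T3 rows are stress iff the subject is in the
    ``test`` group. Requires ``task`` and ``group`` columns.
    """
    for col in ("task", "group"):
        if col not in manifest.columns:
            raise InvalidLabel(f"manifest lacks required column {col!r}")
    bad_task = ~manifest["task"].isin(TASKS)
    bad_group = ~manifest["group"].isin(GROUPS)
    if bad_task.any() or bad_group.any():
        raise InvalidLabel(
            f"unknown task/group codes: "
            f"{sorted(set(manifest.loc[bad_task, 'task']))} "
            f"{sorted(set(manifest.loc[bad_group, 'group']))}"
        )
    out = manifest.copy()
    is_stress = (out["task"] != "T1") & (out["group"] == "test")
    out["stress_label"] = np.where(is_stress, STRESS, NON_STRESS)
    return out


def normality_screen(
    data: pd.DataFrame, features: list[str] | None = None, alpha: float = 0.05
) -> tuple[list[str], dict[str, float], list[str]]:
    """Shapiro-Wilk normality screen.

    Returns ``(retained, p_values, degenerate)``: features with p > ``alpha``
    are retained; constant features are flagged degenerate and rejected.
    """
    if features is None:
        features = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    retained: list[str] = []
    p_values: dict[str, float] = {}
    degenerate: list[str] = []
    for name in features:
        x = data[name].dropna().to_numpy(dtype=float)
        if x.size < 3:
            raise InsufficientData(f"feature {name!r}: need >= 3 observations")
        if np.ptp(x) == 0:
            degenerate.append(name)
            p_values[name] = float("nan")
            continue
        p = float(scipy.stats.shapiro(x).pvalue)
        p_values[name] = p
        if p > alpha:
            retained.append(name)
    return retained, p_values, degenerate


def _groups_for(data: pd.DataFrame, feature: str, grouping: str) -> list[np.ndarray]:
    if grouping not in data.columns:
        raise InvalidArgument(f"grouping column {grouping!r} not in data")
    groups = [
        g.dropna().to_numpy(dtype=float)
        for _, g in data.groupby(grouping, observed=True)[feature]
    ]
    if len(groups) < 2:
        raise InsufficientData("ANOVA needs >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise InsufficientData("every group needs >= 2 observations")
    return groups


def oneway_anova(data: pd.DataFrame, feature: str, grouping: str) -> AnovaResult:
    """Classic one-way ANOVA of ``feature`` across the levels of ``grouping``.

    ``F = MS_between / MS_within`` with degrees of freedom (k−1, N−k); the
    p-value comes from the F distribution.
    """
    groups = _groups_for(data, feature, grouping)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = 0.0 if ms_b == 0 else float("inf")
        p = 1.0 if ms_b == 0 else 0.0
    else:
        F = ms_b / ms_w
        p = float(scipy.stats.f.sf(F, df_b, df_w))
    return AnovaResult(feature=feature, F=float(F), df_between=df_b, df_within=df_w, p=p)


def tukey_pairwise(
    data: pd.DataFrame, feature: str, grouping: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey honest-significant-difference pairwise comparisons.

    Returns one row per group pair: mean difference, adjusted p, and a
    significance flag at ``alpha``. With two groups this degenerates to a
    single comparison.
    """
    if grouping not in data.columns:
        raise InvalidArgument(f"grouping column {grouping!r} not in data")
    grouped = list(data.groupby(grouping, observed=True)[feature])
    names = [name for name, _ in grouped]
    arrays = [g.dropna().to_numpy(dtype=float) for _, g in grouped]
    if len(arrays) < 2:
        raise InsufficientData("Tukey needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise InsufficientData("every group needs >= 2 observations")
    res = scipy.stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def smote_balance(
    data: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "stress_label",
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """SMOTE minority oversampling to equal class counts.

    Each synthetic minority sample is ``x + u · (x_nn − x)`` for a random
    minority sample ``x``, one of its ``k_neighbors`` nearest minority
    neighbors ``x_nn`` (Euclidean, feature space), and ``u ~ Uniform(0, 1)``.
    Original rows pass through unchanged; synthetic rows get
    ``synthetic=True``. Already balanced input is returned as-is.
    """
    rng = np.random.default_rng(seed)
    counts = data[label_col].value_counts()
    if len(counts) != 2:
        raise InvalidArgument(f"expected exactly 2 classes, got {len(counts)}")
    minority_label = counts.idxmin()
    n_min, n_maj = int(counts.min()), int(counts.max())
    out = data.copy()
    if "synthetic" not in out.columns:
        out["synthetic"] = False
    if n_min == n_maj:
        return out
    if n_min <= k_neighbors:
        raise InvalidArgument(
            f"minority class of {n_min} too small for k_neighbors={k_neighbors}"
        )
    X_min = data.loc[data[label_col] == minority_label, feature_cols].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = X_min[base]
    x_nn = X_min[neighbor_idx[base, pick]]
    synthetic = x + u[:, None] * (x_nn - x)
    synth_df = pd.DataFrame(synthetic, columns=feature_cols)
    synth_df[label_col] = minority_label
    synth_df["synthetic"] = True
    return pd.concat([out, synth_df], ignore_index=True)


@dataclass(frozen=True)
class SplitConfig:
    """Held-out evaluation split: stratified, seeded, test fraction 1/3."""

    test_fraction: float = 1.0 / 3.0
    stratify: bool = True


def _make_models(n_trees: int, knn_k: int, seed: int) -> dict[str, object]:
    import lightgbm

    return {
        "RF": RandomForestClassifier(n_estimators=n_trees, random_state=seed),
        "SVM": SVC(kernel="linear", random_state=seed),
        "KNN": KNeighborsClassifier(n_neighbors=knn_k),
        "LightGBM": lightgbm.LGBMClassifier(random_state=seed, verbose=-1),
    }


def fit_eval_classifiers(
    data: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "stress_label",
    split: SplitConfig = SplitConfig(),
    seed: int = 0,
    n_trees: int = 20,
    knn_k: int = 5,
) -> pd.DataFrame:
    """Train and evaluate the four benchmark classifiers.

    Returns one row per model with accuracy/precision/sensitivity/
    specificity/F1 in percent, plus the seed and split echoed. The positive
    class is ``stress`` when present, else the lexicographically last label.
    """
    labels = data[label_col]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise InvalidSplit(f"need exactly 2 classes, got {classes}")
    positive = STRESS if STRESS in classes else classes[-1]
    X = data[feature_cols].astype(float)
    y = (labels == positive).to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=split.test_fraction,
        random_state=seed,
        stratify=y if split.stratify else None,
    )
    if len(set(y_tr)) < 2 or len(set(y_te)) < 2:
        raise InvalidSplit("a partition ended up single-class")

    rows = []
    for name, model in _make_models(n_trees, knn_k, seed).items():
        model.fit(X_tr, y_tr)
        pred = model.predict(X_te)
        c = ConfusionCounts(
            tp=int(np.sum(pred & y_te)),
            fp=int(np.sum(pred & ~y_te)),
            fn=int(np.sum(~pred & y_te)),
            tn=int(np.sum(~pred & ~y_te)),
        )
        m = classification_metrics(c)
        rows.append(
            {
                "model": name,
                "accuracy": m["accuracy"],
                "precision": m["precision"],
                "sensitivity": m["recall"],
                "specificity": m["specificity"],
                "f1": m["f1"],
                "n_test": int(y_te.size),
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
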