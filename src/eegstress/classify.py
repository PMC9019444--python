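"""Feature elimination, subset assembly, SVM classification and metrics.

The analysis asks, for every (subset, intervention, channel, band) cell:
after discarding features whose paired distributions do not differ
(two-sided Wilcoxon signed-rank, eliminate at p >= alpha), how well does a
polynomial-kernel SVM separate the two populations on held-out windows?

Subsets:

    male_vs_female      male intervention windows  vs female intervention windows
    baseline_vs_female  female intervention windows vs female baseline windows
    baseline_vs_male    male intervention windows   vs male baseline windows

The positive class is always the intervention-condition windows (for
male_vs_female, the male windows).  Splitting is a stratified seeded 80/20
partition of the pooled windows; features are standardized with
training-set statistics only.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS

__all__ = [
    "SUBSET_NAMES",
    "SubsetSpec",
    "ClassifierSpec",
    "ConfusionCounts",
    "MetricsResult",
    "wilcoxon_filter",
    "assemble_subset",
    "fit_and_score",
    "performance_metrics",
    "channel_band_sweep",
]

SUBSET_NAMES = ("male_vs_female", "baseline_vs_female", "baseline_vs_male")


@dataclass(frozen=True)
class SubsetSpec:
    """One classification cell: comparison x intervention x channel x band."""

    name: str
    intervention: str
    channel: str
    band: str

    def __post_init__(self):
        if self.name not in SUBSET_NAMES:
            raise ValueError(
                f"unknown subset {self.name!r}; valid: {SUBSET_NAMES}"
            )


@dataclass(frozen=True)
class ClassifierSpec:
    """Polynomial-kernel SVM settings (libsvm via scikit-learn)."""

    kernel: str = "poly"
    degree: int = 3
    C: float = 1.0
    coef0: float = 1.0
    max_iterations: int = 100
    tolerance: float = 0.0010
    train_fraction: float = 0.8
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsResult:
    """Sensitivity / specificity / accuracy in percent (None = undefined)."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def wilcoxon_filter(features_a, features_b, alpha: float = 0.05,
                    feature_cols=FEATURE_COLUMNS):
    """Eliminate features whose paired difference is not significant.

    The two tables must be paired row-for-row (same subject/window ordering).
    Per feature column a two-sided Wilcoxon signed-rank test is run on the
    paired differences; features with p >= alpha are eliminated and features
    with p < alpha retained.  All-zero differences give p = 1 (eliminated).

    Returns ``(retained_names, pvalues)`` with p-values for every feature.
    """
    if len(features_a) != len(features_b):
        raise ValueError(
            f"slices must be paired: {len(features_a)} vs {len(features_b)} rows"
        )
    n = len(features_a)
    if n < 5:
        raise ValueError(f"need >= 5 pairs for the signed-rank test, got {n}")
    pvalues = {}
    retained = []
    for col in feature_cols:
        d = np.asarray(features_a[col], dtype=float) - np.asarray(
            features_b[col], dtype=float
        )
        if np.all(d == 0):
            pvalues[col] = 1.0
            continue
        method = "exact" if np.count_nonzero(d) <= 25 else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tie/zero warnings on tiny n
            try:
                res = stats.wilcoxon(
                    d, zero_method="wilcox", correction=(method == "approx"),
                    alternative="two-sided", method=method,
                )
            except ValueError:
                res = stats.wilcoxon(
                    d, zero_method="wilcox", correction=True,
                    alternative="two-sided", method="approx",
                )
        pvalues[col] = float(res.pvalue)
        if res.pvalue < alpha:
            retained.append(col)
    return retained, pvalues


def subset_slices(features: pd.DataFrame, spec: SubsetSpec):
    """Positive/negative row slices for a cell, ordered for pairing.

    Both slices are sorted by (subject_id, window) — for the baseline
    subsets the pairing is genuinely within-subject; for male_vs_female
    subjects are matched by enrolment order within each group.
    """
    cell = features[
        (features["channel"] == spec.channel) & (features["band"] == spec.band)
    ]
    if cell.empty:
        raise ValueError(
            f"no rows for channel={spec.channel!r}, band={spec.band!r}"
        )
    order = ["subject_id", "window"]
    if spec.name == "male_vs_female":
        pos = cell[(cell["group"] == "male")
                   & (cell["condition"] == spec.intervention)]
        neg = cell[(cell["group"] == "female")
                   & (cell["condition"] == spec.intervention)]
        pos_desc, neg_desc = "male intervention", "female intervention"
    else:
        group = "female" if spec.name == "baseline_vs_female" else "male"
        sub = cell[cell["group"] == group]
        pos = sub[sub["condition"] == spec.intervention]
        neg = sub[sub["condition"] == "baseline"]
        pos_desc, neg_desc = f"{group} {spec.intervention}", f"{group} baseline"
    if pos.empty:
        raise ValueError(f"empty positive class ({pos_desc}) for {spec}")
    if neg.empty:
        raise ValueError(f"empty negative class ({neg_desc}) for {spec}")
    return (pos.sort_values(order).reset_index(drop=True),
            neg.sort_values(order).reset_index(drop=True))


def assemble_subset(features: pd.DataFrame, spec: SubsetSpec,
                    feature_cols=FEATURE_COLUMNS):
    """(X, y) design matrix for a cell; positive class labelled 1."""
    pos, neg = subset_slices(features, spec)
    X = np.vstack([
        pos[list(feature_cols)].to_numpy(float),
        neg[list(feature_cols)].to_numpy(float),
    ])
    y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return X, y


def stratified_split(X, y, train_fraction: float = 0.8, seed: int = 0):
    """Seeded stratified split; train size floors to train_fraction * n."""
    n_train = int(np.floor(train_fraction * len(y)))
    try:
        return train_test_split(
            X, y, train_size=n_train, stratify=y, random_state=seed
        )
    except ValueError as e:
        raise ValueError(
            f"stratified split failed ({e}); use more rows per class or a "
            f"different seed"
        ) from e


def fit_and_score(X, y, spec: ClassifierSpec = ClassifierSpec()):
    """Train the polynomial SVM on a stratified 80/20 split and score the
    held-out part.

    Returns ``(ConfusionCounts, MetricsResult)``.  Features are standardized
    with training-set statistics only (disable via ``spec.standardize``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < 5:
        raise ValueError("need at least 5 rows")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    X_tr, X_te, y_tr, y_te = stratified_split(
        X, y, spec.train_fraction, spec.seed
    )
    for part, name in ((y_tr, "training"), (y_te, "test")):
        if len(np.unique(part)) < 2:
            raise ValueError(
                f"a class is absent from the {name} partition; adjust the "
                f"seed or use stratification with more rows per class"
            )
    if spec.standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr = scaler.transform(X_tr)
        X_te = scaler.transform(X_te)
    clf = SVC(
        kernel=spec.kernel, degree=spec.degree, C=spec.C, coef0=spec.coef0,
        tol=spec.tolerance, max_iter=spec.max_iterations,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # iteration cap is part of the design
        clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y_te == 1))),
        fp=int(np.sum((pred == 1) & (y_te == 0))),
        tn=int(np.sum((pred == 0) & (y_te == 0))),
        fn=int(np.sum((pred == 0) & (y_te == 1))),
    )
    return counts, performance_metrics(counts)


def performance_metrics(c: ConfusionCounts) -> MetricsResult:
    """Sen = TP/(TP+FN), Spec = TN/(TN+FP), Acc = (TP+TN)/total, in percent.

    An empty denominator leaves that metric undefined (None), not zero.
    """
    sen = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spe = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total > 0 else None
    return MetricsResult(sensitivity=sen, specificity=spe, accuracy=acc)


def _cell_seed(base_seed: int, spec: SubsetSpec) -> int:
    key = f"{spec.name}|{spec.intervention}|{spec.channel}|{spec.band}"
    return (int(base_seed) * 1000003 + zlib.crc32(key.encode())) % (2 ** 31)


def channel_band_sweep(
    features: pd.DataFrame,
    subset_names=SUBSET_NAMES,
    interventions=("MI-1", "MI-2", "MI-3", "MI-4"),
    clf_spec: ClassifierSpec = ClassifierSpec(),
    alpha: float = 0.05,
    channels=None,
    bands=None,
    apply_filter: bool = True,
    min_rows_per_class: int = 5,
) -> pd.DataFrame:
    """Run filter + assembly + SVM for every (subset, intervention, channel,
    band) cell; 3 x 4 x 14 x 5 = 840 rows by default.

    Cells that fail a precondition (too few rows, no feature retained,
    degenerate split) are recorded with a ``skip_reason`` instead of
    aborting the sweep.  Each cell gets its own deterministic split seed
    derived from ``clf_spec.seed``.
    """
    if channels is None:
        channels = list(pd.unique(features["channel"]))
    if bands is None:
        bands = list(pd.unique(features["band"]))
    rows = []
    for name in subset_names:
        for mi in interventions:
            for ch in channels:
                for band in bands:
                    spec = SubsetSpec(name, mi, ch, band)
                    row = {
                        "subset": name, "intervention": mi,
                        "channel": ch, "band": band,
                        "n_retained": 0, "retained": "",
                        "sensitivity": np.nan, "specificity": np.nan,
                        "accuracy": np.nan, "skip_reason": "",
                    }
                    try:
                        pos, neg = subset_slices(features, spec)
                        if min(len(pos), len(neg)) < min_rows_per_class:
                            raise ValueError(
                                f"fewer than {min_rows_per_class} rows per class"
                            )
                        cols = list(FEATURE_COLUMNS)
                        if apply_filter:
                            cols, _ = wilcoxon_filter(pos, neg, alpha)
                            if not cols:
                                raise ValueError("no feature passed the filter")
                        X, y = assemble_subset(features, spec, cols)
                        cell = ClassifierSpec(
                            kernel=clf_spec.kernel, degree=clf_spec.degree,
                            C=clf_spec.C, coef0=clf_spec.coef0,
                            max_iterations=clf_spec.max_iterations,
                            tolerance=clf_spec.tolerance,
                            train_fraction=clf_spec.train_fraction,
                            standardize=clf_spec.standardize,
                            seed=_cell_seed(clf_spec.seed, spec),
                        )
                        counts, metrics = fit_and_score(X, y, cell)
                    except ValueError as e:
                        row["skip_reason"] = str(e)
                        rows.append(row)
                        continue
                    row.update({
                        "n_retained": len(cols), "retained": "+".join(cols),
                        "tp": counts.tp, "fp": counts.fp,
                        "tn": counts.tn, "fn": counts.fn,
                        "sensitivity": metrics.sensitivity,
                        "specificity": metrics.specificity,
                        "accuracy": metrics.accuracy,
                    })
                    rows.append(row)
    return pd.DataFrame(rows)
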