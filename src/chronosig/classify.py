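"""Naive-Bayes account classification from empirical timing densities.

Accounts are assigned to classes by a maximum-a-posteriori rule over
non-parametric class densities estimated from pooled training events.
Four feature modes mirror the four ways of using the two timing variables:

* ``itd`` — inter-event-delay marginal only;
* ``tt``  — time-of-day (hour) marginal only;
* ``ji``  — joint of the two assuming independence (product of marginals);
* ``jni`` — joint without the independence assumption (2-D histogram).

The classification score of class c for an account is the sum over the
account's events of the log class density at that event's feature value
(delay, hour, or pair); with uniform priors the MAP rule reduces to maximum
likelihood. Unseen feature values land on the density floor, which keeps
all log-scores finite and comparable across classes.

Evaluation helpers implement leave-one-out cross-validation, repeated
stratified train/test splits, label-shuffled chance baselines, and the
Pearson / Kendall tau independence checks between delay and preceding hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .density import (
    BinConfig,
    DELAY_FLOOR,
    HOUR_FLOOR,
    HourDensity,
    JointDensity,
    LogBinnedDensity,
    density_at,
    fit_delay_density,
    fit_hour_density,
    fit_joint,
)
from .events import EventStream, clock_features, compute_delays

__all__ = [
    "FEATURE_MODES",
    "AccountFeatures",
    "ClassModel",
    "ClassificationOutcome",
    "EvaluationReport",
    "featurize",
    "train",
    "account_score",
    "classify_account",
    "loocv",
    "split_evaluate",
    "shuffled_baseline",
    "independence_tests",
    "correlation_pair",
]

FEATURE_MODES = ("itd", "tt", "ji", "jni")
#: canonical class ordering (ties break towards the earlier class)
CLASS_ORDER = ("personal", "managed", "bot")


@dataclass
class AccountFeatures:
    """Pre-extracted timing features of one account."""

    account_id: str
    label: str
    delays: np.ndarray  # seconds, floored at 1
    preceding_hours: np.ndarray  # local hour before each delay
    event_hours: np.ndarray  # local hour of every event


def featurize(stream: EventStream) -> AccountFeatures:
    series = compute_delays(stream)
    clock = clock_features(stream)
    return AccountFeatures(
        account_id=stream.account_id,
        label=stream.label,
        delays=series.delays,
        preceding_hours=series.preceding_hour,
        event_hours=clock.local_hour,
    )


def _as_features(cohort) -> list[AccountFeatures]:
    out = []
    for item in cohort:
        out.append(item if isinstance(item, AccountFeatures) else featurize(item))
    return out


def _class_order(labels: Iterable[str]) -> tuple[str, ...]:
    present = list(dict.fromkeys(labels))
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(c for c in present if c not in CLASS_ORDER)
    return tuple(ordered)


@dataclass
class ClassModel:
    """Per-class empirical densities plus priors, for one feature mode."""

    classes: tuple[str, ...]
    mode: str
    priors: np.ndarray
    delay_densities: dict[str, LogBinnedDensity] = field(default_factory=dict)
    hour_densities: dict[str, HourDensity] = field(default_factory=dict)
    joint_densities: dict[str, JointDensity] = field(default_factory=dict)
    bin_config: BinConfig = BinConfig()

    def __post_init__(self) -> None:
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode {self.mode!r}")
        self.priors = np.asarray(self.priors, dtype=float)
        if len(self.priors) != len(self.classes):
            raise ValueError("need one prior per class")
        if abs(self.priors.sum() - 1.0) > 1e-9 or np.any(self.priors < 0):
            raise ValueError("priors must be a probability vector")


@dataclass
class ClassificationOutcome:
    account_id: str
    scores: dict[str, float]
    predicted: str
    true_label: str | None = None


@dataclass
class EvaluationReport:
    """Aggregate classification performance."""

    mode: str
    classes: tuple[str, ...]
    accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted
    n_per_class: dict[str, int]
    per_repeat_accuracy: list[float] | None = None

    @property
    def mean_accuracy(self) -> float:
        if self.per_repeat_accuracy:
            return float(np.mean(self.per_repeat_accuracy))
        return self.accuracy

    @property
    def sd_accuracy(self) -> float:
        if self.per_repeat_accuracy and len(self.per_repeat_accuracy) > 1:
            return float(np.std(self.per_repeat_accuracy, ddof=1))
        return 0.0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "n_per_class": self.n_per_class,
            "per_repeat_accuracy": self.per_repeat_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
        }


# ---------------------------------------------------------------------------
# training and scoring

def train(
    cohort,
    mode: str = "ji",
    bin_config: BinConfig = BinConfig(),
    priors: Sequence[float] | None = None,
    delay_floor: float = DELAY_FLOOR,
    hour_floor: float = HOUR_FLOOR,
) -> ClassModel:
    """Fit pooled per-class densities for the requested feature mode.

    All events of all training accounts of a class are pooled into one class
    density. ``tt`` pools the local hour of every event; the joint modes pool
    the paired (delay, preceding hour) samples.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}")
    feats = _as_features(cohort)
    classes = _class_order(f.label for f in feats)
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    model = ClassModel(classes=classes, mode=mode, priors=np.asarray(priors, float),
                       bin_config=bin_config)
    for cls in classes:
        members = [f for f in feats if f.label == cls]
        if not members:
            raise ValueError(f"class {cls!r} has no training accounts")
        delays = np.concatenate([f.delays for f in members])
        pre_hours = np.concatenate([f.preceding_hours for f in members])
        event_hours = np.concatenate([f.event_hours for f in members])
        if delays.size == 0:
            raise ValueError(f"class {cls!r} has no delays")
        if mode in ("itd", "ji", "jni"):
            model.delay_densities[cls] = fit_delay_density(
                delays, bin_config, floor=delay_floor
            )
        if mode == "tt":
            model.hour_densities[cls] = fit_hour_density(event_hours, floor=hour_floor)
        elif mode in ("ji", "jni"):
            # hour marginal of the joint is trained on the preceding hours,
            # keeping it consistent with the paired samples
            model.hour_densities[cls] = fit_hour_density(pre_hours, floor=hour_floor)
        if mode in ("ji", "jni"):
            model.joint_densities[cls] = fit_joint(
                model.delay_densities[cls],
                model.hour_densities[cls],
                mode="independent" if mode == "ji" else "full2d",
                paired_samples=None if mode == "ji" else (delays, pre_hours),
            )
    return model


def account_score(model: ClassModel, account) -> dict[str, float]:
    """Log-likelihood score of each class for one account: the sum over the
    account's events of the log class density at the event's feature value."""
    f = account if isinstance(account, AccountFeatures) else featurize(account)
    if model.mode == "itd":
        if f.delays.size == 0:
            raise ValueError("account has no delays to score")
    elif model.mode == "tt":
        if f.event_hours.size == 0:
            raise ValueError("account has no events to score")
    elif f.delays.size == 0:
        raise ValueError("account has no (delay, hour) pairs to score")
    scores = {}
    for cls in model.classes:
        if model.mode == "itd":
            vals = density_at(model.delay_densities[cls], f.delays)
        elif model.mode == "tt":
            vals = model.hour_densities[cls](f.event_hours)
        else:
            vals = model.joint_densities[cls].evaluate(f.delays, f.preceding_hours)
        scores[cls] = float(np.sum(np.log(vals)))
    return scores


def classify_account(model: ClassModel, account) -> ClassificationOutcome:
    """MAP assignment: argmax of score + log prior, ties to the first class
    in model order."""
    f = account if isinstance(account, AccountFeatures) else featurize(account)
    scores = account_score(model, f)
    posterior = np.array([scores[c] for c in model.classes]) + np.log(model.priors)
    predicted = model.classes[int(np.argmax(posterior))]
    return ClassificationOutcome(
        account_id=f.account_id,
        scores=scores,
        predicted=predicted,
        true_label=f.label if f.label != "unlabelled" else None,
    )


# ---------------------------------------------------------------------------
# evaluation

def _report(mode, classes, outcomes) -> EvaluationReport:
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for out in outcomes:
        confusion[index[out.true_label], index[out.predicted]] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total) if total else float("nan")
    n_per_class = {c: int(confusion[i].sum()) for c, i in index.items()}
    return EvaluationReport(
        mode=mode, classes=classes, accuracy=accuracy,
        confusion=confusion, n_per_class=n_per_class,
    )


def loocv(cohort, mode: str = "ji", bin_config: BinConfig = BinConfig(),
          **train_kwargs) -> EvaluationReport:
    """Leave-one-out cross-validation: each account is classified by a model
    trained on all the others."""
    feats = _as_features(cohort)
    classes = _class_order(f.label for f in feats)
    sizes = {c: sum(1 for f in feats if f.label == c) for c in classes}
    small = [c for c, k in sizes.items() if k < 2]
    if small:
        raise ValueError(f"leave-one-out needs >= 2 accounts per class; too few in {small}")
    outcomes = []
    for i, held_out in enumerate(feats):
        rest = feats[:i] + feats[i + 1:]
        model = train(rest, mode=mode, bin_config=bin_config, **train_kwargs)
        outcomes.append(classify_account(model, held_out))
    return _report(mode, classes, outcomes)


def _stratified_split(feats, train_fraction, rng):
    train_set, test_set = [], []
    classes = _class_order(f.label for f in feats)
    for cls in classes:
        members = [f for f in feats if f.label == cls]
        perm = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        if len(members) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 accounts to split")
        for j, idx in enumerate(perm):
            (train_set if j < n_train else test_set).append(members[idx])
    return train_set, test_set


def split_evaluate(
    cohort,
    mode: str = "ji",
    train_fraction: float = 0.7,
    n_repeats: int = 10,
    seed=None,
    bin_config: BinConfig = BinConfig(),
) -> EvaluationReport:
    """Repeated stratified train/test evaluation.

    Per repeat, each class is reshuffled and split ``train_fraction`` /
    rest; accuracy is aggregated over repeats (mean and SD exposed on the
    report). At least one account per class always lands in each side.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    feats = _as_features(cohort)
    classes = _class_order(f.label for f in feats)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_repeat, all_outcomes = [], []
    for _ in range(n_repeats):
        train_set, test_set = _stratified_split(feats, train_fraction, rng)
        model = train(train_set, mode=mode, bin_config=bin_config)
        outcomes = [classify_account(model, f) for f in test_set]
        correct = sum(1 for o in outcomes if o.predicted == o.true_label)
        per_repeat.append(correct / len(outcomes))
        all_outcomes.extend(outcomes)
    report = _report(mode, classes, all_outcomes)
    report.per_repeat_accuracy = per_repeat
    report.accuracy = float(np.mean(per_repeat))
    return report


def shuffled_baseline(
    cohort,
    mode: str = "ji",
    n_repeats: int = 10,
    seed=None,
    bin_config: BinConfig = BinConfig(),
    _identity: bool = False,
) -> EvaluationReport:
    """Chance baseline: the training data are shuffled across the classes,
    so each trained "class" density pools events from all true classes;
    every account is then classified against these scrambled densities and
    scored against its *true* label. Expected accuracy is 1/K for K
    balanced classes.

    Shuffling happens at the event level — the pooled (delay, preceding
    hour) pairs and the pooled event hours are randomly redistributed among
    the classes, preserving each class's event count — which makes the
    pseudo-class densities near-identical mixtures and concentrates the
    baseline tightly around chance. ``_identity`` short-circuits the
    permutation (every event keeps its true class), reducing the baseline
    to the resubstitution accuracy of a model trained on the full cohort.
    """
    feats = _as_features(cohort)
    classes = _class_order(f.label for f in feats)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_class = {c: [f for f in feats if f.label == c] for c in classes}
    pair_delays, pair_hours, event_hours, n_pairs, n_events = {}, {}, {}, {}, {}
    for c in classes:
        pair_delays[c] = np.concatenate([f.delays for f in by_class[c]])
        pair_hours[c] = np.concatenate([f.preceding_hours for f in by_class[c]])
        event_hours[c] = np.concatenate([f.event_hours for f in by_class[c]])
        n_pairs[c] = pair_delays[c].size
        n_events[c] = event_hours[c].size
    all_delays = np.concatenate([pair_delays[c] for c in classes])
    all_pre = np.concatenate([pair_hours[c] for c in classes])
    all_hours = np.concatenate([event_hours[c] for c in classes])
    per_repeat, all_outcomes = [], []
    for _ in range(n_repeats):
        if _identity:
            p_pairs = np.arange(all_delays.size)
            p_events = np.arange(all_hours.size)
        else:
            p_pairs = rng.permutation(all_delays.size)
            p_events = rng.permutation(all_hours.size)
        pseudo, start_p, start_e = [], 0, 0
        for c in classes:
            sl_p = p_pairs[start_p:start_p + n_pairs[c]]
            sl_e = p_events[start_e:start_e + n_events[c]]
            start_p += n_pairs[c]
            start_e += n_events[c]
            pseudo.append(
                AccountFeatures(
                    account_id=f"pooled-{c}",
                    label=c,
                    delays=all_delays[sl_p],
                    preceding_hours=all_pre[sl_p],
                    event_hours=all_hours[sl_e],
                )
            )
        model = train(pseudo, mode=mode, bin_config=bin_config)
        outcomes = [classify_account(model, f) for f in feats]  # true labels ride along
        correct = sum(1 for o in outcomes if o.predicted == o.true_label)
        per_repeat.append(correct / len(outcomes))
        all_outcomes.extend(outcomes)
    report = _report(mode, classes, all_outcomes)
    report.per_repeat_accuracy = per_repeat
    report.accuracy = float(np.mean(per_repeat))
    return report


# ---------------------------------------------------------------------------
# feature-independence diagnostics

def correlation_pair(delays, hours) -> dict[str, float]:
    """Pearson r and Kendall tau between paired delay and hour values."""
    delays = np.asarray(delays, dtype=float)
    hours = np.asarray(hours, dtype=float)
    if delays.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(delays) == 0 or np.std(hours) == 0:
        raise ValueError("correlation undefined for a constant variable")
    r, r_p = stats.pearsonr(delays, hours)
    tau, tau_p = stats.kendalltau(delays, hours)
    return {
        "pearson_r": float(r),
        "pearson_p": float(r_p),
        "kendall_tau": float(tau),
        "kendall_p": float(tau_p),
    }


def independence_tests(cohort) -> dict[str, dict[str, float]]:
    """Per-class correlation between pooled delays and preceding hours; low
    values support the independence assumption behind the ji mode."""
    feats = _as_features(cohort)
    classes = _class_order(f.label for f in feats)
    results = {}
    for cls in classes:
        members = [f for f in feats if f.label == cls]
        delays = np.concatenate([f.delays for f in members])
        hours = np.concatenate([f.preceding_hours for f in members])
        results[cls] = correlation_pair(delays, hours)
    return results
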