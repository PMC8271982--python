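"""Cross-subject evaluation, metrics, and the joint-ordering experiments.

The experiment harness compares joint orderings: E1 pits the anatomical
control ordering B1 against five whole-group permutations (B2-B6); E2
pits B1 against four fully random joint orders (C2-C5).  Each ordering is
trained over several seeded runs on identical subject splits, so the
ordering is the only varying factor; accuracies are compared with a
one-way ANOVA across orderings and pairwise Student's t-tests against B1.

Metric conventions: accuracies are reported in percent; the multiclass
Matthews correlation coefficient is Gorodkin's R_K statistic over the
confusion matrix; t-tests are pooled-variance (equal-variance) and
one-sided by default, testing whether the control ordering outperforms
the alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import LabeledDataset
from .skeleton import get_ordering

__all__ = [
    "ConfusionMatrix",
    "RunReport",
    "ExperimentReport",
    "cross_subject_split",
    "confusion_matrix",
    "evaluate",
    "mcc_multiclass",
    "one_way_anova",
    "pairwise_t_test",
    "run_experiment",
    "E1_ORDERINGS",
    "E2_ORDERINGS",
]

E1_ORDERINGS: tuple[str, ...] = ("B1", "B2", "B3", "B4", "B5", "B6")
E2_ORDERINGS: tuple[str, ...] = ("B1", "C2", "C3", "C4", "C5")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        k = len(self.classes)
        if arr.shape != (k, k):
            raise ValueError(f"expected {k}×{k} counts, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        """Overall accuracy in percent."""
        return 100.0 * float(np.trace(self.counts)) / self.total

    def per_class_accuracy(self) -> dict[str, float | None]:
        """Diagonal / row-sum in percent; ``None`` for empty true classes."""
        out: dict[str, float | None] = {}
        for i, c in enumerate(self.classes):
            row = self.counts[i].sum()
            out[c] = 100.0 * self.counts[i, i] / row if row else None
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_matrix(
    true: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true, predicted, strict=True):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def mcc_multiclass(cm: ConfusionMatrix | np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin's R_K).

    Computed from the confusion matrix as

        R_K = (c·s − Σ_k p_k t_k) / sqrt((s² − Σ p_k²)(s² − Σ t_k²))

    with c the correctly classified count, s the total, and t_k / p_k the
    true / predicted counts of class k.  Degenerate denominators (e.g.
    all mass in one predicted column) return 0.
    """
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    if counts.sum() <= 0:
        raise ValueError("confusion matrix total must be > 0")
    counts = counts.astype(np.float64)
    s = counts.sum()
    c = np.trace(counts)
    t_k = counts.sum(axis=1)
    p_k = counts.sum(axis=0)
    num = c * s - (p_k * t_k).sum()
    den = np.sqrt((s**2 - (p_k**2).sum()) * (s**2 - (t_k**2).sum()))
    return float(num / den) if den > 0 else 0.0


@dataclass
class RunReport:
    """Metrics of one trained model on one evaluation dataset."""

    seed: int
    ordering_id: str
    accuracy: float  # percent
    per_class_accuracy: dict[str, float | None]
    mcc: float  # [-1, 1]
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "ordering_id": self.ordering_id,
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "mcc": self.mcc,
            "confusion": self.confusion.counts.tolist(),
        }


def evaluate(results, ds: LabeledDataset) -> RunReport:
    """Score fitted-model predictions on an encoded dataset."""
    if len(ds) == 0:
        raise ValueError("evaluation dataset is empty")
    predicted = results.predict_labels(ds)
    true = [s.label for s in ds]
    cm = confusion_matrix(true, predicted, results.classes)
    return RunReport(
        seed=results.seed,
        ordering_id=results.ordering_id,
        accuracy=cm.accuracy(),
        per_class_accuracy=cm.per_class_accuracy(),
        mcc=mcc_multiclass(cm),
        confusion=cm,
    )


def cross_subject_split(
    ds: LabeledDataset,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Split by subject: every sample of a subject lands in one split.

    Subjects are shuffled with ``seed`` and dealt to train/val/test in
    order.  Since every subject contributes the same per-class sample
    counts, subject-level assignment preserves class balance.
    """
    subjects = ds.subjects
    need = n_train + n_val + n_test
    if need > len(subjects):
        raise ValueError(
            f"need {need} subjects, dataset has {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(subjects))
    tr = shuffled[:n_train]
    va = shuffled[n_train : n_train + n_val]
    te = shuffled[n_train + n_val : need]
    return (
        ds.subset_by_subjects(tr),
        ds.subset_by_subjects(va),
        ds.subset_by_subjects(te),
    )


def one_way_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, int, int, float]:
    """Classic one-way ANOVA: (F, df_between, df_within, p).

    df_between = g − 1 and df_within = N − g.  If every group has zero
    within-group variance the F statistic is infinite (warned).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    g = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_between, df_within = g - 1, n_total - g
    if all(np.var(a) == 0 for a in arrays):
        warnings.warn("zero within-group variance everywhere; F is infinite")
        grand = np.concatenate(arrays)
        f = 0.0 if np.var(grand) == 0 else np.inf
        return f, df_between, df_within, 0.0 if f else 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), df_between, df_within, float(p)


def pairwise_t_test(
    a: Sequence[float],
    b: Sequence[float],
    one_sided: bool = True,
) -> tuple[float, int, float]:
    """Pooled-variance independent Student's t-test: (t, df, p).

    df = n1 + n2 − 2.  One-sided by default with the alternative
    mean(a) > mean(b) — the direction of interest when ``a`` is the
    control ordering; ``one_sided=False`` gives the two-sided p.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(
        a, b, equal_var=True, alternative="greater" if one_sided else "two-sided"
    )
    return float(res.statistic), df, float(res.pvalue)


@dataclass
class ExperimentReport:
    """Aggregated multi-run, multi-ordering comparison."""

    kind: str  # "E1" or "E2"
    runs: dict[str, list[RunReport]]  # ordering id → per-run reports
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    t_tests: dict[str, tuple[float, int, float]]  # vs control B1

    @property
    def control(self) -> str:
        return "B1"

    def accuracies(self, ordering_id: str) -> np.ndarray:
        return np.array([r.accuracy for r in self.runs[ordering_id]])

    def mean_sd(self) -> pd.DataFrame:
        """The mean ± s.d. (%) presentation per ordering."""
        rows = []
        for oid, reports in self.runs.items():
            acc = self.accuracies(oid)
            mcc = np.array([r.mcc for r in reports])
            rows.append(
                {
                    "ordering": oid,
                    "n_runs": len(reports),
                    "mean_acc": acc.mean(),
                    "sd_acc": acc.std(ddof=1) if len(acc) > 1 else 0.0,
                    "mean_mcc": 100.0 * mcc.mean(),
                    "sd_mcc": 100.0 * (mcc.std(ddof=1) if len(mcc) > 1 else 0.0),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.mean_sd()
        lines = [
            f"Experiment {self.kind}: {len(self.runs)} orderings × "
            f"{len(next(iter(self.runs.values())))} runs",
            "-" * 60,
        ]
        for _, r in df.iterrows():
            lines.append(
                f"  {r['ordering']:>3}  acc {r['mean_acc']:5.1f}% ± "
                f"{r['sd_acc']:.1f}%   MCC {r['mean_mcc']:5.1f}% ± {r['sd_mcc']:.1f}%"
            )
        lines.append(
            f"ANOVA: F({self.anova_df[0]}, {self.anova_df[1]}) = "
            f"{self.anova_f:.2f}, p = {self.anova_p:.3g}"
        )
        n_cmp = len(self.t_tests)
        lines.append(
            f"pairwise t vs {self.control} ({n_cmp} uncorrected comparisons):"
        )
        for oid, (t, df_t, p) in self.t_tests.items():
            lines.append(f"  {self.control} vs {oid}: t({df_t}) = {t:.2f}, p = {p:.3g}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "kind": self.kind,
            "anova": {
                "F": self.anova_f,
                "df": list(self.anova_df),
                "p": self.anova_p,
            },
            "t_tests": {
                oid: {"t": t, "df": df, "p": p}
                for oid, (t, df, p) in self.t_tests.items()
            },
            "runs": {
                oid: [r.to_dict() for r in reports]
                for oid, reports in self.runs.items()
            },
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def run_experiment(
    kind: str,
    dataset: LabeledDataset,
    config=None,
    *,
    split: tuple[int, int, int] = (20, 5, 7),
    split_seed: int = 0,
    base_seed: int = 0,
    orderings: Sequence[str] | None = None,
    eval_on: str = "test",
) -> ExperimentReport:
    """Run a joint-ordering comparison experiment end to end.

    For each ordering the same cross-subject split is encoded and the
    network is trained ``config.runs`` times with seeds ``base_seed + r``;
    accuracies across orderings are compared by one-way ANOVA and by
    pairwise t-tests against the control B1.  ``eval_on`` selects the
    validation or test split for scoring (protocols without a test split
    use validation).
    """
    from .nn.model import SkeletonActionCNN, TrainingConfig

    config = config or TrainingConfig()
    if orderings is None:
        if kind not in ("E1", "E2"):
            raise ValueError("kind must be 'E1' or 'E2'")
        orderings = E1_ORDERINGS if kind == "E1" else E2_ORDERINGS
    if eval_on not in ("val", "test"):
        raise ValueError("eval_on must be 'val' or 'test'")
    train, val, test = cross_subject_split(dataset, *split, seed=split_seed)
    eval_raw = test if (eval_on == "test" and len(test)) else val
    runs: dict[str, list[RunReport]] = {}
    for oid in orderings:
        ordering = get_ordering(oid)
        model = SkeletonActionCNN.from_sequences(
            train, val if len(val) else None, ordering, config
        )
        eval_ds = eval_raw.encode(ordering)
        reports = []
        for r in range(config.runs):
            results = model.fit(seed=base_seed + r)
            reports.append(evaluate(results, eval_ds))
        runs[oid] = reports
    acc_groups = [[r.accuracy for r in runs[oid]] for oid in orderings]
    f, dfb, dfw, p = one_way_anova(acc_groups)
    control = orderings[0]
    t_tests: dict[str, tuple[float, int, float]] = {}
    for oid in orderings:
        if oid == control:
            continue
        a = [r.accuracy for r in runs[control]]
        b = [r.accuracy for r in runs[oid]]
        try:
            t_tests[oid] = pairwise_t_test(a, b)
        except ValueError:
            # all runs identical (tiny smoke experiments): comparison undefined
            t_tests[oid] = (float("nan"), len(a) + len(b) - 2, float("nan"))
    return ExperimentReport(
        kind=kind,
        runs=runs,
        anova_f=f,
        anova_df=(dfb, dfw),
        anova_p=p,
        t_tests=t_tests,
    )
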