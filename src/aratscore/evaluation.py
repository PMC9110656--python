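"""Leave-one-subject-out evaluation and clinical agreement statistics.

Each fold holds out every row of one subject (both sessions and arms);
per domain, features are standardised on the training fold, the training
fold is SMOTE-rebalanced, an ordinal classifier is fitted and the held
out subject's original rows are scored.  Task-level predictions are
summarised as support-weighted accuracy/precision/recall with confusion
matrices per domain, then summed into total ARAT scores per (subject,
session, arm) and compared with the clinical totals by ordinary least
squares and error statistics (ME, MAE, max |error|, RMSE, relative error
as a percentage of the 57-point maximum).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig
from .features import FEATURE_COLUMNS
from .ordinal import FrankHallOrdinalClassifier
from .registry import DOMAINS, MAX_TOTAL_SCORE, N_TASKS

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Leave-one-subject-out folds: one (train subjects, test subject) pair
    per subject, all sessions and arms of the test subject held out."""

    folds: list[tuple[tuple[str, ...], str]]

    def __len__(self) -> int:
        return len(self.folds)


def make_loso_folds(table: pd.DataFrame) -> FoldPlan:
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = [
        (tuple(s for s in subjects if s != test), test)
        for test in subjects
    ]
    return FoldPlan(folds=folds)


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted."""

    counts: np.ndarray
    labels: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Rows normalised by support (rows with zero support stay zero)."""
        sup = self.supports.astype(float)
        out = np.zeros_like(self.counts, dtype=float)
        nz = sup > 0
        out[nz] = self.counts[nz] / sup[nz, None]
        return out


def confusion_from_predictions(
    true: np.ndarray, predicted: np.ndarray
) -> ConfusionMatrix:
    labels = sorted(set(np.asarray(true).tolist()) | set(np.asarray(predicted).tolist()))
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=[int(c) for c in labels])


def weighted_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Support-weighted (accuracy, precision, recall) of a confusion matrix.

    Per-class precision and recall are averaged with weights
    support/total; classes with zero support or an undefined precision
    (never predicted) contribute 0 with a warning.  Weighted recall
    coincides algebraically with overall accuracy.
    """
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(float)
    sup = cm.supports.astype(float)
    weights = sup / total
    diag = np.diag(counts)
    colsum = counts.sum(axis=0)
    precision = np.zeros(len(cm.labels))
    recall = np.zeros(len(cm.labels))
    for i in range(len(cm.labels)):
        if colsum[i] > 0:
            precision[i] = diag[i] / colsum[i]
        elif sup[i] > 0:
            warnings.warn(
                f"class {cm.labels[i]} never predicted; precision counted as 0",
                stacklevel=2,
            )
        if sup[i] > 0:
            recall[i] = diag[i] / sup[i]
    accuracy = float(diag.sum() / total)
    return accuracy, float(weights @ precision), float(weights @ recall)


def run_cross_validation(
    table: pd.DataFrame,
    model_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """LOSO predictions for every row of the feature table.

    Returns a copy of the table with a ``predicted`` column (pandas
    nullable integer; NA where the row's domain could not be trained in
    its fold for lack of a second class).  Standardisation and SMOTE
    happen inside the classifier, on the training fold only; test rows
    are scored as-is.  Row order of the input does not affect any
    prediction: rows are canonically sorted before each fit.
    """
    cfg = model_config or ModelConfig()
    plan = make_loso_folds(table)
    out = table.copy()
    out["predicted"] = pd.array([pd.NA] * len(out), dtype="Int64")

    order = ["subject", "session", "arm", "task"]
    for train_subjects, test_subject in plan.folds:
        for di, domain in enumerate(DOMAINS):
            dom_mask = table["domain"] == domain
            train = table[dom_mask & (table["subject"] != test_subject)]
            test_idx = table.index[dom_mask & (table["subject"] == test_subject)]
            if len(test_idx) == 0:
                continue
            train = train.sort_values(order)
            y = train["score"].to_numpy(dtype=int)
            if len(np.unique(y)) < 2:
                logger.warning(
                    "fold %s, domain %s: single training class; rows left unpredicted",
                    test_subject,
                    domain,
                )
                continue
            X = train[FEATURE_COLUMNS].to_numpy(dtype=float)
            model = FrankHallOrdinalClassifier(
                C=cfg.C,
                k_neighbors=cfg.k_neighbors,
                random_state=cfg.seed + 1000 * di,
            ).fit(X, y)
            test = table.loc[test_idx].sort_values(order)
            preds = model.predict(test[FEATURE_COLUMNS].to_numpy(dtype=float))
            out.loc[test.index, "predicted"] = preds
    return out


def total_scores(predictions: pd.DataFrame) -> pd.DataFrame:
    """Sum task scores into total ARAT scores per (subject, session, arm).

    Unpredicted rows count as 0 toward the estimated total (mirroring the
    missing-task scoring rule) and are logged.  Totals lie in [0, 57].
    """
    n_na = int(predictions["predicted"].isna().sum())
    if n_na:
        logger.warning("%d unpredicted task rows counted as score 0 in totals", n_na)
    df = predictions.copy()
    df["predicted_filled"] = df["predicted"].fillna(0).astype(int)
    grouped = (
        df.groupby(["subject", "session", "arm"], as_index=False)
        .agg(
            clinical_total=("score", "sum"),
            estimated_total=("predicted_filled", "sum"),
            n_tasks=("task", "count"),
        )
    )
    bad = grouped[grouped["n_tasks"] != N_TASKS]
    if not bad.empty:
        raise ValueError(
            f"every (subject, session, arm) group must have {N_TASKS} task scores; "
            f"offending groups: {bad[['subject', 'session', 'arm']].to_dict('records')}"
        )
    if (grouped["clinical_total"] > MAX_TOTAL_SCORE).any() or (
        grouped["estimated_total"] > MAX_TOTAL_SCORE
    ).any():
        raise ValueError(f"total scores must lie in [0, {MAX_TOTAL_SCORE}]")
    return grouped.drop(columns="n_tasks")


def agreement_stats(
    clinical: np.ndarray, estimated: np.ndarray
) -> dict[str, float]:
    """OLS regression and error block between clinical and estimated totals.

    Errors are estimated minus clinical; relative error is
    100 * RMSE / 57.
    """
    clinical = np.asarray(clinical, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if clinical.shape != estimated.shape:
        raise ValueError("clinical and estimated totals must be paired")
    if clinical.size < 3:
        raise ValueError("need at least 3 pairs for agreement statistics")
    res = stats.linregress(clinical, estimated)
    err = estimated - clinical
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "mean_error": float(err.mean()),
        "mean_absolute_error": float(np.abs(err).mean()),
        "max_absolute_error": float(np.abs(err).max()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "relative_error_pct": float(100.0 * np.sqrt(np.mean(err**2)) / MAX_TOTAL_SCORE),
    }


@dataclass
class EvaluationReport:
    """Everything the LOSO evaluation produces, serialisable to JSON/CSV."""

    per_domain: dict[str, dict[str, float]]
    confusion: dict[str, ConfusionMatrix]
    totals: pd.DataFrame
    agreement: dict[str, float]
    seed: int = 0
    config_hash: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "per_domain": self.per_domain,
            "confusion": {
                d: {"labels": cm.labels, "counts": cm.counts.tolist()}
                for d, cm in self.confusion.items()
            },
            "totals": self.totals.to_dict(orient="records"),
            "agreement": self.agreement,
            **self.extra,
        }

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.totals.to_csv(outdir / "totals.csv", index=False)
        for dom, cm in self.confusion.items():
            pd.DataFrame(
                cm.counts, index=cm.labels, columns=cm.labels
            ).to_csv(outdir / f"confusion_{dom}.csv")

    @classmethod
    def load(cls, outdir: str | Path) -> "EvaluationReport":
        d = json.loads((Path(outdir) / "report.json").read_text())
        return cls(
            per_domain=d["per_domain"],
            confusion={
                dom: ConfusionMatrix(
                    counts=np.asarray(c["counts"]), labels=c["labels"]
                )
                for dom, c in d["confusion"].items()
            },
            totals=pd.DataFrame(d["totals"]),
            agreement=d["agreement"],
            seed=d.get("seed", 0),
            config_hash=d.get("config_hash", ""),
        )


def evaluate(
    table: pd.DataFrame,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    config_hash: str = "",
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Full LOSO evaluation of a feature table.

    Returns the report and the per-row prediction table.
    """
    predictions = run_cross_validation(table, model_config)
    per_domain: dict[str, dict[str, float]] = {}
    confusion: dict[str, ConfusionMatrix] = {}
    for domain in DOMAINS:
        rows = predictions[
            (predictions["domain"] == domain) & predictions["predicted"].notna()
        ]
        if rows.empty:
            continue
        cm = confusion_from_predictions(
            rows["score"].to_numpy(dtype=int), rows["predicted"].to_numpy(dtype=int)
        )
        acc, prec, rec = weighted_metrics(cm)
        per_domain[domain] = {
            "weighted_accuracy": acc,
            "weighted_precision": prec,
            "weighted_recall": rec,
            "n_rows": int(len(rows)),
        }
        confusion[domain] = cm
    totals = total_scores(predictions)
    agreement = agreement_stats(
        totals["clinical_total"].to_numpy(), totals["estimated_total"].to_numpy()
    )
    report = EvaluationReport(
        per_domain=per_domain,
        confusion=confusion,
        totals=totals,
        agreement=agreement,
        seed=seed,
        config_hash=config_hash,
    )
    return report, predictions
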