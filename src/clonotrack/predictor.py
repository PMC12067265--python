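"""Pretreatment-expression predictor of induced BCR diversity.

Genes differentially expressed between patients whose BCR diversity will
increase under PD-1 blockade and those whose will not (Wilcoxon rank-sum,
BH q < 0.05, |log2FC| >= 1) feed a small feed-forward network (one hidden
layer, width 32) on gene-wise standardized inputs. Predictions on external
cohorts are validated by survival stratification, with a non-PD-1 control
arm as the specificity check: a signature specific to checkpoint blockade
must not stratify patients who never received it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from statsmodels.stats.multitest import multipletests

from . import survival as surv
from .config import InputError

MODEL_FORMAT_VERSION = 1
MAX_MISSING_GENE_FRACTION = 0.2
LOW_CONFIDENCE_MARGIN = 0.1

LABEL_POS = "increase"
LABEL_NEG = "no_increase"


@dataclass
class DEResult:
    """Per-gene differential expression with the selected signature."""

    table: pd.DataFrame  # index gene: log2fc, p, q, excluded flag
    selected: list[str]
    q_threshold: float
    lfc_threshold: float


@dataclass
class PredictorModel:
    """A serializable one-hidden-layer classifier over a fixed gene list.

    Prediction is a pure function of the (cohort-standardized) gene
    vector; the manifest stores weights, the training standardization, and
    the training seed so reloads are bit-stable.
    """

    genes: list[str]
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    train_mean: np.ndarray
    train_std: np.ndarray
    seed: int
    withheld_accuracy: float
    withheld_n: int
    format_version: int = MODEL_FORMAT_VERSION

    def decision_scores(self, Z: np.ndarray) -> np.ndarray:
        """Probability of the increase class from standardized inputs."""
        h = Z
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        logits = (h @ self.coefs[-1] + self.intercepts[-1]).ravel()
        return 1.0 / (1.0 + np.exp(-logits))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": self.format_version,
            "genes": self.genes,
            "coefs": [w.tolist() for w in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "train_mean": self.train_mean.tolist(),
            "train_std": self.train_std.tolist(),
            "seed": self.seed,
            "withheld_accuracy": self.withheld_accuracy,
            "withheld_n": self.withheld_n,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictorModel":
        d = json.loads(Path(path).read_text())
        if d["format_version"] != MODEL_FORMAT_VERSION:
            raise InputError(
                f"unsupported model format version {d['format_version']}"
            )
        return cls(
            genes=list(d["genes"]),
            coefs=[np.asarray(w) for w in d["coefs"]],
            intercepts=[np.asarray(b) for b in d["intercepts"]],
            train_mean=np.asarray(d["train_mean"]),
            train_std=np.asarray(d["train_std"]),
            seed=int(d["seed"]),
            withheld_accuracy=float(d["withheld_accuracy"]),
            withheld_n=int(d["withheld_n"]),
        )


def differential_expression(
    matrix: pd.DataFrame,
    labels: pd.Series,
    q_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> DEResult:
    """Wilcoxon rank-sum DE between increase and no-increase samples.

    ``matrix`` is samples x genes normalized expression; ``labels`` holds
    1/increase vs 0/no_increase per sample. Fold change is the log2 ratio
    of group means (increase over no_increase). All-zero genes are
    excluded with a flag.
    """
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise InputError("every sample needs a label")
    y = _binary_labels(labels)
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise InputError("need >= 3 samples per label for DE")
    X = matrix.to_numpy(dtype=float)
    pos, neg = X[y == 1], X[y == 0]
    excluded = (X.sum(axis=0) == 0) | (X.std(axis=0) == 0)
    p = np.full(X.shape[1], np.nan)
    ok = ~excluded
    if ok.any():
        p[ok] = ranksums(pos[:, ok], neg[:, ok], axis=0).pvalue
    eps = 1e-9
    log2fc = np.log2((pos.mean(axis=0) + eps) / (neg.mean(axis=0) + eps))
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "excluded": excluded},
        index=matrix.columns,
    )
    sel = table.index[
        ~table["excluded"]
        & (table["q"] < q_threshold)
        & (table["log2fc"].abs() >= lfc_threshold)
    ]
    return DEResult(table, list(sel), q_threshold, lfc_threshold)


def _binary_labels(labels: pd.Series) -> np.ndarray:
    def conv(v):
        if v in (1, True, LABEL_POS, "1"):
            return 1
        if v in (0, False, LABEL_NEG, "0"):
            return 0
        raise InputError(f"unrecognized label {v!r}")

    return np.array([conv(v) for v in labels])


def _standardize(X: np.ndarray, mean=None, std=None):
    if mean is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return (X - mean) / std, mean, std


def train_predictor(
    matrix: pd.DataFrame,
    labels: pd.Series,
    de_genes: list[str],
    split_fraction: float = 0.2,
    seed: int = 0,
    hidden_width: int = 32,
) -> PredictorModel:
    """Train the network on the DE signature with a stratified withheld
    split and report withheld accuracy."""
    if not de_genes:
        raise InputError("de_genes must be nonempty")
    missing = set(de_genes) - set(matrix.columns)
    if missing:
        raise InputError(f"training matrix lacks genes: {sorted(missing)}")
    y = _binary_labels(labels.reindex(matrix.index))
    X = matrix[de_genes].to_numpy(dtype=float)
    Z, mean, std = _standardize(X)
    for attempt in range(5):
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)), test_size=split_fraction,
            random_state=seed + attempt, stratify=y,
        )
        if len(np.unique(y[idx_te])) == 2:
            if attempt:
                warnings.warn("re-split to obtain both classes in the withheld set",
                              stacklevel=2)
            break
    else:
        raise InputError("could not form a withheld set with both classes")
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden_width,),
        activation="relu",
        random_state=seed,
        max_iter=800,
        early_stopping=True,
        validation_fraction=0.15,
        n_iter_no_change=20,
    )
    clf.fit(Z[idx_tr], y[idx_tr])
    acc = float((clf.predict(Z[idx_te]) == y[idx_te]).mean())
    return PredictorModel(
        genes=list(de_genes),
        coefs=[np.asarray(w) for w in clf.coefs_],
        intercepts=[np.asarray(b) for b in clf.intercepts_],
        train_mean=mean,
        train_std=std,
        seed=seed,
        withheld_accuracy=acc,
        withheld_n=int(len(idx_te)),
    )


def predict_trajectory(
    model: PredictorModel,
    external: pd.DataFrame,
    standardize_cohort: bool = True,
) -> pd.DataFrame:
    """Per-sample class and score on an external cohort.

    External inputs are gene-wise standardized within their own cohort
    (cross-cohort harmonization); model genes missing from the cohort are
    imputed at the training mean (standardized zero) up to 20% of the
    signature, beyond which prediction is refused.
    """
    if external.shape[0] == 0:
        raise InputError("external matrix is empty")
    missing = [g for g in model.genes if g not in external.columns]
    if len(missing) > MAX_MISSING_GENE_FRACTION * len(model.genes):
        raise InputError(
            f"{len(missing)}/{len(model.genes)} model genes missing from the "
            "external cohort; refusing to predict"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} model gene(s) missing; imputed at training means",
            stacklevel=2,
        )
    Z = np.zeros((external.shape[0], len(model.genes)))
    present = [g for g in model.genes if g in external.columns]
    Xp = external[present].to_numpy(dtype=float)
    if standardize_cohort:
        Zp, _, _ = _standardize(Xp)
    else:
        cols = [model.genes.index(g) for g in present]
        Zp = (Xp - model.train_mean[cols]) / np.where(
            model.train_std[cols] == 0, 1.0, model.train_std[cols]
        )
    for k, g in enumerate(present):
        Z[:, model.genes.index(g)] = Zp[:, k]
    score = model.decision_scores(Z)
    return pd.DataFrame(
        {
            "prediction": np.where(score >= 0.5, LABEL_POS, LABEL_NEG),
            "score": score,
            "low_confidence": np.abs(score - 0.5) < LOW_CONFIDENCE_MARGIN,
            "n_imputed_genes": len(missing),
        },
        index=external.index,
    )


def evaluate_predictions(
    predictions: pd.DataFrame,
    survival_df: pd.DataFrame,
    arm_col: str = "arm",
) -> dict:
    """Per-arm survival stratification by predicted class (log-rank and
    two-group Cox). An arm with a single predicted class is flagged
    undefined; in the specificity design only the PD-1 arm should
    stratify."""
    joined = survival_df.merge(
        predictions["prediction"], left_on="patient_id", right_index=True,
        how="inner",
    )
    if joined.empty:
        raise InputError("predictions and survival records do not join")
    out: dict = {}
    for arm, sub in joined.groupby(arm_col):
        if sub["prediction"].nunique() < 2:
            out[str(arm)] = {"undefined": True, "n": int(len(sub))}
            continue
        records = sub.rename(columns={"prediction": "group"})[
            ["patient_id", "time_days", "event", "group"]
        ]
        lr = surv.logrank_test(records)
        cox = surv.cox_two_group(records, group1=LABEL_POS)
        out[str(arm)] = {
            "undefined": False,
            "n": int(len(sub)),
            "logrank_p": lr.p_value,
            "logrank_chi2": lr.chi_square,
            "hazard_ratio": cox.hazard_ratio,
            "ci_low": cox.ci_low,
            "ci_high": cox.ci_high,
        }
    return out
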