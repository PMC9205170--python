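"""Leave-one-out consensus discovery of drug-response expression signatures.

Given a feature x sample count matrix with binary oxaliplatin-resistant (OR)
vs -sensitive (OS) labels, the workflow is:

1. median-of-ratios size-factor normalization (the DESeq normalization);
2. a per-feature two-group differential-expression (DE) ranking — a Wald-type
   t statistic on log2 normalized, pseudocount-shifted counts with
   Benjamini-Hochberg adjustment (a simplified internal statistic, not a full
   negative-binomial shrinkage model);
3. leave-one-out resampling: one dataset per left-out sample, the top-k DE
   features per fold, and the *consensus* = features present in every fold's
   top-k list;
4. a single-feature logistic-regression predictor search scored by
   leave-one-out classification accuracy (a "score of 1" means every held-out
   sample is classified correctly), plus a multi-classifier validation panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ConsensusSignature",
    "PredictorModel",
    "size_factors",
    "de_rank",
    "top_features",
    "loocv_consensus",
    "single_feature_lr_search",
    "classifier_panel",
    "export_signature",
    "NormalizationError",
    "DEFAULT_TOP_K",
    "DEFAULT_EXPRESSION_FLOOR",
    "CLASSIFIERS",
]

DEFAULT_TOP_K = 100
DEFAULT_EXPRESSION_FLOOR = 5.0  # mean normalized count required to test a feature
_PSEUDOCOUNT = 1.0
_LR_RIDGE = 1e-4  # mild L2 penalty keeps separated data finite

LABELS = ("OS", "OR")


class NormalizationError(ValueError):
    """No feature has positive counts in every sample."""


@dataclass(frozen=True)
class CountMatrix:
    """Integer feature x sample count matrix with OR/OS sample labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples), nonnegative integers
    labels: list[str]  # per sample, "OR" or "OS"

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with feature/sample ids")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        if not set(self.labels).issubset(LABELS):
            raise ValueError(f"labels must be in {LABELS}")
        if min(self.labels.count(g) for g in LABELS) < 2:
            raise ValueError("both OR and OS need at least 2 samples")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
                raise ValueError("counts must be nonnegative integers")
            counts = np.round(counts).astype(np.int64)
        object.__setattr__(self, "counts", counts)

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels])

    def drop_sample(self, sample_id: str) -> "CountMatrix":
        j = self.sample_ids.index(sample_id)
        keep = [i for i in range(len(self.sample_ids)) if i != j]
        return CountMatrix(
            self.feature_ids,
            [self.sample_ids[i] for i in keep],
            self.counts[:, keep],
            [self.labels[i] for i in keep],
        )

    @classmethod
    def read(cls, counts_tsv, labels_csv) -> "CountMatrix":
        """Counts TSV (first column feature_id) + two-column label CSV."""
        df = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        lab = pd.read_csv(labels_csv, index_col=0).iloc[:, 0]
        return cls(
            [str(f) for f in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(),
            [str(lab[s]) for s in df.columns],
        )

    def write(self, counts_tsv, labels_csv) -> None:
        pd.DataFrame(self.counts, index=pd.Index(self.feature_ids, name="feature_id"),
                     columns=self.sample_ids).to_csv(counts_tsv, sep="\t")
        pd.DataFrame({"sample_id": self.sample_ids, "label": self.labels}).to_csv(
            labels_csv, index=False
        )


# ---------------------------------------------------------------------------
# normalization and differential-expression ranking
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Restricted to features with positive counts in every sample, each
    sample's factor is the median over features of count / geometric row
    mean.  Scale-equivariant: scaling one sample's library scales only its
    factor.  Accepts a CountMatrix or a bare feature x sample array.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    all_positive = np.all(mat > 0, axis=1)
    if not all_positive.any():
        raise NormalizationError("no feature has positive counts in every sample")
    ref = mat[all_positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
    return np.median(ref / geomean, axis=0)


def _log_normalized(counts: CountMatrix) -> np.ndarray:
    norm = counts.counts / size_factors(counts)[np.newaxis, :]
    return np.log2(norm + _PSEUDOCOUNT)


def de_rank(counts: CountMatrix, expression_floor: float = DEFAULT_EXPRESSION_FLOOR) -> pd.DataFrame:
    """Two-group DE table: log2FC (OR vs OS), Wald-t p, BH-adjusted p, rank.

    Features whose mean normalized count falls below ``expression_floor``
    are excluded before testing (and before BH adjustment).  Ranking is by
    ascending adjusted p, ties broken by descending |log2FC| then feature id,
    so the ordering is fully deterministic.
    """
    norm = counts.counts / size_factors(counts)[np.newaxis, :]
    expressed = norm.mean(axis=1) >= expression_floor
    if not expressed.any():
        raise ValueError("no feature passes the expression floor")
    logx = np.log2(norm[expressed] + _PSEUDOCOUNT)
    mask_or = counts.group_mask("OR")
    a, b = logx[:, ~mask_or], logx[:, mask_or]  # OS, OR
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")

    log2fc = b.mean(axis=1) - a.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    p = np.where(se > 0, p, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "feature_id": [f for f, keep in zip(counts.feature_ids, expressed) if keep],
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "adj_p": adj_p,
        }
    )
    order = table.sort_values(
        by=["adj_p", "log2fc", "feature_id"],
        ascending=[True, True, True],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
    )
    table = order.reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_features(
    de_table: pd.DataFrame,
    k: int,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> list[str]:
    """Top-k differentially expressed features of a ranked DE table.

    A feature counts as differentially expressed when its fold change is at
    least ``fc_threshold`` (|log2FC| >= log2(fc_threshold)) and its
    BH-adjusted p falls below ``alpha``; the top k of those, in rank order,
    are returned (fewer if fewer pass).  Pass ``fc_threshold=1, alpha=1`` to
    rank without filtering.
    """
    passing = de_table[
        (de_table["log2fc"].abs() >= np.log2(fc_threshold)) & (de_table["adj_p"] < alpha)
    ]
    return passing["feature_id"].head(k).tolist()


# ---------------------------------------------------------------------------
# leave-one-out consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusSignature:
    """Per-fold top-k lists and their all-fold intersection."""

    fold_tops: dict[str, list[str]]  # left-out sample id -> top-k features
    consensus: list[str]
    k: int
    n_folds: int

    def consensus_with_direction(self, de_table: pd.DataFrame) -> pd.DataFrame:
        """Consensus features annotated by full-data log2FC sign (OR vs OS)."""
        sub = de_table[de_table["feature_id"].isin(self.consensus)].copy()
        sub["direction"] = np.where(sub["log2fc"] > 0, "up", "down")
        return sub.reset_index(drop=True)


def loocv_consensus(
    counts: CountMatrix,
    k: int = DEFAULT_TOP_K,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
) -> ConsensusSignature:
    """One DE ranking per left-out sample; consensus = features in every top-k.

    With n samples this creates n reduced datasets (each leaving out one
    sample), ranks features in each, takes the top ``k`` differentially
    expressed features (fold change >= ``fc_threshold`` and adjusted
    p < ``alpha``), and intersects the n lists.  Features that owe their
    ranking to a single influential sample drop out of at least one fold, so
    the consensus is robust to any single sample.
    """
    if len(counts.sample_ids) < 4:
        raise ValueError("leave-one-out consensus needs at least 4 samples")
    fold_tops: dict[str, list[str]] = {}
    consensus: set[str] | None = None
    for sid in counts.sample_ids:
        fold = counts.drop_sample(sid)  # validates both groups stay populated
        tops = top_features(de_rank(fold, expression_floor), k, fc_threshold, alpha)
        fold_tops[sid] = tops
        consensus = set(tops) if consensus is None else consensus & set(tops)
    return ConsensusSignature(fold_tops, sorted(consensus), k, len(fold_tops))


# ---------------------------------------------------------------------------
# predictor search and classifier validation panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorModel:
    feature_id: str
    intercept: float
    coefficient: float
    loocv_score: float  # leave-one-out classification accuracy in [0, 1]


def _loocv_accuracy(make_clf, X: np.ndarray, y: np.ndarray) -> float:
    hits = 0
    n = len(y)
    for i in range(n):
        train = np.arange(n) != i
        clf = make_clf()
        clf.fit(X[train], y[train])
        hits += int(clf.predict(X[i : i + 1])[0] == y[i])
    return hits / n


def single_feature_lr_search(counts: CountMatrix, candidates: list[str]) -> list[PredictorModel]:
    """Score each candidate feature as a one-gene logistic-regression predictor.

    Expression is the log2 normalized count; the score is leave-one-out
    classification accuracy.  Constant features are skipped with a warning.
    Models come back sorted by descending score, then feature id.
    """
    unknown = set(candidates) - set(counts.feature_ids)
    if unknown:
        raise KeyError(f"unknown candidate features: {sorted(unknown)}")
    logx = _log_normalized(counts)
    idx = {f: i for i, f in enumerate(counts.feature_ids)}
    y = counts.group_mask("OR").astype(int)
    models = []
    raw = counts.counts
    for feat in candidates:
        x = logx[idx[feat]]
        # a feature with constant raw counts carries no signal even though
        # normalization may leave residual library-size variation
        if np.ptp(x) == 0 or np.ptp(raw[idx[feat]]) == 0:
            warnings.warn(f"feature {feat} is constant; skipped", stacklevel=2)
            continue
        X = x[:, np.newaxis]
        score = _loocv_accuracy(
            lambda: LogisticRegression(C=1.0 / _LR_RIDGE, max_iter=5000), X, y
        )
        full = LogisticRegression(C=1.0 / _LR_RIDGE, max_iter=5000).fit(X, y)
        models.append(
            PredictorModel(feat, float(full.intercept_[0]), float(full.coef_[0, 0]), score)
        )
    return sorted(models, key=lambda m: (-m.loocv_score, m.feature_id))


CLASSIFIERS = (
    "logistic_regression",
    "random_forest",
    "knn",
    "naive_bayes",
    "decision_tree",
    "neural_network",
    "svm",
)


def _make_classifier(name: str, seed: int):
    if name == "logistic_regression":
        return make_pipeline(StandardScaler(), LogisticRegression(C=1.0 / _LR_RIDGE, max_iter=5000))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=3))
    if name == "naive_bayes":
        return GaussianNB()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "neural_network":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=5000, random_state=seed),
        )
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    raise KeyError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def classifier_panel(
    counts: CountMatrix,
    features: list[str],
    classifiers: tuple[str, ...] = CLASSIFIERS,
    seed: int = 0,
) -> pd.DataFrame:
    """LOOCV accuracy of a panel of standard classifiers on a feature subset."""
    if not features:
        raise ValueError("features must be non-empty")
    unknown = set(features) - set(counts.feature_ids)
    if unknown:
        raise KeyError(f"unknown features: {sorted(unknown)}")
    logx = _log_normalized(counts)
    idx = [counts.feature_ids.index(f) for f in features]
    X = logx[idx].T
    y = counts.group_mask("OR").astype(int)
    rows = [
        {"classifier": name, "loocv_accuracy": _loocv_accuracy(lambda: _make_classifier(name, seed), X, y)}
        for name in classifiers
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export for connectivity queries
# ---------------------------------------------------------------------------

def export_signature(de_table: pd.DataFrame, consensus: ConsensusSignature, out_dir) -> dict:
    """Write consensus up/down lists and a ranked .rnk-style TSV.

    The up/down split is by the sign of the full-data log2FC (OR vs OS); the
    .rnk table carries every tested feature with its signed t statistic,
    sorted descending, for rank-based connectivity queries.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotated = consensus.consensus_with_direction(de_table)
    up = annotated.loc[annotated["direction"] == "up", "feature_id"].tolist()
    down = annotated.loc[annotated["direction"] == "down", "feature_id"].tolist()
    (out / "signature_up.txt").write_text("\n".join(up) + ("\n" if up else ""))
    (out / "signature_down.txt").write_text("\n".join(down) + ("\n" if down else ""))
    rnk = de_table[["feature_id", "t_stat"]].sort_values(
        by=["t_stat", "feature_id"], ascending=[False, True]
    )
    rnk.to_csv(out / "signature.rnk", sep="\t", index=False, header=False)
    return {"up": up, "down": down, "rnk": str(out / "signature.rnk")}
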