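"""Computational validation: LASSO reduction, DE baseline, classification.

Gene sets coming out of the network stage (IC, single-measure ICs) are
compared against differential-expression, random and all-gene baselines:
every set is first reduced with an L1-penalized linear fit of the binary
condition label, then scored with a Random-Forest classifier under
stratified 5-fold cross-validation repeated ``n_repetitions`` times, and
the per-repetition metric distributions are compared with paired Wilcoxon
signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso, LassoCV, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

METRIC_NAMES = ("accuracy", "auc", "f1", "precision", "recall", "specificity")


@dataclass
class LassoModel:
    genes: list[str]
    intercept: float
    coefficients: np.ndarray
    alpha: float
    selected: list[str]


@dataclass
class GeneSetCatalog:
    """Named gene sets and their LASSO-reduced counterparts."""

    sets: dict[str, set[str]]
    reduced: dict[str, set[str]]

    def intersections(self) -> pd.DataFrame:
        names = list(self.sets) + [f"{n}_L" for n in self.reduced]
        lookup = {**self.sets, **{f"{n}_L": s for n, s in self.reduced.items()}}
        rows = []
        for a in names:
            for b in names:
                rows.append((a, b, len(lookup[a] & lookup[b])))
        return pd.DataFrame(rows, columns=["set_a", "set_b", "intersection"])


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def lasso_select(
    X: pd.DataFrame,
    labels: np.ndarray,
    policy: str = "cv_1se",
    alpha: float | None = None,
    seed: int = 0,
    family: str = "linear",
) -> LassoModel:
    """L1-penalized fit of the 0/1 label; nonzero-coefficient genes selected.

    Features are standardized before fitting.  Policies:

    * ``cv_1se`` (default): 5-fold CV, largest regularization whose mean CV
      error is within one standard error of the optimum;
    * ``cv_min``: the CV-optimal regularization;
    * ``fixed``: use ``alpha`` directly (``alpha = 0`` falls back to an
      ordinary least-squares fit).

    ``family="logistic"`` swaps in an L1 logistic model (CV-selected C).
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    genes = list(X.columns)
    Z = _standardize(X.to_numpy(dtype=float))

    if family == "logistic":
        clf = LogisticRegressionCV(
            penalty="l1", solver="liblinear", cv=5, random_state=seed, max_iter=5000
        )
        clf.fit(Z, y.astype(int))
        coef = clf.coef_.ravel()
        selected = [g for g, c in zip(genes, coef) if c != 0]
        return LassoModel(genes, float(clf.intercept_[0]), coef, float(1.0 / clf.C_[0]), selected)

    if policy == "fixed":
        if alpha is None:
            raise ValueError("policy='fixed' requires alpha")
        if alpha == 0:
            A = np.column_stack([np.ones(len(y)), Z])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            coef = beta[1:]
            selected = [g for g, c in zip(genes, coef) if c != 0]
            return LassoModel(genes, float(beta[0]), coef, 0.0, selected)
        chosen = float(alpha)
    else:
        cv = LassoCV(cv=5, random_state=seed, alphas=100, max_iter=50000)
        cv.fit(Z, y)
        if policy == "cv_min":
            chosen = float(cv.alpha_)
        elif policy == "cv_1se":
            mean_mse = cv.mse_path_.mean(axis=1)
            se_mse = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
            best = int(np.argmin(mean_mse))
            limit = mean_mse[best] + se_mse[best]
            # alphas_ are sorted descending: the first admissible one is the
            # largest (most regularized) within one SE of the optimum
            admissible = np.nonzero(mean_mse <= limit)[0]
            chosen = float(cv.alphas_[admissible[0]])
        else:
            raise ValueError(f"unknown policy: {policy!r}")
    model = Lasso(alpha=chosen, max_iter=50000)
    model.fit(Z, y)
    coef = model.coef_
    selected = [g for g, c in zip(genes, coef) if c != 0]
    return LassoModel(genes, float(model.intercept_), coef, chosen, selected)


def de_genes(
    normal: pd.DataFrame,
    cancer: pd.DataFrame,
    alpha: float = 0.05,
    lfc: float = 2.0,
) -> pd.DataFrame:
    """Welch-t differential expression on log2(FPKM + 1) with BH adjustment.

    This is a deliberately simple stand-in for a negative-binomial DE
    framework: per gene, a two-sided Welch t-test on log2(x + 1) across
    conditions, Benjamini-Hochberg correction across genes, and a call at
    adj-p < ``alpha`` and |log2FC| > ``lfc``.  Inputs are genes x samples.
    """
    if normal.shape[1] < 2 or cancer.shape[1] < 2:
        raise ValueError("need at least 2 samples per condition")
    genes = list(normal.index)
    if list(cancer.index) != genes:
        raise ValueError("matrices must share the gene universe in the same order")
    ln = np.log2(normal.to_numpy() + 1.0)
    lc = np.log2(cancer.to_numpy() + 1.0)
    log2fc = lc.mean(axis=1) - ln.mean(axis=1)
    tstat, p = stats.ttest_ind(lc, ln, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, adj_p, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj_p}, index=pd.Index(genes, name="gene_id")
    )
    out["is_de"] = (out["adj_p"] < alpha) & (out["log2fc"].abs() > lfc)
    return out


def build_catalog(
    all_genes: list[str],
    ic: set[str],
    eucl_ic: set[str],
    pears_ic: set[str],
    de: set[str],
    X: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    lasso_policy: str = "cv_1se",
) -> GeneSetCatalog:
    """Assemble All/IC/DE/Rand/EuclIC/PearsIC and LASSO-reduce each one.

    Rand is a uniform random subset of ``all_genes`` with the IC
    cardinality.  ``X`` is samples x genes over ``all_genes``.
    """
    universe = set(all_genes)
    for name, s in (("ic", ic), ("eucl_ic", eucl_ic), ("pears_ic", pears_ic), ("de", de)):
        if not s <= universe:
            raise ValueError(f"{name} is not a subset of all_genes")
    rng = np.random.default_rng(seed)
    rand = set(rng.choice(sorted(universe), size=len(ic), replace=False)) if ic else set()
    sets = {
        "All": universe,
        "IC": set(ic),
        "DE": set(de),
        "Rand": rand,
        "EuclIC": set(eucl_ic),
        "PearsIC": set(pears_ic),
    }
    reduced = {}
    for name, s in sets.items():
        if not s:
            reduced[name] = set()
            continue
        cols = sorted(s)
        model = lasso_select(X[cols], labels, policy=lasso_policy, seed=seed)
        reduced[name] = set(model.selected)
    return GeneSetCatalog(sets=sets, reduced=reduced)


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy / precision / recall / specificity / F1 from counts."""
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def classify_and_score(
    X: pd.DataFrame,
    labels: np.ndarray,
    n_repetitions: int = 100,
    seed: int = 0,
    n_estimators: int = 500,
    n_splits: int = 5,
) -> pd.DataFrame:
    """Repeated stratified-CV Random-Forest scoring of one gene set.

    Per repetition the folds are reshuffled and the forest re-randomized;
    out-of-fold predictions are pooled and all metrics computed on the
    pooled confusion counts / probabilities.  Returns one row per
    repetition with columns ``accuracy, auc, f1, precision, recall,
    specificity, tp, tn, fp, fn, n``.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < n_splits:
        raise ValueError("too few samples in the minority class for stratified CV")
    if X.shape[1] == 0:
        raise ValueError("gene set is empty")
    Xa = X.to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * n_repetitions)
    rows = []
    for rep in range(n_repetitions):
        fold_seed = int(rep_seeds[2 * rep] % (2**31 - 1))
        forest_seed = int(rep_seeds[2 * rep + 1] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=fold_seed)
        proba = np.empty(len(y))
        pred = np.empty(len(y), dtype=int)
        for k, (train, test) in enumerate(skf.split(Xa, y)):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                raise ValueError("a CV fold is missing one class; input too small")
            clf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=forest_seed + k, n_jobs=1
            )
            clf.fit(Xa[train], y[train])
            proba[test] = clf.predict_proba(Xa[test])[:, list(clf.classes_).index(1)]
            pred[test] = clf.predict(Xa[test])
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        m = metrics_from_confusion(tp, tn, fp, fn)
        m["auc"] = float(roc_auc_score(y, proba))
        m.update({"tp": tp, "tn": tn, "fp": fp, "fn": fn, "n": len(y), "repetition": rep})
        rows.append(m)
    cols = ["repetition", *METRIC_NAMES, "tp", "tn", "fp", "fn", "n"]
    return pd.DataFrame(rows)[cols]


def compare_gene_sets(
    reference: pd.DataFrame,
    others: dict[str, pd.DataFrame],
    metrics: tuple[str, ...] = ("accuracy", "auc", "f1"),
) -> pd.DataFrame:
    """Paired two-sided Wilcoxon signed-rank tests vs. the reference set.

    Returns one row per (set, metric) with the p-value, a significance
    star code (* / ** / *** at 0.05 / 0.01 / 0.001) and a degenerate flag
    when all paired differences are zero (p reported as 1).
    """
    rows = []
    for name, dist in others.items():
        for metric in metrics:
            a = reference[metric].to_numpy()
            b = dist[metric].to_numpy()
            if len(a) != len(b):
                raise ValueError("paired repetition vectors must have equal length")
            diff = a - b
            if np.all(diff == 0):
                p, degenerate = 1.0, True
            else:
                _, p = stats.wilcoxon(a, b, alternative="two-sided")
                degenerate = False
            if p < 0.001:
                stars = "***"
            elif p < 0.01:
                stars = "**"
            elif p < 0.05:
                stars = "*"
            else:
                stars = ""
            rows.append(
                {
                    "set": name,
                    "metric": metric,
                    "p_value": float(p),
                    "stars": stars,
                    "degenerate": degenerate,
                    "mean_reference": float(a.mean()),
                    "mean_other": float(b.mean()),
                }
            )
    return pd.DataFrame(rows)
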