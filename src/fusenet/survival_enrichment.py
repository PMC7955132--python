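"""Cox proportional-hazards screening and knowledge-based enrichment.

Each candidate gene is fitted one at a time in a univariate Cox model on
standardized log2 expression (Efron tie handling via lifelines); genes
passing the FDR < 0.05 and HR outside [0.9, 1.1] screen feed a joint
multivariate model reported with its Concordance statistic.  Knowledge
flags (literature / druggability) are tested for enrichment in the IC set
with a one-sided Fisher exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HR_BAND = (0.9, 1.1)


@dataclass
class MultivariateCox:
    genes: list[str]
    coefficients: pd.Series
    concordance: float
    concordance_se: float
    baseline_survival: pd.DataFrame  # columns: time, survival


@dataclass
class EnrichmentResult:
    source: str
    flagged_in_ic: int
    unflagged_in_ic: int
    flagged_outside: int
    unflagged_outside: int
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.flagged_in_ic, self.unflagged_in_ic],
            [self.flagged_outside, self.unflagged_outside],
        ]


def _covariate_frame(expr: pd.DataFrame, survival: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Join standardized log2 expression of ``genes`` to the survival table.

    ``expr`` is genes x samples on the FPKM scale; covariates are z-scored
    per gene so hazard ratios are per SD.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from the expression matrix: {missing[:5]}")
    samples = [s for s in survival.index if s in expr.columns]
    if not samples:
        raise ValueError("survival table shares no samples with the expression matrix")
    x = np.log2(expr.loc[genes, samples].to_numpy() + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    df = pd.DataFrame(z.T, index=samples, columns=genes)
    df["time"] = survival.loc[samples, "time"].to_numpy()
    df["event"] = survival.loc[samples, "event"].to_numpy()
    return df


def cox_univariate_screen(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    genes: list[str],
    alpha: float = 0.05,
    hr_band: tuple[float, float] = HR_BAND,
) -> pd.DataFrame:
    """Per-gene univariate Cox fits with BH-FDR and HR-band screening.

    Returns a DataFrame indexed by gene with columns ``coef, hr, p, adj_p,
    significant, informative, passes``.  Non-convergent genes are excluded
    with a warning.
    """
    if int(survival["event"].sum()) < 1:
        raise ValueError("no observed events in the survival table")
    frame = _covariate_frame(expr, survival, genes)
    rows = {}
    for gene in genes:
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    frame[[gene, "time", "event"]],
                    duration_col="time",
                    event_col="event",
                )
        except Exception as exc:  # noqa: BLE001 - any fit failure excludes the gene
            logger.warning("Cox fit failed for %s: %s", gene, exc)
            continue
        coef = float(cph.params_[gene])
        rows[gene] = {"coef": coef, "hr": float(np.exp(coef)), "p": float(cph.summary.loc[gene, "p"])}
    if not rows:
        raise ValueError("no gene produced a convergent Cox fit")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    _, adj_p, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["adj_p"] = adj_p
    out["significant"] = out["adj_p"] < alpha
    out["informative"] = (out["hr"] < hr_band[0]) | (out["hr"] > hr_band[1])
    out["passes"] = out["significant"] & out["informative"]
    return out


def concordance_index(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> tuple[float, int]:
    """Concordance by pair counting.

    A pair is comparable when the earlier time ends in an event; it is
    concordant when the shorter-lived subject has the higher risk; risk
    ties count 1/2.  Returns (C, number of comparable pairs).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    n = len(time)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            short, long_ = (i, j) if time[i] < time[j] else (j, i)
            if not event[short]:
                continue
            comparable += 1
            if risk[short] > risk[long_]:
                concordant += 1.0
            elif risk[short] == risk[long_]:
                concordant += 0.5
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable, comparable


def cox_multivariate(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    genes: list[str],
    ridge_penalty: float = 0.0,
) -> MultivariateCox:
    """Joint Cox fit on the screened genes with Concordance and SE.

    A collinearity failure triggers a ridge-stabilized refit (penalizer
    0.1) with a warning.  The SE of the Concordance is the binomial-style
    approximation sqrt(C * (1 - C) / n_comparable_pairs).  Because the
    covariates are standardized (mean 0), the baseline survival curve is
    the curve at mean covariates.
    """
    if not genes:
        raise ValueError("no screened genes to fit")
    frame = _covariate_frame(expr, survival, genes)
    cph = CoxPHFitter(penalizer=ridge_penalty)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # noqa: BLE001
        logger.warning("multivariate Cox failed (%s); refitting with ridge penalty", exc)
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event")
    risk = cph.predict_partial_hazard(frame).to_numpy().ravel()
    c, n_pairs = concordance_index(
        frame["time"].to_numpy(), frame["event"].to_numpy(), risk
    )
    se = float(np.sqrt(c * (1.0 - c) / n_pairs)) if n_pairs else float("nan")
    baseline = cph.baseline_survival_.reset_index()
    baseline.columns = ["time", "survival"]
    return MultivariateCox(
        genes=list(genes),
        coefficients=cph.params_,
        concordance=float(c),
        concordance_se=se,
        baseline_survival=baseline,
    )


def fisher_enrichment(
    ic_genes: set[str],
    universe: set[str],
    flags: pd.Series,
    source: str = "knowledge",
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher exact enrichment of flagged genes in the IC set."""
    if not ic_genes:
        raise ValueError("IC gene set is empty")
    if not ic_genes <= universe:
        raise ValueError("ic_genes must be a subset of the universe")
    missing = [g for g in universe if g not in flags.index]
    if missing:
        raise ValueError(f"flags missing for genes: {missing[:5]}")
    flagged = {g for g in universe if bool(flags.loc[g])}
    a = len(ic_genes & flagged)
    b = len(ic_genes - flagged)
    c = len(flagged - ic_genes)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(
        source=source,
        flagged_in_ic=a,
        unflagged_in_ic=b,
        flagged_outside=c,
        unflagged_outside=d,
        odds_ratio=float(odds),
        p_value=float(p),
    )
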