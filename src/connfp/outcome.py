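"""Surgical-outcome modelling: backward-stepwise binary logistic regression.

The model classifies patients as seizure-free (coded 1) versus not
seizure-free from the ROI features built by the normative stage (six
binary "increased wDC" indicators and six significant-voxel counts).
Reported alongside the coefficients: the likelihood-ratio model chi-square,
Cox–Snell and Nagelkerke pseudo-R², the Hosmer–Lemeshow calibration
statistic, a classification table at a fixed cutoff, and the ROC curve
with its Mann–Whitney AUC.

Backward elimination follows the likelihood-ratio criterion: at each step
the predictor whose removal test has the largest p-value is dropped while
that p exceeds ``p_remove`` (default 0.10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

import statsmodels.api as sm

__all__ = [
    "SeizureOutcomeModel",
    "SeizureOutcomeResults",
    "ROCResult",
    "fit_logistic",
    "backward_stepwise",
    "fit_indices",
    "hosmer_lemeshow",
    "classification_table",
    "roc_auc",
]

_SEPARATION_COEF = 15.0  # |beta| beyond this on binary/count features ~ separation


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def fit_indices(ll0: float, ll1: float, n: int) -> tuple[float, float, float]:
    """Model chi-square and the two likelihood pseudo-R² indices.

    X² = -2 (LL0 - LL1); Cox–Snell = 1 - exp(-X²/n);
    Nagelkerke rescales Cox–Snell by its maximum 1 - exp(2 LL0 / n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x2 = max(0.0, -2.0 * (ll0 - ll1))
    cox_snell = 1.0 - np.exp(-x2 / n)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else 0.0
    return float(x2), float(cox_snell), float(nagelkerke)


def hosmer_lemeshow(
    p_hat: np.ndarray, y: np.ndarray, n_groups: int = 10
) -> tuple[float, float, int]:
    """Hosmer–Lemeshow C over deciles of risk.

    Patients are grouped by sorted predicted probability with ties kept in
    the same group; the requested group count is reduced automatically when
    fewer distinct probabilities exist. Returns ``(C, p, groups_used)``;
    with fewer than 3 effective groups the statistic is still returned but
    the p-value is NaN (chi-square df would be < 1).
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((p_hat <= 0) | (p_hat >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")

    distinct = np.unique(p_hat)
    g = min(n_groups, distinct.size)
    if distinct.size <= n_groups:
        # one group per distinct fitted probability (binary designs)
        edges = distinct
        group_idx = np.searchsorted(edges, p_hat)
    else:
        ranks = pd.Series(p_hat).rank(method="average")
        group_idx = np.minimum((ranks - 1) * g // len(p_hat), g - 1).astype(int)
        # keep ties together: assign each distinct p the modal group
        frame = pd.DataFrame({"p": p_hat, "g": group_idx})
        remap = frame.groupby("p")["g"].first()
        group_idx = remap.loc[p_hat].to_numpy()
        _, group_idx = np.unique(group_idx, return_inverse=True)
        g = group_idx.max() + 1

    c = 0.0
    for k in range(g):
        sel = group_idx == k
        nk = sel.sum()
        if nk == 0:
            continue
        e1 = p_hat[sel].sum()
        o1 = y[sel].sum()
        e0 = nk - e1
        o0 = nk - o1
        c += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    if g < 3:
        warnings.warn(
            f"Hosmer-Lemeshow has only {g} effective groups; p-value suppressed",
            stacklevel=2,
        )
        return float(c), float("nan"), int(g)
    p = float(stats.chi2.sf(c, g - 2))
    return float(c), p, int(g)


def classification_table(
    p_hat: np.ndarray, y: np.ndarray, cutoff: float = 0.5
) -> dict[str, float]:
    """Percent correctly classified, overall and per class, at a cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y).astype(int)
    pred = (p_hat >= cutoff).astype(int)
    overall = 100.0 * np.mean(pred == y)
    out = {"overall_pct": float(overall), "cutoff": float(cutoff)}
    for cls, name in ((1, "positive_pct"), (0, "negative_pct")):
        sel = y == cls
        out[name] = float(100.0 * np.mean(pred[sel] == cls)) if sel.any() else float("nan")
    out["n"] = int(len(y))
    return out


@dataclass
class ROCResult:
    """ROC coordinates and the Mann–Whitney area under the curve."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })

    def plot(self, ax=None):
        """ROC curve with the chance diagonal; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(1.0 - self.specificity, self.sensitivity,
                drawstyle="steps-post", label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", frameon=False)
        return ax


def roc_auc(p_hat: np.ndarray, y: np.ndarray) -> ROCResult:
    """ROC curve with AUC computed as the Mann–Whitney concordance.

    AUC = P(score_pos > score_neg) + 0.5 P(tie), estimated over all
    positive/negative pairs via midranks.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both outcome classes present")
    ranks = stats.rankdata(p_hat)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(y, p_hat)
    return ROCResult(
        cutoffs=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=float(auc)
    )


# ---------------------------------------------------------------------------
# maximum-likelihood engine
# ---------------------------------------------------------------------------

def _ml_fit(x: pd.DataFrame, y: np.ndarray):
    """Logit MLE with separation handling: returns (params, bse, pvalues,
    llf, converged, separation_flag)."""
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=100, method="newton", tol=1e-8)
        except Exception:
            # Newton collapses under (quasi-)separation; BFGS limps to the
            # boundary and we flag the fit instead of raising
            res = sm.Logit(y, x).fit(disp=0, maxiter=200, method="bfgs")
            separation = True
    for w in caught:
        if "separation" in str(w.message).lower() or "divide" in str(w.message).lower():
            separation = True
    params = pd.Series(np.asarray(res.params, dtype=float), index=x.columns)
    if not bool(res.mle_retvals.get("converged", True)):
        separation = True
    if np.any(np.abs(params.values) > _SEPARATION_COEF) or not np.all(np.isfinite(params)):
        separation = True
    try:
        with np.errstate(all="ignore"):
            bse = pd.Series(np.asarray(res.bse, dtype=float), index=x.columns)
            pvalues = pd.Series(np.asarray(res.pvalues, dtype=float), index=x.columns)
    except Exception:  # singular Hessian at the boundary
        separation = True
        bse = pd.Series(np.nan, index=x.columns)
        pvalues = pd.Series(np.nan, index=x.columns)
    return params, bse, pvalues, float(res.llf), bool(res.mle_retvals.get("converged", True)), separation


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        raise ValueError("outcome is constant; a classification model is undefined")
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class SeizureOutcomeResults:
    """Fitted outcome model: coefficients, fit indices and diagnostics."""

    params: pd.Series
    bse: pd.Series
    wald_pvalues: pd.Series
    llf: float
    llnull: float
    nobs: int
    predictors: list[str]
    fittedvalues: np.ndarray = field(repr=False)
    endog: np.ndarray = field(repr=False)
    converged: bool = True
    separation: bool = False
    removal_log: list[dict] = field(default_factory=list)
    outcome_coding: str = "1 = seizure-free (SF)"

    # -- fit indices ---------------------------------------------------
    @property
    def lr_stat(self) -> float:
        return fit_indices(self.llnull, self.llf, self.nobs)[0]

    @property
    def lr_df(self) -> int:
        return len(self.predictors)

    @property
    def lr_pvalue(self) -> float:
        if self.lr_df == 0:
            return float("nan")
        return float(stats.chi2.sf(self.lr_stat, self.lr_df))

    @property
    def cox_snell_r2(self) -> float:
        return fit_indices(self.llnull, self.llf, self.nobs)[1]

    @property
    def nagelkerke_r2(self) -> float:
        return fit_indices(self.llnull, self.llf, self.nobs)[2]

    def hosmer_lemeshow(self, n_groups: int = 10) -> tuple[float, float, int]:
        return hosmer_lemeshow(self.fittedvalues, self.endog, n_groups)

    def classification_table(self, cutoff: float = 0.5) -> dict[str, float]:
        return classification_table(self.fittedvalues, self.endog, cutoff)

    def roc(self) -> ROCResult:
        return roc_auc(self.fittedvalues, self.endog)

    @property
    def auc(self) -> float:
        return self.roc().auc

    # -- reporting -----------------------------------------------------
    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "B": self.params,
            "SE": self.bse,
            "wald_p": self.wald_pvalues,
        })

    def summary(self) -> str:
        lines = ["Seizure-outcome logistic model"]
        lines.append(f"  outcome coding: {self.outcome_coding}")
        lines.append(f"  n = {self.nobs}; retained predictors: "
                     + (", ".join(self.predictors) if self.predictors else "(none)"))
        if self.separation:
            lines.append("  WARNING: quasi-complete separation detected; "
                         "coefficients lie near the boundary")
        lines.append("")
        lines.append(self.coef_frame().round(4).to_string())
        lines.append("")
        x2, cs, nk = fit_indices(self.llnull, self.llf, self.nobs)
        lines.append(f"  model X2 = {x2:.2f} (df {self.lr_df}, p = {self.lr_pvalue:.4g})")
        lines.append(f"  Cox-Snell R2 = {cs:.3f}   Nagelkerke R2 = {nk:.3f}")
        try:
            c, p_hl, g = self.hosmer_lemeshow()
            lines.append(f"  Hosmer-Lemeshow C = {c:.3f} over {g} groups (p = {p_hl:.3g})")
        except ValueError as exc:  # fitted probabilities on the boundary
            lines.append(f"  Hosmer-Lemeshow unavailable: {exc}")
        ct = self.classification_table()
        lines.append(
            f"  classification at {ct['cutoff']:.2f}: overall {ct['overall_pct']:.1f}%, "
            f"SF {ct['positive_pct']:.1f}%, non-SF {ct['negative_pct']:.1f}%"
        )
        lines.append(f"  ROC AUC = {self.auc:.3f}")
        if self.removal_log:
            lines.append("")
            lines.append("  backward elimination:")
            for entry in self.removal_log:
                lines.append(
                    f"    step {entry['step']}: {entry['action']} {entry['predictor']}"
                    + (f" (removal p = {entry['p']:.3f})" if entry.get("p") is not None else "")
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class SeizureOutcomeModel:
    """Binary logistic model of post-surgical seizure freedom.

    Parameters
    ----------
    endog : array-like of 0/1
        Outcome, 1 = seizure-free.
    exog : DataFrame
        Predictor columns (no constant; one is added internally).
    """

    def __init__(self, endog, exog: pd.DataFrame):
        y = np.asarray(endog).astype(float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome is constant; a classification model is undefined")
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog))
            exog.columns = [f"x{j}" for j in range(exog.shape[1])]
        if exog.shape[0] != len(y):
            raise ValueError("endog and exog lengths differ")
        self.endog = y
        self.exog = exog.astype(float).reset_index(drop=True)
        self.llnull = _null_llf(y)

    @classmethod
    def from_feature_table(
        cls,
        table: pd.DataFrame,
        outcome_col: str = "outcome",
        predictors: list[str] | None = None,
    ) -> "SeizureOutcomeModel":
        """Build from the normative stage's feature table.

        Default predictors are every ``*_ind`` and ``*_nsig`` column — the
        six indicators plus six voxel-count confound variables.
        """
        if predictors is None:
            predictors = [
                c for c in table.columns
                if c.endswith("_ind") or c.endswith("_nsig")
            ]
        if not predictors:
            raise ValueError("no predictor columns found")
        return cls(table[outcome_col], table[predictors])

    # -- fitting ---------------------------------------------------------
    def _fit_subset(self, cols: list[str]):
        x = sm.add_constant(self.exog[cols], has_constant="add")
        return _ml_fit(x, self.endog)

    def fit(self, predictors: list[str] | None = None) -> SeizureOutcomeResults:
        """Maximum-likelihood fit with all (or the given) predictors."""
        cols = list(self.exog.columns) if predictors is None else list(predictors)
        if len(self.endog) <= len(cols) + 1:
            raise ValueError(
                f"n = {len(self.endog)} too small for {len(cols)} predictors"
            )
        params, bse, pvals, llf, converged, sep = self._fit_subset(cols)
        x = sm.add_constant(self.exog[cols], has_constant="add")
        eta = x.to_numpy() @ params.to_numpy()
        fitted = 1.0 / (1.0 + np.exp(-eta))
        return SeizureOutcomeResults(
            params=params, bse=bse, wald_pvalues=pvals,
            llf=llf, llnull=self.llnull, nobs=len(self.endog),
            predictors=cols, fittedvalues=fitted, endog=self.endog,
            converged=converged, separation=sep,
        )

    def fit_backward(self, p_remove: float = 0.10) -> SeizureOutcomeResults:
        """Backward elimination by likelihood-ratio removal tests.

        Starting from all predictors, the predictor whose 1-df removal
        test has the largest p is dropped while that p > ``p_remove``.
        Constant predictor columns are unidentifiable and dropped upfront.
        """
        removal_log: list[dict] = []
        cols = list(self.exog.columns)
        step = 0
        for c in list(cols):
            if self.exog[c].nunique() < 2:
                cols.remove(c)
                removal_log.append({
                    "step": step, "action": "dropped constant column",
                    "predictor": c, "p": None,
                })

        current = self.fit(cols) if cols else self._intercept_only(removal_log)
        while cols:
            pvals = {}
            for c in cols:
                reduced_cols = [k for k in cols if k != c]
                if reduced_cols:
                    _, _, _, llf_red, _, _ = self._fit_subset(reduced_cols)
                else:
                    llf_red = self.llnull
                lr = max(0.0, 2.0 * (current.llf - llf_red))
                pvals[c] = float(stats.chi2.sf(lr, 1))
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= p_remove:
                break
            step += 1
            cols.remove(worst)
            removal_log.append({
                "step": step, "action": "removed", "predictor": worst,
                "p": pvals[worst],
            })
            current = self.fit(cols) if cols else self._intercept_only(removal_log)
        current.removal_log = removal_log
        return current

    def _intercept_only(self, removal_log: list[dict]) -> SeizureOutcomeResults:
        p = self.endog.mean()
        const = float(np.log(p / (1 - p)))
        se = float(1.0 / np.sqrt(len(self.endog) * p * (1 - p)))
        fitted = np.full(len(self.endog), p)
        return SeizureOutcomeResults(
            params=pd.Series({"const": const}),
            bse=pd.Series({"const": se}),
            wald_pvalues=pd.Series({"const": float(2 * stats.norm.sf(abs(const / se)))}),
            llf=self.llnull, llnull=self.llnull, nobs=len(self.endog),
            predictors=[], fittedvalues=fitted, endog=self.endog,
            removal_log=removal_log,
        )


# ---------------------------------------------------------------------------
# function surface
# ---------------------------------------------------------------------------

def fit_logistic(
    feature_table: pd.DataFrame,
    predictors: list[str],
    outcome_col: str = "outcome",
) -> SeizureOutcomeResults:
    """One-shot ML logistic fit on selected feature-table columns."""
    model = SeizureOutcomeModel.from_feature_table(
        feature_table, outcome_col=outcome_col, predictors=predictors
    )
    return model.fit()


def backward_stepwise(
    feature_table: pd.DataFrame,
    outcome_col: str = "outcome",
    predictors: list[str] | None = None,
    p_remove: float = 0.10,
) -> SeizureOutcomeResults:
    """Backward-stepwise logistic regression over the full feature set."""
    model = SeizureOutcomeModel.from_feature_table(
        feature_table, outcome_col=outcome_col, predictors=predictors
    )
    return model.fit_backward(p_remove=p_remove)
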