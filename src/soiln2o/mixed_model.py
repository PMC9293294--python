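"""Per-factor linear mixed models of the emission factor.

For one controlling factor at a time, the EF is modelled as a one-way fixed
classification with a random intercept per experimental location:

    EF_ij = mu_k(i) + u_loc(i) + e_ij,   u ~ N(0, var_location),
                                         e ~ N(0, var_residual)

estimated by REML.  Class means are the fixed effects; their 95% CIs use a
t quantile on a containment-style residual df,

    df = n_obs - n_classes - (n_locations - 1).

Class means are compared with unadjusted pairwise t tests (Fisher's LSD) and
summarized as letter groupings.  Model-level metrics are the F test of equal
class means, the squared correlation between observed EF and fitted values
(including predicted random effects), and the AIC of a maximum-likelihood
refit so that models with different fixed effects are comparable.

Classes with sample size at or below ``min_class_n`` (default 20) are
dropped before fitting to protect the fixed-effect estimates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "FactorEFModel",
    "UnanalyzableFactorError",
    "SingularFitError",
    "fit_factor_model",
    "lsd_fisher",
    "lsd_letters",
    "merge_classes",
    "MergeDecision",
    "model_metrics",
    "results_table",
]


class UnanalyzableFactorError(ValueError):
    """Fewer than the minimum number of analyzable classes remain."""


class SingularFitError(RuntimeError):
    """The REML fit degenerated (zero residual variance)."""


class FactorEFModel(BaseEstimator):
    """Random-intercept model of EF for one controlling factor.

    Parameters
    ----------
    class_col : str
        Column holding the factor's class labels.
    ef_col : str, default "ef"
        Column holding the emission factor response.
    location_col : str, default "location_id"
        Column holding the location identifier (random-intercept grouping).
    min_class_n : int, default 20
        Classes with n <= min_class_n are dropped (with a warning).
    min_classes : int, default 2
        Minimum classes remaining for the factor to be analyzable.  Set to 1
        to allow a single-class (grand mean) fit.
    random_intercept : bool, default True
        If False, the location variance is fixed at zero and the model
        reduces to ordinary least squares on the class indicators.
    alpha : float, default 0.05
        Significance level for CIs and LSD comparisons.
    compute_metrics : bool, default True
        Compute the ML-refit AIC (adds a second optimization).

    Attributes (after ``fit``)
    --------------------------
    classes_, n_per_class_, class_means_, se_, ci95_, lsd_letters_,
    pairwise_p_, model_p_, r2_, aic_, var_location_, var_residual_,
    df_resid_, n_obs_, n_locations_, dropped_classes_.
    """

    def __init__(self, class_col, ef_col="ef", location_col="location_id",
                 min_class_n=20, min_classes=2, random_intercept=True,
                 alpha=0.05, compute_metrics=True):
        self.class_col = class_col
        self.ef_col = ef_col
        self.location_col = location_col
        self.min_class_n = min_class_n
        self.min_classes = min_classes
        self.random_intercept = random_intercept
        self.alpha = alpha
        self.compute_metrics = compute_metrics

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        df = X[[self.class_col, self.ef_col, self.location_col]].copy()
        if y is not None:
            df[self.ef_col] = np.asarray(y, dtype=float)
        df = df.dropna()
        if df.empty:
            raise ValueError("no observations with class, EF and location present")

        counts = df[self.class_col].value_counts()
        keep = counts[counts > self.min_class_n].index
        dropped = sorted(set(counts.index) - set(keep))
        if dropped:
            warnings.warn(
                f"factor {self.class_col!r}: dropping class(es) {dropped} "
                f"with n <= {self.min_class_n}"
            )
        df = df[df[self.class_col].isin(keep)]
        classes = sorted(keep)
        if len(classes) < self.min_classes:
            raise UnanalyzableFactorError(
                f"factor {self.class_col!r}: {len(classes)} class(es) with "
                f"n > {self.min_class_n}; need >= {self.min_classes}"
            )

        endog = df[self.ef_col].to_numpy(dtype=float)
        exog = pd.get_dummies(
            pd.Categorical(df[self.class_col], categories=classes)
        ).to_numpy(dtype=float)
        groups = df[self.location_col].to_numpy()
        k = len(classes)
        n = len(df)
        n_loc = len(pd.unique(groups))

        if self.random_intercept:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    model = sm.MixedLM(endog, exog, groups=groups)
                    res = model.fit(reml=True)
                var_resid = float(res.scale)
                var_loc = float(np.asarray(res.cov_re)[0, 0])
                if var_loc < 0:  # defensive; statsmodels profiles it >= 0
                    warnings.warn("negative location variance clamped at 0")
                    var_loc = 0.0
                means = np.asarray(res.fe_params, dtype=float)
                cov_fe = np.asarray(res.cov_params())[:k, :k]
                df_resid = n - k - (n_loc - 1)
                fitted = np.asarray(res.fittedvalues, dtype=float)
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise SingularFitError(
                    f"mixed-model fit degenerated (zero or singular "
                    f"variance structure): {exc}"
                ) from None
        else:
            res = sm.OLS(endog, exog).fit()
            var_resid = float(res.mse_resid)
            var_loc = 0.0
            means = np.asarray(res.params, dtype=float)
            cov_fe = np.asarray(res.cov_params())
            df_resid = n - k
            fitted = np.asarray(res.fittedvalues, dtype=float)

        if not np.isfinite(var_resid) or var_resid <= 1e-14:
            raise SingularFitError(
                "residual variance estimated at zero: singular fit"
            )
        df_resid = max(int(df_resid), 1)

        se = np.sqrt(np.diag(cov_fe))
        tq = st.t.ppf(1.0 - self.alpha / 2.0, df_resid)
        ci = pd.DataFrame(
            {"low": means - tq * se, "high": means + tq * se}, index=classes
        )

        self.classes_ = list(classes)
        self.n_per_class_ = counts.reindex(classes).astype(int)
        self.class_means_ = pd.Series(means, index=classes, name="mean")
        self.se_ = pd.Series(se, index=classes, name="se")
        self.ci95_ = ci
        self.cov_fe_ = pd.DataFrame(cov_fe, index=classes, columns=classes)
        self.var_location_ = var_loc
        self.var_residual_ = var_resid
        self.df_resid_ = df_resid
        self.n_obs_ = n
        self.n_locations_ = n_loc
        self.dropped_classes_ = dropped

        # model p: F test of equal class means
        if k >= 2:
            R = np.zeros((k - 1, k))
            R[:, 0] = 1.0
            for i in range(k - 1):
                R[i, i + 1] = -1.0
            rb = R @ means
            rvr = R @ cov_fe @ R.T
            fstat = float(rb @ np.linalg.solve(rvr, rb)) / (k - 1)
            self.model_p_ = float(st.f.sf(fstat, k - 1, df_resid))
        else:
            self.model_p_ = np.nan

        # R2: squared correlation between observed and fitted values
        if np.ptp(fitted) < 1e-15 or np.ptp(endog) < 1e-15:
            self.r2_ = np.nan
        else:
            self.r2_ = float(np.corrcoef(endog, fitted)[0, 1] ** 2)

        if self.compute_metrics:
            if self.random_intercept:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    res_ml = sm.MixedLM(endog, exog, groups=groups).fit(reml=False)
                self.aic_ = float(res_ml.aic)
            else:
                self.aic_ = float(res.aic)
        else:
            self.aic_ = np.nan

        self.pairwise_p_, self.lsd_letters_ = lsd_fisher(self) if k >= 2 else (
            pd.DataFrame(index=classes, columns=classes, dtype=float),
            {classes[0]: "A"},
        )
        return self

    # ------------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Marginal (fixed-effect) EF prediction per row's class label."""
        labels = X[self.class_col] if isinstance(X, pd.DataFrame) else pd.Series(X)
        unknown = set(labels.dropna()) - set(self.classes_)
        if unknown:
            raise ValueError(f"unknown class label(s): {sorted(unknown)}")
        return labels.map(self.class_means_).to_numpy(dtype=float)

    def results_frame(self) -> pd.DataFrame:
        """One row per class, mirroring the published summary-table layout."""
        return pd.DataFrame(
            {
                "factor": self.class_col,
                "class": self.classes_,
                "n": self.n_per_class_.values,
                "mean": self.class_means_.values,
                "ci_low": self.ci95_["low"].values,
                "ci_high": self.ci95_["high"].values,
                "letters": [self.lsd_letters_[c] for c in self.classes_],
                "p": self.model_p_,
                "significant": bool(self.model_p_ < self.alpha)
                if np.isfinite(self.model_p_) else False,
                "r2": self.r2_,
                "aic": self.aic_,
            }
        )


def fit_factor_model(observations: pd.DataFrame, class_col: str,
                     **kwargs) -> FactorEFModel:
    """Fit a :class:`FactorEFModel` for one factor (thin wrapper)."""
    return FactorEFModel(class_col=class_col, **kwargs).fit(observations)


# ---------------------------------------------------------------------------
# Fisher's LSD and letter display
# ---------------------------------------------------------------------------
def lsd_fisher(model: FactorEFModel):
    """Unadjusted pairwise t tests on class-mean differences.

    The standard error of each difference comes from the fixed-effect
    covariance; p values use the model's residual df.  Returns the pairwise
    p matrix and the letter grouping (classes sharing no letter differ at
    the model's alpha).
    """
    classes = model.classes_
    if len(classes) < 2:
        raise UnanalyzableFactorError("LSD comparison needs >= 2 classes")
    means = model.class_means_
    V = model.cov_fe_.to_numpy()
    p = pd.DataFrame(np.nan, index=classes, columns=classes, dtype=float)
    for i, j in itertools.combinations(range(len(classes)), 2):
        se_diff = np.sqrt(V[i, i] + V[j, j] - 2.0 * V[i, j])
        tstat = (means.iloc[i] - means.iloc[j]) / se_diff
        pij = 2.0 * st.t.sf(abs(tstat), model.df_resid_)
        p.iloc[i, j] = p.iloc[j, i] = pij
    np.fill_diagonal(p.values, 1.0)
    letters = lsd_letters(p, means, alpha=model.alpha)
    return p, letters


def lsd_letters(p_matrix: pd.DataFrame, means: pd.Series, alpha=0.05):
    """Letter display from a pairwise p matrix.

    Letters are the maximal cliques of the non-significance graph, ordered
    by increasing class mean (so "A" marks the group containing the lowest
    mean).  Two classes share at least one letter iff their pairwise p is
    >= alpha; a class may carry several letters when transitivity fails.
    """
    classes = list(p_matrix.index)
    k = len(classes)
    adj = p_matrix.to_numpy() >= alpha
    np.fill_diagonal(adj, True)

    # enumerate maximal cliques (k is small: <= ~8 classes per factor)
    cliques = []
    for r in range(k, 0, -1):
        for combo in itertools.combinations(range(k), r):
            if all(adj[i, j] for i, j in itertools.combinations(combo, 2)):
                cs = set(combo)
                if not any(cs < c for c in cliques):
                    cliques.append(cs)
    order = np.argsort(means.loc[classes].to_numpy(), kind="stable")
    rank = {idx: pos for pos, idx in enumerate(order)}
    cliques.sort(key=lambda c: min(rank[i] for i in c))
    letters = {c: "" for c in classes}
    for letter, clique in zip(_letter_stream(), cliques):
        for i in sorted(clique, key=lambda i: rank[i]):
            letters[classes[i]] += letter
    return letters


def _letter_stream():
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


# ---------------------------------------------------------------------------
# class merging workflow
# ---------------------------------------------------------------------------
@dataclass
class MergeDecision:
    """Auditable record of a class-merge decision."""

    factor: str
    candidates: tuple[str, ...]
    merged: bool
    merged_label: str | None
    pairwise_p: dict = field(default_factory=dict)
    mean_difference: dict = field(default_factory=dict)


def merge_classes(observations: pd.DataFrame, class_col: str, candidates,
                  merged_label: str | None = None, alpha=0.05,
                  **model_kwargs):
    """Merge candidate classes iff all their pairwise LSD tests are
    non-significant (p >= alpha).

    Returns ``(labels, decision)`` where ``labels`` is the (possibly merged)
    class-label series and ``decision`` a :class:`MergeDecision`.  A
    candidate set with fewer than two labels still present is a no-op, which
    makes the operation idempotent.  Unknown labels raise.
    """
    labels = observations[class_col]
    candidates = tuple(sorted(set(candidates)))
    present = set(labels.dropna().unique())
    unknown = set(candidates) - present
    if unknown:
        raise ValueError(f"unknown class label(s) for {class_col!r}: {sorted(unknown)}")
    if len(candidates) < 2:
        return labels.copy(), MergeDecision(
            factor=class_col, candidates=candidates, merged=False,
            merged_label=None,
        )

    model = FactorEFModel(class_col=class_col, alpha=alpha,
                          compute_metrics=False, **model_kwargs).fit(observations)
    pmat = model.pairwise_p_
    pvals, diffs = {}, {}
    for a, b in itertools.combinations(candidates, 2):
        pvals[(a, b)] = float(pmat.loc[a, b])
        diffs[(a, b)] = float(
            model.class_means_[a] - model.class_means_[b]
        )
    do_merge = all(v >= alpha for v in pvals.values())
    if merged_label is None:
        merged_label = "+".join(candidates)
    decision = MergeDecision(
        factor=class_col, candidates=candidates, merged=do_merge,
        merged_label=merged_label if do_merge else None,
        pairwise_p={f"{a}|{b}": v for (a, b), v in pvals.items()},
        mean_difference={f"{a}|{b}": v for (a, b), v in diffs.items()},
    )
    if not do_merge:
        return labels.copy(), decision
    out = labels.map(lambda v: merged_label if v in candidates else v)
    return out, decision


def model_metrics(model: FactorEFModel):
    """(p, r2, aic) of a fitted factor model, plus a significance flag."""
    p = model.model_p_
    significant = bool(p < model.alpha) if np.isfinite(p) else False
    return {"p": p, "r2": model.r2_, "aic": model.aic_,
            "significant": significant}


def results_table(models) -> pd.DataFrame:
    """Stack per-factor results frames into one summary table."""
    return pd.concat([m.results_frame() for m in models], ignore_index=True)
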