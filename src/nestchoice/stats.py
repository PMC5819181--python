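"""Inference for nursing decisions.

* :class:`PowerNullModel` — the nest-availability null model.  The
  probability y of a communal nest is modelled as a power function of the
  occupancy proportion P, ``y ~ P**a`` (constrained through (0,0) and
  (1,1)), fitted by nonlinear least squares; the null hypothesis of random
  box choice is a = 1, tested with a t statistic from the linearised
  Jacobian.
* :class:`DecisionLogit` — fixed-effect binary logistic regression (IRLS)
  for the communal-vs-solitary decision.
* :class:`ConditionalLogit` — discrete-choice model for partner choice:
  within each event the chosen option competes only against that event's
  option set, P(choose j) = exp(x_j beta) / sum_k exp(x_k beta).
* :func:`mann_whitney` — Wilcoxon-Mann-Whitney rank-sum test with
  midranks, exact by enumeration for small samples.
* :func:`permutation_mean_diff` — event-level label permutation for
  group differences of option-level values (options of one event move
  together, respecting the nesting a random-effects model would absorb).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# power-function null model
# ---------------------------------------------------------------------------

@dataclass
class PowerModelFit:
    a: float
    se: float
    t: float
    p: float
    n: int
    df: int
    residual_variance: float


class PowerNullModel:
    """NLS fit of y ~ P**a with a t test against the random-choice null a=1.

    Events with P = 0 carry no information about a (0**a = 0 for all a) and
    mirror the excluded no-option females; they are dropped unless
    ``include_zero_p`` is set.  The optimiser is a damped Newton iteration
    on the scalar exponent with a bracketing (bounded Brent) fallback;
    convergence is |delta a| < 1e-8.
    """

    def __init__(self, null_a: float = 1.0, include_zero_p: bool = False,
                 max_iter: int = 100, tol: float = 1e-8):
        self.null_a = null_a
        self.include_zero_p = include_zero_p
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, P, y) -> "PowerNullModel":
        P = np.asarray(P, dtype=float)
        y = np.asarray(y, dtype=float)
        if P.shape != y.shape:
            raise ValueError("P and y must have the same length")
        if np.any((P < 0) | (P > 1)):
            raise ValueError("P must lie in [0, 1]")
        if not self.include_zero_p:
            keep = P > 0
            P, y = P[keep], y[keep]
        if len(P) == 0:
            raise ValueError("no events with P > 0")
        if np.all(P == 1.0):
            raise ValueError(
                "exponent unidentifiable: all occupancy proportions are 1")

        a = self._optimise(P, y)
        n = len(P)
        df = n - 1
        resid = y - P ** a
        rss = float(resid @ resid)
        s2 = rss / df
        # dy/da = P^a ln P; the P=1 contribution is exactly 0, and P=0
        # events (if retained) also contribute 0
        safe = np.where(P > 0, P, 1.0)
        J = np.where((P > 0) & (P < 1), safe ** a * np.log(safe), 0.0)
        jtj = float(J @ J)
        if jtj <= 0:
            raise ValueError("degenerate design: Jacobian is zero")
        se = float(np.sqrt(s2 / jtj))
        t = (a - self.null_a) / se
        p = float(2.0 * sps.t.sf(abs(t), df))
        self.a_ = float(a)
        self.se_ = se
        self.t_ = float(t)
        self.p_ = p
        self.n_ = n
        self.df_ = df
        self.rss_ = rss
        self.residual_variance_ = s2
        return self

    def _objective(self, a: float, P, y) -> float:
        r = y - P ** a
        return float(r @ r)

    def _optimise(self, P, y) -> float:
        logP = np.log(np.where(P > 0, P, 1.0))
        a = 1.0
        f = self._objective(a, P, y)
        converged = False
        for _ in range(self.max_iter):
            Pa = P ** a
            r = Pa - y
            g = float(2.0 * np.sum(r * Pa * logP))
            h = float(2.0 * np.sum((Pa * logP) ** 2 + r * Pa * logP ** 2))
            if h <= 0:          # non-convex region: fall back to bracketing
                break
            step = -g / h
            new_a = a + step
            # damping: halve the step until the objective decreases
            for _ in range(50):
                if new_a > 1e-8:
                    f_new = self._objective(new_a, P, y)
                    if f_new <= f + 1e-15:
                        break
                step *= 0.5
                new_a = a + step
            else:
                break
            if abs(new_a - a) < self.tol:
                a, f = new_a, f_new
                converged = True
                break
            a, f = new_a, f_new
        if not converged:
            from scipy.optimize import minimize_scalar
            res = minimize_scalar(lambda aa: self._objective(aa, P, y),
                                  bounds=(1e-6, 50.0), method="bounded",
                                  options={"xatol": 1e-10})
            if not res.success:
                raise RuntimeError(f"power-model fit did not converge: {res}")
            a = float(res.x)
        return a

    @property
    def result_(self) -> PowerModelFit:
        return PowerModelFit(a=self.a_, se=self.se_, t=self.t_, p=self.p_,
                             n=self.n_, df=self.df_,
                             residual_variance=self.residual_variance_)


def fit_power_null(events, **kwargs) -> PowerModelFit:
    """Fit the nest-availability null model to ChoiceEvents or (P, y)."""
    if isinstance(events, tuple) and len(events) == 2:
        P, y = events
    else:
        P = [e.P for e in events]
        y = [e.y for e in events]
    return PowerNullModel(**kwargs).fit(P, y).result_


# ---------------------------------------------------------------------------
# binary logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class ChoiceModelFit:
    kind: str
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame({
            "term": self.names, "estimate": self.coef, "se": self.se,
            "z": z, "p": 2.0 * sps.norm.sf(np.abs(z)),
        })


class DecisionLogit:
    """Maximum-likelihood binary logistic regression via IRLS.

    Mirrors the fixed-effect part of the communal-nursing decision model
    (number of options, nest boxes entered, focal age, experience,
    density, season); random effects are deliberately not fitted.
    Zero-variance covariates are dropped with a flag (their coefficient is
    undefined); quasi-separation triggers a flagged ridge-penalised refit.
    """

    def __init__(self, add_intercept: bool = True, max_iter: int = 100,
                 tol: float = 1e-10, ridge_on_separation: float = 1e-3):
        self.add_intercept = add_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.ridge_on_separation = ridge_on_separation

    def fit(self, X, y, names: list[str] | None = None) -> "DecisionLogit":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and match y")
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        names = list(names)
        flags: list[str] = []

        keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
        if len(keep) < X.shape[1]:
            dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
            flags.append("constant_covariates_dropped:" + ",".join(dropped))
        Xk = X[:, keep]
        kept_names = [names[j] for j in keep]
        if self.add_intercept:
            Xk = np.column_stack([np.ones(len(Xk)), Xk])
            kept_names = ["(intercept)"] + kept_names

        beta, converged = self._irls(Xk, y, 0.0)
        if not converged or np.max(np.abs(beta)) > 30.0:
            flags.append("separation_penalised_refit")
            beta, converged = self._irls(Xk, y, self.ridge_on_separation)

        eta = Xk @ beta
        mu = _sigmoid(eta)
        W = mu * (1.0 - mu)
        info = Xk.T @ (Xk * W[:, None])
        cov = np.linalg.pinv(info)
        se_kept = np.sqrt(np.diag(cov))
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))

        # expand back to the full covariate list, NaN for dropped terms
        full_names = (["(intercept)"] if self.add_intercept else []) + names
        coef = np.full(len(full_names), np.nan)
        se = np.full(len(full_names), np.nan)
        for k, nm in enumerate(kept_names):
            j = full_names.index(nm)
            coef[j] = beta[k]
            se[j] = se_kept[k]

        self.result_ = ChoiceModelFit(
            kind="binary-decision logistic", names=full_names, coef=coef,
            se=se, loglik=ll, n_events=len(y), converged=converged,
            flags=flags)
        self.coef_ = coef
        self.se_ = se
        self.loglik_ = ll
        self.converged_ = converged
        self.flags_ = flags
        return self

    def _irls(self, X, y, ridge: float) -> tuple[np.ndarray, bool]:
        beta = np.zeros(X.shape[1])
        for _ in range(self.max_iter):
            eta = X @ beta
            mu = _sigmoid(eta)
            W = np.clip(mu * (1.0 - mu), 1e-10, None)
            z = eta + (y - mu) / W
            A = X.T @ (X * W[:, None]) + ridge * np.eye(X.shape[1])
            new = np.linalg.solve(A, X.T @ (W * z))
            if np.max(np.abs(new - beta)) < self.tol:
                return new, True
            beta = new
        return beta, False


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_decision_model(frame: pd.DataFrame,
                       predictors: list[str] | None = None,
                       scale: bool = True) -> ChoiceModelFit:
    """Decision model from the per-event covariate table.

    Continuous predictors are z-scaled (means/SDs stored in the result's
    scaling metadata) so coefficient magnitudes are comparable.
    """
    if predictors is None:
        predictors = ["n_options", "n_regular_boxes", "focal_age",
                      "experience", "density", "summer"]
    data = frame.dropna(subset=predictors + ["y"]).copy()
    scaling: dict[str, tuple[float, float]] = {}
    if scale:
        for col in predictors:
            vals = data[col].to_numpy(dtype=float)
            if set(np.unique(vals)) <= {0.0, 1.0}:
                continue  # binary indicators stay on their own scale
            mu, sd = float(vals.mean()), float(vals.std())
            if sd > 0:
                data[col] = (vals - mu) / sd
                scaling[col] = (mu, sd)
    model = DecisionLogit().fit(data[predictors].to_numpy(dtype=float),
                                data["y"].to_numpy(dtype=float),
                                names=predictors)
    model.result_.scaling = scaling
    return model.result_


# ---------------------------------------------------------------------------
# conditional logit for partner choice
# ---------------------------------------------------------------------------

class ConditionalLogit:
    """Discrete-choice ML fit over per-event option sets (Newton-Raphson).

    Events with a single option carry no contrast; they are retained and
    contribute zero information.  The log-likelihood is concave, and the
    iteration uses step-halving to keep it non-decreasing.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-9):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, groups, chosen,
            names: list[str] | None = None) -> "ConditionalLogit":
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        chosen = np.asarray(chosen, dtype=bool)
        if np.isnan(X).any():
            raise ValueError("covariates contain NaN; drop incomplete events first")
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        order = np.argsort(groups, kind="stable")
        X, groups, chosen = X[order], groups[order], chosen[order]
        uniq, starts = np.unique(groups, return_index=True)
        bounds = np.append(starts, len(groups))
        for g, s, e in zip(uniq, bounds[:-1], bounds[1:]):
            if chosen[s:e].sum() != 1:
                raise ValueError(f"event {g} must have exactly one chosen option")

        beta = np.zeros(X.shape[1])
        ll = self._loglik(beta, X, chosen, bounds)
        converged = False
        for _ in range(self.max_iter):
            grad, hess = self._derivs(beta, X, chosen, bounds)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            new = beta + step
            ll_new = self._loglik(new, X, chosen, bounds)
            halvings = 0
            while ll_new < ll - 1e-12 and halvings < 50:
                step *= 0.5
                new = beta + step
                ll_new = self._loglik(new, X, chosen, bounds)
                halvings += 1
            if np.max(np.abs(new - beta)) < self.tol:
                beta, ll = new, ll_new
                converged = True
                break
            beta, ll = new, ll_new
        _, hess = self._derivs(beta, X, chosen, bounds)
        cov = np.linalg.pinv(hess)
        self.coef_ = beta
        # a non-positive variance signals a numerically singular
        # information matrix (e.g. separation on few events): report NaN
        d = np.diag(cov)
        self.se_ = np.where(d > 0, np.sqrt(np.where(d > 0, d, 1.0)), np.nan)
        self.loglik_ = float(ll)
        self.converged_ = converged
        self.names_ = names
        self._fit_data = (X, bounds)
        self.n_events_ = len(uniq)
        self.result_ = ChoiceModelFit(
            kind="conditional logit", names=names, coef=beta, se=self.se_,
            loglik=float(ll), n_events=len(uniq), converged=converged)
        return self

    @staticmethod
    def _event_probs(beta, X, bounds):
        eta = X @ beta
        probs = np.empty_like(eta)
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg = eta[s:e] - eta[s:e].max()
            ex = np.exp(seg)
            probs[s:e] = ex / ex.sum()
        return probs

    def _loglik(self, beta, X, chosen, bounds) -> float:
        probs = self._event_probs(beta, X, bounds)
        return float(np.sum(np.log(np.clip(probs[chosen], 1e-300, None))))

    def _derivs(self, beta, X, chosen, bounds):
        probs = self._event_probs(beta, X, bounds)
        k = X.shape[1]
        grad = np.zeros(k)
        hess = np.zeros((k, k))
        for s, e in zip(bounds[:-1], bounds[1:]):
            p = probs[s:e]
            Xe = X[s:e]
            xbar = p @ Xe
            grad += Xe[chosen[s:e]][0] - xbar
            hess += (Xe * p[:, None]).T @ Xe - np.outer(xbar, xbar)
        return grad, hess     # hess is the information matrix (positive)

    def predict_proba(self, X=None, groups=None) -> np.ndarray:
        """Per-option choice probabilities (sum to 1 within each event)."""
        if X is None:
            Xf, bounds = self._fit_data
            return self._event_probs(self.coef_, Xf, bounds)
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        _, starts = np.unique(groups[order], return_index=True)
        bounds = np.append(starts, len(groups))
        return self._event_probs(self.coef_, X[order], bounds)[inv]


PARTNER_PREDICTORS = ["pup_age", "litter_size_diff", "shared_boxes",
                      "age_diff", "option_age", "r_hat", "association_s",
                      "option_litter_solitary"]


def fit_partner_model(options: pd.DataFrame,
                      predictors: list[str] | None = None,
                      scale: bool = True) -> ChoiceModelFit:
    """Partner choice from the long option table (communal events only).

    Events whose chosen option misses a covariate are dropped with a note
    in the fit's flags (this mirrors the field data's reduction when an
    option female could not be genotyped).
    """
    if predictors is None:
        predictors = PARTNER_PREDICTORS
    data = options.copy()
    data["option_litter_solitary"] = \
        data["option_litter_solitary"].astype(float)
    # keep only events where some option was chosen (communal decisions)
    chosen_events = data.loc[data["chosen"].astype(bool), "event_id"].unique()
    data = data[data["event_id"].isin(chosen_events)]
    bad = data[data[predictors].isna().any(axis=1)]["event_id"].unique()
    flags = []
    if len(bad):
        flags.append(f"dropped_incomplete_events:{len(bad)}")
        data = data[~data["event_id"].isin(bad)]
    if data.empty:
        raise ValueError("no complete communal events to fit")
    scaling: dict[str, tuple[float, float]] = {}
    if scale:
        for col in predictors:
            vals = data[col].to_numpy(dtype=float)
            mu, sd = float(vals.mean()), float(vals.std())
            if sd > 0 and not set(np.unique(vals)) <= {0.0, 1.0}:
                data[col] = (vals - mu) / sd
                scaling[col] = (mu, sd)
    model = ConditionalLogit().fit(
        data[predictors].to_numpy(dtype=float),
        data["event_id"].to_numpy(),
        data["chosen"].to_numpy(dtype=bool),
        names=predictors)
    fit = model.result_
    fit.flags = flags + fit.flags
    fit.scaling = scaling
    return fit


# ---------------------------------------------------------------------------
# rank and permutation tests
# ---------------------------------------------------------------------------

def mann_whitney(sample_a, sample_b,
                 max_exact_combinations: int = 200_000
                 ) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test (two-sided), with midranks.

    Returns (W, p) where W is the U statistic of the first sample (the
    convention R's ``wilcox.test`` prints).  The p value is exact by
    enumeration of all arrangements when min(n, m) <= 8 and the number of
    arrangements is tractable, otherwise a tie-corrected normal
    approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)            # midranks for ties
    W = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if min(n, m) <= 8 and comb(n + m, n) <= max_exact_combinations:
        p = _exact_two_sided(ranks, n, W)
    else:
        N = n + m
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (N * (N - 1))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            return W, 1.0
        z = (W - n * m / 2.0) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return W, min(p, 1.0)


def _exact_two_sided(ranks: np.ndarray, n: int, W_obs: float) -> float:
    total = comb(len(ranks), n)
    offset = n * (n + 1) / 2.0
    lo = hi = 0
    eps = 1e-9
    for idx in itertools.combinations(range(len(ranks)), n):
        u = ranks[list(idx)].sum() - offset
        if u <= W_obs + eps:
            lo += 1
        if u >= W_obs - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def permutation_mean_diff(event_values: list[np.ndarray],
                          event_labels: list[int],
                          n_perm: int = 9999, seed: int = 0
                          ) -> tuple[float, float]:
    """Difference of means between two scenarios, permuting event labels.

    ``event_values[i]`` holds the option-level values of event i and
    ``event_labels[i]`` its scenario (1 = communal, 0 = solitary).  Options
    of one event move together under permutation, respecting the grouping
    the field analysis handled with random effects.  Returns
    (delta = mean(group 1) - mean(group 0), two-sided permutation p).
    """
    values = [np.asarray(v, dtype=float) for v in event_values]
    labels = np.asarray(event_labels)
    if len(values) != len(labels):
        raise ValueError("one label per event required")
    for lab in (0, 1):
        if (labels == lab).sum() < 2:
            raise ValueError(f"fewer than 2 events in group {lab}")

    def delta(lab: np.ndarray) -> float:
        g1 = np.concatenate([v for v, l in zip(values, lab) if l == 1])
        g0 = np.concatenate([v for v, l in zip(values, lab) if l == 0])
        return float(g1.mean() - g0.mean())

    obs = delta(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(delta(rng.permutation(labels))) >= abs(obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return obs, float(p)
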