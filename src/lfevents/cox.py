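"""Cox partial-likelihood estimation on counting-process data.

Implements the extended Cox model for recurrent events in the
statsmodels idiom: :class:`RecurrentCoxModel` is built from an interval
table (``cluster_id, start, stop, status`` plus covariates) and
``fit()`` returns a :class:`RecurrentCoxResults` carrying coefficients,
model-based and cluster-robust (sandwich) covariances, hazard ratios with
Wald confidence intervals, and Schoenfeld-residual diagnostics.

Time-dependent terms are constructed covariate-by-time products
``x * g(t)``; they are evaluated exactly at every event time for every
at-risk interval, so no static episode-splitting of the data is needed.
Tied event times across patients are handled by the Efron (default) or
Breslow correction.

The cluster-robust covariance is the sandwich
``I^{-1} (sum_g U_g U_g^T) I^{-1}`` where ``U_g`` sums the score residuals
of all intervals belonging to one patient; it is used for all reported
confidence intervals and Wald tests.  The proportional-hazards diagnostic
regresses Grambsch–Therneau scaled Schoenfeld residuals on a time
transform (identity by default, matching the extended model's linear
covariate-by-time products).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxModelSpec",
    "RecurrentCoxModel",
    "RecurrentCoxResults",
    "SchoenfeldResult",
    "fit_cox",
    "partial_loglik",
    "two_stage_extended_fit",
]


def _identity(t):
    return t


def _resolve_transform(transform) -> Tuple[Callable, str]:
    if transform in (None, "identity"):
        return _identity, "time"
    if transform == "log":
        return np.log, "log(time)"
    if callable(transform):
        return transform, getattr(transform, "__name__", "g") + "(time)"
    raise ValueError(f"unknown time transform {transform!r}")


@dataclass(frozen=True)
class CoxModelSpec:
    """Specification of an (extended) Cox model on counting-process data."""

    fixed_terms: Tuple[str, ...]
    td_terms: Tuple[Tuple[str, object], ...] = ()
    ties: str = "efron"
    cluster_col: str = "cluster_id"
    tol: float = 1e-9
    max_iter: int = 50

    def __post_init__(self):
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be 'efron' or 'breslow', got {self.ties!r}")
        if not self.tol > 0:
            raise ValueError("tolerance must be positive")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(
            self,
            "td_terms",
            tuple((n, t) for n, t in self.td_terms),
        )


class RecurrentCoxModel:
    """Cox model for recurrent events in Andersen–Gill (start, stop] form."""

    def __init__(self, intervals: pd.DataFrame, spec: CoxModelSpec):
        self.spec = spec
        self.intervals = intervals.reset_index(drop=True)
        df = self.intervals
        for col in ("start", "stop", "status"):
            if col not in df.columns:
                raise ValueError(f"interval table missing column {col!r}")
        missing = [t for t in spec.fixed_terms if t not in df.columns]
        missing += [n for n, _ in spec.td_terms if n not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not in interval table: {missing}")
        if spec.cluster_col not in df.columns:
            raise ValueError(f"cluster column {spec.cluster_col!r} missing")

        self.start = df["start"].to_numpy(dtype=float)
        self.stop = df["stop"].to_numpy(dtype=float)
        self.status = df["status"].to_numpy(dtype=int)
        if np.any(self.stop <= self.start):
            raise ValueError("intervals must satisfy stop > start")
        self.cluster, self.cluster_index = pd.factorize(df[spec.cluster_col])
        self.n_clusters = len(self.cluster_index)

        self._pf = len(spec.fixed_terms)
        self._ptd = len(spec.td_terms)
        self._transforms = [_resolve_transform(t)[0] for _, t in spec.td_terms]
        td_labels = [
            f"{n}:{_resolve_transform(t)[1]}" for n, t in spec.td_terms
        ]
        self.term_names = list(spec.fixed_terms) + td_labels

        cols = [df[t].to_numpy(dtype=float) for t in spec.fixed_terms]
        cols += [df[n].to_numpy(dtype=float) for n, _ in spec.td_terms]
        Xb = np.column_stack(cols) if cols else np.empty((len(df), 0))
        # centering is partial-likelihood invariant and improves conditioning
        self._xmean = Xb.mean(axis=0) if len(df) else np.zeros(Xb.shape[1])
        self.Xb = Xb - self._xmean

        status1 = self.status == 1
        self.event_times = np.unique(self.stop[status1])
        if np.any(self.event_times <= 0):
            raise ValueError("event times must be positive")
        self._death_idx = [
            np.flatnonzero(status1 & (self.stop == t)) for t in self.event_times
        ]
        self._risk_idx = [
            np.flatnonzero((self.start < t) & (t <= self.stop)) for t in self.event_times
        ]
        for t, r in zip(self.event_times, self._risk_idx):
            if len(r) == 0:
                raise ValueError(f"empty risk set at event time {t}")
        self.n_events = int(status1.sum())
        self.n_intervals = len(df)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        intervals: pd.DataFrame,
        fixed_terms: Sequence[str],
        td_terms: Sequence = (),
        **spec_kwargs,
    ) -> "RecurrentCoxModel":
        td = tuple(
            (t, "identity") if isinstance(t, str) else (t[0], t[1]) for t in td_terms
        )
        return cls(intervals, CoxModelSpec(tuple(fixed_terms), td, **spec_kwargs))

    @property
    def n_params(self) -> int:
        return self._pf + self._ptd

    def _g_at(self, t: float) -> np.ndarray:
        return np.array([g(t) for g in self._transforms], dtype=float)

    # ------------------------------------------------------------------
    def _derivs(
        self,
        beta: np.ndarray,
        order: int = 2,
        residuals: bool = False,
        schoenfeld: bool = False,
    ):
        """Partial log-likelihood and derivatives at ``beta``.

        Optionally also per-interval score residuals (``residuals``) and
        per-event Schoenfeld residuals (``schoenfeld``).
        """
        beta = np.asarray(beta, dtype=float)
        p, pf, ptd = self.n_params, self._pf, self._ptd
        if beta.shape != (p,):
            raise ValueError(f"beta must have length {p}")
        Xb = self.Xb
        a = Xb[:, :pf] @ beta[:pf] if pf else np.zeros(len(Xb))
        Wtd = Xb[:, pf:] * beta[pf:] if ptd else None
        efron = self.spec.ties == "efron"

        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        U = np.zeros((self.n_intervals, p)) if residuals else None
        sch_rows, sch_times, sch_clusters = [], [], []

        for t, idx, dk in zip(self.event_times, self._risk_idx, self._death_idx):
            gk = self._g_at(t) if ptd else np.empty(0)
            s_k = np.concatenate([np.ones(pf), gk])
            eta = a[idx]
            if ptd:
                eta = eta + Wtd[idx] @ gk
            c = eta.max()
            psi = np.exp(eta - c)
            Xr = Xb[idx]
            Xs = Xr * s_k
            S0 = psi.sum()
            S1 = Xs.T @ psi
            S2 = (Xs * psi[:, None]).T @ Xs

            d = len(dk)
            pos_d = np.searchsorted(idx, dk)  # death rows within risk index
            psiD = psi[pos_d]
            xD = Xs[pos_d]
            etaD_actual = eta[pos_d]  # includes shift removal below
            S0D = psiD.sum()
            S1D = xD.T @ psiD
            S2D = (xD * psiD[:, None]).T @ xD

            frac = np.arange(d) / d if (efron and d > 1) else np.zeros(d)
            ll += etaD_actual.sum()
            xbar_acc = np.zeros(p)
            for l in range(d):
                f = frac[l]
                S0l = S0 - f * S0D
                S1l = S1 - f * S1D
                v = S1l / S0l
                ll -= c + np.log(S0l)
                if order >= 1:
                    grad -= v
                if order >= 2:
                    S2l = S2 - f * S2D
                    hess -= S2l / S0l - np.outer(v, v)
                if residuals:
                    U[idx] -= (psi / S0l)[:, None] * (Xs - v)
                    if f:
                        U[dk] += (f * psiD / S0l)[:, None] * (xD - v)
                    U[dk] += (xD - v) / d
                if schoenfeld:
                    xbar_acc += v
            if order >= 1:
                grad += xD.sum(axis=0)
            if schoenfeld:
                xbar = xbar_acc / d
                for r in range(d):
                    sch_rows.append(xD[r] - xbar)
                    sch_times.append(t)
                    sch_clusters.append(self.cluster[dk[r]])

        out = {"ll": ll, "grad": grad, "hess": hess}
        if residuals:
            out["score_residuals"] = U
        if schoenfeld:
            out["schoenfeld"] = (
                np.array(sch_rows).reshape(-1, p),
                np.array(sch_times),
                np.array(sch_clusters),
            )
        return out

    # public derivative surface -----------------------------------------
    def loglik(self, beta) -> float:
        return self._derivs(np.asarray(beta, dtype=float), order=0)["ll"]

    def score(self, beta) -> np.ndarray:
        return self._derivs(np.asarray(beta, dtype=float), order=1)["grad"]

    def information(self, beta) -> np.ndarray:
        return -self._derivs(np.asarray(beta, dtype=float), order=2)["hess"]

    def _check_rank(self):
        if self.n_params == 0:
            return
        info = self.information(np.zeros(self.n_params))
        w, v = np.linalg.eigh(info)
        if w[-1] <= 0 or w[0] < 1e-10 * w[-1]:
            null = v[:, 0]
            bad = [self.term_names[j] for j in np.flatnonzero(np.abs(null) > 0.1)]
            raise np.linalg.LinAlgError(
                f"design is rank deficient; collinear terms: {bad}"
            )

    def fit(self, start_params=None) -> "RecurrentCoxResults":
        """Newton–Raphson maximization with step-halving."""
        if self.n_events < 1:
            raise ValueError("at least one event is required")
        p = self.n_params
        self._check_rank()
        beta = np.zeros(p) if start_params is None else np.asarray(start_params, float)
        null_ll = self.loglik(np.zeros(p))
        converged = False
        message = "maximum iterations reached"
        d = self._derivs(beta, order=2)
        ll = d["ll"]
        n_iter = 0
        if p == 0:
            converged, message = True, "empty model"
        for n_iter in range(1, self.spec.max_iter + 1):
            if p == 0:
                break
            info = -d["hess"]
            try:
                step = np.linalg.solve(info, d["grad"])
            except np.linalg.LinAlgError:
                message = "singular information matrix"
                break
            new_beta, new_d = beta + step, None
            for _ in range(40):
                new_d = self._derivs(new_beta, order=2)
                if np.isfinite(new_d["ll"]) and new_d["ll"] >= ll - 1e-13:
                    break
                step = step / 2.0
                new_beta = beta + step
            delta_ll = new_d["ll"] - ll
            beta, d, ll = new_beta, new_d, new_d["ll"]
            if abs(delta_ll) < self.spec.tol:
                converged = True
                message = "converged"
                break
        # divergent coefficients (monotone likelihood): flag on the scale of
        # the covariate so a unit change shifts the hazard absurdly
        if p:
            sd = self.Xb.std(axis=0)
            sd[sd == 0] = 1.0
            if np.any(np.abs(beta) * sd > 10):
                converged = False
                message = "monotone likelihood suspected (diverging coefficients)"
        info = -d["hess"] if p else np.empty((0, 0))
        model_cov = np.linalg.inv(info) if p else np.empty((0, 0))
        final = self._derivs(beta, order=2, residuals=True) if p else d
        U = final.get("score_residuals", np.empty((self.n_intervals, 0)))
        return RecurrentCoxResults(
            model=self,
            params=beta,
            loglik=ll,
            null_loglik=null_ll,
            information=info,
            model_cov=model_cov,
            score_residuals=U,
            converged=converged,
            message=message,
            n_iter=n_iter,
        )


class RecurrentCoxResults:
    """Fitted extended Cox model: estimates, uncertainty and diagnostics."""

    def __init__(
        self,
        model: RecurrentCoxModel,
        params: np.ndarray,
        loglik: float,
        null_loglik: float,
        information: np.ndarray,
        model_cov: np.ndarray,
        score_residuals: np.ndarray,
        converged: bool,
        message: str,
        n_iter: int,
    ):
        self.model = model
        self.params = pd.Series(params, index=model.term_names, name="coef")
        self.loglik = loglik
        self.null_loglik = null_loglik
        self.information = information
        self.model_cov = model_cov
        self.score_residuals = score_residuals
        self.converged = converged
        self.message = message
        self.n_iter = n_iter
        self.n_events = model.n_events
        self.n_intervals = model.n_intervals
        self.n_clusters = model.n_clusters
        self.robust_cov = self._robust_covariance()

    # ------------------------------------------------------------------
    def _robust_covariance(self) -> np.ndarray:
        """Cluster sandwich ``I^{-1} (sum_g U_g U_g') I^{-1}``."""
        p = self.model.n_params
        if p == 0:
            return np.empty((0, 0))
        if self.model.n_clusters < 2:
            raise ValueError("robust variance requires at least two clusters")
        Ug = np.zeros((self.model.n_clusters, p))
        np.add.at(Ug, self.model.cluster, self.score_residuals)
        meat = Ug.T @ Ug
        return self.model_cov @ meat @ self.model_cov

    @property
    def model_se(self) -> pd.Series:
        se = np.sqrt(np.diag(self.model_cov)) if self.model.n_params else np.empty(0)
        return pd.Series(se, index=self.params.index, name="model_se")

    @property
    def robust_se(self) -> pd.Series:
        se = np.sqrt(np.diag(self.robust_cov)) if self.model.n_params else np.empty(0)
        return pd.Series(se, index=self.params.index, name="robust_se")

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.params).rename("hr")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.robust_se
        hi = self.params + z * self.robust_se
        return pd.DataFrame({"coef_low": lo, "coef_high": hi})

    @property
    def wald_z(self) -> pd.Series:
        return (self.params / self.robust_se).rename("z")

    @property
    def wald_p(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.wald_z)), index=self.params.index, name="p"
        )

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Coefficient table with hazard ratios and robust Wald inference."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": self.hr,
                "hr_low": np.exp(ci["coef_low"]),
                "hr_high": np.exp(ci["coef_high"]),
                "robust_se": self.robust_se,
                "model_se": self.model_se,
                "z": self.wald_z,
                "p": self.wald_p,
            }
        )

    # ------------------------------------------------------------------
    def hr_at_time(self, term: str, t: float) -> float:
        """Hazard ratio ``exp(b_main + b_td * t)`` for a term with a
        covariate-by-time product in the model."""
        if t < 0:
            raise ValueError("t must be non-negative")
        td_name = f"{term}:time"
        if term not in self.params.index or td_name not in self.params.index:
            raise KeyError(f"term {term!r} needs both main and {td_name!r} coefficients")
        return float(np.exp(self.params[term] + self.params[td_name] * t))

    def schoenfeld_test(self, transform="identity") -> "SchoenfeldResult":
        """Grambsch–Therneau proportional-hazards test.

        Schoenfeld residuals (event covariate minus risk-set weighted mean,
        Efron-averaged under tied times) are scaled by ``m * V`` and
        regressed on the time transform; per-term and global chi-square
        statistics follow.
        """
        model = self.model
        if model.n_params == 0:
            raise ValueError("PH test needs at least one covariate")
        if model.n_events <= model.n_params:
            raise ValueError("fewer events than model terms")
        d = model._derivs(self.params.to_numpy(), order=0, schoenfeld=True)
        resid, times, clusters = d["schoenfeld"]
        if transform == "rank":
            g, g_name = stats.rankdata(times).astype(float), "rank(time)"
        else:
            g_fun, g_name = _resolve_transform(transform)
            g = np.asarray([g_fun(t) for t in times], dtype=float)
        gc = g - g.mean()
        m = model.n_events
        V = self.model_cov
        D = resid.T @ gc  # p-vector
        ss_g = float(gc @ gc)
        if ss_g <= 0:
            raise ValueError("degenerate time transform (all event times equal)")
        VD = V @ D
        term_stats = m * VD**2 / (np.diag(V) * ss_g)
        term_p = stats.chi2.sf(term_stats, df=1)
        global_stat = float(m * D @ VD / ss_g)
        global_p = float(stats.chi2.sf(global_stat, df=model.n_params))
        scaled = m * resid @ V.T + self.params.to_numpy()
        table = pd.DataFrame(
            {"chisq": term_stats, "df": 1, "p": term_p}, index=model.term_names
        )
        return SchoenfeldResult(
            residuals=pd.DataFrame(resid, columns=model.term_names).assign(
                time=times, cluster=clusters
            ),
            scaled_residuals=pd.DataFrame(scaled, columns=model.term_names).assign(
                time=times
            ),
            table=table,
            global_stat=global_stat,
            global_p=global_p,
            transform=g_name,
        )


@dataclass
class SchoenfeldResult:
    """Proportional-hazards diagnostic based on Schoenfeld residuals."""

    residuals: pd.DataFrame
    scaled_residuals: pd.DataFrame
    table: pd.DataFrame
    global_stat: float
    global_p: float
    transform: str

    def violations(self, alpha: float = 0.05):
        return list(self.table.index[self.table["p"] < alpha])


# ----------------------------------------------------------------------
# functional surface


def partial_loglik(beta, intervals: pd.DataFrame, spec: CoxModelSpec) -> float:
    """Log partial likelihood of ``beta`` on an interval table."""
    return RecurrentCoxModel(intervals, spec).loglik(beta)


def fit_cox(intervals: pd.DataFrame, spec: CoxModelSpec) -> RecurrentCoxResults:
    return RecurrentCoxModel(intervals, spec).fit()


def two_stage_extended_fit(
    intervals: pd.DataFrame,
    base_spec: CoxModelSpec,
    alpha: float = 0.05,
    transform="identity",
):
    """Proportional-hazards fit, PH diagnostic, then extended refit.

    Fits the base model, tests every term's PH assumption, and for each
    term that both violates PH (p < alpha) and has a significant main
    effect (robust Wald p < alpha) adds a covariate-by-time product, then
    refits.  Returns ``(ph_results, schoenfeld_result, extended_results)``;
    the extended results are the PH results when no term qualifies.
    """
    ph = fit_cox(intervals, base_spec)
    sch = ph.schoenfeld_test(transform=transform)
    wald = ph.wald_p
    to_extend = [
        term
        for term in base_spec.fixed_terms
        if sch.table.loc[term, "p"] < alpha and wald[term] < alpha
    ]
    if not to_extend:
        return ph, sch, ph
    ext_spec = replace(
        base_spec,
        td_terms=base_spec.td_terms + tuple((t, transform) for t in to_extend),
    )
    extended = fit_cox(intervals, ext_spec)
    return ph, sch, extended
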