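"""Landmark competing-risk Cox supermodel.

Fits cause-specific proportional-hazards models for infection, death and
discharge on the stacked landmark dataset, with the prediction-window time
u = outcome_time (hours since the landmark) as the Cox time axis and
competing causes censored at their event times.  Ties are handled with the
Efron correction; baselines are Breslow-type, either pooled (one baseline,
landmark-time terms s and s^2 in the design — the van Houwelingen-style
supermodel) or stratified on the landmark levels (one baseline per level;
s and s^2 are dropped from that design since they are constant within a
stratum).

Absolute 48-h infection risk comes from the cumulative incidence function
combining all three cause-specific fits through the Aalen-Johansen product
form, so that the per-cause CIFs and overall survival sum to one exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import CovariateSpec
from .landmarks import StackedDataset

CAUSES = ("infection", "death", "discharge")


class ConvergenceError(RuntimeError):
    """Raised when Newton iterations fail; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message + f" (trace: {trace})")
        self.trace = trace


def _efron_quantities(X, t, d, beta, need_hessian=True):
    """Log partial likelihood, gradient and information for one stratum.

    Rows sorted ascending in time; risk-set sums are suffix cumulative
    sums.  Efron's correction downweights tied events' own contribution to
    the denominator.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max() if n else 0.0  # guard overflow; constant shifts cancel
    r = np.exp(eta)
    rX = r[:, None] * X
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rX[::-1], axis=0)[::-1]
    if need_hessian:
        rXX = rX[:, :, None] * X[:, None, :]
        S2 = np.cumsum(rXX[::-1], axis=0)[::-1]
    ll, g = 0.0, np.zeros(p)
    info = np.zeros((p, p))
    ev_idx = np.nonzero(d)[0]
    if len(ev_idx) == 0:
        return ll, g, info
    ev_times = t[ev_idx]
    boundaries = np.nonzero(np.diff(ev_times) > 0)[0]
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [len(ev_idx)]))
    for a, b in zip(starts, ends):
        D = ev_idx[a:b]
        dn = len(D)
        # risk set = all rows with time >= te, including censored rows tied
        # with the event time
        i0 = int(np.searchsorted(t, t[D[0]], side="left"))
        s0d = r[D].sum()
        s1d = rX[D].sum(axis=0)
        ll += float(eta[D].sum())
        g += X[D].sum(axis=0)
        if need_hessian:
            s2d = rXX[D].sum(axis=0)
        for l in range(dn):
            f = l / dn
            den = S0[i0] - f * s0d
            z1 = S1[i0] - f * s1d
            ll -= math.log(den)
            g -= z1 / den
            if need_hessian:
                z2 = S2[i0] - f * s2d
                info += z2 / den - np.outer(z1, z1) / den**2
    return ll, g, info


def _loglik_only(X, t, d, beta, strata_groups):
    ll = 0.0
    for idx in strata_groups:
        ll += _efron_quantities(X[idx], t[idx], d[idx], beta, need_hessian=False)[0]
    return ll


def cox_loglik(X, t, d, beta, strata=None):
    """Efron log partial likelihood (public, used by fits and the LR test)."""
    X = np.asarray(X, float)
    t = np.asarray(t, float)
    d = np.asarray(d, int)
    groups = _strata_groups(t, strata)
    return _loglik_only(X, t, d, np.asarray(beta, float), groups)


def _strata_groups(t, strata):
    """Sorted (ascending time) row-index groups per stratum."""
    if strata is None:
        return [np.argsort(t, kind="mergesort")]
    strata = np.asarray(strata)
    groups = []
    for s in pd.unique(strata):
        idx = np.nonzero(strata == s)[0]
        groups.append(idx[np.argsort(t[idx], kind="mergesort")])
    return groups


def _newton(X, t, d, strata_groups, max_iter=60, tol=1e-9):
    p = X.shape[1]
    beta = np.zeros(p)
    trace = []
    ll_prev = None
    info = np.eye(p)
    gnorm = np.inf
    for it in range(max_iter):
        ll, g, info = 0.0, np.zeros(p), np.zeros((p, p))
        for idx in strata_groups:
            l_, g_, i_ = _efron_quantities(X[idx], t[idx], d[idx], beta)
            ll += l_
            g += g_
            info += i_
        gnorm = float(np.max(np.abs(g))) if p else 0.0
        trace.append((it, ll, gnorm))
        if ll_prev is not None and ll < ll_prev - 1e-12:
            if abs(ll - ll_prev) < 1e-9 * (abs(ll) + 1.0) and gnorm < 1e-6:
                return beta, info, ll, True, gnorm, trace  # at machine precision
            # step halving
            step = beta - beta_prev
            for _ in range(30):
                step *= 0.5
                beta = beta_prev + step
                ll = _loglik_only(X, t, d, beta, strata_groups)
                if ll >= ll_prev:
                    break
            else:
                raise ConvergenceError("step halving failed", trace)
            ll_prev = None
            continue
        if gnorm < tol or (
            ll_prev is not None and abs(ll - ll_prev) < 1e-12 * (abs(ll) + 1.0)
            and gnorm < 1e-6
        ):
            return beta, info, ll, True, gnorm, trace
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            raise _singular_error(info, None)
        beta_prev, ll_prev = beta.copy(), ll
        beta = beta + step
    ll = _loglik_only(X, t, d, beta, strata_groups)
    if gnorm < 1e-5:  # flat likelihood; accept with converged flag set
        return beta, info, ll, True, gnorm, trace
    raise ConvergenceError(f"no convergence after {max_iter} iterations", trace)


def _singular_error(info, names):
    w, v = np.linalg.eigh(info)
    bad = np.abs(v[:, 0])
    if names is not None:
        culprits = [names[i] for i in np.nonzero(bad > 0.3)[0]]
    else:
        culprits = list(np.nonzero(bad > 0.3)[0])
    return np.linalg.LinAlgError(
        f"singular information matrix; collinear covariates: {culprits}"
    )


@dataclass
class CauseSpecificFit:
    """One cause's proportional-hazards fit on the stacked data."""

    cause: str
    covariates: list
    beta: np.ndarray
    cov: np.ndarray
    baseline: dict  # stratum (None = pooled) -> (event times, Breslow dLambda0)
    loglik: float
    loglik_null: float
    n_events: int
    converged: bool
    grad_norm: float
    centers: np.ndarray
    train_min: np.ndarray
    train_max: np.ndarray
    stratified: bool
    cov_robust: Optional[np.ndarray] = None
    #: log-scale shift applied to the linear predictor when the baseline was
    #: computed (guards exp overflow under near-separation); predictions must
    #: subtract it
    eta_shift: float = 0.0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def hazard_ratios(self) -> pd.DataFrame:
        se = self.se
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.beta,
                "se": se,
                "hr": np.exp(self.beta),
                "hr_lo": np.exp(self.beta - 1.96 * se),
                "hr_hi": np.exp(self.beta + 1.96 * se),
            }
        )

    def cumulative_baseline(self, stratum=None) -> tuple:
        times, dl = self.baseline[stratum]
        return times, np.cumsum(dl)


def fit_cause_specific(
    stacked,
    cause: str,
    spec: Optional[CovariateSpec] = None,
    baseline_mode: str = "pooled",
    covariates: Optional[list] = None,
    robust: bool = False,
) -> CauseSpecificFit:
    """Fit one cause-specific Cox model on the stacked landmark rows.

    Competing causes are censored at their event times; the time axis is
    window time u = outcome_time.  ``baseline_mode`` is ``"pooled"`` (one
    Breslow baseline, landmark terms in the design) or ``"stratified"``
    (one baseline per landmark level).
    """
    if cause not in CAUSES:
        raise ValueError(f"unknown cause {cause!r}")
    if baseline_mode not in ("pooled", "stratified"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    df = stacked.df if isinstance(stacked, StackedDataset) else stacked
    if spec is None and covariates is None:
        raise ValueError("either spec or covariates must be given")
    stratified = baseline_mode == "stratified"
    if covariates is None:
        covariates = spec.cox_covariates(cause, stratified)
    covariates = [c for c in covariates if c in df.columns]
    X = df[covariates].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("NaN covariates: apply an ImputationState before fitting")
    t = df["outcome_time"].to_numpy(float)
    d = (df["outcome_type"] == cause).to_numpy().astype(int)
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError(f"zero events of cause {cause!r}")
    centers = X.mean(axis=0)
    Xc = X - centers
    sd = Xc.std(axis=0)
    const = [covariates[i] for i in np.nonzero(sd == 0)[0]]
    if const:
        raise ValueError(f"constant covariates in design: {const}")
    strat_col = "lm_level" if "lm_level" in df.columns else "t_lm"
    strata = df[strat_col].to_numpy() if stratified else None
    groups = _strata_groups(t, strata)
    # fit on the standardised design for conditioning; back-transform after
    Xs = Xc / sd
    try:
        beta_s, info_s, ll, converged, gnorm, _ = _newton(Xs, t, d, groups)
    except np.linalg.LinAlgError:
        raise _singular_error(Xs.T @ Xs, covariates)
    beta = beta_s / sd
    D = np.diag(1.0 / sd)
    info = np.linalg.multi_dot([np.diag(sd), info_s, np.diag(sd)]) if len(sd) else info_s
    try:
        cov = np.linalg.multi_dot([D, np.linalg.inv(info_s), D])
    except np.linalg.LinAlgError:
        raise _singular_error(info_s, covariates)
    ll0 = _loglik_only(Xs, t, d, np.zeros(X.shape[1]), groups)

    # Breslow baseline increments per stratum at the fitted beta; the
    # linear predictor is shifted by its maximum so exp never overflows
    # under near-separation, and the shift is stored for prediction
    baseline = {}
    eta = Xc @ beta
    eta_shift = float(eta.max()) if len(eta) else 0.0
    r = np.exp(eta - eta_shift)
    for idx in groups:
        key = None if strata is None else df[strat_col].to_numpy()[idx[0]]
        ts, ds_, rs = t[idx], d[idx], r[idx]
        S0 = np.cumsum(rs[::-1])[::-1]
        ev = np.nonzero(ds_)[0]
        if len(ev) == 0:
            baseline[key] = (np.array([]), np.array([]))
            continue
        ev_times, first_pos, counts = np.unique(ts[ev], return_index=True, return_counts=True)
        dl = np.empty(len(ev_times))
        for j, (te, cnt) in enumerate(zip(ev_times, counts)):
            i0 = np.searchsorted(ts, te, side="left")
            dl[j] = cnt / S0[i0]
        baseline[key] = (ev_times, dl)

    cov_rob = _robust_cov(df, Xc, t, d, r, beta, cov, groups, strata) if robust else None
    return CauseSpecificFit(
        cause=cause,
        covariates=list(covariates),
        beta=beta,
        cov=cov,
        baseline=baseline,
        loglik=ll,
        loglik_null=ll0,
        n_events=n_events,
        converged=converged,
        grad_norm=gnorm,
        centers=centers,
        train_min=X.min(axis=0),
        train_max=X.max(axis=0),
        stratified=stratified,
        cov_robust=cov_rob,
        eta_shift=eta_shift,
    )


def _robust_cov(df, Xc, t, d, r, beta, cov, groups, strata):
    """Cluster-by-patient sandwich covariance (Breslow-form score residuals)."""
    n, p = Xc.shape
    U = np.zeros((n, p))
    for idx in groups:
        ts, ds_, rs, Xs = t[idx], d[idx], r[idx], Xc[idx]
        S0 = np.cumsum(rs[::-1])[::-1]
        S1 = np.cumsum((rs[:, None] * Xs)[::-1], axis=0)[::-1]
        ev = np.nonzero(ds_)[0]
        if len(ev) == 0:
            continue
        ev_times = np.unique(ts[ev])
        pos = np.searchsorted(ts, ev_times, side="left")
        xbar = S1[pos] / S0[pos][:, None]
        dcounts = np.array([(ts[ev] == te).sum() for te in ev_times])
        dH = dcounts / S0[pos]
        for k, i in enumerate(idx):
            ti = t[i]
            m = ev_times <= ti
            term = (r[i] * dH[m])[:, None] * (Xc[i] - xbar[m])
            U[i] = d[i] * (Xc[i] - xbar[np.searchsorted(ev_times, ti)]) - term.sum(axis=0) \
                if d[i] and ti in ev_times else -term.sum(axis=0)
    gsum = pd.DataFrame(U).groupby(df["patient_id"].to_numpy()).sum().to_numpy()
    B = gsum.T @ gsum
    return cov @ B @ cov


@dataclass
class SupermodelFit:
    """Cause-specific fits for infection, death and discharge."""

    fits: dict  # cause -> CauseSpecificFit
    covariate_spec: Optional[CovariateSpec]
    baseline_mode: str
    horizon_h: float

    @property
    def infection(self) -> CauseSpecificFit:
        return self.fits["infection"]


def fit_supermodel(
    stacked: StackedDataset,
    spec: Optional[CovariateSpec] = None,
    baseline_mode: str = "pooled",
    robust: bool = False,
) -> SupermodelFit:
    spec = spec or stacked.covariate_spec
    fits = {
        cause: fit_cause_specific(stacked, cause, spec, baseline_mode, robust=robust)
        for cause in CAUSES
    }
    return SupermodelFit(
        fits=fits,
        covariate_spec=spec,
        baseline_mode=baseline_mode,
        horizon_h=stacked.grid.horizon_h,
    )


@dataclass
class CifPrediction:
    """Absolute infection risk within the horizon for one landmark row."""

    cif_infection: float
    horizon_h: float
    times: np.ndarray = field(repr=False, default=None)
    survival: np.ndarray = field(repr=False, default=None)
    cif_by_cause: dict = field(repr=False, default=None)
    out_of_support: bool = False


def _merged_baseline(model: SupermodelFit, stratum):
    times = np.unique(
        np.concatenate([model.fits[c].baseline[stratum][0] for c in CAUSES])
    )
    dL0 = {}
    for c in CAUSES:
        bt, bd = model.fits[c].baseline[stratum]
        arr = np.zeros(len(times))
        arr[np.searchsorted(times, bt)] = bd
        dL0[c] = arr
    return times, dL0


def predict_cif_batch(
    model: SupermodelFit, df: pd.DataFrame, horizon_h: Optional[float] = None,
    chunk: int = 2048,
) -> np.ndarray:
    """Predicted infection CIF at the horizon for each row of ``df``.

    Aalen-Johansen product form over the merged baseline event times: the
    all-cause survival path is the running product of one minus the summed
    cause-specific hazard increments, and the infection CIF accumulates
    survival-weighted infection increments.
    """
    w = horizon_h if horizon_h is not None else model.horizon_h
    out = np.zeros(len(df))
    strat_col = "lm_level" if "lm_level" in df.columns else "t_lm"
    strata = df[strat_col].to_numpy() if model.baseline_mode == "stratified" else np.zeros(len(df))
    for stratum_val in np.unique(strata):
        sel = np.nonzero(strata == stratum_val)[0]
        key = stratum_val if model.baseline_mode == "stratified" else None
        if key is not None and key not in model.fits["infection"].baseline:
            raise KeyError(f"no baseline for landmark stratum {key}")
        times, dL0 = _merged_baseline(model, key)
        m = times <= w + 1e-9
        times = times[m]
        risks = {}
        for c in CAUSES:
            fit = model.fits[c]
            Xc = df.iloc[sel][fit.covariates].to_numpy(float) - fit.centers
            risks[c] = np.exp(np.minimum(Xc @ fit.beta - fit.eta_shift, 700.0))
            dL0[c] = dL0[c][: len(times)]
        for a in range(0, len(sel), chunk):
            b = min(a + chunk, len(sel))
            dlam = {c: risks[c][a:b, None] * dL0[c][None, :] for c in CAUSES}
            tot = sum(dlam.values())
            fac = np.clip(1.0 - tot, 0.0, None)
            S_left = np.cumprod(
                np.concatenate([np.ones((b - a, 1)), fac[:, :-1]], axis=1), axis=1
            )
            out[sel[a:b]] = (S_left * dlam["infection"]).sum(axis=1)
    return out


def predict_cif(model: SupermodelFit, row, horizon_h: Optional[float] = None) -> CifPrediction:
    """Full CIF prediction (survival path and per-cause increments) for one row."""
    w = horizon_h if horizon_h is not None else model.horizon_h
    df = row.to_frame().T if isinstance(row, pd.Series) else pd.DataFrame([row])
    strat_col = "lm_level" if "lm_level" in df.columns else "t_lm"
    key = (
        float(df[strat_col].iloc[0]) if model.baseline_mode == "stratified" else None
    )
    times, dL0 = _merged_baseline(model, key)
    m = times <= w + 1e-9
    times = times[m]
    oos = False
    dlam = {}
    for c in CAUSES:
        fit = model.fits[c]
        x = df[fit.covariates].to_numpy(float)[0]
        if np.any(x < fit.train_min - 1e-12) or np.any(x > fit.train_max + 1e-12):
            oos = True
        eta = min(float((x - fit.centers) @ fit.beta) - fit.eta_shift, 700.0)
        dlam[c] = math.exp(eta) * dL0[c][: len(times)]
    tot = sum(dlam.values())
    fac = np.clip(1.0 - tot, 0.0, None)
    S = np.cumprod(fac)
    S_left = np.concatenate(([1.0], S[:-1]))
    cifs = {c: float((S_left * dlam[c]).sum()) for c in CAUSES}
    return CifPrediction(
        cif_infection=cifs["infection"],
        horizon_h=w,
        times=times,
        survival=S,
        cif_by_cause=cifs,
        out_of_support=oos,
    )


def constant_hazard_fit(rates_per_h: dict, horizon_h: float, step_h: float = 0.02) -> SupermodelFit:
    """Supermodel with covariate-free constant cause-specific hazards.

    Useful as a reference object: with hazards lambda_k the infection CIF
    has the closed form (lambda_inf/lambda_tot) * (1 - exp(-lambda_tot*w)).
    The baselines discretise each hazard on a regular grid.
    """
    times = np.arange(step_h, horizon_h + step_h / 2, step_h)
    fits = {}
    for c in CAUSES:
        lam = rates_per_h.get(c, 0.0)
        dl = np.full(len(times), lam * step_h)
        fits[c] = CauseSpecificFit(
            cause=c,
            covariates=[],
            beta=np.zeros(0),
            cov=np.zeros((0, 0)),
            baseline={None: (times, dl) if lam > 0 else (np.array([]), np.array([]))},
            loglik=0.0,
            loglik_null=0.0,
            n_events=0,
            converged=True,
            grad_norm=0.0,
            centers=np.zeros(0),
            train_min=np.zeros(0),
            train_max=np.zeros(0),
            stratified=False,
        )
    return SupermodelFit(fits=fits, covariate_spec=None, baseline_mode="pooled", horizon_h=horizon_h)


def lr_test(base: SupermodelFit, deep: SupermodelFit) -> tuple:
    """Likelihood-ratio test of the deep vs base infection-cause models.

    The deep design must equal the base design plus the CNN risk score,
    fitted on the same rows; the statistic is twice the log partial
    likelihood gain, with one degree of freedom.
    """
    cb = base.fits["infection"].covariates
    cd = deep.fits["infection"].covariates
    if set(cd) != set(cb) | {"cnn_score"} or "cnn_score" in cb:
        raise ValueError("models are not nested base -> base + cnn_score")
    if base.fits["infection"].n_events != deep.fits["infection"].n_events:
        raise ValueError("fits are not on the same rows")
    stat = 2.0 * (deep.fits["infection"].loglik - base.fits["infection"].loglik)
    p = float(stats.chi2.sf(max(stat, 0.0), df=1))
    return stat, 1, p


def wald_chi2(fit: CauseSpecificFit) -> pd.Series:
    """Per-covariate Wald chi-square statistics (beta/SE)^2."""
    se = fit.se
    if np.any(~np.isfinite(se)) or np.any(se == 0):
        raise np.linalg.LinAlgError("degenerate standard errors")
    return pd.Series((fit.beta / se) ** 2, index=fit.covariates, name="wald_chi2")
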