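"""Group-based trajectory modelling (latent-class growth analysis).

The model: each subject i contributes a longitudinal sequence
``(t_i1, y_i1), ..., (t_in_i, y_in_i)`` of weights over gestational time.
The population is a finite mixture of J latent groups; within group j the
observations are independent Gaussians around a polynomial mean curve,

    y_it | group j  ~  Normal( sum_p beta_jp * t^p ,  sigma_j^2 ).

The marginal likelihood of subject i is therefore

    P(Y_i | T_i) = sum_j pi_j * prod_t phi(y_it; poly_j(t_it), sigma_j),

maximum likelihood is obtained by EM (E-step: posterior group
responsibilities; M-step: responsibility-weighted polynomial least squares,
share and variance updates), optionally polished by a quasi-Newton pass on
the free parameters, and the number of groups / polynomial order is chosen
by minimising BIC = -2 logL + k log(n_subjects).  Model adequacy follows
Nagin's diagnostics: the average posterior probability of assigned members
should exceed 0.70 in every group, and assigned group shares should match
the posterior-expected shares.

Groups are reported in canonical order: ascending mean fitted value at
mid-gestation (week 20 by default), which resolves label switching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy import stats as sps
from sklearn.cluster import KMeans

__all__ = [
    "GBTMSpec",
    "TrajectoryFit",
    "ModelSelectionError",
    "loglikelihood",
    "fit_gbtm",
    "select_model",
    "adequacy_diagnostics",
    "trajectory_slopes",
    "simulate_mixture_trajectories",
    "plot_trajectories",
]

ADEQUACY_THRESHOLD = 0.70  # minimum acceptable average posterior probability
CANONICAL_WEEK = 20.0  # groups ordered by fitted mean at this time

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GBTMSpec:
    """Structural choices of a trajectory model."""

    J: int = 3
    order: int = 1
    variance_mode: str = "shared"  # "shared" or "per_group"

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.variance_mode not in ("shared", "per_group"):
            raise ValueError("variance_mode must be 'shared' or 'per_group'")

    @property
    def n_params(self) -> int:
        """Free parameters: (J-1) shares + J*(order+1) betas + 1 or J sigmas."""
        n_sigma = 1 if self.variance_mode == "shared" else self.J
        return (self.J - 1) + self.J * (self.order + 1) + n_sigma


class _Stacked:
    """Long data flattened to arrays with a subject index."""

    __slots__ = ("ids", "subj", "t", "y", "n_subjects", "starts", "counts")

    def __init__(self, data: pd.DataFrame):
        if len(data) == 0:
            raise ValueError("empty data")
        df = data[["id", "time", "y"]].dropna()
        if len(df) == 0:
            raise ValueError("no complete (id, time, y) observations")
        ids, subj = np.unique(df["id"].to_numpy(), return_inverse=True)
        order = np.argsort(subj, kind="stable")
        self.ids = ids
        self.subj = subj[order]
        self.t = df["time"].to_numpy(dtype=float)[order]
        self.y = df["y"].to_numpy(dtype=float)[order]
        self.n_subjects = len(ids)
        self.counts = np.bincount(self.subj, minlength=self.n_subjects)
        self.starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]])

    def design(self, order: int) -> np.ndarray:
        return self.t[:, None] ** np.arange(order + 1)[None, :]


def _subject_loglik(stk: _Stacked, X, pi, beta, sigma):
    """n_subjects x J matrix: log pi_j + sum_t log phi(y_t; X beta_j, sigma_j)."""
    pi = np.asarray(pi, dtype=float)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    J = beta.shape[0]
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float).ravel(), (J,))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    resid = stk.y[:, None] - X @ beta.T  # n_obs x J
    obs_ll = -0.5 * (_LOG_2PI + 2.0 * np.log(sigma)[None, :] + (resid / sigma) ** 2)
    subj_ll = np.zeros((stk.n_subjects, J))
    for j in range(J):
        subj_ll[:, j] = np.bincount(stk.subj, weights=obs_ll[:, j],
                                    minlength=stk.n_subjects)
    with np.errstate(divide="ignore"):
        return subj_ll + np.log(pi)[None, :]


def loglikelihood(data: pd.DataFrame, pi, beta, sigma) -> float:
    """Mixture log-likelihood of long-format data at fixed parameters.

    ``data`` has columns ``id``, ``time``, ``y``; ``beta`` is J x (order+1)
    (ascending powers); ``sigma`` is scalar (shared) or length J.
    """
    stk = _Stacked(data)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    X = stk.design(beta.shape[1] - 1)
    lj = _subject_loglik(stk, X, pi, beta, sigma)
    return float(logsumexp(lj, axis=1).sum())


@dataclass
class TrajectoryFit:
    """Result of one fitted trajectory model (canonically ordered groups)."""

    spec: GBTMSpec
    pi: np.ndarray
    beta: np.ndarray  # J x (order+1), ascending powers
    sigma: np.ndarray  # length 1 (shared) or J
    loglik: float
    bic: float
    n_subjects: int
    posterior: np.ndarray  # n_subjects x J
    assignment: np.ndarray  # argmax group per subject
    subject_ids: np.ndarray
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    diagnostics: pd.DataFrame | None = None

    def mean_curve(self, times: np.ndarray) -> np.ndarray:
        """J x len(times) fitted mean trajectories."""
        T = np.asarray(times, dtype=float)[:, None] ** np.arange(self.beta.shape[1])[None, :]
        return self.beta @ T.T

    def group_sigma(self) -> np.ndarray:
        return np.broadcast_to(self.sigma, (self.spec.J,))


def _m_step(stk, X, resp, variance_mode, min_sigma=1e-6):
    J = resp.shape[1]
    pi = resp.mean(axis=0)
    w_obs = resp[stk.subj]  # n_obs x J
    P = X.shape[1]
    beta = np.zeros((J, P))
    sse = np.zeros(J)
    wtot = np.zeros(J)
    for j in range(J):
        w = w_obs[:, j]
        Xw = X * w[:, None]
        XtWX = Xw.T @ X
        XtWy = Xw.T @ stk.y
        try:
            beta[j] = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            beta[j] = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
        r = stk.y - X @ beta[j]
        sse[j] = np.sum(w * r * r)
        wtot[j] = w.sum()
    if variance_mode == "shared":
        sigma = np.array([np.sqrt(max(sse.sum() / max(wtot.sum(), 1e-12), min_sigma**2))])
    else:
        sigma = np.sqrt(np.maximum(sse / np.maximum(wtot, 1e-12), min_sigma**2))
    return pi, beta, sigma


def _em(stk, X, spec, pi, beta, sigma, tol, max_iter):
    history = []
    ll_old = -np.inf
    resp = None
    for it in range(max_iter):
        lj = _subject_loglik(stk, X, pi, beta, sigma)
        ll_subj = logsumexp(lj, axis=1)
        ll = float(ll_subj.sum())
        history.append(ll)
        resp = np.exp(lj - ll_subj[:, None])
        if ll - ll_old <= tol * max(abs(ll_old), 1.0) and it > 0:
            return pi, beta, sigma, resp, ll, np.array(history), True
        ll_old = ll
        pi, beta, sigma = _m_step(stk, X, resp, spec.variance_mode)
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()
    return pi, beta, sigma, resp, ll_old, np.array(history), False


def _init_params(stk, X, spec, rng, use_kmeans):
    """Initial responsibilities from k-means on per-subject OLS summaries, or random."""
    J = spec.J
    if use_kmeans:
        # per-subject (intercept, slope) OLS summaries; mean only if 1 point
        summ = np.zeros((stk.n_subjects, 2))
        for i in range(stk.n_subjects):
            s, c = stk.starts[i], stk.counts[i]
            ti, yi = stk.t[s : s + c], stk.y[s : s + c]
            if c >= 2 and np.ptp(ti) > 0:
                A = np.stack([np.ones_like(ti), ti], axis=1)
                summ[i] = np.linalg.lstsq(A, yi, rcond=None)[0]
            else:
                summ[i] = (yi.mean(), 0.0)
        std = summ.std(axis=0)
        std[std == 0] = 1.0
        km = KMeans(n_clusters=J, n_init=10,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(summ / std)
    else:
        labels = rng.integers(0, J, size=stk.n_subjects)
    resp = np.full((stk.n_subjects, J), 0.05 / max(J - 1, 1))
    resp[np.arange(stk.n_subjects), labels] = 0.95
    if J == 1:
        resp[:] = 1.0
    return _m_step(stk, X, resp, spec.variance_mode)


def _pack(pi, beta, sigma):
    # unconstrained parameterisation: softmax logits (first fixed 0), betas, log sigmas
    return np.concatenate([np.log(pi[1:] / pi[0]), beta.ravel(), np.log(sigma)])


def _unpack(theta, spec):
    J, P = spec.J, spec.order + 1
    logits = np.concatenate([[0.0], theta[: J - 1]])
    pi = np.exp(logits - logsumexp(logits))
    beta = theta[J - 1 : J - 1 + J * P].reshape(J, P)
    sigma = np.exp(theta[J - 1 + J * P :])
    return pi, beta, sigma


def _polish(stk, X, spec, pi, beta, sigma):
    """Quasi-Newton (BFGS) refinement of the EM solution on free parameters."""

    def nll(theta):
        p, b, s = _unpack(theta, spec)
        lj = _subject_loglik(stk, X, p, b, np.clip(s, 1e-8, None))
        return -float(logsumexp(lj, axis=1).sum())

    res = minimize(nll, _pack(pi, beta, sigma), method="L-BFGS-B")
    p, b, s = _unpack(res.x, spec)
    return p, b, s, -float(res.fun)


def _canonicalize(pi, beta, sigma, resp, variance_mode):
    order_val = beta @ (CANONICAL_WEEK ** np.arange(beta.shape[1]))
    perm = np.argsort(order_val, kind="stable")
    pi = pi[perm]
    beta = beta[perm]
    if variance_mode == "per_group":
        sigma = sigma[perm]
    resp = resp[:, perm]
    return pi, beta, sigma, resp


def fit_gbtm(
    data: pd.DataFrame,
    spec: GBTMSpec = GBTMSpec(),
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    polish: bool = False,
) -> TrajectoryFit:
    """Maximum-likelihood fit of a trajectory model by multi-start EM.

    The first start initialises from k-means on per-subject OLS (intercept,
    slope) summaries; the remaining starts use random hard assignments.  The
    best log-likelihood wins.  ``polish=True`` adds a quasi-Newton (L-BFGS)
    refinement of the winning solution.  Non-convergence or an empty group
    (pi_j < 1/n) is flagged on the returned fit, never silent.
    """
    stk = _Stacked(data)
    X = stk.design(spec.order)
    if stk.n_subjects <= spec.J * (spec.order + 2):
        raise ValueError(
            f"too few subjects ({stk.n_subjects}) for J={spec.J}, order={spec.order}"
        )
    ss = np.random.SeedSequence(seed)
    best = None
    for start, child in enumerate(ss.spawn(max(n_starts, 1))):
        rng = np.random.default_rng(child)
        try:
            pi0, beta0, sigma0 = _init_params(stk, X, spec, rng, use_kmeans=(start == 0))
            pi, beta, sigma, resp, ll, hist, conv = _em(
                stk, X, spec, pi0, beta0, sigma0, tol, max_iter
            )
        except (np.linalg.LinAlgError, ValueError):
            continue
        if best is None or ll > best[4]:
            best = (pi, beta, sigma, resp, ll, hist, conv)
    if best is None:
        raise RuntimeError("all EM starts failed")
    pi, beta, sigma, resp, ll, hist, conv = best
    if polish:
        try:
            pi_p, beta_p, sigma_p, ll_p = _polish(stk, X, spec, pi, beta, sigma)
            if ll_p > ll:
                pi, beta, sigma, ll = pi_p, beta_p, sigma_p, ll_p
                lj = _subject_loglik(stk, X, pi, beta, sigma)
                resp = np.exp(lj - logsumexp(lj, axis=1)[:, None])
        except Exception:  # polish is best-effort; EM solution stands
            warnings.warn("quasi-Newton polish failed; keeping EM solution",
                          RuntimeWarning, stacklevel=2)
    pi, beta, sigma, resp = _canonicalize(pi, beta, sigma, resp, spec.variance_mode)
    degenerate = bool(np.any(pi < 1.0 / stk.n_subjects))
    if not conv:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations (J={spec.J})",
            RuntimeWarning, stacklevel=2,
        )
    bic = -2.0 * ll + spec.n_params * np.log(stk.n_subjects)
    fit = TrajectoryFit(
        spec=spec,
        pi=pi,
        beta=beta,
        sigma=np.atleast_1d(sigma),
        loglik=ll,
        bic=float(bic),
        n_subjects=stk.n_subjects,
        posterior=resp,
        assignment=resp.argmax(axis=1),
        subject_ids=stk.ids,
        converged=conv,
        degenerate=degenerate,
        n_iter=len(hist),
        loglik_history=hist,
    )
    fit.diagnostics = adequacy_diagnostics(fit)
    return fit


class ModelSelectionError(RuntimeError):
    """All candidate models degenerate/failed; carries the sweep table."""

    def __init__(self, message: str, table: pd.DataFrame):
        super().__init__(message)
        self.table = table


def select_model(
    data: pd.DataFrame,
    J_range: Iterable[int] = (1, 2, 3, 4, 5),
    order_range: Iterable[int] = (1,),
    variance_mode: str = "shared",
    **fit_kwargs,
) -> tuple[TrajectoryFit, pd.DataFrame]:
    """Sweep (J, order) candidates; return the minimum-BIC fit and the sweep table.

    Degenerate fits (an essentially empty group) are excluded from the
    choice; if every candidate is degenerate a :class:`ModelSelectionError`
    carrying the table is raised.
    """
    J_range, order_range = list(J_range), list(order_range)
    if not J_range or not order_range:
        raise ValueError("J_range and order_range must be non-empty")
    rows, fits = [], {}
    for J in J_range:
        for order in order_range:
            spec = GBTMSpec(J=J, order=order, variance_mode=variance_mode)
            try:
                fit = fit_gbtm(data, spec, **fit_kwargs)
            except (ValueError, RuntimeError) as exc:
                rows.append({"J": J, "order": order, "k": spec.n_params,
                             "loglik": np.nan, "bic": np.nan, "degenerate": True,
                             "converged": False, "error": str(exc)})
                continue
            fits[(J, order)] = fit
            rows.append({"J": J, "order": order, "k": spec.n_params,
                         "loglik": fit.loglik, "bic": fit.bic,
                         "degenerate": fit.degenerate, "converged": fit.converged,
                         "error": ""})
    table = pd.DataFrame(rows)
    usable = table[~table["degenerate"] & table["bic"].notna()]
    if usable.empty:
        raise ModelSelectionError("no usable (non-degenerate) fit in the sweep", table)
    best_row = usable.loc[usable["bic"].idxmin()]
    return fits[(int(best_row["J"]), int(best_row["order"]))], table


def adequacy_diagnostics(fit: TrajectoryFit) -> pd.DataFrame:
    """Nagin adequacy report: one row per group.

    ``mean_posterior`` averages each member's posterior probability for the
    group it was assigned to; ``observed_share`` is the assigned fraction and
    ``expected_share`` the mean posterior column (the model's own expectation
    of the group share).  Groups with mean posterior below 0.70 are flagged.
    """
    J = fit.spec.J
    rows = []
    for j in range(J):
        members = fit.assignment == j
        mean_post = float(fit.posterior[members, j].mean()) if members.any() else np.nan
        rows.append({
            "group": j,
            "n_assigned": int(members.sum()),
            "observed_share": float(members.mean()),
            "expected_share": float(fit.posterior[:, j].mean()),
            "mean_posterior": mean_post,
            "below_threshold": bool(members.any() and mean_post < ADEQUACY_THRESHOLD),
        })
    return pd.DataFrame(rows)


def trajectory_slopes(
    fit: TrajectoryFit, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group linear slope with Wald CI, plus pairwise slope-difference tests.

    Standard errors come from the responsibility-weighted least-squares
    information of the final E-step, sigma_j^2 (X' W_j X)^{-1}; they condition
    on the posterior weights (the usual pseudo-class approximation).
    Requires polynomial order >= 1.
    """
    if fit.spec.order < 1:
        raise ValueError("slopes undefined for order-0 (flat) trajectories")
    stk = _Stacked(data)
    if not np.array_equal(stk.ids, fit.subject_ids):
        raise ValueError("data does not match the subjects of the fit")
    X = stk.design(fit.spec.order)
    z = sps.norm.ppf(1 - alpha / 2)
    sig = fit.group_sigma()
    rows = []
    for j in range(fit.spec.J):
        w = fit.posterior[stk.subj, j]
        XtWX = (X * w[:, None]).T @ X
        cov = sig[j] ** 2 * np.linalg.inv(XtWX)
        slope = fit.beta[j, 1]
        se = float(np.sqrt(cov[1, 1]))
        rows.append({
            "group": j, "slope": float(slope), "se": se,
            "ci_lo": float(slope - z * se), "ci_hi": float(slope + z * se),
        })
    slopes = pd.DataFrame(rows)
    pairs = []
    for a in range(fit.spec.J):
        for b in range(a + 1, fit.spec.J):
            diff = slopes.loc[a, "slope"] - slopes.loc[b, "slope"]
            se = float(np.hypot(slopes.loc[a, "se"], slopes.loc[b, "se"]))
            zstat = diff / se if se > 0 else np.inf * np.sign(diff)
            pairs.append({
                "group_a": a, "group_b": b, "diff": float(diff), "se": se,
                "z": float(zstat), "p": float(2 * sps.norm.sf(abs(zstat))),
            })
    return slopes, pd.DataFrame(pairs)


def simulate_mixture_trajectories(
    pi: Sequence[float],
    beta: np.ndarray,
    sigma,
    n_subjects: int,
    times: Sequence[float],
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw long-format data exactly from the mixture model (for recovery studies).

    Returns the long table and the true group of each subject (subjects are
    named ``T00000`` ... in order).
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi, dtype=float)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    J = beta.shape[0]
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float).ravel(), (J,))
    t = np.asarray(times, dtype=float)
    group = rng.choice(J, size=n_subjects, p=pi / pi.sum())
    T = t[None, :].repeat(n_subjects, axis=0)
    mean = beta[group] @ (t[:, None] ** np.arange(beta.shape[1])[None, :]).T
    y = mean + rng.normal(0.0, sigma[group][:, None], size=mean.shape)
    ids = np.array([f"T{i:05d}" for i in range(n_subjects)])
    long = pd.DataFrame({
        "id": np.repeat(ids, len(t)),
        "time": T.ravel(),
        "y": y.ravel(),
    })
    return long, group


def plot_trajectories(fit: TrajectoryFit, data: pd.DataFrame, path=None):
    """Fitted mean curves with pointwise 95% bands over the observed time span."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stk = _Stacked(data)
    grid = np.linspace(stk.t.min(), stk.t.max(), 100)
    X = grid[:, None] ** np.arange(fit.spec.order + 1)[None, :]
    sig = fit.group_sigma()
    fig, ax = plt.subplots(figsize=(7, 5))
    for j in range(fit.spec.J):
        w = fit.posterior[stk.subj, j]
        Xd = stk.design(fit.spec.order)
        cov = sig[j] ** 2 * np.linalg.inv((Xd * w[:, None]).T @ Xd)
        mean = X @ fit.beta[j]
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        label = f"group {chr(65 + j)} ({100 * fit.pi[j]:.1f}%)"
        ax.plot(grid, mean, label=label)
        ax.fill_between(grid, mean - 1.96 * se, mean + 1.96 * se, alpha=0.25)
    ax.set_xlabel("gestational age (weeks)")
    ax.set_ylabel("weight (kg)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
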