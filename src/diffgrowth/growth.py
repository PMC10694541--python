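"""Linear latent growth models estimated by casewise full-information
maximum likelihood (FIML).

The model for a child's observed vector y (three wave scores, optionally
followed by age-8 symptom scales) is

    y_i = nu + Lambda eta_i + kappa * d_i + eps_i,
    eta_i = alpha + Gamma x_i + zeta_i,   zeta_i ~ N(0, Psi),
    eps_i ~ N(0, Theta),

with fixed wave loadings Lambda_w = (1, t_w), time scores t_w = nominal age
minus 5 (the intercept is the age-5 endpoint of the process), d_i the
deviation of the child's actual age at each wave from the nominal age, and
x_i covariates (sex, parity) plus any exposure predictors.  Symptom rows,
when attached, have free intercepts, free loadings on the growth factors,
and free residual variances.  The bivariate variant stacks the behavioural
and emotional subscales with four factors and per-wave 2x2 residual blocks.

Estimation maximises the sum over children of the Gaussian log-density of
each child's *observed* subvector (valid under MAR), with optional
observation weights.  Variance parameters are optimised on a log /
log-Cholesky scale; gradients are analytic.  Standard errors come from a
cluster-robust sandwich A^-1 B A^-1 with clusters defined by mother, A the
observed information and B the outer product of cluster-summed scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

NOMINAL_AGES = np.array([1.5, 3.0, 5.0])
DEFAULT_TIMES = tuple(NOMINAL_AGES - 5.0)


class GrowthModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class GrowthSpec:
    """Declarative definition of a growth model.

    ``predictor_target`` fixes the exposure-to-factor paths that are *not*
    listed to zero; covariate paths are always free.  For the bivariate
    outcome the targets apply to the two intercept / two slope factors.
    """

    outcome: str = "diff"  # diff | tot | beh | emo | bivariate
    times: tuple = DEFAULT_TIMES
    include_age_deviation: bool = True
    covariates: tuple = ("sex", "parity")
    predictors: tuple = ()
    predictor_target: str = "both"  # both | intercept_only | slope_only
    symptoms: tuple = ()
    symptom_target: str = "both"
    equal_residuals: bool = False
    weights: str | None = None
    cluster: str | None = "mother_id"
    biv_prefixes: tuple = ("z_beh", "z_emo")

    def __post_init__(self):
        if self.predictor_target not in ("both", "intercept_only", "slope_only"):
            raise GrowthModelError(f"bad predictor_target {self.predictor_target!r}")
        if self.symptom_target not in ("both", "intercept_only", "slope_only"):
            raise GrowthModelError(f"bad symptom_target {self.symptom_target!r}")
        if self.outcome == "bivariate" and self.symptoms:
            raise GrowthModelError("symptom outcomes are supported for univariate models only")

    @property
    def n_factors(self) -> int:
        return 4 if self.outcome == "bivariate" else 2

    @property
    def factor_names(self) -> tuple:
        if self.outcome == "bivariate":
            return ("I_beh", "S_beh", "I_emo", "S_emo")
        return ("I", "S")


def _target_rows(target: str, m: int) -> tuple:
    if m == 2:
        return {"both": (0, 1), "intercept_only": (0,), "slope_only": (1,)}[target]
    return {"both": (0, 1, 2, 3), "intercept_only": (0, 2), "slope_only": (1, 3)}[target]


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------


class _Layout:
    """Maps between the packed parameter vector and model matrices.

    Two coordinate systems share one entry list: the unconstrained
    optimisation scale (log variances, log-Cholesky covariance factors) and
    the natural scale (variances/covariances), used for reporting and for
    the sandwich covariance.  Natural-scale evaluation is supported for
    univariate models.
    """

    def __init__(self, spec: GrowthSpec, xcols: list, symcols: list):
        self.spec = spec
        self.m = spec.n_factors
        self.biv = spec.outcome == "bivariate"
        self.n_waves = 3
        self.k_wave = 6 if self.biv else 3
        self.symcols = list(symcols)
        self.k = self.k_wave + len(symcols)
        self.xcols = list(xcols)
        t = np.asarray(spec.times, dtype=float)

        # fixed part of Lambda
        Lam0 = np.zeros((self.k, self.m))
        if self.biv:
            for w in range(3):
                Lam0[w, 0] = 1.0
                Lam0[w, 1] = t[w]
                Lam0[3 + w, 2] = 1.0
                Lam0[3 + w, 3] = t[w]
        else:
            for w in range(3):
                Lam0[w, 0] = 1.0
                Lam0[w, 1] = t[w]
        self.Lam0 = Lam0

        fac = spec.factor_names
        cov_rows = tuple(range(self.m))
        pred_rows = _target_rows(spec.predictor_target, self.m)
        sym_rows = _target_rows(spec.symptom_target, 2)

        entries = []  # (name, kind, info)
        for f in range(self.m):
            entries.append((f"alpha_{fac[f]}", "alpha", f))
        for j, xc in enumerate(xcols):
            rows = cov_rows if xc in spec.covariates else pred_rows
            for f in rows:
                entries.append((f"b_{xc}_{fac[f]}", "gamma", (f, j)))
        self.n_kappa = 0
        if spec.include_age_deviation:
            self.n_kappa = 2 if self.biv else 1
            if self.biv:
                entries.append(("kappa_beh", "kappa", 0))
                entries.append(("kappa_emo", "kappa", 1))
            else:
                entries.append(("kappa", "kappa", 0))
        for i in range(self.m):
            for j in range(i + 1):
                entries.append((f"psi_{fac[j]}_{fac[i]}" if i != j else f"psi_{fac[i]}_{fac[i]}",
                                "psi", (i, j)))
        if self.biv:
            for w in range(3):
                for (a, b) in ((0, 0), (1, 0), (1, 1)):
                    entries.append((f"thetaL_w{w + 1}_{a}{b}", "thetaL", (w, a, b)))
        elif spec.equal_residuals:
            entries.append(("theta", "theta", tuple(range(3))))
        else:
            for w in range(3):
                entries.append((f"theta_w{w + 1}", "theta", (w,)))
        for r, sc in enumerate(symcols):
            row = self.k_wave + r
            entries.append((f"nu_{sc}", "nu", row))
            for f in sym_rows:
                entries.append((f"lam_{sc}_{fac[f]}", "lam", (row, f)))
            entries.append((f"theta_{sc}", "theta_sym", row))
        self.entries = entries
        self.names = [e[0] for e in entries]
        self.p = len(entries)

    # -- unpacking ----------------------------------------------------------

    def unpack(self, vec: np.ndarray, natural: bool):
        """Return (alpha, Gamma, kappa, Psi, Lam, nu, theta_diag, offdiag)."""
        if natural and self.biv:
            raise GrowthModelError("natural-scale evaluation is univariate-only")
        m, k = self.m, self.k
        alpha = np.zeros(m)
        Gamma = np.zeros((m, len(self.xcols)))
        kappa = np.zeros(max(self.n_kappa, 1))
        Lpsi = np.zeros((m, m))
        Psi = np.zeros((m, m))
        Lam = self.Lam0.copy()
        nu = np.zeros(k)
        theta = np.zeros(k)
        LW = np.zeros((3, 2, 2))
        offdiag = []
        for v, (name, kind, info) in zip(vec, self.entries):
            if kind == "alpha":
                alpha[info] = v
            elif kind == "gamma":
                Gamma[info] = v
            elif kind == "kappa":
                kappa[info] = v
            elif kind == "psi":
                i, j = info
                if natural:
                    Psi[i, j] = Psi[j, i] = v
                else:
                    Lpsi[i, j] = np.exp(v) if i == j else v
            elif kind == "theta":
                val = v if natural else np.exp(v)
                for w in info:
                    theta[w] = val
            elif kind == "thetaL":
                w, a, b = info
                LW[w, a, b] = np.exp(v) if a == b else v
            elif kind == "nu":
                nu[info] = v
            elif kind == "lam":
                Lam[info] = v
            elif kind == "theta_sym":
                theta[info] = v if natural else np.exp(v)
        if not natural:
            Psi = Lpsi @ Lpsi.T
        if self.biv:
            for w in range(3):
                B = LW[w] @ LW[w].T
                theta[w] = B[0, 0]
                theta[3 + w] = B[1, 1]
                offdiag.append((w, 3 + w, B[1, 0]))
        return alpha, Gamma, kappa, Psi, Lam, nu, theta, offdiag, Lpsi, LW

    def u_to_natural(self, u: np.ndarray) -> np.ndarray:
        """Convert an unconstrained vector to the natural vector (univariate)."""
        alpha, Gamma, kappa, Psi, Lam, nu, theta, _, _, _ = self.unpack(u, natural=False)
        out = np.empty(self.p)
        for idx, (name, kind, info) in enumerate(self.entries):
            if kind == "alpha":
                out[idx] = alpha[info]
            elif kind == "gamma":
                out[idx] = Gamma[info]
            elif kind == "kappa":
                out[idx] = kappa[info]
            elif kind == "psi":
                i, j = info
                out[idx] = Psi[i, j]
            elif kind == "theta":
                out[idx] = theta[info[0]]
            elif kind == "nu":
                out[idx] = nu[info]
            elif kind == "lam":
                out[idx] = Lam[info]
            elif kind == "theta_sym":
                out[idx] = theta[info]
            else:
                raise GrowthModelError(f"cannot map {kind} to natural scale")
        return out

    def natural_to_u(self, nat: np.ndarray) -> np.ndarray:
        alpha, Gamma, kappa, Psi, Lam, nu, theta, _, _, _ = self.unpack(nat, natural=True)
        L = np.linalg.cholesky(Psi + 1e-12 * np.eye(self.m))
        out = np.empty(self.p)
        for idx, (name, kind, info) in enumerate(self.entries):
            if kind == "psi":
                i, j = info
                out[idx] = np.log(L[i, i]) if i == j else L[i, j]
            elif kind == "theta":
                out[idx] = np.log(theta[info[0]])
            elif kind == "theta_sym":
                out[idx] = np.log(theta[info])
            else:
                out[idx] = nat[idx]
        return out


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class _ModelData:
    Y: np.ndarray          # (n, k) with NaN for missing
    Dage: np.ndarray       # (n, 3) age deviations (0 where unknown)
    X: np.ndarray          # (n, q)
    w: np.ndarray          # (n,)
    clusters: np.ndarray   # (n,) cluster codes
    child_id: np.ndarray
    patterns: list         # list of (obs_idx ndarray, row_idx ndarray)
    Dfull: list            # per kappa group: (n, k) age-deviation design


def _prepare(data: pd.DataFrame, spec: GrowthSpec, layout: _Layout) -> _ModelData:
    n = len(data)
    if spec.outcome == "bivariate":
        cols = [f"{spec.biv_prefixes[0]}_{w}" for w in (1, 2, 3)] + [
            f"{spec.biv_prefixes[1]}_{w}" for w in (1, 2, 3)
        ]
    else:
        cols = [f"{spec.outcome}_{w}" for w in (1, 2, 3)]
    cols = cols + list(spec.symptoms)
    Y = data[cols].to_numpy(dtype=float)

    if spec.include_age_deviation and all(f"age_{w}" in data for w in (1, 2, 3)):
        ages = data[[f"age_{w}" for w in (1, 2, 3)]].to_numpy(dtype=float)
        Dage = np.nan_to_num(ages - NOMINAL_AGES, nan=0.0)
    else:
        Dage = np.zeros((n, 3))

    xcols = layout.xcols
    if xcols:
        X = data[list(xcols)].to_numpy(dtype=float)
        if np.isnan(X).any():
            bad = [c for c in xcols if data[c].isna().any()]
            raise GrowthModelError(f"missing values in covariates/predictors {bad}")
    else:
        X = np.zeros((n, 0))

    w = (
        data[spec.weights].to_numpy(dtype=float)
        if spec.weights
        else np.ones(n)
    )
    if (w < 0).any() or np.isnan(w).any():
        raise GrowthModelError("weights must be non-negative and non-missing")
    clusters = (
        pd.factorize(data[spec.cluster])[0]
        if spec.cluster and spec.cluster in data
        else np.arange(n)
    )
    child_id = (
        data["child_id"].to_numpy() if "child_id" in data else np.arange(n)
    )

    wave_obs = ~np.isnan(Y[:, : layout.k_wave])
    keep = wave_obs.any(axis=1)
    if not keep.all():
        Y, Dage, X, w = Y[keep], Dage[keep], X[keep], w[keep]
        clusters, child_id = clusters[keep], child_id[keep]
        n = keep.sum()

    obs = ~np.isnan(Y)
    codes = obs @ (1 << np.arange(layout.k))
    patterns = []
    for code in np.unique(codes):
        rows = np.nonzero(codes == code)[0]
        o = np.nonzero(obs[rows[0]])[0]
        patterns.append((o, rows))

    Dfull = []
    for g in range(max(layout.n_kappa, 1)):
        Dg = np.zeros((n, layout.k))
        if layout.n_kappa:
            if layout.biv:
                Dg[:, 3 * g : 3 * g + 3] = Dage
            else:
                Dg[:, :3] = Dage
        Dfull.append(Dg)
    return _ModelData(Y, Dage, X, w, clusters, child_id, patterns, Dfull)


# ---------------------------------------------------------------------------
# likelihood and gradient
# ---------------------------------------------------------------------------

_LOG2PI = np.log(2.0 * np.pi)


def _build_sigma(layout, Psi, Lam, theta, offdiag):
    Sigma = Lam @ Psi @ Lam.T + np.diag(theta)
    for (i, j, c) in offdiag:
        Sigma[i, j] += c
        Sigma[j, i] += c
    return Sigma


def _loglik_core(vec, layout: _Layout, data: _ModelData, natural: bool,
                 want_grad: bool):
    alpha, Gamma, kappa, Psi, Lam, nu, theta, offdiag, Lpsi, LW = layout.unpack(
        vec, natural
    )
    Sigma = _build_sigma(layout, Psi, Lam, theta, offdiag)
    Mfac = alpha + data.X @ Gamma.T                      # (n, m)
    Mu = nu + Mfac @ Lam.T                               # (n, k)
    for g in range(layout.n_kappa):
        Mu = Mu + kappa[g] * data.Dfull[g]
    R = data.Y - Mu

    n, k = data.Y.shape
    ll = 0.0
    Smean = np.zeros((n, k)) if want_grad else None
    Dmat = np.zeros((k, k)) if want_grad else None

    for o, rows in data.patterns:
        So = Sigma[np.ix_(o, o)]
        try:
            cf = cho_factor(So, lower=True)
        except np.linalg.LinAlgError as exc:
            raise GrowthModelError(
                f"singular implied covariance for observation pattern {tuple(o)}"
            ) from exc
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        Rp = R[np.ix_(rows, o)]
        S = cho_solve(cf, Rp.T).T                        # (n_p, k_o): s_i'
        quad = np.einsum("ij,ij->i", Rp, S)
        wp = data.w[rows]
        ll += -0.5 * (wp * (len(o) * _LOG2PI + logdet + quad)).sum()
        if want_grad:
            Smean[np.ix_(rows, o)] = wp[:, None] * S
            Sinv = cho_solve(cf, np.eye(len(o)))
            Dmat[np.ix_(o, o)] += 0.5 * ((S * wp[:, None]).T @ S - wp.sum() * Sinv)

    if not want_grad:
        return ll, None

    g_alpha = Lam.T @ Smean.sum(axis=0)
    Gfac = Smean @ Lam                                   # (n, m)
    g_Gamma = Gfac.T @ data.X if data.X.shape[1] else np.zeros((layout.m, 0))
    Mmat = Lam.T @ Dmat @ Lam                            # (m, m)
    DLP = Dmat @ Lam @ Psi                               # (k, m)
    GLpsi = 2.0 * Mmat @ Lpsi if not natural else None
    nu_grad = Smean.sum(axis=0)

    grad = np.empty(layout.p)
    for idx, (name, kind, info) in enumerate(layout.entries):
        if kind == "alpha":
            grad[idx] = g_alpha[info]
        elif kind == "gamma":
            grad[idx] = g_Gamma[info]
        elif kind == "kappa":
            grad[idx] = (Smean * data.Dfull[info]).sum()
        elif kind == "psi":
            i, j = info
            if natural:
                grad[idx] = Mmat[i, i] if i == j else 2.0 * Mmat[i, j]
            else:
                grad[idx] = GLpsi[i, j] * (Lpsi[i, i] if i == j else 1.0)
        elif kind == "theta":
            g = sum(Dmat[w, w] for w in info)
            grad[idx] = g if natural else g * theta[info[0]]
        elif kind == "thetaL":
            w, a, b = info
            Mb = Dmat[np.ix_((w, 3 + w), (w, 3 + w))]
            GL2 = 2.0 * Mb @ LW[w]
            grad[idx] = GL2[a, b] * (LW[w][a, a] if a == b else 1.0)
        elif kind == "nu":
            grad[idx] = nu_grad[info]
        elif kind == "lam":
            r, f = info
            grad[idx] = 2.0 * DLP[r, f] + (Smean[:, r] * Mfac[:, f]).sum()
        elif kind == "theta_sym":
            r = info
            grad[idx] = Dmat[r, r] * (1.0 if natural else theta[r])
    return ll, grad


def _score_matrix(nat: np.ndarray, layout: _Layout, data: _ModelData) -> np.ndarray:
    """Per-child score vectors of the weighted loglik, natural scale (univariate)."""
    alpha, Gamma, kappa, Psi, Lam, nu, theta, offdiag, _, _ = layout.unpack(
        nat, natural=True
    )
    Sigma = _build_sigma(layout, Psi, Lam, theta, offdiag)
    Mfac = alpha + data.X @ Gamma.T
    Mu = nu + Mfac @ Lam.T
    for g in range(layout.n_kappa):
        Mu = Mu + kappa[g] * data.Dfull[g]
    R = data.Y - Mu

    n, k = data.Y.shape
    scores = np.zeros((n, layout.p))
    for o, rows in data.patterns:
        So = Sigma[np.ix_(o, o)]
        cf = cho_factor(So, lower=True)
        Sinv = cho_solve(cf, np.eye(len(o)))
        Rp = R[np.ix_(rows, o)]
        S = Rp @ Sinv                                    # s_i'
        Lo = Lam[o]
        A = S @ Lo                                       # (n_p, m)
        Q = Lo.T @ Sinv @ Lo                             # (m, m)
        H = Lo @ Psi                                     # (k_o, m)
        SH = S @ H                                       # (n_p, m)
        Z = Sinv @ H                                     # (k_o, m)
        pos = {int(r): idx for idx, r in enumerate(o)}
        Dage_o = data.Dfull[0][np.ix_(rows, o)] if layout.n_kappa else None

        blk = np.zeros((len(rows), layout.p))
        for idx, (name, kind, info) in enumerate(layout.entries):
            if kind == "alpha":
                blk[:, idx] = A[:, info]
            elif kind == "gamma":
                f, j = info
                blk[:, idx] = A[:, f] * data.X[rows, j]
            elif kind == "kappa":
                blk[:, idx] = np.einsum("ij,ij->i", S, Dage_o)
            elif kind == "psi":
                i, j = info
                if i == j:
                    blk[:, idx] = 0.5 * (A[:, i] ** 2 - Q[i, i])
                else:
                    blk[:, idx] = A[:, i] * A[:, j] - Q[i, j]
            elif kind == "theta":
                acc = np.zeros(len(rows))
                for w in info:
                    if w in pos:
                        pw = pos[w]
                        acc += 0.5 * (S[:, pw] ** 2 - Sinv[pw, pw])
                blk[:, idx] = acc
            elif kind == "nu":
                if info in pos:
                    blk[:, idx] = S[:, pos[info]]
            elif kind == "lam":
                r, f = info
                if r in pos:
                    pr = pos[r]
                    blk[:, idx] = (
                        S[:, pr] * SH[:, f] - Z[pr, f] + S[:, pr] * Mfac[rows, f]
                    )
            elif kind == "theta_sym":
                r = info
                if r in pos:
                    pr = pos[r]
                    blk[:, idx] = 0.5 * (S[:, pr] ** 2 - Sinv[pr, pr])
        scores[rows] = data.w[rows, None] * blk
    return scores


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def implied_moments(spec: GrowthSpec, theta_nat: np.ndarray | dict,
                    x: np.ndarray | None = None,
                    age_dev: np.ndarray | None = None):
    """Model-implied (mu, Sigma) of the observed vector for one child.

    ``theta_nat`` is a natural-scale vector in layout order (or a
    name->value mapping).  ``x`` gives the child's covariate/predictor
    values (defaults to zeros), ``age_dev`` the wave age deviations.
    """
    layout = _Layout(spec, list(spec.covariates) + list(spec.predictors),
                     list(spec.symptoms))
    if isinstance(theta_nat, dict):
        missing = [nme for nme in layout.names if nme not in theta_nat]
        if missing:
            raise GrowthModelError(f"theta is missing parameters {missing}")
        theta_nat = np.array([theta_nat[nme] for nme in layout.names])
    theta_nat = np.asarray(theta_nat, dtype=float)
    if theta_nat.shape != (layout.p,):
        raise GrowthModelError(
            f"theta has wrong dimension {theta_nat.shape}, expected ({layout.p},)"
        )
    if layout.biv:
        raise GrowthModelError("implied_moments is univariate-only")
    alpha, Gamma, kappa, Psi, Lam, nu, theta, offdiag, _, _ = layout.unpack(
        theta_nat, natural=True
    )
    x = np.zeros(len(layout.xcols)) if x is None else np.asarray(x, dtype=float)
    if x.shape != (len(layout.xcols),):
        raise GrowthModelError(f"x has wrong dimension {x.shape}")
    mu = nu + Lam @ (alpha + Gamma @ x)
    if layout.n_kappa and age_dev is not None:
        d = np.zeros(layout.k)
        d[:3] = np.asarray(age_dev, dtype=float)
        mu = mu + kappa[0] * d
    Sigma = _build_sigma(layout, Psi, Lam, theta, offdiag)
    return mu, Sigma


def fiml_loglik(data: pd.DataFrame, spec: GrowthSpec,
                theta_nat: np.ndarray | dict) -> float:
    """Casewise FIML log-likelihood at a natural-scale parameter vector."""
    layout = _Layout(spec, list(spec.covariates) + list(spec.predictors),
                     list(spec.symptoms))
    if isinstance(theta_nat, dict):
        theta_nat = np.array([theta_nat[nme] for nme in layout.names])
    md = _prepare(data, spec, layout)
    ll, _ = _loglik_core(np.asarray(theta_nat, float), layout, md,
                         natural=not layout.biv, want_grad=False)
    return ll


@dataclass
class GrowthFit:
    spec: GrowthSpec
    names: list
    estimates: pd.Series          # natural scale (univariate); u-scale for bivariate
    loglik: float
    n_children: int
    n_clusters: int
    n_params: int
    converged: bool
    n_iter: int
    vcov_cluster: pd.DataFrame | None
    vcov_model: pd.DataFrame | None
    x_sd: pd.Series
    x_cov: pd.DataFrame
    natural: bool = True
    message: str = ""
    _layout: _Layout | None = field(default=None, repr=False)

    def se(self) -> pd.Series:
        if self.vcov_cluster is None:
            raise GrowthModelError("no cluster-robust vcov available")
        return pd.Series(np.sqrt(np.diag(self.vcov_cluster)), index=self.names)

    def params(self) -> dict:
        layout = self._layout
        alpha, Gamma, kappa, Psi, Lam, nu, theta, offdiag, _, _ = layout.unpack(
            self.estimates.to_numpy(), natural=self.natural
        )
        return {
            "alpha": alpha,
            "Gamma": pd.DataFrame(Gamma, index=self.spec.factor_names,
                                  columns=layout.xcols),
            "kappa": kappa[: layout.n_kappa],
            "Psi": Psi,
            "Lam": Lam,
            "nu": nu,
            "theta": theta,
            "offdiag": offdiag,
        }

    def wald_table(self) -> pd.DataFrame:
        se = self.se()
        est = self.estimates
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        ci = 1.96 * se
        return pd.DataFrame(
            {"estimate": est, "se": se, "ci_low": est - ci, "ci_high": est + ci,
             "z": z, "p": p}
        )

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_children) * self.n_params

    def to_dict(self) -> dict:
        d = {
            "outcome": self.spec.outcome,
            "estimates": dict(self.estimates),
            "se": dict(self.se()) if self.vcov_cluster is not None else None,
            "loglik": self.loglik,
            "n_children": int(self.n_children),
            "n_clusters": int(self.n_clusters),
            "n_params": int(self.n_params),
            "aic": self.aic(),
            "bic": self.bic(),
            "converged": bool(self.converged),
        }
        return d


def _start_values(layout: _Layout, md: _ModelData) -> np.ndarray:
    """Moment-based starting values on the unconstrained scale."""
    Y = md.Y
    u0 = np.zeros(layout.p)
    if layout.biv:
        means = np.nanmean(Y, axis=0)
        var = np.nanvar(Y, axis=0) + 1e-6
        for idx, (name, kind, info) in enumerate(layout.entries):
            if kind == "alpha":
                f = info
                block = 0 if f < 2 else 3
                if f % 2 == 0:
                    u0[idx] = means[block + 2]
                else:
                    u0[idx] = (means[block + 2] - means[block]) / 3.5
            elif kind == "psi":
                i, j = info
                if i == j:
                    base = var[2] if i in (0, 2) else var[2] / 20
                    u0[idx] = 0.5 * np.log(max(base / 2, 1e-4))
            elif kind == "thetaL":
                w, a, b = info
                if a == b:
                    v = var[w] if a == 0 else var[3 + w]
                    u0[idx] = 0.5 * np.log(max(v / 2, 1e-4))
        return u0
    means = np.nanmean(Y[:, :3], axis=0)
    var = np.nanvar(Y[:, :3], axis=0) + 1e-6
    for idx, (name, kind, info) in enumerate(layout.entries):
        if kind == "alpha":
            u0[idx] = means[2] if info == 0 else (means[2] - means[0]) / 3.5
        elif kind == "psi":
            i, j = info
            if i == j:
                base = var[2] / 2 if i == 0 else var[2] / 20
                u0[idx] = 0.5 * np.log(max(base, 1e-4))
        elif kind == "theta":
            u0[idx] = np.log(max(var[info[0]] / 2, 1e-4))
        elif kind == "nu":
            u0[idx] = np.nanmean(Y[:, info])
        elif kind == "theta_sym":
            u0[idx] = np.log(max(np.nanvar(Y[:, info]), 1e-4))
    return u0


def fit_growth(data: pd.DataFrame, spec: GrowthSpec,
               *, compute_vcov: bool = True, max_restarts: int = 4,
               gtol: float = 1e-7) -> GrowthFit:
    """Fit a growth model by FIML with optional observation weights.

    Quasi-Newton (L-BFGS-B) on the unconstrained scale with analytic
    gradients; jittered restarts on non-convergence; the ``converged`` flag
    reflects the final gradient norm honestly.
    """
    layout = _Layout(spec, list(spec.covariates) + list(spec.predictors),
                     list(spec.symptoms))
    md = _prepare(data, spec, layout)
    n_w = md.w.sum()
    if n_w <= 0:
        raise GrowthModelError("all weights are zero")

    def objective(u):
        ll, g = _loglik_core(u, layout, md, natural=False, want_grad=True)
        return -ll / n_w, -g / n_w

    u0 = _start_values(layout, md)
    best_res, best_ok = None, False
    rng = np.random.default_rng(12345)
    n_iter = 0
    for attempt in range(max_restarts + 1):
        start = u0 if attempt == 0 else u0 + rng.normal(0, 0.2, layout.p)
        try:
            res = optimize.minimize(
                objective, start, jac=True, method="L-BFGS-B",
                options={"maxiter": 3000, "ftol": 1e-13, "gtol": gtol},
            )
        except GrowthModelError:
            continue
        n_iter += res.nit
        ok = np.max(np.abs(res.jac)) < max(gtol * 100, 1e-5)
        if best_res is None or res.fun < best_res.fun - 1e-12:
            best_res, best_ok = res, ok
        if best_ok:
            break
    if best_res is None:
        raise GrowthModelError("optimisation failed on all starts")
    res, converged = best_res, best_ok
    u_hat = res.x
    loglik = -res.fun * n_w

    univ = not layout.biv
    if univ:
        est = pd.Series(layout.u_to_natural(u_hat), index=layout.names)
    else:
        est = pd.Series(u_hat, index=layout.names)

    xdf = pd.DataFrame(md.X, columns=layout.xcols)
    x_sd = xdf.std(ddof=1) if len(layout.xcols) else pd.Series(dtype=float)
    x_cov = xdf.cov() if len(layout.xcols) else pd.DataFrame()
    n_clusters = len(np.unique(md.clusters))

    vcov_cluster = vcov_model = None
    if compute_vcov and univ:
        vcov_cluster, vcov_model = _sandwich(est.to_numpy(), layout, md)
        vcov_cluster = pd.DataFrame(vcov_cluster, index=layout.names,
                                    columns=layout.names)
        vcov_model = pd.DataFrame(vcov_model, index=layout.names,
                                  columns=layout.names)
        if n_clusters < layout.p:
            warnings.warn(
                f"fewer clusters ({n_clusters}) than parameters ({layout.p}); "
                "cluster-robust covariance may be rank-deficient"
            )

    return GrowthFit(
        spec=spec, names=layout.names, estimates=est, loglik=float(loglik),
        n_children=len(md.Y), n_clusters=n_clusters, n_params=layout.p,
        converged=bool(converged), n_iter=n_iter,
        vcov_cluster=vcov_cluster, vcov_model=vcov_model,
        x_sd=x_sd, x_cov=x_cov, natural=univ,
        message=res.message if isinstance(res.message, str) else "",
        _layout=layout,
    )


def _sandwich(nat: np.ndarray, layout: _Layout, md: _ModelData):
    """Cluster-robust A^-1 B A^-1 and model-based A^-1 on the natural scale."""
    p = layout.p

    def grad_nat(v):
        _, g = _loglik_core(v, layout, md, natural=True, want_grad=True)
        return g

    H = np.zeros((p, p))
    base_h = 1e-5
    for i in range(p):
        h = base_h * max(1.0, abs(nat[i]))
        vp, vm = nat.copy(), nat.copy()
        vp[i] += h
        vm[i] -= h
        H[i] = (grad_nat(vp) - grad_nat(vm)) / (2 * h)
    H = 0.5 * (H + H.T)
    A = -H  # observed information

    scores = _score_matrix(nat, layout, md)
    G = len(np.unique(md.clusters))
    cl_scores = np.zeros((G, p))
    np.add.at(cl_scores, pd.factorize(md.clusters)[0], scores)
    B = cl_scores.T @ cl_scores * (G / max(G - 1, 1))

    Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv
    return 0.5 * (V + V.T), 0.5 * (Ainv + Ainv.T)


def cluster_robust_vcov(fit: GrowthFit, data: pd.DataFrame) -> pd.DataFrame:
    """Recompute the mother-clustered sandwich covariance for a fit."""
    if not fit.converged:
        raise GrowthModelError("cluster_robust_vcov requires a converged fit")
    layout = fit._layout
    md = _prepare(data, fit.spec, layout)
    V, _ = _sandwich(fit.estimates.to_numpy(), layout, md)
    return pd.DataFrame(V, index=fit.names, columns=fit.names)


# -- derived quantities -----------------------------------------------------


def delta_method(fit: GrowthFit, func, *, use_cluster: bool = True):
    """(value, se) of a scalar function of the natural parameter vector."""
    nat = fit.estimates.to_numpy()
    V = (fit.vcov_cluster if use_cluster else fit.vcov_model).to_numpy()
    val = func(nat)
    J = np.empty(len(nat))
    for i in range(len(nat)):
        h = 1e-6 * max(1.0, abs(nat[i]))
        vp, vm = nat.copy(), nat.copy()
        vp[i] += h
        vm[i] -= h
        J[i] = (func(vp) - func(vm)) / (2 * h)
    return float(val), float(np.sqrt(max(J @ V @ J, 0.0)))


def _marginal_factor_cov(fit: GrowthFit, nat: np.ndarray) -> np.ndarray:
    layout = fit._layout
    alpha, Gamma, kappa, Psi, Lam, nu, theta, offdiag, _, _ = layout.unpack(
        nat, natural=True
    )
    if len(layout.xcols):
        Sx = fit.x_cov.to_numpy()
        return Psi + Gamma @ Sx @ Gamma.T
    return Psi


def factor_correlation(fit: GrowthFit, *, marginal: bool = True,
                       factors: tuple = (0, 1)):
    """Slope-intercept correlation of the latent factors, with delta-method SE."""
    i, j = factors

    def f(nat):
        P = (_marginal_factor_cov(fit, nat) if marginal
             else fit._layout.unpack(nat, natural=True)[3])
        return P[i, j] / np.sqrt(P[i, i] * P[j, j])

    return delta_method(fit, f)


def standardised_beta(fit: GrowthFit, predictor: str, factor: str = "I",
                      *, scale_sd: float | None = None):
    """Per-SD-of-predictor effect on the factor, in factor-SD units.

    ``scale_sd`` overrides the predictor SD used for standardisation --
    e.g. to put a within-family deviation coefficient on the scale of the
    raw exposure so adjusted and unadjusted estimates are comparable.
    """
    layout = fit._layout
    f = fit.spec.factor_names.index(factor)
    j = layout.xcols.index(predictor)
    sx = fit.x_sd[predictor] if scale_sd is None else float(scale_sd)

    def g(nat):
        alpha, Gamma, *_ = layout.unpack(nat, natural=True)
        P = _marginal_factor_cov(fit, nat)
        return Gamma[f, j] * sx / np.sqrt(P[f, f])

    return delta_method(fit, g)


# ---------------------------------------------------------------------------
# saturated / baseline models and fit indices
# ---------------------------------------------------------------------------


@dataclass
class MomentsFit:
    mu: np.ndarray
    Sigma: np.ndarray
    loglik: float
    n_params: int
    n: int
    converged: bool = True


def _mvn_loglik_patterns(Y, w, mu, Sigma):
    obs = ~np.isnan(Y)
    codes = obs @ (1 << np.arange(Y.shape[1]))
    ll = 0.0
    for code in np.unique(codes):
        rows = np.nonzero(codes == code)[0]
        o = np.nonzero(obs[rows[0]])[0]
        So = Sigma[np.ix_(o, o)]
        cf = cho_factor(So, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        Rp = Y[np.ix_(rows, o)] - mu[o]
        quad = np.einsum("ij,ij->i", Rp, cho_solve(cf, Rp.T).T)
        ll += -0.5 * (w[rows] * (len(o) * _LOG2PI + logdet + quad)).sum()
    return ll


def fit_saturated(Y: np.ndarray, weights: np.ndarray | None = None,
                  *, tol: float = 1e-9, max_iter: int = 2000) -> MomentsFit:
    """Unrestricted MVN mean/covariance by FIML (EM when data are missing)."""
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    obs = ~np.isnan(Y)
    if obs.all():
        wn = w / w.sum()
        mu = wn @ Y
        R = Y - mu
        Sigma = (R * wn[:, None]).T @ R
        ll = _mvn_loglik_patterns(Y, w, mu, Sigma)
        return MomentsFit(mu, Sigma, ll, k + k * (k + 1) // 2, n)

    mu = np.nanmean(Y, axis=0)
    Sigma = np.diag(np.nanvar(Y, axis=0) + 1e-6)
    codes = obs @ (1 << np.arange(k))
    groups = []
    for code in np.unique(codes):
        rows = np.nonzero(codes == code)[0]
        o = np.nonzero(obs[rows[0]])[0]
        m = np.nonzero(~obs[rows[0]])[0]
        groups.append((o, m, rows))
    W = w.sum()
    last_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        Ey = np.zeros(k)
        Eyy = np.zeros((k, k))
        for o, m, rows in groups:
            wp = w[rows]
            Yp = np.zeros((len(rows), k))
            Yp[:, o] = Y[np.ix_(rows, o)]
            if len(m):
                cf = cho_factor(Sigma[np.ix_(o, o)], lower=True)
                Bm = cho_solve(cf, Sigma[np.ix_(o, m)])  # (k_o, k_m)
                cond = mu[m] + (Y[np.ix_(rows, o)] - mu[o]) @ Bm
                Yp[:, m] = cond
                Cmm = Sigma[np.ix_(m, m)] - Sigma[np.ix_(m, o)] @ Bm
            Ey += wp @ Yp
            Eyy += (Yp * wp[:, None]).T @ Yp
            if len(m):
                Eyy[np.ix_(m, m)] += wp.sum() * Cmm
        mu = Ey / W
        Sigma = Eyy / W - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _mvn_loglik_patterns(Y, w, mu, Sigma)
        if abs(ll - last_ll) < tol * (1 + abs(ll)):
            converged = True
            break
        last_ll = ll
    return MomentsFit(mu, Sigma, ll, k + k * (k + 1) // 2, n, converged)


def fit_baseline(Y: np.ndarray, weights: np.ndarray | None = None) -> MomentsFit:
    """Independence model: free means and variances, zero covariances.

    With a diagonal covariance the casewise likelihood factorises per
    column, so the FIML solution is the per-column weighted MLE.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    mu = np.zeros(k)
    var = np.zeros(k)
    for j in range(k):
        o = ~np.isnan(Y[:, j])
        wj = w[o]
        mu[j] = (wj @ Y[o, j]) / wj.sum()
        var[j] = (wj @ (Y[o, j] - mu[j]) ** 2) / wj.sum()
    Sigma = np.diag(var)
    ll = _mvn_loglik_patterns(Y, w, mu, Sigma)
    return MomentsFit(mu, Sigma, ll, 2 * k, n)


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    aic: float
    bic: float
    chi2_baseline: float
    df_baseline: int
    flagged: bool = False


def fit_indices(fit: GrowthFit, saturated: MomentsFit,
                baseline: MomentsFit) -> FitIndices:
    """Moment-based fit statistics for a measurement-model fit.

    Requires a fit of the wave scores alone (no covariates, predictors,
    symptoms or age-deviation term), so that the saturated model -- the
    unrestricted mean/covariance of the wave scores -- nests it.
    """
    spec = fit.spec
    if spec.covariates or spec.predictors or spec.symptoms or spec.include_age_deviation:
        raise GrowthModelError(
            "fit_indices needs a measurement-only fit: use measurement_fit()"
        )
    k = fit._layout.k
    n_mom = k + k * (k + 1) // 2
    chi2 = max(2.0 * (saturated.loglik - fit.loglik), 0.0)
    df = n_mom - fit.n_params
    chi2_b = max(2.0 * (saturated.loglik - baseline.loglik), 0.0)
    df_b = n_mom - baseline.n_params
    n = fit.n_children

    p = stats.chi2.sf(chi2, df) if df > 0 else np.nan
    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * n)) if df > 0 else 0.0
    d_m = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    flagged = chi2_b < chi2
    cfi = 1.0 - d_m / max(d_b, d_m, np.finfo(float).tiny)
    cfi = float(np.clip(cfi, 0.0, 1.05))
    if chi2_b > 0 and df_b > 0 and df > 0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / max((chi2_b / df_b) - 1.0,
                                                    np.finfo(float).tiny)
        tli = float(np.clip(tli, 0.0, 1.05))
    else:
        tli = np.nan

    pars = fit.params()
    mu_m = pars["nu"] + pars["Lam"] @ pars["alpha"]
    Sigma_m = _build_sigma(fit._layout, pars["Psi"], pars["Lam"], pars["theta"],
                           pars["offdiag"])
    sd = np.sqrt(np.diag(saturated.Sigma))
    e = []
    for i in range(k):
        e.append((saturated.mu[i] - mu_m[i]) / sd[i])
        for j in range(i + 1):
            e.append(
                (saturated.Sigma[i, j] - Sigma_m[i, j]) / (sd[i] * sd[j])
            )
    srmr = float(np.sqrt(np.mean(np.square(e))))

    return FitIndices(
        chi2=float(chi2), df=int(df), p=float(p), cfi=cfi, tli=tli,
        rmsea=float(rmsea), srmr=srmr, aic=fit.aic(), bic=fit.bic(),
        chi2_baseline=float(chi2_b), df_baseline=int(df_b), flagged=flagged,
    )


def measurement_fit(data: pd.DataFrame, outcome: str = "diff",
                    **fit_kwargs) -> tuple[GrowthFit, FitIndices]:
    """Fit the bare growth model to the wave scores and compute fit indices."""
    spec = GrowthSpec(outcome=outcome, covariates=(), predictors=(),
                      symptoms=(), include_age_deviation=False)
    fit = fit_growth(data, spec, **fit_kwargs)
    cols = [f"{outcome}_{w}" for w in (1, 2, 3)]
    Y = data[cols].to_numpy(dtype=float)
    keep = ~np.isnan(Y).all(axis=1)
    Y = Y[keep]
    sat = fit_saturated(Y)
    base = fit_baseline(Y)
    return fit, fit_indices(fit, sat, base)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float
    bic_full: float
    bic_nested: float
    advisory: str = ""


def lrt(fit_full: GrowthFit, fit_nested: GrowthFit) -> LRTResult:
    """Likelihood-ratio test of nested fits (same children required).

    The BIC comparison is attached for the non-nested decision path.
    """
    if fit_full.n_children != fit_nested.n_children:
        raise GrowthModelError("LRT requires fits on the same children")
    df = fit_full.n_params - fit_nested.n_params
    if df < 0:
        raise GrowthModelError("fit_full has fewer parameters than fit_nested")
    stat = 2.0 * (fit_full.loglik - fit_nested.loglik)
    advisory = ""
    if stat < -1e-6 * max(1.0, abs(fit_full.loglik)):
        advisory = "negative LR statistic beyond tolerance: refit advised"
    stat = max(stat, 0.0)
    p = stats.chi2.sf(stat, df) if df > 0 else 1.0
    return LRTResult(float(stat), int(df), float(p),
                     fit_full.bic(), fit_nested.bic(), advisory)


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------


def factor_scores(fit: GrowthFit, data: pd.DataFrame,
                  method: str = "regression") -> pd.DataFrame:
    """Expected (intercept, slope) per child given observed waves and covariates.

    The regression method shrinks toward the conditional mean given
    covariates; Bartlett scores require at least as many observed rows as
    factors and are unshrunken.
    """
    layout = fit._layout
    if layout.biv:
        raise GrowthModelError("factor scores are univariate-only")
    md = _prepare(data, fit.spec, layout)
    pars = fit.params()
    alpha, Gamma, Psi, Lam, nu, theta = (
        pars["alpha"], pars["Gamma"].to_numpy(), pars["Psi"], pars["Lam"],
        pars["nu"], pars["theta"],
    )
    kappa = pars["kappa"]
    Sigma = _build_sigma(layout, Psi, Lam, theta, pars["offdiag"])
    Mfac = alpha + md.X @ Gamma.T
    Mu = nu + Mfac @ Lam.T
    if layout.n_kappa:
        Mu = Mu + kappa[0] * md.Dfull[0]
    R = md.Y - Mu

    n = len(md.Y)
    eta = np.full((n, 2), np.nan)
    n_obs = np.zeros(n, dtype=int)
    for o, rows in md.patterns:
        Rp = R[np.ix_(rows, o)]
        n_obs[rows] = len(o)
        if method == "regression":
            cf = cho_factor(Sigma[np.ix_(o, o)], lower=True)
            K = Psi @ Lam[o].T @ cho_solve(cf, np.eye(len(o)))
            eta[rows] = Mfac[rows] + Rp @ K.T
        elif method == "bartlett":
            if len(o) < layout.m:
                continue
            Lo = Lam[o]
            Ti = np.diag(1.0 / theta[o])
            W = np.linalg.solve(Lo.T @ Ti @ Lo, Lo.T @ Ti)
            resid = md.Y[np.ix_(rows, o)] - nu[o]
            if layout.n_kappa:
                resid = resid - kappa[0] * md.Dfull[0][np.ix_(rows, o)]
            eta[rows] = resid @ W.T
        else:
            raise GrowthModelError(f"unknown factor-score method {method!r}")
    out = pd.DataFrame(
        {"child_id": md.child_id, "eta_I": eta[:, 0], "eta_S": eta[:, 1],
         "n_waves": n_obs}
    )
    out.attrs["method"] = method
    return out


# ---------------------------------------------------------------------------
# model-exact simulation (oracle helper)
# ---------------------------------------------------------------------------


def simulate_growth(n: int, rng: np.random.Generator, *,
                    outcome: str = "diff",
                    alpha=(0.0, 0.0),
                    psi=((1.0, 0.202386), (0.202386, 0.1)),
                    theta=(0.65, 1.4, 1.0),
                    times=DEFAULT_TIMES,
                    kappa: float = 0.0,
                    age_jitter_sd: float = 0.0) -> pd.DataFrame:
    """Draw wave scores exactly from the univariate linear growth model.

    Defaults are the differentiation process of the cohort generator's
    default parameterisation: factor variances (1, 0.1) with correlation
    0.64, and wave residual variances equal to the sum of the two
    subscales' residuals.
    """
    t = np.asarray(times)
    psi = np.asarray(psi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    eta = rng.multivariate_normal(np.asarray(alpha, float), psi, size=n,
                                  method="cholesky")
    dev = (
        rng.standard_normal((n, 3)) * age_jitter_sd
        if age_jitter_sd > 0
        else np.zeros((n, 3))
    )
    Y = (
        eta[:, [0]]
        + eta[:, [1]] * t
        + kappa * dev
        + rng.standard_normal((n, 3)) * np.sqrt(theta)
    )
    out = pd.DataFrame({f"{outcome}_{w + 1}": Y[:, w] for w in range(3)})
    for w in range(3):
        out[f"age_{w + 1}"] = NOMINAL_AGES[w] + dev[:, w]
    out["child_id"] = np.arange(n)
    out["mother_id"] = np.arange(n)
    out["eta_I_true"] = eta[:, 0]
    out["eta_S_true"] = eta[:, 1]
    return out
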