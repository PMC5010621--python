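"""Bayesian Poisson ecological regression with BYM random effects.

The disease model for area i is

    O_i ~ Poisson(E_i * lambda_i),
    log(lambda_i) = alpha + beta * expos_i + sum_j delta_j Soc_ij
                    + gamma * Indus_i + u_i + v_i,

where u is an intrinsic CAR (ICAR) spatially structured effect on the
municipal adjacency graph — constrained to sum to zero per connected
component — and v is an unstructured iid normal effect (the
Besag–York–Mollié decomposition).  Exposure enters either as quartile
dummies (first quartile reference), as the quartile ordinal treated as
continuous (the trend test), or as the continuous log concentration.

Inference is by the package's HMC sampler with a non-centred
parameterisation of both random effects and a soft sum-to-zero constraint
on the ICAR component; priors are weakly informative and exposed in
``PriorConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hmc import McmcConfig, McmcResult, diagnostics, sample_hmc, summarize
from .universe import _components


import math


def _sexp(x):
    """exp with clipping: keeps warmup excursions of log-SD parameters finite."""
    x = float(x)
    return math.exp(-12.0 if x < -12.0 else (6.0 if x > 6.0 else x))


EXPOSURE_CODINGS = ("quartile_factor", "quartile_ordinal", "continuous_log")


@dataclass
class PriorConfig:
    """Weakly-informative defaults: N(0, 10^2) on fixed effects,
    half-Normal(1) on the random-effect SDs."""

    fixed_sd: float = 10.0
    sigma_u_scale: float = 1.0
    sigma_v_scale: float = 1.0


@dataclass
class BymSpec:
    """Model specification for the ecological regression.

    ``adjacency`` is a list of undirected (i, j) index pairs on the area
    table's row order; ``covariates`` names columns used as confounders
    (the ``industry_within_5km`` flag and the ``size_class`` factor get
    their natural encodings).
    """

    adjacency: list
    exposure_coding: str = "quartile_factor"
    covariates: list = dc_field(default_factory=list)
    priors: PriorConfig = dc_field(default_factory=PriorConfig)
    include_u: bool = True
    include_v: bool = True

    def __post_init__(self) -> None:
        if self.exposure_coding not in EXPOSURE_CODINGS:
            raise ValueError(f"unknown exposure coding {self.exposure_coding!r}")


@dataclass
class FitResult:
    """Posterior summaries of a fitted disease model."""

    summary: pd.DataFrame  # index: parameter; columns mean, median, q2.5, q97.5
    rr_table: pd.DataFrame  # exp() of the exposure/covariate rows
    area_rr: np.ndarray  # posterior mean relative risk per area
    draws: dict  # name -> flattened posterior draws (reported parameters)
    diagnostics: dict  # rhat/ess arrays aligned with reported parameters
    converged: bool
    meta: dict = dc_field(default_factory=dict)

    def rr(self, name: str) -> dict:
        row = self.rr_table.loc[name]
        return {"rr": row["rr"], "lo": row["q2.5"], "hi": row["q97.5"]}


def quartile_code(exposures) -> tuple:
    """Quartile levels 1-4 with cut points at the 25/50/75 percentiles.

    Percentiles use the linear-interpolation rule (numpy default, type 7).
    Intervals are [low, high) except the last, which is closed above.
    Raises if ties collapse any quartile to empty.
    """
    x = np.asarray(exposures, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError(
            "fewer than 4 distinct exposure values; quartile coding is degenerate "
            "- use continuous coding"
        )
    cuts = np.percentile(x, [25.0, 50.0, 75.0])
    codes = 1 + np.searchsorted(cuts, x, side="right")
    # values exactly at a cut belong to the upper interval ([low, high))
    counts = np.bincount(codes, minlength=5)[1:]
    if (counts == 0).any():
        raise ValueError(
            f"ties collapse a quartile to empty (counts {counts.tolist()}); "
            "use continuous coding"
        )
    return codes, cuts


def significance_flag(lo: float, hi: float) -> bool:
    """True iff the 95% credibility interval strictly excludes RR = 1."""
    return bool(hi < 1.0 or lo > 1.0)


def _design_matrix(data: pd.DataFrame, spec: BymSpec, exposure_col: str = "expos"):
    """Build the design matrix and column names for the configured coding."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["alpha"]
    meta = {}
    expos = data[exposure_col].to_numpy(dtype=float)
    if spec.exposure_coding == "quartile_factor":
        codes, cuts = quartile_code(expos)
        for q in (2, 3, 4):
            cols.append((codes == q).astype(float))
            names.append(f"beta_q{q}")
        meta["quartile_cuts"] = cuts
    elif spec.exposure_coding == "quartile_ordinal":
        codes, cuts = quartile_code(expos)
        cols.append(codes.astype(float))
        names.append("beta_trend")
        meta["quartile_cuts"] = cuts
    else:  # continuous_log
        cols.append(expos)
        names.append("beta")
    for cov in spec.covariates:
        if cov == "size_class":
            for lev in ("semi-urban", "urban"):
                cols.append((data["size_class"] == lev).to_numpy(float))
                names.append(f"delta_size_{lev}")
        elif cov == "industry_within_5km":
            cols.append(data[cov].to_numpy(float))
            names.append("gamma_industry")
        else:
            cols.append(data[cov].to_numpy(float))
            names.append(f"delta_{cov}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names, meta


class _BymPosterior:
    """Log posterior and gradient of the BYM Poisson model (non-centred)."""

    def __init__(self, O, E, X, spec: BymSpec, n_areas: int):
        self.O = np.asarray(O, dtype=float)
        self.logE = np.log(np.maximum(np.asarray(E, dtype=float), 1e-300))
        if not (np.asarray(E) > 0).any():
            raise ValueError("all expected counts are zero")
        self.X = X
        self.spec = spec
        self.n = n_areas
        self.p = X.shape[1]
        edges = spec.adjacency
        if spec.include_u:
            rows = np.repeat(np.arange(len(edges)), 2)
            cols = np.array(edges).ravel()
            vals = np.tile([1.0, -1.0], len(edges))
            D = sp.csr_matrix((vals, (rows, cols)), shape=(len(edges), n_areas))
            self.L = (D.T @ D).tocsr()
            self.components = _components(edges, n_areas)
        # parameter layout: [b(p), u_raw(n)?, v_raw(n)?, log_su?, log_sv?]
        self.dim = self.p
        self.sl_u = self.sl_v = None
        self.i_lsu = self.i_lsv = None
        if spec.include_u:
            self.sl_u = slice(self.dim, self.dim + n_areas)
            self.dim += n_areas
        if spec.include_v:
            self.sl_v = slice(self.dim, self.dim + n_areas)
            self.dim += n_areas
        if spec.include_u:
            self.i_lsu = self.dim
            self.dim += 1
        if spec.include_v:
            self.i_lsv = self.dim
            self.dim += 1

    def initial(self) -> np.ndarray:
        th = np.zeros(self.dim)
        smr = (self.O.sum() + 0.5) / max(np.exp(self.logE).sum(), 1e-12)
        th[0] = np.log(smr)
        if self.i_lsu is not None:
            th[self.i_lsu] = np.log(0.1)
        if self.i_lsv is not None:
            th[self.i_lsv] = np.log(0.1)
        return th

    def unpack(self, th):
        b = th[: self.p]
        u = v = 0.0
        su = sv = None
        if self.sl_u is not None:
            su = _sexp(th[self.i_lsu])
            u = su * th[self.sl_u]
        if self.sl_v is not None:
            sv = _sexp(th[self.i_lsv])
            v = sv * th[self.sl_v]
        return b, u, v, su, sv

    def linpred(self, th):
        b, u, v, _, _ = self.unpack(th)
        return self.X @ b + u + v

    def __call__(self, th):
        pr = self.spec.priors
        b = th[: self.p]
        eta = self.X @ b + self.logE
        grad = np.zeros_like(th)
        logp = 0.0
        u_raw = v_raw = None
        su = sv = None
        if self.sl_u is not None:
            su = _sexp(th[self.i_lsu])
            u_raw = th[self.sl_u]
            eta = eta + su * u_raw
        if self.sl_v is not None:
            sv = _sexp(th[self.i_lsv])
            v_raw = th[self.sl_v]
            eta = eta + sv * v_raw
        mu = np.exp(np.minimum(eta, 50.0))
        r = self.O - mu
        logp += float(self.O @ eta - mu.sum())
        grad[: self.p] = self.X.T @ r
        # fixed-effect prior
        logp += float(-0.5 * (b @ b) / pr.fixed_sd**2)
        grad[: self.p] += -b / pr.fixed_sd**2
        if self.sl_u is not None:
            Lu = self.L @ u_raw
            logp += float(-0.5 * (u_raw @ Lu))
            g_u = su * r - Lu
            for members in self.components:
                s = u_raw[members].sum()
                scale = 0.001 * len(members)
                logp += -0.5 * (s / scale) ** 2
                g_u[members] -= s / scale**2
            grad[self.sl_u] = g_u
            # half-normal prior on sigma_u (log parameterisation, Jacobian incl.)
            logp += float(-0.5 * su**2 / pr.sigma_u_scale**2 + np.log(su))
            grad[self.i_lsu] = su * (u_raw @ r) - su**2 / pr.sigma_u_scale**2 + 1.0
        if self.sl_v is not None:
            logp += float(-0.5 * (v_raw @ v_raw))
            grad[self.sl_v] = sv * r - v_raw
            logp += float(-0.5 * sv**2 / pr.sigma_v_scale**2 + np.log(sv))
            grad[self.i_lsv] = sv * (v_raw @ r) - sv**2 / pr.sigma_v_scale**2 + 1.0
        return logp, grad


def fit_bym(
    data: pd.DataFrame,
    spec: BymSpec,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    observed_col: str = "observed_men",
    expected_col: str = "expected_men",
    exposure_col: str = "expos",
) -> FitResult:
    """Fit the (optionally adjusted) BYM ecological regression by HMC.

    Returns posterior summaries, the relative-risk table (exp of the
    coefficient summaries, reference quartile RR fixed at 1), per-area
    smoothed RRs, and convergence diagnostics (a fit with any reported
    R-hat > 1.05 is flagged, never silently returned as converged).
    """
    mcmc = mcmc or McmcConfig()
    O = data[observed_col].to_numpy(float)
    E = data[expected_col].to_numpy(float)
    if not (E > 0).any() or E.sum() <= 0:
        raise ValueError("sum of expected counts must be > 0")
    X, names, meta = _design_matrix(data, spec, exposure_col)
    # centre non-intercept columns: decorrelates the intercept from the
    # slopes for the sampler; the intercept draws are shifted back after
    col_means = X[:, 1:].mean(axis=0)
    Xc = X.copy()
    Xc[:, 1:] -= col_means
    post = _BymPosterior(O, E, Xc, spec, len(data))
    res = sample_hmc(post, post.initial(), mcmc, seed)
    fit = _build_fit_result(post, res, names, meta, spec, mcmc)
    _uncentre(fit, res, post, names, col_means)
    return fit


def _uncentre(fit: FitResult, res: McmcResult, post, names, col_means) -> None:
    """Shift the intercept posterior back to the uncentred parameterisation."""
    flat = res.flat
    alpha = flat[:, 0] - flat[:, 1 : post.p] @ col_means
    fit.draws["alpha"] = alpha
    s = summarize(alpha)
    for k, v in s.items():
        fit.summary.loc["alpha", k] = v


def _build_fit_result(post, res: McmcResult, names, meta, spec, mcmc) -> FitResult:
    flat = res.flat
    p = post.p
    report_idx = list(range(p))
    report_names = list(names)
    if post.i_lsu is not None:
        report_idx.append(post.i_lsu)
        report_names.append("log_sigma_u")
    if post.i_lsv is not None:
        report_idx.append(post.i_lsv)
        report_names.append("log_sigma_v")
    diag = diagnostics(res.draws[:, :, report_idx], report_names)
    converged = bool(np.all(diag["rhat"] < 1.05))
    rows = {}
    draws = {}
    for k, name in zip(report_idx, report_names):
        s = flat[:, k]
        if name.startswith("log_sigma"):
            name = name.replace("log_", "")
            s = np.exp(s)
        rows[name] = summarize(s)
        draws[name] = s
    summary = pd.DataFrame(rows).T[["mean", "median", "q2.5", "q97.5"]]
    rr_rows = {}
    for name in report_names[:p]:
        if name == "alpha":
            continue
        s = np.exp(flat[:, names.index(name)])
        rr_rows[name] = {**{k: v for k, v in summarize(s).items()}}
        rr_rows[name]["rr"] = rr_rows[name].pop("mean")
    rr_table = pd.DataFrame(rr_rows).T
    if len(rr_table):
        rr_table = rr_table[["rr", "median", "q2.5", "q97.5"]]
        rr_table["significant"] = [
            significance_flag(lo, hi) for lo, hi in zip(rr_table["q2.5"], rr_table["q97.5"])
        ]
    # per-area smoothed relative risks: mean over draws of exp(linpred)
    lam = np.zeros(post.n)
    take = flat[:: max(1, len(flat) // 500)]
    for th in take:
        lam += np.exp(np.minimum(post.linpred(th), 50.0))
    lam /= len(take)
    return FitResult(
        summary=summary,
        rr_table=rr_table,
        area_rr=lam,
        draws=draws,
        diagnostics=diag,
        converged=converged,
        meta={**meta, "accept_rate": res.accept_rate, "step_size": res.step_size,
              "coding": spec.exposure_coding},
    )


def trend_test(
    data: pd.DataFrame, spec: BymSpec, mcmc: McmcConfig | None = None, seed: int = 0, **kw
) -> FitResult:
    """Dose-response (trend) test: the quartile ordinal as a continuous
    covariate; the reported RR is per one-quartile increment."""
    from dataclasses import replace

    return fit_bym(data, replace(spec, exposure_coding="quartile_ordinal"), mcmc, seed, **kw)


def smoothed_risk_map(
    fit: FitResult, areas: pd.DataFrame, n_classes: int = 4
) -> pd.DataFrame:
    """Join per-area posterior-mean RRs to the area table with quantile
    class labels (quartiles by default, quintiles via ``n_classes=5``)."""
    out = areas[["area_id", "x_km", "y_km"]].copy()
    out["rr_posterior_mean"] = fit.area_rr
    out["rr_class"] = pd.qcut(fit.area_rr, n_classes, labels=[f"c{k+1}" for k in range(n_classes)]).astype(str)
    return out


class BymPoissonRegression:
    """Scikit-learn-style estimator wrapper around :func:`fit_bym`.

    Parameters mirror :class:`BymSpec` plus the sampler settings; after
    ``fit`` the posterior is available as ``result_`` with the usual
    trailing-underscore convention, and ``summary_``/``rr_table_`` aliases.
    """

    def __init__(
        self,
        adjacency=None,
        exposure_coding="quartile_factor",
        covariates=(),
        priors=None,
        include_u=True,
        include_v=True,
        n_warmup=400,
        n_draws=400,
        n_chains=2,
        seed=0,
    ):
        self.adjacency = adjacency
        self.exposure_coding = exposure_coding
        self.covariates = covariates
        self.priors = priors
        self.include_u = include_u
        self.include_v = include_v
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.n_chains = n_chains
        self.seed = seed

    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "adjacency exposure_coding covariates priors include_u include_v "
                "n_warmup n_draws n_chains seed".split()
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame, observed_col="observed_men", expected_col="expected_men",
            exposure_col="expos"):
        spec = BymSpec(
            adjacency=list(self.adjacency),
            exposure_coding=self.exposure_coding,
            covariates=list(self.covariates),
            priors=self.priors or PriorConfig(),
            include_u=self.include_u,
            include_v=self.include_v,
        )
        mcmc = McmcConfig(n_warmup=self.n_warmup, n_draws=self.n_draws, n_chains=self.n_chains)
        self.result_ = fit_bym(
            data, spec, mcmc, self.seed,
            observed_col=observed_col, expected_col=expected_col, exposure_col=exposure_col,
        )
        self.summary_ = self.result_.summary
        self.rr_table_ = self.result_.rr_table
        return self

    def predict(self, areas: pd.DataFrame = None) -> np.ndarray:
        """Posterior-mean smoothed relative risk per area of the fit."""
        return self.result_.area_rr
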