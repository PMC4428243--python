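"""Negative-binomial disease-mapping models with spatial random effects.

The county-level association model is

    Y_i ~ NB(mu_i, r),   Var(Y_i) = mu_i + mu_i^2 / r
    log mu_i = log E_i + alpha + X_i beta + e_i + phi_i

with E_i the expected deaths from indirect standardization (log E_i enters
as an offset), e_i ~ N(0, sigma_e^2) unstructured heterogeneity, and phi an
intrinsic CAR (ICAR) spatial effect: conditional on its neighbors, phi_i is
normal with mean the neighbor average and variance sigma_phi^2 / m_i.  The
ICAR prior is improper; identifiability is restored by a sum-to-zero
constraint (per connected component), with the intercept absorbing the
level.

Two fitting routes are exposed through the :class:`NegativeBinomialCAR`
model object:

* ``fit_glm()`` — maximum-likelihood NB regression without random effects
  (the non-spatial baseline), backed by statsmodels;
* ``fit()`` — the full Bayesian model by Metropolis-within-Gibbs MCMC with
  component-wise adaptive random-walk proposals (adaptation frozen at the
  end of burn-in), returning an :class:`NBCARResults` with posterior
  summaries, risk ratios and convergence diagnostics.

Priors default to the weakly-informative disease-mapping standard:
alpha, beta ~ N(0, 10^2); r ~ Gamma(0.1, 0.1); sigma_e, sigma_phi ~
half-Normal(0, 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .regions import CountyMap

__all__ = [
    "Priors",
    "ModelData",
    "NegativeBinomialCAR",
    "NBGLMResults",
    "NBCARResults",
    "nb_glm_fit",
    "nbcar_mcmc",
    "risk_ratios",
    "convergence_diagnostics",
    "ess_rhat",
]


@dataclass(frozen=True)
class Priors:
    alpha_sd: float = 10.0
    beta_sd: float = 10.0
    r_shape: float = 0.1
    r_rate: float = 0.1
    sigma_e_scale: float = 5.0
    sigma_phi_scale: float = 5.0


@dataclass
class ModelData:
    """Aligned model inputs for a set of (non-suppressed) counties."""

    y: np.ndarray                 # observed deaths
    X: np.ndarray                 # covariates (no intercept column)
    offset: np.ndarray            # log expected deaths
    neighbors: list[list[int]]    # adjacency on the retained counties
    ids: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            self.X = self.X.T
        self.offset = np.asarray(self.offset, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n or self.offset.size != n:
            raise ValueError("y, X and offset must be aligned")
        if len(self.neighbors) != n:
            raise ValueError("adjacency must cover every county")
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite (expected deaths > 0)")
        if not self.ids:
            self.ids = [str(i) for i in range(n)]
        if not self.covariate_names:
            self.covariate_names = [f"x{k}" for k in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.y.size


def nb_loglik(y: np.ndarray, mu: np.ndarray, r: float) -> np.ndarray:
    """Pointwise NB log-likelihood with mean mu and dispersion r."""
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * (np.log(r) - np.log(r + mu))
            + y * (np.log(mu) - np.log(r + mu)))


# --------------------------------------------------------------------- GLM


@dataclass
class NBGLMResults:
    """Maximum-likelihood NB regression results (no random effects)."""

    alpha: float
    beta: np.ndarray
    r: float
    bse: np.ndarray               # standard errors for (alpha, beta..., ln r)
    converged: bool
    loglike: float
    covariate_names: list[str]

    def summary(self) -> pd.DataFrame:
        names = ["alpha"] + list(self.covariate_names) + ["r"]
        est = np.concatenate([[self.alpha], self.beta, [self.r]])
        return pd.DataFrame({"estimate": est, "se": self.bse}, index=names)


def nb_glm_fit(data: ModelData) -> NBGLMResults:
    """Fit the NB GLM baseline by maximum likelihood (statsmodels NB2).

    statsmodels parameterizes overdispersion as Var = mu + a*mu^2, so its
    ``alpha`` is 1/r.
    """
    import statsmodels.api as sm

    n, p = data.X.shape
    if n <= p + 1:
        raise ValueError("need more counties than parameters")
    exog = np.column_stack([np.ones(n), data.X])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    model = sm.NegativeBinomial(data.y, exog, offset=data.offset,
                                loglike_method="nb2")
    try:
        res = model.fit(disp=0, maxiter=500, method="bfgs")
    except Exception:
        res = model.fit(disp=0, maxiter=1000, method="nm")
    if not res.mle_retvals.get("converged", False):
        res = model.fit(disp=0, maxiter=2000, method="nm",
                        start_params=res.params)
    params = np.asarray(res.params)
    a_disp = max(params[-1], 1e-8)
    return NBGLMResults(
        alpha=float(params[0]), beta=params[1:-1].copy(), r=float(1.0 / a_disp),
        bse=np.asarray(res.bse), converged=bool(res.mle_retvals.get("converged", True)),
        loglike=float(res.llf), covariate_names=list(data.covariate_names))


# -------------------------------------------------------------------- MCMC


def _graph_coloring(neighbors: list[list[int]]) -> list[np.ndarray]:
    """Partition nodes into independent sets (no two adjacent share a color)
    so phi can be updated in vectorized blocks."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(neighbors)))
    for i, nbrs in enumerate(neighbors):
        g.add_edges_from((i, j) for j in nbrs if j > i)
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values(), default=0) + 1
    return [np.array(sorted(v for v, c in coloring.items() if c == col), dtype=int)
            for col in range(n_colors)]


def _components(neighbors: list[list[int]]) -> list[np.ndarray]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(neighbors)))
    for i, nbrs in enumerate(neighbors):
        g.add_edges_from((i, j) for j in nbrs if j > i)
    return [np.array(sorted(c)) for c in nx.connected_components(g)]


class NegativeBinomialCAR:
    """Bayesian NB regression with BYM-type convolution random effects.

    Parameters
    ----------
    y, X, offset : array-like
        Observed counts, covariate matrix (no intercept) and log expected
        counts, aligned by county.
    neighbors : list of neighbor-index lists (Queen adjacency) or CountyMap
    priors : Priors, optional
    """

    def __init__(self, y, X, offset, neighbors, ids=None,
                 covariate_names=None, priors: Priors | None = None):
        if isinstance(neighbors, CountyMap):
            neighbors = neighbors.neighbors
        self.data = ModelData(y=y, X=X, offset=offset,
                              neighbors=[list(nb) for nb in neighbors],
                              ids=list(ids) if ids is not None else [],
                              covariate_names=list(covariate_names)
                              if covariate_names is not None else [])
        self.priors = priors or Priors()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, counties: CountyMap,
                       covariates: list[str],
                       observed: str = "observed", expected: str = "expected",
                       priors: Priors | None = None) -> "NegativeBinomialCAR":
        """Build from a county-level frame, dropping suppressed counties.

        ``df`` must carry ``county_id``, the observed/expected columns and
        the covariates; a boolean ``suppressed`` column, when present,
        filters rows out.  Adjacency is re-induced on the retained
        counties.
        """
        d = df.copy()
        if "suppressed" in d.columns:
            d = d[~d["suppressed"].astype(bool)]
        keep_ids = d["county_id"].astype(str).tolist()
        idx = [counties.index_of(cid) for cid in keep_ids]
        pos = {old: new for new, old in enumerate(idx)}
        sub_neighbors = [[pos[j] for j in counties.neighbors[old] if j in pos]
                         for old in idx]
        e = d[expected].to_numpy(dtype=float)
        if np.any(e <= 0):
            raise ValueError("expected deaths must be positive")
        return cls(y=d[observed].to_numpy(dtype=float),
                   X=d[covariates].to_numpy(dtype=float),
                   offset=np.log(e), neighbors=sub_neighbors, ids=keep_ids,
                   covariate_names=covariates, priors=priors)

    # -------------------------------------------------------------- fits

    def fit_glm(self) -> NBGLMResults:
        return nb_glm_fit(self.data)

    def fit(self, n_burn: int = 5000, n_iter: int = 10000,
            seed: int | None = None,
            rng: np.random.Generator | None = None,
            fix_sigmas: tuple[float, float] | None = None,
            start: dict | None = None) -> "NBCARResults":
        """Run the Metropolis-within-Gibbs sampler.

        ``fix_sigmas=(sigma_e, sigma_phi)`` holds the random-effect scales
        fixed (degenerate priors); near zero this collapses the model onto
        the NB GLM.  Returns retained draws after ``n_burn`` iterations.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        d = self.data
        pr = self.priors
        n, p = d.X.shape
        y, X, off = d.y, d.X, d.offset

        cards = np.array([len(nb) for nb in d.neighbors], dtype=float)
        colors = _graph_coloring(d.neighbors)
        comps = _components(d.neighbors)
        n_comp = len(comps)
        # sparse-ish neighbor sum operator
        import scipy.sparse as sp
        rows = np.concatenate([np.full(len(nb), i, dtype=int)
                               for i, nb in enumerate(d.neighbors)]) \
            if any(d.neighbors) else np.array([], dtype=int)
        cols = np.concatenate([np.asarray(nb, dtype=int)
                               for nb in d.neighbors if len(nb)]) \
            if any(d.neighbors) else np.array([], dtype=int)
        A = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))

        glm_start = start or {}
        alpha = float(glm_start.get("alpha", np.log(max(y.sum(), 1.0))
                                    - np.log(np.exp(off).sum())))
        beta = np.asarray(glm_start.get("beta", np.zeros(p)), dtype=float).copy()
        r = float(glm_start.get("r", 10.0))
        e = np.zeros(n)
        phi = np.zeros(n)
        if fix_sigmas is not None:
            sig_e, sig_phi = (max(float(fix_sigmas[0]), 1e-8),
                              max(float(fix_sigmas[1]), 1e-8))
        else:
            sig_e, sig_phi = 0.1, 0.1

        lin = off + alpha + X @ beta
        eta = lin + e + phi

        # NB log-likelihood kernels: for moves in eta at fixed r the gammaln
        # terms cancel, so only the dispersion update pays for them.
        def ll_eta(eta_, r_):
            return y * eta_ - (r_ + y) * np.log(r_ + np.exp(eta_))

        def ll_r(r_, mu_):
            return float(np.sum(gammaln(y + r_)) - n * gammaln(r_)
                         + n * r_ * np.log(r_)
                         - np.sum((r_ + y) * np.log(r_ + mu_)))

        # adaptive scales
        s_alpha, s_beta, s_logr = 0.1, np.full(p, 0.02), 0.3
        s_e = np.full(n, 0.3)
        s_phi = np.full(n, 0.3)
        s_lse, s_lsp = 0.3, 0.3
        adapt_rate = 0.05
        target = 0.35

        keep = {
            "alpha": np.empty(n_iter), "beta": np.empty((n_iter, p)),
            "r": np.empty(n_iter), "sigma_e": np.empty(n_iter),
            "sigma_phi": np.empty(n_iter),
            "e": np.empty((n_iter, n)), "phi": np.empty((n_iter, n)),
        }
        accept = {"alpha": 0, "beta": np.zeros(p), "r": 0,
                  "e": 0.0, "phi": 0.0, "sigma_e": 0, "sigma_phi": 0}
        free_sigmas = fix_sigmas is None

        total = n_burn + n_iter
        for it in range(total):
            adapting = it < n_burn

            # ---- alpha (random walk; prior N(0, alpha_sd^2))
            prop = alpha + s_alpha * rng.standard_normal()
            eta_prop = eta + (prop - alpha)
            logacc = (float((ll_eta(eta_prop, r) - ll_eta(eta, r)).sum())
                      + (alpha ** 2 - prop ** 2) / (2 * pr.alpha_sd ** 2))
            if np.log(rng.random()) < logacc:
                alpha, eta, lin = prop, eta_prop, lin + (prop - alpha)
                accept["alpha"] += 1
                if adapting:
                    s_alpha *= np.exp(adapt_rate * (1 - target))
            elif adapting:
                s_alpha *= np.exp(-adapt_rate * target)

            # ---- beta, one coordinate at a time
            for k in range(p):
                prop_k = beta[k] + s_beta[k] * rng.standard_normal()
                delta = (prop_k - beta[k]) * X[:, k]
                eta_prop = eta + delta
                logacc = (float((ll_eta(eta_prop, r) - ll_eta(eta, r)).sum())
                          + (beta[k] ** 2 - prop_k ** 2) / (2 * pr.beta_sd ** 2))
                if np.log(rng.random()) < logacc:
                    beta[k] = prop_k
                    eta = eta_prop
                    lin = lin + delta
                    accept["beta"][k] += 1
                    if adapting:
                        s_beta[k] *= np.exp(adapt_rate * (1 - target))
                elif adapting:
                    s_beta[k] *= np.exp(-adapt_rate * target)

            # ---- r on the log scale; prior Gamma(shape, rate) + Jacobian
            lprop = np.log(r) + s_logr * rng.standard_normal()
            r_prop = float(np.exp(lprop))
            mu_cur = np.exp(eta)
            logacc = (ll_r(r_prop, mu_cur) - ll_r(r, mu_cur)
                      + pr.r_shape * (lprop - np.log(r))
                      - pr.r_rate * (r_prop - r))
            if np.log(rng.random()) < logacc:
                r = r_prop
                accept["r"] += 1
                if adapting:
                    s_logr *= np.exp(adapt_rate * (1 - target))
            elif adapting:
                s_logr *= np.exp(-adapt_rate * target)

            # ---- e: element-wise parallel random walk (likelihood factorizes)
            prop_e = e + s_e * rng.standard_normal(n)
            eta_prop = lin + prop_e + phi
            logacc_i = (ll_eta(eta_prop, r) - ll_eta(eta, r)
                        + (e ** 2 - prop_e ** 2) / (2 * sig_e ** 2))
            acc = np.log(rng.random(n)) < logacc_i
            e = np.where(acc, prop_e, e)
            eta = lin + e + phi
            accept["e"] += acc.mean()
            if adapting:
                s_e *= np.exp(adapt_rate * np.where(acc, 1 - target, -target))

            # ---- phi: block updates by graph color (neighbors held fixed)
            acc_frac = 0.0
            for block in colors:
                if block.size == 0:
                    continue
                nb_sum = A @ phi
                prop_b = phi[block] + s_phi[block] * rng.standard_normal(block.size)
                y_b = y[block]
                eta_b = eta[block]
                eta_b_prop = lin[block] + e[block] + prop_b
                ll_cur_b = y_b * eta_b - (r + y_b) * np.log(r + np.exp(eta_b))
                ll_prop_b = y_b * eta_b_prop - (r + y_b) * np.log(r + np.exp(eta_b_prop))
                m_b = cards[block]
                # ICAR joint-density change when only this block moves
                quad_cur = m_b * phi[block] ** 2 - 2 * phi[block] * nb_sum[block]
                quad_prop = m_b * prop_b ** 2 - 2 * prop_b * nb_sum[block]
                logacc_b = (ll_prop_b - ll_cur_b
                            + (quad_cur - quad_prop) / (2 * sig_phi ** 2))
                acc_b = np.log(rng.random(block.size)) < logacc_b
                phi[block] = np.where(acc_b, prop_b, phi[block])
                eta[block] = lin[block] + e[block] + phi[block]
                acc_frac += acc_b.sum()
                if adapting:
                    s_phi[block] *= np.exp(
                        adapt_rate * np.where(acc_b, 1 - target, -target))
            accept["phi"] += acc_frac / n

            # ---- re-center phi (ICAR identifiability); shift into alpha
            if n_comp == 1:
                m = phi.mean()
                phi -= m
                alpha += m
                lin += m
                # eta unchanged
            else:
                for comp in comps:
                    phi[comp] -= phi[comp].mean()
                eta = lin + e + phi

            if free_sigmas:
                # ---- sigma_e: log random walk, half-normal prior
                lp = np.log(sig_e) + s_lse * rng.standard_normal()
                sp_ = float(np.exp(lp))
                logacc = (-n * (lp - np.log(sig_e))
                          - (e ** 2).sum() / 2 * (1 / sp_ ** 2 - 1 / sig_e ** 2)
                          - (sp_ ** 2 - sig_e ** 2) / (2 * pr.sigma_e_scale ** 2)
                          + (lp - np.log(sig_e)))  # Jacobian
                if np.log(rng.random()) < logacc:
                    sig_e = sp_
                    accept["sigma_e"] += 1
                    if adapting:
                        s_lse *= np.exp(adapt_rate * (1 - target))
                elif adapting:
                    s_lse *= np.exp(-adapt_rate * target)

                # ---- sigma_phi: log random walk against the ICAR density
                quad = float(phi @ (cards * phi) - phi @ (A @ phi))  # phi' Q phi
                lp = np.log(sig_phi) + s_lsp * rng.standard_normal()
                sp_ = float(np.exp(lp))
                rank = n - n_comp
                logacc = (-rank * (lp - np.log(sig_phi))
                          - quad / 2 * (1 / sp_ ** 2 - 1 / sig_phi ** 2)
                          - (sp_ ** 2 - sig_phi ** 2) / (2 * pr.sigma_phi_scale ** 2)
                          + (lp - np.log(sig_phi)))
                if np.log(rng.random()) < logacc:
                    sig_phi = sp_
                    accept["sigma_phi"] += 1
                    if adapting:
                        s_lsp *= np.exp(adapt_rate * (1 - target))
                elif adapting:
                    s_lsp *= np.exp(-adapt_rate * target)

            if it >= n_burn:
                j = it - n_burn
                keep["alpha"][j] = alpha
                keep["beta"][j] = beta
                keep["r"][j] = r
                keep["sigma_e"][j] = sig_e
                keep["sigma_phi"][j] = sig_phi
                keep["e"][j] = e
                keep["phi"][j] = phi

        acc_rates = {
            "alpha": accept["alpha"] / total,
            "beta": accept["beta"] / total,
            "r": accept["r"] / total,
            "e": accept["e"] / total,
            "phi": accept["phi"] / total,
            "sigma_e": accept["sigma_e"] / total if free_sigmas else np.nan,
            "sigma_phi": accept["sigma_phi"] / total if free_sigmas else np.nan,
        }
        return NBCARResults(
            model=self, alpha=keep["alpha"], beta=keep["beta"], r=keep["r"],
            sigma_e=keep["sigma_e"], sigma_phi=keep["sigma_phi"],
            e=keep["e"], phi=keep["phi"], n_burn=n_burn, n_iter=n_iter,
            seed=seed, acceptance=acc_rates)


# ------------------------------------------------------------------ results


def ess_rhat(draws: np.ndarray) -> tuple[float, float]:
    """Effective sample size and split-chain R-hat for one scalar chain."""
    import arviz as az

    x = np.asarray(draws, dtype=float)
    half = x.size // 2
    two = np.vstack([x[:half], x[half:2 * half]])
    return float(az.ess(two)), float(az.rhat(two))


@dataclass
class NBCARResults:
    """Posterior draws and summaries from the NB-CAR sampler."""

    model: NegativeBinomialCAR
    alpha: np.ndarray
    beta: np.ndarray              # (n_iter, p)
    r: np.ndarray
    sigma_e: np.ndarray
    sigma_phi: np.ndarray
    e: np.ndarray                 # (n_iter, n)
    phi: np.ndarray               # (n_iter, n)
    n_burn: int
    n_iter: int
    seed: int | None
    acceptance: dict

    @property
    def covariate_names(self) -> list[str]:
        return self.model.data.covariate_names

    def _scalar_draws(self) -> dict[str, np.ndarray]:
        out = {"alpha": self.alpha}
        for k, name in enumerate(self.covariate_names):
            out[f"beta[{name}]"] = self.beta[:, k]
        out.update({"r": self.r, "sigma_e": self.sigma_e,
                    "sigma_phi": self.sigma_phi})
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% equal-tailed interval, ESS and R-hat."""
        rows = {}
        for name, draws in self._scalar_draws().items():
            ess, rhat = ess_rhat(draws)
            rows[name] = {
                "mean": draws.mean(), "sd": draws.std(ddof=1),
                "q2.5": np.percentile(draws, 2.5),
                "q97.5": np.percentile(draws, 97.5),
                "ess": ess, "rhat": rhat,
            }
        return pd.DataFrame(rows).T

    def risk_ratios(self, unit_deltas: dict[str, float] | None = None
                    ) -> pd.DataFrame:
        """Posterior risk ratios exp(beta_k * delta_k) per covariate."""
        return risk_ratios(self, unit_deltas)

    def diagnostics(self) -> pd.DataFrame:
        return convergence_diagnostics(self)

    def to_frame(self) -> pd.DataFrame:
        """Scalar draws as a tidy DataFrame (one column per parameter)."""
        return pd.DataFrame(self._scalar_draws())


def nbcar_mcmc(data: ModelData, priors: Priors | None = None,
               n_burn: int = 5000, n_iter: int = 10000,
               seed: int | None = None, **kwargs) -> NBCARResults:
    """Functional wrapper around :meth:`NegativeBinomialCAR.fit`."""
    model = NegativeBinomialCAR(y=data.y, X=data.X, offset=data.offset,
                                neighbors=data.neighbors, ids=data.ids,
                                covariate_names=data.covariate_names,
                                priors=priors)
    return model.fit(n_burn=n_burn, n_iter=n_iter, seed=seed, **kwargs)


def risk_ratios(post: NBCARResults,
                unit_deltas: dict[str, float] | None = None) -> pd.DataFrame:
    """Posterior-mean risk ratio per covariate with 95% credible interval.

    ``unit_deltas`` maps covariate name to the change Delta on its own unit
    (default 1).  RR draws are exp(beta_k * Delta); the interval is the
    equal-tailed 2.5/97.5 percentile range of those draws.
    """
    unit_deltas = unit_deltas or {}
    rows = {}
    for k, name in enumerate(post.covariate_names):
        delta = float(unit_deltas.get(name, 1.0))
        rr = np.exp(post.beta[:, k] * delta)
        rows[name] = {
            "delta": delta,
            "rr": rr.mean(),
            "rr_2.5": np.percentile(rr, 2.5),
            "rr_97.5": np.percentile(rr, 97.5),
        }
    return pd.DataFrame(rows).T


def convergence_diagnostics(post: NBCARResults) -> pd.DataFrame:
    """ESS and split-chain R-hat per scalar parameter; warns above 1.05."""
    import warnings

    draws = post._scalar_draws()
    any_draws = next(iter(draws.values()))
    if any_draws.size < 200:
        raise ValueError("need >= 200 retained draws for diagnostics")
    rows = {}
    for name, x in draws.items():
        ess, rhat = ess_rhat(x)
        rows[name] = {"ess": ess, "rhat": rhat}
        if np.isfinite(rhat) and rhat > 1.05:
            warnings.warn(f"R-hat for {name} is {rhat:.3f} (> 1.05): "
                          "chain may not have converged", stacklevel=2)
    return pd.DataFrame(rows).T
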