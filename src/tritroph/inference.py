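"""Statistical layer: Bayesian two-group comparison, correlations,
residual regressions, recursive path analysis and the sample-size sweep.

The two model-fitting facilities follow the Model -> fit() -> Results
pattern: :class:`BestModel` is the Bayesian "estimation supersedes the
t-test" two-group comparison (t-distributed likelihood, posterior via
affine-invariant ensemble MCMC), and :class:`PathModel` is a recursive
(directed-acyclic, no latent variable) path model whose standardized
coefficients are per-equation standardized least squares, with a maximum-
likelihood discrepancy on the correlation matrix providing chi-square, df,
p and AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import ConfigurationError, TritrophError

__all__ = [
    "BestModel",
    "BestResults",
    "best_compare",
    "PathModel",
    "PathResults",
    "species_interaction_correlation",
    "residual_regression",
    "ResidualRegressionResult",
    "coefficient_sweep",
    "DEFAULT_SWEEP_SIZES",
]


# --------------------------------------------------------------------------
# Bayesian two-group comparison (BEST)
# --------------------------------------------------------------------------

def _t_logpdf(y: np.ndarray, nu: float, mu: float, sigma: float) -> float:
    z = (y - mu) / sigma
    n = y.size
    return float(
        n * (gammaln((nu + 1) / 2) - gammaln(nu / 2)
             - 0.5 * np.log(nu * np.pi) - np.log(sigma))
        - (nu + 1) / 2 * np.sum(np.log1p(z * z / nu))
    )


class BestModel:
    """Bayesian two-group comparison with a t likelihood.

    Each group g has mean mu_g, scale sigma_g and a shared normality
    parameter nu:  y ~ t(nu, mu_g, sigma_g).  Default priors: broad normal
    on the means (variance 100x the pooled variance around the pooled
    mean), uniform on (pooled sd/1000, pooled sd*1000) for the scales, and
    1 + Exponential(mean 29) for nu.  Prior location/scale for the means
    can be overridden (e.g. to centre on an observed difference).
    """

    def __init__(
        self,
        group_a,
        group_b,
        names: tuple[str, str] = ("a", "b"),
        mu_prior_mean: float | None = None,
        mu_prior_sd: float | None = None,
    ) -> None:
        self.a = np.asarray(group_a, dtype=float)
        self.b = np.asarray(group_b, dtype=float)
        if self.a.size < 2 or self.b.size < 2:
            raise TritrophError("each group needs n >= 2")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise TritrophError("non-finite values in input groups")
        self.names = names
        pooled = np.concatenate([self.a, self.b])
        self._pooled_mean = float(pooled.mean())
        self._pooled_sd = float(pooled.std(ddof=1))
        if self._pooled_sd == 0:
            self._pooled_sd = 1e-6
        self.mu_prior_mean = self._pooled_mean if mu_prior_mean is None else mu_prior_mean
        self.mu_prior_sd = (10.0 * self._pooled_sd if mu_prior_sd is None
                            else mu_prior_sd)
        self._sigma_lo = self._pooled_sd / 1000.0
        self._sigma_hi = self._pooled_sd * 1000.0

    # parameter vector: (mu_a, mu_b, log sigma_a, log sigma_b, log(nu - 1))
    def log_posterior(self, theta: np.ndarray) -> float:
        mu_a, mu_b, ls_a, ls_b, lnu = theta
        sigma_a, sigma_b = np.exp(ls_a), np.exp(ls_b)
        if not (self._sigma_lo < sigma_a < self._sigma_hi):
            return -np.inf
        if not (self._sigma_lo < sigma_b < self._sigma_hi):
            return -np.inf
        nu = 1.0 + np.exp(lnu)
        if nu > 1e6:
            return -np.inf
        lp = 0.0
        for mu in (mu_a, mu_b):
            lp += -0.5 * ((mu - self.mu_prior_mean) / self.mu_prior_sd) ** 2
        # uniform prior on sigma sampled on log scale: jacobian sigma
        lp += ls_a + ls_b
        # nu - 1 ~ Exponential(mean 29), sampled as log(nu - 1)
        lp += -(nu - 1.0) / 29.0 + lnu
        lp += _t_logpdf(self.a, nu, mu_a, sigma_a)
        lp += _t_logpdf(self.b, nu, mu_b, sigma_b)
        return lp

    def fit(
        self,
        draws: int = 1000,
        tune: int = 1000,
        walkers: int = 16,
        rng: np.random.Generator | int | None = None,
    ) -> "BestResults":
        """Sample the posterior with emcee and summarize it."""
        import emcee

        rng = np.random.default_rng(rng)
        ndim = 5
        start = np.array([
            float(self.a.mean()),
            float(self.b.mean()),
            np.log(max(self.a.std(ddof=1), self._sigma_lo * 2)),
            np.log(max(self.b.std(ddof=1), self._sigma_lo * 2)),
            np.log(29.0),
        ])
        p0 = start + 1e-3 * np.abs(start).clip(min=1.0) * rng.standard_normal(
            (walkers, ndim)
        )
        sampler = emcee.EnsembleSampler(walkers, ndim, self.log_posterior)
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2**31 - 1))
        ).get_state()
        sampler.run_mcmc(p0, tune + draws, progress=False)
        chain = sampler.get_chain(discard=tune)  # (draws, walkers, ndim)
        return BestResults(model=self, chain=chain)


@dataclass
class BestResults:
    """Posterior summary of a :class:`BestModel` fit."""

    model: BestModel
    chain: np.ndarray  # (draws, walkers, 5)
    hdi_prob: float = 0.95
    _flat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._flat = self.chain.reshape(-1, self.chain.shape[-1])

    # posterior draws ------------------------------------------------------
    @property
    def mu_a(self) -> np.ndarray:
        return self._flat[:, 0]

    @property
    def mu_b(self) -> np.ndarray:
        return self._flat[:, 1]

    @property
    def sigma_a(self) -> np.ndarray:
        return np.exp(self._flat[:, 2])

    @property
    def sigma_b(self) -> np.ndarray:
        return np.exp(self._flat[:, 3])

    @property
    def nu(self) -> np.ndarray:
        return 1.0 + np.exp(self._flat[:, 4])

    @property
    def mean_diff(self) -> np.ndarray:
        return self.mu_a - self.mu_b

    @property
    def effect_size(self) -> np.ndarray:
        """Standardized mean difference (mu_a - mu_b)/sqrt((s_a^2+s_b^2)/2)."""
        return self.mean_diff / np.sqrt((self.sigma_a**2 + self.sigma_b**2) / 2.0)

    @property
    def n_samples(self) -> int:
        return self._flat.shape[0]

    # summaries ------------------------------------------------------------
    def hdi(self, draws: np.ndarray) -> tuple[float, float]:
        import arviz

        lo, hi = arviz.hdi(np.asarray(draws), hdi_prob=self.hdi_prob)
        return float(lo), float(hi)

    def rhat(self) -> pd.Series:
        import arviz

        names = ["mu_a", "mu_b", "log_sigma_a", "log_sigma_b", "log_nu_m1"]
        # arviz expects (chains, draws); emcee walkers act as chains
        values = {n: arviz.rhat(np.swapaxes(self.chain[:, :, i], 0, 1).copy())
                  for i, n in enumerate(names)}
        return pd.Series(values)

    @property
    def converged(self) -> bool:
        return bool((self.rhat() < 1.1).all())

    def summary(self) -> pd.DataFrame:
        rows = []
        quantities = {
            f"mu_{self.model.names[0]}": self.mu_a,
            f"mu_{self.model.names[1]}": self.mu_b,
            "mean_diff": self.mean_diff,
            f"sigma_{self.model.names[0]}": self.sigma_a,
            f"sigma_{self.model.names[1]}": self.sigma_b,
            "nu": self.nu,
            "effect_size": self.effect_size,
        }
        for name, draws in quantities.items():
            lo, hi = self.hdi(draws)
            rows.append({"quantity": name, "mean": float(np.mean(draws)),
                         "hdi_low": lo, "hdi_high": hi})
        return pd.DataFrame(rows).set_index("quantity")


def best_compare(
    group_a,
    group_b,
    draws: int = 1000,
    tune: int = 1000,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> BestResults:
    """Convenience wrapper: build and fit a :class:`BestModel`."""
    return BestModel(group_a, group_b, **kwargs).fit(draws=draws, tune=tune, rng=rng)


# --------------------------------------------------------------------------
# correlations and residual regressions
# --------------------------------------------------------------------------

def species_interaction_correlation(
    metrics: pd.DataFrame,
    networks=("PH", "HE", "PHE"),
    species_col: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation and OLS of interaction on species diversity.

    One row per network view: r, p, slope, intercept, r_squared, n.  By
    default each view is paired with its own species diversity column
    (``spdiv_<network>``); pass ``species_col`` to use a single column for
    all views.  Webs with missing values for a network are dropped for
    that network.
    """
    rows = []
    for net in networks:
        sp_col = species_col or f"spdiv_{net}"
        sub = metrics[[sp_col, f"intdiv_{net}"]].dropna()
        if len(sub) < 3:
            raise TritrophError(f"need >= 3 webs with defined metrics for {net}")
        x = sub[sp_col].to_numpy()
        y = sub[f"intdiv_{net}"].to_numpy()
        if x.std() == 0 or y.std() == 0:
            raise TritrophError(f"zero variance in {net} metrics")
        r, p = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        rows.append({
            "network": net, "r": float(r), "p": float(p),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2), "n": len(sub),
        })
    return pd.DataFrame(rows).set_index("network")


# predictor column used for each network's diet-breadth regression
DIET_PREDICTOR = {
    "PH": "mean_herb_breadth",
    "HE": "mean_enemy_breadth",
    "PHE": "mean_consumer_breadth",
}


@dataclass(frozen=True)
class ResidualRegressionResult:
    network: str
    predictor: str
    beta: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def residual_regression(
    metrics: pd.DataFrame,
    network: str,
    predictor: str,
    species_col: str | None = None,
    residuals_from: str = "interaction_on_species",
) -> ResidualRegressionResult:
    """OLS of diversity-relationship residuals on a community predictor.

    Residuals come from regressing the view's interaction diversity on its
    species diversity (positive residuals = more interaction diversity
    than the species diversity predicts); the orientation is switchable.
    The residuals are then regressed on the predictor column (mean diet
    breadth, network richness, or network abundance).
    """
    import statsmodels.api as sm

    species_col = species_col or f"spdiv_{network}"
    cols = [species_col, f"intdiv_{network}", predictor]
    sub = metrics[cols].dropna()
    if len(sub) < 3:
        raise TritrophError("need >= 3 complete webs")
    if residuals_from == "interaction_on_species":
        y, x = sub[f"intdiv_{network}"], sub[species_col]
    elif residuals_from == "species_on_interaction":
        y, x = sub[species_col], sub[f"intdiv_{network}"]
    else:
        raise ValueError("residuals_from must be 'interaction_on_species' or "
                         "'species_on_interaction'")
    z = sub[predictor].to_numpy()
    if np.std(z) == 0:
        raise TritrophError(f"degenerate predictor {predictor}: zero variance")
    resid = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit().resid
    fit = sm.OLS(resid, sm.add_constant(z)).fit()
    return ResidualRegressionResult(
        network=network, predictor=predictor,
        beta=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), p_value=float(fit.pvalues[1]),
        n=len(sub),
    )


# --------------------------------------------------------------------------
# recursive path model
# --------------------------------------------------------------------------

class PathModel:
    """Recursive path model (DAG, observed variables only).

    ``edges`` is a list of (source, target) pairs.  Variables with no
    incoming edge are exogenous; their variances and covariances are free.
    Endogenous variables get one linear equation on their parents with
    independent residuals.  All variables are standardized before fitting,
    so coefficients are standardized path coefficients.
    """

    def __init__(self, data: pd.DataFrame, edges: list[tuple[str, str]]) -> None:
        import networkx as nx

        self.edges = [tuple(e) for e in edges]
        self.variables = sorted({v for e in self.edges for v in e},
                                key=lambda v: str(v))
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise ConfigurationError(f"variables not in data: {missing}")
        graph = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            raise ConfigurationError("path structure must be acyclic")
        order = list(nx.topological_sort(graph))
        self.variables = order  # topological order fixes equation ordering
        self.exogenous = [v for v in order if graph.in_degree(v) == 0]
        self.endogenous = [v for v in order if graph.in_degree(v) > 0]
        self.parents = {v: sorted(graph.predecessors(v)) for v in self.endogenous}
        self.data = data[self.variables].dropna()
        if len(self.data) <= len(self.variables) + 1:
            raise TritrophError("too few complete observations for the path model")

    def fit(self) -> "PathResults":
        X = self.data.to_numpy(dtype=float)
        n, p = X.shape
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [v for v, s in zip(self.variables, sd) if s == 0]
            raise TritrophError(f"zero-variance variables: {bad}")
        Z = (X - X.mean(axis=0)) / sd
        S = np.corrcoef(Z, rowvar=False)
        idx = {v: i for i, v in enumerate(self.variables)}

        A = np.zeros((p, p))  # A[i, j]: coefficient of j in equation of i
        resid_var = {}
        coef: dict[tuple[str, str], float] = {}
        for v in self.endogenous:
            pars = self.parents[v]
            ii = [idx[u] for u in pars]
            Rxx = S[np.ix_(ii, ii)]
            rxy = S[ii, idx[v]]
            beta = np.linalg.solve(Rxx, rxy)
            if not np.all(np.isfinite(beta)):
                raise TritrophError(f"singular design for equation of {v}")
            for u, b in zip(pars, beta):
                A[idx[v], idx[u]] = b
                coef[(u, v)] = float(b)
            resid_var[v] = float(1.0 - beta @ rxy)

        # RAM-style implied correlation matrix
        Psi = np.zeros((p, p))
        ex = [idx[v] for v in self.exogenous]
        Psi[np.ix_(ex, ex)] = S[np.ix_(ex, ex)]
        for v in self.endogenous:
            Psi[idx[v], idx[v]] = max(resid_var[v], 1e-12)
        Iminus = np.linalg.inv(np.eye(p) - A)
        Sigma = Iminus @ Psi @ Iminus.T

        sign_S, logdet_S = np.linalg.slogdet(S)
        sign_Sig, logdet_Sig = np.linalg.slogdet(Sigma)
        if sign_S <= 0 or sign_Sig <= 0:
            raise TritrophError("non-positive-definite covariance matrix")
        F = logdet_Sig - logdet_S + float(np.trace(S @ np.linalg.inv(Sigma))) - p
        F = max(F, 0.0)
        chi2 = (n - 1) * F

        n_exo = len(self.exogenous)
        free = len(self.edges) + n_exo * (n_exo + 1) // 2 + len(self.endogenous)
        df = p * (p + 1) // 2 - free
        p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
        aic = chi2 + 2 * free

        return PathResults(
            model=self, coefficients=coef, resid_var=resid_var, A=A,
            chi_square=float(chi2), df=int(df), p_value=p_value,
            aic=float(aic), n_obs=int(n),
        )


@dataclass
class PathResults:
    """Standardized coefficients and fit statistics of a path model."""

    model: PathModel
    coefficients: dict[tuple[str, str], float]
    resid_var: dict[str, float]
    A: np.ndarray
    chi_square: float
    df: int
    p_value: float
    aic: float
    n_obs: int

    def coef(self, source: str, target: str) -> float:
        return self.coefficients[(source, target)]

    def total_effects(self) -> pd.DataFrame:
        """Total (direct + indirect) standardized effects, source x target."""
        p = self.A.shape[0]
        total = np.linalg.inv(np.eye(p) - self.A) - np.eye(p)
        names = self.model.variables
        return pd.DataFrame(total.T, index=names, columns=names)

    def indirect_effects(self) -> pd.DataFrame:
        """Indirect effects: products of direct effects along all paths."""
        names = self.model.variables
        direct = pd.DataFrame(self.A.T, index=names, columns=names)
        return self.total_effects() - direct

    def coefficients_frame(self) -> pd.DataFrame:
        rows = [{"source": s, "target": t, "coefficient": c}
                for (s, t), c in self.coefficients.items()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Recursive path model (standardized coefficients)",
            f"  n = {self.n_obs}, chi2 = {self.chi_square:.3f}, df = {self.df}, "
            f"p = {self.p_value:.3f}, AIC = {self.aic:.1f}",
            "  paths:",
        ]
        for (s, t), c in sorted(self.coefficients.items(), key=lambda kv: kv[0][1]):
            lines.append(f"    {s:>24s} -> {t:<24s} {c:+.3f}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# path-coefficient-vs-sample-size sweep
# --------------------------------------------------------------------------

DEFAULT_SWEEP_SIZES = (5, 10, 25, 50, 75, 100, 150, 200, 250, 300, 400, 500)


def coefficient_sweep(
    sequences,
    exogenous: pd.DataFrame,
    edges: list[tuple[str, str]],
    sizes=DEFAULT_SWEEP_SIZES,
    min_webs: int = 30,
) -> pd.DataFrame:
    """Refit the (connectance-free) path model at increasing sample sizes.

    For each sample size n, per-web endogenous metrics are recomputed from
    the first n interaction-bearing sampled rows of each community's
    :class:`~tritroph.sampling.SampleSequence`; communities with fewer than
    n such rows drop out of that fit.  ``exogenous`` carries the whole-web
    exogenous columns (plant abundance, mean diet breadths), indexed like
    ``sequences``.  Sizes retaining fewer than ``min_webs`` webs are
    skipped.  Returns long-format coefficients per size.
    """
    from .metrics import sample_metrics

    if len(sizes) < 2:
        raise ConfigurationError("need at least two sample sizes")
    prefix_rows = [seq.interaction_rows() for seq in sequences]
    records = []
    for n in sorted(sizes):
        rows_per_web = []
        for web_idx, rows in zip(exogenous.index, prefix_rows):
            if len(rows) < n:
                continue
            m = sample_metrics(rows.iloc[:n])
            m.update(exogenous.loc[web_idx].to_dict())
            rows_per_web.append(m)
        data = pd.DataFrame(rows_per_web).dropna()
        if len(data) < min_webs:
            continue
        res = PathModel(data, edges).fit()
        for (s, t), c in res.coefficients.items():
            records.append({
                "sample_size": n, "source": s, "target": t,
                "coefficient": c, "n_webs": res.n_obs,
                "chi_square": res.chi_square, "df": res.df,
                "p_value": res.p_value,
            })
    out = pd.DataFrame(records)
    if out.empty:
        raise TritrophError("no sample size retained enough webs")
    return out
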