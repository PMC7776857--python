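"""Mixed-effects models and piecewise structural equation modeling.

The workhorse is a Gaussian linear mixed model with a random intercept
per group (site, optionally with a second nested intercept, e.g. shrub
within site) and AR(1)-correlated residuals within groups ordered by
year::

    y_ij = x_ij' beta + b_i (+ c_ij) + e_ij,
    b_i ~ N(0, sb^2),  e_i ~ N(0, se^2 * R(rho)),  R_st = rho^|t_s - t_t|

Estimation is exact maximum likelihood: for fixed variance parameters
the fixed effects profile out as a GLS solve, and the remaining
2-3-dimensional problem (log-variances, atanh rho) is minimised
numerically.  Coefficient tests use a containment-style degrees of
freedom approximation ``df = n_obs - n_groups - p`` (p the number of
slope terms).  Marginal R^2 is the fixed-effects variance share and
conditional R^2 adds the random-intercept variance, following the
variance-components (Nakagawa-style) formulation.

A piecewise SEM is a set of such node-wise regressions over a directed
acyclic path diagram.  Overall fit uses Shipley's d-separation test:
every nonadjacent pair (with at least one endpoint endogenous) yields
an independence claim, tested by regressing the topologically later
variable on the earlier one plus the union of both variables' parents;
Fisher's C = -2 sum ln p_i is chi-square with 2k degrees of freedom
under the model.  Model-level AICc follows the piecewise-SEM
convention C + 2K n/(n - K - 1) with K the total number of estimated
parameters.  Candidate mixed models sharing a response are ranked by
ordinary AICc and Akaike weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "MixedModelFit",
    "PathDiagram",
    "PsemResult",
    "ModelRanking",
    "fit_mixed_model",
    "fit_piecewise_sem",
    "rank_models",
    "fishers_c",
    "aicc",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class MixedModelFit:
    response: str
    fixed: list[str]
    grouping: str
    betas: pd.DataFrame  # index term; columns beta, std_beta, se, df, t, p
    sigma_group: float
    sigma_nested: float
    sigma_resid: float
    ar1_rho: float
    loglik: float
    n_obs: int
    n_groups: int
    k_params: int
    r2_marginal: float
    r2_conditional: float
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k_params, self.n_obs)

    def coef(self, term: str) -> pd.Series:
        return self.betas.loc[term]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _group_blocks(
    data: pd.DataFrame, group: str, nested: str | None, time: str | None
) -> list[dict]:
    blocks = []
    for _, g in data.groupby(group, sort=True):
        if time is not None:
            g = g.sort_values(time)
            t = g[time].to_numpy(float)
        else:
            t = np.arange(len(g), dtype=float)
        block = {"idx": g.index.to_numpy(), "t": t}
        if nested is not None:
            codes = pd.factorize(g[nested])[0]
            block["nested"] = codes
        blocks.append(block)
    return blocks


def fit_mixed_model(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str,
    nested: str | None = None,
    ar1: bool = True,
    time: str | None = "year",
    sqrt_response: bool = False,
) -> MixedModelFit:
    """ML fit of a random-intercept mixed model with optional AR(1) residuals.

    ``fixed`` lists slope terms (an intercept is always included).
    ``nested`` adds a second random intercept nested in ``group``.
    Residuals within a group are AR(1) in the ``time`` column (falling
    back to within-group order when the column is absent).  Groups of
    length 1 contribute no autocorrelation information but are retained.
    """
    fixed = list(fixed)
    cols = [response, *fixed, group] + ([nested] if nested else [])
    if time and time in data.columns:
        cols.append(time)
    else:
        time = None
    df = data[list(dict.fromkeys(cols))].dropna().reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError("no complete observations")
    y = df[response].to_numpy(float)
    if sqrt_response:
        if np.any(y < 0):
            raise ValueError("square-root transform requires non-negative response")
        y = np.sqrt(y)
    X = np.column_stack([np.ones(n)] + [df[f].to_numpy(float) for f in fixed])
    p = X.shape[1]
    blocks = _group_blocks(df, group, nested, time)
    n_groups = len(blocks)
    if n_groups < 1 or (n_groups == 1 and n == 1):
        raise ValueError("grouping structure is not identifiable")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is singular")

    var_y = float(np.var(y)) or 1.0

    def build_V(block, sb2, sn2, se2, rho):
        t = block["t"]
        m = t.size
        if ar1 and m > 1:
            lag = np.abs(t[:, None] - t[None, :])
            R = rho**lag
        else:
            R = np.eye(m)
        V = se2 * R + sb2
        if nested is not None:
            same = block["nested"][:, None] == block["nested"][None, :]
            V = V + sn2 * same
        return V

    def unpack(theta):
        i = 0
        sb2 = math.exp(theta[i]); i += 1
        sn2 = math.exp(theta[i]) if nested else 0.0
        if nested:
            i += 1
        se2 = math.exp(theta[i]); i += 1
        rho = math.tanh(theta[i]) if ar1 else 0.0
        return sb2, sn2, se2, rho

    def profile(theta):
        sb2, sn2, se2, rho = unpack(theta)
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        chols = []
        for block in blocks:
            V = build_V(block, sb2, sn2, se2, rho)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return None
            idx = block["idx"]
            Lx = solve_triangular(L, X[idx], lower=True)
            Ly = solve_triangular(L, y[idx], lower=True)
            XtVX += Lx.T @ Lx
            XtVy += Lx.T @ Ly
            logdet += 2.0 * float(np.log(np.diag(L)).sum())
            chols.append((L, idx))
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return None
        quad = 0.0
        for L, idx in chols:
            r = solve_triangular(L, y[idx] - X[idx] @ beta, lower=True)
            quad += float(r @ r)
        ll = -0.5 * (n * _LOG2PI + logdet + quad)
        return beta, XtVX, ll

    def nll(theta):
        res = profile(theta)
        if res is None:
            return 1e12
        return -res[2]

    theta0 = [math.log(0.1 * var_y)]
    if nested:
        theta0.append(math.log(0.1 * var_y))
    theta0.append(math.log(0.8 * var_y))
    if ar1:
        theta0.append(0.0)
    opt = optimize.minimize(nll, np.array(theta0), method="L-BFGS-B")
    res = profile(opt.x)
    if res is None:
        raise RuntimeError("mixed-model fit failed: singular covariance at optimum")
    beta, XtVX, ll = res
    sb2, sn2, se2, rho = unpack(opt.x)

    cov = np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    df_coef = max(n - n_groups - (p - 1), 1)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_coef)
    sd_y = float(np.std(y)) or 1.0
    std = [math.nan] + [float(np.std(X[:, j + 1])) / sd_y for j in range(p - 1)]
    betas = pd.DataFrame(
        {
            "beta": beta,
            "std_beta": beta * np.array(std),
            "se": se,
            "df": float(df_coef),
            "t": tvals,
            "p": pvals,
        },
        index=pd.Index(["(Intercept)"] + fixed, name="term"),
    )

    fixed_part = X[:, 1:] @ beta[1:] if p > 1 else np.zeros(n)
    var_f = float(np.var(fixed_part))
    denom = var_f + sb2 + sn2 + se2
    r2m = var_f / denom if denom > 0 else math.nan
    r2c = (var_f + sb2 + sn2) / denom if denom > 0 else math.nan

    # k = p fixed coefs + sigma_group (+ sigma_nested) + sigma_resid (+ rho)
    k = p + 1 + (1 if nested else 0) + 1 + (1 if ar1 else 0)
    return MixedModelFit(
        response=response,
        fixed=fixed,
        grouping=group + (f"/{nested}" if nested else ""),
        betas=betas,
        sigma_group=math.sqrt(sb2),
        sigma_nested=math.sqrt(sn2) if nested else 0.0,
        sigma_resid=math.sqrt(se2),
        ar1_rho=rho if ar1 else 0.0,
        loglik=ll,
        n_obs=n,
        n_groups=n_groups,
        k_params=k,
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=bool(opt.success),
    )


@dataclass(frozen=True)
class PathDiagram:
    """A directed acyclic path diagram given as (cause, effect) edges."""

    edges: tuple[tuple[str, str], ...]

    @classmethod
    def from_strings(cls, specs: Sequence[str]) -> "PathDiagram":
        edges = []
        for s in specs:
            parts = [p.strip() for p in s.split("->")]
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"edge spec must be 'cause -> effect', got {s!r}")
            edges.append((parts[0], parts[1]))
        return cls(tuple(edges))

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def parents(self, node: str) -> list[str]:
        return [a for a, b in self.edges if b == node]

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.topological_order() if self.parents(v)]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.nodes if not self.parents(v)]

    def topological_order(self) -> list[str]:
        import networkx as nx

        g = nx.DiGraph(list(self.edges))
        g.add_nodes_from(self.nodes)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path diagram contains a cycle")
        order = list(nx.topological_sort(g))
        return order

    def basis_set(self) -> list[tuple[str, str, tuple[str, ...]]]:
        """Shipley's basis set: (earlier, later, conditioning set) claims.

        All nonadjacent ordered pairs with the later variable
        endogenous; conditioned on the union of both variables'
        parents.  Pairs of two exogenous variables are free to covary
        and are not claimed.
        """
        order = self.topological_order()
        pos = {v: i for i, v in enumerate(order)}
        adjacent = {frozenset(e) for e in self.edges}
        claims = []
        for i, a in enumerate(order):
            for b in order[i + 1 :]:
                if frozenset((a, b)) in adjacent:
                    continue
                if not self.parents(a) and not self.parents(b):
                    continue
                x, yv = (a, b) if pos[a] < pos[b] else (b, a)
                cond = tuple(dict.fromkeys(self.parents(x) + self.parents(yv)))
                cond = tuple(c for c in cond if c not in (x, yv))
                claims.append((x, yv, cond))
        return claims


def fishers_c(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C over independence-claim p-values; returns (C, df, p)."""
    ps = np.clip(np.asarray(list(pvalues), float), 1e-300, 1.0)
    k = ps.size
    if k == 0:
        return 0.0, 0, 1.0
    c = float(-2.0 * np.log(ps).sum())
    return c, 2 * k, float(stats.chi2.sf(c, 2 * k))


@dataclass
class PsemResult:
    diagram: PathDiagram
    node_models: dict[str, MixedModelFit]
    dsep: list  # (claim_x, claim_y, conditioning, p)
    fisher_c: float
    dsep_df: int
    dsep_p: float
    aicc: float
    k_params: int
    n_obs: int

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for node, fit in self.node_models.items():
            t = fit.betas.drop(index="(Intercept)").reset_index()
            t.insert(0, "node", node)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def r2(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r2_marginal": {k: m.r2_marginal for k, m in self.node_models.items()},
                "r2_conditional": {k: m.r2_conditional for k, m in self.node_models.items()},
            }
        )

    def path_coefficient(self, cause: str, effect: str) -> float:
        return float(self.node_models[effect].betas.loc[cause, "std_beta"])


def fit_piecewise_sem(
    diagram: PathDiagram,
    data: pd.DataFrame,
    group: str,
    nested: str | None = None,
    ar1: bool = True,
    time: str | None = "year",
) -> PsemResult:
    """Fit one mixed model per endogenous node and test d-separation.

    All paths are retained regardless of significance.  The total
    parameter count K across node models enters the piecewise-SEM AICc,
    ``C + 2K n/(n - K - 1)``.
    """
    missing = [v for v in diagram.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"diagram nodes missing from data: {missing}")
    node_models: dict[str, MixedModelFit] = {}
    for node in diagram.topological_order():
        parents = diagram.parents(node)
        if parents:
            node_models[node] = fit_mixed_model(
                data, node, parents, group, nested=nested, ar1=ar1, time=time
            )

    claim_ps = []
    dsep = []
    for x, yv, cond in diagram.basis_set():
        fit = fit_mixed_model(
            data, yv, list(cond) + [x], group, nested=nested, ar1=ar1, time=time
        )
        pval = float(fit.betas.loc[x, "p"])
        claim_ps.append(pval)
        dsep.append((x, yv, cond, pval))

    c, dof, pval = fishers_c(claim_ps)
    n = min(m.n_obs for m in node_models.values()) if node_models else len(data)
    K = sum(m.k_params for m in node_models.values())
    if n > K + 1:
        aicc_val = c + 2.0 * K * n / (n - K - 1)
    else:
        aicc_val = math.inf
    return PsemResult(
        diagram=diagram,
        node_models=node_models,
        dsep=dsep,
        fisher_c=c,
        dsep_df=dof,
        dsep_p=pval,
        aicc=aicc_val,
        k_params=K,
        n_obs=n,
    )


@dataclass
class ModelRanking:
    table: pd.DataFrame  # index model name; columns k, loglik, aicc, delta_aicc, weight
    fits: dict[str, MixedModelFit]

    @property
    def best(self) -> str:
        return str(self.table.index[0])


def rank_models(
    candidates: Mapping[str, Sequence[str]],
    data: pd.DataFrame,
    response: str,
    group: str,
    nested: str | None = None,
    ar1: bool = True,
    time: str | None = "year",
    sqrt_response: bool = False,
) -> ModelRanking:
    """Fit and AICc-rank candidate fixed-effect sets for one response.

    ``candidates`` maps model name -> list of fixed terms; include a
    null model (empty list).  Akaike weights are normalised
    exp(-delta/2).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models (including a null)")
    fits = {}
    rows = []
    for name, terms in candidates.items():
        fit = fit_mixed_model(
            data, response, terms, group, nested=nested, ar1=ar1, time=time,
            sqrt_response=sqrt_response,
        )
        fits[name] = fit
        rows.append((name, fit.k_params, fit.loglik, fit.aicc))
    tab = pd.DataFrame(rows, columns=["model", "k", "loglik", "aicc"]).set_index("model")
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    w = np.exp(-0.5 * tab["delta_aicc"])
    tab["weight"] = w / w.sum()
    tab = tab.sort_values("aicc")
    return ModelRanking(table=tab, fits=fits)
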