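"""Recursive observed-variable path models: fit, fit indices, effects.

The model class is deliberately narrow: a directed acyclic graph over
observed variables with mutually uncorrelated residuals (a *recursive*
model). For this class the maximum-likelihood estimates coincide with
equation-wise least squares — each endogenous variable regressed on its
parents — so the fit is closed form, with the ML discrepancy evaluated
afterwards for the covariance-based fit statistics:

    F_ML  = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - v
    chi^2 = (n - 1) * F_ML

plus GFI, CFI (against the independence baseline), SRMR and AIC. On
standardised input the path coefficients are standardised effects and each
endogenous equation's R^2 equals one minus its residual-variance estimate.

Effect decomposition enumerates every directed chain from source to
target: the direct effect is the single edge, each indirect contribution
is the product of coefficients along one mediating chain, and the total is
the sum over all chains. Standard errors for products and sums of products
come from the delta method with a block-diagonal (per-equation)
coefficient covariance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ModelError

Edge = tuple[str, str]


@dataclass(frozen=True)
class PathModelSpec:
    """A directed acyclic path diagram over named observed variables."""

    variables: tuple[str, ...]
    paths: tuple[Edge, ...]

    @classmethod
    def from_strings(
        cls, path_strings: list[str], variables: list[str] | None = None
    ) -> "PathModelSpec":
        """Parse ``"X -> Y"`` strings; variable order defaults to first
        appearance."""
        paths: list[Edge] = []
        seen: list[str] = []
        for s in path_strings:
            try:
                src, tgt = (part.strip() for part in s.split("->"))
            except ValueError as exc:
                raise ModelError(f"cannot parse path {s!r}") from exc
            paths.append((src, tgt))
            for v in (src, tgt):
                if v not in seen:
                    seen.append(v)
        return cls(tuple(variables) if variables else tuple(seen), tuple(paths))

    def __post_init__(self) -> None:
        for src, tgt in self.paths:
            if src not in self.variables or tgt not in self.variables:
                raise ModelError(f"path {src}->{tgt} uses an unknown variable")
        if len(set(self.paths)) != len(self.paths):
            raise ModelError("duplicate paths in specification")
        self.topological_order()  # raises on cycles

    def parents(self, var: str) -> list[str]:
        return [s for s, t in self.paths if t == var]

    def children(self, var: str) -> list[str]:
        return [t for s, t in self.paths if s == var]

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.variables if self.parents(v)]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.variables if not self.parents(v)]

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises :class:`ModelError` on a cycle."""
        indeg = {v: len(self.parents(v)) for v in self.variables}
        queue = [v for v in self.variables if indeg[v] == 0]
        order: list[str] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for c in self.children(v):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.variables):
            raise ModelError("path diagram contains a cycle (model not recursive)")
        return order

    def chains(self, source: str, target: str) -> list[tuple[Edge, ...]]:
        """All directed chains from source to target, as edge tuples."""
        out: list[tuple[Edge, ...]] = []

        def walk(node: str, trail: tuple[Edge, ...]) -> None:
            if node == target and trail:
                out.append(trail)
                return
            for child in self.children(node):
                walk(child, trail + ((node, child),))

        walk(source, ())
        return out


def model_df(spec: PathModelSpec) -> int:
    """Degrees of freedom: unique covariance moments minus free parameters.

    Free parameters are the path coefficients, the exogenous variances and
    covariances, and one residual variance per endogenous variable.
    """
    v = len(spec.variables)
    n_exog = len(spec.exogenous)
    moments = v * (v + 1) // 2
    free = (
        len(spec.paths)
        + n_exog * (n_exog + 1) // 2  # exogenous (co)variances
        + len(spec.endogenous)        # residual variances
    )
    return moments - free


@dataclass
class PathFitResult:
    spec: PathModelSpec
    n: int
    beta: dict[Edge, float]
    se: dict[Edge, float]
    p_values: dict[Edge, float]
    beta_cov: dict[str, pd.DataFrame]   # per-equation coefficient covariance
    r2: dict[str, float]
    residual_var: dict[str, float]
    S: pd.DataFrame                     # sample covariance
    sigma_theta: pd.DataFrame           # model-implied covariance
    chi2: float
    df: int
    p_value: float
    gfi: float
    cfi: float
    srmr: float
    aic_chi2: float                     # chi^2 + 2k
    aic_loglik: float                   # -2 logL + 2k
    standardized: bool

    @property
    def fit_acceptable(self) -> dict[str, bool]:
        """Conventional covariance-fit screening thresholds."""
        return {
            "chi2_p_gt_05": self.p_value > 0.05,
            "srmr_lt_08": self.srmr < 0.08,
            "gfi_gt_95": self.gfi > 0.95,
        }

    def coefficient_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": s,
                "target": t,
                "beta": self.beta[(s, t)],
                "se": self.se[(s, t)],
                "p_value": self.p_values[(s, t)],
            }
            for s, t in self.spec.paths
        ]
        return pd.DataFrame(rows)


def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper-tail p of the chi-square distribution."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.chi2.sf(chi2, df))


def _structural_matrices(
    spec: PathModelSpec,
    beta: dict[Edge, float],
    psi_endog: dict[str, float],
    exog_cov: pd.DataFrame,
) -> pd.DataFrame:
    """Model-implied covariance (I-B)^-1 Psi (I-B)^-T."""
    names = list(spec.variables)
    v = len(names)
    idx = {name: i for i, name in enumerate(names)}
    B = np.zeros((v, v))
    for (s, t), b in beta.items():
        B[idx[t], idx[s]] = b
    Psi = np.zeros((v, v))
    for e1, e2 in itertools.product(spec.exogenous, repeat=2):
        Psi[idx[e1], idx[e2]] = exog_cov.loc[e1, e2]
    for var, psi in psi_endog.items():
        Psi[idx[var], idx[var]] = psi
    inv = np.linalg.inv(np.eye(v) - B)
    return pd.DataFrame(inv @ Psi @ inv.T, index=names, columns=names)


def fit(
    spec: PathModelSpec, data: pd.DataFrame, standardized: bool = True
) -> PathFitResult:
    """Fit the recursive model by equation-wise least squares.

    ``data`` is a plots x variables table containing every model variable;
    with ``standardized=True`` (default) columns are z-scored first so the
    coefficients are standardised effects.
    """
    missing = [v for v in spec.variables if v not in data.columns]
    if missing:
        raise ModelError(f"data lacks model variables {missing}")
    X = data[list(spec.variables)].astype(float)
    n, v = X.shape
    if n <= v:
        raise DegenerateDataError("need more rows than model variables")
    if X.isna().any().any():
        raise DegenerateDataError("model data contain missing values")
    if standardized:
        X = (X - X.mean()) / X.std(ddof=1)
    else:
        X = X - X.mean()

    S = X.cov()  # ddof=1; correlation matrix when standardized
    if np.linalg.matrix_rank(S.to_numpy()) < v:
        raise DegenerateDataError("singular sample covariance")

    beta: dict[Edge, float] = {}
    se: dict[Edge, float] = {}
    p_values: dict[Edge, float] = {}
    beta_cov: dict[str, pd.DataFrame] = {}
    r2: dict[str, float] = {}
    psi: dict[str, float] = {}
    for target in spec.endogenous:
        parents = spec.parents(target)
        Xp = X[parents].to_numpy()
        y = X[target].to_numpy()
        coef, *_ = np.linalg.lstsq(Xp, y, rcond=None)
        resid = y - Xp @ coef
        rss = float(resid @ resid)
        tss = float(y @ y)
        dof = n - len(parents)  # columns are centred; no intercept fitted
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(Xp.T @ Xp)
        beta_cov[target] = pd.DataFrame(cov, index=parents, columns=parents)
        for j, parent in enumerate(parents):
            b = float(coef[j])
            s_ = math.sqrt(cov[j, j])
            beta[(parent, target)] = b
            se[(parent, target)] = s_
            p_values[(parent, target)] = float(
                2 * sps.t.sf(abs(b) / s_, dof) if s_ > 0 else 0.0
            )
        r2[target] = 1.0 - rss / tss
        psi[target] = rss / (n - 1)  # same divisor as S: saturated => Sigma == S

    exog_cov = S.loc[spec.exogenous, spec.exogenous]
    sigma = _structural_matrices(spec, beta, psi, exog_cov)

    Sm = S.to_numpy()
    Sg = sigma.to_numpy()
    sign_s, logdet_s = np.linalg.slogdet(Sm)
    sign_g, logdet_g = np.linalg.slogdet(Sg)
    if sign_s <= 0 or sign_g <= 0:
        raise DegenerateDataError("non-positive-definite covariance matrix")
    sig_inv = np.linalg.inv(Sg)
    f_ml = logdet_g + float(np.trace(Sm @ sig_inv)) - logdet_s - v
    chi2 = max((n - 1) * f_ml, 0.0)
    df = model_df(spec)
    p_value = chi2_pvalue(chi2, df) if df > 0 else 1.0

    # GFI: share of S "explained" by Sigma(theta)
    M = sig_inv @ Sm
    gfi = 1.0 - np.trace((M - np.eye(v)) @ (M - np.eye(v))) / np.trace(M @ M)

    # CFI against the independence (diagonal) baseline;
    # F_base = ln|diag(S)| + tr(S diag(S)^-1) - ln|S| - v, and the trace is v
    base_logdet = float(np.sum(np.log(np.diag(Sm))))
    chi2_base = max((n - 1) * (base_logdet - logdet_s), 0.0)
    df_base = v * (v - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    cfi = float(np.clip(cfi, 0.0, 1.0))

    # SRMR over the lower triangle incl. diagonal, on correlation scale
    d = np.sqrt(np.diag(Sm))
    resid_std = (Sm - Sg) / np.outer(d, d)
    tril = resid_std[np.tril_indices(v)]
    srmr = float(np.sqrt(np.mean(tril**2)))

    k = v * (v + 1) // 2 - df  # number of free parameters
    S_ml = Sm * (n - 1) / n
    minus2ll = n * (v * math.log(2 * math.pi) + logdet_g + float(np.trace(S_ml @ sig_inv)))
    return PathFitResult(
        spec=spec,
        n=n,
        beta=beta,
        se=se,
        p_values=p_values,
        beta_cov=beta_cov,
        r2=r2,
        residual_var=psi,
        S=S,
        sigma_theta=sigma,
        chi2=float(chi2),
        df=df,
        p_value=float(p_value),
        gfi=float(gfi),
        cfi=cfi,
        srmr=srmr,
        aic_chi2=float(chi2 + 2 * k),
        aic_loglik=float(minus2ll + 2 * k),
        standardized=standardized,
    )


def _chain_label(chain: tuple[Edge, ...]) -> str:
    if len(chain) == 1:
        return "direct"
    mediators = [t for _, t in chain[:-1]]
    return "via " + " -> ".join(mediators)


def _delta_se(
    chains: list[tuple[Edge, ...]],
    beta: dict[Edge, float],
    beta_cov: dict[str, pd.DataFrame] | None,
) -> float | None:
    """Delta-method SE of sum over chains of the edge-coefficient products.

    Coefficient covariance is block-diagonal by equation (edges sharing a
    target covary; edges with different targets are treated as
    independent), matching the equation-wise estimator.
    """
    if beta_cov is None:
        return None
    grad: dict[Edge, float] = {}
    for chain in chains:
        for edge in chain:
            others = math.prod(beta[e] for e in chain if e != edge)
            grad[edge] = grad.get(edge, 0.0) + others
    var = 0.0
    by_target: dict[str, list[Edge]] = {}
    for edge in grad:
        by_target.setdefault(edge[1], []).append(edge)
    for target, edges in by_target.items():
        cov = beta_cov[target]
        g = np.array([grad[e] for e in edges])
        sub = cov.loc[[e[0] for e in edges], [e[0] for e in edges]].to_numpy()
        var += float(g @ sub @ g)
    return math.sqrt(var)


def decompose_effects(
    spec: PathModelSpec,
    beta: dict[Edge, float],
    beta_cov: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Direct / indirect / total standardised effects for every connected pair.

    Returns a tidy frame with one row per (source, target, pathway) where
    pathway is ``direct``, ``via <mediator chain>`` or ``total``. When
    ``beta_cov`` is supplied (as from :func:`fit`), delta-method standard
    errors and normal two-sided p-values accompany each effect.
    """
    rows = []
    order = spec.topological_order()
    for source, target in itertools.permutations(order, 2):
        chains = spec.chains(source, target)
        if not chains:
            continue
        effects = {}
        for chain in chains:
            effects[_chain_label(chain)] = (
                math.prod(beta[e] for e in chain),
                [chain],
            )
        total = sum(val for val, _ in effects.values())
        effects["total"] = (total, chains)
        for pathway, (value, used_chains) in effects.items():
            se = _delta_se(used_chains, beta, beta_cov)
            p = (
                float(2 * sps.norm.sf(abs(value) / se))
                if se not in (None, 0.0)
                else np.nan
            )
            rows.append(
                {
                    "source": source,
                    "target": target,
                    "pathway": pathway,
                    "effect": value,
                    "se": np.nan if se is None else se,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def decompose_fit(fit_result: PathFitResult) -> pd.DataFrame:
    """Effect decomposition of a fitted model (with delta-method SEs)."""
    return decompose_effects(
        fit_result.spec, fit_result.beta, fit_result.beta_cov
    )
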