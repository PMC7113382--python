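"""Recursive path models: covariate residualization, ML fitting, fit indices,
backward trimming and bootstrap confidence intervals for indirect effects.

The models are acyclic systems of linear structural equations among observed
variables with uncorrelated disturbances. For such models the normal-theory
likelihood factorizes equation by equation, so the maximum-likelihood
solution is available in closed form: each endogenous variable's path
coefficients are its OLS regression on its parents, residual variances are
the corresponding conditional variances, and the exogenous covariance block
is free (fitted at its sample value). The ML discrepancy

    F_ML = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^-1) - p

is evaluated analytically at that optimum; chi2 = (n-1) F_ML, and CFI/RMSEA
follow from chi2, the model df and the independence baseline.

Indirect (mediated) effects are products of path coefficients along a chain,
with significance assessed by nonparametric case-resampling bootstrap and
percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathModelSpec",
    "PathEstimate",
    "PathFitResult",
    "IndirectEffect",
    "residualize",
    "fit_path_model",
    "indirect_effect",
    "trim_model",
]


def residualize(
    data_table: pd.DataFrame,
    target_columns: Sequence[str],
    covariate_columns: Sequence[str],
) -> pd.DataFrame:
    """Replace each target column by its OLS residual against the covariates.

    An intercept is always included, so residuals are centred. Covariate
    columns are dropped from the output; all other columns pass through.
    """
    targets = list(target_columns)
    covs = list(covariate_columns)
    missing = [c for c in targets + covs if c not in data_table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    if data_table[targets + covs].isna().any().any():
        raise ValueError("missing values in targets or covariates")
    design = np.column_stack(
        (np.ones(len(data_table)), data_table[covs].to_numpy(dtype=float))
    ) if covs else np.ones((len(data_table), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"covariate design rank-deficient (columns {covs})")
    out = data_table.drop(columns=covs).copy()
    y = data_table[targets].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    out[targets] = y - design @ beta
    return out


@dataclass(frozen=True)
class PathModelSpec:
    """A directed acyclic path diagram among observed variables."""

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        seen = set()
        for src, tgt in self.edges:
            if src not in self.variables or tgt not in self.variables:
                raise ValueError(f"edge ({src}, {tgt}) references unknown variable")
            if src == tgt:
                raise ValueError(f"self-loop on {src}")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge ({src}, {tgt})")
            seen.add((src, tgt))
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[str]:
        indeg = {v: 0 for v in self.variables}
        for _, tgt in self.edges:
            indeg[tgt] += 1
        order, ready = [], [v for v in self.variables if indeg[v] == 0]
        while ready:
            v = ready.pop(0)
            order.append(v)
            for src, tgt in self.edges:
                if src == v:
                    indeg[tgt] -= 1
                    if indeg[tgt] == 0:
                        ready.append(tgt)
        if len(order) != len(self.variables):
            raise ValueError("path model must be acyclic (recursive)")
        return order

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {tgt for _, tgt in self.edges}
        return tuple(v for v in self.variables if v not in targets)

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {tgt for _, tgt in self.edges}
        return tuple(v for v in self.variables if v in targets)

    def parents(self, variable: str) -> tuple[str, ...]:
        return tuple(src for src, tgt in self.edges if tgt == variable)

    def without_edge(self, edge: tuple[str, str]) -> "PathModelSpec":
        if edge not in self.edges:
            raise ValueError(f"edge {edge} not in model")
        return PathModelSpec(self.variables, tuple(e for e in self.edges if e != edge))

    def n_free_parameters(self) -> int:
        q = len(self.exogenous)
        return len(self.edges) + len(self.endogenous) + q * (q + 1) // 2

    def degrees_of_freedom(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_parameters()

    @classmethod
    def from_text(cls, text: str, variables: Sequence[str] | None = None) -> "PathModelSpec":
        """Parse one ``source -> target`` edge per line ('#' starts a comment)."""
        edges: list[tuple[str, str]] = []
        names: list[str] = list(variables) if variables is not None else []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValueError(f"cannot parse edge line: {raw!r}")
            src, tgt = (part.strip() for part in line.split("->", 1))
            edges.append((src, tgt))
            for v in (src, tgt):
                if v not in names:
                    names.append(v)
        return cls(tuple(names), tuple(edges))

    def to_text(self) -> str:
        return "\n".join(f"{src} -> {tgt}" for src, tgt in self.edges) + "\n"


@dataclass(frozen=True)
class PathEstimate:
    unstandardized: float
    standardized: float
    se: float
    statistic: float
    p: float


@dataclass(frozen=True)
class PathFitResult:
    spec: PathModelSpec
    estimates: dict[tuple[str, str], PathEstimate]
    residual_variances: dict[str, float]
    chi_square: float
    df: int
    p_fit: float
    cfi: float
    rmsea: float
    r_squared: dict[str, float]
    n: int

    def estimate(self, src: str, tgt: str) -> PathEstimate:
        return self.estimates[(src, tgt)]


def _coeffs_for(S: np.ndarray, idx: dict[str, int], target: str, parents: Sequence[str]):
    par = [idx[p] for p in parents]
    y = idx[target]
    Spp = S[np.ix_(par, par)]
    beta = np.linalg.solve(Spp, S[par, y])
    psi = float(S[y, y] - S[y, par] @ beta)
    return np.asarray(beta), psi, Spp


def fit_path_model(spec: PathModelSpec, data_table: pd.DataFrame) -> PathFitResult:
    """Fit a recursive path model by (closed-form) maximum likelihood."""
    X = data_table[list(spec.variables)].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > number of variables ({p}); got n={n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in data")
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ValueError("sample covariance is not positive definite") from None
    if spec.degrees_of_freedom() < 0:
        raise ValueError("model is over-parameterized (df < 0)")
    return _fit_from_cov(spec, S, n)


def _fit_from_cov(spec: PathModelSpec, S: np.ndarray, n: int) -> PathFitResult:
    names = list(spec.variables)
    p = len(names)
    idx = {v: i for i, v in enumerate(names)}
    B = np.zeros((p, p))
    psi_mat = np.zeros((p, p))
    exo = [idx[v] for v in spec.exogenous]
    psi_mat[np.ix_(exo, exo)] = S[np.ix_(exo, exo)]

    raw: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    residual_variances: dict[str, float] = {}
    for target in spec.endogenous:
        parents = spec.parents(target)
        beta, psi, Spp = _coeffs_for(S, idx, target, parents)
        residual_variances[target] = psi
        psi_mat[idx[target], idx[target]] = psi
        k = len(parents)
        dof = n - k - 1
        sigma2 = psi * (n - 1) / dof if dof > 0 else np.inf
        cov_beta = sigma2 * np.linalg.inv((n - 1) * Spp)
        for j, src in enumerate(parents):
            B[idx[target], idx[src]] = beta[j]
            se = float(np.sqrt(max(cov_beta[j, j], 0.0)))
            tstat = beta[j] / se if se > 0 else np.inf * np.sign(beta[j])
            pval = float(2 * stats.t.sf(abs(tstat), dof)) if dof > 0 else np.nan
            raw[(src, target)] = (float(beta[j]), se, float(tstat), pval)

    inv_imb = np.linalg.inv(np.eye(p) - B)
    sigma = inv_imb @ psi_mat @ inv_imb.T

    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("degenerate covariance encountered during fit")
    f_ml = max(logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p, 0.0)
    chi_square = (n - 1) * f_ml
    df = spec.degrees_of_freedom()
    p_fit = float(stats.chi2.sf(chi_square, df)) if df > 0 else 1.0

    # Independence baseline: all covariances zero, variances free.
    f_base = max(float(np.sum(np.log(np.diag(S)))) - logdet_s, 0.0)
    chi_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2
    excess = max(chi_square - df, 0.0)
    denom = max(chi_base - df_base, excess, 0.0)
    cfi = 1.0 if denom == 0 else float(np.clip(1.0 - excess / denom, 0.0, 1.0))
    rmsea = float(np.sqrt(excess / (df * (n - 1)))) if df > 0 else 0.0

    implied_sd = np.sqrt(np.diag(sigma))
    estimates = {
        (src, tgt): PathEstimate(
            unstandardized=b,
            standardized=b * implied_sd[idx[src]] / implied_sd[idx[tgt]],
            se=se,
            statistic=tstat,
            p=pval,
        )
        for (src, tgt), (b, se, tstat, pval) in raw.items()
    }
    r_squared = {
        v: float(1.0 - residual_variances[v] / sigma[idx[v], idx[v]]) for v in spec.endogenous
    }
    return PathFitResult(
        spec=spec,
        estimates=estimates,
        residual_variances=residual_variances,
        chi_square=float(chi_square),
        df=df,
        p_fit=p_fit,
        cfi=cfi,
        rmsea=rmsea,
        r_squared=r_squared,
        n=n,
    )


@dataclass(frozen=True)
class IndirectEffect:
    path: tuple[str, ...]
    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_failed: int = 0


def _path_product(S: np.ndarray, idx: dict[str, int], chain_parents) -> float:
    prod = 1.0
    for target, parents, src_pos in chain_parents:
        beta, _, _ = _coeffs_for(S, idx, target, parents)
        prod *= beta[src_pos]
    return prod


def indirect_effect(
    spec: PathModelSpec,
    data_table: pd.DataFrame,
    path: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    max_failure_fraction: float = 0.05,
) -> IndirectEffect:
    """Bootstrap an indirect effect: the product of coefficients along ``path``.

    Case-resampling bootstrap with percentile CI; replicates whose resampled
    covariance is degenerate are dropped and counted, and more than
    ``max_failure_fraction`` failures aborts. ``n_boot=1`` yields the
    documented degenerate CI equal to the single replicate.
    """
    path = tuple(path)
    if len(path) < 2:
        raise ValueError("path needs at least two variables")
    for src, tgt in zip(path[:-1], path[1:]):
        if (src, tgt) not in spec.edges:
            raise ValueError(f"edge ({src}, {tgt}) not in model spec")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    X = data_table[list(spec.variables)].to_numpy(dtype=float)
    n = X.shape[0]
    idx = {v: i for i, v in enumerate(spec.variables)}
    chain = []
    for src, tgt in zip(path[:-1], path[1:]):
        parents = spec.parents(tgt)
        chain.append((tgt, parents, parents.index(src)))

    point = _path_product(np.cov(X, rowvar=False, ddof=1), idx, chain)

    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    kept = 0
    failed = 0
    for _ in range(n_boot):
        sample = X[rng.integers(0, n, n)]
        Sb = np.cov(sample, rowvar=False, ddof=1)
        try:
            value = _path_product(Sb, idx, chain)
        except np.linalg.LinAlgError:
            failed += 1
            continue
        if not np.isfinite(value):
            failed += 1
            continue
        draws[kept] = value
        kept += 1
    if failed > max_failure_fraction * n_boot:
        raise RuntimeError(f"{failed}/{n_boot} bootstrap replicates failed to fit")
    draws = draws[:kept]
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return IndirectEffect(
        path=path,
        point_estimate=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        n_failed=failed,
    )


def trim_model(
    spec: PathModelSpec, data_table: pd.DataFrame, alpha: float = 0.05
) -> tuple[PathModelSpec, PathFitResult]:
    """Backward elimination of nonsignificant paths.

    Repeatedly drops the single least significant path (largest p > alpha,
    ties broken by edge order) and refits, until every remaining path is
    significant at ``alpha`` or no removable edge remains. Deterministic.
    """
    current = spec
    fit = fit_path_model(current, data_table)
    while True:
        worst_edge, worst_p = None, alpha
        for edge in current.edges:
            p = fit.estimates[edge].p
            if np.isfinite(p) and p > worst_p:
                worst_edge, worst_p = edge, p
        if worst_edge is None:
            return current, fit
        current = current.without_edge(worst_edge)
        fit = fit_path_model(current, data_table)
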