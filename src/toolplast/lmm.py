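"""Random-intercept mixed models with orthogonal polynomial covariates.

The core model, per kinematic parameter (or the PCA meta-parameter), is

    y ~ condition + poly(puberty, d) + condition : poly(puberty, d) + (1 | subject)

with the condition factor (PRE/POST session, or FIRST/LAST tool block) coded
sum-to-zero as -1/2 / +1/2 and the puberty covariate expanded on an
orthonormal polynomial basis (degree d = 1 or 2).  Inference follows the
conventional mixed-model workflow: REML fits for coefficient and Type III
Wald chi-square reporting, ML refits for likelihood-ratio comparison of the
linear vs quadratic bases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "OrthogonalBasis",
    "ModelFit",
    "MetaParameter",
    "orthogonal_poly_basis",
    "fit_lmm",
    "wald_type3",
    "lrt_poly_vs_linear",
    "pca_meta",
    "imitation_regression",
]


@dataclass(frozen=True)
class OrthogonalBasis:
    """Orthonormal polynomial basis (constant column excluded).

    Built by the Forsythe three-term recurrence on the observed covariate
    values; ``alpha`` and ``norm2`` are the recurrence coefficients, which
    allow exact re-evaluation at the knots and evaluation on out-of-sample
    grids (e.g. the crossing-point grid).
    """

    degree: int
    alpha: tuple[float, ...]
    norm2: tuple[float, ...]     # squared norms of the raw recurrence polys, j = 0..degree
    knots: np.ndarray = field(repr=False)
    columns: np.ndarray = field(repr=False)

    def evaluate(self, x) -> np.ndarray:
        """Basis values at arbitrary covariate values, shape (m, degree)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        polys = [np.ones_like(x)]
        for j in range(self.degree):
            p = (x - self.alpha[j]) * polys[j]
            if j > 0:
                p = p - (self.norm2[j] / self.norm2[j - 1]) * polys[j - 1]
            polys.append(p)
        cols = [polys[j + 1] / np.sqrt(self.norm2[j + 1]) for j in range(self.degree)]
        return np.column_stack(cols)


def orthogonal_poly_basis(x, degree: int) -> OrthogonalBasis:
    """Orthonormal polynomial basis of the covariate, R ``poly()`` style.

    Columns have zero mean, unit norm and are mutually orthogonal; the
    constant column is excluded.  Requires at least ``degree + 1`` distinct
    covariate values.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(np.unique(x)) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct covariate values for degree {degree}"
        )
    polys = [np.ones_like(x)]
    alpha, norm2 = [], [float(len(x))]
    for j in range(degree):
        pj = polys[j]
        a = float(np.sum(x * pj * pj) / np.sum(pj * pj))
        alpha.append(a)
        p_next = (x - a) * pj
        if j > 0:
            p_next = p_next - (norm2[j] / norm2[j - 1]) * polys[j - 1]
        polys.append(p_next)
        norm2.append(float(np.sum(p_next * p_next)))
    columns = np.column_stack(
        [polys[j + 1] / np.sqrt(norm2[j + 1]) for j in range(degree)]
    )
    return OrthogonalBasis(
        degree=degree,
        alpha=tuple(alpha),
        norm2=tuple(norm2),
        knots=x.copy(),
        columns=columns,
    )


@dataclass
class ModelFit:
    """A fitted random-intercept linear mixed model.

    Carries everything the downstream stages need: fixed coefficients with
    their covariance, variance components, the likelihood criterion, and the
    design metadata (basis transform, contrast coding, term blocks) required
    to rebuild design rows on arbitrary puberty grids.
    """

    outcome: str
    params: np.ndarray
    cov_params: np.ndarray
    column_names: list[str]
    term_blocks: dict[str, list[int]]
    basis: OrthogonalBasis
    condition_col: str
    condition_contrasts: dict[str, float]
    covariate_col: str
    covariate_range: tuple[float, float]
    subject_var: float
    resid_var: float
    llf: float
    reml: bool
    converged: bool
    singular: bool
    n_obs: int
    n_subjects: int

    def design_row(self, condition_label: str, covariate_value) -> np.ndarray:
        """Fixed-effects design rows for a condition at covariate values."""
        s = self.condition_contrasts[condition_label]
        x = np.atleast_1d(np.asarray(covariate_value, dtype=float))
        basis_vals = self.basis.evaluate(x)
        rows = np.column_stack(
            [np.ones_like(x), np.full_like(x, s), basis_vals, s * basis_vals]
        )
        return rows

    def predict(self, condition_label: str, covariate_value) -> np.ndarray:
        """Fixed-effect (population-level) prediction, random effects at 0."""
        return self.design_row(condition_label, covariate_value) @ self.params

    def to_dict(self) -> dict:
        """JSON-serialisable summary: coefficients, covariance, variance
        components and the basis transform needed to rebuild predictions."""
        return {
            "outcome": self.outcome,
            "coefficients": dict(zip(self.column_names, self.params.tolist())),
            "cov_params": self.cov_params.tolist(),
            "term_blocks": self.term_blocks,
            "basis": {"degree": self.basis.degree,
                      "alpha": list(self.basis.alpha),
                      "norm2": list(self.basis.norm2)},
            "condition_contrasts": self.condition_contrasts,
            "covariate": self.covariate_col,
            "covariate_range": list(self.covariate_range),
            "subject_var": self.subject_var,
            "resid_var": self.resid_var,
            "llf": self.llf,
            "reml": self.reml,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


def _build_design(
    data: pd.DataFrame,
    condition_col: str,
    condition_levels: tuple[str, str],
    covariate_col: str,
    degree: int,
    basis: OrthogonalBasis | None,
):
    levels = list(condition_levels)
    observed = set(data[condition_col].astype(str).unique())
    missing = [l for l in levels if str(l) not in observed]
    if missing:
        raise ValueError(f"condition level(s) {missing} absent from data")
    contrasts = {str(levels[0]): -0.5, str(levels[1]): +0.5}
    s = data[condition_col].astype(str).map(contrasts).to_numpy(float)
    x = data[covariate_col].to_numpy(float)
    if basis is None:
        basis = orthogonal_poly_basis(x, degree)
        basis_cols = basis.columns
    else:
        basis_cols = basis.evaluate(x)
    X = np.column_stack(
        [np.ones(len(data)), s, basis_cols, s[:, None] * basis_cols]
    )
    names = (
        ["intercept", condition_col]
        + [f"poly{j + 1}" for j in range(degree)]
        + [f"{condition_col}:poly{j + 1}" for j in range(degree)]
    )
    term_blocks = {
        "condition": [1],
        "covariate": list(range(2, 2 + degree)),
        "interaction": list(range(2 + degree, 2 + 2 * degree)),
    }
    return X, names, term_blocks, basis, contrasts


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    condition_col: str = "session",
    condition_levels: tuple[str, str] = ("PRE", "POST"),
    covariate_col: str = "puberty",
    degree: int = 2,
    subject_col: str = "subject_id",
    reml: bool = True,
    basis: OrthogonalBasis | None = None,
) -> ModelFit:
    """Fit ``outcome ~ condition * poly(covariate, degree) + (1 | subject)``.

    A singular fit (random-intercept variance estimated at zero) is reported
    via the ``singular`` flag, not as a failure; non-convergence after
    optimizer fallbacks raises.
    """
    cols = {outcome, condition_col, covariate_col, subject_col}
    missing = cols - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = data.dropna(subset=list(cols))
    if data[subject_col].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    y = data[outcome].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {outcome!r} is constant")

    X, names, blocks, basis, contrasts = _build_design(
        data, condition_col, condition_levels, covariate_col, degree, basis
    )
    groups = data[subject_col].to_numpy()

    model = sm.MixedLM(y, X, groups=groups)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "cg"):
            try:
                candidate = model.fit(reml=reml, method=method)
            except Exception:  # noqa: BLE001 - try the next optimizer
                continue
            if not np.isfinite(candidate.llf):
                continue
            if result is None or candidate.llf > result.llf + 1e-8:
                result = candidate
            if candidate.converged:
                break
    if result is None:
        raise RuntimeError(f"mixed model for {outcome!r} failed to converge")

    subject_var = float(np.squeeze(result.cov_re))
    k = X.shape[1]
    fit = ModelFit(
        outcome=outcome,
        params=np.asarray(result.fe_params, dtype=float),
        cov_params=np.asarray(result.cov_params())[:k, :k],
        column_names=names,
        term_blocks=blocks,
        basis=basis,
        condition_col=condition_col,
        condition_contrasts=contrasts,
        covariate_col=covariate_col,
        covariate_range=(float(data[covariate_col].min()),
                         float(data[covariate_col].max())),
        subject_var=subject_var,
        resid_var=float(result.scale),
        llf=float(result.llf),
        reml=reml,
        converged=bool(result.converged),
        singular=subject_var <= 1e-10 * float(result.scale),
        n_obs=len(data),
        n_subjects=int(data[subject_col].nunique()),
    )
    if fit.singular:
        log.warning("singular fit for %s: random-intercept variance ~ 0", outcome)
    return fit


def wald_type3(fit: ModelFit) -> pd.DataFrame:
    """Type III Wald chi-square table: per term, chi2 = b' V^-1 b on the
    term's coefficient block (valid under the sum-to-zero contrast and
    orthogonal-basis coding used by :func:`fit_lmm`)."""
    rows = []
    for term, idx in fit.term_blocks.items():
        b = fit.params[idx]
        V = fit.cov_params[np.ix_(idx, idx)]
        if np.linalg.cond(V) > 1e12:
            raise np.linalg.LinAlgError(f"rank-deficient covariance block for {term}")
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        rows.append((term, chi2, df, float(stats.chi2.sf(chi2, df))))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])


def lrt_poly_vs_linear(
    data: pd.DataFrame,
    outcome: str,
    condition_col: str = "session",
    condition_levels: tuple[str, str] = ("PRE", "POST"),
    covariate_col: str = "puberty",
    subject_col: str = "subject_id",
    alpha: float = 0.05,
) -> dict:
    """Likelihood-ratio comparison of the quadratic vs linear puberty basis.

    Both models are refit by ML on identical rows; the quadratic model adds
    two coefficients (quadratic main effect + quadratic interaction), so the
    statistic is referred to chi-square with 2 df.  The quadratic basis is
    selected when p < alpha.
    """
    rows = data.dropna(subset=[outcome, condition_col, covariate_col, subject_col])
    fit_lin = fit_lmm(rows, outcome, condition_col, condition_levels,
                      covariate_col, degree=1, subject_col=subject_col, reml=False)
    fit_quad = fit_lmm(rows, outcome, condition_col, condition_levels,
                       covariate_col, degree=2, subject_col=subject_col, reml=False)
    if fit_lin.n_obs != fit_quad.n_obs:
        raise ValueError("nested fits used different row sets")
    chi2 = 2.0 * (fit_quad.llf - fit_lin.llf)
    if chi2 < -1e-6:
        raise RuntimeError(
            f"ML log-likelihood decreased under nesting (delta={chi2 / 2:.3g}); "
            "optimizer failure"
        )
    chi2 = max(chi2, 0.0)
    df = 2
    p = float(stats.chi2.sf(chi2, df))
    return {
        "chi2": float(chi2),
        "df": df,
        "p": p,
        "selected": "quadratic" if p < alpha else "linear",
        "llf_linear": fit_lin.llf,
        "llf_quadratic": fit_quad.llf,
    }


@dataclass
class MetaParameter:
    """First principal component of the correlation matrix of the kinematic
    parameters, used as a multivariate summary outcome."""

    loadings: pd.Series
    explained_variance_fraction: float
    scores: pd.Series
    orientation_reference: str
    n_dropped: int
    eigenvalues: np.ndarray


def pca_meta(
    wide: pd.DataFrame,
    parameter_names: list[str] | tuple[str, ...],
    orientation_reference: str = "vel_amplitude",
) -> MetaParameter:
    """First principal component via spectral decomposition of the
    correlation matrix of the parameters.

    The correlation (not covariance) matrix makes the component independent
    of the parameters' units.  Scores are the standardized parameters
    projected on the first eigenvector; the sign is fixed so the loading on
    ``orientation_reference`` (default: the velocity peak amplitude, or the
    first listed parameter if absent) is positive.  Rows with missing values
    are dropped with a logged count.
    """
    names = list(parameter_names)
    missing = [n for n in names if n not in wide.columns]
    if missing:
        raise ValueError(f"parameters absent from table: {missing}")
    block = wide[names]
    complete = block.dropna()
    n_dropped = len(block) - len(complete)
    if n_dropped:
        log.info("pca_meta: dropped %d incomplete rows", n_dropped)
    if len(complete) < 10:
        raise ValueError("need at least 10 complete rows for the PCA")
    values = complete.to_numpy(float)
    sds = values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        constant = [names[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant parameter(s): {constant}")
    z = (values - values.mean(axis=0)) / sds
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    v = eigvecs[:, 0]
    ref = orientation_reference if orientation_reference in names else names[0]
    if v[names.index(ref)] < 0:
        v = -v
    scores = pd.Series(z @ v, index=complete.index, name="meta")
    return MetaParameter(
        loadings=pd.Series(v, index=names, name="loading"),
        explained_variance_fraction=float(eigvals[0] / len(names)),
        scores=scores,
        orientation_reference=ref,
        n_dropped=n_dropped,
        eigenvalues=eigvals,
    )


def imitation_regression(scores, puberty, alpha: float = 0.05) -> dict:
    """Linear vs quadratic simple regression of imitation totals on puberty.

    Totals must lie in [0, 72].  Degree selection uses the ML likelihood
    ratio (1 extra coefficient, chi-square with 1 df) at the same threshold
    as the mixed-model comparison.
    """
    scores = np.asarray(scores, dtype=float)
    puberty = np.asarray(puberty, dtype=float)
    if scores.shape != puberty.shape:
        raise ValueError("scores and puberty must have equal length")
    if len(scores) < 4:
        raise ValueError("need at least 4 subjects")
    if np.any((scores < 0) | (scores > 72)):
        raise ValueError("imitation totals must lie in [0, 72]")
    basis = orthogonal_poly_basis(puberty, 2)
    cols = basis.evaluate(puberty)
    X1 = np.column_stack([np.ones_like(puberty), cols[:, 0]])
    X2 = np.column_stack([np.ones_like(puberty), cols])
    fit1 = sm.OLS(scores, X1).fit()
    fit2 = sm.OLS(scores, X2).fit()
    chi2 = max(0.0, 2.0 * (fit2.llf - fit1.llf))
    p = float(stats.chi2.sf(chi2, 1))
    return {
        "linear_fit": {"params": fit1.params.tolist(), "llf": float(fit1.llf)},
        "quadratic_fit": {"params": fit2.params.tolist(), "llf": float(fit2.llf),
                          "quadratic_coef": float(fit2.params[-1])},
        "chi2": float(chi2),
        "df": 1,
        "p": p,
        "selected": "quadratic" if p < alpha else "linear",
    }
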