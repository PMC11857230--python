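"""Per-analyte response-surface regression and backward elimination.

Each analyte's peak area (or area ratio) is modeled by ordinary least
squares on the treatment-coded model matrix

    Y = b0 + b1·X1 + b2·X2 + b22·X2² + b3·X3 + b4·X4 + b44·X4²
        + b12·X1X2 + b34·X3X4 + b13·X1X3

and reduced by iterative backward elimination: the single eligible term with
the largest partial-F p-value ≥ α is removed and the model refit, until every
remaining term is significant.  Categorical terms (all dummies of a factor)
are removed atomically; under weak heredity a main effect is protected while
any retained interaction contains it.  Non-detect rows are excluded from the
fit — a failed extraction is not a zero measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import Condition, Design, FactorSpace, ModelSpec, model_matrix, term_column_labels

__all__ = ["FittedModel", "fit_model", "backward_eliminate"]

_INTERACTION_PARENTS = {
    "inter(X1,X2)": ("main(X1)", "main(X2)"),
    "inter(X3,X4)": ("main(X3)", "main(X4)"),
    "inter(X1,X3)": ("main(X1)", "main(X3)"),
}

_RANK_TOL = 1e-9


@dataclass
class FittedModel:
    """OLS fit of one analyte's response surface.

    `coefficients` / `std_errors` are keyed by model-matrix column label;
    `term_pvalues` by whole term (partial F-test of the nested model omitting
    that term).  The fitting data are retained so that backward elimination
    can refit reduced specs.
    """

    analyte: str
    spec: ModelSpec
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    term_pvalues: dict[str, float]
    residual_sd: float
    n_obs: int
    r_squared: float
    _conditions: list[Condition] = field(repr=False, default_factory=list)
    _y: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    _space: FactorSpace = field(repr=False, default_factory=FactorSpace)

    def predict(self, conditions: list[Condition]) -> np.ndarray:
        X, labels = model_matrix(conditions, self.spec, self._space)
        beta = np.array([self.coefficients[lab] for lab in labels])
        return X @ beta

    def report_frame(self) -> pd.DataFrame:
        """Per-column report: term, column, coefficient, std_error, term_pvalue."""
        cols = term_column_labels(self.spec, self._space)
        rows = []
        for term, labels in cols.items():
            for lab in labels:
                rows.append(
                    (
                        term,
                        lab,
                        self.coefficients[lab],
                        self.std_errors[lab],
                        self.term_pvalues.get(term, np.nan),
                    )
                )
        return pd.DataFrame(
            rows, columns=["term", "column", "coefficient", "std_error", "term_pvalue"]
        )


def _ols(X: np.ndarray, y: np.ndarray, labels: list[str]):
    """QR least squares; raises on rank deficiency, naming collinear columns."""
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"underdetermined fit: {n} usable observations for {p} model-matrix columns"
        )
    # scale columns for the rank check so µL² columns don't mask deficiency
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        bad = [labels[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"rank-deficient model matrix; all-zero columns: {bad}")
    Q, R = np.linalg.qr(X / norms)
    diag = np.abs(np.diag(R))
    if (diag < _RANK_TOL).any():
        bad = [labels[i] for i in np.flatnonzero(diag < _RANK_TOL)]
        raise ValueError(f"rank-deficient model matrix; collinear columns: {bad}")
    beta_scaled = np.linalg.solve(R, Q.T @ y)
    beta = beta_scaled / norms
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    Rinv = np.linalg.solve(R, np.eye(p))
    cov = (Rinv @ Rinv.T) * sigma2
    se = np.sqrt(np.diag(cov)) / norms
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return beta, se, rss, dof, r2


def fit_model(
    responses: pd.DataFrame,
    design: Design,
    spec: ModelSpec,
    analyte: str | None = None,
    space: FactorSpace | None = None,
    response: str = "peak_area",
) -> FittedModel:
    """Fit one analyte's response surface by OLS.

    `responses` is the long-format response table (run_id, replicate,
    analyte, peak_area, is_area, area_ratio, non_detect); rows flagged
    non-detect are excluded.  Term p-values come from partial F-tests of the
    nested model omitting each whole term.
    """
    space = space or FactorSpace()
    tab = responses
    if analyte is not None:
        tab = tab[tab["analyte"] == analyte]
    else:
        uniq = tab["analyte"].unique()
        if len(uniq) != 1:
            raise ValueError("response table holds several analytes; pass `analyte`")
        analyte = str(uniq[0])
    tab = tab[~tab["non_detect"].astype(bool)]
    if len(tab) == 0:
        raise ValueError(f"analyte {analyte!r} is unmodellable: all observations non-detect")
    cond_by_run = dict(zip(design.run_ids, design.runs))
    try:
        conditions = [cond_by_run[rid] for rid in tab["run_id"]]
    except KeyError as exc:
        raise ValueError(f"response table references unknown run id {exc}") from exc
    y = tab[response].to_numpy(dtype=float)
    return _fit(conditions, y, spec, analyte, space)


def _fit(
    conditions: list[Condition],
    y: np.ndarray,
    spec: ModelSpec,
    analyte: str,
    space: FactorSpace,
) -> FittedModel:
    X, labels = model_matrix(conditions, spec, space)
    beta, se, rss_full, dof, r2 = _ols(X, y, labels)
    n = len(y)
    term_cols = term_column_labels(spec, space)
    pvals: dict[str, float] = {}
    for term in spec.terms:
        if term == "intercept":
            continue
        reduced = spec.without(term)
        Xr, labs_r = model_matrix(conditions, reduced, space)
        beta_r, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_r = float(((y - Xr @ beta_r) ** 2).sum())
        q = len(term_cols[term])
        if rss_full <= 0:
            pvals[term] = 0.0 if rss_r > 0 else 1.0
        else:
            f = ((rss_r - rss_full) / q) / (rss_full / dof)
            pvals[term] = float(stats.f.sf(max(f, 0.0), q, dof))
    return FittedModel(
        analyte=analyte,
        spec=spec,
        coefficients=dict(zip(labels, beta)),
        std_errors=dict(zip(labels, se)),
        term_pvalues=pvals,
        residual_sd=float(np.sqrt(rss_full / dof)),
        n_obs=n,
        r_squared=r2,
        _conditions=conditions,
        _y=y,
        _space=space,
    )


def backward_eliminate(
    model: FittedModel,
    alpha: float = 0.05,
    heredity: bool = True,
) -> FittedModel:
    """Iteratively remove the least significant term until all are significant.

    One term per iteration — the eligible term with the largest partial-F
    p-value ≥ `alpha` — then refit.  With `heredity`, a main effect is
    ineligible while any retained interaction contains it.  Whole categorical
    terms are removed atomically.  The intercept-only model is a valid
    terminal state.
    """
    current = model
    while True:
        protected: set[str] = set()
        if heredity:
            for inter, parents in _INTERACTION_PARENTS.items():
                if inter in current.spec.terms:
                    protected.update(parents)
        candidates = [
            (term, p)
            for term, p in current.term_pvalues.items()
            if p >= alpha and term not in protected
        ]
        if not candidates:
            return current
        worst = max(candidates, key=lambda tp: tp[1])[0]
        reduced = current.spec.without(worst)
        current = _fit(
            current._conditions, current._y, reduced, current.analyte, current._space
        )
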