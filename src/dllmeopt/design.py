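"""Factor space, model matrices and exact D-optimal design construction.

The experimental domain is the four-variable DLLME factor space: extraction
solvent type (categorical, 5 levels), extraction solvent volume (µL, 5
levels), disperser solvent type (categorical, 3 levels) and disperser solvent
volume (µL, 3 levels).  Categorical factors enter the model matrix as
treatment-coded indicator columns relative to a reference level (chloroform
and acetone by default); quantitative factors enter as raw µL values, with
optional quadratic columns; interactions are elementwise products.

Exact n-run D-optimal designs are selected from the enumerated candidate grid
by a multi-start Fedorov exchange maximizing det(XᵀX).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FactorSpace",
    "Condition",
    "Design",
    "ModelSpec",
    "FULL_MODEL_TERMS",
    "enumerate_grid",
    "model_matrix",
    "d_criterion",
    "d_optimal_design",
]


# term grammar: intercept, main(Xi), quad(Xi), inter(Xi,Xj)
FULL_MODEL_TERMS = (
    "intercept",
    "main(X1)",
    "main(X2)",
    "quad(X2)",
    "main(X3)",
    "main(X4)",
    "quad(X4)",
    "inter(X1,X2)",
    "inter(X3,X4)",
    "inter(X1,X3)",
)


@dataclass(frozen=True)
class FactorSpace:
    """Level sets of the four DLLME variables plus categorical references."""

    extraction_solvent_levels: tuple[str, ...] = (
        "chloroform",
        "DCM",
        "hexane",
        "pentane",
        "CH:P (2:1)",
    )
    extraction_volume_levels: tuple[float, ...] = (500, 750, 1000, 1500, 2000)
    disperser_solvent_levels: tuple[str, ...] = ("acetone", "acetonitrile", "methanol")
    disperser_volume_levels: tuple[float, ...] = (500, 1000, 1500)
    reference_extraction_solvent: str = "chloroform"
    reference_disperser_solvent: str = "acetone"

    def __post_init__(self) -> None:
        for name, levels in (
            ("extraction_solvent_levels", self.extraction_solvent_levels),
            ("extraction_volume_levels", self.extraction_volume_levels),
            ("disperser_solvent_levels", self.disperser_solvent_levels),
            ("disperser_volume_levels", self.disperser_volume_levels),
        ):
            if len(levels) == 0:
                raise ValueError(f"factor space unusable: {name} is empty")
            if len(set(levels)) != len(levels):
                raise ValueError(f"duplicate levels in {name}: {levels}")
        for vols in (self.extraction_volume_levels, self.disperser_volume_levels):
            arr = np.asarray(vols, dtype=float)
            if not (arr > 0).all() or not (np.diff(arr) > 0).all():
                raise ValueError(f"volumes must be positive and strictly increasing: {vols}")
        if self.reference_extraction_solvent not in self.extraction_solvent_levels:
            raise ValueError(
                f"reference extraction solvent {self.reference_extraction_solvent!r} "
                "not among levels"
            )
        if self.reference_disperser_solvent not in self.disperser_solvent_levels:
            raise ValueError(
                f"reference disperser solvent {self.reference_disperser_solvent!r} "
                "not among levels"
            )

    def validate_condition(self, cond: "Condition") -> None:
        if cond.x1 not in self.extraction_solvent_levels:
            raise ValueError(f"extraction solvent {cond.x1!r} not in factor space")
        if cond.x2 not in self.extraction_volume_levels:
            raise ValueError(f"extraction volume {cond.x2!r} µL not in factor space")
        if cond.x3 not in self.disperser_solvent_levels:
            raise ValueError(f"disperser solvent {cond.x3!r} not in factor space")
        if cond.x4 not in self.disperser_volume_levels:
            raise ValueError(f"disperser volume {cond.x4!r} µL not in factor space")


@dataclass(frozen=True)
class Condition:
    """One realization (X1, X2, X3, X4) of the factor space."""

    x1: str
    x2: float
    x3: str
    x4: float

    @property
    def total_solvent_volume(self) -> float:
        return self.x2 + self.x4


@dataclass(frozen=True)
class Design:
    """An ordered set of experimental runs, each a Condition."""

    runs: tuple[Condition, ...]
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def run_ids(self) -> list[str]:
        return [f"run{i + 1:03d}" for i in range(len(self.runs))]


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term structure of the response-surface model.

    Terms are drawn from the grammar of the full model: intercept, four main
    effects, quadratics of the two volumes, and the three two-factor
    interactions X1:X2, X3:X4, X1:X3.
    """

    terms: tuple[str, ...] = FULL_MODEL_TERMS

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in FULL_MODEL_TERMS]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate model terms")
        if "intercept" not in self.terms:
            raise ValueError("intercept term is required")
        for inter, parents in (
            ("inter(X1,X2)", ("main(X1)", "main(X2)")),
            ("inter(X3,X4)", ("main(X3)", "main(X4)")),
            ("inter(X1,X3)", ("main(X1)", "main(X3)")),
        ):
            # interactions are representable without parents; nothing enforced here
            pass

    def without(self, term: str) -> "ModelSpec":
        if term == "intercept":
            raise ValueError("cannot remove the intercept")
        return ModelSpec(tuple(t for t in self.terms if t != term))


REDUCED_ETHYL_OCTANOATE_TERMS = (
    "intercept",
    "main(X1)",
    "main(X2)",
    "main(X3)",
    "inter(X1,X2)",
)


def enumerate_grid(space: FactorSpace) -> list[Condition]:
    """Full Cartesian product of factor levels, in nested field order.

    For the default space this yields the complete 5×5×3×3 = 225-condition
    grid over which fitted models are interpolated.
    """
    return [
        Condition(x1, float(x2), x3, float(x4))
        for x1, x2, x3, x4 in itertools.product(
            space.extraction_solvent_levels,
            space.extraction_volume_levels,
            space.disperser_solvent_levels,
            space.disperser_volume_levels,
        )
    ]


def _term_columns(term: str, space: FactorSpace) -> list[str]:
    """Deterministic column labels contributed by one model term."""
    x1_dummies = [
        f"X1[{lv}]"
        for lv in space.extraction_solvent_levels
        if lv != space.reference_extraction_solvent
    ]
    x3_dummies = [
        f"X3[{lv}]"
        for lv in space.disperser_solvent_levels
        if lv != space.reference_disperser_solvent
    ]
    if term == "intercept":
        return ["intercept"]
    if term == "main(X1)":
        return x1_dummies
    if term == "main(X2)":
        return ["X2"]
    if term == "quad(X2)":
        return ["X2^2"]
    if term == "main(X3)":
        return x3_dummies
    if term == "main(X4)":
        return ["X4"]
    if term == "quad(X4)":
        return ["X4^2"]
    if term == "inter(X1,X2)":
        return [f"{d}:X2" for d in x1_dummies]
    if term == "inter(X3,X4)":
        return [f"{d}:X4" for d in x3_dummies]
    if term == "inter(X1,X3)":
        return [f"{d1}:{d3}" for d1 in x1_dummies for d3 in x3_dummies]
    raise ValueError(f"unknown term {term!r}")


def term_column_labels(spec: ModelSpec, space: FactorSpace) -> dict[str, list[str]]:
    """Map each term of `spec` to the model-matrix columns it expands into."""
    return {t: _term_columns(t, space) for t in spec.terms}


def model_matrix(
    conditions: list[Condition],
    spec: ModelSpec,
    space: FactorSpace,
) -> tuple[np.ndarray, list[str]]:
    """Build the numeric model matrix for `conditions` under `spec`.

    Treatment coding relative to the space's reference levels; quantitative
    factors in raw µL; quadratics as squared raw values; interactions as
    elementwise products of constituent columns.  Returns (matrix, labels).
    """
    for cond in conditions:
        space.validate_condition(cond)
    n = len(conditions)
    cols: dict[str, np.ndarray] = {}
    x2 = np.array([c.x2 for c in conditions], dtype=float)
    x4 = np.array([c.x4 for c in conditions], dtype=float)
    x1_ind = {
        lv: np.array([1.0 if c.x1 == lv else 0.0 for c in conditions])
        for lv in space.extraction_solvent_levels
        if lv != space.reference_extraction_solvent
    }
    x3_ind = {
        lv: np.array([1.0 if c.x3 == lv else 0.0 for c in conditions])
        for lv in space.disperser_solvent_levels
        if lv != space.reference_disperser_solvent
    }
    for term in spec.terms:
        if term == "intercept":
            cols["intercept"] = np.ones(n)
        elif term == "main(X1)":
            for lv, v in x1_ind.items():
                cols[f"X1[{lv}]"] = v
        elif term == "main(X2)":
            cols["X2"] = x2
        elif term == "quad(X2)":
            cols["X2^2"] = x2**2
        elif term == "main(X3)":
            for lv, v in x3_ind.items():
                cols[f"X3[{lv}]"] = v
        elif term == "main(X4)":
            cols["X4"] = x4
        elif term == "quad(X4)":
            cols["X4^2"] = x4**2
        elif term == "inter(X1,X2)":
            for lv, v in x1_ind.items():
                cols[f"X1[{lv}]:X2"] = v * x2
        elif term == "inter(X3,X4)":
            for lv, v in x3_ind.items():
                cols[f"X3[{lv}]:X4"] = v * x4
        elif term == "inter(X1,X3)":
            for lv1, v1 in x1_ind.items():
                for lv3, v3 in x3_ind.items():
                    cols[f"X1[{lv1}]:X3[{lv3}]"] = v1 * v3
    labels = [lab for t in spec.terms for lab in _term_columns(t, space)]
    X = np.column_stack([cols[lab] for lab in labels]) if labels else np.empty((n, 0))
    return X, labels


def d_criterion(
    conditions: list[Condition],
    spec: ModelSpec,
    space: FactorSpace,
) -> float:
    """det(XᵀX) of the model matrix of `conditions`; 0 if singular.

    Permutation-invariant over runs and strictly positive iff the model
    matrix has full column rank.
    """
    X, labels = model_matrix(conditions, spec, space)
    if len(conditions) < len(labels):
        return 0.0
    M = X.T @ X
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return 0.0
    return float(sign * np.exp(logdet))


def _fedorov_exchange(
    F: np.ndarray,
    idx: np.ndarray,
    max_passes: int = 50,
    rtol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """One monotone Fedorov exchange from starting rows `idx` of candidates F.

    Uses the classic delta formula: exchanging run x_i for candidate x_j
    scales det(XᵀX) by 1 + Δ with
    Δ = d(x_j) − d(x_i) − [d(x_i)d(x_j) − d(x_i,x_j)²],
    where d(u,v) = uᵀ(XᵀX)⁻¹v.  Returns (final indices, log-det).
    """
    X = F[idx]
    M = X.T @ X
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return idx, -np.inf
    Minv = np.linalg.inv(M)
    idx = idx.copy()
    for _ in range(max_passes):
        improved = False
        for pos in range(len(idx)):
            xi = F[idx[pos]]
            G = F @ Minv  # (n_cand, p)
            dj = np.einsum("ij,ij->i", G, F)
            di = float(xi @ Minv @ xi)
            gij = G @ xi
            delta = dj - di - (di * dj - gij**2)
            j = int(np.argmax(delta))
            if delta[j] > rtol:
                idx[pos] = j
                X = F[idx]
                M = X.T @ X
                sign, new_logdet = np.linalg.slogdet(M)
                if sign <= 0:  # numerical breakdown; reject the swap
                    continue
                logdet = new_logdet
                Minv = np.linalg.inv(M)
                improved = True
        if not improved:
            break
    return idx, float(logdet)


def d_optimal_design(
    space: FactorSpace,
    spec: ModelSpec,
    n_runs: int,
    seed: int = 0,
    n_starts: int = 20,
    n_replicates: int = 1,
) -> Design:
    """Exact D-optimal design by multi-start Fedorov exchange.

    Selects `n_runs` conditions (repetition allowed) from the enumerated
    candidate grid, maximizing det(XᵀX) of the model matrix under `spec`.
    Deterministic given `seed`; each random start is improved monotonically
    and the best final design over all starts is returned.
    """
    grid = enumerate_grid(space)
    F, labels = model_matrix(grid, spec, space)
    p = len(labels)
    if n_runs < p:
        raise ValueError(
            f"model is inestimable: {n_runs} runs < {p} model-matrix columns"
        )
    rng = np.random.default_rng(seed)
    best_idx: np.ndarray | None = None
    best_logdet = -np.inf
    for _ in range(n_starts):
        idx = None
        for _attempt in range(100):  # resample until a nonsingular start
            cand = rng.integers(0, len(grid), size=n_runs)
            sign, _ = np.linalg.slogdet(F[cand].T @ F[cand])
            if sign > 0:
                idx = cand
                break
        if idx is None:
            continue
        idx, logdet = _fedorov_exchange(F, idx)
        if logdet > best_logdet:
            best_logdet = logdet
            best_idx = idx
    if best_idx is None:
        raise RuntimeError(
            "no nonsingular starting design found; candidate set may not "
            "support the model"
        )
    runs = tuple(grid[i] for i in sorted(best_idx))
    return Design(runs=runs, n_replicates=n_replicates)
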