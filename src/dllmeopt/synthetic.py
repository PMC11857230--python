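"""Synthetic GC-MS response generator for the DLLME optimization pipeline.

Emulates the statistical structure of a designed DLLME wine-aroma study:
per-run peak areas drawn from a ground-truth linear predictor over the factor
space with multiplicative Gaussian noise (constant CV — precision in this
field is quoted as RSD%), deterministic non-detects for solvents that fail to
form a cloudy ternary emulsion, six-level duplicate internal-standard
calibration series, and paired spiked/unspiked matrix studies with a known
matrix-effect factor, so every downstream stage (model fitting, grid
prediction, ranking, validation mathematics) is testable without wet-lab
data.

It does not simulate chromatograms, retention times or co-elution; the
response is the already-integrated peak area (or area ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Condition, Design, FactorSpace, ModelSpec, model_matrix

__all__ = [
    "ANALYTES",
    "ANALYTE_CLASSES",
    "NEVER_DETECTED",
    "ETHYL_OCTANOATE_TRUTH",
    "GroundTruthModel",
    "SyntheticStudyConfig",
    "generate_design_responses",
    "generate_calibration_samples",
    "generate_matrix_study",
    "make_random_truths",
]

# 36 target aroma compounds, grouped by class
ANALYTE_CLASSES: dict[str, tuple[str, ...]] = {
    "alcohols_aldehydes": (
        "1-butanol",
        "benzaldehyde",
        "benzyl alcohol",
        "isoamyl alcohol",
        "isobutanol",
        "methionol",
        "phenylethyl alcohol",
    ),
    "C6_compounds": (
        "1-hexanol",
        "cis-2-hexen-1-ol",
        "cis-3-hexen-1-ol",
        "hexanal",
        "trans-2-hexen-1-ol",
        "trans-2-hexenal",
        "trans-3-hexen-1-ol",
    ),
    "esters": (
        "ethyl decanoate",
        "ethyl hexanoate",
        "ethyl octanoate",
        "ethyl phenyl acetate",
        "hexyl acetate",
        "isoamyl acetate",
        "beta-phenylethyl acetate",
    ),
    "fatty_acids": (
        "decanoic acid",
        "hexanoic acid",
        "isobutyric acid",
        "isovaleric acid",
        "octanoic acid",
    ),
    "norisoprenoids": ("alpha-ionone", "beta-damascenone", "beta-ionone"),
    "terpenes": ("geraniol", "linalool", "nerol", "alpha-terpineol", "beta-citronellol"),
    "phenols": ("4-ethyl guaiacol", "4-ethyl phenol"),
}

ANALYTES: tuple[str, ...] = tuple(
    a for names in ANALYTE_CLASSES.values() for a in names
)

# analytes below the detection floor in every design run
NEVER_DETECTED: frozenset[str] = frozenset(
    {"beta-citronellol", "trans-2-hexen-1-ol", "geraniol"}
)


@dataclass(frozen=True)
class GroundTruthModel:
    """True linear predictor of one analyte's peak area over the factor space.

    `coefficients` maps model-matrix column labels (e.g. ``"X1[pentane]"``,
    ``"X2"``, ``"X1[pentane]:X2"``) to values; omitted columns are zero.
    Runs whose extraction solvent is in `failing_solvents` are emitted as
    non-detects regardless of the predictor.
    """

    analyte: str
    coefficients: dict[str, float]
    noise_cv: float = 0.05
    failing_solvents: frozenset[str] = frozenset()
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def linear_predictor(self, conditions: list[Condition], space: FactorSpace) -> np.ndarray:
        X, labels = model_matrix(conditions, ModelSpec(), space)
        unknown = set(self.coefficients) - set(labels)
        if unknown:
            raise ValueError(
                f"coefficient labels not constructible from the factor space: "
                f"{sorted(unknown)}"
            )
        beta = np.array([self.coefficients.get(lab, 0.0) for lab in labels])
        return X @ beta


# reduced ethyl octanoate model recovered from the optimization study
# (treatment coding vs chloroform/acetone, raw-µL volumes)
ETHYL_OCTANOATE_TRUTH = GroundTruthModel(
    analyte="ethyl octanoate",
    coefficients={
        "intercept": 58_296.0,
        "X1[CH:P (2:1)]": 36_300.0,
        "X1[DCM]": 3_872.0,
        "X1[hexane]": 13_362.0,
        "X1[pentane]": 173_542.0,
        "X2": 36.0,
        "X3[acetonitrile]": -29_513.0,
        "X3[methanol]": -20_206.0,
        "X1[CH:P (2:1)]:X2": -38.0,
        "X1[DCM]:X2": -18.0,
        "X1[hexane]:X2": 9.0,
        "X1[pentane]:X2": -126.0,
    },
    noise_cv=0.05,
)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-level settings shared by the synthetic generators."""

    seed: int = 0
    n_replicates: int = 3
    analytes: tuple[str, ...] = ANALYTES
    internal_standard_area: float = 100_000.0
    calibration_levels: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    n_calibration_duplicates: int = 2
    spike_levels: dict[str, float] = field(
        default_factory=lambda: {"low": 5.0, "medium": 20.0, "high": 50.0}
    )
    matrix_effect_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        lv = np.asarray(self.calibration_levels, dtype=float)
        if not (np.diff(lv) > 0).all():
            raise ValueError("calibration levels must be strictly increasing")
        if any(v <= 0 for v in self.spike_levels.values()):
            raise ValueError("spike levels must be positive")


def generate_design_responses(
    design: Design,
    truths: list[GroundTruthModel],
    config: SyntheticStudyConfig,
    space: FactorSpace | None = None,
) -> pd.DataFrame:
    """Simulate replicate peak areas for every design run × analyte.

    Mean response is the ground-truth linear predictor at the run's
    condition; the observed area is mean × (1 + ε) with ε ~ N(0, noise_cv²),
    truncated below at zero.  Areas at or below the truth's detection floor,
    and all runs of a failing solvent, are flagged non-detect.  Deterministic
    given ``config.seed``.

    Returns a long-format table: run_id, replicate, analyte, peak_area,
    is_area, area_ratio, non_detect.
    """
    space = space or FactorSpace()
    rng = np.random.default_rng(config.seed)
    conditions = list(design.runs)
    run_ids = design.run_ids
    rows = []
    for truth in truths:
        mu = truth.linear_predictor(conditions, space)
        for i, (rid, cond) in enumerate(zip(run_ids, conditions)):
            for rep in range(1, config.n_replicates + 1):
                eps = rng.normal(0.0, truth.noise_cv) if truth.noise_cv > 0 else 0.0
                is_eps = rng.normal(0.0, truth.noise_cv) if truth.noise_cv > 0 else 0.0
                is_area = config.internal_standard_area * max(1.0 + is_eps, 1e-12)
                if cond.x1 in truth.failing_solvents:
                    rows.append((rid, rep, truth.analyte, np.nan, is_area, np.nan, True))
                    continue
                area = max(mu[i] * (1.0 + eps), 0.0)
                if area <= truth.detection_floor:
                    rows.append((rid, rep, truth.analyte, np.nan, is_area, np.nan, True))
                else:
                    rows.append(
                        (rid, rep, truth.analyte, area, is_area, area / is_area, False)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "replicate",
            "analyte",
            "peak_area",
            "is_area",
            "area_ratio",
            "non_detect",
        ],
    )


def generate_calibration_samples(
    slope: float,
    intercept: float,
    sigma: float,
    levels: tuple[float, ...],
    n_duplicates: int = 2,
    seed: int = 0,
    analyte: str = "analyte",
) -> pd.DataFrame:
    """Simulate an internal-standard calibration series for one analyte.

    area_ratio at level c = intercept + slope·c + N(0, σ²).  The ground-truth
    slope S and residual σ are what the downstream LOD = 3.3σ/S and
    LOQ = 10σ/S estimates should recover.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    lv = np.asarray(levels, dtype=float)
    if len(np.unique(lv)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    if not (np.diff(lv) > 0).all():
        raise ValueError("calibration levels must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for li, c in enumerate(lv, start=1):
        for _dup in range(n_duplicates):
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append((analyte, li, c, intercept + slope * c + noise))
    return pd.DataFrame(
        rows, columns=["analyte", "level_index", "concentration", "area_ratio"]
    )


def generate_matrix_study(
    baseline_concentrations: dict[str, float],
    spike_levels: dict[str, float],
    matrix_effect_factor: float,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
    matrix_id: str = "matrix1",
    slope: float = 1.0,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Simulate a paired spiked/unspiked matrix-effect study.

    The unspiked response encodes each analyte's baseline concentration Cb;
    the spiked response encodes Cb + factor·Cs, so that quantifying both
    through the calibration line and applying R = (Co − Cb)/Cs × 100 recovers
    the matrix-effect factor × 100 exactly at zero noise.
    """
    if matrix_effect_factor <= 0:
        raise ValueError("matrix_effect_factor must be > 0")
    if any(cs <= 0 for cs in spike_levels.values()):
        raise ValueError("spike levels must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for analyte, cb in baseline_concentrations.items():
        for level, cs in spike_levels.items():
            for spiked, conc in ((False, cb), (True, cb + matrix_effect_factor * cs)):
                signal = intercept + slope * conc
                for rep in range(1, n_replicates + 1):
                    eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
                    rows.append(
                        (matrix_id, analyte, spiked, level, rep, signal * (1.0 + eps))
                    )
    return pd.DataFrame(
        rows,
        columns=["matrix_id", "analyte", "spiked", "level", "replicate", "area_ratio"],
    )


def make_random_truths(
    analytes: tuple[str, ...] = ANALYTES,
    seed: int = 0,
    noise_cv: float = 0.05,
    space: FactorSpace | None = None,
    never_detected: frozenset[str] = NEVER_DETECTED,
) -> list[GroundTruthModel]:
    """Seeded ground-truth set for a full 36-analyte demonstration study.

    The printed ethyl octanoate model is packaged verbatim; the remaining
    analytes get randomized reduced models whose qualitative structure
    mirrors the study system: chloroform-family extraction solvents and
    acetonitrile dispersers extract best, response grows with extraction
    volume, disperser volume matters little.  Analytes in `never_detected`
    fail in every run (all extraction solvents failing).
    """
    space = space or FactorSpace()
    rng = np.random.default_rng(seed)
    truths: list[GroundTruthModel] = []
    for analyte in analytes:
        if analyte in never_detected:
            truths.append(
                GroundTruthModel(
                    analyte=analyte,
                    coefficients={"intercept": 0.0},
                    noise_cv=noise_cv,
                    failing_solvents=frozenset(space.extraction_solvent_levels),
                )
            )
            continue
        if analyte == ETHYL_OCTANOATE_TRUTH.analyte:
            truths.append(
                GroundTruthModel(
                    analyte=analyte,
                    coefficients=dict(ETHYL_OCTANOATE_TRUTH.coefficients),
                    noise_cv=noise_cv,
                )
            )
            continue
        base = float(np.exp(rng.normal(np.log(1e5), 0.8)))
        coef: dict[str, float] = {"intercept": base}
        # solvent-type penalties relative to chloroform
        coef["X1[DCM]"] = base * rng.normal(-0.15, 0.08)
        coef["X1[hexane]"] = base * rng.normal(-0.45, 0.10)
        coef["X1[pentane]"] = base * rng.normal(-0.35, 0.10)
        coef["X1[CH:P (2:1)]"] = base * rng.normal(-0.08, 0.06)
        # volume benefit: +0.2..0.8 base over the 500→2000 µL span
        coef["X2"] = base * rng.uniform(0.2, 0.8) / 1500.0
        # disperser: acetonitrile favored over acetone, methanol slightly worse
        coef["X3[acetonitrile]"] = base * rng.normal(0.25, 0.06)
        coef["X3[methanol]"] = base * rng.normal(-0.10, 0.05)
        coef["X4"] = base * rng.normal(0.0, 0.015) / 1000.0
        # non-reference solvents gain less from extra volume
        for lv in ("DCM", "hexane", "pentane", "CH:P (2:1)"):
            coef[f"X1[{lv}]:X2"] = base * rng.normal(-0.05, 0.03) / 1500.0
        truths.append(
            GroundTruthModel(analyte=analyte, coefficients=coef, noise_cv=noise_cv)
        )
    return truths
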