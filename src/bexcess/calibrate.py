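"""Statistical engine: SBE-on-PCO2 regression, ANCOVA, and the beta sweep.

A CO2-invariant base excess should show zero slope when regressed on PCO2.
Because BE(beta) = (HCO3 - 24.8) + (pH - 7.40)*beta is linear in beta, the
pooled OLS slope of BE(beta) on PCO2 decomposes exactly as

    slope(beta) = a + b * beta

where ``a`` is the OLS slope of (HCO3 - 24.8) on PCO2 and ``b`` that of
(pH - 7.40) on PCO2.  The beta sweep evaluates slope(beta) over a dense
grid (default 10,000 points on [5, 20]) and takes the zero crossing
beta* = argmin |slope(beta)| as the in vivo buffer power; the closed form
-a/b is its analytic twin.  The 95% CI on beta* is obtained by test
inversion: the set of grid betas whose slope CI contains zero.  A
delta-method CI for -a/b is reported alongside as a cross-check.

Pooled OLS across subjects is the default (a cluster-robust option is
available); the ANCOVA fits SBE ~ PCO2 * study with dummy coding and
tests study main effects and the study x PCO2 interaction jointly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import DEFAULT_CONSTANTS, AcidBaseConstants, BufferPower, _beta_value
from .simulate import TitrationDataset

__all__ = [
    "RegressionFit",
    "SlopeDecomposition",
    "BetaSweepResult",
    "AncovaResult",
    "SubjectDeltas",
    "DegenerateDesignError",
    "fit_sbe_slope",
    "slope_decomposition",
    "beta_sweep",
    "ancova",
    "max_delta_sbe",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = (5.0, 20.0, 10_000)


class DegenerateDesignError(ValueError):
    """The observation set cannot support the requested fit."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS slope of SBE on PCO2 with its t-based CI and p-value."""

    slope: float
    intercept: float
    slope_se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    dof: int
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "dof": self.dof,
            "level": self.level,
        }


@dataclass(frozen=True)
class SlopeDecomposition:
    """Components of slope(beta) = a + b*beta on one observation set.

    ``a``: slope of (HCO3 - 24.8) on PCO2; ``b``: slope of (pH - 7.40) on
    PCO2.  ``var_a``, ``var_b``, ``cov_ab`` are the OLS sampling
    (co)variances needed for the delta-method CI of -a/b.
    """

    a: float
    b: float
    var_a: float
    var_b: float
    cov_ab: float
    n: int
    dof: int

    @property
    def beta_zero_crossing(self) -> float:
        """Analytic CO2-invariant buffer power -a/b."""
        return -self.a / self.b

    def slope_at(self, beta) -> np.ndarray | float:
        return self.a + self.b * np.asarray(beta, dtype=float)

    def delta_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Delta-method CI for -a/b from the joint (a, b) covariance."""
        g = -self.a / self.b
        grad = np.array([-1.0 / self.b, self.a / self.b**2])
        cov = np.array([[self.var_a, self.cov_ab], [self.cov_ab, self.var_b]])
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))  # guard fp round-off
        t = scipy.stats.t.ppf(0.5 + level / 2.0, self.dof)
        return (g - t * se, g + t * se)


@dataclass(frozen=True)
class BetaSweepResult:
    """slope(beta) over the grid, the zero crossing, and its CIs."""

    grid: np.ndarray = field(repr=False)
    slopes: np.ndarray = field(repr=False)
    beta_star: float
    ci_low: float
    ci_high: float
    grid_spec: tuple[float, float, int]
    level: float = 0.95
    identifiable: bool = True
    ci_degenerate: bool = False
    ci_contiguous: bool = True
    beta_analytic: float = float("nan")
    delta_ci_low: float = float("nan")
    delta_ci_high: float = float("nan")

    def to_dict(self, include_curve: bool = True) -> dict:
        out = {
            "beta_star": self.beta_star,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "grid_spec": list(self.grid_spec),
            "level": self.level,
            "identifiable": self.identifiable,
            "ci_degenerate": self.ci_degenerate,
            "ci_contiguous": self.ci_contiguous,
            "beta_analytic": self.beta_analytic,
            "delta_ci_low": self.delta_ci_low,
            "delta_ci_high": self.delta_ci_high,
        }
        if include_curve:
            out["grid"] = self.grid.tolist()
            out["slopes"] = self.slopes.tolist()
        return out


@dataclass(frozen=True)
class AncovaResult:
    """Joint F-tests for study intercept and slope differences.

    Both tests are computed within the full interaction model
    SBE ~ PCO2 + study + PCO2:study; ``intercept_p_reduced`` is the
    main-effects-only alternative, kept for transparency.
    """

    intercept_f: float
    intercept_p: float
    slope_f: float
    slope_p: float
    intercept_f_reduced: float
    intercept_p_reduced: float
    per_study_fits: dict[str, RegressionFit]
    n: int

    def to_dict(self) -> dict:
        return {
            "intercept_f": self.intercept_f,
            "intercept_p": self.intercept_p,
            "slope_f": self.slope_f,
            "slope_p": self.slope_p,
            "intercept_f_reduced": self.intercept_f_reduced,
            "intercept_p_reduced": self.intercept_p_reduced,
            "n": self.n,
            "per_study_fits": {
                k: v.to_dict() for k, v in self.per_study_fits.items()
            },
        }


@dataclass(frozen=True)
class SubjectDeltas:
    """Per-subject SBE changes from the lowest-PCO2 (baseline) exposure."""

    per_subject: pd.DataFrame = field(repr=False)
    cohort_min: float
    cohort_max: float
    n_subjects: int
    n_excluded: int


def _frame(observations) -> pd.DataFrame:
    if isinstance(observations, TitrationDataset):
        return observations.frame
    return observations


def _sbe_column(
    frame: pd.DataFrame, beta: float, constants: AcidBaseConstants
) -> np.ndarray:
    hco3 = frame["hco3_mmol_l"].to_numpy(dtype=float)
    ph = frame["ph"].to_numpy(dtype=float)
    return (hco3 - constants.hco3_ref) + (ph - constants.ph_ref) * beta


def _check_design(x: np.ndarray) -> None:
    if x.size < 3:
        raise DegenerateDesignError(
            f"need >= 3 observations, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError("pco2 is constant; slope not estimable")


def fit_sbe_slope(
    observations,
    beta: float | BufferPower,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
    *,
    level: float = 0.95,
    cluster_robust: bool = False,
) -> RegressionFit:
    """Pooled OLS of base_excess(HCO3, pH, beta) on PCO2.

    CI and two-sided p-value for the slope come from the t distribution on
    the residual degrees of freedom.  With ``cluster_robust=True`` the
    standard errors are clustered on subject instead (off by default:
    pooled OLS is the primary analysis).
    """
    frame = _frame(observations)
    b = _beta_value(beta)
    x = frame["pco2_mmhg"].to_numpy(dtype=float)
    _check_design(x)
    y = _sbe_column(frame, b, constants)
    X = sm.add_constant(x)
    model = sm.OLS(y, X)
    if cluster_robust:
        groups = (
            frame["study_id"].astype(str) + "/" + frame["subject_id"].astype(str)
        )
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        res = model.fit()
    ci = res.conf_int(alpha=1.0 - level)
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(res.pvalues[1]),
        n=int(res.nobs),
        dof=int(res.df_resid),
        level=level,
    )


def slope_decomposition(
    observations, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> SlopeDecomposition:
    """Closed-form components (a, b) of slope(beta) = a + b*beta.

    Computed from centered sums of products; the joint sampling covariance
    of (a, b) uses the cross-residual moment of the two regressions, which
    share the same design column.
    """
    frame = _frame(observations)
    x = frame["pco2_mmhg"].to_numpy(dtype=float)
    _check_design(x)
    u = frame["hco3_mmol_l"].to_numpy(dtype=float) - constants.hco3_ref
    v = frame["ph"].to_numpy(dtype=float) - constants.ph_ref
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    a = float(xc @ u) / sxx
    b = float(xc @ v) / sxx
    eu = u - u.mean() - a * xc
    ev = v - v.mean() - b * xc
    dof = n - 2
    s_uu = float(eu @ eu) / dof
    s_vv = float(ev @ ev) / dof
    s_uv = float(eu @ ev) / dof
    return SlopeDecomposition(
        a=a,
        b=b,
        var_a=s_uu / sxx,
        var_b=s_vv / sxx,
        cov_ab=s_uv / sxx,
        n=n,
        dof=dof,
    )


def beta_sweep(
    observations,
    grid_spec: tuple[float, float, int] = DEFAULT_GRID,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
    *,
    level: float = 0.95,
    b_identifiability_tol: float = 1e-12,
) -> BetaSweepResult:
    """Evaluate slope(beta) on a uniform inclusive grid and invert for beta*.

    For every grid beta the response BE(beta) is regressed on PCO2 (exact
    OLS via sufficient statistics, vectorized over the grid).  beta* is
    the grid point with minimal |slope| (ties break to the smaller beta);
    the CI is the min/max of {beta : slope CI contains 0}, flagged
    degenerate when that set is empty and non-contiguous when it has gaps.
    When |b| < tol the zero crossing is unidentifiable and flagged.
    """
    frame = _frame(observations)
    lo, hi, n_points = grid_spec
    if not (n_points >= 2 and hi > lo):
        raise ValueError(f"invalid grid_spec {grid_spec}")
    x = frame["pco2_mmhg"].to_numpy(dtype=float)
    _check_design(x)
    u = frame["hco3_mmol_l"].to_numpy(dtype=float) - constants.hco3_ref
    v = frame["ph"].to_numpy(dtype=float) - constants.ph_ref
    n = x.size
    grid = np.linspace(lo, hi, int(n_points))

    xc = x - x.mean()
    uc = u - u.mean()
    vc = v - v.mean()
    sxx = float(xc @ xc)
    sxu = float(xc @ uc)
    sxv = float(xc @ vc)
    # response y(beta) = u + beta*v: slope and residual SS are quadratic in beta
    slopes = (sxu + grid * sxv) / sxx
    syy = float(uc @ uc) + 2.0 * grid * float(uc @ vc) + grid**2 * float(vc @ vc)
    sse = np.maximum(syy - slopes**2 * sxx, 0.0)
    dof = n - 2
    se = np.sqrt(sse / dof / sxx)
    tcrit = scipy.stats.t.ppf(0.5 + level / 2.0, dof)
    contains_zero = np.abs(slopes) <= tcrit * se

    i_star = int(np.argmin(np.abs(slopes)))  # first minimum = smallest beta
    beta_star = float(grid[i_star])

    decomp = slope_decomposition(frame, constants)
    identifiable = abs(decomp.b) >= b_identifiability_tol
    if not identifiable:
        logger.warning(
            "pH-on-PCO2 slope b=%.3g below identifiability tolerance; "
            "beta sweep has no zero crossing",
            decomp.b,
        )

    idx = np.flatnonzero(contains_zero)
    if idx.size == 0:
        logger.warning(
            "test-inversion CI empty on grid [%g, %g]: min |slope|/se = %.3g "
            "at beta=%.4g; reporting degenerate CI",
            lo,
            hi,
            float(np.min(np.abs(slopes) / se)),
            beta_star,
        )
        ci_low = ci_high = float("nan")
        degenerate = True
        contiguous = True
    else:
        ci_low = float(grid[idx[0]])
        ci_high = float(grid[idx[-1]])
        degenerate = False
        contiguous = bool(idx.size == idx[-1] - idx[0] + 1)

    if identifiable:
        delta_lo, delta_hi = decomp.delta_ci(level)
        beta_analytic = decomp.beta_zero_crossing
    else:
        delta_lo = delta_hi = beta_analytic = float("nan")

    return BetaSweepResult(
        grid=grid,
        slopes=slopes,
        beta_star=beta_star,
        ci_low=ci_low,
        ci_high=ci_high,
        grid_spec=(float(lo), float(hi), int(n_points)),
        level=level,
        identifiable=identifiable,
        ci_degenerate=degenerate,
        ci_contiguous=contiguous,
        beta_analytic=beta_analytic,
        delta_ci_low=delta_lo,
        delta_ci_high=delta_hi,
    )


def ancova(
    observations,
    beta: float | BufferPower | None = None,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
    *,
    level: float = 0.95,
) -> AncovaResult:
    """ANCOVA of SBE on PCO2 with study as the grouping factor.

    Fits SBE ~ PCO2 + study + PCO2:study (dummy coding).  ``slope_p`` is
    the joint F-test that all interaction terms vanish (equal slopes);
    ``intercept_p`` the joint F-test of the study main effects within the
    same full model.  ``beta`` defaults to the standard 16.2.
    """
    frame = _frame(observations).copy()
    b = constants.standard_beta if beta is None else _beta_value(beta)
    studies = list(dict.fromkeys(frame["study_id"]))
    if len(studies) < 2:
        raise DegenerateDesignError("ANCOVA requires >= 2 studies")
    for sid in studies:
        sub = frame[frame["study_id"] == sid]
        x = sub["pco2_mmhg"].to_numpy(dtype=float)
        if x.size < 3 or np.ptp(x) == 0:
            raise DegenerateDesignError(
                f"study {sid!r}: need >= 3 observations with varying pco2"
            )
    frame["sbe"] = _sbe_column(frame, b, constants)
    # center the covariate so the study main effects compare SBE at the
    # grand-mean PCO2 rather than at an extrapolated PCO2 = 0
    frame["pco2"] = frame["pco2_mmhg"].astype(float)
    frame["pco2_c"] = frame["pco2"] - frame["pco2"].mean()

    full = smf.ols("sbe ~ pco2_c * C(study_id)", data=frame).fit()
    if full.df_resid <= 0 or np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise DegenerateDesignError("rank-deficient ANCOVA design matrix")
    names = full.model.exog_names
    inter_terms = [nm for nm in names if ":" in nm]
    main_terms = [nm for nm in names if nm.startswith("C(study_id)") and ":" not in nm]
    slope_test = full.f_test([f"{nm} = 0" for nm in inter_terms])
    inter_test = full.f_test([f"{nm} = 0" for nm in main_terms])

    reduced = smf.ols("sbe ~ pco2_c + C(study_id)", data=frame).fit()
    red_names = [
        nm for nm in reduced.model.exog_names if nm.startswith("C(study_id)")
    ]
    red_test = reduced.f_test([f"{nm} = 0" for nm in red_names])
    logger.info(
        "ANCOVA intercept F-test: full model p=%.4g, main-effects model p=%.4g",
        float(inter_test.pvalue),
        float(red_test.pvalue),
    )

    fits = {
        sid: fit_sbe_slope(
            frame[frame["study_id"] == sid], b, constants, level=level
        )
        for sid in studies
    }
    return AncovaResult(
        intercept_f=float(inter_test.fvalue),
        intercept_p=float(inter_test.pvalue),
        slope_f=float(slope_test.fvalue),
        slope_p=float(slope_test.pvalue),
        intercept_f_reduced=float(red_test.fvalue),
        intercept_p_reduced=float(red_test.pvalue),
        per_study_fits=fits,
        n=len(frame),
    )


def max_delta_sbe(
    observations,
    beta: float | BufferPower,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> SubjectDeltas:
    """Per-subject SBE change from the baseline (lowest-PCO2) exposure.

    Returns, per subject, the minimum, maximum, and largest-magnitude
    signed delta across exposures, plus the cohort-wide range.  Subjects
    with a single exposure are excluded with a warning.
    """
    frame = _frame(observations).copy()
    b = _beta_value(beta)
    frame["sbe"] = _sbe_column(frame, b, constants)
    records = []
    n_excluded = 0
    for (sid, subj), grp in frame.groupby(["study_id", "subject_id"], sort=False):
        if len(grp) < 2:
            n_excluded += 1
            warnings.warn(
                f"subject {sid}/{subj} has a single exposure; excluded "
                "from delta-SBE summary",
                stacklevel=2,
            )
            continue
        base = grp.loc[grp["pco2_mmhg"].idxmin()]
        deltas = grp["sbe"] - float(base["sbe"])
        extreme = float(deltas.iloc[np.argmax(np.abs(deltas.to_numpy()))])
        records.append(
            {
                "study_id": sid,
                "subject_id": subj,
                "baseline_pco2_mmhg": float(base["pco2_mmhg"]),
                "delta_min": float(deltas.min()),
                "delta_max": float(deltas.max()),
                "delta_extreme": extreme,
            }
        )
    if not records:
        raise DegenerateDesignError("no subject has >= 2 exposures")
    per_subject = pd.DataFrame.from_records(records)
    return SubjectDeltas(
        per_subject=per_subject,
        cohort_min=float(per_subject["delta_min"].min()),
        cohort_max=float(per_subject["delta_max"].max()),
        n_subjects=len(per_subject),
        n_excluded=n_excluded,
    )
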