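"""Allometric body-mass calibration and prediction from canal radii.

Across mammals, semicircular-canal radius of curvature scales with body
mass; on log-log axes the relationship is close to linear. The calibration
fits ordinary least squares of log10 body mass (grams) on log10 canal radius
(mm), using either the mean radius over the three canals or any subset of
the per-canal radii as predictors. Candidate predictor sets are ranked by
the Amemiya Prediction Criterion

    APC = (RSS / n) * (n + p) / (n - p),

with p counting all estimated coefficients including the intercept; lower is
better. Fossil body masses are predicted with a t-based prediction interval
and converted to kilograms at the reporting boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import CanalmorphError, SelectionError
from .measurements_io import CalibrationTable, SpecimenRecord
from .morphometry import canal_radius, mean_canal_radius

logger = logging.getLogger(__name__)

PREDICTORS = ("mean_radius", "anterior_radius", "posterior_radius", "horizontal_radius")

PredictorSpec = tuple[str, ...]


def _normalize_spec(predictor_spec: str | Sequence[str]) -> PredictorSpec:
    if isinstance(predictor_spec, str):
        predictor_spec = (predictor_spec,)
    spec = tuple(predictor_spec)
    unknown = [p for p in spec if p not in PREDICTORS]
    if unknown:
        raise CanalmorphError(f"unknown predictor(s) {unknown}; choose from {PREDICTORS}")
    if len(set(spec)) != len(spec):
        raise CanalmorphError(f"duplicated predictor in {spec}")
    if not spec:
        raise CanalmorphError("predictor spec is empty")
    return spec


def _log10_radii(rec: SpecimenRecord, spec: PredictorSpec) -> np.ndarray:
    radii = []
    for name in spec:
        if name == "mean_radius":
            radii.append(mean_canal_radius(rec).mean_radius)
        else:
            canal = rec.canal(name.removesuffix("_radius"))  # type: ignore[arg-type]
            radii.append(canal_radius(canal.major_d, canal.minor_d))
    return np.log10(np.asarray(radii, dtype=float))


@dataclass(frozen=True)
class AllometricModel:
    """Fitted log-log calibration: log10 BM(g) = intercept + slopes · log10 R(mm)."""

    predictor_spec: PredictorSpec
    slopes: tuple[float, ...]
    intercept: float
    n: int
    r: float  # Pearson r (single predictor) / sqrt(R²) (multiple)
    r2: float
    adj_r2: float
    apc: float
    resid_sd: float  # sqrt(RSS / (n - p - 1)), log10-gram units
    p_value: float  # two-sided slope t-test (single) / overall F (multiple)
    rss: float
    # calibration geometry needed for prediction intervals / extrapolation flag
    xtx_inv: tuple[tuple[float, ...], ...] = field(repr=False)
    x_min: tuple[float, ...] = field(repr=False)
    x_max: tuple[float, ...] = field(repr=False)

    @property
    def slope(self) -> float:
        """The slope, for single-predictor models."""
        if len(self.slopes) != 1:
            raise CanalmorphError("model has multiple slopes; use .slopes")
        return self.slopes[0]

    def to_text(self) -> str:
        """Serialize as flat key=value lines (single-predictor summary fields)."""
        lines = [
            f"predictors={','.join(self.predictor_spec)}",
            f"intercept={self.intercept!r}",
        ]
        lines += [
            f"slope_{name}={s!r}" for name, s in zip(self.predictor_spec, self.slopes)
        ]
        lines += [
            f"n={self.n}",
            f"r={self.r!r}",
            f"r2={self.r2!r}",
            f"adj_r2={self.adj_r2!r}",
            f"apc={self.apc!r}",
            f"resid_sd={self.resid_sd!r}",
            f"p_value={self.p_value!r}",
            f"rss={self.rss!r}",
            "xtx_inv=" + ";".join(",".join(repr(v) for v in row) for row in self.xtx_inv),
            "x_min=" + ",".join(repr(v) for v in self.x_min),
            "x_max=" + ",".join(repr(v) for v in self.x_max),
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AllometricModel":
        kv = dict(line.split("=", 1) for line in text.strip().splitlines())
        spec = tuple(kv["predictors"].split(","))
        return cls(
            predictor_spec=spec,
            slopes=tuple(float(kv[f"slope_{name}"]) for name in spec),
            intercept=float(kv["intercept"]),
            n=int(kv["n"]),
            r=float(kv["r"]),
            r2=float(kv["r2"]),
            adj_r2=float(kv["adj_r2"]),
            apc=float(kv["apc"]),
            resid_sd=float(kv["resid_sd"]),
            p_value=float(kv["p_value"]),
            rss=float(kv["rss"]),
            xtx_inv=tuple(
                tuple(float(v) for v in row.split(","))
                for row in kv["xtx_inv"].split(";")
            ),
            x_min=tuple(float(v) for v in kv["x_min"].split(",")),
            x_max=tuple(float(v) for v in kv["x_max"].split(",")),
        )


@dataclass(frozen=True)
class BodyMassEstimate:
    specimen_id: str
    log10_bm_grams: float
    bm_kg: float
    pi_low_kg: float
    pi_high_kg: float
    extrapolated: bool  # predictor outside the calibration range
    alpha: float = 0.05


def amemiya_pc(rss: float, n: int, p: int) -> float:
    """Amemiya Prediction Criterion (RSS/n)·(n+p)/(n−p); p includes the intercept."""
    if rss < 0:
        raise CanalmorphError(f"rss must be non-negative, got {rss}")
    if n <= p:
        raise CanalmorphError(f"need n > p, got n={n}, p={p}")
    return (rss / n) * (n + p) / (n - p)


def fit_allometry(
    cal: CalibrationTable, predictor_spec: str | Sequence[str] = "mean_radius"
) -> AllometricModel:
    """Closed-form OLS of log10 body mass on the chosen log10 radii."""
    spec = _normalize_spec(predictor_spec)
    p_coef = len(spec) + 1  # coefficients incl. intercept
    n = len(cal)
    if n <= p_coef:
        raise CanalmorphError(f"need n > {p_coef} records for {spec}, got {n}")
    X = np.array([_log10_radii(rec, spec) for rec in cal.records])
    y = np.array([rec.log10_bm_grams for rec in cal.records], dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CanalmorphError(f"collinear predictors in {spec}")
    fit = sm.OLS(y, design).fit()
    rss = float(fit.ssr)
    r2 = float(fit.rsquared)
    if len(spec) == 1:
        r = float(np.corrcoef(X[:, 0], y)[0, 1])
        p_value = float(fit.pvalues[1])
    else:
        r = math.sqrt(r2)
        p_value = float(fit.f_pvalue)
    xtx_inv = np.linalg.inv(design.T @ design)
    return AllometricModel(
        predictor_spec=spec,
        slopes=tuple(float(b) for b in fit.params[1:]),
        intercept=float(fit.params[0]),
        n=n,
        r=r,
        r2=r2,
        adj_r2=float(fit.rsquared_adj),
        apc=amemiya_pc(rss, n, p_coef),
        resid_sd=float(np.sqrt(fit.mse_resid)),
        p_value=p_value,
        rss=rss,
        xtx_inv=tuple(tuple(float(v) for v in row) for row in xtx_inv),
        x_min=tuple(float(v) for v in X.min(axis=0)),
        x_max=tuple(float(v) for v in X.max(axis=0)),
    )


def rank_models_apc(
    cal: CalibrationTable, candidates: Sequence[str | Sequence[str]]
) -> list[AllometricModel]:
    """Fit every candidate and rank by APC (ties: fewer predictors, then
    declaration order)."""
    if not candidates:
        raise SelectionError("no candidate predictor specs supplied")
    fitted: list[tuple[float, int, int, AllometricModel]] = []
    for order, cand in enumerate(candidates):
        try:
            model = fit_allometry(cal, cand)
        except CanalmorphError as exc:
            logger.warning("candidate %r skipped: %s", cand, exc)
            continue
        fitted.append((model.apc, len(model.predictor_spec), order, model))
    if not fitted:
        raise SelectionError("every candidate model failed to fit")
    fitted.sort(key=lambda t: t[:3])
    ranking = [m for *_, m in fitted]
    for rank, m in enumerate(ranking, start=1):
        logger.info(
            "APC rank %d: %s apc=%.6g r2=%.4f", rank, m.predictor_spec, m.apc, m.r2
        )
    return ranking


DEFAULT_CANDIDATES: tuple[PredictorSpec, ...] = (
    ("mean_radius",),
    ("anterior_radius",),
    ("posterior_radius",),
    ("horizontal_radius",),
    ("anterior_radius", "posterior_radius"),
    ("anterior_radius", "horizontal_radius"),
    ("posterior_radius", "horizontal_radius"),
    ("anterior_radius", "posterior_radius", "horizontal_radius"),
)


def select_model_apc(
    cal: CalibrationTable,
    candidates: Sequence[str | Sequence[str]] = DEFAULT_CANDIDATES,
) -> AllometricModel:
    """Return the minimum-APC model among the candidates."""
    return rank_models_apc(cal, candidates)[0]


def predict_body_mass(
    model: AllometricModel, rec: SpecimenRecord, alpha: float = 0.05
) -> BodyMassEstimate:
    """Point prediction and t prediction interval for one specimen.

    PI = point ± t(1-alpha/2, n-p-1) · resid_sd · sqrt(1 + leverage) on the
    log10-gram scale, then converted to kg. Predictors outside the
    calibration range set ``extrapolated`` (a flag, not an error).
    """
    from scipy import stats

    if not (0.0 < alpha < 1.0):
        raise CanalmorphError(f"alpha must be in (0, 1), got {alpha}")
    x = _log10_radii(rec, model.predictor_spec)
    x0 = np.concatenate([[1.0], x])
    point = float(x0 @ np.concatenate([[model.intercept], model.slopes]))
    leverage = float(x0 @ np.asarray(model.xtx_inv) @ x0)
    df = model.n - len(model.slopes) - 1
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    half = t_crit * model.resid_sd * math.sqrt(1.0 + leverage)
    extrapolated = bool(
        np.any(x < np.asarray(model.x_min)) or np.any(x > np.asarray(model.x_max))
    )
    if extrapolated:
        logger.warning(
            "%s: predictor value outside the calibration range; prediction is "
            "an extrapolation",
            rec.specimen_id,
        )
    to_kg = lambda log10_g: 10.0**log10_g / 1000.0  # noqa: E731
    return BodyMassEstimate(
        specimen_id=rec.specimen_id,
        log10_bm_grams=point,
        bm_kg=to_kg(point),
        pi_low_kg=to_kg(point - half),
        pi_high_kg=to_kg(point + half),
        extrapolated=extrapolated,
        alpha=alpha,
    )
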