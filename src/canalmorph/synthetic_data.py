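"""Seeded generators for synthetic measurement datasets.

Two generators cover the two halves of the analysis:

* :func:`gen_labyrinth_dataset` emulates the replicated-measurement study —
  a few specimens, each with fixed canal ellipses, five replicate lumen
  diameters per canal and five replicate inter-canal angles per pair, with
  independent Gaussian measurement noise around the true values. Defaults
  mirror the observed panels: angles within ~1–2° of 90° with session noise
  SD 0.8°, lumen diameters 0.4–0.7 mm with noise SD 0.08 mm.
* :func:`gen_allometric_dataset` emulates the extant-mammal calibration —
  log10 radii uniform over the observed range, log10 body mass linear in
  log10 radius with Gaussian residuals (defaults: slope 5.78, intercept
  4.18, residual SD 1.0, n = 32). Canal diameters are constructed so each
  record's mean radius reproduces its drawn log10 radius exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CanalmorphError
from .measurements_io import (
    ANGLE_VARIABLES,
    CANAL_IDS,
    LUMEN_VARIABLES,
    CalibrationTable,
    CanalEllipse,
    ReplicatePanel,
    SpecimenRecord,
)


@dataclass(frozen=True)
class LabyrinthSimConfig:
    """Conditions for the replicated-measurement simulation.

    ``true_angles`` are (anterior–horizontal, posterior–horizontal,
    anterior–posterior) in degrees; ``true_lumen`` are the (anterior,
    posterior, horizontal) lumen diameters in mm; ``true_ellipses`` the
    (major, minor) axis diameters in mm per canal.
    """

    n_specimens: int = 3
    n_reps: int = 5
    true_angles: tuple[float, float, float] = (91.2, 90.3, 89.3)
    angle_noise_sd: float = 0.8  # degrees
    true_lumen: tuple[float, float, float] = (0.72, 0.41, 0.69)
    lumen_noise_sd: float = 0.08  # mm
    true_ellipses: tuple[tuple[float, float], ...] = (
        (5.1, 2.5),
        (4.3, 1.9),
        (3.2, 1.8),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.angle_noise_sd < 0 or self.lumen_noise_sd < 0:
            raise CanalmorphError("noise SDs must be non-negative")
        if self.n_specimens < 1 or self.n_reps < 1:
            raise CanalmorphError("need at least one specimen and one replicate")
        for maj, mnr in self.true_ellipses:
            if not (maj >= mnr > 0):
                raise CanalmorphError(f"invalid ellipse axes ({maj}, {mnr})")


@dataclass(frozen=True)
class AllometrySimConfig:
    """Conditions for the synthetic allometric calibration set."""

    n_taxa: int = 32
    slope: float = 5.78
    intercept: float = 4.18  # log10 grams at R = 1 mm
    resid_sd: float = 1.0  # log10-gram units
    log_radius_range: tuple[float, float] = (-0.6, 0.31)
    eccentricity: float = 0.6  # shared by the synthetic canal outlines
    canal_radius_spread: float = 0.05  # log-normal sigma of per-canal jitter
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.log_radius_range
        if not (low < high):
            raise CanalmorphError("log_radius_range must be (low, high) with low < high")
        if self.resid_sd < 0 or self.canal_radius_spread < 0:
            raise CanalmorphError("spread parameters must be non-negative")
        if not (0.0 <= self.eccentricity < 1.0):
            raise CanalmorphError("eccentricity must be in [0, 1)")


def gen_labyrinth_dataset(cfg: LabyrinthSimConfig) -> list[SpecimenRecord]:
    """Simulate specimens with replicated angle and lumen panels.

    Each replicate is the true value plus independent Gaussian noise;
    identical seeds give identical datasets.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    for s in range(cfg.n_specimens):
        canals = {
            cid: CanalEllipse(canal_id=cid, major_d=maj, minor_d=mnr)
            for cid, (maj, mnr) in zip(CANAL_IDS, cfg.true_ellipses)
        }
        panels = {}
        for vid, mu in zip(LUMEN_VARIABLES, cfg.true_lumen):
            vals = mu + cfg.lumen_noise_sd * rng.standard_normal(cfg.n_reps)
            panels[vid] = ReplicatePanel(variable_id=vid, values=tuple(vals))
        for vid, mu in zip(ANGLE_VARIABLES, cfg.true_angles):
            vals = mu + cfg.angle_noise_sd * rng.standard_normal(cfg.n_reps)
            panels[vid] = ReplicatePanel(variable_id=vid, values=tuple(vals))
        records.append(
            SpecimenRecord(
                specimen_id=f"SIM-{s + 1:03d}", taxon="Simulatus", canals=canals,
                panels=panels,
            )
        )
    return records


def _ellipse_from_radius(canal_id: str, radius: float, e: float) -> CanalEllipse:
    """Axes (major + minor)/4 = radius with the requested eccentricity."""
    q = math.sqrt(1.0 - e * e)  # minor/major ratio
    major = 4.0 * radius / (1.0 + q)
    return CanalEllipse(canal_id=canal_id, major_d=major, minor_d=q * major)


def gen_allometric_dataset(cfg: AllometrySimConfig) -> CalibrationTable:
    """Simulate an extant calibration table with a known true allometry.

    log10 radii are uniform over ``log_radius_range``; log10 BM(g) =
    intercept + slope·x + N(0, resid_sd). Per-canal radii are jittered
    around the target but rescaled so the three-canal mean radius equals
    10^x exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    low, high = cfg.log_radius_range
    x = rng.uniform(low, high, size=cfg.n_taxa)
    y = cfg.intercept + cfg.slope * x + cfg.resid_sd * rng.standard_normal(cfg.n_taxa)
    records = []
    for i in range(cfg.n_taxa):
        mean_r = 10.0 ** x[i]
        jitter = np.exp(cfg.canal_radius_spread * rng.standard_normal(3))
        radii = mean_r * jitter / jitter.mean()
        canals = {
            cid: _ellipse_from_radius(cid, r, cfg.eccentricity)
            for cid, r in zip(CANAL_IDS, radii)
        }
        records.append(
            SpecimenRecord(
                specimen_id=f"SIMTAX-{i + 1:03d}",
                taxon=f"Simulatus{i + 1:03d}",
                canals=canals,
                log10_bm_grams=float(y[i]),
                bm_estimated=False,
            )
        )
    return CalibrationTable(records=records)
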