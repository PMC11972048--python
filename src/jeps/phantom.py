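"""Synthetic multimodal patient cohorts with known ground truth.

Each phantom patient carries the three modalities a radiotherapy outcome
model consumes — a pseudo-CT volume with a tumor, a peaked dose field
scaled to the prescription, planning structures (PTV plus both parotid
glands) — together with a tabular clinical record and a survival outcome
generated from a known logistic model:

    logit(p_death) = b0 + bt*z_tab + bs*z_vol + bi*z_tab*z_vol + noise

where ``z_tab`` is a standardized tabular risk score (partially observable
through the clinical fields) and ``z_vol`` is a standardized spatial
feature: the fraction of tumor voxels receiving less than 90% of the
prescribed dose (the "cold-margin fraction").  The cold margin is
invisible to tabular-only models and is destroyed by intensity-only
summaries unless the dose channel is present, so recovering it separates
the fusion designs.  The intercept ``b0`` is calibrated so the cohort's
expected death prevalence matches the configured value.

Outcomes are generated as exponential time-to-event and binarized at 24
months, so proportional-hazards baselines receive genuine (time, event)
pairs.  Follow-up always exceeds 24 months: no case is censored before
the endpoint.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, special

AIR_HU = -1000.0
TISSUE_HU = 40.0
BONE_HU = 700.0
TUMOR_HU = 60.0
PAROTID_HU = 30.0

#: numeric and categorical clinical fields emitted for every patient
CLINICAL_SCHEMA: dict[str, str] = {
    "age": "numeric",
    "weight_kg": "numeric",
    "sex": "categorical",
    "smoking": "categorical",
    "hpv_status": "categorical",
    "overall_stage": "categorical",
    "disease_site": "categorical",
    "marital_status": "categorical",
}


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 222
    grid_shape: tuple[int, int, int] = (46, 64, 64)     # (depth, height, width)
    spacing_mm: tuple[float, float, float] = (2.5, 2.0, 2.0)
    prevalence: float = 63 / 222
    tabular_effect: float = 1.5
    spatial_effect: float = 1.5
    interaction_effect: float = 1.0
    noise_sd: float = 0.5
    prescribed_dose_gy: float = 70.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be strictly between 0 and 1")
        if any(g <= 0 for g in self.grid_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid_shape and spacing_mm must be positive")
        for name in ("tabular_effect", "spatial_effect", "interaction_effect", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.prescribed_dose_gy <= 0:
            raise ValueError("prescribed_dose_gy must be positive")
        if min(self.grid_shape) < 8:
            raise ValueError(
                f"grid {self.grid_shape} too small to contain the anatomy template "
                "(need at least 8 voxels per axis)")


#: reduced profile used throughout tests and the reproduction scripts so a
#: full cross-validated comparison trains in minutes on one CPU core
MICRO_GRID = (12, 16, 16)
MICRO_SPACING = (10.0, 9.0, 9.0)


def micro_config(**overrides) -> PhantomConfig:
    base = dict(n_patients=200, grid_shape=MICRO_GRID, spacing_mm=MICRO_SPACING)
    base.update(overrides)
    return PhantomConfig(**base)


@dataclass
class PhantomPatient:
    patient_id: str
    ct_volume: np.ndarray                  # pseudo-HU, (D, H, W)
    dose_volume: np.ndarray                # Gy, (D, H, W)
    structures: dict[str, list]            # ROI name -> list of (z_mm, polygon Nx2 in mm)
    clinical: dict[str, object]
    ipsilateral_side: str
    survival_months: float
    event: int
    label_2yr: int
    true_risk: float = field(repr=False, default=float("nan"))
    z_tab: float = field(repr=False, default=float("nan"))
    z_vol: float = field(repr=False, default=float("nan"))


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm):
    zz, yy, xx = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                             indexing="ij")
    return (((zz - center_mm[0]) / radii_mm[0]) ** 2
            + ((yy - center_mm[1]) / radii_mm[1]) ** 2
            + ((xx - center_mm[2]) / radii_mm[2]) ** 2) <= 1.0


def _ellipse_polygon(center_yx_mm, radii_yx_mm, n_vertices=24):
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.stack([center_yx_mm[1] + radii_yx_mm[1] * np.cos(th),
                     center_yx_mm[0] + radii_yx_mm[0] * np.sin(th)], axis=1)  # (x, y) mm


def _ellipsoid_contours(shape, spacing, center_mm, radii_mm):
    """Per-slice elliptical contours of an ellipsoid, tagged with z position."""
    contours = []
    for k in range(shape[0]):
        z = k * spacing[0]
        dz = (z - center_mm[0]) / radii_mm[0]
        if abs(dz) >= 1.0:
            continue
        scale = np.sqrt(1.0 - dz * dz)
        poly = _ellipse_polygon((center_mm[1], center_mm[2]),
                                (radii_mm[1] * scale, radii_mm[2] * scale))
        contours.append((z, poly))
    return contours


def _patient_anatomy(cfg: PhantomConfig, rng: np.random.Generator):
    """CT volume, dose field, structures and the spatial risk feature."""
    shape, sp = cfg.grid_shape, cfg.spacing_mm
    extent = np.array(shape) * np.array(sp)              # physical mm
    # head: large soft-tissue ellipsoid with a thin bone shell
    head_c = extent / 2.0
    head_r = extent * np.array([0.46, 0.40, 0.38])
    head = _ellipsoid_mask(shape, sp, head_c, head_r)
    shell = _ellipsoid_mask(shape, sp, head_c, head_r) & ~_ellipsoid_mask(
        shape, sp, head_c, head_r * 0.88)
    ct = np.full(shape, AIR_HU, dtype=np.float32)
    ct[head] = TISSUE_HU
    ct[shell] = BONE_HU
    ct += rng.normal(0.0, 12.0, size=shape).astype(np.float32) * head

    side = "left" if rng.random() < 0.5 else "right"
    lateral_sign = -1.0 if side == "left" else 1.0      # width axis offset

    # tumor: ellipsoid near the midline, offset toward the ipsilateral side
    tumor_r = rng.uniform(0.10, 0.16, size=3) * extent
    tumor_c = head_c + np.array([
        rng.uniform(-0.08, 0.08) * extent[0],
        rng.uniform(0.00, 0.12) * extent[1],
        lateral_sign * rng.uniform(0.04, 0.12) * extent[2],
    ])
    tumor = _ellipsoid_mask(shape, sp, tumor_c, tumor_r) & head
    if not tumor.any():
        tumor = _ellipsoid_mask(shape, sp, head_c, tumor_r)
    ct[tumor] = TUMOR_HU + rng.normal(0, 6.0, size=int(tumor.sum())).astype(np.float32)

    # parotid glands: small ellipsoids lateral of the midline at tumor depth
    par_r = extent * np.array([0.10, 0.08, 0.06])
    parotids = {}
    for name, sgn in (("Parotid_L", -1.0), ("Parotid_R", 1.0)):
        c = head_c + np.array([rng.uniform(-0.03, 0.03) * extent[0],
                               0.0, sgn * 0.24 * extent[2]])
        parotids[name] = (c, par_r)

    # dose: smooth peaked field centered near (but not exactly on) the tumor
    offset = rng.normal(0.0, 0.25, size=3) * tumor_r
    dose_c = tumor_c + offset
    dose_width = tumor_r * rng.uniform(1.1, 1.7)
    zz, yy, xx = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, sp)), indexing="ij")
    r2 = (((zz - dose_c[0]) / dose_width[0]) ** 2
          + ((yy - dose_c[1]) / dose_width[1]) ** 2
          + ((xx - dose_c[2]) / dose_width[2]) ** 2)
    dose = np.exp(-0.5 * r2).astype(np.float32)
    dose *= cfg.prescribed_dose_gy * rng.uniform(0.96, 1.0) / dose.max()

    # spatial risk feature: fraction of tumor voxels below 90% of prescription
    cold_fraction = float((dose[tumor] < 0.9 * cfg.prescribed_dose_gy).mean())

    structures = {
        "PTV": _ellipsoid_contours(shape, sp, tumor_c, tumor_r),
        "Parotid_L": _ellipsoid_contours(shape, sp, *parotids["Parotid_L"]),
        "Parotid_R": _ellipsoid_contours(shape, sp, *parotids["Parotid_R"]),
    }
    return ct, dose, structures, side, cold_fraction


def _clinical_record(z_tab: float, rng: np.random.Generator) -> dict[str, object]:
    """Observable fields correlated with the latent tabular risk score."""
    rec = {
        "age": round(float(62.0 + 8.0 * (0.7 * z_tab + 0.7 * rng.normal())), 1),
        "weight_kg": round(float(85.0 - 10.0 * (0.5 * z_tab + 0.9 * rng.normal())), 1),
        "sex": "male" if rng.random() < 0.8 else "female",
        "marital_status": rng.choice(["married", "single", "divorced", "other"],
                                     p=[0.55, 0.28, 0.08, 0.09]),
    }
    u = z_tab + rng.normal(0, 0.8)
    rec["smoking"] = "current" if u > 0.8 else ("former" if u > -0.3 else "never")
    v = -z_tab + rng.normal(0, 0.8)
    rec["hpv_status"] = "positive" if v > 0.0 else ("negative" if v > -1.2 else "unknown")
    w = z_tab + rng.normal(0, 0.9)
    rec["overall_stage"] = ("IV" if w > 0.5 else "III" if w > -0.4 else
                            "II" if w > -1.1 else "I")
    rec["disease_site"] = rng.choice(["pharynx", "larynx", "other"], p=[0.72, 0.18, 0.10])
    return rec


def generate_cohort(config: PhantomConfig) -> list[PhantomPatient]:
    """Generate a deterministic cohort of phantom patients."""
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    patient_seeds = master.spawn(cfg.n_patients)

    patients, z_tabs, colds = [], [], []
    for i, ss in enumerate(patient_seeds):
        rng = np.random.default_rng(ss)
        z_tab = float(rng.normal())
        ct, dose, structures, side, cold = _patient_anatomy(cfg, rng)
        clinical = _clinical_record(z_tab, rng)
        patients.append(PhantomPatient(
            patient_id=f"P{i:04d}", ct_volume=ct, dose_volume=dose,
            structures=structures, clinical=clinical, ipsilateral_side=side,
            survival_months=np.nan, event=0, label_2yr=0))
        z_tabs.append(z_tab)
        colds.append(cold)

    z_tab = np.asarray(z_tabs)
    cold = np.asarray(colds)
    z_vol = (cold - cold.mean()) / max(cold.std(), 1e-9)

    outcome_rng = np.random.default_rng(master.spawn(1)[0])
    noise = outcome_rng.normal(0.0, cfg.noise_sd, size=cfg.n_patients)
    lin = (cfg.tabular_effect * z_tab + cfg.spatial_effect * z_vol
           + cfg.interaction_effect * z_tab * z_vol + noise)

    def excess(b0):
        return special.expit(b0 + lin).mean() - cfg.prevalence
    b0 = optimize.brentq(excess, -30.0, 30.0)
    risk = special.expit(b0 + lin)

    u = outcome_rng.random(cfg.n_patients)
    rate = -np.log1p(-risk) / 24.0                      # P(T <= 24) = risk
    t_death = -np.log(u) / np.maximum(rate, 1e-12)
    followup = outcome_rng.uniform(30.0, 84.0, size=cfg.n_patients)
    for p, td, fu, r, zt, zv in zip(patients, t_death, followup, risk, z_tab, z_vol):
        event = int(td <= fu)
        p.survival_months = float(min(td, fu))
        p.event = event
        p.label_2yr = int(event == 1 and p.survival_months <= 24.0)
        p.true_risk = float(r)
        p.z_tab = float(zt)
        p.z_vol = float(zv)
    return patients


def true_risk(patient: PhantomPatient, config: PhantomConfig) -> float:
    """Generating-model probability of death within 24 months."""
    r = patient.true_risk
    if not np.isfinite(r):
        raise ValueError("patient was not generated with an attached risk")
    return r


def write_manifest(patients: list[PhantomPatient], path) -> None:
    """One row per patient: id, outcome, side, and the clinical fields."""
    path = Path(path)
    fields = list(CLINICAL_SCHEMA)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label_2yr", "survival_months", "event",
                    "ipsilateral_side"] + fields)
        for p in patients:
            w.writerow([p.patient_id, p.label_2yr, f"{p.survival_months:.3f}",
                        p.event, p.ipsilateral_side]
                       + [p.clinical[f] for f in fields])


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
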