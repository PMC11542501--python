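"""Synthetic OCT B-scan generator with ground-truth boundaries and masks.

Generates grayscale B-scans that emulate the gross structure of macular OCT:
stacked horizontal layer strata with smooth, non-crossing boundaries, a
Gaussian foveal dip of the inner layers, per-layer reflectivity, multiplicative
speckle noise, and — for diseased eyes — hyporeflective intraretinal cysts,
collapse of the outer layers, pre-retinal space and background below the RPE.
A "patient" is a group of scans sharing one geometry draw (layer thicknesses
and reflectivities), which creates within-patient correlation and makes
patient-level dataset splitting meaningful.

The generator makes no claim of physical speckle statistics or of disease
morphometry; it provides a controllable substrate on which segmentation
training schemes can be compared end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError
from .preprocess import (
    CANONICAL_BOUNDARIES,
    BoundarySet,
    ClassMask,
    boundaries_to_mask,
)
from .scheme import BACKGROUND, COLLAPSED, CYST, PRERETINAL

#: anatomical layer order matching CANONICAL_BOUNDARIES[:-1]
LAYERS = CANONICAL_BOUNDARIES[:-1]


@dataclass
class SimulationParams:
    """Geometry, optics and pathology parameters of the simulator.

    Thicknesses and all lengths are in pixels; reflectivities are arbitrary
    intensity units in [0, 1].  Defaults describe a 64x64 desk-scale scan with
    the ten layers occupying ~40 rows between the pre-retinal space and the
    background below the RPE.
    """

    height: int = 64
    width: int = 64
    #: mean thickness per layer, top to bottom (ILM..RPE)
    layer_thickness: tuple[float, ...] = (2, 5, 6, 5, 5, 4, 2, 3, 3, 4)
    #: mean reflectivity per layer, top to bottom
    layer_reflectivity: tuple[float, ...] = (
        0.75, 0.85, 0.35, 0.55, 0.28, 0.60, 0.70, 0.85, 0.40, 0.95,
    )
    preretinal_reflectivity: float = 0.04
    background_reflectivity: float = 0.10
    collapsed_reflectivity: float = 0.20
    cyst_reflectivity: float = 0.05
    #: relative sd of the per-patient thickness draw
    thickness_jitter: float = 0.12
    #: sd (pixels) of the smooth low-frequency boundary perturbation
    boundary_smoothness: float = 1.5
    fovea_depth: float = 6.0
    fovea_width: float = 8.0
    #: multiplicative speckle strength (dimensionless)
    speckle: float = 0.15
    #: mean depth of the ILM below the top of the scan
    top_margin: float = 10.0
    cyst_count_range: tuple[int, int] = (1, 3)
    cyst_semiaxis_rows: tuple[float, float] = (2.0, 5.0)
    cyst_semiaxis_cols: tuple[float, float] = (3.0, 8.0)
    collapse_prob: float = 0.5
    collapse_extent: tuple[int, int] = (8, 20)
    disease_prevalence: float = 0.5

    def validate(self) -> None:
        t = np.asarray(self.layer_thickness, dtype=float)
        if t.size != len(LAYERS):
            raise ParameterError(
                f"layer_thickness needs {len(LAYERS)} entries, got {t.size}"
            )
        if np.any(t <= 0):
            raise ParameterError("all layer thicknesses must be > 0")
        if len(self.layer_reflectivity) != len(LAYERS):
            raise ParameterError("one reflectivity per layer required")
        if self.top_margin + t.sum() + self.fovea_depth > self.height:
            raise ParameterError(
                "sum of mean thicknesses plus margins exceeds image height"
            )
        if self.speckle < 0:
            raise ParameterError("speckle strength must be >= 0")
        if not 0.0 <= self.disease_prevalence <= 1.0:
            raise ParameterError("disease_prevalence must lie in [0, 1]")
        if self.cyst_count_range[0] < 0 or self.cyst_count_range[1] < self.cyst_count_range[0]:
            raise ParameterError("cyst_count_range must be a non-negative ordered pair")
        for lo, hi in (self.cyst_semiaxis_rows, self.cyst_semiaxis_cols):
            if lo <= 0 or hi < lo:
                raise ParameterError("cyst semi-axis ranges must be positive and ordered")
        if not 0.0 <= self.collapse_prob <= 1.0:
            raise ParameterError("collapse_prob must lie in [0, 1]")

    def reflectivity_table(self) -> np.ndarray:
        """Reflectivity per class id 0..13."""
        table = np.zeros(14)
        table[PRERETINAL] = self.preretinal_reflectivity
        for i, r in enumerate(self.layer_reflectivity):
            table[i + 1] = r
        table[BACKGROUND] = self.background_reflectivity
        table[COLLAPSED] = self.collapsed_reflectivity
        table[CYST] = self.cyst_reflectivity
        return table


@dataclass
class PatientGeometry:
    """One patient's layer thicknesses and reflectivities."""

    thickness: np.ndarray
    reflectivity: np.ndarray

    @classmethod
    def draw(cls, params: SimulationParams, rng: np.random.Generator) -> "PatientGeometry":
        base = np.asarray(params.layer_thickness, dtype=float)
        jitter = 1.0 + params.thickness_jitter * rng.standard_normal(base.size)
        thickness = np.clip(base * jitter, 1.0, None)
        # rescale so the retina never outgrows the scan for this patient
        budget = params.height - params.top_margin - params.fovea_depth - 2.0
        if thickness.sum() > budget:
            thickness *= budget / thickness.sum()
        refl = np.clip(
            np.asarray(params.layer_reflectivity)
            + 0.03 * rng.standard_normal(base.size),
            0.05,
            1.0,
        )
        return cls(thickness=thickness, reflectivity=refl)


@dataclass
class SyntheticSample:
    """One generated B-scan with its ground truth and provenance."""

    image: np.ndarray
    boundaries: BoundarySet
    mask: ClassMask
    patient_id: str
    eye: str
    diseased: bool
    fovea_col: int
    params: SimulationParams
    seed: int

    def learned_mask(self) -> ClassMask:
        """The 13-class view of the ground truth: cyst pixels revert to the
        layer class implied by the boundaries (collapse, id 12, is learned)."""
        labels = self.mask.labels.copy()
        cysts = labels == CYST
        if cysts.any():
            base = boundaries_to_mask(self.boundaries, labels.shape[0]).labels
            labels[cysts] = base[cysts]
        return ClassMask(labels, provenance="ground_truth")


def _smooth_profile(rng: np.random.Generator, width: int, amplitude: float) -> np.ndarray:
    """Low-frequency random profile with standard deviation ``amplitude``."""
    if amplitude <= 0:
        return np.zeros(width)
    g = gaussian_filter1d(rng.standard_normal(width), sigma=max(width / 10.0, 1.0),
                          mode="reflect")
    sd = g.std()
    if sd < 1e-9:
        return np.zeros(width)
    return g * (amplitude / sd)


def _build_boundaries(
    params: SimulationParams,
    geometry: PatientGeometry,
    rng: np.random.Generator,
    fovea_col: int,
) -> BoundarySet:
    w = params.width
    x = np.arange(w)
    shared = _smooth_profile(rng, w, params.boundary_smoothness)
    if params.fovea_depth > 0:
        dip = params.fovea_depth * np.exp(
            -0.5 * ((x - fovea_col) / max(params.fovea_width, 1e-6)) ** 2
        )
    else:
        dip = np.zeros(w)

    n_lines = len(LAYERS) + 1
    depths = np.empty((n_lines, w))
    cum = params.top_margin + np.concatenate([[0.0], np.cumsum(geometry.thickness)])
    # the dip thins the inner layers: full displacement at the ILM, tapering
    # to zero by the ELM (line index 6)
    taper = np.clip(1.0 - np.arange(n_lines) / 7.0, 0.0, 1.0)
    for k in range(n_lines):
        wiggle = _smooth_profile(rng, w, params.boundary_smoothness / 3.0)
        depths[k] = cum[k] + shared + taper[k] * dip + wiggle
    # enforce non-crossing with a minimum 1-px layer thickness, then bounds
    for k in range(1, n_lines):
        depths[k] = np.maximum(depths[k], depths[k - 1] + 1.0)
    depths = np.clip(depths, 0.0, params.height)
    for k in range(1, n_lines):  # re-assert ordering after the clip
        depths[k] = np.maximum(depths[k], depths[k - 1])
    return BoundarySet(list(CANONICAL_BOUNDARIES), depths)


def _add_collapse(
    labels: np.ndarray, rng: np.random.Generator, params: SimulationParams
) -> bool:
    """Replace the outer layers (ELM/PR1/PR2, ids 7-9) with collapsed_layers
    over a contiguous column range."""
    w = labels.shape[1]
    lo, hi = params.collapse_extent
    extent = int(rng.integers(lo, hi + 1))
    extent = min(extent, w)
    col0 = int(rng.integers(0, max(w - extent, 0) + 1))
    region = labels[:, col0 : col0 + extent]
    hit = np.isin(region, (7, 8, 9))
    region[hit] = COLLAPSED
    return bool(hit.any())


def _add_cysts(
    labels: np.ndarray,
    boundaries: BoundarySet,
    rng: np.random.Generator,
    params: SimulationParams,
    count: int,
) -> int:
    """Insert ``count`` disjoint hyporeflective ellipses strictly inside the
    retinal band (classes 2..9).  Returns the number actually placed."""
    h, w = labels.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    band = (labels >= 2) & (labels <= 9)
    occupied = np.zeros_like(labels, dtype=bool)
    placed = 0
    for _ in range(count):
        for _attempt in range(60):
            a = rng.uniform(*params.cyst_semiaxis_rows)   # row semi-axis
            b = rng.uniform(*params.cyst_semiaxis_cols)   # column semi-axis
            c0 = rng.uniform(b + 1, w - b - 1) if w > 2 * b + 2 else w / 2
            top = boundaries.depths[1]   # RNFL line: top of the class-2 band
            bot = boundaries.depths[9]   # RPE line: bottom of the class-9 band
            col_i = int(np.clip(round(c0), 0, w - 1))
            r_lo = top[col_i] + a + 1
            r_hi = bot[col_i] - a - 1
            if r_hi <= r_lo:
                continue
            r0 = rng.uniform(r_lo, r_hi)
            ellipse = ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0
            ellipse &= band
            if not ellipse.any():
                continue
            # keep cysts disjoint with a 2-px separation so components stay distinct
            dil = np.zeros_like(ellipse)
            er, ec = np.where(ellipse)
            for dr in (-2, -1, 0, 1, 2):
                for dc in (-2, -1, 0, 1, 2):
                    rr = np.clip(er + dr, 0, h - 1)
                    cc = np.clip(ec + dc, 0, w - 1)
                    dil[rr, cc] = True
            if (dil & occupied).any():
                continue
            labels[ellipse] = CYST
            occupied |= dil
            placed += 1
            break
    return placed


def simulate_bscan(
    params: SimulationParams,
    seed: int,
    diseased: bool = False,
    geometry: Optional[PatientGeometry] = None,
    patient_id: Optional[str] = None,
    eye: str = "left",
) -> SyntheticSample:
    """Generate one synthetic B-scan, deterministically from (params, seed).

    When ``diseased`` is true the sample carries at least one pathology
    feature (a cyst or a collapse region), reflected in the mask.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = PatientGeometry.draw(params, rng)
    fovea_col = int(rng.integers(params.width // 4, 3 * params.width // 4 + 1)) \
        if params.width >= 4 else params.width // 2

    boundaries = _build_boundaries(params, geometry, rng, fovea_col)
    mask = boundaries_to_mask(boundaries, params.height)
    labels = mask.labels

    if diseased:
        collapsed = rng.random() < params.collapse_prob and _add_collapse(
            labels, rng, params
        )
        lo, hi = params.cyst_count_range
        n_cysts = int(rng.integers(lo, hi + 1))
        placed = _add_cysts(labels, boundaries, rng, params, n_cysts)
        if not collapsed and placed == 0:
            # a diseased scan must show at least one pathology feature
            placed = _add_cysts(labels, boundaries, rng, params, 1)
            if placed == 0:
                _add_collapse(labels, rng, params)

    table = params.reflectivity_table()
    refl = table.copy()
    refl[1 : len(LAYERS) + 1] = geometry.reflectivity
    clean = refl[labels]
    if params.speckle > 0:
        noise = 1.0 + params.speckle * rng.standard_normal(clean.shape)
        image = clean * noise
    else:
        image = clean
    image = np.clip(image, 0.0, 1.0)

    return SyntheticSample(
        image=image,
        boundaries=boundaries,
        mask=ClassMask(labels, provenance="ground_truth"),
        patient_id=patient_id or f"P{seed}",
        eye=eye,
        diseased=diseased,
        fovea_col=fovea_col,
        params=params,
        seed=seed,
    )


# --------------------------------------------------------------------------
# dataset generation


def _scan_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def make_dataset(
    params: SimulationParams,
    n_patients: int,
    scans_per_patient: int,
    labeled_fraction: float,
    seed: int,
    out_dir,
):
    """Generate a dataset on disk with an 80:10:10 patient-level split.

    Among training patients, a ``labeled_fraction`` share (rounded, at least
    one required) is labeled; the rest contribute unlabeled scans only.  Scans
    are diseased with probability ``params.disease_prevalence``; the test
    split is forced to contain both diseased and non-diseased scans.
    """
    from .dataio import DatasetManifest, largest_remainder_split

    params.validate()
    if n_patients < 10:
        raise ParameterError("need n_patients >= 10 so each split is nonempty")
    if scans_per_patient < 1:
        raise ParameterError("scans_per_patient must be >= 1")
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ParameterError("labeled_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_train, n_val, n_test = largest_remainder_split(n_patients, (0.8, 0.1, 0.1))
    order = rng.permutation(n_patients)
    roles: dict[int, str] = {}
    for i, p in enumerate(order):
        roles[p] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")

    train_patients = [p for p in order if roles[p] == "train"]
    n_labeled = int(round(labeled_fraction * len(train_patients)))
    if n_labeled == 0:
        raise ParameterError(
            "labeled_fraction yields zero labeled training patients"
        )
    labeled_set = set(train_patients[:n_labeled])

    plan = []
    for p in range(n_patients):
        split = roles[p]
        labeled = split != "train" or p in labeled_set
        flags = rng.random(scans_per_patient) < params.disease_prevalence
        plan.append((p, split, labeled, list(flags)))

    # the test split must contain both diseased and non-diseased scans
    test_flags = [f for p, s, l, fl in plan for f in fl if s == "test"]
    if test_flags and len(set(test_flags)) == 1:
        for entry in plan:
            if entry[1] == "test":
                entry[3][0] = not entry[3][0]
                break

    return _write_dataset(params, plan, scans_per_patient, seed, out_dir)


def make_benchmark_dataset(
    params: SimulationParams,
    seed: int,
    out_dir,
    n_labeled_patients: int = 4,
    n_unlabeled_patients: int = 100,
    n_val_patients: int = 5,
    n_test_patients: int = 15,
    scans_per_patient: int = 2,
):
    """Patient-level dataset with explicit per-role patient counts.

    Used for the desk-scale semi-supervised benchmark, whose labeled /
    unlabeled / test scan counts (8 / 200 / 30 at the defaults) are fixed
    study conditions rather than a ratio of the patient pool.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    plan = []
    p = 0
    for _ in range(n_labeled_patients):
        flags = rng.random(scans_per_patient) < params.disease_prevalence
        plan.append((p, "train", True, list(flags)))
        p += 1
    for _ in range(n_unlabeled_patients):
        flags = rng.random(scans_per_patient) < params.disease_prevalence
        plan.append((p, "train", False, list(flags)))
        p += 1
    for _ in range(n_val_patients):
        flags = rng.random(scans_per_patient) < params.disease_prevalence
        plan.append((p, "val", True, list(flags)))
        p += 1
    for i in range(n_test_patients):
        flags = rng.random(scans_per_patient) < params.disease_prevalence
        flags[0] = i % 2 == 0  # guarantee a diseased/healthy mix in the test set
        plan.append((p, "test", True, list(flags)))
        p += 1
    return _write_dataset(params, plan, scans_per_patient, seed, out_dir)


def _write_dataset(params, plan, scans_per_patient, seed, out_dir):
    from .dataio import DatasetManifest, ManifestRecord

    out = Path(out_dir)
    for sub in ("images", "masks", "boundaries"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    n_patients = len(plan)
    patient_seeds = _scan_seeds(seed + 1, n_patients)
    manifest = DatasetManifest(root=out)
    for p, split, labeled, flags in plan:
        prng = np.random.default_rng(patient_seeds[p])
        geometry = PatientGeometry.draw(params, prng)
        pid = f"P{p:04d}"
        eye = "left" if p % 2 == 0 else "right"
        scan_seed_list = _scan_seeds(patient_seeds[p], scans_per_patient)
        for s in range(scans_per_patient):
            sample = simulate_bscan(
                params,
                seed=scan_seed_list[s],
                diseased=bool(flags[s]),
                geometry=geometry,
                patient_id=pid,
                eye=eye,
            )
            scan_id = f"{pid}_s{s}"
            from .dataio import save_image, save_mask

            img_rel = f"images/{scan_id}.png"
            save_image(out / img_rel, sample.image)
            mask_rel = boundaries_rel = None
            if labeled:
                mask_rel = f"masks/{scan_id}.png"
                save_mask(out / mask_rel, sample.mask)
                boundaries_rel = f"boundaries/{scan_id}.csv"
                sample.boundaries.to_csv(out / boundaries_rel)
            manifest.records.append(
                ManifestRecord(
                    scan_id=scan_id,
                    patient_id=pid,
                    split=split,
                    labeled=labeled,
                    diseased=bool(flags[s]),
                    eye=eye,
                    image_path=img_rel,
                    mask_path=mask_rel,
                    boundaries_path=boundaries_rel,
                    fovea_col=sample.fovea_col,
                    seed=sample.seed,
                )
            )
    manifest.validate()
    manifest.save()
    return manifest
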