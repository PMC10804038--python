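"""Synthetic retinal phantoms with controlled, labelled quality degradations.

Real reading-centre image quality datasets are private, so this module
generates reproducible stand-ins: circular field-of-view (FOV) fundus
phantoms with a branching vessel tree, optic disc and macula, rendered
either as colour fundus (CF, RGB) or fluorescein angiography (FA,
single-channel) images.  Controlled degradations in the modality's quality
categories are applied with a severity in [0, 1] that maps deterministically
to a Likert grade 1-5, so every image carries consistent labels by
construction.

Everything here is a pure function of its spec/seed: identical inputs give
bit-identical images and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import gaussian

from .categories import (
    ALL_LIKERT_COLUMNS,
    DEGRADATION_ORDER,
    categories_for,
    check_modality,
    degradable_categories,
)

#: severity -> Likert bin edges; severity <= 0.15 stays grade 1 so mild
#: artefacts still count as good quality
DEFAULT_LIKERT_EDGES = (0.15, 0.35, 0.55, 0.75)


# ---------------------------------------------------------------------------
# phantom specification and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for one clean phantom image.

    Parameters
    ----------
    seed : int
        Seeds every random element of the rendering (vessel tree shape,
        texture); identical specs render bit-identical images.
    modality : {"CF", "FA"}
    side_px : int
        Square image side in pixels, at least 64.
    fov_fraction : float
        Field-of-view disc diameter relative to the image side, in
        (0.5, 1]; pixels outside the disc are black.
    vessel_branches : int
        Number of primary vessel branches leaving the optic disc (>= 4).
    disc_offset : tuple of float
        Optic-disc centre relative to the FOV centre, in units of the FOV
        radius (normalised coordinates).
    fa_phase : float
        Dye phase for FA in [0, 1]: 0 is the early, pre-dye phase (dark,
        low contrast), 1 is peak fluorescence.  Ignored for CF.
    """

    seed: int
    modality: str
    side_px: int = 128
    fov_fraction: float = 0.9
    vessel_branches: int = 8
    disc_offset: tuple[float, float] = (0.55, 0.0)
    fa_phase: float = 1.0

    def validate(self) -> None:
        check_modality(self.modality)
        if self.side_px < 64:
            raise ValueError(f"side_px must be >= 64, got {self.side_px}")
        if not (0.5 < self.fov_fraction <= 1.0):
            raise ValueError(f"fov_fraction must be in (0.5, 1], got {self.fov_fraction}")
        if self.vessel_branches < 4:
            raise ValueError(f"vessel_branches must be >= 4, got {self.vessel_branches}")
        if not (0.0 <= self.fa_phase <= 1.0):
            raise ValueError(f"fa_phase must be in [0, 1], got {self.fa_phase}")


def fov_mask(side_px: int, fov_fraction: float) -> np.ndarray:
    """Boolean disc mask of the field of view."""
    c = (side_px - 1) / 2.0
    yy, xx = np.mgrid[0:side_px, 0:side_px]
    r = fov_fraction * side_px / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


def _render_vessels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterise a branching vessel tree into a [0, 1] intensity map.

    Branches perform a curvature-biased random walk from the optic disc,
    stamping soft discs of decaying width; each primary branch spawns one
    secondary branch partway along.
    """
    side = spec.side_px
    c = (side - 1) / 2.0
    r_fov = spec.fov_fraction * side / 2.0
    disc = np.array([c + spec.disc_offset[1] * r_fov, c + spec.disc_offset[0] * r_fov])

    acc = np.zeros((side, side))
    yy, xx = np.mgrid[0:side, 0:side]

    def stamp(pos: np.ndarray, width: float) -> None:
        y0, x0 = pos
        lo_y = max(int(y0 - 3 * width), 0)
        hi_y = min(int(y0 + 3 * width) + 1, side)
        lo_x = max(int(x0 - 3 * width), 0)
        hi_x = min(int(x0 + 3 * width) + 1, side)
        if lo_y >= hi_y or lo_x >= hi_x:
            return
        d2 = (yy[lo_y:hi_y, lo_x:hi_x] - y0) ** 2 + (xx[lo_y:hi_y, lo_x:hi_x] - x0) ** 2
        patch = np.exp(-d2 / (2.0 * max(width, 0.5) ** 2))
        np.maximum(acc[lo_y:hi_y, lo_x:hi_x], patch, out=acc[lo_y:hi_y, lo_x:hi_x])

    def walk(pos: np.ndarray, angle: float, width: float, length: int, depth: int) -> None:
        step = side / 64.0
        branch_at = rng.integers(length // 3, max(length // 3 + 1, 2 * length // 3))
        for i in range(length):
            angle += rng.normal(0.0, 0.12)
            pos = pos + step * np.array([math.sin(angle), math.cos(angle)])
            if (pos[0] - c) ** 2 + (pos[1] - c) ** 2 > (0.98 * r_fov) ** 2:
                return
            stamp(pos, width)
            width *= 0.985
            if depth > 0 and i == branch_at:
                walk(
                    pos.copy(),
                    angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0),
                    width * 0.7,
                    int(length * 0.6),
                    depth - 1,
                )

    n = spec.vessel_branches
    base = rng.uniform(0.0, 2.0 * math.pi)
    for k in range(n):
        angle = base + 2.0 * math.pi * k / n + rng.normal(0.0, 0.2)
        width = side / 96.0 * rng.uniform(0.8, 1.3)
        walk(disc.copy(), angle, width, int(side * 0.55), depth=2)
    return np.clip(acc, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a clean phantom image.

    Returns
    -------
    ndarray
        ``(side, side, 3)`` float array in [0, 1] for CF, ``(side, side, 1)``
        for FA.  Pixels outside the circular field of view are exactly 0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    side = spec.side_px
    c = (side - 1) / 2.0
    r_fov = spec.fov_fraction * side / 2.0
    mask = fov_mask(side, spec.fov_fraction)

    yy, xx = np.mgrid[0:side, 0:side]
    d_c = np.sqrt((yy - c) ** 2 + (xx - c) ** 2) / r_fov

    # landmarks: optic disc offset from FOV centre, macula mirrored inward
    disc_y = c + spec.disc_offset[1] * r_fov
    disc_x = c + spec.disc_offset[0] * r_fov
    mac_y = c - 0.25 * spec.disc_offset[1] * r_fov
    mac_x = c - 0.25 * spec.disc_offset[0] * r_fov
    r_disc = 0.16 * r_fov
    r_mac = 0.22 * r_fov
    disc_prof = np.exp(-((yy - disc_y) ** 2 + (xx - disc_x) ** 2) / (2 * r_disc**2))
    mac_prof = np.exp(-((yy - mac_y) ** 2 + (xx - mac_x) ** 2) / (2 * r_mac**2))

    # low-frequency texture shared by both modalities
    tex = gaussian(rng.normal(0.0, 1.0, (side, side)), sigma=side / 24.0)
    tex = tex / (np.abs(tex).max() + 1e-12)

    vessels = _render_vessels(spec, rng)
    shade = 1.0 - 0.25 * np.clip(d_c, 0.0, 1.2) ** 2

    if spec.modality == "CF":
        base = np.array([0.82, 0.42, 0.14])
        img = shade[..., None] * base[None, None, :] * (1.0 + 0.08 * tex[..., None])
        img = img * (1.0 - 0.30 * mac_prof[..., None])
        disc_col = np.array([0.98, 0.85, 0.55])
        img = img * (1.0 - disc_prof[..., None]) + disc_prof[..., None] * disc_col
        # vessels: dark red, attenuating green/blue more strongly
        vess_att = np.stack(
            [1.0 - 0.45 * vessels, 1.0 - 0.75 * vessels, 1.0 - 0.75 * vessels], axis=-1
        )
        img = img * vess_att
    else:
        phase = spec.fa_phase
        bg = 0.04 + 0.20 * phase * shade * (1.0 + 0.10 * tex)
        v_bright = vessels * (0.10 + 0.80 * phase)
        img = bg * (1.0 - 0.6 * mac_prof) + v_bright + 0.25 * phase * disc_prof
        img = img[..., None]

    img = np.clip(img, 0.0, 1.0)
    img *= mask[..., None]
    return img


# ---------------------------------------------------------------------------
# degradations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegradationSpec:
    """One artefact applied to an image.

    ``severity`` in [0, 1] controls the artefact strength; severity 0 is an
    exact no-op.  ``geometry`` overrides the category-specific placement
    parameters (all in normalised [0, 1] image coordinates); anything not
    given is drawn deterministically from ``seed``.
    """

    category: str
    severity: float
    seed: int = 0
    geometry: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.category not in DEGRADATION_ORDER:
            raise ValueError(f"unknown degradation category {self.category!r}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")


def _support_mask(image: np.ndarray) -> np.ndarray:
    """FOV proxy: pixels with any nonzero channel in the input image."""
    return image.max(axis=-1) > 0


def _apply_contrast(img: np.ndarray, mask: np.ndarray, s: float, rng, geom) -> np.ndarray:
    # affine compression toward the in-FOV mean; severity 1 leaves 15% of range
    m = img[mask].mean(axis=0)
    out = img.copy()
    out[mask] = m + (img[mask] - m) * (1.0 - 0.85 * s)
    return out


def _apply_focus(img: np.ndarray, mask: np.ndarray, s: float, rng, geom) -> np.ndarray:
    sigma = geom.get("sigma_scale", 2.5) * s * img.shape[0] / 64.0
    if sigma <= 0:
        return img
    out = gaussian(img, sigma=sigma, channel_axis=-1, preserve_range=True)
    return out * mask[..., None]


def _apply_illumination(img: np.ndarray, mask: np.ndarray, s: float, rng, geom) -> np.ndarray:
    side = img.shape[0]
    cy = geom.get("center", (rng.uniform(0.3, 0.7), rng.uniform(0.3, 0.7)))
    radius = geom.get("radius", rng.uniform(0.5, 0.9))
    yy, xx = np.mgrid[0:side, 0:side]
    d = np.sqrt((yy / side - cy[0]) ** 2 + (xx / side - cy[1]) ** 2)
    vignette = 1.0 - 0.55 * s * np.clip(d / radius, 0.0, 1.0) ** 2
    gain = (1.0 - 0.35 * s) * vignette
    return img * gain[..., None]


def _apply_shadow_reflection(img: np.ndarray, mask: np.ndarray, s: float, rng, geom) -> np.ndarray:
    side = img.shape[0]
    polarity = geom.get("polarity", int(rng.integers(0, 2)) * 2 - 1)
    cy = geom.get("center", (rng.uniform(0.3, 0.7), rng.uniform(0.3, 0.7)))
    axes = geom.get("axes", (rng.uniform(0.12, 0.25), rng.uniform(0.12, 0.25)))
    theta = geom.get("angle", rng.uniform(0.0, math.pi))
    yy, xx = np.mgrid[0:side, 0:side]
    dy = yy / side - cy[0]
    dx = xx / side - cy[1]
    u = dy * math.cos(theta) + dx * math.sin(theta)
    v = -dy * math.sin(theta) + dx * math.cos(theta)
    q = (u / axes[0]) ** 2 + (v / axes[1]) ** 2
    prof = np.exp(-q)
    target = 1.0 if polarity > 0 else 0.0
    alpha = (0.8 * s * prof)[..., None]
    out = img * (1.0 - alpha) + alpha * target
    return out * mask[..., None]


def _apply_noise(img: np.ndarray, mask: np.ndarray, s: float, rng, geom) -> np.ndarray:
    sd = geom.get("noise_sd", 0.12)
    speckle = rng.normal(0.0, 1.0, img.shape)
    additive = rng.normal(0.0, 1.0, img.shape)
    out = img * (1.0 + 0.25 * s * speckle) + sd * s * additive
    return out * mask[..., None]


_OPERATORS = {
    "contrast": _apply_contrast,
    "focus": _apply_focus,
    "illumination": _apply_illumination,
    "shadow_reflection": _apply_shadow_reflection,
    "noise": _apply_noise,
}


def severity_to_likert(severity: float, edges: tuple[float, ...] = DEFAULT_LIKERT_EDGES) -> int:
    """Map a degradation severity in [0, 1] to a Likert grade 1 (best) to 5 (worst).

    The mapping is a nondecreasing step function with configurable bin
    edges; an edge value belongs to the higher (worse) grade.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    return 1 + int(np.searchsorted(np.asarray(edges), severity, side="right"))


def derive_overall_likert(likert: dict[str, int]) -> int:
    """Overall grade of a synthetic image: the worst category grade."""
    if not likert:
        raise ValueError("empty Likert map")
    return max(likert.values())


def apply_degradation(
    image: np.ndarray,
    specs: list[DegradationSpec],
    *,
    likert_edges: tuple[float, ...] = DEFAULT_LIKERT_EDGES,
) -> tuple[np.ndarray, dict[str, int]]:
    """Apply degradations to a phantom and return the image plus Likert labels.

    Degradations are composed in the fixed order contrast -> focus ->
    illumination -> shadow & reflection -> noise, regardless of list order.
    The returned Likert map covers every non-overall category of the
    modality (severity 0, i.e. grade 1, for categories without a spec).

    The modality is inferred from the channel count (3 = CF, 1 = FA); the
    FOV is taken to be the nonzero support of the input image.
    """
    if image.ndim != 3 or image.shape[-1] not in (1, 3):
        raise ValueError("image must be (H, W, 1) for FA or (H, W, 3) for CF")
    modality = "CF" if image.shape[-1] == 3 else "FA"
    valid = degradable_categories(modality)

    by_cat: dict[str, DegradationSpec] = {}
    for spec in specs:
        spec.validate()
        if spec.category not in valid:
            raise ValueError(
                f"category {spec.category!r} does not apply to modality {modality}"
            )
        if spec.category in by_cat:
            raise ValueError(f"duplicate degradation category {spec.category!r}")
        by_cat[spec.category] = spec

    mask = _support_mask(image)
    out = image.astype(np.float64, copy=True)
    likert: dict[str, int] = {}
    for cat in DEGRADATION_ORDER:
        if cat not in valid:
            continue
        spec = by_cat.get(cat)
        sev = 0.0 if spec is None else float(spec.severity)
        likert[cat] = severity_to_likert(sev, likert_edges)
        if spec is None or sev == 0.0:
            continue
        rng = np.random.default_rng(spec.seed)
        out = _OPERATORS[cat](out, mask, sev, rng, spec.geometry)
    out = np.clip(out, 0.0, 1.0)
    out *= mask[..., None]
    return out, likert


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    """Recipe for a labelled synthetic dataset with patient-level splits.

    Per-category severities follow a two-component mixture: with
    probability ``poor_prob`` the category is degraded with a severity
    drawn uniformly from ``poor_range``, otherwise from ``good_range``.
    The overall Likert grade is the worst category grade; on the training
    split it is recorded for only ``overall_label_fraction`` of images
    (the rest are missing, mirroring partially annotated archives).

    Patients are assigned to train/validation/test; validation:test is
    about 1:2 by patient count.  ``n_images_per_split`` switches to exact
    per-split image quotas (one visit per patient, visit sizes drawn from
    ``images_per_visit`` and clipped to hit the quota).
    """

    modality: str = "CF"
    seed: int = 0
    n_patients: int = 45
    visits_per_patient: int = 1
    images_per_visit: tuple[int, int] = (3, 16)
    train_fraction: float = 0.70
    n_images_per_split: tuple[int, int, int] | None = None
    side_px: int = 128
    poor_prob: float = 0.3
    good_range: tuple[float, float] = (0.0, 0.1)
    poor_range: tuple[float, float] = (0.7, 1.0)
    overall_label_fraction: float | None = None  # default 0.81 CF / 0.74 FA
    likert_edges: tuple[float, ...] = DEFAULT_LIKERT_EDGES
    fa_phase_range: tuple[float, float] = (0.5, 1.0)

    def resolved_overall_fraction(self) -> float:
        if self.overall_label_fraction is not None:
            return self.overall_label_fraction
        return 0.81 if self.modality == "CF" else 0.74

    def validate(self) -> None:
        check_modality(self.modality)
        lo, hi = self.images_per_visit
        if not (3 <= lo <= hi <= 16):
            raise ValueError(
                f"images_per_visit must lie within [3, 16], got {self.images_per_visit}"
            )
        if self.n_patients < 3 and self.n_images_per_split is None:
            raise ValueError("need at least 3 patients (one per split)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        frac = self.resolved_overall_fraction()
        if not (0.0 <= frac <= 1.0):
            raise ValueError("overall_label_fraction must be in [0, 1]")


def _plan_visit_sizes(quota: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Visit sizes in [lo, hi] summing exactly to ``quota``."""
    k_min = math.ceil(quota / hi)
    k_max = quota // lo
    if k_min > k_max or quota < lo:
        raise ValueError(
            f"image quota {quota} cannot be met with visit sizes in [{lo}, {hi}]"
        )
    k = int(rng.integers(k_min, k_max + 1))
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(k)]
    # nudge sizes within bounds until they sum to the quota
    diff = quota - sum(sizes)
    j = 0
    while diff != 0:
        if diff > 0 and sizes[j % k] < hi:
            sizes[j % k] += 1
            diff -= 1
        elif diff < 0 and sizes[j % k] > lo:
            sizes[j % k] -= 1
            diff += 1
        j += 1
    return sizes


def _split_patients(config: DatasetConfig, rng: np.random.Generator) -> dict[str, int]:
    """Patients per split; validation:test about 1:2 by patient count."""
    n = config.n_patients
    n_train = max(1, round(n * config.train_fraction))
    rest = n - n_train
    n_val = max(1, round(rest / 3))
    n_test = rest - n_val
    if n_test < 1:
        raise ValueError("too few patients for a validation and test split")
    return {"train": n_train, "validation": n_val, "test": n_test}


def sample_severities(
    modality: str, config: DatasetConfig, rng: np.random.Generator
) -> dict[str, float]:
    sev = {}
    for cat in degradable_categories(modality):
        if rng.random() < config.poor_prob:
            sev[cat] = float(rng.uniform(*config.poor_range))
        else:
            sev[cat] = float(rng.uniform(*config.good_range))
    return sev


def make_dataset(config: DatasetConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate images and a manifest on disk; returns the manifest frame.

    Writes 8-bit PNGs (RGB for CF, grayscale for FA) under
    ``out_dir/images`` and ``out_dir/manifest.csv`` with one row per image.
    Missing labels are empty fields; categories of the other modality stay
    empty.  Fully deterministic in ``config.seed``.
    """
    config.validate()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    modality = config.modality
    cats = degradable_categories(modality)
    master = np.random.SeedSequence(config.seed)
    plan_rng = np.random.default_rng(master.spawn(1)[0])

    # plan the patient -> visit -> image hierarchy per split
    splits: list[tuple[str, list[list[int]]]] = []  # (split, per-patient visit sizes)
    if config.n_images_per_split is not None:
        for split, quota in zip(("train", "validation", "test"), config.n_images_per_split):
            sizes = _plan_visit_sizes(quota, *config.images_per_visit, rng=plan_rng)
            splits.append((split, [[s] for s in sizes]))  # one visit per patient
    else:
        counts = _split_patients(config, plan_rng)
        lo, hi = config.images_per_visit
        for split, n_pat in counts.items():
            patients = [
                [int(plan_rng.integers(lo, hi + 1)) for _ in range(config.visits_per_patient)]
                for _ in range(n_pat)
            ]
            splits.append((split, patients))

    overall_frac = config.resolved_overall_fraction()
    rows = []
    patient_counter = 0
    for split, patients in splits:
        for patient_visits in patients:
            patient_counter += 1
            pid = f"P{patient_counter:04d}"
            for v_idx, n_img in enumerate(patient_visits, start=1):
                vid = f"{pid}V{v_idx:02d}"
                eye = "OD" if plan_rng.random() < 0.5 else "OS"
                for i_idx in range(n_img):
                    (img_seed,) = master.spawn(1)
                    img_rng = np.random.default_rng(img_seed)
                    base_seed = int(img_rng.integers(0, 2**31 - 1))
                    spec = PhantomSpec(
                        seed=base_seed,
                        modality=modality,
                        side_px=config.side_px,
                        fov_fraction=float(img_rng.uniform(0.72, 0.95)),
                        vessel_branches=int(img_rng.integers(6, 11)),
                        disc_offset=(
                            float(img_rng.uniform(0.35, 0.6)) * (1 if eye == "OD" else -1),
                            float(img_rng.uniform(-0.15, 0.15)),
                        ),
                        fa_phase=float(img_rng.uniform(*config.fa_phase_range)),
                    )
                    clean = generate_phantom(spec)
                    severities = sample_severities(modality, config, img_rng)
                    specs = [
                        DegradationSpec(
                            category=cat,
                            severity=severities[cat],
                            seed=int(img_rng.integers(0, 2**31 - 1)),
                        )
                        for cat in cats
                        if severities[cat] > 0
                    ]
                    degraded, likert = apply_degradation(
                        clean, specs, likert_edges=config.likert_edges
                    )
                    name = f"{vid}_{i_idx:02d}.png"
                    _write_png(degraded, out_dir / "images" / name)

                    row = {
                        "image_path": f"images/{name}",
                        "patient_id": pid,
                        "visit_id": vid,
                        "eye": eye,
                        "modality": modality,
                        "split": split,
                    }
                    for col in ALL_LIKERT_COLUMNS:
                        row[col] = pd.NA
                    for cat, grade in likert.items():
                        row[f"likert_{cat}"] = grade
                    overall = derive_overall_likert(likert)
                    keep = split != "train" or img_rng.random() < overall_frac
                    row["likert_overall"] = overall if keep else pd.NA
                    rows.append(row)

    manifest = pd.DataFrame(rows)
    header = ["image_path", "patient_id", "visit_id", "eye", "modality", "split"]
    manifest = manifest[header + list(ALL_LIKERT_COLUMNS)]
    for col in ALL_LIKERT_COLUMNS:
        manifest[col] = manifest[col].astype("Int64")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _write_png(image: np.ndarray, path: Path) -> None:
    arr = np.round(np.clip(image, 0.0, 1.0) * 255.0).astype(np.uint8)
    if arr.shape[-1] == 1:
        pil = Image.fromarray(arr[..., 0], mode="L")
    else:
        pil = Image.fromarray(arr, mode="RGB")
    pil.save(path)


# ---------------------------------------------------------------------------
# image-statistic proxies used to check label/image consistency
# ---------------------------------------------------------------------------


def category_proxy(image: np.ndarray, category: str,
                   reference: np.ndarray | None = None) -> float:
    """Scalar image statistic that tracks the severity of one category.

    contrast: in-FOV intensity std (falls with severity); focus: mean
    gradient magnitude (falls); illumination: in-FOV mean intensity
    (falls); shadow & reflection: max local-mean deviation (rises) —
    measured against the seed-matched clean ``reference`` when given,
    since the phantom's own bright structures otherwise dominate the
    statistic at low severity; noise: high-pass variance (rises).
    """
    from skimage.filters import sobel

    mask = _support_mask(image)
    gray = image.mean(axis=-1)
    if category == "contrast":
        return float(gray[mask].std())
    if category == "focus":
        return float(sobel(gray)[mask].mean())
    if category == "illumination":
        return float(gray[mask].mean())
    if category == "shadow_reflection":
        sigma = gray.shape[0] / 16.0
        if reference is not None:
            resid = gray - reference.mean(axis=-1)
            return float(np.abs(gaussian(resid, sigma=sigma))[mask].max())
        smoothed = gaussian(gray, sigma=sigma)
        return float(np.abs(smoothed[mask] - gray[mask].mean()).max())
    if category == "noise":
        resid = gray - gaussian(gray, sigma=1.5)
        return float(resid[mask].var())
    raise ValueError(f"unknown category {category!r}")
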