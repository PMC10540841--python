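"""Synthetic face cohorts for exercising the screening pipeline.

Real clinical photographs cannot be redistributed, so every stage of the
pipeline is developed and tested against schematic faces rendered here: an
elliptical head with eyes, brows, nose and mouth, annotated with the standard
68-point landmark scheme (jaw 0-16, brows 17-26, nose 27-35, eyes 36-47,
mouth 48-67, 0-based), plus a crescent-shaped sub-orbital "fat pad" region
under each eye.

The fat-pad appearance carries the class signal.  Each subject draws a latent
appearance value ``a = effect_size * z + eps`` with ``eps ~ N(0, 1)`` and
``z`` the at-risk indicator (NRS-2002 >= 3); ``a`` modulates both the
crescent's thickness (mask area) and its brightness/texture, so downstream
gradient descriptors see a structural signal, not only a mean-intensity one.
Demographic attributes (age group, gender, site) are sampled independently of
the label, matching a cohort in which chi-square tests find no association.

Rendering is a pure function of (spec, subject index): identical inputs give
bit-identical images, landmarks and masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nfio

__all__ = [
    "CohortSpec",
    "SubjectParams",
    "SampleRecord",
    "sample_subject",
    "render_face",
    "generate_cohort",
    "records_from_metadata",
]


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a generated cohort.

    Defaults mirror the clinical cohort the pipeline was designed around:
    24% at-risk prevalence (123/515), 16.5% elderly, 61.5% male, and 37.7%
    of subjects recruited at remote-area hospitals.
    """

    n_subjects: int
    prevalence: float = 123 / 515
    elderly_fraction: float = 0.165
    male_fraction: float = 0.615
    remote_fraction: float = 194 / 515
    effect_size: float = 2.0
    jitter_rotation_deg: float = 10.0
    jitter_translation_px: float = 10.0
    canvas_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("elderly_fraction", "male_fraction", "remote_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.canvas_size < 128:
            raise ValueError("canvas_size must be >= 128")


@dataclass(frozen=True)
class SubjectParams:
    """Everything needed to render one subject deterministically."""

    sample_id: str
    at_risk: bool
    nrs_score: int
    age_group: str  # elderly | non_elderly
    gender: str  # male | female
    site: str  # remote | non_remote
    appearance: float  # latent a = effect_size*z + eps
    rotation_deg: float
    translation: tuple[float, float]
    noise_seed: int


@dataclass
class SampleRecord:
    """One subject as seen by the pipeline."""

    sample_id: str
    image_path: Path
    mask_path: Path
    landmarks_path: Path
    nrs_score: int
    age_group: str
    gender: str
    site: str
    split: str
    landmarks: np.ndarray | None = None

    @property
    def at_risk(self) -> bool:
        return self.nrs_score >= 3


# --- canonical face layout -------------------------------------------------

def face_layout(canvas_size: int) -> dict:
    """Feature centers/radii for a canvas of side S, all proportional to S."""
    s = float(canvas_size)
    return {
        "face_center": np.array([0.50 * s, 0.52 * s]),
        "face_radii": np.array([0.29 * s, 0.37 * s]),
        "eye_left": np.array([0.383 * s, 0.400 * s]),
        "eye_right": np.array([0.617 * s, 0.400 * s]),
        "eye_radii": np.array([0.055 * s, 0.027 * s]),
        "mouth_center": np.array([0.50 * s, 0.645 * s]),
        "mouth_radii": np.array([0.088 * s, 0.031 * s]),
        "nose_tip": np.array([0.50 * s, 0.520 * s]),
        "scale": s / 512.0,
    }


def _canonical_landmarks(layout: dict) -> np.ndarray:
    pts = np.zeros((68, 2))
    fc, fr = layout["face_center"], layout["face_radii"]
    el, er, erad = layout["eye_left"], layout["eye_right"], layout["eye_radii"]
    mc, mrad = layout["mouth_center"], layout["mouth_radii"]
    s = layout["scale"] * 512.0

    # jaw 0-16: lower face ellipse, left ear -> chin -> right ear
    psi = np.linspace(np.pi, 0.0, 17)
    pts[0:17, 0] = fc[0] + fr[0] * np.cos(psi)
    pts[0:17, 1] = fc[1] + fr[1] * np.sin(psi)

    # brows 17-26: arched rows above each eye
    for base, ec in ((17, el), (22, er)):
        xs = np.linspace(ec[0] - 1.4 * erad[0], ec[0] + 1.4 * erad[0], 5)
        arch = 0.008 * s * np.sin(np.linspace(0, np.pi, 5))
        pts[base : base + 5, 0] = xs
        pts[base : base + 5, 1] = ec[1] - 0.055 * s - arch

    # nose 27-30 bridge, 31-35 base row
    pts[27:31, 0] = fc[0]
    pts[27:31, 1] = np.linspace(0.42 * s, 0.50 * s, 4)
    pts[31:36, 0] = fc[0] + s * np.array([-0.04, -0.02, 0.0, 0.02, 0.04])
    pts[31:36, 1] = 0.52 * s

    # eyes 36-41 / 42-47: six symmetric points on each eye ellipse; the
    # symmetry makes the group centroid coincide with the ellipse center
    ang = np.deg2rad([180.0, 240.0, 300.0, 0.0, 60.0, 120.0])
    for base, ec in ((36, el), (42, er)):
        pts[base : base + 6, 0] = ec[0] + erad[0] * np.cos(ang)
        pts[base : base + 6, 1] = ec[1] + erad[1] * np.sin(ang)

    # mouth 48-59 outer (every 30 deg), 60-67 inner (every 45 deg)
    outer = np.deg2rad(np.arange(12) * 30.0)
    inner = np.deg2rad(np.arange(8) * 45.0)
    pts[48:60, 0] = mc[0] + mrad[0] * np.cos(outer)
    pts[48:60, 1] = mc[1] + mrad[1] * np.sin(outer)
    pts[60:68, 0] = mc[0] + 0.6 * mrad[0] * np.cos(inner)
    pts[60:68, 1] = mc[1] + 0.6 * mrad[1] * np.sin(inner)
    return pts


def sample_subject(spec: CohortSpec, index: int) -> SubjectParams:
    """Draw one subject's label, demographics and rendering jitter.

    Pure in (spec, index); independent subjects use independent streams.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    at_risk = bool(rng.random() < spec.prevalence)
    nrs_score = int(rng.integers(3, 6)) if at_risk else int(rng.integers(0, 3))
    age_group = "elderly" if rng.random() < spec.elderly_fraction else "non_elderly"
    gender = "male" if rng.random() < spec.male_fraction else "female"
    site = "remote" if rng.random() < spec.remote_fraction else "non_remote"
    appearance = spec.effect_size * float(at_risk) + float(rng.standard_normal())
    rotation = float(rng.uniform(-spec.jitter_rotation_deg, spec.jitter_rotation_deg))
    tx = float(rng.uniform(-spec.jitter_translation_px, spec.jitter_translation_px))
    ty = float(rng.uniform(-spec.jitter_translation_px, spec.jitter_translation_px))
    noise_seed = int(rng.integers(0, 2**31 - 1))
    return SubjectParams(
        sample_id=f"s{index:05d}",
        at_risk=at_risk,
        nrs_score=nrs_score,
        age_group=age_group,
        gender=gender,
        site=site,
        appearance=appearance,
        rotation_deg=rotation,
        translation=(tx, ty),
        noise_seed=noise_seed,
    )


def _inside_ellipse(x, y, center, radii):
    return ((x - center[0]) / radii[0]) ** 2 + ((y - center[1]) / radii[1]) ** 2 <= 1.0


def render_face(
    params: SubjectParams, canvas_size: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one subject.

    Returns ``(image, landmarks, mask)``: a float grayscale image in [0, 1],
    the 68x2 landmark array in the rendered (jittered) frame, and the uint8
    {0, 255} fat-pad mask marking exactly the rendered crescent pixels.

    The face is laid out in a canonical frame, then a rigid jitter (rotation
    about the eye midpoint, plus translation) is applied: the raster is
    produced by inverse-mapping canvas pixels into the canonical frame and
    evaluating analytic shape membership, and landmarks are forward-mapped,
    so the two are exactly consistent.
    """
    if canvas_size < 128:
        raise ValueError("canvas_size must be >= 128 to place all features")
    s = float(canvas_size)
    layout = face_layout(canvas_size)
    lm = _canonical_landmarks(layout)
    rng = np.random.default_rng(np.random.SeedSequence([params.noise_seed]))

    # appearance signal: crescent thickness and brightness both follow the
    # latent value; scales keep the crescent inside the cheek for |a| <~ 4
    a = params.appearance
    scale = layout["scale"]
    thickness = float(np.clip(24.0 + 3.0 * a, 10.0, 40.0)) * scale
    brightness = 0.18 + 0.02 * a

    theta = np.deg2rad(params.rotation_deg)
    pivot = 0.5 * (layout["eye_left"] + layout["eye_right"])
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    trans = np.asarray(params.translation)

    # forward-map landmarks: rotate about the eye midpoint, then translate
    lm_out = (lm - pivot) @ rot.T + pivot + trans

    # inverse-map the pixel grid into the canonical frame
    yy, xx = np.mgrid[0:canvas_size, 0:canvas_size].astype(np.float64)
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1)
    canon = (pix - pivot - trans) @ rot + pivot
    cx = canon[:, 0].reshape(xx.shape)
    cy = canon[:, 1].reshape(yy.shape)

    img = np.full((canvas_size, canvas_size), 0.04)
    face = _inside_ellipse(cx, cy, layout["face_center"], layout["face_radii"])
    img[face] = 0.75

    # brows: thin dark bands above the eyes
    erad = layout["eye_radii"]
    for ec in (layout["eye_left"], layout["eye_right"]):
        brow_c = np.array([ec[0], ec[1] - 0.055 * s])
        brow = _inside_ellipse(cx, cy, brow_c, np.array([1.5 * erad[0], 0.010 * s]))
        img[brow] = 0.35

    # nose: small bright wedge
    nose = _inside_ellipse(
        cx, cy, layout["nose_tip"], np.array([0.022 * s, 0.050 * s])
    )
    img[nose] = 0.82

    mouth = _inside_ellipse(cx, cy, layout["mouth_center"], layout["mouth_radii"])
    img[mouth] = 0.35

    mask = np.zeros(img.shape, dtype=bool)
    pad_gap = 3.0 * scale
    for ec in (layout["eye_left"], layout["eye_right"]):
        outer = np.array([2.0 * erad[0], erad[1] + pad_gap + thickness])
        inner = np.array([2.0 * erad[0], erad[1] + pad_gap])
        band = _inside_ellipse(cx, cy, ec, outer) & ~_inside_ellipse(cx, cy, ec, inner)
        # keep the crescent strictly below the lowest eye landmark
        band &= cy >= ec[1] + erad[1] + 2.0 * scale
        mask |= band

    ridges = 0.03 * np.sin(2.0 * np.pi * cy / (4.0 * scale))
    img[mask] = 0.75 + brightness + ridges[mask]

    eyes = _inside_ellipse(cx, cy, layout["eye_left"], erad) | _inside_ellipse(
        cx, cy, layout["eye_right"], erad
    )
    img[eyes] = 0.12

    img += rng.normal(0.0, 0.015, img.shape)
    img = np.clip(img, 0.0, 1.0)
    # round-trip through 8-bit so in-memory use matches PNG-on-disk use
    img = np.rint(img * 255.0) / 255.0

    mask_u8 = np.where(mask, 255, 0).astype(np.uint8)
    return img, lm_out, mask_u8


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path, split_fraction: float = 0.8
) -> list[SampleRecord]:
    """Render a full cohort to disk and return its sample records.

    Writes ``images/<id>.png``, ``masks/<id>.png``, ``landmarks/<id>.csv``
    and a single ``metadata.csv``.  The train/test split is a seeded random
    partition with ``round(split_fraction * n)`` training subjects.
    """
    out_dir = Path(out_dir)
    for sub in ("images", "masks", "landmarks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    n = spec.n_subjects
    split_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**30]))
    order = split_rng.permutation(n)
    n_train = int(round(split_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split_fraction leaves an empty train or test set")
    is_train = np.zeros(n, dtype=bool)
    is_train[order[:n_train]] = True

    records: list[SampleRecord] = []
    for i in range(n):
        p = sample_subject(spec, i)
        img, lm, mask = render_face(p, spec.canvas_size)
        image_path = out_dir / "images" / f"{p.sample_id}.png"
        mask_path = out_dir / "masks" / f"{p.sample_id}.png"
        lm_path = out_dir / "landmarks" / f"{p.sample_id}.csv"
        nfio.save_image(image_path, img)
        nfio.save_mask(mask_path, mask)
        nfio.save_landmarks(lm_path, lm)
        records.append(
            SampleRecord(
                sample_id=p.sample_id,
                image_path=image_path,
                mask_path=mask_path,
                landmarks_path=lm_path,
                nrs_score=p.nrs_score,
                age_group=p.age_group,
                gender=p.gender,
                site=p.site,
                split="train" if is_train[i] else "test",
                landmarks=lm,
            )
        )

    meta = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "image_path": [str(r.image_path) for r in records],
            "mask_path": [str(r.mask_path) for r in records],
            "landmarks_path": [str(r.landmarks_path) for r in records],
            "nrs_score": [r.nrs_score for r in records],
            "age_group": [r.age_group for r in records],
            "gender": [r.gender for r in records],
            "site": [r.site for r in records],
            "split": [r.split for r in records],
        }
    )
    nfio.save_metadata(out_dir / "metadata.csv", meta)
    return records


def records_from_metadata(path: str | Path) -> list[SampleRecord]:
    """Load sample records (with landmarks) from a cohort metadata CSV."""
    df = nfio.load_metadata(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                image_path=Path(row.image_path),
                mask_path=Path(row.mask_path),
                landmarks_path=Path(row.landmarks_path),
                nrs_score=int(row.nrs_score),
                age_group=row.age_group,
                gender=row.gender,
                site=row.site,
                split=row.split,
                landmarks=nfio.load_landmarks(row.landmarks_path),
            )
        )
    return records
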