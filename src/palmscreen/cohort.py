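"""Synthetic palm-image cohort generator.

Emulates a pediatric anemia-screening dataset: under-five subjects with a
measured hemoglobin (Hb) value, labelled anemic when Hb < 11 g/dL, each with
one RGB photograph of the palm. Anemic palms are rendered paler (lower
CIELAB a*, i.e. less red) than non-anemic palms; the default class means
(134 vs 168 in the offset a*+128 encoding) straddle the literature
discrimination thresholds of 142 and 160.

The rendered "palm" is a parametric blob (ellipse plus five finger lobes)
on a dark gray background — enough structure for histogram-based
segmentation, with no claim to anatomical realism. Each foreground pixel
draws its own a* from Normal(class mean, a_sd); i.i.d. per-pixel draws make
the per-image mean a* concentrate tightly on the class mean, which is the
statistical structure the downstream thresholds assume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import color
from .errors import PalmscreenError

logger = logging.getLogger(__name__)

#: Hb cutoff (g/dL) separating anemic from non-anemic in children 6-59 months.
HB_CUTOFF_G_DL = 11.0

ANEMIC = "anemic"
NON_ANEMIC = "non_anemic"

#: Class-conditional probability of female sex (fitted to a 58%-prevalence
#: screening cohort: 180/304 anemic female, 118/223 non-anemic female).
P_FEMALE = {ANEMIC: 180 / 304, NON_ANEMIC: 118 / 223}


def label_from_hb(hb_value: float) -> str:
    """Anemia label from hemoglobin: anemic iff Hb < 11 g/dL."""
    return ANEMIC if hb_value < HB_CUTOFF_G_DL else NON_ANEMIC


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One subject: id, Hb (g/dL), demographics and the Hb-derived label."""

    patient_id: str
    hb_value: float
    age: int
    sex: str
    label: str

    def __post_init__(self):
        if self.label != label_from_hb(self.hb_value):
            raise ValueError(
                f"label {self.label!r} inconsistent with hb={self.hb_value} "
                f"under the {HB_CUTOFF_G_DL} g/dL cutoff"
            )
        if not 0 <= self.age <= 5:
            raise ValueError(f"age {self.age} outside the under-five study population")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def remark(self) -> str:
        """Human-readable label as printed in the metadata table."""
        return "Anemic" if self.label == ANEMIC else "Non-anemic"


@dataclasses.dataclass
class PalmImage:
    """An RGB raster tied to a patient; the unit flowing through the pipeline."""

    patient_id: str
    pixels: np.ndarray  # H x W x 3 uint8
    provenance: str = "original"  # original | augmented
    transform_tag: str = ""

    def __post_init__(self):
        self.pixels = np.ascontiguousarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValueError("palm images must be at least 32 x 32")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")

    @property
    def image_id(self) -> str:
        return f"{self.patient_id}__{self.transform_tag}" if self.transform_tag else self.patient_id


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of the stated synthetic world.

    a* means and sds are in the offset encoding (a*+128); the defaults put
    the anemic mass below 142 and the non-anemic mass above 160 —
    the two literature discrimination thresholds — with per-pixel sd 4.
    subject_sd adds a between-subject random effect to the target a* mean
    (default 0: every subject sits exactly on the class mean, the fully
    separable world; raise it to emulate overlapping cohorts).
    noise_sd is additive per-pixel RGB sensor noise in 8-bit channel units.
    """

    n_anemic: int = 304
    n_non_anemic: int = 223
    anemic_a_mean: float = 134.0
    non_anemic_a_mean: float = 168.0
    a_sd: float = 4.0
    subject_sd: float = 0.0
    noise_sd: float = 3.0
    seed: int = 0
    height: int = 96
    width: int = 96
    lightness: float = 65.0  # foreground L*
    b_mean: float = 152.0  # foreground b*, offset encoding (native +24: skin is yellowish)
    background_gray: int = 40

    def __post_init__(self):
        if self.n_anemic < 0 or self.n_non_anemic < 0 or self.n_anemic + self.n_non_anemic == 0:
            raise ValueError("cohort counts must be non-negative and not both zero")
        if self.a_sd < 0 or self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def class_a_mean(self, label: str) -> float:
        return self.anemic_a_mean if label == ANEMIC else self.non_anemic_a_mean


def sample_patient(class_label: str, rng: np.random.Generator, index: int = 1) -> PatientRecord:
    """Draw one patient record of the requested class.

    Anemic Hb ~ Uniform(6.0, 10.9) g/dL, non-anemic ~ Uniform(11.0, 14.0);
    age uniform on 0-5 years; sex from class-conditional marginals.
    """
    if class_label == ANEMIC:
        hb = float(rng.uniform(6.0, 10.9))
    elif class_label == NON_ANEMIC:
        hb = float(rng.uniform(11.0, 14.0))
    else:
        raise ValueError(f"unknown class label {class_label!r}")
    age = int(rng.integers(0, 6))
    sex = "female" if rng.random() < P_FEMALE[class_label] else "male"
    return PatientRecord(
        patient_id=f"PID-{index:03d}",
        hb_value=round(hb, 1),
        age=age,
        sex=sex,
        label=label_from_hb(round(hb, 1)),
    )


def hand_mask(height: int, width: int) -> np.ndarray:
    """Ground-truth foreground: an elliptical palm with five finger lobes.

    Deterministic given the raster shape, so tests can recover the exact
    foreground the renderer painted.
    """
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    y, x = yy / height, xx / width
    mask = ((y - 0.62) / 0.24) ** 2 + ((x - 0.50) / 0.23) ** 2 <= 1.0  # palm
    # five fingers fanning upward from the palm top
    for cx, cy, rx, ry in (
        (0.26, 0.40, 0.045, 0.16),
        (0.38, 0.30, 0.045, 0.20),
        (0.50, 0.26, 0.045, 0.22),
        (0.62, 0.30, 0.045, 0.20),
        (0.74, 0.42, 0.045, 0.14),
    ):
        mask |= ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0
    return mask


def render_palm(record: PatientRecord, spec: CohortSpec, rng: np.random.Generator) -> PalmImage:
    """Render one palm image for a patient.

    The subject's target a* is the class mean plus (if subject_sd > 0) a
    between-subject random effect; foreground pixels then draw i.i.d.
    a* ~ Normal(target, a_sd) (offset encoding) at fixed L* and b*, are
    mapped CIELAB -> sRGB, and receive
    additive Gaussian channel noise of sd ``noise_sd``; the background is a
    flat dark gray with the same noise. Out-of-gamut targets are clamped to
    the sRGB boundary with a logged warning.
    """
    h, w = spec.height, spec.width
    fg = hand_mask(h, w)
    n_fg = int(fg.sum())

    target = spec.class_a_mean(record.label)
    if spec.subject_sd > 0:
        target += rng.normal(0.0, spec.subject_sd)
    a_offset = rng.normal(target, spec.a_sd, size=n_fg)
    lab = np.column_stack(
        [
            np.full(n_fg, spec.lightness),
            color.a_from_offset(a_offset),
            np.full(n_fg, color.a_from_offset(spec.b_mean)),
        ]
    )
    fg_rgb, clipped = color.lab_to_rgb(lab, return_clipped=True)
    n_clip = int(np.count_nonzero(clipped))
    if n_clip:
        logger.warning(
            "render_palm(%s): %d/%d foreground pixels outside sRGB gamut, clamped",
            record.patient_id, n_clip, n_fg,
        )

    img = np.full((h, w, 3), spec.background_gray, dtype=np.float64)
    img[fg] = fg_rgb
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return PalmImage(patient_id=record.patient_id, pixels=pixels)


def make_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], list[PalmImage]]:
    """Generate the full cohort: one record and one original image per subject.

    Deterministic given ``spec.seed`` (byte-identical rasters across runs).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    images: list[PalmImage] = []
    labels = [ANEMIC] * spec.n_anemic + [NON_ANEMIC] * spec.n_non_anemic
    for i, lab in enumerate(labels, start=1):
        rec = sample_patient(lab, rng, index=i)
        records.append(rec)
        images.append(render_palm(rec, spec, rng))
    return records, images


def write_cohort(records: list[PatientRecord], images: list[PalmImage], directory) -> Path:
    """Serialize a cohort: PNG per image, one metadata CSV, a JSON manifest.

    Returns the manifest path. The CSV mirrors the field record sheet:
    patient_id, hb_value, age, sex, remark.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        img_dir = directory / "images"
        img_dir.mkdir(exist_ok=True)
        entries = []
        for img in images:
            fname = f"{img.image_id}.png"
            Image.fromarray(img.pixels).save(img_dir / fname)
            entries.append(
                {
                    "patient_id": img.patient_id,
                    "file": f"images/{fname}",
                    "provenance": img.provenance,
                    "transform_tag": img.transform_tag,
                }
            )
        meta = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in records],
                "hb_value": [r.hb_value for r in records],
                "age": [r.age for r in records],
                "sex": [r.sex for r in records],
                "remark": [r.remark for r in records],
            }
        )
        meta.to_csv(directory / "metadata.csv", index=False)
        manifest = directory / "manifest.json"
        manifest.write_text(
            json.dumps({"metadata": "metadata.csv", "images": entries}, indent=2)
        )
    except OSError as exc:
        raise PalmscreenError(f"failed writing cohort under {directory}: {exc}") from exc
    return manifest


def read_cohort(directory) -> tuple[list[PatientRecord], list[PalmImage]]:
    """Inverse of :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    meta = pd.read_csv(directory / manifest["metadata"])
    records = [
        PatientRecord(
            patient_id=row.patient_id,
            hb_value=float(row.hb_value),
            age=int(row.age),
            sex=row.sex,
            label=ANEMIC if row.remark == "Anemic" else NON_ANEMIC,
        )
        for row in meta.itertuples()
    ]
    images = []
    for entry in manifest["images"]:
        pixels = np.asarray(Image.open(directory / entry["file"]).convert("RGB"))
        images.append(
            PalmImage(
                patient_id=entry["patient_id"],
                pixels=pixels,
                provenance=entry["provenance"],
                transform_tag=entry["transform_tag"],
            )
        )
    return records, images
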