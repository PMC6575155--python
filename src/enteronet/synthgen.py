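"""Seeded synthetic biopsy-style cohorts for pipeline testing.

Real duodenal biopsy slides are not redistributable, so this module
generates image cohorts that carry the statistical structure the rest of
the pipeline assumes: three tissue classes (control, celiac disease,
environmental enteropathy) whose micro-texture differs in dark-blob
density (a stand-in for secretory-cell populations), blob eccentricity
and sinusoidal ridge amplitude (a stand-in for villus structure); a
per-site constant hue shift emulating inter-laboratory H-E staining
differences; and a biomarker panel linearly linked (plus Gaussian noise)
to each case's latent texture parameters.

Every generated artifact is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

CLASS_LABELS = ("control", "CD", "EE")

#: latent texture parameter names, in the order used by biomarker links
LATENT_NAMES = ("blob_density", "blob_eccentricity", "ridge_amplitude")

_BACKGROUND = np.array([231, 187, 201], dtype=np.float64)  # pale eosin pink
_BLOB_COLOR = np.array([98, 61, 130], dtype=np.float64)  # hematoxylin purple


class SpecValidationError(ValueError):
    """A cohort or link spec violates its invariants."""


class ManifestParseError(ValueError):
    """A manifest file on disk is malformed."""


class MissingLatentsError(RuntimeError):
    """Manifest lacks the latent-parameter sidecar needed for biomarkers."""


@dataclass(frozen=True)
class ClassTexture:
    """Per-class mean texture parameters.

    blob_density is expressed in blobs per megapixel so that it is
    independent of the generated image size.
    """

    blob_density: float
    blob_eccentricity: float
    ridge_amplitude: float
    blob_radius: float = 6.0  # equivalent-area radius in pixels
    ridge_period: float = 60.0  # mean band spacing in pixels
    noise_sd: float = 4.0  # per-pixel intensity noise

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.blob_density, self.blob_eccentricity, self.ridge_amplitude]
        )


#: default class textures: secretory-cell-like blob density rises from
#: control to CD to EE, EE blobs are more eccentric, villus-like ridges
#: are strongest in control tissue and flattened in disease.
DEFAULT_CLASS_TEXTURES: Mapping[str, ClassTexture] = {
    "control": ClassTexture(blob_density=20.0, blob_eccentricity=0.2, ridge_amplitude=25.0),
    "CD": ClassTexture(blob_density=60.0, blob_eccentricity=0.4, ridge_amplitude=12.0),
    "EE": ClassTexture(blob_density=120.0, blob_eccentricity=0.6, ridge_amplitude=5.0),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    ``site_hue_shift`` maps site id to a constant per-channel RGB offset
    (each component in [-30, 30]); shifted pixels are clipped to
    [0, 255]. ``class_sites`` maps each class label to the cycle of site
    ids its cases are assigned to (round-robin).
    """

    n_cases_per_class: int = 10
    images_per_case: int = 5
    image_height: int = 1024
    image_width: int = 1360
    class_texture_params: Mapping[str, ClassTexture] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TEXTURES)
    )
    site_hue_shift: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"siteA": (0.0, 0.0, 0.0)}
    )
    class_sites: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {c: ("siteA",) for c in CLASS_LABELS}
    )
    latent_jitter: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_cases_per_class < 1:
            bad.append("n_cases_per_class")
        if self.images_per_case < 1:
            bad.append("images_per_case")
        if self.image_height < 1:
            bad.append("image_height")
        if self.image_width < 1:
            bad.append("image_width")
        for label in CLASS_LABELS:
            if label not in self.class_texture_params:
                bad.append(f"class_texture_params[{label}]")
            if label not in self.class_sites or not self.class_sites[label]:
                bad.append(f"class_sites[{label}]")
        for site, shift in self.site_hue_shift.items():
            if len(shift) != 3 or any(abs(s) > 30 for s in shift):
                bad.append(f"site_hue_shift[{site}]")
        for label, sites in self.class_sites.items():
            for s in sites:
                if s not in self.site_hue_shift:
                    bad.append(f"class_sites[{label}] references unknown site {s!r}")
        if not (0 <= self.latent_jitter < 1):
            bad.append("latent_jitter")
        if bad:
            raise SpecValidationError(f"invalid cohort spec fields: {', '.join(bad)}")


@dataclass(frozen=True)
class BiomarkerLinkSpec:
    """Linear link between latent texture parameters and named markers.

    ``link_weights`` has shape (n_markers, n_latents) with latent order
    ``LATENT_NAMES``; marker_i = weights_i . latent + N(0, noise_sd_i^2).
    """

    marker_names: tuple[str, ...]
    link_weights: np.ndarray
    noise_sd: np.ndarray
    seed: int = 0

    def validate(self) -> None:
        bad = []
        w = np.asarray(self.link_weights, dtype=float)
        sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if w.shape != (len(self.marker_names), len(LATENT_NAMES)):
            bad.append(
                f"link_weights shape {w.shape} != "
                f"({len(self.marker_names)}, {len(LATENT_NAMES)})"
            )
        if sd.shape not in ((1,), (len(self.marker_names),)):
            bad.append("noise_sd length")
        elif np.any(sd < 0):
            bad.append("noise_sd must be >= 0")
        if len(set(self.marker_names)) != len(self.marker_names):
            bad.append("marker_names must be unique")
        if bad:
            raise SpecValidationError(f"invalid biomarker link spec: {', '.join(bad)}")


@dataclass
class CaseRecord:
    case_id: str
    class_label: str
    site_id: str
    image_paths: list[str]


@dataclass
class CohortManifest:
    """Cohort listing: one record per case, plus optional latent sidecar.

    ``latents`` (case_id -> latent parameter vector) is populated by
    :func:`generate_cohort` and persisted in a sidecar next to the
    manifest file so the biomarker link is reproducible.
    """

    records: list[CaseRecord]
    root: Path | None = None
    latents: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ManifestParseError("duplicate case_id in manifest")
        for r in self.records:
            if r.class_label not in CLASS_LABELS:
                raise ManifestParseError(
                    f"case {r.case_id}: class {r.class_label!r} not in {CLASS_LABELS}"
                )

    @property
    def case_ids(self) -> list[str]:
        return [r.case_id for r in self.records]

    def classes(self) -> list[str]:
        return [r.class_label for r in self.records]

    def resolve(self, rel: str) -> Path:
        return (self.root / rel) if self.root is not None else Path(rel)

    def subset(self, case_ids: Sequence[str]) -> "CohortManifest":
        keep = set(case_ids)
        recs = [r for r in self.records if r.case_id in keep]
        lat = {c: v for c, v in self.latents.items() if c in keep}
        return CohortManifest(records=recs, root=self.root, latents=lat)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortManifest):
            return NotImplemented
        if len(self.records) != len(other.records):
            return False
        for a, b in zip(self.records, other.records):
            if (a.case_id, a.class_label, a.site_id, a.image_paths) != (
                b.case_id,
                b.class_label,
                b.site_id,
                b.image_paths,
            ):
                return False
        return True


def _render_image(
    rng: np.random.Generator,
    height: int,
    width: int,
    latent: np.ndarray,
    texture: ClassTexture,
    hue_shift: tuple[float, float, float],
) -> np.ndarray:
    """Render one 8-bit RGB image from latent texture parameters."""
    blob_density, ecc, ridge_amp = latent
    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = _BACKGROUND
    # villus-like ridges: sinusoidal intensity bands at a random angle
    theta = rng.uniform(0, math.pi)
    period = rng.uniform(0.75 * texture.ridge_period, 1.25 * texture.ridge_period)
    yy, xx = np.mgrid[0:height, 0:width]
    phase = rng.uniform(0, 2 * math.pi)
    ridge = ridge_amp * np.sin(
        2 * math.pi * (xx * math.cos(theta) + yy * math.sin(theta)) / period + phase
    )
    img += ridge[..., None]
    # secretory-cell-like dark elliptical blobs
    n_blobs = rng.poisson(blob_density * height * width / 1e6)
    base_r = texture.blob_radius
    for _ in range(n_blobs):
        cy = rng.uniform(0, height)
        cx = rng.uniform(0, width)
        # eccentricity e relates semi-axes by b = a*sqrt(1-e^2), area kept fixed
        a = base_r / max(math.sqrt(math.sqrt(1 - min(ecc, 0.95) ** 2)), 1e-3)
        b = base_r * math.sqrt(math.sqrt(1 - min(ecc, 0.95) ** 2))
        rot = rng.uniform(0, math.pi)
        rr, cc = ellipse(cy, cx, a, b, shape=(height, width), rotation=rot)
        img[rr, cc] = _BLOB_COLOR
    # pixel noise, then the site's constant staining offset
    if texture.noise_sd > 0:
        img += rng.normal(0.0, texture.noise_sd, size=img.shape)
    img += np.asarray(hue_shift, dtype=np.float64)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> CohortManifest:
    """Generate a cohort of images on disk and return its manifest.

    Produces exactly ``n_cases_per_class * 3`` cases; each case's latent
    texture parameters are drawn around its class means (multiplicative
    jitter of ``latent_jitter``) and stored on the manifest. Identical
    (spec, seed) yields byte-identical image files.
    """
    spec.validate()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    rng = np.random.default_rng(spec.seed)
    records: list[CaseRecord] = []
    latents: dict[str, np.ndarray] = {}
    for label in CLASS_LABELS:
        texture = spec.class_texture_params[label]
        sites = list(spec.class_sites[label])
        for i in range(spec.n_cases_per_class):
            case_id = f"{label}_{i:03d}"
            site = sites[i % len(sites)]
            jitter = 1.0 + spec.latent_jitter * rng.standard_normal(len(LATENT_NAMES))
            latent = np.clip(texture.as_array() * jitter, 0.0, None)
            latent[1] = min(latent[1], 0.95)
            case_dir = out_dir / case_id
            case_dir.mkdir(exist_ok=True)
            paths = []
            for j in range(spec.images_per_case):
                img = _render_image(
                    rng,
                    spec.image_height,
                    spec.image_width,
                    latent,
                    texture,
                    spec.site_hue_shift[site],
                )
                rel = f"{case_id}/img_{j:03d}.png"
                iio.imwrite(out_dir / rel, img)
                paths.append(rel)
            records.append(CaseRecord(case_id, label, site, paths))
            latents[case_id] = latent
    manifest = CohortManifest(records=records, root=out_dir, latents=latents)
    write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest


@dataclass
class BiomarkerTable:
    """Case x marker measurement table (wraps a DataFrame indexed by case_id)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise SpecValidationError("duplicate case ids in biomarker table")
        if self.data.columns.has_duplicates:
            raise SpecValidationError("duplicate marker names in biomarker table")

    @property
    def marker_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index)


def generate_biomarker_table(
    manifest: CohortManifest, link: BiomarkerLinkSpec
) -> BiomarkerTable:
    """Simulate a biomarker panel linearly linked to case latent textures."""
    link.validate()
    if not manifest.latents:
        raise MissingLatentsError(
            "manifest carries no latent texture parameters; regenerate the "
            "cohort with generate_cohort (or load the latent sidecar)"
        )
    w = np.asarray(link.link_weights, dtype=float)
    sd = np.broadcast_to(
        np.atleast_1d(np.asarray(link.noise_sd, dtype=float)), (len(link.marker_names),)
    )
    rng = np.random.default_rng(link.seed)
    rows = {}
    for rec in manifest.records:
        latent = manifest.latents[rec.case_id]
        noise = rng.standard_normal(len(link.marker_names)) * sd
        rows[rec.case_id] = w @ latent + noise
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(link.marker_names)
    )
    frame.index.name = "case_id"
    return BiomarkerTable(frame)


_MANIFEST_HEADER = ["case_id", "class", "site", "images"]


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest (and its latent sidecar) as tab-separated text."""
    path = Path(path)
    lines = ["\t".join(_MANIFEST_HEADER)]
    for r in manifest.records:
        lines.append(
            "\t".join([r.case_id, r.class_label, r.site_id, ";".join(r.image_paths)])
        )
    path.write_text("\n".join(lines) + "\n")
    if manifest.latents:
        side = ["\t".join(["case_id", *LATENT_NAMES])]
        for r in manifest.records:
            vals = manifest.latents[r.case_id]
            side.append("\t".join([r.case_id, *(f"{v:.12g}" for v in vals)]))
        _sidecar_path(path).write_text("\n".join(side) + "\n")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".latents.tsv")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a manifest written by :func:`write_manifest`.

    Raises :class:`ManifestParseError` (with a line number) on malformed
    rows, duplicate case ids, or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    lines = path.read_text().splitlines()
    if not lines:
        raise ManifestParseError(f"{path}: empty manifest file")
    if lines[0].split("\t") != _MANIFEST_HEADER:
        raise ManifestParseError(f"{path}: line 1: bad header {lines[0]!r}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields_ = line.split("\t")
        if len(fields_) != 4:
            raise ManifestParseError(
                f"{path}: line {lineno}: expected 4 tab-separated fields, "
                f"got {len(fields_)}"
            )
        case_id, label, site, images = fields_
        if label not in CLASS_LABELS:
            raise ManifestParseError(
                f"{path}: line {lineno}: unknown class {label!r}"
            )
        records.append(CaseRecord(case_id, label, site, images.split(";")))
    if not records:
        raise ManifestParseError(f"{path}: manifest contains no cases")
    try:
        manifest = CohortManifest(records=records, root=path.parent)
    except ManifestParseError as exc:
        raise ManifestParseError(f"{path}: {exc}") from None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        frame = pd.read_csv(sidecar, sep="\t", index_col="case_id")
        manifest.latents = {
            str(cid): row.to_numpy(dtype=float) for cid, row in frame.iterrows()
        }
    return manifest


def write_biomarker_table(table: BiomarkerTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="case_id")


def read_biomarker_table(path: str | Path) -> BiomarkerTable:
    if not Path(path).exists():
        raise FileNotFoundError(f"biomarker table not found: {path}")
    return BiomarkerTable(pd.read_csv(path, sep="\t", index_col="case_id"))
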