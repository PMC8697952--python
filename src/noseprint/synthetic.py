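"""Synthetic nose-pattern cohort generator.

The canine nose tip carries an interlocking pattern of raised polygonal
*beads* separated by narrow sunken *grooves*; the pattern is fixed per
individual and stable over time.  Because no public image set of this kind
exists, this module synthesises cohorts with the statistical structure the
downstream analysis assumes: a latent, time-invariant per-subject texture,
re-captured several times under photometric and geometric perturbation.

The texture model is a nearest-site tessellation (Voronoi-style): random
site points partition the canvas into polygonal cells (beads) and pixels
near a cell boundary are darkened (grooves).  Captures apply, in order, an
affine warp, an illumination tilt plane, contrast/brightness, Gaussian
blur and additive Gaussian noise — a stand-in for re-photographing the
same nose months apart.

Everything is a pure function of seeds: per-subject and per-capture random
streams are derived from the cohort master seed through a counter scheme
keyed by (subject index, capture index), so appending subjects never
perturbs existing subjects' data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import CaptureError, CohortSpecError, ParameterError

# Intensity range of rendered patterns.  Kept strictly inside [0, 1] so
# that moderate additive capture noise is not clipped away at the rails.
_INTENSITY_LO = 0.12
_INTENSITY_HI = 0.95

_MIN_CANVAS = 64
_MIN_SITES = 8


# ---------------------------------------------------------------------------
# identity patterns


@dataclass(frozen=True)
class IdentityGenParams:
    """Sampling ranges for identity generation.

    Each range is an inclusive (low, high) pair; a subject's concrete
    values are drawn once from its identity stream and then frozen for
    life.  Defaults give beads ~30 px across on a 256 px canvas, i.e.
    ~8 px after resampling to the 64 px analysis grid, inside the
    passband of the default Gabor bank.
    """

    canvas_size: tuple[int, int] = (256, 256)
    n_sites: tuple[int, int] = (48, 64)
    groove_halfwidth: tuple[float, float] = (3.0, 5.0)
    bead_relief: tuple[float, float] = (0.2, 0.4)


@dataclass(frozen=True)
class IdentityPattern:
    """The latent, time-invariant bead/groove field of one subject."""

    subject_id: str
    seed: int
    canvas_size: tuple[int, int]  # (height, width) px
    site_points: np.ndarray  # (n, 2) float, (row, col) px
    groove_halfwidth: float  # px
    bead_relief: float  # amplitude in [0, 1]


def generate_identity(
    subject_id: str, seed: int, params: IdentityGenParams | None = None
) -> IdentityPattern:
    """Draw one subject's latent pattern. Deterministic in (seed, params)."""
    params = params or IdentityGenParams()
    h, w = params.canvas_size
    if h < _MIN_CANVAS or w < _MIN_CANVAS:
        raise ParameterError(f"canvas {params.canvas_size} below {_MIN_CANVAS}x{_MIN_CANVAS}")
    if params.n_sites[0] < _MIN_SITES:
        raise ParameterError(f"site count range {params.n_sites} below minimum {_MIN_SITES}")
    rng = np.random.default_rng(seed)
    n_sites = int(rng.integers(params.n_sites[0], params.n_sites[1] + 1))
    halfwidth = float(rng.uniform(*params.groove_halfwidth))
    relief = float(rng.uniform(*params.bead_relief))
    sites = np.column_stack([rng.uniform(0, h, n_sites), rng.uniform(0, w, n_sites)])
    return IdentityPattern(
        subject_id=subject_id,
        seed=seed,
        canvas_size=(h, w),
        site_points=sites,
        groove_halfwidth=halfwidth,
        bead_relief=relief,
    )


def render_pattern(identity: IdentityPattern) -> np.ndarray:
    """Render the latent pattern as a grayscale image in [0, 1].

    Pixel intensity encodes distance to the nearest tessellation edge:
    the boundary between the two nearest-site regions is the groove
    (dark), bead interiors are bright, with a gentle dome modulated by
    ``bead_relief`` so beads are not flat.
    """
    h, w = identity.canvas_size
    rows, cols = np.mgrid[0:h, 0:w]
    pix = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    d, _ = cKDTree(identity.site_points).query(pix, k=2)
    # distance from a pixel to the Voronoi edge between its two nearest sites
    edge_dist = ((d[:, 1] - d[:, 0]) / 2.0).reshape(h, w)
    hw = identity.groove_halfwidth
    if hw > 0:
        # flat-bottomed groove: fully dark within hw/2 of the edge, then ramp
        core = np.clip((edge_dist - hw / 2.0) / (hw / 2.0), 0.0, 1.0)
    else:
        core = np.ones_like(edge_dist)
    dome_scale = 2.0 * max(hw, 1.0)
    raw = core * (1.0 - identity.bead_relief * np.exp(-edge_dist / dome_scale))
    return _INTENSITY_LO + (_INTENSITY_HI - _INTENSITY_LO) * raw


# ---------------------------------------------------------------------------
# captures


@dataclass(frozen=True)
class CaptureParams:
    """One capture's perturbation: geometry, photometry, optics, sensor."""

    rotation: float = 0.0  # degrees, counter-clockwise about canvas centre
    translation: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px
    scale: float = 1.0
    brightness_offset: float = 0.0  # intensity units
    contrast_gain: float = 1.0
    blur_sigma: float = 0.0  # px
    noise_sigma: float = 0.0  # intensity units
    illumination_tilt: tuple[float, float] = (0.0, 0.0)  # (gx, gy) intensity/px
    capture_seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ParameterError("blur_sigma and noise_sigma must be >= 0")


def render_capture(identity: IdentityPattern, cp: CaptureParams) -> np.ndarray:
    """Simulate one acquisition of ``identity`` under perturbation ``cp``.

    Applies, in order: affine warp (rotation, translation, scale about the
    canvas centre), illumination tilt plane, contrast/brightness, Gaussian
    blur, additive Gaussian noise seeded by ``capture_seed``; the result is
    clipped to [0, 1].  All-neutral parameters return the rendered pattern
    bit-for-bit.  Deterministic in (identity, cp).
    """
    return _perturb(render_pattern(identity), cp)


def _perturb(img: np.ndarray, cp: CaptureParams) -> np.ndarray:
    h, w = img.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    neutral_warp = (
        cp.rotation == 0.0 and cp.scale == 1.0 and cp.translation == (0.0, 0.0)
    )
    if not neutral_warp:
        theta = np.deg2rad(cp.rotation)
        # forward map: out = s*R(theta)@(in - c) + c + t; ndimage wants inverse
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        inv = rot.T / cp.scale
        t = np.array([cp.translation[1], cp.translation[0]])  # (dy, dx) -> row, col
        offset = centre - inv @ (centre + t)
        src_oob = _oob_fraction(inv, offset, h, w)
        if src_oob > 0.20:
            raise CaptureError(
                f"warp leaves {src_oob:.0%} of the ROI outside the canvas (limit 20%)"
            )
        img = ndimage.affine_transform(img, inv, offset=offset, order=1, mode="nearest")
    if cp.illumination_tilt != (0.0, 0.0):
        gx, gy = cp.illumination_tilt
        rows, cols = np.mgrid[0:h, 0:w]
        img = img + gx * (cols - centre[1]) + gy * (rows - centre[0])
    if cp.contrast_gain != 1.0 or cp.brightness_offset != 0.0:
        img = (img - 0.5) * cp.contrast_gain + 0.5 + cp.brightness_offset
    if cp.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cp.blur_sigma, mode="reflect")
    if cp.noise_sigma > 0:
        rng = np.random.default_rng(cp.capture_seed)
        img = img + rng.normal(0.0, cp.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _oob_fraction(inv: np.ndarray, offset: np.ndarray, h: int, w: int) -> float:
    rows, cols = np.mgrid[0:h, 0:w]
    out = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    src = out @ inv.T + offset
    oob = (src[:, 0] < 0) | (src[:, 0] > h - 1) | (src[:, 1] < 0) | (src[:, 1] > w - 1)
    return float(oob.mean())


# ---------------------------------------------------------------------------
# cohorts


def _as_range(v) -> tuple[float, float]:
    if np.isscalar(v):
        return (float(v), float(v))
    lo, hi = v
    return (float(lo), float(hi))


@dataclass(frozen=True)
class CaptureRanges:
    """Uniform sampling ranges for per-capture perturbations.

    Defaults model careful hand-held re-photography of a cooperative
    animal: small rotations and translations, mild optical scale change,
    modest exposure drift, and sensor noise.
    """

    rotation: tuple[float, float] = (-5.0, 5.0)  # degrees
    translation: tuple[float, float] = (-4.0, 4.0)  # px, each axis
    scale: tuple[float, float] = (0.95, 1.05)
    brightness_offset: tuple[float, float] = (-0.10, 0.10)
    contrast_gain: tuple[float, float] = (0.85, 1.15)
    blur_sigma: tuple[float, float] = (0.0, 1.2)  # px
    noise_sigma: tuple[float, float] = (0.0, 0.03)
    illumination_tilt: tuple[float, float] = (-8e-4, 8e-4)  # intensity/px, each axis


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the dataset is a pure
    function of this object (byte-identical rerun)."""

    subjects: tuple[tuple[str, int], ...]
    identity_params: IdentityGenParams = field(default_factory=IdentityGenParams)
    capture_ranges: CaptureRanges = field(default_factory=CaptureRanges)
    master_seed: int = 0

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise CohortSpecError("duplicate subject_ids in cohort spec")
        if any(n < 1 for _, n in self.subjects):
            raise CohortSpecError("every subject needs n_captures >= 1")

    @staticmethod
    def from_dict(cfg: dict) -> "CohortSpec":
        subjects: list[tuple[str, int]] = []
        for grp in cfg.get("groups", []):
            n, caps = int(grp["count"]), int(grp["captures"])
            start = len(subjects)
            subjects += [(f"S{start + i:03d}", caps) for i in range(n)]
        for sub in cfg.get("subjects", []):
            subjects.append((str(sub["id"]), int(sub["captures"])))
        kw: dict = {}
        if "identity" in cfg:
            ident = cfg["identity"]
            kw["identity_params"] = IdentityGenParams(
                canvas_size=tuple(ident.get("canvas_size", (256, 256))),
                n_sites=tuple(int(x) for x in _as_range(ident.get("n_sites", (48, 64)))),
                groove_halfwidth=_as_range(ident.get("groove_halfwidth", (3.0, 5.0))),
                bead_relief=_as_range(ident.get("bead_relief", (0.2, 0.4))),
            )
        if "capture" in cfg:
            cap = cfg["capture"]
            defaults = CaptureRanges()
            kw["capture_ranges"] = CaptureRanges(
                **{
                    f: _as_range(cap.get(f, getattr(defaults, f)))
                    for f in defaults.__dataclass_fields__
                }
            )
        return CohortSpec(
            subjects=tuple(subjects),
            master_seed=int(cfg.get("master_seed", 0)),
            **kw,
        )


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """The baseline longitudinal cohort: 60 subjects, 3 captures each."""
    return CohortSpec(
        subjects=tuple((f"S{i:03d}", 3) for i in range(60)), master_seed=master_seed
    )


def combined_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """The enlarged cohort: 60 subjects x 3 captures plus 10 extra
    subjects (8 with 10 captures, 2 with 9), 278 images of 70 subjects."""
    subjects = [(f"S{i:03d}", 3) for i in range(60)]
    subjects += [(f"X{i:03d}", 10) for i in range(8)]
    subjects += [(f"X{i:03d}", 9) for i in range(8, 10)]
    return CohortSpec(subjects=tuple(subjects), master_seed=master_seed)


def _derived_seed(master_seed: int, subject_index: int, counter: int) -> int:
    ss = np.random.SeedSequence([master_seed, subject_index, counter])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def identity_for(spec: CohortSpec, subject_index: int) -> IdentityPattern:
    """Subject's latent pattern under the cohort's counter seeding scheme
    (counter 0 of the subject's stream)."""
    sid, _ = spec.subjects[subject_index]
    seed = _derived_seed(spec.master_seed, subject_index, 0)
    return generate_identity(sid, seed, spec.identity_params)


def capture_params_for(
    spec: CohortSpec, subject_index: int, capture_index: int
) -> CaptureParams:
    """Capture perturbation drawn from the (subject, capture) stream
    (counter = capture_index + 1; counter 0 is the identity stream)."""
    r = spec.capture_ranges
    seed = _derived_seed(spec.master_seed, subject_index, capture_index + 1)
    rng = np.random.default_rng(seed)
    return CaptureParams(
        rotation=float(rng.uniform(*r.rotation)),
        translation=(float(rng.uniform(*r.translation)), float(rng.uniform(*r.translation))),
        scale=float(rng.uniform(*r.scale)),
        brightness_offset=float(rng.uniform(*r.brightness_offset)),
        contrast_gain=float(rng.uniform(*r.contrast_gain)),
        blur_sigma=float(rng.uniform(*r.blur_sigma)),
        noise_sigma=float(rng.uniform(*r.noise_sigma)),
        illumination_tilt=(
            float(rng.uniform(*r.illumination_tilt)),
            float(rng.uniform(*r.illumination_tilt)),
        ),
        capture_seed=int(rng.integers(2**31)),
    )


MANIFEST_COLUMNS = ("subject_id", "capture_index", "path", "roi_x", "roi_y", "roi_w", "roi_h")


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write the cohort to ``out_dir``: one 8-bit grayscale PNG per
    (subject, capture) plus ``manifest.csv``.  Returns the manifest path.

    The ROI of a synthetic image is the whole canvas (nostril/philtrum
    surround is not modelled), so every manifest ROI rectangle covers the
    full image.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    h, w = spec.identity_params.canvas_size
    rows = []
    for s_idx, (sid, n_caps) in enumerate(spec.subjects):
        pattern = render_pattern(identity_for(spec, s_idx))
        for c_idx in range(n_caps):
            cp = capture_params_for(spec, s_idx, c_idx)
            img = _perturb(pattern, cp)
            rel = f"images/{sid}_{c_idx:02d}.png"
            _write_png(out_dir / rel, img)
            rows.append((sid, c_idx, rel, 0, 0, w, h))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest


def _write_png(path: Path, img: np.ndarray) -> None:
    u8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(u8, mode="L").save(path, format="PNG")
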