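"""Gabor-bank encoding of an ROI into a binary biometric template.

The template is a rectangular array of 0s and 1s: the ROI is correlated
with a bank of zero-mean complex Gabor kernels (several orientations x
wavelengths), the responses are sampled on a coarse grid, and each
sampled component is binarized by sign.  Both quadrature components
(real and imaginary) are encoded by default, one bit plane each; a
real-only mode is retained for the single-bit-per-filter reading.

Response convention: ``response(p) = sum_u roi(p + u) * conj(g(u))``
(correlation with the conjugate kernel) with reflect border handling.
The real (even) kernel part has its mean subtracted so a constant ROI
yields exactly zero response; the imaginary (odd) part is zero-mean by
antisymmetry.
"""

from __future__ import annotations

import csv
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .errors import ParameterError
from .roi import ROIImage

@dataclass(frozen=True)
class GaborBankParams:
    """Filter-bank layout.

    Defaults — 4 orientations (0/45/90/135 deg), wavelengths 8 and 16 px
    on the 64 px analysis grid, envelope sigma = 0.5 x wavelength, grid
    stride 2 — put typical synthetic bead spacings inside the passband.
    """

    n_orientations: int = 4
    wavelengths: tuple[float, ...] = (8.0, 16.0)
    gaussian_sigma_ratio: float = 0.5
    sample_stride: int = 2
    phase_planes: str = "real_and_imag"  # or "real_only"

    def __post_init__(self) -> None:
        if self.n_orientations < 1:
            raise ParameterError("n_orientations must be >= 1")
        if any(w < 2 for w in self.wavelengths):
            raise ParameterError("all wavelengths must be >= 2 px")
        if self.sample_stride < 1:
            raise ParameterError("sample_stride must be >= 1")
        if self.phase_planes not in ("real_only", "real_and_imag"):
            raise ParameterError(f"unknown phase_planes mode: {self.phase_planes!r}")

    @property
    def orientations(self) -> np.ndarray:
        """Orientations in radians, evenly spaced over [0, pi)."""
        return np.arange(self.n_orientations) * (np.pi / self.n_orientations)

    @property
    def n_filters(self) -> int:
        return self.n_orientations * len(self.wavelengths)

    @property
    def n_planes(self) -> int:
        return self.n_filters * (2 if self.phase_planes == "real_and_imag" else 1)

    def fingerprint(self) -> int:
        """Stable 32-bit hash identifying the bank configuration."""
        desc = repr(
            (
                self.n_orientations,
                tuple(float(w) for w in self.wavelengths),
                float(self.gaussian_sigma_ratio),
                int(self.sample_stride),
                self.phase_planes,
            )
        )
        return zlib.crc32(desc.encode()) & 0xFFFFFFFF


@dataclass(frozen=True)
class Template:
    """Binary biometric template: bit planes on the sampling grid."""

    subject_id: str
    capture_index: int
    bits: np.ndarray  # (planes, grid_h, grid_w) uint8 of 0/1
    sample_stride: int
    origin: tuple[int, int]  # ROI pixel of grid cell (0, 0)
    bank_fingerprint: int

    def comparable_with(self, other: "Template") -> bool:
        return (
            self.bits.shape == other.bits.shape
            and self.bank_fingerprint == other.bank_fingerprint
        )


def gabor_kernel(wavelength: float, orientation: float, sigma_ratio: float) -> np.ndarray:
    """Zero-mean complex Gabor kernel (carrier along ``orientation``,
    Gaussian envelope sigma = sigma_ratio * wavelength)."""
    sigma = sigma_ratio * wavelength
    radius = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    u = x * np.cos(orientation) + y * np.sin(orientation)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    kern = envelope * np.exp(1j * 2.0 * np.pi * u / wavelength)
    kern = kern - kern.real.mean()  # imaginary part is zero-mean by antisymmetry
    kern = kern - 1j * kern.imag.mean()
    return kern


def _bank_kernels(bank: GaborBankParams) -> list[np.ndarray]:
    return [
        gabor_kernel(wl, theta, bank.gaussian_sigma_ratio)
        for theta in bank.orientations
        for wl in bank.wavelengths
    ]


def gabor_responses(roi: ROIImage | np.ndarray, bank: GaborBankParams) -> np.ndarray:
    """Complex response stack, shape (n_filters, grid_h, grid_w).

    Filter order: orientation-major, wavelength-minor.  Responses are the
    dense correlation (reflect borders) evaluated at pixels spaced by
    ``sample_stride`` starting at (0, 0).
    """
    img = np.asarray(roi.pixels if isinstance(roi, ROIImage) else roi, dtype=np.float64)
    h, w = img.shape
    if max(bank.wavelengths) > min(h, w):
        raise ParameterError(
            f"wavelength {max(bank.wavelengths)} exceeds ROI side {min(h, w)}"
        )
    s = bank.sample_stride
    out = []
    for kern in _bank_kernels(bank):
        radius = kern.shape[0] // 2
        padded = np.pad(img, radius, mode="symmetric")
        # corr(p) = sum_u img(p+u) conj(g(u)); convolution with the flipped
        # conjugate kernel realises it
        dense = fftconvolve(padded, np.conj(kern)[::-1, ::-1], mode="valid")
        out.append(dense[::s, ::s])
    return np.stack(out)


def binarize(
    responses: np.ndarray,
    bank: GaborBankParams,
    subject_id: str = "",
    capture_index: int = 0,
) -> Template:
    """Sign-binarize a response stack into a template.

    bit = 1 where the component is >= 0, else 0.  With
    ``real_and_imag``, filter k contributes planes 2k (real) and
    2k+1 (imaginary).
    """
    responses = np.asarray(responses)
    if not np.all(np.isfinite(responses)):
        raise ParameterError("non-finite responses")
    if bank.phase_planes == "real_and_imag":
        planes = np.empty((2 * responses.shape[0],) + responses.shape[1:])
        planes[0::2] = responses.real
        planes[1::2] = responses.imag
    else:
        planes = responses.real
    bits = (planes >= 0).astype(np.uint8)
    return Template(
        subject_id=subject_id,
        capture_index=capture_index,
        bits=bits,
        sample_stride=bank.sample_stride,
        origin=(0, 0),
        bank_fingerprint=bank.fingerprint(),
    )


def encode(roi: ROIImage, bank: GaborBankParams | None = None) -> Template:
    """ROI -> binary template (gabor_responses then binarize)."""
    bank = bank or GaborBankParams()
    return binarize(
        gabor_responses(roi, bank), bank, roi.subject_id, roi.capture_index
    )


# ---------------------------------------------------------------------------
# template storage: one "CNT1" binary file per template plus an index CSV

_MAGIC = b"CNT1"
_HEADER = struct.Struct("<5I")  # planes, grid_h, grid_w, stride, bank fingerprint


def template_to_bytes(t: Template) -> bytes:
    """Serialize: magic, little-endian header, row-major bit-packed
    payload (8 bits/byte, rows zero-padded to whole bytes)."""
    p, h, w = t.bits.shape
    packed = np.packbits(t.bits, axis=-1)  # pads each row to a byte boundary
    return (
        _MAGIC
        + _HEADER.pack(p, h, w, t.sample_stride, t.bank_fingerprint)
        + packed.tobytes()
    )


def template_from_bytes(data: bytes, subject_id: str = "", capture_index: int = 0) -> Template:
    if data[:4] != _MAGIC:
        raise ValueError("not a CNT1 template file")
    p, h, w, stride, fp = _HEADER.unpack_from(data, 4)
    row_bytes = (w + 7) // 8
    payload = np.frombuffer(data, dtype=np.uint8, offset=4 + _HEADER.size)
    if payload.size != p * h * row_bytes:
        raise ValueError("template payload size mismatch")
    bits = np.unpackbits(payload.reshape(p, h, row_bytes), axis=-1, count=w)
    return Template(
        subject_id=subject_id,
        capture_index=capture_index,
        bits=np.ascontiguousarray(bits),
        sample_stride=stride,
        origin=(0, 0),
        bank_fingerprint=fp,
    )


def save_templates(templates: list[Template], out_dir: str | Path) -> Path:
    """Write one .cnt file per template and an index.csv; returns the
    index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = out_dir / "index.csv"
    with open(index, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "capture_index", "path"])
        for t in templates:
            name = f"{t.subject_id}_{t.capture_index:02d}.cnt"
            (out_dir / name).write_bytes(template_to_bytes(t))
            writer.writerow([t.subject_id, t.capture_index, name])
    return index


def load_templates(in_dir: str | Path) -> list[Template]:
    in_dir = Path(in_dir)
    index = in_dir / "index.csv"
    out = []
    with open(index, newline="") as fh:
        for row in csv.DictReader(fh):
            data = (in_dir / row["path"]).read_bytes()
            out.append(
                template_from_bytes(data, row["subject_id"], int(row["capture_index"]))
            )
    return out
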