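"""Reading and writing plate scans with physical scale, and the plate filename dialect.

A plate scan is a single RGB TIFF of all detached leaves of one plant, taken
once per leaf side (abaxial = lower, adaxial = upper; the plate is turned over
between the two exposures).  Metadata — which side, which ecotype, which
biological replicate, how many leaves were mounted — is carried in the file
name as an underscore-delimited token string, e.g. ``D_A_1_I_2_K1_12``.

The exact token layout varies between labs, so it is expressed as a
configurable template (see :class:`FilenameTemplate`) rather than hard-coded.
Physical scale precedence on read: explicit argument > TIFF resolution tag >
configured default dpi.

Conventions used throughout the package: pixel coordinates are 0-based,
row-major with the origin at the top-left corner; boxes are half-open
``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

import fractions
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "ABAXIAL",
    "ADAXIAL",
    "SIDES",
    "DEFAULT_SIDE_CODES",
    "DEFAULT_TEMPLATE",
    "MICRONS_PER_INCH",
    "ScanMeta",
    "ScanImage",
    "FilenameTemplate",
    "FilenameError",
    "parse_scan_filename",
    "encode_scan_filename",
    "dpi_to_um_per_px",
    "read_scan",
    "write_scan",
]

ABAXIAL = "abaxial"
ADAXIAL = "adaxial"
SIDES = (ABAXIAL, ADAXIAL)

#: Default mapping from filename side token to side name.  "D" (dolna/down)
#: marks the lower (abaxial) surface, "G" the upper (adaxial) one.
DEFAULT_SIDE_CODES: Mapping[str, str] = {"D": ABAXIAL, "G": ADAXIAL}

MICRONS_PER_INCH = 25400.0

#: Maximum plate edge supported, in mm (10 x 10 cm scanning area).
MAX_PLATE_MM = 100.0


class FilenameError(ValueError):
    """A scan filename does not match the configured template."""


@dataclass(frozen=True)
class ScanMeta:
    """Decoded plate-scan filename metadata."""

    side: str
    ecotype_label: str
    ecotype_index: int
    replicate: int
    declared_leaf_count: int
    batch: str = "K1"
    raw_name: str = ""

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        for name in ("ecotype_index", "replicate", "declared_leaf_count"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def plant_key(self) -> tuple:
        """Identity of the plant this scan belongs to (both sides share it)."""
        return (self.ecotype_label, self.ecotype_index, self.replicate, self.batch)


@dataclass(frozen=True)
class FilenameTemplate:
    """Positional token layout of a plate-scan filename.

    ``fields`` is an ordered sequence of token roles.  Recognised roles:
    ``side``, ``ecotype_label``, ``ecotype_index``, ``replicate``,
    ``batch``, ``leaf_count`` and ``literal:<text>`` for fixed separator
    tokens.  The default layout decodes ``D_A_1_I_2_K1_12`` as
    side=abaxial, ecotype A-1, replicate 2 (tagged "I"), batch K1,
    12 leaves declared.
    """

    fields: Sequence[str] = (
        "side",
        "ecotype_label",
        "ecotype_index",
        "literal:I",
        "replicate",
        "batch",
        "leaf_count",
    )
    side_codes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SIDE_CODES)
    )

    def code_for_side(self, side: str) -> str:
        for code, s in self.side_codes.items():
            if s == side:
                return code
        raise FilenameError(f"no filename code configured for side {side!r}")


DEFAULT_TEMPLATE = FilenameTemplate()


def parse_scan_filename(
    name: str, template: FilenameTemplate = DEFAULT_TEMPLATE
) -> ScanMeta:
    """Decode a plate-scan filename into :class:`ScanMeta`.

    ``name`` may carry a directory and/or a ``.tif``/``.tiff`` extension;
    both are stripped before tokenising.

    Raises
    ------
    FilenameError
        If the token count does not match the template, a literal token
        differs, the side code is unknown, or an integer token does not
        parse as a positive integer.
    """
    stem = os.path.basename(name)
    for ext in (".tiff", ".tif", ".TIF", ".TIFF"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    tokens = stem.split("_")
    if len(tokens) != len(template.fields):
        raise FilenameError(
            f"{name!r}: expected {len(template.fields)} underscore-delimited "
            f"tokens, got {len(tokens)}"
        )
    values: dict = {}
    for tok, role in zip(tokens, template.fields):
        if role.startswith("literal:"):
            want = role.split(":", 1)[1]
            if tok != want:
                raise FilenameError(f"{name!r}: expected literal token {want!r}, got {tok!r}")
        elif role == "side":
            if tok not in template.side_codes:
                raise FilenameError(
                    f"{name!r}: unknown side code {tok!r} "
                    f"(known: {sorted(template.side_codes)})"
                )
            values["side"] = template.side_codes[tok]
        elif role == "ecotype_label":
            values["ecotype_label"] = tok
        elif role == "batch":
            values["batch"] = tok
        elif role in ("ecotype_index", "replicate", "leaf_count"):
            try:
                ival = int(tok)
            except ValueError:
                raise FilenameError(f"{name!r}: token {tok!r} for {role} is not an integer")
            if ival < 1:
                raise FilenameError(f"{name!r}: {role} must be >= 1, got {ival}")
            key = "declared_leaf_count" if role == "leaf_count" else role
            values[key] = ival
        else:  # pragma: no cover - template validated at construction in practice
            raise FilenameError(f"unknown template role {role!r}")
    missing = {"side", "ecotype_label", "ecotype_index", "replicate", "declared_leaf_count"} - set(values)
    if missing:
        raise FilenameError(f"template does not populate fields: {sorted(missing)}")
    return ScanMeta(raw_name=stem, **values)


def encode_scan_filename(
    meta: ScanMeta, template: FilenameTemplate = DEFAULT_TEMPLATE
) -> str:
    """Inverse of :func:`parse_scan_filename`: metadata back to a name stem."""
    tokens = []
    for role in template.fields:
        if role.startswith("literal:"):
            tokens.append(role.split(":", 1)[1])
        elif role == "side":
            tokens.append(template.code_for_side(meta.side))
        elif role == "ecotype_label":
            tokens.append(meta.ecotype_label)
        elif role == "ecotype_index":
            tokens.append(str(meta.ecotype_index))
        elif role == "replicate":
            tokens.append(str(meta.replicate))
        elif role == "batch":
            tokens.append(meta.batch)
        elif role == "leaf_count":
            tokens.append(str(meta.declared_leaf_count))
        else:
            raise FilenameError(f"unknown template role {role!r}")
    return "_".join(tokens)


def dpi_to_um_per_px(dpi: float) -> float:
    """Physical pixel edge length in µm for a scan resolution in dots/inch.

    8500 dpi — the scanning resolution the protocol targets — gives
    25400/8500 ≈ 2.988 µm, i.e. approximately 3 µm per pixel.
    """
    if not np.isfinite(dpi) or dpi <= 0:
        raise ValueError(f"dpi must be a positive finite number, got {dpi}")
    return MICRONS_PER_INCH / float(dpi)


@dataclass
class ScanImage:
    """One plate scan: 8-bit RGB pixels plus physical scale and metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    um_per_px: float
    side: str
    meta: ScanMeta | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 3) uint8 array")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be > 0")
        max_px = MAX_PLATE_MM * 1000.0 / self.um_per_px
        if px.shape[0] > max_px + 1 or px.shape[1] > max_px + 1:
            raise ValueError(
                f"image of {px.shape[:2]} px at {self.um_per_px} µm/px exceeds "
                f"the {MAX_PLATE_MM/10:g} cm plate"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]

    @property
    def dpi(self) -> float:
        return MICRONS_PER_INCH / self.um_per_px

    @property
    def px_area_mm2(self) -> float:
        """Area of one pixel in mm²."""
        return (self.um_per_px / 1000.0) ** 2

    def with_meta(self, meta: ScanMeta) -> "ScanImage":
        return ScanImage(self.pixels, self.um_per_px, self.side, meta)


def _resolution_to_dpi(tags) -> float | None:
    """Extract dots-per-inch from TIFF X/YResolution + ResolutionUnit tags."""
    try:
        xres = tags["XResolution"].value
        unit = tags.get("ResolutionUnit")
        unit_val = getattr(unit, "value", 2)
        unit_code = int(getattr(unit_val, "value", unit_val))
    except (KeyError, TypeError):
        return None
    if isinstance(xres, tuple):
        num, den = xres
        if den == 0:
            return None
        per_unit = num / den
    else:
        per_unit = float(xres)
    if per_unit <= 0:
        return None
    if unit_code == 2:  # inch
        return per_unit
    if unit_code == 3:  # centimetre
        return per_unit * 2.54
    return None


def read_scan(
    path: str,
    *,
    um_per_px: float | None = None,
    default_dpi: float | None = None,
    template: FilenameTemplate = DEFAULT_TEMPLATE,
    meta_override: ScanMeta | None = None,
) -> ScanImage:
    """Read a plate-scan TIFF, resolving scale and filename metadata.

    Scale precedence: explicit ``um_per_px`` argument, then the file's
    resolution tags, then ``default_dpi``; if none is available an error is
    raised rather than guessing.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            pixels = page.asarray()
            tag_dpi = _resolution_to_dpi(page.tags)
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path}: not a readable TIFF file ({exc})") from exc
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit pixels, got {pixels.dtype}")

    if um_per_px is None:
        if tag_dpi is not None:
            um_per_px = dpi_to_um_per_px(tag_dpi)
        elif default_dpi is not None:
            um_per_px = dpi_to_um_per_px(default_dpi)
        else:
            raise ValueError(
                f"{path}: no resolution tag and no configured default dpi; "
                "cannot establish physical scale"
            )

    meta = meta_override
    if meta is None:
        try:
            meta = parse_scan_filename(path, template)
        except FilenameError:
            meta = None
    side = meta.side if meta is not None else ABAXIAL
    return ScanImage(pixels=pixels, um_per_px=um_per_px, side=side, meta=meta)


def write_scan(scan: ScanImage, path: str) -> str:
    """Write a scan as an 8-bit RGB TIFF with resolution tags; returns ``path``."""
    dpi = fractions.Fraction(scan.dpi).limit_denominator(10**6)
    tifffile.imwrite(
        path,
        scan.pixels,
        photometric="rgb",
        resolution=((dpi.numerator, dpi.denominator), (dpi.numerator, dpi.denominator)),
        resolutionunit=2,
    )
    return path
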