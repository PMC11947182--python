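"""Reading and writing MSI image data and tabular resources.

Pixel spectra travel as :class:`MSISample` objects built from imzML/ibd file
pairs (continuous or processed binary mode).  Acquisition order is taken to be
the spectrum storage order of the imzML file, the only ordering observable in
the format; line-scanning instruments store spectra in the order they were
acquired.  Coordinates follow the imzML convention and are 1-based.

Tabular resources — the LC-MS/MS-validated lipid annotation library, manual
m/z exclusion lists and cluster-to-region maps — are plain CSV/TSV/YAML.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("msiregion")

#: Lipid classes recognised by the shorthand parser.
LIPID_CLASSES = frozenset(
    {
        "FA", "AC", "CL", "Cer", "CE", "DhSM", "HexCer",
        "LPC", "LPE", "LPG", "LPI", "SM",
        "PA", "PC", "PE", "PG", "PI", "PS", "TG",
    }
)

#: Glycerophospholipid classes (incl. lyso forms); major lung-surfactant lipids.
GLYCEROPHOSPHOLIPID_CLASSES = frozenset(
    {"PC", "PE", "PG", "PI", "PS", "PA", "LPC", "LPE", "LPG", "LPI"}
)

_SHORTHAND_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+)\s+(?P<chains>\d+:\d+(?:/\d+:\d+)*)\s*$"
)


class SchemaError(ValueError):
    """A required column is missing from a tabular resource."""


@dataclass
class PixelSpectrum:
    """One pixel's mass spectrum with its raster position.

    ``x``/``y`` are 1-based imzML coordinates; ``acquisition_index`` is the
    1-based position in the instrument's acquisition sequence.
    """

    x: int
    y: int
    acquisition_index: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("pixel m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.x < 1 or self.y < 1 or self.acquisition_index < 1:
            raise ValueError("coordinates and acquisition index are 1-based")


@dataclass
class MSISample:
    """A tissue section's pixel spectra plus acquisition metadata."""

    sample_id: str
    ionization_mode: str  # "positive" | "negative"
    pixels: list[PixelSpectrum]
    group: str = ""
    sex: str = ""
    run_order: int = 1
    scan_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.ionization_mode not in ("positive", "negative"):
            raise ValueError(f"unknown ionization mode {self.ionization_mode!r}")
        coords = [(p.x, p.y) for p in self.pixels]
        if len(set(coords)) != len(coords):
            raise ValueError(f"duplicate pixel coordinates in sample {self.sample_id}")
        idx = sorted(p.acquisition_index for p in self.pixels)
        if idx != list(range(1, len(self.pixels) + 1)):
            raise ValueError("acquisition indices must be a permutation of 1..n_pixels")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def pixels_in_acquisition_order(self) -> list[PixelSpectrum]:
        return sorted(self.pixels, key=lambda p: p.acquisition_index)


@dataclass
class LibraryEntry:
    """One LC-MS/MS-validated lipid: identity plus expected observed m/z.

    ``expected_mz`` is the m/z of the observed species — the LC-MS/MS table
    already encodes the adduct, so no adduct enumeration happens here.
    """

    lipid_name: str
    lipid_class: str
    total_carbons: Optional[int]
    total_double_bonds: Optional[int]
    expected_mz: float
    ionization_mode: str
    source: str = "slide_scrape"
    caveat: str = ""


@dataclass
class AnnotationLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.expected_mz <= 0:
                raise ValueError(f"non-positive expected m/z for {e.lipid_name}")
            key = (e.lipid_name, e.ionization_mode, round(e.expected_mz, 6))
            if key in seen:
                raise ValueError(f"duplicate library row {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def for_mode(self, mode: str) -> "AnnotationLibrary":
        return AnnotationLibrary(
            [e for e in self.entries if e.ionization_mode == mode]
        )


def parse_lipid_shorthand(name: str) -> Optional[tuple[str, int, int]]:
    """Parse shorthand like ``"PC 32:0"`` or ``"PE 18:0/22:6"``.

    Returns ``(class, total_carbons, total_double_bonds)`` with chain sums, or
    None when the string does not follow the grammar or the class token is
    unknown.
    """
    m = _SHORTHAND_RE.match(name)
    if not m:
        return None
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        return None
    carbons = 0
    dbs = 0
    for chain in m.group("chains").split("/"):
        c, d = chain.split(":")
        carbons += int(c)
        dbs += int(d)
    return cls, carbons, dbs


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def read_imzml(
    path: str | Path,
    sample_id: Optional[str] = None,
    ionization_mode: str = "positive",
    group: str = "",
    sex: str = "",
    run_order: int = 1,
) -> MSISample:
    """Read a paired .imzML/.ibd file into an :class:`MSISample`.

    Both continuous and processed binary modes are supported.  The spectrum
    storage order defines ``acquisition_index`` (1-based); re-reading never
    permutes pixels.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise IOError(f"imzML file not found: {path}")
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise IOError(f"missing binary data file: {ibd}")

    parser = ImzMLParser(str(path))
    pixels: list[PixelSpectrum] = []
    for i, coord in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        pixels.append(
            PixelSpectrum(
                x=int(coord[0]),
                y=int(coord[1]),
                acquisition_index=i + 1,
                mz=np.asarray(mz, dtype=np.float64),
                intensity=np.asarray(inten, dtype=np.float64),
            )
        )
    mz_min = min((p.mz[0] for p in pixels if p.mz.size), default=0.0)
    mz_max = max((p.mz[-1] for p in pixels if p.mz.size), default=0.0)
    return MSISample(
        sample_id=sample_id or path.stem,
        ionization_mode=ionization_mode,
        pixels=pixels,
        group=group,
        sex=sex,
        run_order=run_order,
        scan_range=(mz_min, mz_max),
    )


def write_imzml(sample: MSISample, path: str | Path, mode: str = "processed") -> Path:
    """Write an :class:`MSISample` as standard imzML+ibd.

    ``mode`` is the imzML binary mode: "processed" stores per-pixel m/z axes,
    "continuous" a shared axis.  Spectra are written in acquisition order so
    that a round trip preserves it.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if sample.n_pixels == 0:
        raise ValueError("cannot write a sample with no pixel spectra")
    path = Path(path)
    try:
        with ImzMLWriter(str(path), mode=mode) as writer:
            for p in sample.pixels_in_acquisition_order():
                writer.addSpectrum(p.mz, p.intensity, (p.x, p.y))
    except OSError as exc:
        raise IOError(f"cannot write imzML to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Tabular resources
# ---------------------------------------------------------------------------

def load_annotation_library(
    path: str | Path,
    name_col: str = "name",
    class_col: str = "class",
    mz_col: str = "mz",
    mode_col: str = "mode",
    source_col: str = "source",
) -> AnnotationLibrary:
    """Load a lipid annotation library from a CSV/TSV table.

    Lipid shorthand names are parsed into class / total carbons / total double
    bonds; rows whose name does not follow the grammar keep their name and
    take the class from the explicit class column.  Parsing is total: every
    row yields an entry or a counted, logged skip — nothing drops silently.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (name_col, class_col, mz_col, mode_col):
        if col not in df.columns:
            raise SchemaError(f"annotation library missing required column {col!r}")
    if df.empty:
        warnings.warn(f"annotation library {path} is empty", stacklevel=2)
        return AnnotationLibrary([])

    entries: list[LibraryEntry] = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            mz = float(row[mz_col])
            mode = str(row[mode_col]).strip().lower()
            if mode not in ("positive", "negative"):
                raise ValueError(f"unknown mode {mode!r}")
            name = str(row[name_col]).strip()
            parsed = parse_lipid_shorthand(name)
            if parsed is not None:
                cls, carbons, dbs = parsed
            else:
                cls = str(row[class_col]).strip()
                carbons, dbs = None, None
            entries.append(
                LibraryEntry(
                    lipid_name=name,
                    lipid_class=cls,
                    total_carbons=carbons,
                    total_double_bonds=dbs,
                    expected_mz=mz,
                    ionization_mode=mode,
                    source=str(row.get(source_col, "slide_scrape")),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping library row %s: %s", dict(row), exc)
    lib = AnnotationLibrary(entries)
    lib.n_skipped = n_skipped
    return lib


def load_exclusion_list(
    path: str | Path,
    mz_col: str = "mz",
    tol_col: str = "tolerance_ppm",
    default_tolerance_ppm: float = 5.0,
) -> list[tuple[float, float]]:
    """Load manual exclusion windows as ``(mz, tolerance_ppm)`` pairs."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if mz_col not in df.columns:
        raise SchemaError(f"exclusion list missing required column {mz_col!r}")
    tol = (
        df[tol_col].astype(float)
        if tol_col in df.columns
        else pd.Series(default_tolerance_ppm, index=df.index)
    )
    return list(zip(df[mz_col].astype(float), tol))


def load_region_map(path: str | Path) -> dict[str, dict[int, str]]:
    """Load a cluster-to-region map: ``{sample_id: {cluster_id: region}}``.

    YAML format; region vocabulary is validated downstream by
    :func:`msiregion.segment.assign_regions`.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        str(sample): {int(k): str(v) for k, v in mapping.items()}
        for sample, mapping in (raw or {}).items()
    }


def load_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Load the per-sample metadata manifest (sample_id, mode, group, sex, run_order)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "ionization_mode", "group", "sex", "run_order"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"sample metadata missing columns: {sorted(missing)}")
    return df
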