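"""Readers and writers for every external representation the pipeline touches.

Supported formats
-----------------
* profile spectra: mzML (subset: 64/32-bit little-endian float arrays,
  optional zlib compression) and two-column ``xy`` text (whitespace or
  comma separated)
* peak tables: TSV with a fixed header
* aligned sequences: aligned FASTA
* trees: Newick (write)
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("algafp")

DEFAULT_MASS_WINDOW = (2000.0, 20000.0)

PEAK_TABLE_COLUMNS = ["sample_id", "mz", "intensity", "snr", "width"]

SEQ_ALPHABET = set("ACGTUN-")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


# ---------------------------------------------------------------------------
# ProfileSpectrum
# ---------------------------------------------------------------------------

@dataclass
class ProfileSpectrum:
    """A continuous m/z-intensity trace with acquisition metadata.

    Invariants (enforced on construction): equal-length arrays, strictly
    increasing m/z, finite intensities, all points inside ``mass_window``.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_index: int = 1
    burst_index: int | None = None
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("mz and intensity must be 1-D")
        if len(self.mz) != len(self.intensity):
            raise FormatError(
                f"length mismatch: {len(self.mz)} mz vs {len(self.intensity)} intensities"
            )
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise FormatError("mz values must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("intensities must be finite")
        if self.replicate_index < 1:
            raise FormatError("replicate_index must be >= 1")
        lo, hi = self.mass_window
        if len(self.mz) and (self.mz[0] < lo or self.mz[-1] > hi):
            raise FormatError("mz values outside mass_window")

    def __len__(self) -> int:
        return len(self.mz)

    def replace_intensity(self, intensity: np.ndarray) -> "ProfileSpectrum":
        """Return a copy with a new intensity array on the same m/z grid."""
        return ProfileSpectrum(
            mz=self.mz.copy(),
            intensity=np.asarray(intensity, dtype=float),
            sample_id=self.sample_id,
            replicate_index=self.replicate_index,
            burst_index=self.burst_index,
            mass_window=self.mass_window,
            metadata=dict(self.metadata),
        )

    def replace_mz(self, mz: np.ndarray) -> "ProfileSpectrum":
        return ProfileSpectrum(
            mz=np.asarray(mz, dtype=float),
            intensity=self.intensity.copy(),
            sample_id=self.sample_id,
            replicate_index=self.replicate_index,
            burst_index=self.burst_index,
            mass_window=self.mass_window,
            metadata=dict(self.metadata),
        )


def _window_and_repair(
    mz: np.ndarray,
    intensity: np.ndarray,
    mass_window: tuple[float, float],
    source: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Sort, merge duplicate m/z by intensity sum, and clip to the window."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    # merge duplicates by summing intensities (preserves total ion signal)
    if len(mz):
        uniq, inverse = np.unique(mz, return_inverse=True)
        if len(uniq) < len(mz):
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, intensity)
            logger.warning(
                "%s: merged %d duplicate m/z points by intensity sum",
                source, len(mz) - len(uniq),
            )
            mz, intensity = uniq, summed
    lo, hi = mass_window
    keep = (mz >= lo) & (mz <= hi)
    if not np.all(keep):
        logger.warning(
            "%s: dropped %d points outside mass window (%g, %g)",
            source, int((~keep).sum()), lo, hi,
        )
    return mz[keep], intensity[keep]


def read_xy_text(
    path: str | Path,
    sample_id: str | None = None,
    replicate_index: int = 1,
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
) -> ProfileSpectrum:
    """Read one spectrum from two-column (m/z, intensity) text.

    Columns may be separated by whitespace or commas; ``#`` lines are
    comments.
    """
    path = Path(path)
    mzs: list[float] = []
    ints: list[float] = []
    header_sample: str | None = None
    header_replicate: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                # honor the metadata comment our writer emits
                for token in line.lstrip("#").split():
                    if token.startswith("sample_id="):
                        header_sample = token.split("=", 1)[1]
                    elif token.startswith("replicate="):
                        header_replicate = int(token.split("=", 1)[1])
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    mz, intensity = _window_and_repair(np.array(mzs), np.array(ints), mass_window, str(path))
    if sample_id is None:
        sample_id = header_sample if header_sample is not None else path.stem
    if header_replicate is not None:
        replicate_index = header_replicate
    return ProfileSpectrum(
        mz=mz,
        intensity=intensity,
        sample_id=sample_id,
        replicate_index=replicate_index,
        mass_window=mass_window,
    )


def write_xy_text(spectrum: ProfileSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={spectrum.sample_id} replicate={spectrum.replicate_index}\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")


# -- minimal mzML support ---------------------------------------------------

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MZ = "MS:1000514"
_ACC_INTENSITY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary(elem: ET.Element) -> tuple[np.ndarray | None, str | None]:
    accs = {cv.get("accession") for cv in elem.iter() if cv.tag.endswith("cvParam")}
    if _ACC_MZ in accs:
        kind = "mz"
    elif _ACC_INTENSITY in accs:
        kind = "intensity"
    else:
        kind = None
    dtype = "<f8" if _ACC_F64 in accs else "<f4"
    node = elem.find(_MZML_NS + "binary")
    if node is None or node.text is None:
        return np.array([]), kind
    raw = base64.b64decode(node.text)
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float), kind


def read_mzml(
    path: str | Path,
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
) -> list[ProfileSpectrum]:
    """Read profile spectra from an mzML file (uncompressed or zlib,
    32/64-bit float arrays)."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not parseable as mzML ({exc})") from exc
    spectra: list[ProfileSpectrum] = []
    for idx, spec_elem in enumerate(tree.getroot().iter(_MZML_NS + "spectrum")):
        arrays: dict[str, np.ndarray] = {}
        for bda in spec_elem.iter(_MZML_NS + "binaryDataArray"):
            values, kind = _decode_binary(bda)
            if kind is not None:
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise FormatError(f"{path}: spectrum {idx} lacks m/z or intensity array")
        mz, intensity = _window_and_repair(
            arrays["mz"], arrays["intensity"], mass_window, f"{path}#{idx}"
        )
        sid = spec_elem.get("id", f"spectrum={idx}")
        spectra.append(
            ProfileSpectrum(
                mz=mz, intensity=intensity, sample_id=sid,
                replicate_index=idx + 1, mass_window=mass_window,
            )
        )
    if not spectra:
        raise FormatError(f"{path}: no spectra found")
    return spectra


def write_mzml(spectra: Sequence[ProfileSpectrum], path: str | Path) -> None:
    """Write spectra to a minimal, standard-conformant mzML file."""

    def b64(a: np.ndarray) -> str:
        return base64.b64encode(struct.pack(f"<{len(a)}d", *a)).decode()

    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        f'  <run id="run1"><spectrumList count="{len(spectra)}">',
    ]
    for i, s in enumerate(spectra):
        parts.append(
            f'    <spectrum index="{i}" id="{s.sample_id}" defaultArrayLength="{len(s)}">'
        )
        parts.append('      <binaryDataArrayList count="2">')
        for acc, name, arr in (
            (_ACC_MZ, "m/z array", s.mz),
            (_ACC_INTENSITY, "intensity array", s.intensity),
        ):
            parts.append("        <binaryDataArray>")
            parts.append(f'          <cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float"/>')
            parts.append(f'          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>')
            parts.append(f'          <cvParam cvRef="MS" accession="{acc}" name="{name}"/>')
            parts.append(f"          <binary>{b64(arr)}</binary>")
            parts.append("        </binaryDataArray>")
        parts.append("      </binaryDataArrayList>")
        parts.append("    </spectrum>")
    parts.append("  </spectrumList></run>")
    parts.append("</mzML>")
    Path(path).write_text("\n".join(parts))


def read_profile_spectra(
    path: str | Path,
    format: str = "xy_text",
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
    **kwargs,
) -> list[ProfileSpectrum]:
    """Read profile spectra from ``path``; ``format`` is ``mzml`` or ``xy_text``."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "mzml":
        return read_mzml(path, mass_window=mass_window)
    if format == "xy_text":
        return [read_xy_text(path, mass_window=mass_window, **kwargs)]
    raise ValueError(f"unknown format {format!r} (expected 'mzml' or 'xy_text')")


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

def validate_peak_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in PEAK_TABLE_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"missing column {col}")
    table = table[PEAK_TABLE_COLUMNS].copy()
    table["sample_id"] = table["sample_id"].astype(str)
    for col in ("mz", "intensity", "snr", "width"):
        table[col] = table[col].astype(float)
    if (table["snr"] < 0).any():
        raise FormatError("snr must be >= 0")
    for sid, group in table.groupby("sample_id"):
        if not group["mz"].is_monotonic_increasing:
            raise FormatError(f"mz not sorted ascending within sample {sid!r}")
    return table


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_peak_table(table).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    table = pd.read_csv(path, sep="\t")
    return validate_peak_table(table)


# ---------------------------------------------------------------------------
# Alignments and trees
# ---------------------------------------------------------------------------

@dataclass
class SeqAlignment:
    """Equal-length aligned sequences over {A,C,G,T,U,N,-} with unique labels."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise FormatError("labels and sequences differ in count")
        if not self.sequences:
            raise FormatError("empty alignment")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("duplicate sequence labels")
        length = len(self.sequences[0])
        for lab, seq in zip(self.labels, self.sequences):
            if len(seq) != length:
                raise FormatError(
                    f"ragged alignment: {lab!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq.upper()) - SEQ_ALPHABET
            if bad:
                raise FormatError(f"{lab!r}: invalid characters {sorted(bad)}")
        self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def read_alignment(path: str | Path) -> SeqAlignment:
    """Read an aligned FASTA file."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    labels: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if labels:
                    seqs.append("".join(current))
                labels.append(line[1:].split()[0])
                current = []
            else:
                current.append(line)
    if labels:
        seqs.append("".join(current))
    if not labels:
        raise FormatError(f"{path}: empty FASTA")
    return SeqAlignment(labels=labels, sequences=seqs)


def write_alignment(aln: SeqAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{lab}\n{seq}\n")


def write_tree(newick: str, path: str | Path) -> None:
    """Write a Newick string (appending the terminating semicolon if absent)."""
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")
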