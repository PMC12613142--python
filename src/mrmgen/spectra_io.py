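"""Reading and writing of multi-CE MS/MS data and transition tables.

Spectra arrive either as centroided mzML plus a manifest (delimited text
mapping spectrum ids to compound, polarity, collision energy and precursor
m/z) or as a flat delimited peak-list fixture.  Both routes produce the same
compound-centric :class:`CompoundSpectrumSet` structures, keyed by collision
energy in eV.

The manifest is authoritative for collision energy and precursor m/z; mzML
metadata, when present and conflicting by more than 0.5 eV, triggers a logged
warning only.  All delimited formats are UTF-8, comma by default with tab
accepted, ``#`` starts a comment line.
"""

from __future__ import annotations

import base64
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

logger = logging.getLogger("mrmgen")

# column orders are fixed so files import into QqQ method editors unchanged
MANIFEST_COLUMNS = ["spectrum_id", "compound_id", "polarity", "collision_energy", "precursor_mz"]
PEAKLIST_COLUMNS = ["compound_id", "polarity", "precursor_mz", "ce", "mz", "intensity"]
TRANSITION_COLUMNS = ["compound_id", "polarity", "precursor_mz", "product_mz", "ce_eV", "role", "rank"]

#: precursor m/z agreement required among spectra of one compound set (Th)
PRECURSOR_MZ_CONSISTENCY = 0.01
#: manifest-vs-mzML collision energy disagreement that triggers a warning (eV)
CE_METADATA_WARN = 0.5


class MrmgenError(Exception):
    """Base class for all package errors."""


class FormatError(MrmgenError):
    """A delimited or mzML input does not have the expected structure."""


class ValidationError(MrmgenError):
    """An input violates a declared invariant (duplicate ids, negative intensity...)."""


class SpectrumNotFoundError(MrmgenError):
    """A manifest spectrum_id is not resolvable in the mzML input."""


class SpectrumModeError(MrmgenError):
    """A spectrum is profile-mode where centroided data is required."""


_POLARITY_ALIASES = {
    "positive": "positive", "pos": "positive", "+": "positive", "p": "positive",
    "negative": "negative", "neg": "negative", "-": "negative", "n": "negative",
}


def normalize_polarity(value: str) -> str:
    """Map a polarity string (case-insensitive; +/-, pos/neg accepted) to
    ``"positive"`` or ``"negative"``."""
    key = str(value).strip().lower()
    if key not in _POLARITY_ALIASES:
        raise ValidationError(f"unrecognized polarity {value!r}")
    return _POLARITY_ALIASES[key]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """One centroided ion signal: m/z in Th, absolute intensity >= 0."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"peak mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class MsmsSpectrum:
    """One centroided MS/MS spectrum at a single collision energy.

    Peaks are stored strictly ascending in m/z; peaks sharing an identical
    m/z are merged by summing intensity on construction (centroiding
    artifact handling).
    """

    compound_id: str
    polarity: str
    collision_energy: float
    precursor_mz: float
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        self.polarity = normalize_polarity(self.polarity)
        if not np.isfinite(self.collision_energy) or self.collision_energy < 0:
            raise ValidationError(
                f"collision energy must be finite and >= 0, got {self.collision_energy}")
        self.peaks = _merge_and_sort(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


def _merge_and_sort(peaks: Iterable[Peak]) -> tuple[Peak, ...]:
    merged: dict[float, float] = {}
    for p in peaks:
        merged[p.mz] = merged.get(p.mz, 0.0) + p.intensity
    return tuple(Peak(mz, inten) for mz, inten in sorted(merged.items()))


@dataclass
class CompoundSpectrumSet:
    """All MS/MS spectra of one compound in one polarity, keyed by CE (eV)."""

    compound_id: str
    polarity: str
    precursor_mz: float
    spectra: dict[float, MsmsSpectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polarity = normalize_polarity(self.polarity)
        if not self.spectra:
            raise ValidationError(f"{self.compound_id}: compound set needs >= 1 spectrum")
        for ce, spec in self.spectra.items():
            if spec.compound_id != self.compound_id or spec.polarity != self.polarity:
                raise ValidationError(
                    f"{self.compound_id}: member spectrum belongs to "
                    f"{spec.compound_id}/{spec.polarity}")
            if abs(spec.precursor_mz - self.precursor_mz) > PRECURSOR_MZ_CONSISTENCY:
                raise ValidationError(
                    f"{self.compound_id}: precursor m/z disagreement "
                    f"({spec.precursor_mz} vs {self.precursor_mz})")
            if abs(spec.collision_energy - ce) > 1e-9:
                raise ValidationError(f"{self.compound_id}: CE key {ce} != spectrum CE")

    @property
    def ce_grid(self) -> list[float]:
        """Sorted collision energies present for this compound."""
        return sorted(self.spectra)


@dataclass
class Manifest:
    """Rows of (spectrum_id, compound_id, polarity, collision_energy, precursor_mz)."""

    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# delimited readers
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         skip_blank_lines=True, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {what} {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{what} {path} is empty (header row required)") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} {path} is missing required column {col!r}")
    return df


def read_manifest(path: str | Path) -> Manifest:
    """Parse a manifest file mapping spectrum ids to compound metadata.

    Polarity is normalized to {positive, negative}; collision energy must be
    a non-negative number; duplicate spectrum ids are a validation error.
    """
    df = _read_delimited(path, MANIFEST_COLUMNS, "manifest")
    if df.empty:
        return Manifest(pd.DataFrame(columns=MANIFEST_COLUMNS))
    out = pd.DataFrame({
        "spectrum_id": df["spectrum_id"].str.strip(),
        "compound_id": df["compound_id"].str.strip(),
        "polarity": df["polarity"].map(normalize_polarity),
        "collision_energy": pd.to_numeric(df["collision_energy"], errors="raise"),
        "precursor_mz": pd.to_numeric(df["precursor_mz"], errors="raise"),
    })
    dupes = out["spectrum_id"][out["spectrum_id"].duplicated()]
    if not dupes.empty:
        raise ValidationError(f"duplicate spectrum_id in manifest: {sorted(set(dupes))}")
    if (out["collision_energy"] < 0).any():
        raise ValidationError("negative collision energy in manifest")
    return Manifest(out.reset_index(drop=True))


def _assemble_sets(records: pd.DataFrame) -> list[CompoundSpectrumSet]:
    """Group per-peak records into CompoundSpectrumSets.

    ``records`` columns: compound_id, polarity, precursor_mz, ce, mz, intensity.
    Shared by the mzML and peak-list routes so both have identical semantics.
    """
    sets: list[CompoundSpectrumSet] = []
    for (cid, pol), group in records.groupby(["compound_id", "polarity"], sort=True):
        precursor = float(group["precursor_mz"].iloc[0])
        spectra: dict[float, MsmsSpectrum] = {}
        for ce, scan in group.groupby("ce", sort=True):
            peaks = tuple(Peak(float(m), float(i))
                          for m, i in zip(scan["mz"], scan["intensity"]))
            spectra[float(ce)] = MsmsSpectrum(
                compound_id=cid, polarity=pol, collision_energy=float(ce),
                precursor_mz=precursor, peaks=peaks)
        sets.append(CompoundSpectrumSet(cid, pol, precursor, spectra))
    return sets


def read_peaklist_fixture(path: str | Path) -> list[CompoundSpectrumSet]:
    """Read a flat delimited peak list into compound sets.

    Columns: compound_id, polarity, precursor_mz, ce, mz, intensity.  Same
    grouping semantics as :func:`load_compound_sets`.
    """
    df = _read_delimited(path, PEAKLIST_COLUMNS, "peak list")
    if df.empty:
        return []
    records = pd.DataFrame({
        "compound_id": df["compound_id"].str.strip(),
        "polarity": df["polarity"].map(normalize_polarity),
        "precursor_mz": pd.to_numeric(df["precursor_mz"]),
        "ce": pd.to_numeric(df["ce"]),
        "mz": pd.to_numeric(df["mz"]),
        "intensity": pd.to_numeric(df["intensity"]),
    })
    if (records["intensity"] < 0).any():
        bad = records.index[records["intensity"] < 0][0]
        raise ValidationError(f"negative intensity in peak list row {bad}")
    return _assemble_sets(records)


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------
# A compact reader for the subset of mzML this pipeline consumes: centroided
# MS2 scans with base64 float arrays (32/64-bit, zlib or uncompressed).

_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_CE = "MS:1000045"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(array_elem) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>; returns (kind, values) with kind in
    {'mz', 'intensity', None}."""
    import zlib

    dtype = np.float64
    compressed = False
    kind = None
    text = ""
    for child in array_elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = np.float32
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)


def _parse_mzml_scans(path: str | Path) -> dict[str, dict]:
    """Parse an mzML file into {spectrum_id: scan dict} with keys ms_level,
    centroid, profile, collision_energy, mz, intensity."""
    import xml.etree.ElementTree as ET

    scans: dict[str, dict] = {}
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _local(elem.tag) != "spectrum":
                continue
            sid = elem.get("id", "")
            scan: dict = {"ms_level": None, "centroid": False, "profile": False,
                          "collision_energy": None,
                          "mz": np.array([]), "intensity": np.array([])}
            for child in elem.iter():
                name = _local(child.tag)
                if name == "cvParam":
                    acc = child.get("accession", "")
                    if acc == _ACC_MS_LEVEL:
                        scan["ms_level"] = int(child.get("value", "0"))
                    elif acc == _ACC_CENTROID:
                        scan["centroid"] = True
                    elif acc == _ACC_PROFILE:
                        scan["profile"] = True
                    elif acc == _ACC_CE:
                        scan["collision_energy"] = float(child.get("value"))
                elif name == "binaryDataArray":
                    kind, values = _decode_binary_array(child)
                    if kind:
                        scan[kind] = values
            scans[sid] = scan
            elem.clear()
    except ET.ParseError as exc:
        raise FormatError(f"cannot parse mzML {path}: {exc}") from exc
    return scans


def load_compound_sets(mzml_path: str | Path, manifest: Manifest) -> list[CompoundSpectrumSet]:
    """Resolve every manifest row against a centroided-MS2 mzML file and group
    the spectra into one CompoundSpectrumSet per (compound_id, polarity).

    Raises SpectrumNotFoundError for unresolvable ids and SpectrumModeError for
    profile-mode scans.  Manifest CE/precursor values win over mzML metadata;
    a >0.5 eV CE conflict is logged as a warning.
    """
    if not Path(mzml_path).exists():
        raise FormatError(f"mzML file not found: {mzml_path}")
    scans = _parse_mzml_scans(mzml_path)
    frames = []
    for row in manifest.rows.itertuples(index=False):
        scan = scans.get(row.spectrum_id)
        if scan is None:
            raise SpectrumNotFoundError(
                f"spectrum_id {row.spectrum_id!r} not found in {mzml_path}")
        if scan["profile"] and not scan["centroid"]:
            raise SpectrumModeError(
                f"spectrum {row.spectrum_id!r} is profile-mode; centroided data required")
        embedded_ce = scan["collision_energy"]
        if embedded_ce is not None and abs(embedded_ce - row.collision_energy) > CE_METADATA_WARN:
            logger.warning(
                "spectrum %s: mzML collision energy %.1f eV conflicts with "
                "manifest %.1f eV; manifest wins",
                row.spectrum_id, embedded_ce, row.collision_energy)
        frames.append(pd.DataFrame({
            "compound_id": row.compound_id,
            "polarity": row.polarity,
            "precursor_mz": row.precursor_mz,
            "ce": row.collision_energy,
            "mz": scan["mz"],
            "intensity": scan["intensity"],
        }))
    if not frames:
        return []
    return _assemble_sets(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# transition tables
# ---------------------------------------------------------------------------

def write_transition_table(transitions: Sequence, path: str | Path) -> None:
    """Write transitions as delimited text (fixed column order; m/z at 4
    decimals, CE as integer eV).  An empty list yields a header-only file."""
    rows = [{
        "compound_id": t.compound_id,
        "polarity": t.polarity,
        "precursor_mz": f"{t.precursor_mz:.4f}",
        "product_mz": f"{t.product_mz:.4f}",
        "ce_eV": int(round(t.ce_eV)),
        "role": t.role,
        "rank": int(t.rank),
    } for t in transitions]
    df = pd.DataFrame(rows, columns=TRANSITION_COLUMNS)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise MrmgenError(f"cannot write transition table {path}: {exc}") from exc


def read_transition_table(path: str | Path):
    """Read a transition table written by :func:`write_transition_table`
    (extra columns are ignored).  Returns a TransitionTable."""
    from .transitions import Transition, TransitionTable

    df = _read_delimited(path, [c.lower() for c in TRANSITION_COLUMNS], "transition table")
    rows = []
    for i, r in df.iterrows():
        try:
            rows.append(Transition(
                compound_id=str(r["compound_id"]).strip(),
                polarity=normalize_polarity(r["polarity"]),
                precursor_mz=float(r["precursor_mz"]),
                product_mz=float(r["product_mz"]),
                ce_eV=int(round(float(r["ce_ev"]))),
                role=str(r["role"]).strip(),
                rank=int(float(r["rank"])),
            ))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"transition table {path}, row {i + 2}: {exc}") from exc
    return TransitionTable(rows)


# ---------------------------------------------------------------------------
# minimal mzML writer (centroided MS2 only)
# ---------------------------------------------------------------------------

def _b64(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *map(float, values))
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="{sid}" defaultArrayLength="{npeaks}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor_mz:.6f}"/>
              </selectedIon>
            </selectedIonList>
            <activation>
              <cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="{ce:.2f}"/>
            </activation>
          </precursor>
        </precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(spectra: Sequence[tuple[str, MsmsSpectrum]], path: str | Path,
               run_id: str = "mrmgen_synthetic") -> None:
    """Write (spectrum_id, MsmsSpectrum) pairs as a minimal centroided mzML.

    Arrays are 64-bit little-endian floats, base64, uncompressed; each scan
    carries ms level 2, polarity, selected-ion m/z and collision energy so
    the file round-trips through standard mzML readers.
    """
    parts = [_MZML_HEADER.format(run_id=escape(run_id, {'"': "&quot;"}), count=len(spectra))]
    for index, (sid, spec) in enumerate(spectra):
        mz_b64 = _b64(spec.mz_array)
        int_b64 = _b64(spec.intensity_array)
        pol_acc, pol_name = (("MS:1000130", "positive scan") if spec.polarity == "positive"
                             else ("MS:1000129", "negative scan"))
        parts.append(_MZML_SPECTRUM.format(
            index=index, sid=escape(sid, {'"': "&quot;"}), npeaks=len(spec.peaks),
            pol_acc=pol_acc, pol_name=pol_name, precursor_mz=spec.precursor_mz,
            ce=spec.collision_energy, mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64))
    parts.append(_MZML_FOOTER)
    try:
        Path(path).write_text("".join(parts), encoding="utf-8")
    except OSError as exc:
        raise MrmgenError(f"cannot write mzML {path}: {exc}") from exc
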