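"""Data model and file I/O for MRM transition panels, peak reports and matrices.

The pipeline consumes four plain-text inputs:

* a **transition table** (CSV) describing the dynamic-MRM acquisition panel:
  one row per compound and isotope channel, with precursor/product m/z,
  fragmentor and collision voltages, retention time and window.  The heavy
  channel of a compound is recognised by a trailing ``13C``/``C13`` token in
  its name; every light-channel compound with a heavy partner is a member of
  the stable-isotope-labelled internal standard (SILIS).
* a **peak report** (CSV): per sample, compound and channel, the integrated
  area under the chromatographic peak (AUC) and its signal-to-noise ratio.
* **UV areas** (CSV): the 254 nm areas of the four canonical nucleosides
  C, U, G, A per sample, used as a loading normaliser.
* **sample metadata** (CSV): tissue, size fraction, post-mortem time,
  replicate, frozen flag.

Abundance matrices (modifications x samples) are written as TSV with
``#``-prefixed comment lines carrying the normalization stage and provenance.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ModificationID",
    "Transition",
    "TransitionTable",
    "PeakRecord",
    "PeakTable",
    "UVRecord",
    "SampleMeta",
    "NormalizedMatrix",
    "STAGES",
    "FRACTIONS",
    "CANONICAL_BASE",
    "normalize_mod_name",
    "split_channel",
    "read_transition_table",
    "read_peak_report",
    "write_peak_report",
    "read_uv_areas",
    "write_uv_areas",
    "read_sample_meta",
    "write_sample_meta",
    "read_matrix",
    "write_matrix",
    "load_table1",
    "load_table2",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


#: Canonical nucleobase of every modification in the acquisition panel
#: (MODOMICS-style short names, ASCII only).
CANONICAL_BASE: dict[str, str] = {
    "Am": "A", "Cm": "C", "D": "U", "Gm": "G", "I": "A", "i6A": "A",
    "m1A": "A", "m1G": "G", "m2,2G": "G", "m6,6A": "A", "m2A": "A",
    "m2G": "G", "m3C": "C", "m3U": "U", "m5C": "C", "m5U": "U",
    "m6A": "A", "m7G": "G", "mcm5U": "U", "ms2i6A": "A", "Psi": "U",
    "Q": "G", "s2C": "C", "s2U": "U", "t6A": "A", "Tm": "U", "Um": "U",
}

# Synonym handling: Unicode superscripts and the Greek Psi appear in the
# literature; keys used throughout the package are ASCII short names.
_SUPERSCRIPTS = str.maketrans("⁰¹²³⁴⁵⁶⁷⁸⁹", "0123456789")
_SYNONYMS = {"Ψ": "Psi", "psi": "Psi", "Y": "Psi"}

#: Closed vocabulary of size fractions.
FRACTIONS = ("tRNA", "RF", "rRNA18S", "rRNA28S", "mRNA", "total")

#: Normalization stages, in the only order in which they may be applied.
STAGES = ("ratio", "uv_normalized", "mean_scaled", "absolute_percent_A")


def normalize_mod_name(name: str) -> str:
    """Return the canonical ASCII short name for a modification.

    Strips caret markup (``m^6,6^A`` -> ``m6,6A``), translates Unicode
    superscript digits, and maps known synonyms (``Ψ`` -> ``Psi``).
    """
    s = name.strip().replace("^", "").translate(_SUPERSCRIPTS)
    return _SYNONYMS.get(s, s)


def split_channel(compound: str) -> tuple[str, str]:
    """Split a compound label into (modification short name, channel).

    The heavy channel is marked by a trailing ``13C`` or ``C13`` token,
    e.g. ``"m6,6A 13C"`` or ``"m1A C13"``; anything else is the light
    (``C12``) channel.
    """
    parts = compound.strip().split()
    if parts and parts[-1].upper() in ("13C", "C13"):
        return normalize_mod_name(" ".join(parts[:-1])), "C13"
    return normalize_mod_name(compound), "C12"


@dataclass(frozen=True)
class ModificationID:
    short_name: str
    canonical_base: str

    def __post_init__(self):
        if self.canonical_base not in "ACGU":
            raise ValueError(f"canonical base must be one of A,C,G,U: {self.canonical_base!r}")


@dataclass(frozen=True)
class Transition:
    """One dynamic-MRM transition (one compound in one isotope channel)."""

    compound: str
    precursor_mz: float
    product_mz: float
    fragmentor: float
    collision_energy: float
    cell_accel: float
    ret_time: float
    ret_window: float
    polarity: str
    channel: str

    def __post_init__(self):
        if not (self.precursor_mz > self.product_mz > 0):
            raise FormatError(
                f"{self.compound}: require precursor m/z > product m/z > 0, "
                f"got {self.precursor_mz}/{self.product_mz}"
            )
        if self.ret_window <= 0:
            raise FormatError(f"{self.compound}: retention window must be positive")
        if self.channel not in ("C12", "C13"):
            raise ValueError(f"channel must be C12 or C13, got {self.channel!r}")


class TransitionTable:
    """The MRM acquisition panel: transitions paired across isotope channels.

    ``silis_members`` is the set of modifications whose light transition has a
    heavy (13C) partner; these are normalised through the internal-standard
    ratio, the remainder (``no_silis``) through raw areas.
    """

    def __init__(self, transitions: Iterable[Transition]):
        self.transitions: list[Transition] = list(transitions)
        seen: set[tuple[str, str]] = set()
        for t in self.transitions:
            key = (t.compound, t.channel)
            if key in seen:
                raise FormatError(f"duplicate transition for {key}")
            seen.add(key)
        c12 = {t.compound for t in self.transitions if t.channel == "C12"}
        c13 = {t.compound for t in self.transitions if t.channel == "C13"}
        self.silis_members: set[str] = c12 & c13
        self.no_silis: set[str] = c12 - c13
        orphans = c13 - c12
        if orphans:
            raise FormatError(f"heavy-channel transitions without light partner: {sorted(orphans)}")

    @property
    def modifications(self) -> list[str]:
        """Panel modifications (light channel), in acquisition order."""
        return [t.compound for t in self.transitions if t.channel == "C12"]

    def get(self, compound: str, channel: str = "C12") -> Transition:
        for t in self.transitions:
            if t.compound == compound and t.channel == channel:
                return t
        raise KeyError((compound, channel))

    def __len__(self) -> int:
        return len(self.transitions)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for t in self.transitions:
            name = t.compound if t.channel == "C12" else f"{t.compound} 13C"
            rows.append({
                "compound": name, "precursor_mz": t.precursor_mz,
                "product_mz": t.product_mz, "fragmentor": t.fragmentor,
                "collision_energy": t.collision_energy, "cell_accel": t.cell_accel,
                "ret_time": t.ret_time, "ret_window": t.ret_window,
                "polarity": t.polarity,
            })
        pd.DataFrame(rows).to_csv(path, index=False)


_T1_COLUMNS = [
    "compound", "precursor_mz", "product_mz", "fragmentor", "collision_energy",
    "cell_accel", "ret_time", "ret_window", "polarity",
]


def read_transition_table(path: str | Path) -> TransitionTable:
    """Read an acquisition panel CSV (nine columns, channel inferred from name)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _T1_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    transitions = []
    for _, row in df.iterrows():
        name, channel = split_channel(str(row["compound"]))
        try:
            transitions.append(Transition(
                compound=name,
                precursor_mz=float(row["precursor_mz"]),
                product_mz=float(row["product_mz"]),
                fragmentor=float(row["fragmentor"]),
                collision_energy=float(row["collision_energy"]),
                cell_accel=float(row["cell_accel"]),
                ret_time=float(row["ret_time"]),
                ret_window=float(row["ret_window"]),
                polarity=str(row["polarity"]).lower(),
                channel=channel,
            ))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: bad row for {row['compound']!r}: {exc}") from exc
    table = TransitionTable(transitions)
    for mod in table.no_silis:
        logger.warning("panel modification %s has no 13C partner (no_silis)", mod)
    return table


@dataclass(frozen=True)
class PeakRecord:
    sample_id: str
    compound: str
    channel: str
    auc: float
    snr: float

    def __post_init__(self):
        if not (np.isfinite(self.auc) and self.auc >= 0):
            raise FormatError(f"{self.sample_id}/{self.compound}: AUC must be finite and >= 0")
        if not (np.isfinite(self.snr) and self.snr >= 0):
            raise FormatError(f"{self.sample_id}/{self.compound}: S/N must be finite and >= 0")


class PeakTable:
    """Per-sample, per-compound, per-channel integrated peak areas with S/N."""

    def __init__(self, records: Iterable[PeakRecord]):
        self.records: list[PeakRecord] = list(records)
        self._index: dict[tuple[str, str, str], PeakRecord] = {}
        for r in self.records:
            key = (r.sample_id, r.compound, r.channel)
            if key in self._index:
                raise FormatError(f"duplicate peak record for {key}")
            self._index[key] = r

    def get(self, sample_id: str, compound: str, channel: str) -> PeakRecord:
        return self._index[(sample_id, compound, channel)]

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._index

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.sample_id not in out:
                out.append(r.sample_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.compound, r.channel, r.auc, r.snr) for r in self.records],
            columns=["sample", "compound", "channel", "auc", "snr"],
        )


def read_peak_report(
    path: str | Path,
    table: TransitionTable,
    allow_extra: bool = False,
) -> PeakTable:
    """Read a peak report CSV (columns sample, compound, channel, auc, snr).

    Compounds not in the acquisition panel are rejected unless
    ``allow_extra``.  Panel (sample, modification) pairs absent from the file
    are materialised as zero-area, zero-S/N records with a logged warning, so
    downstream arithmetic never meets missing cells.
    """
    df = pd.read_csv(path, comment="#")
    required = ["sample", "compound", "channel", "auc", "snr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    known = set(table.modifications)
    records = []
    for i, row in df.iterrows():
        name = normalize_mod_name(str(row["compound"]))
        if name not in known:
            if allow_extra:
                continue
            raise FormatError(f"{path}: row {i + 2}: unknown compound {row['compound']!r}")
        for col in ("auc", "snr"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {i + 2}: non-numeric {col} {row[col]!r}"
                ) from None
        records.append(PeakRecord(
            sample_id=str(row["sample"]), compound=name,
            channel=str(row["channel"]), auc=float(row["auc"]), snr=float(row["snr"]),
        ))
    pt = PeakTable(records)
    filled = []
    for sample in pt.samples:
        for mod in table.modifications:
            for channel in ("C12",) + (("C13",) if mod in table.silis_members else ()):
                if (sample, mod, channel) not in pt:
                    logger.warning(
                        "peak report %s: missing (%s, %s, %s), recorded as 0/0",
                        path, sample, mod, channel,
                    )
                    filled.append(PeakRecord(sample, mod, channel, 0.0, 0.0))
    if filled:
        pt = PeakTable(pt.records + filled)
    return pt


def write_peak_report(peaks: PeakTable, path: str | Path) -> None:
    peaks.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class UVRecord:
    """254 nm UV areas of the four canonical nucleosides for one sample."""

    sample_id: str
    area_C: float
    area_U: float
    area_G: float
    area_A: float

    def __post_init__(self):
        for base in "CUGA":
            v = getattr(self, f"area_{base}")
            if not (np.isfinite(v) and v >= 0):
                raise FormatError(f"{self.sample_id}: UV area {base} must be finite and >= 0")

    @property
    def average(self) -> float:
        return (self.area_C + self.area_U + self.area_G + self.area_A) / 4.0


def read_uv_areas(path: str | Path) -> dict[str, UVRecord]:
    df = pd.read_csv(path, comment="#")
    required = ["sample", "area_C", "area_U", "area_G", "area_A"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = {}
    for _, row in df.iterrows():
        rec = UVRecord(str(row["sample"]), float(row["area_C"]), float(row["area_U"]),
                       float(row["area_G"]), float(row["area_A"]))
        out[rec.sample_id] = rec
    return out


def write_uv_areas(records: Mapping[str, UVRecord] | Iterable[UVRecord], path: str | Path) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    pd.DataFrame(
        [(r.sample_id, r.area_C, r.area_U, r.area_G, r.area_A) for r in records],
        columns=["sample", "area_C", "area_U", "area_G", "area_A"],
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    fraction: str
    time_postmortem: float = 0.0
    replicate: str = "1"
    frozen: bool = True

    def __post_init__(self):
        if self.fraction not in FRACTIONS:
            raise FormatError(
                f"{self.sample_id}: fraction {self.fraction!r} not in {FRACTIONS}"
            )
        if self.time_postmortem < 0:
            raise FormatError(f"{self.sample_id}: post-mortem time must be >= 0")


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, comment="#")
    required = ["sample", "tissue", "fraction", "time_postmortem", "replicate", "frozen"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = {}
    for _, row in df.iterrows():
        meta = SampleMeta(
            sample_id=str(row["sample"]), tissue=str(row["tissue"]),
            fraction=str(row["fraction"]), time_postmortem=float(row["time_postmortem"]),
            replicate=str(row["replicate"]), frozen=bool(row["frozen"]),
        )
        out[meta.sample_id] = meta
    return out


def write_sample_meta(metas: Mapping[str, SampleMeta] | Iterable[SampleMeta], path: str | Path) -> None:
    if isinstance(metas, Mapping):
        metas = metas.values()
    pd.DataFrame(
        [(m.sample_id, m.tissue, m.fraction, m.time_postmortem, m.replicate, m.frozen)
         for m in metas],
        columns=["sample", "tissue", "fraction", "time_postmortem", "replicate", "frozen"],
    ).to_csv(path, index=False)


class NormalizedMatrix:
    """A modifications x samples abundance matrix at a declared stage.

    Values are dense and non-negative; absent peaks are zeros by contract.
    ``stage`` advances only forward through :data:`STAGES`.
    """

    def __init__(self, values: pd.DataFrame, stage: str, provenance: Iterable[str] = ()):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}, expected one of {STAGES}")
        if values.isna().any().any():
            raise ValueError("NormalizedMatrix may not contain missing cells")
        if (values.to_numpy() < 0).any():
            raise ValueError("NormalizedMatrix values must be non-negative")
        self.values = values.astype(float)
        self.stage = stage
        self.provenance: list[str] = list(provenance)

    @property
    def modifications(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def advance(self, new_stage: str, values: pd.DataFrame, note: str) -> "NormalizedMatrix":
        if STAGES.index(new_stage) <= STAGES.index(self.stage):
            raise ValueError(f"stage may only advance: {self.stage} -> {new_stage}")
        return NormalizedMatrix(values, new_stage, self.provenance + [note])

    def row(self, modification: str) -> pd.Series:
        return self.values.loc[modification]


def write_matrix(matrix: NormalizedMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (modifications as rows) with comment headers.

    Round-trips through :func:`read_matrix` to 12 significant digits.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# stage: {matrix.stage}\n")
    for line in matrix.provenance:
        buf.write(f"# provenance: {line}\n")
    out = matrix.values.copy()
    out.index.name = "modification"
    out.to_csv(buf, sep="\t", float_format="%.12g")
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc


def read_matrix(path: str | Path) -> NormalizedMatrix:
    path = Path(path)
    stage = None
    provenance = []
    body_lines = []
    # '#' marks whole comment lines only: sample names may contain '#'
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("stage:"):
                stage = body.split(":", 1)[1].strip()
            elif body.startswith("provenance:"):
                provenance.append(body.split(":", 1)[1].strip())
        else:
            body_lines.append(line)
    if stage is None:
        raise FormatError(f"{path}: missing '# stage:' header")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t",
                     index_col="modification")
    df.index = [normalize_mod_name(str(m)) for m in df.index]
    df.index.name = "modification"
    return NormalizedMatrix(df, stage, provenance)


def _data_path(name: str):
    return resources.files("epimark.data").joinpath(name)


def load_table1() -> TransitionTable:
    """The packaged dynamic-MRM acquisition panel (27 modifications, 2 channels)."""
    with resources.as_file(_data_path("table1_transitions.csv")) as p:
        return read_transition_table(p)


def load_table2(with_flags: bool = False):
    """The packaged absolute-quantification reference matrix.

    17 modifications x 9 samples in % of the adenosine UV signal; below-
    detection-limit cells are zeros, with their location (and above-
    calibration-range flags) in a parallel flags table returned when
    ``with_flags`` is true.
    """
    with resources.as_file(_data_path("table2_absolute.tsv")) as p:
        matrix = read_matrix(p)
    if not with_flags:
        return matrix
    with resources.as_file(_data_path("table2_flags.tsv")) as p:
        flags = pd.read_csv(p, sep="\t")
    return matrix, flags
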