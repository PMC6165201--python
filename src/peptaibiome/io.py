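"""Readers, writers and fixtures binding the pipeline stages together.

File contracts
--------------
* Peak-list CSV: columns ``mz, intensity`` plus optional ``kind`` (MNa,
  M2Na, b, y7, ms2) and ``rt``; header required, decimal point, UTF-8.
* Calibration CSV: columns ``concentration, area``.
* Compound-table TSV: the packaged study tables (characteristic ions,
  retention time, area percent, sequence) and any user table of the same
  shape.
* Assignment report TSV: one row per position (position, token, provenance)
  plus observed mass and closure residual.

Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .annotate import DbEntry
from .chem import PeptaibolSequence, ResidueLibrary, default_library
from .errors import FormatError
from .sequencer import Assignment, Peak, PeakList

# -- peak lists ---------------------------------------------------------------


def read_peaklist_csv(path: str | Path) -> PeakList:
    """Read an observed-ion CSV into a :class:`PeakList`."""
    peaks: list[Peak] = []
    rt = 0.0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "mz" not in reader.fieldnames:
            raise FormatError(f"{path}: missing required column 'mz'")
        if "intensity" not in reader.fieldnames:
            raise FormatError(f"{path}: missing required column 'intensity'")
        for lineno, row in enumerate(reader, start=2):
            try:
                kind = (row.get("kind") or "").strip() or None
                peaks.append(Peak(mz=float(row["mz"]),
                                  intensity=float(row["intensity"]),
                                  kind=kind))
                if row.get("rt"):
                    rt = float(row["rt"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PeakList(tuple(peaks), rt=rt)


def write_peaklist_csv(peaklist: PeakList, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mz", "intensity", "kind", "rt"])
        for p in peaklist.peaks:
            writer.writerow([f"{p.mz:.5f}", f"{p.intensity:.3f}", p.kind or "",
                             f"{peaklist.rt:.3f}"])


# -- calibration --------------------------------------------------------------


def read_calibration_csv(path: str | Path) -> list[tuple[float, float]]:
    points: list[tuple[float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("concentration", "area"):
            if reader.fieldnames is None or col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                points.append((float(row["concentration"]), float(row["area"])))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return points


def write_calibration_csv(points: Iterable[tuple[float, float]],
                          path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concentration", "area"])
        for c, a in points:
            writer.writerow([f"{c:g}", f"{a:g}"])


# -- compound tables (packaged study fixtures) --------------------------------


@dataclass(frozen=True)
class CompoundRow:
    """One compound of a study table: characteristic ions + sequence."""

    peptide: str
    M: float
    m_na: float
    m_2na: float
    b12: float
    y7: float
    rt_min: float
    area_percent: float
    sequence: PeptaibolSequence


def read_compound_table(path: str | Path,
                        library: ResidueLibrary | None = None) -> list[CompoundRow]:
    library = library or default_library()
    rows: list[CompoundRow] = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            try:
                rows.append(CompoundRow(
                    peptide=rec["peptide"],
                    M=float(rec["M"]), m_na=float(rec["m_na"]),
                    m_2na=float(rec["m_2na"]), b12=float(rec["b12"]),
                    y7=float(rec["y7"]), rt_min=float(rec["rt_min"]),
                    area_percent=float(rec["area_percent"]),
                    sequence=PeptaibolSequence.parse(rec["sequence"], library),
                ))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def _packaged(name: str) -> Path:
    with resources.as_file(resources.files("peptaibiome.data").joinpath(name)) as p:
        return Path(p)


def load_table1() -> list[CompoundRow]:
    """The 19 compounds of the T. gamsii run."""
    return read_compound_table(_packaged("table1_gamsii.tsv"))


def load_table2() -> list[CompoundRow]:
    """The 11 Koningiopsin compounds of the T. koningiopsis run."""
    return read_compound_table(_packaged("table2_koningiopsis.tsv"))


def load_all_compounds() -> list[CompoundRow]:
    return load_table1() + load_table2()


@dataclass(frozen=True)
class ExpectedRelation:
    """One transcribed relation row: query vs database entry or run isomer."""

    query: str
    target: str
    relation: str  # identical | exchanges | isomer_of
    exchanges: tuple[tuple[int, str, str], ...] = ()  # (pos, db_class, query_class)


def load_expected_relations() -> list[ExpectedRelation]:
    """The transcribed similarity annotations of the two study tables."""
    out: list[ExpectedRelation] = []
    with open(_packaged("relations_expected.tsv"), encoding="utf-8") as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            parts = line.split("\t")
            rec = dict(zip(header, parts))
            exchanges: list[tuple[int, str, str]] = []
            exch_text = rec.get("exchanges") or ""
            if exch_text and not exch_text.startswith("["):
                for item in exch_text.split(";"):
                    pos, pair = item.split(":")
                    db_tok, q_tok = pair.split(">")
                    exchanges.append((int(pos), db_tok, q_tok))
            out.append(ExpectedRelation(
                query=rec["query"], target=rec["target"],
                relation=rec["relation"], exchanges=tuple(exchanges)))
    return out


# -- assignment reports -------------------------------------------------------


def write_assignment_tsv(assignment: Assignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# M_obs\t{assignment.neutral_mass_obs:.4f}\n")
        fh.write(f"# closure_residual\t{assignment.closure_residual:.4f}\n")
        fh.write(f"# status\t{assignment.status}\n")
        fh.write("position\ttoken\tprovenance\n")
        for i, call in enumerate(assignment.calls, start=1):
            fh.write(f"{i}\t{call.token or '?'}\t{call.provenance}\n")


# -- run configuration --------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline-wide tunables, serialisable to/from JSON."""

    tolerance: float = 0.6  # Da, fragment matching
    cluster_window: float = 1.2  # min, co-elution window for naming
    temperature: float = 300.0  # K, free-energy transform
    hbond_dist_cut: float = 3.0  # A
    hbond_ang_cut: float = 135.0  # degrees
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in ("tolerance", "cluster_window", "temperature",
                     "hbond_dist_cut", "hbond_ang_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
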