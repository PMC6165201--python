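"""Calibration-based quantitation of peptaibol content and composition.

A single external standard (alamethicin, a 20-residue peptaibol) calibrates
the chromatographic response; a proportional (through-origin) model maps
peak area to concentration with one response factor for all compounds --
a single external standard cannot provide compound-specific factors.
Because response depends on peptide length and structure, only compounds of
similar length to the standard (17-20 residues) are flagged as accurately
quantified; shorter peptaibols (with their Pro-induced structural
deformation) get a low-accuracy flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DegenerateRunError, InvalidCalibrationError

#: Sequence-length window quantifiable with high accuracy against a
#: 20-residue standard.
ACCURATE_LENGTH_RANGE = (17, 20)


@dataclass(frozen=True)
class CalibrationModel:
    """Proportional response model: concentration = response_factor x area."""

    response_factor: float
    residual_rms: float
    n_points: int


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Least-squares proportional fit of concentration on area, through origin.

    Minimising sum (c_k - f a_k)^2 gives f = sum(a c) / sum(a^2).
    """
    if not points:
        raise InvalidCalibrationError("no calibration points")
    if any(a <= 0 for _, a in points):
        raise InvalidCalibrationError("calibration areas must be positive")
    num = sum(a * c for c, a in points)
    den = sum(a * a for _, a in points)
    factor = num / den
    if factor <= 0:
        raise InvalidCalibrationError("fitted response factor is not positive")
    rss = sum((c - factor * a) ** 2 for c, a in points)
    return CalibrationModel(response_factor=factor,
                            residual_rms=math.sqrt(rss / len(points)),
                            n_points=len(points))


@dataclass(frozen=True)
class CompoundQuant:
    """Quantitation of one compound in a run."""

    name: str
    area: float
    area_percent: float
    content: float  # concentration units of the calibration (e.g. ug/mL)
    accuracy_flag: str  # accurate | low_accuracy
    rt: float = float("nan")


@dataclass(frozen=True)
class QuantReport:
    compounds: tuple[CompoundQuant, ...]
    total_content: float


def quantify(areas: Sequence[tuple[str, float, int]],
             model: CalibrationModel,
             rts: Sequence[float] | None = None) -> QuantReport:
    """Per-compound content and relative composition for one run.

    ``areas`` holds (name, peak area, sequence length) triples.  Contents
    are area x response_factor; area percentages normalise to 100; the
    accuracy flag marks compounds outside the 17-20-residue window.
    """
    if not areas:
        raise DegenerateRunError("no compounds to quantify")
    total_area = sum(a for _, a, _ in areas)
    if total_area <= 0:
        raise DegenerateRunError("all areas are zero")
    lo, hi = ACCURATE_LENGTH_RANGE
    rts = rts if rts is not None else [float("nan")] * len(areas)
    compounds = tuple(
        CompoundQuant(
            name=name,
            area=area,
            area_percent=100.0 * area / total_area,
            content=area * model.response_factor,
            accuracy_flag="accurate" if lo <= length <= hi else "low_accuracy",
            rt=rt,
        )
        for (name, area, length), rt in zip(areas, rts)
    )
    return QuantReport(compounds=compounds,
                       total_content=sum(c.content for c in compounds))


def write_quant_tsv(report: QuantReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\trt\tarea\tarea_percent\tcontent_ug_per_ml\taccuracy_flag\n")
        for c in report.compounds:
            fh.write(f"{c.name}\t{c.rt:.3f}\t{c.area:.4f}\t{c.area_percent:.2f}\t"
                     f"{c.content:.4f}\t{c.accuracy_flag}\n")
        fh.write(f"TOTAL\t\t\t100.00\t{report.total_content:.4f}\t\n")
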