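"""End-to-end pipeline: assemble -> annotate -> name -> quantify.

Given one peak-list CSV per compound, a known-peptaibol database and an
external-standard calibration, produce a study-table-style report: the
characteristic ions, the de novo sequence, the closest known peptaibols and
the quantitative composition of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import io as pio
from .annotate import AnnotationResult, DbEntry, annotate_against_db, assign_names
from .chem import characteristic_ions
from .errors import PeptaibiomeError
from .io import RunConfig
from .quant import CalibrationModel, QuantReport, fit_calibration, quantify
from .sequencer import Assignment, PeakList, assemble_sequence

log = logging.getLogger("peptaibiome")


@dataclass
class CompoundResult:
    source: str
    peaklist: PeakList
    assignment: Assignment
    annotation: AnnotationResult
    name: str = ""

    @property
    def area(self) -> float:
        """Precursor ([M+Na]+) intensity stands in for the integrated area."""
        na = self.peaklist.of_kind("MNa")
        if na:
            return max(p.intensity for p in na)
        return max((p.intensity for p in self.peaklist.peaks), default=0.0)


@dataclass
class PipelineReport:
    compounds: list[CompoundResult]
    quant: QuantReport | None

    def write_tsv(self, path: str | Path) -> None:
        """One study-table-style row per compound."""
        n_res = max((len(c.assignment) for c in self.compounds), default=0)
        with open(path, "w", encoding="utf-8") as fh:
            cols = ["peptide", "source", "M", "m_na", "m_2na", "b12", "y7", "rt",
                    "area_percent"]
            cols += [f"R{i}" for i in range(1, n_res + 1)]
            cols += ["closure_residual", "status", "relation"]
            fh.write("\t".join(cols) + "\n")
            quant_by_source = {}
            if self.quant:
                quant_by_source = {c.name: c for c in self.quant.compounds}
            for c in self.compounds:
                seq = c.assignment.to_sequence()
                ions = characteristic_ions(seq)
                q = quant_by_source.get(c.source)
                best = c.annotation.best
                if best is None:
                    relation = "no hit (new)"
                else:
                    entry, report = best
                    detail = "" if not report.exchanges else (
                        ": " + ", ".join(str(e) for e in report.exchanges))
                    relation = f"{report.relation} {entry.name}{detail}"
                    if c.annotation.is_new:
                        relation = "New: " + relation
                row = [c.name, c.source, f"{ions.M:.3f}", f"{ions.m_na:.3f}",
                       f"{ions.m_2na:.3f}",
                       f"{ions.b12:.3f}" if ions.b12 else "",
                       f"{ions.y7:.3f}" if ions.y7 else "",
                       f"{c.peaklist.rt:.3f}",
                       f"{q.area_percent:.2f}" if q else ""]
                row += list(c.assignment.tokens())
                row += [f"{c.assignment.closure_residual:.4f}", c.assignment.status,
                        relation]
                fh.write("\t".join(str(x) for x in row) + "\n")

    def summary(self) -> dict:
        return {
            "n_compounds": len(self.compounds),
            "names": [c.name for c in self.compounds],
            "new_flags": [c.annotation.is_new for c in self.compounds],
            "total_content": self.quant.total_content if self.quant else None,
        }


def run_pipeline(peaklists: Sequence[tuple[str, PeakList]],
                 db: Sequence[DbEntry],
                 calibration: Sequence[tuple[float, float]] | None = None,
                 config: RunConfig | None = None,
                 name_prefix: str = "Pept-") -> PipelineReport:
    """Assemble, annotate, name and quantify a set of compound peak lists.

    ``peaklists`` holds (label, PeakList) pairs, one per compound.  Raises
    the first stage error encountered (the CLI maps these to exit status).
    """
    config = config or RunConfig()
    log.info("run_pipeline: tolerance=%.3g Da, cluster_window=%.3g min",
             config.tolerance, config.cluster_window)

    results: list[CompoundResult] = []
    for label, peaklist in peaklists:
        assignment = assemble_sequence(peaklist, tol=config.tolerance)
        seq = assignment.to_sequence()
        annotation = annotate_against_db(seq, db)
        results.append(CompoundResult(source=label, peaklist=peaklist,
                                      assignment=assignment, annotation=annotation))
        log.debug("%s: %s (%s)", label, seq, assignment.status)

    if results:
        triples = []
        for c in results:
            seq = c.assignment.to_sequence()
            ions = characteristic_ions(seq)
            triples.append((c.peaklist.rt, ions.b12 or 0.0, ions.y7 or 0.0))
        labels = assign_names(triples, prefix=name_prefix,
                              cluster_window=config.cluster_window)
        for c, label in zip(results, labels):
            c.name = label

    quant = None
    if calibration and results:
        model = fit_calibration(calibration)
        areas = [(c.source, c.area, len(c.assignment)) for c in results]
        quant = quantify(areas, model, rts=[c.peaklist.rt for c in results])
    return PipelineReport(compounds=results, quant=quant)


def run_pipeline_from_paths(peak_paths: Sequence[str | Path],
                            db_path: str | Path | None = None,
                            calibration_path: str | Path | None = None,
                            config: RunConfig | None = None) -> PipelineReport:
    from .annotate import load_database

    peaklists = [(Path(p).stem, pio.read_peaklist_csv(p)) for p in sorted(map(str, peak_paths))]
    db = load_database(db_path)
    calibration = (pio.read_calibration_csv(calibration_path)
                   if calibration_path else None)
    return run_pipeline(peaklists, db, calibration, config)
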