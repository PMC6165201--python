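"""Residue-level mass chemistry for peptaibols.

Peptaibols are linear non-ribosomal fungal peptides with an acetylated
N-terminus, a C-terminal 1,2-amino alcohol, and a high content of the
non-proteinogenic residues Aib (alpha-aminoisobutyric acid) and Iva
(isovaline).  This module provides:

* a residue library (20 standard residues + Aib/Iva + C-terminal amino
  alcohols) with elemental compositions and monoisotopic/average masses,
* :class:`PeptaibolSequence` -- the capped residue-token chain used by every
  pipeline stage, supporting isobaric class tokens (Lxx = Leu/Ile,
  Vxx = Val/Iva, Lxxol = Leuol/Ileol),
* neutral mass, sodiated adduct m/z and acetyl-capped b / amino-alcohol y
  fragment-ion series.

Mass conventions
----------------
Monoisotopic atomic masses: H 1.007825, C 12.0, N 14.003074, O 15.994915,
Na 22.989770; electron 0.000549; proton 1.007276 Da.  Sodium cationisation
uses the Na+ cation mass (atomic Na minus one electron).  Amino-alcohol
residues carry the reduced-carboxyl composition (parent residue - O + 2H),
so the C-terminal alcohol correction (-13.97926 Da relative to the parent
peptide) is built into their residue masses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import InvalidSequenceError, MassDomainError, UnknownResidueError

# -- atomic constants ---------------------------------------------------------

MONOISOTOPIC_ATOM = {
    "H": 1.007825,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
    "Na": 22.989770,
}

#: IUPAC 2021 standard atomic weights (conventional values).
AVERAGE_ATOM = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Na": 22.98977,
}

ELECTRON = 0.000549
PROTON = 1.007276
NA_CATION = MONOISOTOPIC_ATOM["Na"] - ELECTRON  # 22.989221

WATER_MONO = 2 * MONOISOTOPIC_ATOM["H"] + MONOISOTOPIC_ATOM["O"]  # 18.010565
ACETYL_MONO = 2 * MONOISOTOPIC_ATOM["C"] + 2 * MONOISOTOPIC_ATOM["H"] + MONOISOTOPIC_ATOM["O"]
WATER_AVG = 2 * AVERAGE_ATOM["H"] + AVERAGE_ATOM["O"]
ACETYL_AVG = 2 * AVERAGE_ATOM["C"] + 2 * AVERAGE_ATOM["H"] + AVERAGE_ATOM["O"]

#: Nominal Gln + Aib dipeptide block mass; the stable Gln6-Aib7 bond makes a
#: 213 Da jump the signature gap of peptaibol b-ion ladders.
GLN_AIB_BLOCK_NOMINAL = 213

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string like ``C5H8N2O2``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _normalise_kind(kind: str) -> str:
    k = kind.lower()
    if k in ("monoisotopic", "mono"):
        return "monoisotopic"
    if k in ("average", "avg"):
        return "average"
    raise ValueError(f"unknown mass kind {kind!r}")


def formula_mass(formula: str | Mapping[str, int], kind: str = "monoisotopic") -> float:
    """Mass of an elemental composition under the requested mass scale."""
    table = MONOISOTOPIC_ATOM if _normalise_kind(kind) == "monoisotopic" else AVERAGE_ATOM
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    try:
        return sum(table[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - library misconfiguration
        raise ValueError(f"no atomic mass for element {exc.args[0]!r}") from exc


# -- residue library ----------------------------------------------------------


@dataclass(frozen=True)
class ResidueSpec:
    """One residue entry: token, composition, masses and isobaric class."""

    code: str
    formula: str
    mono_mass: float
    avg_mass: float
    iso_class: str

    @property
    def is_alcohol(self) -> bool:
        """Amino-alcohol residues are flagged terminal-only."""
        return self.code.endswith("ol")


class ResidueLibrary:
    """Token -> :class:`ResidueSpec` mapping, extensible from TSV.

    The packaged default ships the 20 standard residues, Aib, Iva, the
    C-terminal amino alcohols, and the isobaric class tokens Lxx/Vxx/Lxxol
    as first-class symbols (class members are isobaric, so a class token has
    a well-defined mass).
    """

    def __init__(self, specs: Iterable[ResidueSpec]):
        self._specs: dict[str, ResidueSpec] = {s.code: s for s in specs}

    # construction -----------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueLibrary":
        """Load a library from a TSV with columns ``code, formula, iso_class``."""
        specs = []
        with open(path, encoding="utf-8") as fh:
            header: list[str] | None = None
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                row = dict(zip(header, line.split("\t")))
                specs.append(
                    ResidueSpec(
                        code=row["code"],
                        formula=row["formula"],
                        mono_mass=formula_mass(row["formula"], "monoisotopic"),
                        avg_mass=formula_mass(row["formula"], "average"),
                        iso_class=row.get("iso_class") or row["code"],
                    )
                )
        return cls(specs)

    @classmethod
    def default(cls) -> "ResidueLibrary":
        with resources.as_file(
            resources.files("peptaibiome.data").joinpath("residues.tsv")
        ) as p:
            return cls.from_tsv(p)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("code\tformula\tiso_class\n")
            for spec in self._specs.values():
                fh.write(f"{spec.code}\t{spec.formula}\t{spec.iso_class}\n")

    # mapping behaviour ------------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self._specs

    def __getitem__(self, code: str) -> ResidueSpec:
        try:
            return self._specs[code]
        except KeyError:
            raise UnknownResidueError(code) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def mass(self, code: str, kind: str = "monoisotopic") -> float:
        spec = self[code]
        return spec.mono_mass if _normalise_kind(kind) == "monoisotopic" else spec.avg_mass

    def iso_class(self, code: str) -> str:
        return self[code].iso_class

    def same_class(self, a: str, b: str) -> bool:
        return self.iso_class(a) == self.iso_class(b)


_DEFAULT_LIBRARY: ResidueLibrary | None = None


def default_library() -> ResidueLibrary:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = ResidueLibrary.default()
    return _DEFAULT_LIBRARY


# -- sequences ----------------------------------------------------------------


@dataclass(frozen=True)
class PeptaibolSequence:
    """Capped residue-token chain; positions are 1-based throughout.

    ``n_cap`` is ``"Ac"`` (acetylated, the peptaibol rule) or ``"H"`` (free
    amine).  Tokens may be specific residues or isobaric class tokens.  An
    amino-alcohol token may only appear at the C-terminus.
    """

    residues: tuple[str, ...]
    n_cap: str = "Ac"
    library: ResidueLibrary = field(default_factory=default_library, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_cap not in ("Ac", "H"):
            raise InvalidSequenceError(f"n_cap must be 'Ac' or 'H', got {self.n_cap!r}")
        if not self.residues:
            raise InvalidSequenceError("empty residue list")
        if len(self.residues) > 25:
            raise InvalidSequenceError(f"sequence too long ({len(self.residues)} residues)")
        for i, tok in enumerate(self.residues, start=1):
            spec = self.library[tok]  # raises UnknownResidueError
            if spec.is_alcohol and i != len(self.residues):
                raise InvalidSequenceError(
                    f"amino-alcohol residue {tok!r} at interior position {i}"
                )

    # construction / formatting ---------------------------------------------

    @classmethod
    def parse(cls, text: str, library: ResidueLibrary | None = None) -> "PeptaibolSequence":
        """Parse token notation ``[Ac-]Tok(-Tok)*``, e.g. ``Ac-Aib-Gly-...-Leuol``."""
        library = library or default_library()
        tokens = [t for t in text.strip().split("-") if t]
        if not tokens:
            raise InvalidSequenceError(f"cannot parse sequence {text!r}")
        cap = "H"
        if tokens[0] in ("Ac", "H"):
            cap = tokens[0]
            tokens = tokens[1:]
        return cls(residues=tuple(tokens), n_cap=cap, library=library)

    def __str__(self) -> str:
        return "-".join((self.n_cap, *self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """1-based residue access."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} out of range 1..{len(self.residues)}")
        return self.residues[position - 1]

    # derived views ----------------------------------------------------------

    def iso_classes(self) -> tuple[str, ...]:
        """The sequence collapsed to isobaric class tokens."""
        return tuple(self.library.iso_class(t) for t in self.residues)

    def with_residue(self, position: int, token: str) -> "PeptaibolSequence":
        res = list(self.residues)
        res[position - 1] = token
        return PeptaibolSequence(tuple(res), self.n_cap, self.library)

    @property
    def has_alcohol_terminus(self) -> bool:
        return self.library[self.residues[-1]].is_alcohol


# -- mass operations ----------------------------------------------------------


def residue_mass(code: str, kind: str = "monoisotopic",
                 library: ResidueLibrary | None = None) -> float:
    """Residue (not free amino acid) mass; alcohols return the reduced mass."""
    return (library or default_library()).mass(code, kind)


def neutral_mass(seq: PeptaibolSequence, kind: str = "monoisotopic") -> float:
    """Neutral molecular mass M of a capped peptaibol.

    M = sum(residues) + H2O (termini) + acetyl (if Ac-capped); the
    C-terminal alcohol reduction is carried by the alcohol residue mass.
    """
    mono = _normalise_kind(kind) == "monoisotopic"
    water = WATER_MONO if mono else WATER_AVG
    acetyl = ACETYL_MONO if mono else ACETYL_AVG
    total = sum(seq.library.mass(t, kind) for t in seq.residues) + water
    if seq.n_cap == "Ac":
        total += acetyl
    return total


def adduct_mz(M: float, adduct: str) -> float:
    """m/z of a sodiated adduct of a neutral of mass ``M``."""
    if M <= 0:
        raise MassDomainError(f"neutral mass must be positive, got {M}")
    if adduct in ("M+Na", "MNa"):
        return M + NA_CATION
    if adduct in ("M+2Na", "M2Na"):
        return (M + 2 * NA_CATION) / 2
    raise ValueError(f"unknown adduct {adduct!r} (supported: M+Na, M+2Na)")


def b_ion_mz(seq: PeptaibolSequence, n: int, kind: str = "monoisotopic") -> float:
    """Singly charged acylium b_n: prefix residues + N-cap + proton."""
    if not 1 <= n < len(seq):
        raise IndexError(f"b-ion index {n} out of range 1..{len(seq) - 1}")
    mono = _normalise_kind(kind) == "monoisotopic"
    total = sum(seq.library.mass(t, kind) for t in seq.residues[:n]) + PROTON
    if seq.n_cap == "Ac":
        total += ACETYL_MONO if mono else ACETYL_AVG
    return total


def y_ion_mz(seq: PeptaibolSequence, k: int, kind: str = "monoisotopic") -> float:
    """Protonated C-terminal fragment y_k (suffix of length ``k``)."""
    if not 1 <= k <= len(seq):
        raise IndexError(f"y-ion suffix length {k} out of range 1..{len(seq)}")
    mono = _normalise_kind(kind) == "monoisotopic"
    water = WATER_MONO if mono else WATER_AVG
    return sum(seq.library.mass(t, kind) for t in seq.residues[-k:]) + water + PROTON


@dataclass(frozen=True)
class MassRecord:
    """The five characteristic masses of a peptaibol compound."""

    M: float
    m_na: float
    m_2na: float
    b12: float | None
    y7: float | None
    mass_kind: str = "monoisotopic"


def characteristic_ions(seq: PeptaibolSequence, kind: str = "monoisotopic") -> MassRecord:
    """Neutral M, both sodiated adducts, b12 and y7 (where defined)."""
    M = neutral_mass(seq, kind)
    return MassRecord(
        M=M,
        m_na=adduct_mz(M, "M+Na"),
        m_2na=adduct_mz(M, "M+2Na"),
        b12=b_ion_mz(seq, 12, kind) if len(seq) > 12 else None,
        y7=y_ion_mz(seq, 7, kind) if len(seq) >= 7 else None,
        mass_kind=_normalise_kind(kind),
    )


#: Trikoningin KA V, the 19-residue reference peptaibol used for the
#: conformational study; seven Aib residues, Ac cap, leucinol terminus.
TRIKONINGIN_KA_V = (
    "Ac-Aib-Gly-Ala-Aib-Ile-Gln-Aib-Aib-Aib-Ser-Leu-Aib-Pro-Val-Aib-Ile-Gln-Gln-Leuol"
)


def trikoningin_ka_v(library: ResidueLibrary | None = None) -> PeptaibolSequence:
    return PeptaibolSequence.parse(TRIKONINGIN_KA_V, library)
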