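"""Similarity annotation and nomenclature for assembled peptaibol sequences.

Sequences determined by unit-resolution MS are compared against a database of
known peptaibols at isobaric-class resolution (Lxx = Leu = Ile and so on),
because MS cannot discriminate class members.  Relations mirror the reporting
style of peptaibiomics tables: a compound is *identical by class* to a known
entry, a *positional isomer* of it (same residue-class multiset, different
order), or differs by an explicit exchange list ``[X]^i -> [Y]^i``.

Compound naming follows chromatographic convention: compounds are numbered by
elution order with Roman numerals; co-eluting compounds that differ in their
characteristic fragment ions (b12, y7) share one numeral and are distinguished
by letters a, b, ... in ascending y7 mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .chem import PeptaibolSequence, ResidueLibrary, default_library
from .errors import EmptyDatabaseError, FormatError

# relation ranks: lower sorts first
_RELATION_RANK = {"identical_by_class": 0, "positional_isomer": 1, "exchanges": 2,
                  "different_length": 3}


@dataclass(frozen=True)
class DbEntry:
    """One known peptaibol: name, sequence and a literature pointer."""

    name: str
    sequence: PeptaibolSequence
    source_ref: str = ""


@dataclass(frozen=True)
class Exchange:
    """A single residue exchange [db_token]^position -> [query_token]^position."""

    position: int
    db_token: str
    query_token: str

    def __str__(self) -> str:
        return f"[{self.db_token}]^{self.position}->[{self.query_token}]^{self.position}"


@dataclass(frozen=True)
class MatchReport:
    """Relation of a query sequence to one database entry."""

    relation: str
    exchanges: tuple[Exchange, ...] = ()

    @property
    def n_exchanges(self) -> int:
        return len(self.exchanges)


def load_database(path: str | Path | None = None,
                  library: ResidueLibrary | None = None) -> list[DbEntry]:
    """Read a known-peptaibol TSV (columns name, sequence, source_ref).

    With no path, loads the packaged database of trikoningin / tricholongin /
    trichostrigocin / trichorzianin comparison sequences.
    """
    library = library or default_library()
    if path is None:
        with resources.as_file(
            resources.files("peptaibiome.data").joinpath("known_peptaibols.tsv")
        ) as p:
            return load_database(p, library)
    entries: list[DbEntry] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                for col in ("name", "sequence"):
                    if col not in header:
                        raise FormatError(f"{path}: missing column {col!r}")
                continue
            row = dict(zip(header, line.split("\t")))
            name = row["name"]
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate database name {name!r}")
            names.add(name)
            entries.append(DbEntry(
                name=name,
                sequence=PeptaibolSequence.parse(row["sequence"], library),
                source_ref=row.get("source_ref", ""),
            ))
    return entries


def compare(query: PeptaibolSequence, entry: DbEntry, strict: bool = False) -> MatchReport:
    """Position-wise comparison of a query against one database entry.

    Comparison runs at isobaric-class resolution unless ``strict`` is set.
    Exchange records carry the tokens as stored (database member tokens and
    query class tokens), compared through their classes.
    """
    db_seq = entry.sequence
    if len(query) != len(db_seq):
        return MatchReport(relation="different_length")

    def key(seq: PeptaibolSequence) -> tuple[str, ...]:
        return tuple(seq.residues) if strict else seq.iso_classes()

    q_keys, d_keys = key(query), key(db_seq)
    if q_keys == d_keys:
        return MatchReport(relation="identical_by_class")
    if sorted(q_keys) == sorted(d_keys):
        return MatchReport(relation="positional_isomer")
    exchanges = tuple(
        Exchange(position=i, db_token=db_seq[i], query_token=query[i])
        for i in range(1, len(query) + 1)
        if q_keys[i - 1] != d_keys[i - 1]
    )
    return MatchReport(relation="exchanges", exchanges=exchanges)


def annotate_against_db(query: PeptaibolSequence, db: Sequence[DbEntry],
                        max_exchanges: int | None = None,
                        strict: bool = False) -> "AnnotationResult":
    """Rank all database entries by similarity to the query.

    Entries sort by relation rank (identical < positional isomer < exchanges),
    then ascending exchange count, then name.  Entries with more than
    ``max_exchanges`` exchanges (or of different length) are omitted.  The
    query is flagged *new* when no identical-by-class hit exists.
    """
    if not db:
        raise EmptyDatabaseError("known-peptaibol database is empty")
    hits = []
    for entry in db:
        report = compare(query, entry, strict=strict)
        if report.relation == "different_length":
            continue
        if max_exchanges is not None and report.n_exchanges > max_exchanges:
            continue
        hits.append((entry, report))
    hits.sort(key=lambda h: (_RELATION_RANK[h[1].relation], h[1].n_exchanges, h[0].name))
    is_new = not any(r.relation == "identical_by_class" for _, r in hits)
    return AnnotationResult(hits=tuple(hits), is_new=is_new)


@dataclass(frozen=True)
class AnnotationResult:
    hits: tuple[tuple[DbEntry, MatchReport], ...]
    is_new: bool

    @property
    def best(self) -> tuple[DbEntry, MatchReport] | None:
        return self.hits[0] if self.hits else None


# -- nomenclature -------------------------------------------------------------

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("Roman numerals start at I")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class CompoundIons:
    """The (rt, b12, y7) triple that identifies one eluting compound."""

    rt: float
    b12: float
    y7: float


def assign_names(compounds: Iterable[tuple[float, float, float] | CompoundIons],
                 prefix: str = "", cluster_window: float = 1.2,
                 family_tol: float = 0.5) -> list[str]:
    """Name compounds by elution order: Roman numerals, letters for variants.

    Compounds are sorted by retention time.  A compound joins the current
    cluster when it elutes within ``cluster_window`` minutes of the previous
    member *and* its y7 mass is larger by more than ``family_tol`` Da (letters
    run in ascending y7 mass, which in these chromatograms coincides with
    elution order within a co-eluting pair); otherwise a new numeral starts.
    Singleton clusters get a bare numeral.  Returns labels aligned with the
    input order; the assignment is invariant under input permutation.
    """
    items = [c if isinstance(c, CompoundIons) else CompoundIons(*c) for c in compounds]
    if not items:
        return []
    order = sorted(range(len(items)),
                   key=lambda i: (items[i].rt, items[i].y7, items[i].b12))
    clusters: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        prev = items[clusters[-1][-1]]
        cur = items[idx]
        if cur.rt - prev.rt <= cluster_window and cur.y7 - prev.y7 > family_tol:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    labels = [""] * len(items)
    for num, cluster in enumerate(clusters, start=1):
        if len(cluster) == 1:
            labels[cluster[0]] = f"{prefix}{roman(num)}"
        else:
            for letter_i, idx in enumerate(cluster):
                labels[idx] = f"{prefix}{roman(num)}{chr(ord('a') + letter_i)}"
    return labels
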