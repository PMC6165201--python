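"""De novo assembly of peptaibol sequences from characteristic-ion peak lists.

The assembly mirrors how 19-residue peptaibols are sequenced on a
unit-resolution ESI ion trap:

1. *Adduct deconvolution*: the neutral mass M is read off the sodiated
   precursors [M+Na]+ and [M+2Na]2+ (free peptaibols barely protonate).
2. *b-ladder walking*: consecutive differences of the acetyl-capped b-series
   are matched to single residues or two-residue composites.  The b1 acylium
   is essentially never observed, so the first peak may be any b_n with
   n <= 3, resolved by composite enumeration; the classic 213.11 Da jump is
   the stable Gln-Aib block and expands in that order.
3. *y7 resolution*: the y7 fragment (suffix 13-19 of the scaffold
   Pro-Vxx-Aib-Xxx-Gln-Zxx-Lxxol) falls into one of four canonical variants
   distinguishing Lxx/Vxx at 16 and Gln/Glu at 18; MS2 sub-ions, when
   present, refine individual suffix positions.
4. *Motif fill*: cleavage after the Aib12-Pro13 bond suppresses b13/b14, so
   positions 13-15 are predicted from the conserved Aib-Pro-Vxx-Aib motif.
5. *Mass closure*: the assembled sequence must reproduce the observed M.

Residue calls are reported at isobaric-class resolution only (Lxx, Vxx,
Lxxol): unit-resolution MS cannot discriminate Leu/Ile or Val/Iva.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from . import chem
from .chem import (ACETYL_MONO, PROTON, WATER_MONO, PeptaibolSequence,
                   ResidueLibrary, adduct_mz, default_library, neutral_mass,
                   y_ion_mz)
from .errors import (ClosureError, InconsistentAdductsError,
                     InsufficientLadderError, MotifConflictError,
                     NoPrecursorError, UnassignedY7Error)

#: Matching tolerance for a unit-resolution ion trap, Da.
DEFAULT_TOL = 0.6

#: Residues that occur in peptaibols; basic and sulfur residues are excluded
#: from ladder matching by default (Lys is 0.036 Da from Gln -- indistinguishable
#: at unit resolution and absent from peptaibols anyway).  Isobaric classes
#: stand in for their members.
SEQUENCING_ALPHABET = (
    "Gly", "Ala", "Ser", "Pro", "Vxx", "Thr", "Lxx", "Asn", "Asp",
    "Gln", "Glu", "Phe", "Trp", "Aib",
)

#: The conserved turn motif filled in for positions 13-15.
MOTIF_13_15 = ("Pro", "Vxx", "Aib")

#: Gln is invariant at position 17 across the 19-residue scaffold.
FIXED_POSITION_17 = "Gln"

#: Scaffold C-terminus: a leucinol/isoleucinol amino alcohol.
SCAFFOLD_TERMINUS = "Lxxol"

SCAFFOLD_LENGTH = 19


# -- peak lists ---------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0
    kind: str | None = None  # one of MNa, M2Na, b, y7, ms2 or None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PeakList:
    """Observed ions of one compound; peaks sorted ascending by m/z."""

    peaks: tuple[Peak, ...]
    rt: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks",
                           tuple(sorted(self.peaks, key=lambda p: (p.mz, p.intensity))))
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")

    def of_kind(self, kind: str) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.kind == kind)

    def mzs(self, kind: str | None = None) -> list[float]:
        if kind is None:
            return [p.mz for p in self.peaks]
        return [p.mz for p in self.of_kind(kind)]


# -- assignments --------------------------------------------------------------

PROVENANCES = ("ladder", "ms2", "motif", "closure", "unresolved")


@dataclass(frozen=True)
class Call:
    token: str | None
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class Assignment:
    """Per-position residue calls with provenance, plus closure bookkeeping."""

    calls: tuple[Call, ...]
    neutral_mass_obs: float = float("nan")
    closure_residual: float = float("nan")
    status: str = "partial"  # partial | complete

    def __len__(self) -> int:
        return len(self.calls)

    def __getitem__(self, position: int) -> Call:
        return self.calls[position - 1]

    def tokens(self) -> tuple[str | None, ...]:
        return tuple(c.token for c in self.calls)

    def to_sequence(self, n_cap: str = "Ac",
                    library: ResidueLibrary | None = None) -> PeptaibolSequence:
        if any(c.token is None for c in self.calls):
            raise ValueError("assignment has unresolved positions")
        return PeptaibolSequence(tuple(c.token for c in self.calls), n_cap,
                                 library or default_library())


# -- adduct deconvolution -----------------------------------------------------


@dataclass(frozen=True)
class Deconvolution:
    """Neutral mass recovered from sodiated adducts, with the cross-check."""

    M: float
    residual: float | None  # M([M+Na]+) - M([M+2Na]2+) when both were seen


def deconvolute_adducts(peaks: PeakList, tol: float = DEFAULT_TOL) -> Deconvolution:
    """Recover the neutral mass M from [M+Na]+ / [M+2Na]2+ peaks.

    Labelled adduct peaks are used when present; otherwise every peak is
    tried as [M+Na]+ and accepted only if another peak supports it as
    [M+2Na]2+.  When both adducts are seen, M comes from [M+Na]+ (the
    singly-charged ion is the better-determined one) and the disagreement
    between the two is recorded; beyond 2 x tol the peaks are rejected as
    inconsistent.
    """
    na = peaks.mzs("MNa")
    two_na = peaks.mzs("M2Na")
    if na or two_na:
        m_from_na = max(na) - chem.NA_CATION if na else None
        m_from_2na = 2 * max(two_na) - 2 * chem.NA_CATION if two_na else None
        if m_from_na is not None and m_from_2na is not None:
            residual = m_from_na - m_from_2na
            if abs(residual) > 2 * tol:
                raise InconsistentAdductsError(m_from_na, m_from_2na, tol)
            return Deconvolution(M=m_from_na, residual=residual)
        if m_from_na is not None:
            return Deconvolution(M=m_from_na, residual=None)
        return Deconvolution(M=m_from_2na, residual=None)

    # unlabelled: look for a supported [M+Na]+ / [M+2Na]2+ pair
    mzs = peaks.mzs()
    best: Deconvolution | None = None
    for mz in mzs:
        m = mz - chem.NA_CATION
        if m <= 0:
            continue
        expect_2na = adduct_mz(m, "M+2Na")
        support = [o for o in mzs if abs(o - expect_2na) <= tol]
        if support:
            residual = m - (2 * support[0] - 2 * chem.NA_CATION)
            if best is None or abs(residual) < abs(best.residual or 0):
                best = Deconvolution(M=m, residual=residual)
    if best is None:
        raise NoPrecursorError("no adduct peak found or matchable")
    return best


# -- b-ladder walking ---------------------------------------------------------


@dataclass(frozen=True)
class LadderCandidate:
    """One way of reading a b-ladder: tokens per walked position."""

    tokens: tuple[str, ...]
    n_composites: int
    error: float  # summed |mass mismatch| over matched steps
    pref: int = 0  # summed rank of non-preferred branch choices (0 = all preferred)


def _single_matches(delta: float, tol: float, alphabet: Sequence[str],
                    library: ResidueLibrary) -> list[tuple[float, str]]:
    out = [(abs(library.mass(t) - delta), t) for t in alphabet
           if abs(library.mass(t) - delta) <= tol]
    out.sort()
    return out


def _pair_matches(delta: float, tol: float, alphabet: Sequence[str],
                  library: ResidueLibrary) -> list[tuple[float, tuple[str, str]]]:
    """Ordered two-residue expansions of a composite jump, ranked.

    The 213.11 Da Gln+Aib block expands as Gln-then-Aib (the conserved motif
    order); other ambiguous composites rank by mass error, then by an
    Aib-first prior (Aib is the signature peptaibol residue), then
    lexicographically for determinism.
    """
    hits: list[tuple[float, tuple[str, str]]] = []
    seen: set[tuple[str, str]] = set()
    for a, b in itertools.product(alphabet, repeat=2):
        err = abs(library.mass(a) + library.mass(b) - delta)
        if err <= tol and (a, b) not in seen:
            seen.add((a, b))
            hits.append((err, (a, b)))

    def rank(item: tuple[float, tuple[str, str]]):
        err, (a, b) = item
        gln_aib = 0 if (a, b) == ("Gln", "Aib") else 1
        aib_first = 0 if a == "Aib" else 1
        return (round(err, 6), gln_aib, aib_first, (a, b))

    hits.sort(key=rank)
    return hits


def walk_b_ladder(b_peaks: Sequence[float], tol: float = DEFAULT_TOL,
                  alphabet: Sequence[str] = SEQUENCING_ALPHABET,
                  library: ResidueLibrary | None = None,
                  n_cap: str = "Ac", max_candidates: int = 16,
                  head_max: int = 3) -> list[LadderCandidate]:
    """Read residue tokens off an ascending b-ion ladder.

    The first observed peak is expanded as a composite of 1..``head_max``
    residues (b1 is assumed absent).  Consecutive differences then match a
    single residue or a two-residue composite; larger jumps terminate the
    walk (the remainder is left for scaffold-aware assembly).  Returns
    candidates ranked by (composite count, summed mass error, token string).
    """
    if len(b_peaks) < 2:
        raise InsufficientLadderError(
            f"need >= 2 b-series peaks to walk a ladder, got {len(b_peaks)}")
    library = library or default_library()
    b_peaks = sorted(b_peaks)
    cap_mass = ACETYL_MONO if n_cap == "Ac" else 0.0

    # head: composite of up to head_max residues summing to b_first - cap - proton
    head_target = b_peaks[0] - cap_mass - PROTON
    heads: list[tuple[float, tuple[str, ...], int]] = []  # (err, tokens, n_composites)
    for size in range(1, head_max + 1):
        if size == 1:
            for err, tok in _single_matches(head_target, tol, alphabet, library):
                heads.append((err, (tok,), 0))
        elif size == 2:
            for err, pair in _pair_matches(head_target, tol, alphabet, library):
                heads.append((err, pair, 1))
        else:
            for combo in itertools.product(alphabet, repeat=size):
                err = abs(sum(library.mass(t) for t in combo) - head_target)
                if err <= tol:
                    heads.append((err, combo, 1))
    if not heads:
        heads = [(0.0, (), 0)]  # unreadable head; walk from the first peak anyway

    def head_rank(h: tuple[float, tuple[str, ...], int]):
        err, toks, _ = h
        aib_first = 0 if (toks and toks[0] == "Aib") else 1
        return (round(err, 6), aib_first, toks)

    heads.sort(key=head_rank)
    heads = heads[:max_candidates]

    # interior: extend each head along consecutive differences
    candidates: list[LadderCandidate] = []
    for head_pref, (head_err, head_tokens, head_comp) in enumerate(heads):
        walks = [(head_tokens, head_comp, head_err, head_pref)]
        for prev, cur in zip(b_peaks, b_peaks[1:]):
            delta = cur - prev
            singles = _single_matches(delta, tol, alphabet, library)
            pairs = _pair_matches(delta, tol, alphabet, library) if not singles else []
            new_walks = []
            for tokens, n_comp, err, pref in walks:
                if singles:
                    for rank, (s_err, tok) in enumerate(singles[:2]):
                        new_walks.append((tokens + (tok,), n_comp, err + s_err,
                                          pref + rank))
                elif pairs:
                    for rank, (p_err, pair) in enumerate(pairs[:4]):
                        new_walks.append((tokens + pair, n_comp + 1, err + p_err,
                                          pref + rank))
                else:
                    new_walks.append((tokens, n_comp, err, pref))  # unreadable jump
            walks = sorted(new_walks,
                           key=lambda w: (w[1], round(w[2], 6), w[3], w[0]))[:max_candidates]
            if not singles and not pairs:
                break
        candidates.extend(LadderCandidate(t, n, e, p) for t, n, e, p in walks)

    candidates.sort(key=lambda c: (c.n_composites, round(c.error, 6), c.pref, c.tokens))
    # deduplicate token strings
    unique: list[LadderCandidate] = []
    seen: set[tuple[str, ...]] = set()
    for c in candidates:
        if c.tokens not in seen:
            seen.add(c.tokens)
            unique.append(c)
    return unique[:max_candidates]


# -- y7 resolution ------------------------------------------------------------


@dataclass(frozen=True)
class Y7Variant:
    """One canonical y7 family of the Pro-Vxx-Aib-Xxx-Gln-Zxx-Lxxol scaffold."""

    name: str
    r16: str  # Lxx or Vxx
    r18: str  # Gln or Glu

    def suffix(self, library: ResidueLibrary | None = None) -> PeptaibolSequence:
        return PeptaibolSequence(
            ("Pro", "Vxx", "Aib", self.r16, FIXED_POSITION_17, self.r18,
             SCAFFOLD_TERMINUS),
            n_cap="H", library=library or default_library())

    def mz(self, library: ResidueLibrary | None = None) -> float:
        return y_ion_mz(self.suffix(library), 7)


Y7_VARIANTS = (
    Y7Variant("Vxx16/Gln18", "Vxx", "Gln"),
    Y7Variant("Vxx16/Glu18", "Vxx", "Glu"),
    Y7Variant("Lxx16/Gln18", "Lxx", "Gln"),
    Y7Variant("Lxx16/Glu18", "Lxx", "Glu"),
)


@dataclass(frozen=True)
class Y7Resolution:
    variant: Y7Variant
    residual: float
    calls: dict[int, Call] = field(default_factory=dict)  # positions 13..19


def resolve_y7(y7_mz: float, ms2_subions: Sequence[float] = (),
               tol: float = DEFAULT_TOL,
               library: ResidueLibrary | None = None) -> Y7Resolution:
    """Assign the y7 family and refine suffix positions from MS2 sub-ions.

    The y7 mass itself separates the four variants (nearest-variant
    assignment; the Gln/Glu pairs sit ~1 Da apart, the Lxx/Vxx pairs ~14 Da).
    Sub-ions are interpreted as the y1..y6 series of the suffix; consecutive
    differences then call individual positions with provenance ``ms2``.
    Positions 13-15 are left unresolved when no sub-ions cover them (they are
    filled later from the conserved motif).
    """
    if y7_mz <= 0:
        raise ValueError("y7 m/z must be positive")
    library = library or default_library()
    scored = sorted((abs(v.mz(library) - y7_mz), v) for v in Y7_VARIANTS)
    residual, variant = scored[0]
    if residual > tol:
        raise UnassignedY7Error(y7_mz, variant.name, y7_mz - variant.mz(library))

    calls: dict[int, Call] = {
        16: Call(variant.r16, "ms2"),
        17: Call(FIXED_POSITION_17, "closure"),
        18: Call(variant.r18, "ms2"),
        19: Call(SCAFFOLD_TERMINUS, "closure"),
    }

    if ms2_subions:
        # interpret sub-ions as y1..yk; walk differences up the suffix
        series = sorted(ms2_subions) + [y7_mz]
        suffix = variant.suffix(library)
        alphabet = SEQUENCING_ALPHABET + (SCAFFOLD_TERMINUS,)
        for k, (lo, hi) in enumerate(zip(series, series[1:]), start=1):
            position = SCAFFOLD_LENGTH - k  # y_{k+1} - y_k is the residue at 19-k
            if not 13 <= position <= 19:
                break
            matches = _single_matches(hi - lo, tol, alphabet, library)
            if matches:
                calls[position] = Call(matches[0][1], "ms2")
        # y1 itself confirms the terminus
        y1_expect = y_ion_mz(suffix, 1)
        if abs(series[0] - y1_expect) <= tol:
            calls[19] = Call(SCAFFOLD_TERMINUS, "ms2")
    return Y7Resolution(variant=variant, residual=residual, calls=calls)


# -- motif fill ---------------------------------------------------------------


def fill_motif(assignment: Assignment) -> Assignment:
    """Fill positions 13-15 with the conserved Aib-Pro-Vxx-Aib turn motif.

    Cleavage N-terminal to Pro13 suppresses the b13/b14 ions and the
    y7-internal sub-ions, so these positions are predicted, not observed.
    An observed call is never overwritten; a clash raises.
    """
    calls = list(assignment.calls)
    for offset, motif_token in enumerate(MOTIF_13_15):
        position = 13 + offset
        existing = calls[position - 1]
        if existing.token is None or existing.provenance == "unresolved":
            calls[position - 1] = Call(motif_token, "motif")
        elif existing.token != motif_token:
            raise MotifConflictError(position, existing.token, motif_token)
    return replace(assignment, calls=tuple(calls))


# -- full assembly ------------------------------------------------------------


def _anchor_tail(b_mzs: Sequence[float], M_obs: float, y7: Y7Resolution,
                 tol: float, library: ResidueLibrary) -> dict[int, float]:
    """Map observed high-mass b peaks to indices b15..b18 via the scaffold.

    With M and the y7 family known, the expected b15..b18 follow from the
    suffix composition; observed peaks matching them anchor the tail of the
    ladder even across the b13/b14 gap.
    """
    suffix_tokens = [y7.calls[p].token for p in (16, 17, 18, 19)]
    expected: dict[int, float] = {}
    running = M_obs - WATER_MONO + PROTON
    for idx, tok in zip((18, 17, 16, 15), reversed(suffix_tokens)):
        # b18 = M - water - R19 + proton, then peel residues moving left
        running -= library.mass(tok)
        expected[idx] = running
    anchors: dict[int, float] = {}
    for idx, exp in expected.items():
        near = [mz for mz in b_mzs if abs(mz - exp) <= tol]
        if near:
            anchors[idx] = min(near, key=lambda mz: abs(mz - exp))
    return anchors


def assemble_sequence(peaks: PeakList, tol: float = DEFAULT_TOL,
                      library: ResidueLibrary | None = None,
                      alphabet: Sequence[str] = SEQUENCING_ALPHABET) -> Assignment:
    """Full de novo pipeline: deconvolute, walk, resolve y7, fill motif, close.

    Candidate readings (composite-jump expansions) are ranked by fewer
    composite jumps, then smaller |closure residual|, then the Aib-first
    scaffold prior, then token string.  The result is ``complete`` iff every
    position is called and the closure residual is within tolerance.
    """
    library = library or default_library()
    n = SCAFFOLD_LENGTH

    deconv = deconvolute_adducts(peaks, tol)

    y7_peaks = peaks.mzs("y7")
    if not y7_peaks:
        # fall back: any peak near a canonical variant
        variant_mzs = [v.mz(library) for v in Y7_VARIANTS]
        y7_peaks = [mz for mz in peaks.mzs()
                    if any(abs(mz - v) <= tol for v in variant_mzs)]
    if not y7_peaks:
        raise UnassignedY7Error(0.0 if not peaks.peaks else peaks.peaks[0].mz,
                                "none observed", float("nan"))
    y7 = resolve_y7(max(y7_peaks), peaks.mzs("ms2"), tol, library)

    b_mzs = sorted(peaks.mzs("b"))
    if len(b_mzs) < 2:
        raise InsufficientLadderError("peak set has no usable b-series")

    anchors = _anchor_tail(b_mzs, deconv.M, y7, tol, library)
    head_mzs = [mz for mz in b_mzs if mz not in set(anchors.values())]
    tail_calls: dict[int, Call] = {}
    anchor_idxs = sorted(anchors)
    for lo, hi in zip(anchor_idxs, anchor_idxs[1:]):
        if hi - lo == 1:
            delta = anchors[hi] - anchors[lo]
            matches = _single_matches(delta, tol, alphabet, library)
            if matches:
                tail_calls[hi] = Call(matches[0][1], "ladder")

    if len(head_mzs) < 2:
        raise InsufficientLadderError("peak set has no usable b-series")
    ladder_candidates = walk_b_ladder(head_mzs, tol, alphabet, library)

    best: Assignment | None = None
    best_key: tuple | None = None
    best_residual = float("inf")
    for cand in ladder_candidates:
        calls: list[Call] = [Call(None, "unresolved") for _ in range(n)]
        for i, tok in enumerate(cand.tokens[:12], start=1):
            calls[i - 1] = Call(tok, "ladder")
        for position, call in tail_calls.items():
            calls[position - 1] = call
        for position, call in y7.calls.items():
            if calls[position - 1].token is None:
                calls[position - 1] = call
        assignment = Assignment(tuple(calls), neutral_mass_obs=deconv.M)
        try:
            assignment = fill_motif(assignment)
        except MotifConflictError:
            continue
        if any(c.token is None for c in assignment.calls):
            residual = float("inf")
            status = "partial"
        else:
            theor = neutral_mass(assignment.to_sequence(library=library))
            residual = deconv.M - theor
            status = "complete" if abs(residual) <= tol else "partial"
        assignment = replace(assignment, closure_residual=residual, status=status)
        key = (0 if status == "complete" else 1, cand.n_composites,
               round(abs(residual), 6), cand.pref, assignment.tokens())
        if best_key is None or key < best_key:
            best, best_key = assignment, key
        best_residual = min(best_residual, residual, key=abs)
    if best is None or best.status != "complete":
        if best is not None and best.status == "partial" and any(
                c.token is None for c in best.calls):
            return best  # structurally incomplete: report the partial assignment
        raise ClosureError(best_residual if best is not None else float("nan"), tol)
    return best
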