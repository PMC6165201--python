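"""Exception hierarchy for the peptaibiome pipeline.

Every stage raises a subclass of :class:`PeptaibiomeError`, so callers
(and the CLI) can distinguish user/data errors from bugs.
"""


class PeptaibiomeError(Exception):
    """Base class for all pipeline errors."""


class UnknownResidueError(PeptaibiomeError, KeyError):
    """A sequence token does not resolve in the residue library."""

    def __init__(self, token: str):
        super().__init__(f"unknown residue token: {token!r}")
        self.token = token


class InvalidSequenceError(PeptaibiomeError, ValueError):
    """A peptaibol sequence violates a structural invariant."""


class MassDomainError(PeptaibiomeError, ValueError):
    """A mass-domain precondition (e.g. M > 0) was violated."""


class NoPrecursorError(PeptaibiomeError):
    """No sodiated adduct peak could be found in a peak list."""


class InconsistentAdductsError(PeptaibiomeError):
    """[M+Na]+ and [M+2Na]2+ peaks imply neutral masses that disagree."""

    def __init__(self, m_from_na: float, m_from_2na: float, tol: float):
        super().__init__(
            f"adducts disagree: M from [M+Na]+ = {m_from_na:.3f}, "
            f"M from [M+2Na]2+ = {m_from_2na:.3f} (beyond 2 x tol = {2 * tol:.3f})"
        )
        self.m_from_na = m_from_na
        self.m_from_2na = m_from_2na


class InsufficientLadderError(PeptaibiomeError):
    """Fewer than two b-series peaks: no ladder to walk."""


class UnassignedY7Error(PeptaibiomeError):
    """A y7 m/z matched none of the canonical scaffold variants."""

    def __init__(self, mz: float, nearest: str, residual: float):
        super().__init__(
            f"y7 m/z {mz:.3f} matches no canonical variant; "
            f"nearest is {nearest} (residual {residual:+.3f} Da)"
        )
        self.mz = mz
        self.nearest = nearest
        self.residual = residual


class MotifConflictError(PeptaibiomeError):
    """An observed call in positions 13-15 clashes with the Aib-Pro-Vxx-Aib motif."""

    def __init__(self, position: int, observed: str, motif: str):
        super().__init__(
            f"position {position}: observed {observed!r} conflicts with motif residue {motif!r}"
        )
        self.position = position
        self.observed = observed
        self.motif = motif


class ClosureError(PeptaibiomeError):
    """All candidate sequences fail the mass-closure check."""

    def __init__(self, best_residual: float, tol: float):
        super().__init__(
            f"no candidate closes: best |M_obs - M_theor| = {abs(best_residual):.3f} Da "
            f"(tolerance {tol:.3f})"
        )
        self.best_residual = best_residual


class EmptyDatabaseError(PeptaibiomeError):
    """annotate_against_db was handed an empty database."""


class InvalidCalibrationError(PeptaibiomeError, ValueError):
    """Calibration points unusable (non-positive area, no points)."""


class DegenerateRunError(PeptaibiomeError):
    """All chromatographic areas are zero; relative composition undefined."""


class TopologyError(PeptaibiomeError):
    """Required backbone atoms are missing from an ensemble."""


class InsufficientEnsembleError(PeptaibiomeError):
    """An operation requiring >= 2 frames received fewer."""


class FormatError(PeptaibiomeError, ValueError):
    """A delimited input file violates its schema."""
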