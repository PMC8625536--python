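"""Exception hierarchy.

Every error raised by the package derives from :class:`ECpHError`, so callers
(and the CLI) can catch the package's failures without masking programming
errors.
"""


class ECpHError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ECpHError, ValueError):
    """A physical parameter is out of its admissible range (e.g. Hill n <= 0)."""


class InvalidGeometryError(ECpHError, ValueError):
    """A geometric quantity is unphysical (e.g. pair distance <= 0)."""


class SingularGeometryError(InvalidGeometryError):
    """Two non-excluded atoms overlap within numerical resolution."""


class UnknownSiteError(ECpHError, KeyError):
    """A pKa override references a residue absent from the structure."""


class UnparameterizedResidueError(ECpHError, KeyError):
    """A titratable residue has no matching template."""


class MissingProtonError(ECpHError, ValueError):
    """The titratable proton named by the template is absent from the
    structure; the caller must add hydrogens first."""


class CannotNeutralizeError(ECpHError, ValueError):
    """Nonzero excess charge but no water molecules to carry the correction."""


class InsufficientDataError(ECpHError, ValueError):
    """An estimator was given too few samples (e.g. empty pKa sample list)."""


class SelectionError(ECpHError, ValueError):
    """An atom/residue selection resolved to nothing, or to the wrong count."""


class NoDihedralError(SelectionError):
    """The residue type has no defined chi angle of the requested order."""


class NoSidechainError(SelectionError):
    """The residue has no side-chain heavy atoms (glycine)."""


class NoContactsError(ECpHError, ValueError):
    """The reference structure yields an empty native-contact set."""


class UnderdeterminedFitError(ECpHError, ValueError):
    """Too few data points for the requested fit or superposition."""


class UnstableIntegrationError(ECpHError, RuntimeError):
    """Force overflow during dynamics; carries the offending step index."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration became unstable at step {step}")


class ParseError(ECpHError, ValueError):
    """Malformed input file; message names the file and line number."""
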