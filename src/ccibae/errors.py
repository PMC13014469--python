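"""Exception hierarchy for ccibae.

All package-specific errors derive from :class:`CCIBAEError` so callers can
catch one base class; the CLI converts them into nonzero exit codes.
"""


class CCIBAEError(Exception):
    """Base class for all ccibae errors."""


class ValidationError(CCIBAEError):
    """An in-memory object violates one of its invariants."""


class FormatError(CCIBAEError):
    """A file does not conform to the expected on-disk layout."""


class EmptyFeatureSpaceError(CCIBAEError):
    """No ligand-receptor features remain after filtering/matching."""


class EmptyPairSetError(CCIBAEError):
    """No (sender, receiver) cell pairs remain."""


class ConstantFeatureError(CCIBAEError):
    """A feature column has zero variance and cannot be standardized."""


class NumericalError(CCIBAEError):
    """A computation produced non-finite values."""


class NoCandidateError(CCIBAEError):
    """The boosting candidate set is empty."""


class ShapeError(CCIBAEError):
    """Array dimensions are inconsistent."""


class InputSizeError(CCIBAEError):
    """Input too small for the requested operation (e.g. UMAP neighbors)."""


class CompatibilityError(CCIBAEError):
    """A checkpoint and a CCIM do not refer to the same feature space."""


class SpecError(CCIBAEError):
    """A simulation specification violates its invariants."""
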