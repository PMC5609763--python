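"""Typed exceptions raised across the toolbox."""


class AmaresError(Exception):
    """Base class for all toolbox errors."""


class ValidationError(AmaresError, ValueError):
    """A model parameter or data field violates its invariants."""


class ConstraintError(AmaresError, ValueError):
    """A prior-knowledge specification cannot be compiled (duplicate names,
    unresolvable or inconsistent group references, ratios without a group)."""


class FitError(AmaresError, RuntimeError):
    """The fit cannot be run (NaN in data, inconsistent bounds)."""


class ExpressionError(AmaresError, ValueError):
    """A derived-quantity expression fails to parse or evaluate."""


class UnknownIdentifierError(ExpressionError):
    """An identifier in a derived expression is neither a parameter label
    nor a supplied constant."""

    def __init__(self, identifier: str):
        self.identifier = identifier
        super().__init__(
            f"unknown identifier {identifier!r}: not a fitted-parameter "
            "label and no constant with this name was supplied"
        )


class NotSpectroscopyError(AmaresError, ValueError):
    """A DICOM file is not MR spectroscopy data."""

    def __init__(self, sop_class_uid: str):
        self.sop_class_uid = sop_class_uid
        super().__init__(
            f"DICOM file is not MR spectroscopy (SOP class {sop_class_uid})"
        )


class CsaParseError(AmaresError, ValueError):
    """A Siemens CSA private header block is malformed or truncated."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)


class SchemaError(AmaresError, ValueError):
    """A fixture or prior-knowledge file violates its schema.  The message
    names the offending field."""
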