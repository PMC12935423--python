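"""Exception hierarchy for the bradyssa package."""


class BradyssaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BradyssaError):
    """A file did not conform to one of the documented CSV dialects."""


class ParameterError(BradyssaError, ValueError):
    """A parameter is outside its documented range."""


class LengthError(BradyssaError, ValueError):
    """A series is too short for the requested operation."""


class PairingError(BradyssaError):
    """ON/OFF rows could not be matched participant-by-participant."""


class SpecError(BradyssaError, ValueError):
    """A simulation specification is internally inconsistent."""


class InsufficientDataError(BradyssaError):
    """A statistical routine received fewer observations than it requires."""
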