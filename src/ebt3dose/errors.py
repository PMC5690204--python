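"""Exception hierarchy for the film read-out pipeline.

Exit-code classes used by the CLI: configuration problems (2), bad input
data (3), fatal QC failures (4).
"""


class Ebt3DoseError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(Ebt3DoseError):
    """Invalid or missing configuration / archive."""

    exit_code = 2


class InputError(Ebt3DoseError):
    """Invalid input data (wrong format, inconsistent scans, bad values)."""

    exit_code = 3


class BitDepthError(InputError):
    """Image is not 16 bits per channel RGB."""


class GeometryError(InputError):
    """ROI / band / stripe placement outside the image bounds."""


class InsufficientDataError(InputError):
    """Too few scans, pieces or calibration points for the operation."""


class DomainError(InputError):
    """Value outside the mathematical domain (non-positive PV, zero OD...)."""


class CoverageError(InputError):
    """Stripe series does not cover the requested transversal columns."""


class FitQualityError(Ebt3DoseError):
    """Calibration fit violates a required property (e.g. monotonicity)."""


class ExtrapolationError(Ebt3DoseError):
    """Requested dose/OD lies outside the calibrated range."""


class QCError(Ebt3DoseError):
    """Fatal quality-control failure."""

    exit_code = 4
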