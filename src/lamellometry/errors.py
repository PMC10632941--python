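"""Exception hierarchy for the lamellar measurement pipeline."""


class LamellometryError(Exception):
    """Base class for all pipeline errors."""


class MissingMarkerError(LamellometryError):
    """Fewer than two fiducial components of a required marker color were found."""


class AmbiguousMarkerError(LamellometryError):
    """More than two fiducial components of a marker color were found."""


class DegenerateMarkerError(LamellometryError):
    """The two red markers coincide; no rotation angle is defined."""


class MissingROIError(LamellometryError):
    """No yellow rectangle pixels were found in the rotated image."""


class MalformedROIError(LamellometryError):
    """Yellow pixels exist but do not enclose a non-empty interior."""


class ImageTooShortError(LamellometryError):
    """Image height does not exceed the threshold window size."""


class AllColumnsRejectedError(LamellometryError):
    """Every pixel column failed the quality filters.

    Usually means the expected bright/dark lamella counts are mis-set, or the
    region of interest does not contain clean parallel bands.
    """


class AllZeroDifferencesError(LamellometryError):
    """Every paired difference is zero; the sign test is undefined."""


class FixtureSpecError(LamellometryError):
    """A synthetic fixture specification is internally inconsistent."""


class DefectOutsideROIError(FixtureSpecError):
    """A requested defect blob does not lie inside the region of interest."""
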