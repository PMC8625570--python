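"""Exception hierarchy shared across the package."""


class RhoselectError(Exception):
    """Base class for all package errors."""


class ValidationError(RhoselectError, ValueError):
    """Invalid value, sequence code, range, or configuration."""


class ParseError(RhoselectError, ValueError):
    """Malformed input file (FASTA, PDB, TSV)."""


class LabelingError(RhoselectError, ValueError):
    """Alignment lacks the binder/nonbinder labels an analysis needs."""


class FitError(RhoselectError, RuntimeError):
    """A model fit failed or did not converge."""


class CalibrationError(RhoselectError, ValueError):
    """Unusable SEC calibration (too few standards, wrong slope sign)."""
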