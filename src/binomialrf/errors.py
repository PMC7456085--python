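"""Exception hierarchy; the CLI maps these to exit codes (2 and 3)."""


class BinomialRFError(Exception):
    """Base class for package errors."""


class ValidationError(BinomialRFError, ValueError):
    """Malformed input: bad parameters, shapes, labels or file contents."""


class DegenerateDistributionError(BinomialRFError, ValueError):
    """A (p, rho, V) combination that does not yield a valid distribution."""
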