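"""Exception hierarchy for hdxkit.

All exceptions derive from :class:`HdxError` so callers can catch the
package's failures with one clause; validation-type errors additionally
derive from ``ValueError`` so they behave normally in generic code.
"""


class HdxError(Exception):
    """Base class for all hdxkit errors."""


class InputError(HdxError, ValueError):
    """Malformed or out-of-range user input (sequences, parameters)."""


class CoordinateError(HdxError, ValueError):
    """A residue span falls outside the sequence or protein bounds."""


class DegenerateControlError(HdxError, ValueError):
    """Missing or unusable undeuterated / fully-deuterated control rows
    (e.g. m_f <= m_0, which makes percent exchange undefined)."""


class InsufficientReplicationError(HdxError, ValueError):
    """An operation requiring replicate dispersion got < 2 replicates."""


class AlignmentError(HdxError, ValueError):
    """Two inputs that must share a grid (peptides, time points) do not."""


class ParseError(HdxError, ValueError):
    """A file does not conform to the expected dialect."""


class FitError(HdxError, RuntimeError):
    """A curve fit failed to converge or produced a degenerate model."""
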