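"""Exception hierarchy for pwmscale.

All library errors derive from :class:`PwmScaleError` so callers can catch
one base class at CLI boundaries.
"""


class PwmScaleError(Exception):
    """Base class for all pwmscale errors."""


class ParseError(PwmScaleError):
    """A motif file block could not be parsed; message names block and line."""


class ParameterError(PwmScaleError):
    """An invalid parameter value (e.g. pseudocount <= 0, lambda <= 0)."""


class DegenerateMotifError(PwmScaleError):
    """Motif has zero information content; lambda is undefined."""


class ShortMotifError(PwmScaleError):
    """The score landscape collapses at the requested quantile.

    The top-quantile score equals the maximum score, so the score range in
    the lambda equation is zero. Typical for very short motifs, whose
    k-mer space is too small for a top-0.1% boundary distinct from the
    consensus.
    """


class EmptyLandscapeError(PwmScaleError):
    """No scorable window was found in the supplied sequences."""


class InsufficientSampleError(PwmScaleError):
    """Empirical landscape too small to resolve the requested quantile."""


class EmptyProfileError(PwmScaleError):
    """No site lies beyond the minimum log-quantile boundary."""


class IncomparableProfilesError(PwmScaleError):
    """Fewer than two log-quantile bins are occupied in both profiles."""


class UndefinedZScoreError(PwmScaleError):
    """A motif-length group cannot be z-normalized (singleton or zero spread)."""
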