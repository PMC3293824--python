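"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`TaxonovelError`
so callers (and the CLI) can distinguish domain errors from bugs.
"""


class TaxonovelError(Exception):
    """Base class for all taxonovel errors."""


class FormatError(TaxonovelError, ValueError):
    """A file or record does not conform to the expected dialect."""


class LinkageError(TaxonovelError, ValueError):
    """A record references a taxon or sequence that does not exist."""


class EmptyDatabaseError(TaxonovelError, ValueError):
    """An operation produced or received a reference database with no genera."""


class ConfigurationError(TaxonovelError, ValueError):
    """Invalid parameter values or an infeasible experimental design."""


class InputError(TaxonovelError, ValueError):
    """Invalid runtime input (mismatched keys, missing scores, bad ranges)."""


class NoValidWordsError(InputError):
    """A query yields no unambiguous words; unclassifiable rather than erroneous."""


class TooShortReadError(InputError):
    """A query has too few valid words for bootstrap resampling."""


class DegenerateScoresError(TaxonovelError, ValueError):
    """A score set contains a single class; no ROC can be built from it."""


class UndefinedMetricError(TaxonovelError, ArithmeticError):
    """A metric's denominator class is empty (reported as absent, never as 0)."""
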