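"""Exception hierarchy used across the package."""


class SalmofatError(Exception):
    """Base class for package errors."""


class InvalidConfigError(SalmofatError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class AlignmentError(SalmofatError, ValueError):
    """Sample/gene identifiers of two inputs cannot be aligned."""


class EmptyPanelError(SalmofatError, ValueError):
    """Every SNP was removed by quality control."""


class MonomorphicSNPError(SalmofatError, ValueError):
    """A monomorphic SNP reached a stage that requires polymorphic markers."""


class FormatError(SalmofatError, ValueError):
    """A file on disk does not conform to the expected dialect."""


class DegenerateTraitError(SalmofatError, ValueError):
    """A response variable is constant or otherwise unusable."""


class DegenerateGeneError(SalmofatError, ValueError):
    """A gene's expression vector is constant; its slope is undefined."""


class UndefinedStatisticError(SalmofatError, ValueError):
    """A requested statistic is undefined for the given input (e.g. zero margin)."""
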