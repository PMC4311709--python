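"""Exception hierarchy for rarepulse.

All domain errors derive from :class:`RarePulseError` so callers can catch
one base class; parameter-validation problems additionally derive from
``ValueError`` to behave like standard library misuse errors.
"""


class RarePulseError(Exception):
    """Base class for all rarepulse-specific errors."""


class InvalidParameterError(RarePulseError, ValueError):
    """A parameter violates its documented domain (negative depth, |rho| >= 1, ...)."""


class NoPeakError(RarePulseError):
    """A gradient profile is flat at zero copies: no DNA peak can be selected."""


class SingularFitError(RarePulseError):
    """The regression design matrix is rank deficient (e.g. constant moisture and CO2)."""


class InsufficientDepthError(RarePulseError):
    """Requested rarefaction depth exceeds a sample's total count."""

    def __init__(self, sample_id, total, depth):
        self.sample_id = sample_id
        self.total = int(total)
        self.depth = int(depth)
        super().__init__(
            f"sample {sample_id!r} has {total} reads, fewer than rarefaction depth {depth}"
        )


class UndefinedDistanceError(RarePulseError):
    """Bray-Curtis is undefined when both count vectors are all zero."""


class UndefinedFractionError(RarePulseError):
    """A compositional fraction has an empty denominator (empty sample or set)."""


class UndefinedRatioError(RarePulseError):
    """Fold change is undefined because the reference (dry) net production is zero."""

    def __init__(self, rewetted_value, dry_value):
        self.rewetted_value = rewetted_value
        self.dry_value = dry_value
        super().__init__(
            f"fold change undefined: dry net production is 0 (rewetted={rewetted_value})"
        )


class UnsupportedDesignError(RarePulseError):
    """The factorial design is unbalanced or incomplete for classic two-way ANOVA."""


class DegenerateFactorError(RarePulseError):
    """A PERMANOVA factor has a single level and carries no degrees of freedom."""


class ParseError(RarePulseError, ValueError):
    """A file failed validation; message names the offending line."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class PipelineError(RarePulseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")
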