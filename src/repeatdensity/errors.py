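"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, LoadError /
ValidationError -> 3, StageError -> 4.
"""


class RepeatDensityError(Exception):
    """Base class for all errors raised by this package."""


class LoadError(RepeatDensityError):
    """An input file could not be parsed or failed validation at load time."""


class ValidationError(RepeatDensityError):
    """Loaded data violate an invariant (cross-file consistency, group sizes...)."""


class ConfigError(RepeatDensityError):
    """A configuration value is missing, unknown, or inconsistent.

    ``problems`` lists every violation found so a user can fix them all at once.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class StageError(RepeatDensityError):
    """A pipeline stage failed; the message names the stage."""
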