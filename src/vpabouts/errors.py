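"""Exception types shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError -> 3,
ValidityError -> 4.
"""


class ConfigError(ValueError):
    """Invalid configuration or impossible schedule/parameter combination."""


class FormatError(ValueError):
    """Malformed input file (missing column, broken epoch grid, bad cell)."""


class ValidityError(RuntimeError):
    """A subject or cohort was excluded by the validity rules."""
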