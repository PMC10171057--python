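"""Exception hierarchy shared across the package.

The command-line layer maps these onto exit codes: configuration
problems (bad paths, malformed run configs) exit with 2, data problems
(schema violations, bad lexicon files, inconsistent inputs) with 3.
"""


class ReportTriageError(Exception):
    """Base class for all errors raised by reportriage."""


class ConfigError(ReportTriageError):
    """A run configuration is missing, malformed or self-inconsistent."""


class DataError(ReportTriageError):
    """Input data violates a contract (lengths, identifiers, values)."""


class SchemaError(DataError):
    """A tabular input does not match the expected column schema."""


class LexiconError(DataError):
    """A lexicon file is empty, duplicated or otherwise invalid."""
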