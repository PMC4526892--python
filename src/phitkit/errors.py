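"""Exception hierarchy for the engine.

Exit-code mapping used by the CLI lives in :mod:`phitkit.cli`.
"""


class PhitError(Exception):
    """Base class for all engine errors."""


class LexError(PhitError):
    """Bad token stream in a logic script (position included in message)."""


class LogicParseError(PhitError):
    """Structurally invalid logic program."""


class DefinitionError(PhitError):
    """Invalid instrument/advisor XML definition."""


class ConfigError(PhitError):
    """Invalid or unresolvable app/study/protocol configuration."""


class RuntimeLogicError(PhitError):
    """Error raised while executing a logic program or a session."""


class ScheduleError(PhitError):
    """Unparseable schedule spec or unknown task id."""


class StorageError(PhitError):
    """Datastore failure (e.g. writing to a read-only database)."""


class QueryError(PhitError):
    """Invalid datastore query arguments."""
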