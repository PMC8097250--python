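"""Exception hierarchy for the rxstew pipeline."""


class RxStewError(Exception):
    """Base class for all rxstew errors."""


class ConfigError(RxStewError):
    """Invalid configuration (bad pattern, conflicting lexicon keywords, bad rates)."""


class AmbiguousHeaderError(RxStewError):
    """Two source headers in one file resolve to the same canonical column."""


class SchemaError(RxStewError):
    """An invoice file maps to none of the essential canonical columns."""


class AmbiguousDateError(RxStewError):
    """A file's dates cannot be parsed unambiguously under the configured dialect."""


class IntegrityError(RxStewError):
    """Rows that must agree disagree (e.g. one prescription number across facilities)."""


class InsufficientDataError(RxStewError):
    """A statistical operation was given fewer points than it requires."""


class PairingError(RxStewError):
    """Two series that must be paired observation-for-observation cannot be."""
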