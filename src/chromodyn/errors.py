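"""Exception hierarchy shared across the package."""


class ChromodynError(Exception):
    """Base class for all package errors."""


class UsageError(ChromodynError):
    """A caller asked for something the API does not support (bad mode/flag)."""


class ValidationError(ChromodynError):
    """Input data violated a stated contract (ranges, subsets, duplicates)."""


class ConfigurationError(ChromodynError):
    """Sample/axis/config declarations are inconsistent or incomplete."""


class PeakParseError(ChromodynError):
    """A peak file row could not be parsed; message carries the line number."""


class CapacityError(ChromodynError):
    """A synthetic genome is too small for the requested interval layout."""
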