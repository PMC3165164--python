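"""Exception hierarchy for cmprof."""


class CmprofError(Exception):
    """Base class for all cmprof errors."""


class InputError(CmprofError):
    """Invalid input values (empty files, bad sizes, out-of-range parameters)."""


class FormatError(CmprofError):
    """Malformed file content (ragged alignments, unparseable PSSM rows)."""


class ConfigError(CmprofError):
    """Inconsistent configuration (missing scoring-term inputs, unknown presets)."""


class DegenerateError(CmprofError):
    """Geometrically degenerate input (too few or collinear points)."""
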