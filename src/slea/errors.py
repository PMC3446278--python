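"""Exception hierarchy.

``FormatError`` marks malformed input files (CLI exit code 2); every other
package error derives from ``SleaError`` (CLI exit code 1).
"""


class SleaError(Exception):
    """Base class for runtime errors raised by this package."""


class FormatError(SleaError):
    """A file did not conform to its expected format."""
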