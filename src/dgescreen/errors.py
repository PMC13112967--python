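"""Exception hierarchy mapped onto CLI exit codes.

Exit-code contract: 0 success, 2 config/schema error, 3 data integrity
error, 4 any other runtime failure.
"""


class ScreenError(Exception):
    """Base class for all pipeline failures."""

    exit_code = 4


class SchemaError(ScreenError):
    """Malformed configuration or an input file violating its schema."""

    exit_code = 2


class IntegrityError(ScreenError):
    """Structurally valid input whose content is inconsistent.

    Examples: duplicate gene symbols, negative CPM values, contrast cells
    missing from the dataset.
    """

    exit_code = 3
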