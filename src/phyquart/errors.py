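"""Exception hierarchy shared across the package."""


class InputError(ValueError):
    """Malformed user input (alignment, clan file, configuration)."""


class DegenerateAlignmentError(InputError):
    """A quartet alignment with no usable columns after site exclusion."""
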