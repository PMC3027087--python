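"""Exception hierarchy shared by all netmark modules.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`ContractError` and :class:`PipelineError` -> 3.
"""


class NetmarkError(Exception):
    """Base class for all netmark errors."""


class InputError(NetmarkError):
    """Malformed or inconsistent user-supplied input (files, mappings)."""


class ContractError(NetmarkError):
    """A function precondition was violated by the caller."""


class PipelineError(NetmarkError):
    """A pipeline stage cannot proceed (e.g. empty protein pool)."""
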