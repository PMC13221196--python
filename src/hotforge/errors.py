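"""Exception types shared across hotforge modules."""


class HotforgeError(Exception):
    """Base class for all hotforge errors."""


class EmptyStructureError(HotforgeError):
    """A structure source contained no usable atom records."""


class UnknownChainError(HotforgeError):
    """A requested chain label is not present in the model."""


class UnknownResidueError(HotforgeError):
    """A requested residue key is not present in the model."""


class ParameterizationError(HotforgeError):
    """A (res_name, atom_name) pair has no entry in the parameter table."""


class DialectError(HotforgeError):
    """An external contact table row could not be mapped to canonical keys."""


class SuperpositionError(HotforgeError):
    """Too few mapped residues to compute a rigid-body superposition."""
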