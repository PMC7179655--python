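"""Exception hierarchy."""


class MMGBSAError(Exception):
    """Base class for all package errors."""


class ParseError(MMGBSAError):
    """Malformed structure or trajectory input."""


class EmptyInputError(MMGBSAError):
    """An input that must be non-empty was empty."""


class MissingParameterError(MMGBSAError):
    """Atoms left without force-field parameters after attachment."""

    def __init__(self, atoms):
        self.atoms = list(atoms)
        names = ", ".join(str(a) for a in self.atoms[:10])
        more = "" if len(self.atoms) <= 10 else f" (+{len(self.atoms) - 10} more)"
        super().__init__(f"no parameters for atoms: {names}{more}")


class AmbiguousParameterError(MMGBSAError):
    """Duplicate key in a parameter table."""


class ClassificationError(MMGBSAError):
    """Residue name outside the polarity-class table."""


class TopologyError(MMGBSAError):
    """Inconsistent molecular topology (missing ligand, missing Cβ, ...)."""


class MutationError(MMGBSAError):
    """Unsupported alanine mutation (e.g. glycine target)."""


class SingularityError(MMGBSAError):
    """Pairwise energy requested for (near-)coincident atoms."""


class WindowError(MMGBSAError):
    """Trajectory too short for the requested window plan, or too few windows."""


class ConfigError(MMGBSAError):
    """Invalid run configuration."""
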