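"""Exception hierarchy for hcrforge.

Every error raised by the library derives from :class:`HcrForgeError`, so
callers (and the CLI) can catch a single base class.
"""


class HcrForgeError(Exception):
    """Base class for all hcrforge errors."""


class AlphabetError(HcrForgeError):
    """Sequence contains characters outside the declared nucleotide alphabet."""


class EmptySequenceError(HcrForgeError):
    """An operation received an empty sequence."""


class DegenerateHelixError(HcrForgeError):
    """A duplex shorter than 2 bp has no nearest-neighbor stack."""


class ImpossibleLoopError(HcrForgeError):
    """Hairpin loops below 3 nt are sterically impossible."""


class MalformedHairpinError(HcrForgeError):
    """Hairpin segments violate the stem/loop/toehold contract."""


class DesignError(HcrForgeError):
    """A hairpin pair could not be constructed from the target."""


class TargetTooShortError(DesignError):
    """Target is too short for the requested toehold/stem layout."""


class ExtensionFailureError(DesignError):
    """Stem extension could not reach the leak-resistance benchmark."""


class PartitionError(HcrForgeError):
    """Target too short to partition into regions a/b/c."""


class IndelError(HcrForgeError):
    """Homolog comparison only supports equal-length sequences."""


class IndistinguishableHomologError(HcrForgeError):
    """A homolog is identical to the target; no toehold end can separate them."""


class InfeasiblePlanError(HcrForgeError):
    """No discrimination plan satisfies the melt-window constraints.

    ``blocking_homolog`` names the panel member that made the plan infeasible,
    ``stage`` the pipeline stage that failed.
    """

    def __init__(self, message, *, stage=None, blocking_homolog=None):
        super().__init__(message)
        self.stage = stage
        self.blocking_homolog = blocking_homolog


class NotNucleatedError(HcrForgeError):
    """Toehold binding below the nucleation minimum; no branch migration."""


class FastaError(HcrForgeError):
    """Named FASTA parse error (empty file, duplicate id, bad characters)."""


class ConfigError(HcrForgeError):
    """Invalid or unknown configuration keys/values."""
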