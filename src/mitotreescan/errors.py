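"""Exception hierarchy shared across the pipeline stages."""


class MitoTreeScanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MitoTreeScanError, ValueError):
    """Malformed input file (unequal alignment rows, empty FASTA, bad TSV)."""


class LookupError_(MitoTreeScanError, KeyError):
    """A referenced identifier is absent (sample, representative, parent)."""


class ConsistencyError(MitoTreeScanError, ValueError):
    """Inputs contradict each other (overlapping variants, conflicting roles)."""


class BoundsError(MitoTreeScanError, ValueError):
    """A coordinate falls outside the reference."""


class DegenerateInputError(MitoTreeScanError, ValueError):
    """Input too small or too uniform for the operation (e.g. < 2 haplotypes)."""


class CapacityError(MitoTreeScanError, ValueError):
    """An enumeration would exceed a configured cap; message names the count."""


class PedigreeError(MitoTreeScanError, ValueError):
    """Pedigree structure invalid (cycle, individual its own ancestor)."""


class ParameterError(MitoTreeScanError, ValueError):
    """An analysis parameter is out of its valid range."""
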