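"""Exception hierarchy for epiblup.

All package-specific failures derive from :class:`EpiblupError` so callers
can catch one base class at pipeline boundaries.
"""


class EpiblupError(Exception):
    """Base class for all epiblup errors."""


class PhaseRequiredError(EpiblupError):
    """Unphased genotype encountered where phase is required."""


class UnsupportedRecordError(EpiblupError):
    """Variant record that the panel model cannot represent (e.g. multi-allelic)."""


class DuplicateSiteError(EpiblupError):
    """Two SNPs share a (chromosome, position) coordinate."""


class MissingGenotypeError(EpiblupError):
    """Missing genotype call; the panel model assumes fully imputed data."""


class MalformedFileError(EpiblupError):
    """Structurally invalid input file."""


class EmptyPanelError(EpiblupError):
    """A filter removed every SNP."""


class DegenerateSNPError(EpiblupError):
    """Monomorphic SNP where a polymorphic one is required."""


class DegenerateGRMError(EpiblupError):
    """Relationship matrix with (numerically) zero diagonal — no variance."""


class InvalidSchemeError(EpiblupError):
    """Invalid haplotype blocking scheme."""


class ConsistencyError(EpiblupError):
    """Mismatched identifiers or incompatible objects combined."""


class EmptyModelError(EpiblupError):
    """Effect screening retained nothing."""


class UndefinedAccuracyError(EpiblupError):
    """Pearson accuracy undefined (constant vector or too few points)."""


class UndefinedIncreaseError(EpiblupError):
    """Percent accuracy increase undefined (zero baseline)."""


class TooFewIndividualsError(EpiblupError):
    """Not enough individuals for the requested fold plan."""


class GeneratorError(EpiblupError):
    """Synthetic-data generator could not satisfy its constraints."""


class ConfigError(EpiblupError):
    """Invalid simulation or model configuration."""
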