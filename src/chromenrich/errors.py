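"""Exception hierarchy shared across the pipeline stages."""


class ChromenrichError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ChromenrichError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataIntegrityError(ChromenrichError):
    """Inputs that contradict each other (CLI exit code 3).

    Examples: a risk SNP missing from its background set, or a variant
    whose reference allele disagrees with the genome sequence.
    """


class MonomorphicVariantError(ChromenrichError):
    """LD is undefined for a monomorphic allele vector; callers may skip."""


class FeasibilityError(ChromenrichError):
    """Requested haplotype frequencies violate the Frechet bounds."""
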