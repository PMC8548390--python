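"""Exception hierarchy shared across the pipeline stages."""


class HeteroprotError(ValueError):
    """Base class for all validation and domain errors raised by heteroprot."""


class DesignError(HeteroprotError):
    """The sample map does not describe a valid female/male/hybrid trio design."""


class FormatError(HeteroprotError):
    """An input table violates its structural contract (duplicates, bad header...)."""


class ConfigError(HeteroprotError):
    """A simulation or run configuration is inconsistent."""


class UndefinedIndexError(HeteroprotError):
    """A heterosis index is undefined because its denominator is zero."""
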