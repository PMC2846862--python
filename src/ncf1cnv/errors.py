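"""Exception hierarchy for the NCF1 CNV pipeline."""


class Ncf1Error(Exception):
    """Base class for all pipeline errors."""


class DomainError(Ncf1Error):
    """An operation was applied outside its mathematical domain
    (e.g. a zero-total copy-number trio, or an undefined ratio)."""


class InputError(Ncf1Error):
    """Malformed user input: bad peak heights, out-of-range fractions,
    missing columns. Carries row/sample context where available."""


class ConfigurationError(Ncf1Error):
    """Contradictory or empty caller/simulator configuration."""


class PedigreeError(Ncf1Error):
    """Structurally invalid pedigree (missing parents, cycles)."""


class AssayInconsistencyError(Ncf1Error):
    """The two cDNA assays disagree beyond tolerance (negative implied share)."""


class FitError(Ncf1Error):
    """A regression/standard-curve fit could not be performed."""
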