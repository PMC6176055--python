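"""Exception hierarchy for matflux."""


class MatfluxError(Exception):
    """Base class for all matflux errors."""


class CatalogError(MatfluxError):
    """Invalid pathway/marker-gene catalog (duplicate symbol, bad class, ...)."""


class InputError(MatfluxError):
    """Malformed or inconsistent user-supplied tables or parameters."""


class UndefinedPoolError(MatfluxError):
    """The dissolved substrate pool is empty: enrichment is undefined."""


class InfeasibleScenarioError(MatfluxError):
    """A simulation scenario implies a physically impossible observation."""
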