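"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`LfqStabError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class LfqStabError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(LfqStabError, ValueError):
    """Invalid simulation or analysis parameters."""


class ParseError(LfqStabError, ValueError):
    """Malformed input file."""


class PreprocessError(LfqStabError, ValueError):
    """Normalization or routing failure (e.g. a sample with no data)."""


class DesignError(LfqStabError, ValueError):
    """Unusable study design (e.g. batch confounded with disease)."""


class ImputationError(LfqStabError, ValueError):
    """A protein lacks enough observed values to impute from."""


class EstimationError(LfqStabError, ValueError):
    """Empirical-Bayes hyperparameter estimation is impossible."""


class AggregationError(LfqStabError, ValueError):
    """Imputation rounds disagree on the protein set."""


class ValidationError(LfqStabError, ValueError):
    """Generic input-contract violation."""
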