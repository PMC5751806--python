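"""Exception hierarchy for ale."""


class AleError(Exception):
    """Base class for all errors raised by ale."""


class MetadataError(AleError):
    """Unreadable metadata source or a record violating the data model."""


class OntologyError(AleError):
    """Malformed ontology: unknown term id, cyclic is_a graph, empty graph."""


class ExpressionError(AleError):
    """Expression-matrix problem: shape mismatch, missing genes, bad labels."""


class EvaluationError(AleError):
    """Evaluation cannot proceed: empty input, too few series for k folds."""


class UnknownUnitError(AleError, ValueError):
    """An age unit that is not in the synonym table and was not defaulted."""
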