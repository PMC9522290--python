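"""Exception hierarchy for scoring-annotation handling and analysis."""


class PsgAgreeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PsgAgreeError):
    """Malformed annotation file content (bad timestamp, bad row, bad TAL)."""


class VocabularyError(PsgAgreeError):
    """Annotation label not present in the registered vocabulary."""


class StructuralError(PsgAgreeError):
    """File or recording violates structural requirements (e.g. missing
    lights markers, empty time-in-bed, empty hypnogram)."""


class ConflictError(PsgAgreeError):
    """Two files claim the same recording x scorer x method x task cell."""


class ConsistencyError(PsgAgreeError):
    """Scorers of one recording disagree on shared facts (lights markers)."""


class AlignmentError(PsgAgreeError):
    """Label sequences or recordings do not share a common grid / TIB."""


class CoverageError(PsgAgreeError):
    """A context hypnogram does not cover the requested analysis grid."""


class DomainError(PsgAgreeError):
    """A statistic was requested on inputs outside its domain."""


class DegenerateDataError(DomainError):
    """The statistic is undefined on this input (e.g. ICC on a constant
    matrix)."""


class DesignError(PsgAgreeError):
    """Assembled samples do not match the expected study design."""
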