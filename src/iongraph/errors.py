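"""Exception hierarchy for the ionic-liquid property pipeline."""


class IonGraphError(Exception):
    """Base class for all package errors."""


class ParseError(IonGraphError):
    """A SMILES string could not be parsed."""


class ChargeBalanceError(IonGraphError):
    """Ion charges do not match the expected cation/anion pattern."""


class GeometryError(IonGraphError):
    """3D embedding or force-field optimization failed for an ion."""


class CapabilityError(IonGraphError):
    """A requested backend or charge scheme is unavailable."""


class ChargeComputationError(IonGraphError):
    """A partial-charge calculation produced invalid (non-finite) values."""


class FeaturizationError(IonGraphError):
    """Node featurization inputs are inconsistent."""


class ScenarioError(IonGraphError):
    """A graph operation was applied to the wrong graph scenario."""


class CurationError(IonGraphError):
    """Outlier filtering produced an unusable dataset."""


class SplitError(IonGraphError):
    """Train/validation/test partitioning is inconsistent."""


class ConfigError(IonGraphError):
    """Invalid model or training configuration."""


class TrainingError(IonGraphError):
    """Training diverged or could not be completed."""


class TransferError(IonGraphError):
    """Pretrained weights are incompatible with the target task."""


class ReportError(IonGraphError):
    """Experiment results could not be rendered or written."""
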