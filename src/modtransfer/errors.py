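"""Exception hierarchy."""


class ModTransferError(Exception):
    """Base class for package errors."""


class SpecError(ModTransferError, ValueError):
    """Inconsistent network or experiment specification."""


class ShapeError(ModTransferError, ValueError):
    """Input shape incompatible with a network contract."""


class TransferError(ModTransferError, ValueError):
    """Weight transfer failed (shape or group mismatch)."""


class ConfigError(ModTransferError, ValueError):
    """Invalid configuration value (balancing strategy, epochs, ...)."""


class DataError(ModTransferError, ValueError):
    """Invalid data (missing labels, out-of-range classes, empty input)."""


class ProtocolError(ModTransferError, ValueError):
    """Split protocol cannot run on the provided metadata."""


class MetricError(ModTransferError, ValueError):
    """A metric is undefined on the provided predictions."""


class AnalysisError(ModTransferError, ValueError):
    """Interpretability analysis cannot handle the network."""
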