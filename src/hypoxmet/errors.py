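"""Exception hierarchy for the hypoxmet pipeline."""


class HypoxmetError(Exception):
    """Base class for all pipeline errors."""


class InputStructureError(HypoxmetError):
    """A file or table violates the structural contract (missing columns,
    intensity columns without metadata, dimension mismatches)."""


class ValidationError(HypoxmetError):
    """Values violate a domain invariant (negative intensities, duplicate
    identifiers, single-class responses)."""


class ConfigurationError(HypoxmetError):
    """A parameter combination is unusable (no blank injections for blank
    removal, unknown config keys, inconsistent feature counts)."""


class ConstantFeatureError(ValidationError):
    """A feature column has zero variance and cannot be autoscaled."""

    def __init__(self, feature_ids):
        self.feature_ids = list(feature_ids)
        super().__init__(
            "zero-variance feature(s) cannot be autoscaled: "
            + ", ".join(map(str, self.feature_ids))
        )
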