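"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a documented invariant (bad panel row, bad trace, ...)."""


class PanelError(ValidationError):
    """Antibody panel file is malformed or internally inconsistent."""


class TraceError(ValidationError):
    """Chromatogram trace is malformed (non-monotone time, length mismatch, ...)."""


class WindowError(ValidationError):
    """Integration window lies outside the trace or is degenerate."""


class UndefinedRatioError(ValueError):
    """Control expression level is zero; the treated/control ratio is undefined.

    Signals a failed control immunoprecipitation rather than a true zero.
    """


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicate measurements; spread statistics are undefined."""
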