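"""Exception types shared across the analysis chain."""


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateRatioError(ValueError):
    """The precursor response is too small to form a meaningful ratio."""


class DegenerateModelError(ValueError):
    """The requested fit is structurally unidentifiable (e.g. 90-degree readout)."""


class FitError(RuntimeError):
    """A least-squares fit failed to converge.

    Carries the last iterate so a caller can inspect where the
    optimizer stalled.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class NoPlateauError(ValueError):
    """No constant-concentration window could be identified."""


class ParseError(ValueError):
    """A tabular input file could not be parsed; carries line numbers."""
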