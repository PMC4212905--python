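"""Exception types shared across the package."""


class WingmorphError(ValueError):
    """Base class for all wingmorph errors."""


class LandmarkParseError(WingmorphError):
    """A landmark file could not be parsed."""


class DimensionError(WingmorphError):
    """Landmark counts or coordinate dimensions disagree."""


class DegenerateShapeError(WingmorphError):
    """A configuration carries no shape information (e.g. all landmarks coincide)."""
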