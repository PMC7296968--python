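"""Exception hierarchy for the phenotyping pipeline."""


class PlotPhenoError(Exception):
    """Base class for all pipeline errors."""


class RasterIOError(PlotPhenoError):
    """Unreadable, malformed or incompatible raster input."""


class VectorIOError(PlotPhenoError):
    """Shapefile problems: bad geometry type, missing fields, duplicate ids."""


class EmptyPlotError(PlotPhenoError):
    """A plot polygon covers no pixel center of the target grid."""

    def __init__(self, plot_id: str):
        self.plot_id = plot_id
        super().__init__(f"empty plot: polygon {plot_id!r} covers no pixel center")


class InsufficientTargetsError(PlotPhenoError):
    """Fewer than two calibration targets with distinct reflectance."""


class SingularFitError(PlotPhenoError):
    """Calibration targets do not span a line (identical reflectances or DNs)."""


class DegenerateHistogramError(PlotPhenoError):
    """All values identical: no threshold can separate two classes."""


class NoValidPixelsError(PlotPhenoError):
    """A plot/layer combination has no finite pixel to summarize."""

    def __init__(self, layer: str, plot_id: str):
        self.layer = layer
        self.plot_id = plot_id
        super().__init__(f"no valid pixels for layer {layer!r} in plot {plot_id!r}")


class MissingStageError(PlotPhenoError):
    """A stage required by a multi-temporal combination is absent for a plot."""

    def __init__(self, plot_id: str, stage: str):
        self.plot_id = plot_id
        self.stage = stage
        super().__init__(f"plot {plot_id!r} has no record for stage {stage!r}")


class ConfigError(PlotPhenoError):
    """Invalid run configuration; message lists every problem found."""
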