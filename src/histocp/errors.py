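"""Exception hierarchy shared across the package."""


class HistocpError(Exception):
    """Base class for all package errors."""


class UnknownClassIntensityError(HistocpError):
    """A red-channel intensity has no entry in the class map."""

    def __init__(self, intensity: int):
        self.intensity = int(intensity)
        super().__init__(
            f"red-channel intensity {self.intensity} is not present in the class map"
        )


class InconsistentMaskError(HistocpError):
    """An instance's pixels span more than one class intensity."""

    def __init__(self, instance_id: int, intensities):
        self.instance_id = int(instance_id)
        self.intensities = sorted(int(v) for v in intensities)
        super().__init__(
            f"instance {self.instance_id} spans multiple red intensities "
            f"{self.intensities}; the class map must be single-valued per instance"
        )


class InstanceOverlapError(HistocpError):
    """Two instances claim the same pixels when rendering a mask."""

    def __init__(self, colliding_ids):
        self.colliding_ids = sorted(int(v) for v in colliding_ids)
        super().__init__(f"instance masks overlap: ids {self.colliding_ids}")


class InvalidAnnotationError(HistocpError):
    """An annotation cannot be expressed (e.g. empty mask)."""


class ReferentialIntegrityError(HistocpError):
    """A COCO annotation references a missing image or category id."""


class MappingIncompleteError(HistocpError):
    """A class-grouping mapping does not cover every original label."""

    def __init__(self, missing_labels):
        self.missing_labels = sorted(missing_labels)
        super().__init__(f"grouping has no entry for labels: {self.missing_labels}")


class EmptyDatasetError(HistocpError):
    """An operation received no usable instances (e.g. all-zero counts)."""


class EmptyInputError(HistocpError):
    """An image or array input is empty."""


class NoValidLocationError(HistocpError):
    """An instance is too large for any placement point to exist."""


class InvalidBoxError(HistocpError):
    """A bounding box has zero or negative area."""


class ZeroGroundTruthError(HistocpError):
    """A metric that needs ground-truth instances received none."""
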