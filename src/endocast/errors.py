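"""Exception types shared across the package."""


class EndocastError(Exception):
    """Base class for all package-specific errors."""


class DegenerateCloudError(EndocastError):
    """Point cloud cannot support a 3D tetrahedralization (too few points,
    or all points coplanar/collinear)."""

    def __init__(self, n_points: int, reason: str = "degenerate cloud"):
        self.n_points = n_points
        super().__init__(f"{reason}: {n_points} points do not span 3D space")


class UnderdeterminedError(EndocastError):
    """Too few or collinear markers for a rigid-body fit."""


class MeshFormatError(EndocastError):
    """Mesh file could not be parsed."""


class NotWatertightError(EndocastError):
    """Mesh has boundary edges and cannot be used for volume computation."""

    def __init__(self, boundary_edges: int, name: str = ""):
        self.boundary_edges = boundary_edges
        label = f" '{name}'" if name else ""
        super().__init__(
            f"mesh{label} is not watertight: {boundary_edges} boundary edge(s)"
        )


class ConfigError(EndocastError):
    """Invalid configuration value."""


class PhantomSpecError(EndocastError):
    """Invalid phantom specification."""
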