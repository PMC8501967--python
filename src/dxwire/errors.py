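"""Exception hierarchy.

Every stage raises a subclass of :class:`DesignError` so the CLI can report
the failing stage and exit non-zero without a traceback.
"""


class DesignError(Exception):
    """Base class for all design-time failures."""


class PlyParseError(DesignError):
    """Malformed PLY header or body."""


class MeshValidationError(DesignError):
    """Mesh violates a structural invariant (unreferenced vertex, non-manifold edge, ...)."""


class CatalogueError(DesignError):
    """Unknown fixture name."""


class BoundsError(DesignError):
    """A numeric parameter is outside its documented range."""


class RoutingError(DesignError):
    """Scaffold routing failed (disconnected graph, loop-closure violation, ...)."""


class ScaffoldLengthError(DesignError):
    """Provided scaffold sequence is shorter than the design requires."""


class AlphabetError(DesignError):
    """Sequence contains letters outside A/C/G/T."""


class StapleDesignError(DesignError):
    """An edge cannot be tiled under the staple length constraints."""


class GeometryError(DesignError):
    """Degenerate geometry (zero-length edge, coincident helices, ...)."""


class TopologyError(DesignError):
    """Base-node links are inconsistent (unexpected cycle or break in a strand)."""


class CapacityError(DesignError):
    """Index exceeds what the hybrid PDB encoding can represent."""


class PdbBoundsError(DesignError):
    """Atom coordinate outside the fixed-column PDB coordinate range."""
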