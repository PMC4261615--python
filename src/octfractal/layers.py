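"""Canonical intraretinal layer and boundary naming.

Seven cellular layers delimited by eight boundaries, ordered from the
vitreous downward.  Every module in the package indexes layers and
boundaries through these sequences so the anatomical order is defined in
exactly one place.
"""

from __future__ import annotations

#: The 7 intraretinal layers, vitreous side first.
LAYERS: tuple[str, ...] = (
    "RNFL",      # retinal nerve fiber layer
    "GCL+IPL",   # ganglion cell + inner plexiform complex
    "INL",       # inner nuclear layer
    "OPL",       # outer plexiform layer
    "ONL+IS",    # outer nuclear layer + photoreceptor inner segments
    "OS",        # photoreceptor outer segments
    "RPE",       # retinal pigment epithelium
)

#: The 8 boundaries delimiting the layers, vitreous side first.
BOUNDARIES: tuple[str, ...] = (
    "vitreous/RNFL",
    "RNFL/GCL+IPL",
    "GCL+IPL/INL",
    "INL/OPL",
    "OPL/ONL+IS",
    "ONL+IS/OS",
    "OS/RPE",
    "RPE/choroid",
)

LAYER_INDEX: dict[str, int] = {name: i for i, name in enumerate(LAYERS)}
BOUNDARY_INDEX: dict[str, int] = {name: i for i, name in enumerate(BOUNDARIES)}

#: Layers that thin toward the foveal pit (the inner retina).
INNER_LAYERS: tuple[str, ...] = ("RNFL", "GCL+IPL", "INL", "OPL")


def layer_bounds(layer: str) -> tuple[int, int]:
    """Indices of the (upper, lower) boundary delimiting ``layer``."""
    i = LAYER_INDEX[layer]
    return i, i + 1


def check_layer(layer: str) -> str:
    if layer not in LAYER_INDEX:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    return layer
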