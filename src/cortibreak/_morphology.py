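"""Shared binary-morphology primitives.

Every "step" or "voxel" of dilation/erosion in the pipeline is one
iteration with the face-connected 3D cross (the unit ball of the
city-block metric), so n steps reach exactly city-block distance n.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: 6-connected (face) structuring element — one "voxel" of morphological distance
CROSS = ndimage.generate_binary_structure(3, 1)

_CONNECTIVITY = {"face": 1, "face_edge": 2, "face_edge_vertex": 3}


def structure_for(connectivity: str) -> np.ndarray:
    try:
        return ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    except KeyError:
        raise ValueError(f"unknown connectivity {connectivity!r}") from None


def dilate(mask: np.ndarray, steps: int = 1) -> np.ndarray:
    if steps == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=CROSS, iterations=steps)


def erode(mask: np.ndarray, steps: int = 1) -> np.ndarray:
    if steps == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=CROSS, iterations=steps)


def fill_cavities(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the lattice border.

    Background connectivity is face-connectivity, consistent with the
    structuring element used everywhere else.
    """
    return ndimage.binary_fill_holes(mask, structure=CROSS)
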