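"""Cortical-mask construction and interruption detection.

A cortical interruption is a void pathway through the cortical shell
connecting the periosteal (outer) and endosteal (inner) boundary — the
imaging correlate of early bone erosion in inflammatory arthritis.  To
suppress noise, only discontinuities with an opening of at least 5 voxels
through the cortex count: a plus-shaped cross-section spanning at least 3
consecutive slices with an in-plane width of at least 3 voxels (0.246 mm
at the 82 µm first-generation voxel size).

The analysis compartment is a constant-thickness shell (the cortical
mask): the filled periosteal solid eroded by ``mask_thickness_voxels`` and
subtracted from itself.  The default thickness of 4 voxels (0.328 mm)
slightly undercuts the mean finger-joint cortical thickness of 0.39 mm
because the juxta-articular rim, where interruptions concentrate, is
thinner still.  At the 61 µm second-generation voxel size a thickness of
5 voxels gives a comparable 0.305 mm mask and a smaller 0.183 mm minimum
interruption width.

Detection proceeds on the void phase: bone inside the mask is dilated by
1 voxel (erasing openings narrower than 3 voxels), the image is inverted,
void components still connected to both the periosteal and endosteal face
are kept, and the survivors are dilated back by 1 voxel (clipped to the
mask and to non-bone) to approximately restore their original volume.
The minimal detectable interruption is therefore 20 voxels (5-voxel
opening times the 4-voxel mask depth), i.e. 0.011 mm^3 at 82 µm.

All dilations/erosions use the face-connected 3D cross, one iteration per
voxel of distance; component labeling defaults to face connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from ._morphology import dilate, erode, structure_for
from .contouring import ContourSolid
from .volume_io import BinaryVolume, LabelMap, ValidationError

__all__ = [
    "DetectionParams",
    "CorticalMask",
    "InterruptionRecord",
    "JointResult",
    "build_cortical_mask",
    "detect_interruptions",
    "summarize",
]


@dataclass
class DetectionParams:
    """Tunable constants of the interruption detector.

    mask_thickness_voxels : cortical-mask thickness (4 at 82 µm; use 5 at
        the 61 µm second-generation voxel size for a comparable 0.305 mm).
    dilation_radius_voxels : radius of the bone dilation / void restoration
        (1 voxel — defines the minimal 3-voxel opening).
    min_component_voxels : minimal intra-cortical interruption volume in
        voxels; 20 = 5-voxel opening x 4-voxel depth.
    void_connectivity : connectivity used to label void components
        ("face", "face_edge" or "face_edge_vertex").
    """

    mask_thickness_voxels: int = 4
    dilation_radius_voxels: int = 1
    min_component_voxels: int = 20
    void_connectivity: str = "face"

    def __post_init__(self) -> None:
        if self.mask_thickness_voxels < 2:
            raise ValidationError("mask_thickness_voxels must be >= 2")
        if self.min_component_voxels < 1:
            raise ValidationError("min_component_voxels must be >= 1")
        if self.dilation_radius_voxels < 0:
            raise ValidationError("dilation_radius_voxels must be >= 0")
        structure_for(self.void_connectivity)  # validates the enum


@dataclass
class CorticalMask:
    """Constant-thickness shell with its two boundary layers.

    ``shell`` = solid minus erode(solid, thickness).  ``periosteal_face``
    are shell voxels face-adjacent to background outside the solid;
    ``endosteal_face`` are shell voxels face-adjacent to the eroded
    interior.  Where the solid is thinner than the mask thickness the
    interior vanishes and the endosteal face is empty there.
    """

    shell: BinaryVolume
    periosteal_face: BinaryVolume
    endosteal_face: BinaryVolume
    thickness_voxels: int

    @property
    def thickness_mm(self) -> float:
        return self.thickness_voxels * self.shell.voxel_size_mm


@dataclass
class InterruptionRecord:
    """One detected interruption.

    ``surface_mm2`` is the interruption surface: intra-cortical volume
    divided by the physical mask thickness (an area proxy for lesion size;
    exact identity surface * thickness = volume holds by construction).
    """

    label: int
    voxel_count: int
    volume_mm3: float
    surface_mm2: float
    centroid: tuple[float, float, float]
    bbox: tuple[int, int, int, int, int, int]


@dataclass
class JointResult:
    """All interruptions of one joint plus the labeled void map."""

    records: list[InterruptionRecord]
    label_map: LabelMap
    params: DetectionParams

    @property
    def n_interruptions(self) -> int:
        return len(self.records)

    @property
    def total_surface_mm2(self) -> float:
        return float(sum(r.surface_mm2 for r in self.records))

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(r.volume_mm3 for r in self.records))


def build_cortical_mask(solid: ContourSolid, p: DetectionParams | None = None) -> CorticalMask:
    """Erode the periosteal solid and subtract, leaving the outer shell."""
    p = p or DetectionParams()
    s = solid.solid.data
    if not s.any():
        raise ValidationError("empty contour solid")
    interior = erode(s, p.mask_thickness_voxels)
    shell = s & ~interior
    outside = ~s
    periosteal = shell & dilate(outside, 1)
    endosteal = shell & dilate(interior, 1) if interior.any() else np.zeros_like(shell)
    if not interior.any():
        warnings.warn(
            "solid thinner than mask everywhere: endosteal face is empty, "
            "interruption detection is impossible",
            stacklevel=2,
        )
    vx = solid.solid.voxel_size_mm
    return CorticalMask(
        shell=BinaryVolume(data=shell, voxel_size_mm=vx),
        periosteal_face=BinaryVolume(data=periosteal, voxel_size_mm=vx),
        endosteal_face=BinaryVolume(data=endosteal, voxel_size_mm=vx),
        thickness_voxels=p.mask_thickness_voxels,
    )


def _touches(labels: np.ndarray, n: int, face: np.ndarray) -> np.ndarray:
    """Boolean per label (1..n): does the component touch ``face``?

    Touching means containing a face voxel or being face-adjacent to one.
    """
    if n == 0 or not face.any():
        return np.zeros(n, dtype=bool)
    reach = dilate(face, 1)  # includes face itself
    touched = np.unique(labels[reach & (labels > 0)])
    out = np.zeros(n, dtype=bool)
    out[touched - 1] = True
    return out


def detect_interruptions(
    bone: BinaryVolume, mask: CorticalMask, p: DetectionParams | None = None
) -> JointResult:
    """Detect void pathways through the cortical mask.

    Pipeline: intersect bone with the shell; dilate the cortical bone by
    ``dilation_radius_voxels`` (equivalently erode the void); label the
    remaining void; keep components connected to both the periosteal and
    endosteal face; dilate the survivors back, clipped to shell-and-not-
    bone; relabel, drop components below ``min_component_voxels``.
    Components merged by the restoring dilation stay merged.  Records are
    sorted by descending voxel count (ties: lexicographic centroid).
    """
    p = p or DetectionParams()
    if bone.shape != mask.shell.shape:
        raise ValidationError("bone and cortical mask are on different lattices")
    vx = bone.voxel_size_mm
    shell = mask.shell.data
    cortical_bone = bone.data & shell
    dilated_bone = dilate(cortical_bone, p.dilation_radius_voxels)
    eroded_void = shell & ~dilated_bone

    structure = structure_for(p.void_connectivity)
    labels, n = ndimage.label(eroded_void, structure=structure)
    keep = _touches(labels, n, mask.periosteal_face.data) & _touches(
        labels, n, mask.endosteal_face.data
    )
    kept_mask = keep[labels - 1] & (labels > 0) if n else np.zeros_like(eroded_void)

    restored = dilate(kept_mask, p.dilation_radius_voxels) & shell & ~bone.data
    final_labels, n_final = ndimage.label(restored, structure=structure)

    records: list[InterruptionRecord] = []
    if n_final:
        counts = ndimage.sum_labels(
            np.ones_like(final_labels), final_labels, index=np.arange(1, n_final + 1)
        ).astype(int)
        centroids = ndimage.center_of_mass(
            restored, final_labels, index=np.arange(1, n_final + 1)
        )
        slices = ndimage.find_objects(final_labels)
        survivors = [
            (int(c), tuple(float(x) for x in cen), i + 1, sl)
            for i, (c, cen, sl) in enumerate(zip(counts, centroids, slices))
            if c >= p.min_component_voxels
        ]
        survivors.sort(key=lambda t: (-t[0], t[1]))
        relabeled = np.zeros_like(final_labels)
        thickness_mm = mask.thickness_mm
        for new_label, (count, cen, old_label, sl) in enumerate(survivors, start=1):
            relabeled[final_labels == old_label] = new_label
            volume = count * vx**3
            bbox = (
                sl[0].start, sl[1].start, sl[2].start,
                sl[0].stop, sl[1].stop, sl[2].stop,
            )
            records.append(
                InterruptionRecord(
                    label=new_label,
                    voxel_count=count,
                    volume_mm3=volume,
                    surface_mm2=volume / thickness_mm,
                    centroid=cen,
                    bbox=bbox,
                )
            )
        final_labels = relabeled

    return JointResult(
        records=records,
        label_map=LabelMap(data=final_labels.astype(np.int32), voxel_size_mm=vx),
        params=p,
    )


def summarize(result: JointResult) -> pd.DataFrame:
    """Per-interruption table plus joint-level totals as a DataFrame.

    Columns: label, voxel_count, volume_mm3, surface_mm2, centroid_*.
    Joint aggregates (n, total and median surface) live in ``df.attrs``.
    """
    rows = [
        {
            "label": r.label,
            "voxel_count": r.voxel_count,
            "volume_mm3": r.volume_mm3,
            "surface_mm2": r.surface_mm2,
            "centroid_slice": r.centroid[0],
            "centroid_row": r.centroid[1],
            "centroid_col": r.centroid[2],
        }
        for r in result.records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "label", "voxel_count", "volume_mm3", "surface_mm2",
            "centroid_slice", "centroid_row", "centroid_col",
        ],
    )
    df.attrs["n_interruptions"] = result.n_interruptions
    df.attrs["total_surface_mm2"] = result.total_surface_mm2
    df.attrs["median_surface_mm2"] = (
        float(df["surface_mm2"].median()) if len(df) else 0.0
    )
    df.attrs["total_volume_mm3"] = result.total_volume_mm3
    return df
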