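"""ROI mean extraction from spatially normalized volumes with a label atlas.

Volumes are NIfTI (via nibabel) or plain arrays already resampled to a
common grid; the label volume assigns each voxel an integer region id
(0 = background). Non-finite voxels — the typical NaN padding outside the
brain in normalized PET images — are ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec

__all__ = ["extract_roi_means", "reference_mean"]


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, (str, Path)):
        import nibabel as nib

        volume = nib.load(str(volume))
    if hasattr(volume, "get_fdata"):
        volume = volume.get_fdata()
    return np.asarray(volume)


def extract_roi_means(image, labels, atlas: AtlasSpec) -> pd.DataFrame:
    """Mean image value and voxel count per atlas region.

    Parameters
    ----------
    image, labels
        NIfTI paths, nibabel images, or ndarrays on the same grid. Labels
        must be non-negative integers; label 0 is background.

    Returns
    -------
    DataFrame indexed by region id with columns ``name``, ``mean``,
    ``n_voxels``, ``is_reference``. Means ignore non-finite voxels; the
    reported voxel count is the number of finite voxels averaged.

    Raises
    ------
    ValueError
        If the grids differ in shape or a region has no (finite) voxels.
    """
    img = _as_array(image).astype(float)
    lab = _as_array(labels)
    if img.shape != lab.shape:
        raise ValueError(f"image shape {img.shape} != label shape {lab.shape}")
    if np.any(lab < 0) or not np.allclose(lab, np.round(lab)):
        raise ValueError("labels must be non-negative integers")
    lab = np.round(lab).astype(int)

    rows = []
    for region in atlas.regions:
        mask = (lab == region.id) & np.isfinite(img)
        count = int(mask.sum())
        if count == 0:
            raise ValueError(
                f"region {region.id} ({region.name}) has no finite voxels in the image"
            )
        rows.append(
            dict(
                region_id=region.id,
                name=region.name,
                mean=float(img[mask].mean()),
                n_voxels=count,
                is_reference=region.is_reference,
            )
        )
    return pd.DataFrame(rows).set_index("region_id")


def reference_mean(roi_table: pd.DataFrame, weighted: bool = True) -> float:
    """Pooled mean over the reference (cerebellar) labels.

    Voxel-count weighted by default — equivalent to the mean over the union
    of all reference voxels; unweighted averages the per-label means.
    """
    ref = roi_table[roi_table["is_reference"]]
    if ref.empty:
        raise ValueError("ROI table contains no reference regions")
    if weighted:
        return float(np.average(ref["mean"], weights=ref["n_voxels"]))
    return float(ref["mean"].mean())
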