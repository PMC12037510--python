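"""Atlas specification: analysis regions vs. reference (cerebellar) labels.

A parcellation atlas assigns every brain voxel an integer label. For the
metabolic covariance analysis we distinguish *analysis* regions (the network
nodes, e.g. the 90 cerebral regions of an AAL-style parcellation) from
*reference* labels (cerebellum) whose mean uptake normalises each subject's
SUV values into SUVRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Region", "AtlasSpec", "synthetic_atlas"]


@dataclass(frozen=True)
class Region:
    """One atlas region: integer label, name, centre-of-mass in mm."""

    id: int
    name: str
    center: tuple[float, float, float]
    is_reference: bool = False


@dataclass
class AtlasSpec:
    """Ordered collection of regions, split into analysis and reference sets.

    Parameters
    ----------
    regions
        All regions in atlas order. Analysis regions (``is_reference=False``)
        define the node order of every SUVR table and network built on this
        atlas.
    """

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region ids in atlas: {dupes}")

    @property
    def analysis_regions(self) -> list[Region]:
        return [r for r in self.regions if not r.is_reference]

    @property
    def reference_regions(self) -> list[Region]:
        return [r for r in self.regions if r.is_reference]

    @property
    def n_analysis(self) -> int:
        return len(self.analysis_regions)

    @property
    def analysis_ids(self) -> list[int]:
        return [r.id for r in self.analysis_regions]

    @property
    def analysis_names(self) -> list[str]:
        return [r.name for r in self.analysis_regions]

    def centers(self) -> np.ndarray:
        """(n_analysis, 3) array of analysis-region centres in mm."""
        return np.asarray([r.center for r in self.analysis_regions], dtype=float)

    def require_reference(self) -> None:
        if not self.reference_regions:
            raise ValueError(
                "atlas has no reference regions; SUVR normalization and ROI "
                "reference extraction need a non-empty reference set"
            )


def synthetic_atlas(n_regions: int = 90, n_reference: int = 8) -> AtlasSpec:
    """Build a synthetic atlas with ``n_regions`` analysis regions.

    The region names and coordinates are synthetic placeholders: names are
    ``region_001`` ... and centres lie on a regular 3-D grid (10 mm pitch),
    which is sufficient for network construction, file export, and toy-image
    ROI extraction. Reference labels (``cerebellum_ref_*``) follow the
    analysis labels, mimicking a cerebellar reference set.
    """
    regions: list[Region] = []
    side = int(np.ceil((n_regions + n_reference) ** (1 / 3)))
    k = 0
    for i in range(n_regions):
        center = (10.0 * (k % side), 10.0 * ((k // side) % side), 10.0 * (k // side**2))
        regions.append(Region(id=i + 1, name=f"region_{i + 1:03d}", center=center))
        k += 1
    for j in range(n_reference):
        center = (10.0 * (k % side), 10.0 * ((k // side) % side), 10.0 * (k // side**2))
        regions.append(
            Region(
                id=n_regions + j + 1,
                name=f"cerebellum_ref_{j + 1:02d}",
                center=center,
                is_reference=True,
            )
        )
        k += 1
    return AtlasSpec(regions=regions)
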