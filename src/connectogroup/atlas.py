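"""Region atlases for connectome analyses.

The default parcellation is the 90-region cortical/subcortical subset of the
AAL atlas (cerebellum excluded), the standard choice for whole-brain
structural connectomes.  Atlases of other sizes are supported so that
simulation studies can run on smaller graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# AAL (version 1) cortical and subcortical regions in atlas order,
# cerebellum excluded.  Odd AAL indices are left hemisphere (_L), even are
# right (_R); this interleaved ordering is preserved.
AAL90_NAMES: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
)


@dataclass(frozen=True)
class RegionAtlasLabels:
    """Ordered region names shared by every connectome of a cohort.

    Indexing is 0-based internally; reports print 1-based atlas positions
    alongside names.
    """

    names: tuple[str, ...] = field(default_factory=lambda: AAL90_NAMES)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("region names must be unique")
        if len(self.names) < 2:
            raise ValueError("an atlas needs at least 2 regions")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def aal90() -> RegionAtlasLabels:
    """The default 90-region AAL atlas (cerebellum excluded)."""
    labels = RegionAtlasLabels(AAL90_NAMES)
    assert len(labels) == 90
    return labels


def generic_atlas(n_regions: int) -> RegionAtlasLabels:
    """Numbered placeholder atlas for simulation studies on small graphs."""
    return RegionAtlasLabels(tuple(f"Region_{i + 1:03d}" for i in range(n_regions)))


def read_labels(path) -> RegionAtlasLabels:
    """Read a region-label file: one region name per line."""
    with open(path) as fh:
        names = tuple(line.strip() for line in fh if line.strip())
    return RegionAtlasLabels(names)


def write_labels(labels: RegionAtlasLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(labels.names) + "\n")
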