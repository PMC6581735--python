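"""Brain parcellation tables: subregions, hemispheric and merged regions, flags.

A parcellation maps each network node (an atlas subregion) to an anatomical
region. Bilateral atlases define each region once per hemisphere; for
region-level modelling the left/right homologues are merged, so the table
carries both a hemispheric and a merged region column. Flags mark special
subregions (e.g. the one containing the lateral habenula).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Parcellation",
    "brainnetome_parcellation",
    "uniform_parcellation",
]

# Bilateral region structure of the 246-subregion human Brainnetome Atlas:
# (abbreviation, subregions per hemisphere). 24 regions, 123 per hemisphere.
_BRAINNETOME_REGIONS: list[tuple[str, int]] = [
    ("SFG", 7),    # superior frontal gyrus
    ("MFG", 7),    # middle frontal gyrus
    ("IFG", 6),    # inferior frontal gyrus
    ("OrG", 6),    # orbital gyrus
    ("PrG", 6),    # precentral gyrus
    ("PCL", 2),    # paracentral lobule
    ("STG", 6),    # superior temporal gyrus
    ("MTG", 4),    # middle temporal gyrus
    ("ITG", 7),    # inferior temporal gyrus
    ("FuG", 3),    # fusiform gyrus
    ("PhG", 6),    # parahippocampal gyrus
    ("pSTS", 2),   # posterior superior temporal sulcus
    ("SPL", 5),    # superior parietal lobule
    ("IPL", 6),    # inferior parietal lobule
    ("Pcun", 4),   # precuneus
    ("PoG", 4),    # postcentral gyrus
    ("INS", 6),    # insular gyrus
    ("CG", 7),     # cingulate gyrus
    ("MVOcC", 5),  # medioventral occipital cortex
    ("LOcC", 6),   # lateral occipital cortex
    ("Amyg", 2),   # amygdala
    ("Hipp", 2),   # hippocampus
    ("BG", 6),     # basal ganglia
    ("Tha", 8),    # thalamus
]

# Thalamic subregion abbreviations in atlas order; PPtha hosts the lateral
# habenula (carried as a flag, right side per the dominant laterality).
_THALAMUS_SUBREGIONS = [
    "mPFtha", "mPMtha", "Stha", "rTtha", "PPtha", "Otha", "cTtha", "lPFtha",
]

LHB_FLAG = "contains_LHb"


@dataclass(frozen=True)
class Parcellation:
    """Node-to-region lookup for a brain network.

    Attributes
    ----------
    subregion_labels : list of str
        One label per network node, in node order.
    hemispheric_region_of : dict
        Subregion label -> hemisphere-specific region name (e.g. ``Tha_L``).
    merged_region_of : dict
        Subregion label -> bilateral (merged) region name (e.g. ``Tha``).
    hemisphere_of : dict
        Subregion label -> ``"L"`` or ``"R"``.
    flags : dict
        Subregion label -> set of marker strings.
    """

    subregion_labels: list[str]
    hemispheric_region_of: dict[str, str]
    merged_region_of: dict[str, str]
    hemisphere_of: dict[str, str]
    flags: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in self.subregion_labels if s not in self.merged_region_of]
        if missing:
            raise ValueError(f"subregions without a region assignment: {missing[:5]}")
        if len(set(self.subregion_labels)) != len(self.subregion_labels):
            raise ValueError("duplicate subregion labels")

    @property
    def n_nodes(self) -> int:
        return len(self.subregion_labels)

    @property
    def merged_regions(self) -> list[str]:
        """Merged region names in first-appearance (atlas) order."""
        seen: dict[str, None] = {}
        for s in self.subregion_labels:
            seen.setdefault(self.merged_region_of[s], None)
        return list(seen)

    @property
    def hemispheric_regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subregion_labels:
            seen.setdefault(self.hemispheric_region_of[s], None)
        return list(seen)

    def index_of(self, subregion: str) -> int:
        return self.subregion_labels.index(subregion)

    def nodes_of(self, name: str) -> list[int]:
        """Node indices of a merged region, hemispheric region, or subregion.

        Resolution order: merged region, hemispheric region, single subregion.
        Raises ``KeyError`` for unknown names.
        """
        idx = [
            i for i, s in enumerate(self.subregion_labels)
            if self.merged_region_of[s] == name
        ]
        if idx:
            return idx
        idx = [
            i for i, s in enumerate(self.subregion_labels)
            if self.hemispheric_region_of[s] == name
        ]
        if idx:
            return idx
        if name in self.merged_region_of:
            return [self.subregion_labels.index(name)]
        raise KeyError(f"unknown region or subregion name: {name!r}")

    def subregions_of(self, merged_region: str) -> list[str]:
        return [self.subregion_labels[i] for i in self.nodes_of(merged_region)]

    def flagged(self, flag: str) -> list[str]:
        return [s for s in self.subregion_labels if flag in self.flags.get(s, set())]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form; subregion_index is 1-based (atlas convention)."""
        rows = []
        for i, s in enumerate(self.subregion_labels):
            rows.append(
                {
                    "subregion_label": s,
                    "subregion_index": i + 1,
                    "hemispheric_region": self.hemispheric_region_of[s],
                    "merged_region": self.merged_region_of[s],
                    "hemisphere": self.hemisphere_of[s],
                    "flags": ";".join(sorted(self.flags.get(s, set()))),
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        required = {
            "subregion_label", "subregion_index", "hemispheric_region",
            "merged_region", "hemisphere",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        df = df.sort_values("subregion_index")
        labels = df["subregion_label"].tolist()
        flags: dict[str, set[str]] = {}
        if "flags" in df.columns:
            for s, f in zip(labels, df["flags"].fillna("")):
                if f:
                    flags[s] = set(str(f).split(";"))
        return cls(
            subregion_labels=labels,
            hemispheric_region_of=dict(zip(labels, df["hemispheric_region"])),
            merged_region_of=dict(zip(labels, df["merged_region"])),
            hemisphere_of=dict(zip(labels, df["hemisphere"])),
            flags=flags,
        )


def brainnetome_parcellation() -> Parcellation:
    """The 246-subregion bilateral parcellation (24 merged / 48 hemispheric
    regions, thalamus with 16 subregions, right PPtha flagged as containing
    the lateral habenula). Subregions are interleaved left/right within each
    region, following atlas numbering."""
    labels: list[str] = []
    hemi_of: dict[str, str] = {}
    merged_of: dict[str, str] = {}
    hemisphere: dict[str, str] = {}
    flags: dict[str, set[str]] = {}
    for region, count in _BRAINNETOME_REGIONS:
        for k in range(count):
            if region == "Tha":
                stem = _THALAMUS_SUBREGIONS[k]
            else:
                stem = f"{region}_{k + 1}"
            for side in ("L", "R"):
                label = f"{stem}_{side}"
                labels.append(label)
                hemi_of[label] = f"{region}_{side}"
                merged_of[label] = region
                hemisphere[label] = side
    flags["PPtha_R"] = {LHB_FLAG}
    return Parcellation(labels, hemi_of, merged_of, hemisphere, flags)


def uniform_parcellation(n_nodes: int, region_size: int = 4) -> Parcellation:
    """A toy parcellation for synthetic cohorts of arbitrary size: regions
    ``R1, R2, ...`` of ``region_size`` consecutive subregions (last region may
    be short), hemispheres alternating within each region."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    if region_size < 1:
        raise ValueError("region_size must be positive")
    labels = []
    hemi_of = {}
    merged_of = {}
    hemisphere = {}
    for i in range(n_nodes):
        r = i // region_size + 1
        side = "L" if i % 2 == 0 else "R"
        label = f"R{r}s{i % region_size + 1}_{side}"
        labels.append(label)
        merged_of[label] = f"R{r}"
        hemi_of[label] = f"R{r}_{side}"
        hemisphere[label] = side
    return Parcellation(labels, hemi_of, merged_of, hemisphere)
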