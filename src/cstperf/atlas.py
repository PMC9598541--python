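"""Compartment taxonomy and atlas label volumes.

The analysis unit everywhere in cstperf is the *compartment*: one
(structure, functional subdivision, hemisphere) triple, where structure is
cortex (C), striatum (S) or thalamus (T) and the subdivision is one of six
functional territories defined by cortico-subcortical connectivity
(prefrontal, rostral motor, caudal motor, parietal, occipital, temporal).
With two hemispheres this gives 3 x 6 x 2 = 36 compartments per examination.

Connectivity atlases of the striatum and thalamus ship seven source
subregions per structure; a merge rule set collapses them to the common six
subdivisions (striatal limbic + executive -> prefrontal; thalamic sensory +
posterior parietal -> parietal; thalamic premotor -> rostral motor and
primary motor -> caudal motor; identity elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, NamedTuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, LabelTableError


class Structure(str, Enum):
    """Cerebral structure; ordering cortex -> striatum -> thalamus is the
    donut-ring order (outer to inner)."""

    CORTEX = "cortex"
    STRIATUM = "striatum"
    THALAMUS = "thalamus"


class Subdivision(str, Enum):
    """The six functional subdivisions; ordering drives donut sector layout
    (clockwise from the top)."""

    PREFRONTAL = "prefrontal"
    ROSTRAL_MOTOR = "rostral_motor"
    CAUDAL_MOTOR = "caudal_motor"
    PARIETAL = "parietal"
    OCCIPITAL = "occipital"
    TEMPORAL = "temporal"


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class CompartmentKey(NamedTuple):
    structure: Structure
    subdivision: Subdivision
    hemisphere: Hemisphere

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.structure.value}/{self.subdivision.value}/{self.hemisphere.value}"


#: All 36 compartment keys in canonical order (structure, subdivision, hemisphere).
COMPARTMENT_KEYS: tuple[CompartmentKey, ...] = tuple(
    CompartmentKey(st, sd, h)
    for st in Structure
    for sd in Subdivision
    for h in Hemisphere
)


class RegionLabel(NamedTuple):
    """Meaning of one integer label id in an atlas volume.

    ``subregion`` is the source subregion name before merging (after merging
    it equals a :class:`Subdivision` value). ``hemisphere`` may be ``None``
    for atlases that do not split hemispheres; see
    :func:`assign_hemispheres_by_midline`.
    """

    structure: Structure
    subregion: str
    hemisphere: Hemisphere | None


#: Source subregion names of the seven-part connectivity atlases.
STRIATAL_SUBREGIONS = (
    "limbic", "executive", "rostral_motor", "caudal_motor",
    "parietal", "occipital", "temporal",
)
THALAMIC_SUBREGIONS = (
    "prefrontal", "premotor", "primary_motor", "sensory",
    "posterior_parietal", "occipital", "temporal",
)
CORTICAL_SUBREGIONS = tuple(s.value for s in Subdivision)


@dataclass
class AtlasLabelVolume:
    """An integer label image plus the table giving each label's meaning.

    Label 0 is background. All nonzero labels present in ``data`` must
    appear in ``labels``.
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, RegionLabel]
    space: str = "fixture"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError("label volume must be integer-valued")
        if self.data.ndim != 3:
            raise FormatError("label volume must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        present = set(np.unique(self.data).tolist()) - {0}
        unknown = present - set(self.labels)
        if unknown:
            raise LabelTableError(
                f"labels present in volume but missing from table: {sorted(unknown)}"
            )
        if 0 in self.labels:
            raise LabelTableError("label 0 is reserved for background")

    # -- basic geometry/queries -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def mask(self, label_id: int) -> np.ndarray:
        return self.data == label_id

    def voxel_counts(self) -> dict[int, int]:
        counts = np.bincount(self.data.ravel())
        return {i: int(counts[i]) for i in self.labels if i < len(counts)}

    def structures(self) -> set[Structure]:
        return {lbl.structure for lbl in self.labels.values()}

    # -- merged-atlas conveniences ---------------------------------------------

    def compartment_labels(self) -> dict[CompartmentKey, int]:
        """Map compartment keys to label ids (merged atlases only)."""
        out: dict[CompartmentKey, int] = {}
        for lid, lbl in self.labels.items():
            try:
                key = CompartmentKey(
                    Structure(lbl.structure), Subdivision(lbl.subregion),
                    Hemisphere(lbl.hemisphere),
                )
            except ValueError as exc:
                raise ConfigurationError(
                    f"label {lid} ({lbl}) is not a merged compartment label"
                ) from exc
            if key in out:
                raise ConfigurationError(f"duplicate compartment label for {key}")
            out[key] = lid
        return out

    # -- I/O ---------------------------------------------------------------------

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        nib.save(img, str(path))

    def write_label_table(self, path) -> None:
        rows = [
            {
                "label_id": lid,
                "structure": lbl.structure.value,
                "subregion": lbl.subregion,
                "hemisphere": lbl.hemisphere.value if lbl.hemisphere else "",
            }
            for lid, lbl in sorted(self.labels.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_label_table(path) -> dict[int, RegionLabel]:
    frame = pd.read_csv(path, sep="\t", dtype={"label_id": int})
    required = {"label_id", "structure", "subregion", "hemisphere"}
    if not required.issubset(frame.columns):
        raise LabelTableError(f"label table needs columns {sorted(required)}")
    table: dict[int, RegionLabel] = {}
    for row in frame.itertuples(index=False):
        hemi = getattr(row, "hemisphere")
        hemi = None if (pd.isna(hemi) or hemi == "") else Hemisphere(hemi)
        table[int(row.label_id)] = RegionLabel(Structure(row.structure), str(row.subregion), hemi)
    return table


def load_atlas(
    path,
    label_table,
    *,
    prob_threshold: float = 0.25,
    space: str = "unspecified",
) -> AtlasLabelVolume:
    """Load an atlas volume (NIfTI) with its label table (TSV path or mapping).

    A 3-D integer volume is used as-is. A 4-D volume is treated as a
    probabilistic atlas: each voxel gets the label (= 4th-axis index + 1) of
    its maximum probability, or background if that maximum is below
    ``prob_threshold``. Ties go to the lowest label id.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if isinstance(label_table, Mapping):
        table = dict(label_table)
    else:
        table = read_label_table(label_table)

    if data.ndim == 4:
        data = max_probability_labels(data, prob_threshold)
    elif data.ndim == 3:
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=0, rtol=0):
                raise FormatError(
                    f"{path}: 3-D atlas volume is not integer-valued; pass a 4-D "
                    "stack for probabilistic atlases"
                )
            data = rounded.astype(np.int32)
    else:
        raise FormatError(f"{path}: expected a 3-D or 4-D volume, got {data.ndim}-D")
    return AtlasLabelVolume(data.astype(np.int32), img.affine, table, space=space)


def max_probability_labels(stack: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Reduce a 4-D probabilistic stack to a max-probability label image.

    Label ids are the 4th-axis index + 1; voxels whose maximum probability is
    below ``threshold`` become background. ``np.argmax`` returns the first
    (lowest-id) maximum, which is the documented tie-break.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise FormatError("probabilistic atlas must be 4-D")
    winners = np.argmax(stack, axis=3).astype(np.int32) + 1
    peak = np.max(stack, axis=3)
    winners[peak < threshold] = 0
    return winners


def assign_hemispheres_by_midline(atlas: AtlasLabelVolume) -> AtlasLabelVolume:
    """Split labels without a hemisphere tag by the sign of world x (RAS+).

    Voxels exactly on the x = 0 plane become background. Labels that already
    carry a hemisphere are kept unchanged; split labels get fresh ids.
    """
    needs_split = [lid for lid, lbl in atlas.labels.items() if lbl.hemisphere is None]
    if not needs_split:
        return atlas
    data = atlas.data.copy()
    labels = {lid: lbl for lid, lbl in atlas.labels.items() if lbl.hemisphere is not None}
    next_id = max(atlas.labels) + 1
    ii, jj, kk = np.indices(atlas.shape)
    world_x = (
        atlas.affine[0, 0] * ii + atlas.affine[0, 1] * jj
        + atlas.affine[0, 2] * kk + atlas.affine[0, 3]
    )
    for lid in needs_split:
        lbl = atlas.labels[lid]
        mask = atlas.data == lid
        for hemi, side in ((Hemisphere.LEFT, world_x < 0), (Hemisphere.RIGHT, world_x > 0)):
            sel = mask & side
            if sel.any():
                data[sel] = next_id
                labels[next_id] = RegionLabel(lbl.structure, lbl.subregion, hemi)
                next_id += 1
        data[mask & (world_x == 0)] = 0
    return AtlasLabelVolume(data, atlas.affine, labels, space=atlas.space)


# ---------------------------------------------------------------------------
# merge rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeRuleSet:
    """Total mapping (structure, source subregion) -> Subdivision."""

    rules: Mapping[tuple[Structure, str], Subdivision] = field(default_factory=dict)

    def target(self, structure: Structure, subregion: str) -> Subdivision:
        try:
            return self.rules[(structure, subregion)]
        except KeyError:
            raise ConfigurationError(
                f"no merge rule for subregion {subregion!r} of {structure.value}"
            ) from None

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping[str, str]]) -> "MergeRuleSet":
        rules = {
            (Structure(st), src): Subdivision(dst)
            for st, pairs in mapping.items()
            for src, dst in pairs.items()
        }
        return cls(rules)

    def to_mapping(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for (st, src), dst in self.rules.items():
            out.setdefault(st.value, {})[src] = dst.value
        return out

    @classmethod
    def from_yaml(cls, path) -> "MergeRuleSet":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh)


def default_merge_rules() -> MergeRuleSet:
    """Merge rules collapsing the 7-part connectivity atlases to 6 subdivisions.

    Striatum: limbic + executive -> prefrontal, identity elsewhere.
    Thalamus: premotor -> rostral motor, primary motor -> caudal motor,
    sensory + posterior parietal -> parietal, identity elsewhere.
    Cortex: identity over the six subdivisions.
    """
    rules: dict[tuple[Structure, str], Subdivision] = {}
    striatal = {
        "limbic": Subdivision.PREFRONTAL,
        "executive": Subdivision.PREFRONTAL,
        "rostral_motor": Subdivision.ROSTRAL_MOTOR,
        "caudal_motor": Subdivision.CAUDAL_MOTOR,
        "parietal": Subdivision.PARIETAL,
        "occipital": Subdivision.OCCIPITAL,
        "temporal": Subdivision.TEMPORAL,
    }
    thalamic = {
        "prefrontal": Subdivision.PREFRONTAL,
        "premotor": Subdivision.ROSTRAL_MOTOR,
        "primary_motor": Subdivision.CAUDAL_MOTOR,
        "sensory": Subdivision.PARIETAL,
        "posterior_parietal": Subdivision.PARIETAL,
        "occipital": Subdivision.OCCIPITAL,
        "temporal": Subdivision.TEMPORAL,
    }
    for src, dst in striatal.items():
        rules[(Structure.STRIATUM, src)] = dst
    for src, dst in thalamic.items():
        rules[(Structure.THALAMUS, src)] = dst
    for name in CORTICAL_SUBREGIONS:
        rules[(Structure.CORTEX, name)] = Subdivision(name)
    return MergeRuleSet(rules)


#: Default grouping of AAL cortical region (base) names into the six
#: subdivisions, for use with real AAL parcellations. This grouping is a
#: documented package choice; the canonical AAL names carry an _L/_R suffix
#: which encodes the hemisphere. Purely subcortical AAL regions (hippocampus,
#: amygdala, basal ganglia, thalamus) and the insula are deliberately absent:
#: they are not part of the cortical ribbon analyzed here.
DEFAULT_AAL_CORTICAL_GROUPING: dict[str, Subdivision] = {
    **{name: Subdivision.PREFRONTAL for name in (
        "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid", "Frontal_Mid_Orb",
        "Frontal_Inf_Oper", "Frontal_Inf_Tri", "Frontal_Inf_Orb",
        "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Olfactory",
        "Cingulum_Ant",
    )},
    **{name: Subdivision.ROSTRAL_MOTOR for name in (
        "Supp_Motor_Area", "Cingulum_Mid",
    )},
    **{name: Subdivision.CAUDAL_MOTOR for name in (
        "Precentral", "Rolandic_Oper", "Paracentral_Lobule",
    )},
    **{name: Subdivision.PARIETAL for name in (
        "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
        "Angular", "Precuneus", "Cingulum_Post",
    )},
    **{name: Subdivision.OCCIPITAL for name in (
        "Calcarine", "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid",
        "Occipital_Inf", "Fusiform",
    )},
    **{name: Subdivision.TEMPORAL for name in (
        "Temporal_Sup", "Temporal_Pole_Sup", "Temporal_Mid",
        "Temporal_Pole_Mid", "Temporal_Inf", "Heschl", "ParaHippocampal",
    )},
}


def apply_merge_rules(atlas: AtlasLabelVolume, rules: MergeRuleSet) -> AtlasLabelVolume:
    """Relabel an atlas so each label is one (structure, subdivision, hemisphere).

    Voxel membership is conserved: no voxel gains or loses foreground status.
    Each structure present in the atlas must end up with all six subdivisions.
    """
    key_to_new: dict[CompartmentKey, int] = {
        key: i + 1 for i, key in enumerate(COMPARTMENT_KEYS)
    }
    max_old = max(atlas.labels) if atlas.labels else 0
    lut = np.zeros(max_old + 1, dtype=np.int32)
    new_labels: dict[int, RegionLabel] = {}
    for lid, lbl in atlas.labels.items():
        if lbl.hemisphere is None:
            raise ConfigurationError(
                f"label {lid} has no hemisphere; run assign_hemispheres_by_midline first"
            )
        subdivision = rules.target(lbl.structure, lbl.subregion)
        key = CompartmentKey(lbl.structure, subdivision, lbl.hemisphere)
        nid = key_to_new[key]
        lut[lid] = nid
        new_labels[nid] = RegionLabel(lbl.structure, subdivision.value, lbl.hemisphere)
    data = lut[atlas.data]
    merged = AtlasLabelVolume(data, atlas.affine, new_labels, space=atlas.space)
    for st in merged.structures():
        n_sub = {
            lbl.subregion for lbl in merged.labels.values() if lbl.structure == st
        }
        if len(n_sub) != len(Subdivision):
            raise ConfigurationError(
                f"{st.value}: merged atlas has {len(n_sub)} subdivisions, expected 6"
            )
    return merged


def enumerate_compartments(n_examinations: int) -> list[tuple[int, CompartmentKey]]:
    """All (examination index, compartment key) pairs in canonical order.

    With 3 structures x 6 subdivisions x 2 hemispheres there are 36
    compartments per examination, e.g. 144 for 4 examinations, 504 for 14
    and 288 for 8.
    """
    if not isinstance(n_examinations, (int, np.integer)) or n_examinations < 1:
        raise ValueError("n_examinations must be a positive integer")
    return [(exam, key) for exam in range(int(n_examinations)) for key in COMPARTMENT_KEYS]
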