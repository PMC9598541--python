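"""Per-compartment CBF extraction from normalized ASL volumes.

Two measures are computed per compartment:

* **A-CBF** — the arithmetic mean of the quantified CBF values
  (ml/100 g/min) over the compartment's voxels.
* **R-CBF** — the same mean divided by the whole-brain-cortex mean, i.e. the
  voxel-weighted mean over the union of all twelve cortical compartments.
  R-CBF is dimensionless and removes global perfusion differences (age,
  sedation, labeling efficiency), exposing the *relative* regional pattern.

Volumes are consumed already quantified, co-registered and spatially
normalized; no smoothing or partial-volume correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import COMPARTMENT_KEYS, AtlasLabelVolume, CompartmentKey, Structure
from .errors import EmptyRoiError, GeometryError, PairingError

AFFINE_ATOL = 1e-4


@dataclass
class ExamMetadata:
    subject_id: str
    exam_id: str
    age_months: float
    scanner: str
    sedation: bool
    state: str = "control"  # ictal | interictal | control
    group: str | None = None
    artifact: bool = False  # set upstream by visual QC; artifacted images are discarded

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "exam_id": self.exam_id,
            "age_months": self.age_months,
            "scanner": self.scanner,
            "sedation": self.sedation,
            "state": self.state,
            "group": self.group,
            "artifact": self.artifact,
        }


@dataclass
class CbfVolume:
    """A quantified CBF image (ml/100 g/min) with examination metadata."""

    data: np.ndarray
    affine: np.ndarray
    meta: ExamMetadata

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CBF volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def n_nonpositive(self) -> int:
        """Count of voxels with CBF <= 0 (ASL noise floor); flagged, not removed."""
        return int(np.count_nonzero(self.data <= 0))

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


def load_cbf_volume(path, meta: ExamMetadata) -> CbfVolume:
    img = nib.load(str(path))
    return CbfVolume(np.asanyarray(img.dataobj, dtype=float), img.affine, meta)


def _check_aligned(cbf: CbfVolume, atlas: AtlasLabelVolume) -> None:
    if cbf.shape != atlas.shape:
        raise GeometryError(f"grid mismatch: CBF {cbf.shape} vs atlas {atlas.shape}")
    if not np.allclose(cbf.affine, atlas.affine, atol=AFFINE_ATOL, rtol=0):
        raise GeometryError("affine mismatch between CBF volume and atlas")


def roi_mean(
    cbf: CbfVolume, atlas: AtlasLabelVolume, key: CompartmentKey
) -> tuple[float, int]:
    """Mean CBF over the voxels of one compartment, with the voxel count."""
    _check_aligned(cbf, atlas)
    label_id = atlas.compartment_labels().get(key)
    mask = atlas.data == label_id if label_id is not None else np.zeros(atlas.shape, bool)
    count = int(np.count_nonzero(mask))
    if count == 0:
        raise EmptyRoiError(f"compartment {key} has no voxels")
    return float(cbf.data[mask].mean()), count


def whole_cortex_mean(cbf: CbfVolume, atlas: AtlasLabelVolume) -> float:
    """Voxel-weighted mean CBF over all cortical compartments, both hemispheres."""
    _check_aligned(cbf, atlas)
    cortical_ids = [
        lid for lid, lbl in atlas.labels.items() if lbl.structure == Structure.CORTEX
    ]
    mask = np.isin(atlas.data, cortical_ids)
    if not mask.any():
        raise EmptyRoiError("atlas contains no cortical voxels")
    return float(cbf.data[mask].mean())


@dataclass
class CbfTable:
    """Per-compartment A-CBF / R-CBF values for one examination.

    ``frame`` has one row per compartment (canonical order) with columns
    structure, subdivision, hemisphere, voxel_count, a_cbf, r_cbf.
    Invariant: ``r_cbf * whole_cortex_mean == a_cbf`` row-wise.
    """

    frame: pd.DataFrame
    whole_cortex_mean: float
    meta: ExamMetadata

    def value(self, key: CompartmentKey, measure: str) -> float:
        row = self.frame[
            (self.frame.structure == key.structure.value)
            & (self.frame.subdivision == key.subdivision.value)
            & (self.frame.hemisphere == key.hemisphere.value)
        ]
        return float(row[measure].iloc[0])

    def to_long(self) -> pd.DataFrame:
        """Frame with exam metadata columns prepended (for cohort assembly)."""
        out = self.frame.copy()
        for col, val in reversed(list(self.meta.to_dict().items())):
            out.insert(0, col, val)
        out["whole_cortex_mean"] = self.whole_cortex_mean
        return out

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "CbfTable":
        frame = pd.read_csv(path, sep="\t")
        meta = ExamMetadata(
            subject_id=str(frame.subject_id.iloc[0]),
            exam_id=str(frame.exam_id.iloc[0]),
            age_months=float(frame.age_months.iloc[0]),
            scanner=str(frame.scanner.iloc[0]),
            sedation=bool(frame.sedation.iloc[0]),
            state=str(frame.state.iloc[0]),
            group=None if pd.isna(frame.group.iloc[0]) else str(frame.group.iloc[0]),
        )
        wcm = float(frame.whole_cortex_mean.iloc[0])
        cols = ["structure", "subdivision", "hemisphere", "voxel_count", "a_cbf", "r_cbf"]
        return cls(frame[cols].reset_index(drop=True), wcm, meta)


def build_cbf_table(
    cbf: CbfVolume,
    atlas: AtlasLabelVolume,
    *,
    exclude_nonpositive: bool = False,
) -> CbfTable:
    """Extract the full 36-compartment A-CBF / R-CBF table in one pass.

    ``exclude_nonpositive`` drops voxels with CBF <= 0 from every mean
    (off by default: the pipeline mirrors image-level QC only).
    """
    _check_aligned(cbf, atlas)
    key_to_label = atlas.compartment_labels()

    labels_flat = atlas.data.ravel()
    values_flat = cbf.data.ravel()
    if exclude_nonpositive:
        keep = values_flat > 0
        labels_flat = labels_flat[keep]
        values_flat = values_flat[keep]
    minlength = max(atlas.labels, default=0) + 1
    counts = np.bincount(labels_flat, minlength=minlength)
    sums = np.bincount(labels_flat, weights=values_flat, minlength=minlength)

    empty = [str(key) for key in COMPARTMENT_KEYS
             if counts[key_to_label.get(key, 0)] == 0 or key not in key_to_label]
    if empty:
        raise EmptyRoiError("empty compartments: " + ", ".join(empty))

    cortical_ids = [key_to_label[k] for k in COMPARTMENT_KEYS
                    if k.structure == Structure.CORTEX]
    wcm = float(sums[cortical_ids].sum() / counts[cortical_ids].sum())
    if wcm <= 0:
        raise EmptyRoiError("whole-cortex mean is non-positive")

    rows = []
    for key in COMPARTMENT_KEYS:
        lid = key_to_label[key]
        mean = sums[lid] / counts[lid]
        rows.append(
            {
                "structure": key.structure.value,
                "subdivision": key.subdivision.value,
                "hemisphere": key.hemisphere.value,
                "voxel_count": int(counts[lid]),
                "a_cbf": float(mean),
                "r_cbf": float(mean / wcm),
            }
        )
    return CbfTable(pd.DataFrame(rows), wcm, cbf.meta)


def subtraction_map(ictal: CbfVolume, interictal: CbfVolume) -> CbfVolume:
    """Voxelwise ictal - inter-ictal difference for one subject.

    Highlights the perfusion change attributable to the ictal state itself,
    independent of the subject's baseline perfusion pattern.
    """
    if ictal.meta.subject_id != interictal.meta.subject_id:
        raise PairingError(
            f"subjects differ: {ictal.meta.subject_id!r} vs {interictal.meta.subject_id!r}"
        )
    if ictal.shape != interictal.shape or not np.allclose(
        ictal.affine, interictal.affine, atol=AFFINE_ATOL, rtol=0
    ):
        raise PairingError("ictal and inter-ictal volumes are not on the same grid")
    meta = replace(
        ictal.meta,
        exam_id=f"{ictal.meta.exam_id}-minus-{interictal.meta.exam_id}",
        state="subtraction",
    )
    return CbfVolume(ictal.data - interictal.data, ictal.affine.copy(), meta)


def read_metadata_table(path) -> pd.DataFrame:
    """Examination metadata TSV: subject_id, exam_id, age_months, scanner,
    sedation, state, group."""
    frame = pd.read_csv(path, sep="\t")
    frame["sedation"] = frame["sedation"].astype(bool)
    return frame
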