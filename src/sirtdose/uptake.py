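"""Count-based uptake estimation: partitions, lung shunt, T/N, 11-mm margin.

A :class:`PartitionTable` books one row per dosimetric partition: the lung,
each normal-liver territory, each (26-connected) tumor, and optionally the
margin shell excluded around tumors.  Counts from the MAA-SPECT-like image
serve as relative activity weights; masses come from voxel volumes times a
tissue density.

The margin rule excludes all normal-liver voxels within the maximum Y-90
tissue emission range (default 11 mm) of any tumor voxel: counts there are
dominated by spill-out from the tumor and would otherwise inflate the
normal-liver dose estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridMismatchError, InvalidInputError, UndefinedRatioError

__all__ = [
    "MarginPolicy",
    "PartitionTable",
    "tumor_margin",
    "partition_counts",
    "partition_masses",
    "lung_shunt_fraction",
    "tn_ratio",
    "ROLE_LUNG",
    "ROLE_NL",
    "ROLE_TUMOR",
    "ROLE_MARGIN",
]

ROLE_LUNG = "lung"
ROLE_NL = "normal_liver_territory"
ROLE_TUMOR = "tumor"
ROLE_MARGIN = "excluded_margin"

LIVER_SIDE_ROLES = (ROLE_NL, ROLE_TUMOR, ROLE_MARGIN)

DEFAULT_TISSUE_DENSITY = 1.05  # kg/L, soft tissue
DEFAULT_LUNG_DENSITY = 0.30  # kg/L, inflated lung parenchyma

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class MarginPolicy:
    """How to treat the tumor-margin shell.

    ``excluded_partition`` (default) books margin counts in a separate row
    that stays liver-side for activity bookkeeping but enters no reported
    normal-liver or tumor dose and no planning constraint;
    ``merge_into_tumor`` adds each margin voxel to its nearest tumor;
    ``drop`` removes margin voxels from the analysis entirely.
    """

    margin_mm: float = 11.0
    disposition: str = "excluded_partition"

    def __post_init__(self):
        if self.margin_mm < 0:
            raise InvalidInputError("margin_mm must be >= 0")
        if self.disposition not in ("excluded_partition", "merge_into_tumor", "drop"):
            raise InvalidInputError(f"unknown margin disposition {self.disposition!r}")


class PartitionTable:
    """Per-partition bookkeeping: volumes, masses, counts, and (later) doses.

    Wraps a pandas DataFrame with columns ``partition, role, region_id,
    voxels, volume_mL, mass_kg, counts`` plus ``activity_GBq, f, dose_Gy``
    filled by the dosimetry layer, and an optional integer region-label
    volume aligned with ``region_id`` for dose-map rendering.
    """

    COLUMNS = [
        "partition",
        "role",
        "region_id",
        "voxels",
        "volume_mL",
        "mass_kg",
        "counts",
        "activity_GBq",
        "f",
        "dose_Gy",
    ]

    def __init__(self, df: pd.DataFrame, region_labels: np.ndarray | None = None,
                 spacing: tuple[float, float, float] | None = None,
                 dropped_counts: float = 0.0):
        for col in ("activity_GBq", "f", "dose_Gy"):
            if col not in df.columns:
                df = df.assign(**{col: np.nan})
        self.df = df.reset_index(drop=True)[self.COLUMNS]
        self.region_labels = region_labels
        self.spacing = spacing
        self.dropped_counts = float(dropped_counts)
        self._validate()

    def _validate(self):
        roles = self.df["role"]
        if (roles == ROLE_LUNG).sum() > 1:
            raise InvalidInputError("at most one lung row allowed")
        if (self.df["counts"] < 0).any():
            raise InvalidInputError("negative counts in partition table")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "PartitionTable":
        """Build a table from plain dicts (no label volume), for direct math."""
        df = pd.DataFrame(rows)
        for col in ("region_id", "voxels", "volume_mL"):
            if col not in df.columns:
                df[col] = 0
        if "mass_kg" not in df.columns:
            df["mass_kg"] = np.nan
        return cls(df)

    # -- row accessors ------------------------------------------------------

    def rows(self, role: str) -> pd.DataFrame:
        return self.df[self.df["role"] == role]

    @property
    def lung(self) -> pd.Series | None:
        r = self.rows(ROLE_LUNG)
        return None if r.empty else r.iloc[0]

    def liver_side(self) -> pd.DataFrame:
        """Rows inside the liver-side activity total (NL + tumors + margin)."""
        return self.df[self.df["role"].isin(LIVER_SIDE_ROLES)]

    def copy(self) -> "PartitionTable":
        return PartitionTable(
            self.df.copy(), self.region_labels, self.spacing, self.dropped_counts
        )

    # -- serialization ------------------------------------------------------

    def to_csv(self, path=None):
        if path is None:
            buf = StringIO()
            self.df.to_csv(buf, index=False)
            return buf.getvalue()
        self.df.to_csv(path, index=False)

    def to_json(self) -> str:
        return self.df.to_json(orient="records", indent=2)

    def __repr__(self):
        return f"PartitionTable({len(self.df)} rows)\n{self.df}"


def partition_masses(voxels, spacing, density_kg_per_L: float) -> np.ndarray:
    """Mass in kg from voxel counts: n * voxel volume * density."""
    if density_kg_per_L <= 0:
        raise InvalidInputError("density must be > 0")
    voxel_mL = float(np.prod(spacing)) / 1000.0
    return np.asarray(voxels, dtype=float) * voxel_mL / 1000.0 * density_kg_per_L


def tumor_margin(
    tumor_union: np.ndarray,
    liver_mask: np.ndarray,
    margin_mm: float,
    spacing,
) -> np.ndarray:
    """Voxels within ``margin_mm`` (world mm) of any tumor voxel, inside the
    liver and outside the tumors."""
    if margin_mm < 0:
        raise InvalidInputError("margin_mm must be >= 0")
    tumor = np.asarray(tumor_union, dtype=bool)
    liver = np.asarray(liver_mask, dtype=bool)
    if margin_mm == 0 or not tumor.any():
        return np.zeros(tumor.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~tumor, sampling=spacing)
    return (dist <= margin_mm) & liver & ~tumor


def partition_counts(
    count_image: np.ndarray,
    territory_labels: np.ndarray,
    tumor_masks,
    lung_mask: np.ndarray | None,
    margin_policy: MarginPolicy = MarginPolicy(),
    spacing=(1.0, 1.0, 1.0),
    liver_mask: np.ndarray | None = None,
    density_kg_per_L: float = DEFAULT_TISSUE_DENSITY,
    lung_density_kg_per_L: float = DEFAULT_LUNG_DENSITY,
    territory_names: dict[int, str] | None = None,
) -> PartitionTable:
    """Sum counts per partition into a :class:`PartitionTable`.

    ``territory_labels`` is an integer volume (0 background, k >= 1 normal
    liver territory k); tumor voxels are split into 26-connected components,
    one partition each; the margin shell around tumors is carved out of the
    territories and booked according to ``margin_policy``.  ``liver_mask``
    defaults to territories + tumors.
    """
    counts = np.asarray(count_image, dtype=float)
    labels = np.asarray(territory_labels)
    if counts.shape != labels.shape:
        raise GridMismatchError(counts.shape, labels.shape, what="counts/territories")

    tumor_union = np.zeros(counts.shape, dtype=bool)
    for t in tumor_masks:
        t = np.asarray(getattr(t, "data", t), dtype=bool)
        if t.shape != counts.shape:
            raise GridMismatchError(counts.shape, t.shape, what="counts/tumor mask")
        tumor_union |= t
    if lung_mask is not None:
        lung = np.asarray(getattr(lung_mask, "data", lung_mask), dtype=bool)
        if lung.shape != counts.shape:
            raise GridMismatchError(counts.shape, lung.shape, what="counts/lung mask")
    else:
        lung = np.zeros(counts.shape, dtype=bool)

    if liver_mask is None:
        liver = (labels > 0) | tumor_union
    else:
        liver = np.asarray(getattr(liver_mask, "data", liver_mask), dtype=bool)
        if liver.shape != counts.shape:
            raise GridMismatchError(counts.shape, liver.shape, what="counts/liver mask")

    margin = tumor_margin(tumor_union, liver, margin_policy.margin_mm, spacing)
    nl_region = (labels > 0) & ~tumor_union & ~margin
    if not nl_region.any():
        raise InvalidInputError(
            "the tumor margin consumes the entire normal liver; no NL partition left"
        )

    tumor_cc, n_tumors = ndimage.label(tumor_union, structure=_STRUCT26)

    voxel_mL = float(np.prod(spacing)) / 1000.0
    regions = np.zeros(counts.shape, dtype=np.int32)
    rows = []
    rid = 0

    def add_row(name, role, mask, density):
        nonlocal rid
        rid += 1
        regions[mask] = rid
        nvox = int(mask.sum())
        rows.append(
            {
                "partition": name,
                "role": role,
                "region_id": rid,
                "voxels": nvox,
                "volume_mL": nvox * voxel_mL,
                "mass_kg": float(partition_masses(nvox, spacing, density)),
                "counts": float(counts[mask].sum()),
            }
        )

    if lung_mask is not None:
        add_row("lung", ROLE_LUNG, lung, lung_density_kg_per_L)

    for k in sorted(np.unique(labels[nl_region])):
        name = (territory_names or {}).get(int(k), f"territory_{int(k):02d}")
        add_row(name, ROLE_NL, nl_region & (labels == k), density_kg_per_L)

    tumor_row_idx = {}
    for t in range(1, n_tumors + 1):
        tumor_row_idx[t] = len(rows)
        add_row(f"tumor_{t:02d}", ROLE_TUMOR, tumor_cc == t, density_kg_per_L)

    dropped = 0.0
    if margin.any():
        if margin_policy.disposition == "excluded_partition":
            add_row("margin", ROLE_MARGIN, margin, density_kg_per_L)
        elif margin_policy.disposition == "merge_into_tumor":
            # each margin voxel joins its nearest tumor component
            _, (ix, iy, iz) = ndimage.distance_transform_edt(
                ~tumor_union, sampling=spacing, return_indices=True
            )
            owner = tumor_cc[ix, iy, iz]
            for t in range(1, n_tumors + 1):
                sub = margin & (owner == t)
                if not sub.any():
                    continue
                row = rows[tumor_row_idx[t]]
                regions[sub] = row["region_id"]
                nvox = int(sub.sum())
                row["voxels"] += nvox
                row["volume_mL"] += nvox * voxel_mL
                row["mass_kg"] += float(
                    partition_masses(nvox, spacing, density_kg_per_L)
                )
                row["counts"] += float(counts[sub].sum())
        else:  # drop
            dropped = float(counts[margin].sum())

    return PartitionTable(
        pd.DataFrame(rows),
        region_labels=regions,
        spacing=tuple(float(s) for s in spacing),
        dropped_counts=dropped,
    )


def lung_shunt_fraction(table: PartitionTable) -> float:
    """Lung shunt fraction L = c_L / (c_L + c_NL + c_T).

    The denominator sums lung plus all liver-side counts (normal-liver
    territories, tumors, and the margin partition when it is kept
    liver-side).
    """
    lung = table.lung
    c_lung = 0.0 if lung is None else float(lung["counts"])
    c_liver = float(table.liver_side()["counts"].sum())
    total = c_lung + c_liver
    if total <= 0:
        raise InvalidInputError("zero total counts; lung shunt undefined")
    return c_lung / total


def tn_ratio(table: PartitionTable) -> float:
    """Tumor-to-normal uptake ratio T/N = (c_T/m_T) / (c_NL/m_NL).

    Aggregated over all tumor rows and all normal-liver territory rows;
    margin counts belong to neither side.
    """
    nl = table.rows(ROLE_NL)
    tum = table.rows(ROLE_TUMOR)
    if tum.empty:
        raise UndefinedRatioError("no tumor partitions")
    m_t = float(tum["mass_kg"].sum())
    m_nl = float(nl["mass_kg"].sum())
    c_nl = float(nl["counts"].sum())
    if m_t <= 0:
        raise UndefinedRatioError("tumor mass is zero")
    if m_nl <= 0:
        raise UndefinedRatioError("normal liver mass is zero")
    if c_nl <= 0:
        raise UndefinedRatioError("normal liver counts are zero; T/N undefined")
    c_t = float(tum["counts"].sum())
    return (c_t / m_t) / (c_nl / m_nl)
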