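"""Core data containers for region-level c-Fos activity and behavioral trials.

The central object is a regions x subjects table of c-Fos+ cell counts
(one value per region per animal: the per-subject mean over bilateral
sampling windows across sections) together with a design table that
assigns each subject a genotype (WT / KO) and an exposure condition
(HC / object / conspecific).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KO")
CONDITIONS = ("HC", "object", "conspecific")

#: The 21 brain regions pre-selected for c-Fos quantification, in the
#: anterior-to-posterior order used throughout (matrix rows/columns keep
#: this order; no re-sorting anywhere downstream).
DEFAULT_REGIONS = (
    "MO", "PrL", "IL", "AcbSh", "AcbC", "LSI", "LSD", "Pir", "MS", "MPOM",
    "PV", "PT", "RE", "BLA", "CA1", "CA2", "CA3", "DG", "LH", "PMCo", "PAG",
)

#: Minimum subjects per (genotype, condition) cell for a Pearson p-value
#: (t-based p needs df = n - 2 >= 2).
MIN_GROUP_SIZE = 4


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class RegionActivityTable:
    """c-Fos+ cell counts per sampling window: one row per region, one
    column per subject.

    Counts are stored as reals, not integers, because the per-subject
    value is a mean over bilateral counts across at least three sections.
    """

    regions: list[str]
    subject_ids: list[str]
    counts: np.ndarray  # shape (n_regions, n_subjects)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        nr, ns = self.counts.shape
        if nr != len(self.regions):
            raise ValidationError(
                f"counts has {nr} rows but {len(self.regions)} region labels"
            )
        if ns != len(self.subject_ids):
            raise ValidationError(
                f"counts has {ns} columns but {len(self.subject_ids)} subject ids"
            )
        if len(set(self.regions)) != len(self.regions):
            dupes = sorted({r for r in self.regions if self.regions.count(r) > 1})
            raise ValidationError(f"duplicate region labels: {dupes}")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject ids")
        if not np.all(np.isfinite(self.counts)):
            bad = np.argwhere(~np.isfinite(self.counts))[0]
            raise ValidationError(
                f"non-finite count at region {self.regions[bad[0]]!r}, "
                f"subject {self.subject_ids[bad[1]]!r}"
            )
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at region {self.regions[bad[0]]!r}, "
                f"subject {self.subject_ids[bad[1]]!r}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        """Regions x subjects DataFrame preserving both orders."""
        return pd.DataFrame(self.counts, index=self.regions, columns=self.subject_ids)

    def subset_subjects(self, subject_ids: list[str]) -> "RegionActivityTable":
        missing = [s for s in subject_ids if s not in self.subject_ids]
        if missing:
            raise ValidationError(f"unknown subject ids: {missing}")
        idx = [self.subject_ids.index(s) for s in subject_ids]
        return RegionActivityTable(
            regions=list(self.regions),
            subject_ids=list(subject_ids),
            counts=self.counts[:, idx],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionActivityTable":
        return cls(
            regions=[str(r) for r in frame.index],
            subject_ids=[str(c) for c in frame.columns],
            counts=frame.to_numpy(dtype=float),
        )


@dataclass
class GroupDesign:
    """Assignment of each subject to a (genotype, condition) cell."""

    table: pd.DataFrame  # columns: subject_id, genotype, condition

    def __post_init__(self) -> None:
        required = {"subject_id", "genotype", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["subject_id"].duplicated().any():
            dupes = self.table.loc[
                self.table["subject_id"].duplicated(), "subject_id"
            ].tolist()
            raise ValidationError(f"subjects listed more than once in design: {dupes}")
        bad_gen = sorted(set(self.table["genotype"]) - set(GENOTYPES))
        if bad_gen:
            raise ValidationError(
                f"unknown genotype levels {bad_gen}; expected {list(GENOTYPES)}"
            )
        bad_cond = sorted(set(self.table["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValidationError(
                f"unknown condition levels {bad_cond}; expected {list(CONDITIONS)}"
            )

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.table["subject_id"]]

    def group_of(self, subject_id: str) -> tuple[str, str]:
        row = self.table[self.table["subject_id"] == subject_id]
        if row.empty:
            raise ValidationError(f"subject {subject_id!r} not in design")
        return str(row.iloc[0]["genotype"]), str(row.iloc[0]["condition"])

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (genotype, condition) cells in design order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.table.iterrows():
            key = (str(row["genotype"]), str(row["condition"]))
            if key not in seen:
                seen.append(key)
        return seen

    def subjects_in(self, genotype: str, condition: str) -> list[str]:
        mask = (self.table["genotype"] == genotype) & (
            self.table["condition"] == condition
        )
        return [str(s) for s in self.table.loc[mask, "subject_id"]]

    def small_groups(self, min_n: int = MIN_GROUP_SIZE) -> list[tuple[str, str, int]]:
        """(genotype, condition, n) for every cell with fewer than min_n subjects."""
        out = []
        for gen, cond in self.groups():
            n = len(self.subjects_in(gen, cond))
            if n < min_n:
                out.append((gen, cond, n))
        return out


@dataclass
class BehavioralTrial:
    """One animal's three-chamber sociability trial (plus optional
    light-dark time).

    Times are seconds. Tc/To/Tm are chamber times; Tnc/Tno are times in
    close proximity (<5 cm) to the conspecific / object cylinder.
    """

    subject_id: str
    Tc: float
    To: float
    Tm: float
    Tnc: float
    Tno: float
    distance: float = 0.0
    latency: float = 0.0
    lit_time: float | None = None
    session_length: float | None = None

    def __post_init__(self) -> None:
        for name in ("Tc", "To", "Tm", "Tnc", "Tno", "distance", "latency"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name} must be finite and >= 0 for subject "
                    f"{self.subject_id!r}, got {v}"
                )
        if self.Tnc > self.Tc + 1e-9:
            raise ValidationError(
                f"Tnc > Tc for subject {self.subject_id!r} "
                f"({self.Tnc} > {self.Tc}): proximity time cannot exceed chamber time"
            )
        if self.Tno > self.To + 1e-9:
            raise ValidationError(
                f"Tno > To for subject {self.subject_id!r} ({self.Tno} > {self.To})"
            )
        if self.session_length is not None:
            if self.Tc + self.To + self.Tm > self.session_length + 1e-6:
                raise ValidationError(
                    f"chamber times exceed session length for subject "
                    f"{self.subject_id!r}"
                )
        if self.lit_time is not None and self.lit_time < 0:
            raise ValidationError(
                f"lit_time must be >= 0 for subject {self.subject_id!r}"
            )


def concat_tables(
    pairs: list[tuple["RegionActivityTable", "GroupDesign"]],
) -> tuple["RegionActivityTable", "GroupDesign"]:
    """Stack tables that share a region list into one multi-group table.

    Useful when different groups are drawn from different generator specs.
    """
    if not pairs:
        raise ValidationError("nothing to concatenate")
    regions = pairs[0][0].regions
    for table, _ in pairs[1:]:
        if table.regions != regions:
            raise ValidationError("tables have mismatched region lists")
    table = RegionActivityTable(
        regions=list(regions),
        subject_ids=[s for t, _ in pairs for s in t.subject_ids],
        counts=np.concatenate([t.counts for t, _ in pairs], axis=1),
    )
    design = GroupDesign(
        pd.concat([d.table for _, d in pairs], ignore_index=True)
    )
    return table, design
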