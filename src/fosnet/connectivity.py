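"""Per-group interregional correlation matrices and the Fisher-Z network
density comparison.

For each (genotype, condition) group, Pearson r is computed across that
group's subjects for every region pair, with a two-sided p-value from
t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom. For the
group comparison, r-values are transformed to Fisher Z = arctanh(r), a
two-factor ANOVA (genotype x exposure condition) with Bonferroni-adjusted
pairwise contrasts is run on the Z values, and per-group means are
retransformed to r = tanh(mean Z) for reporting.

The ANOVA treats each off-diagonal region pair's Z as one observation
(21 regions -> 210 pairs per group; 4 groups -> 840 observations,
residual df 836). Pairs within one matrix share subjects, so these
observations are not independent; the p-values are reported under that
caveat (see the provenance metadata of pipeline outputs).

Note on thresholds: with n = 7 the two-sided significance criterion
p < 0.05 requires |r| > ~0.754, so it dominates an r > 0.60 edge
threshold; a one-sided switch is provided for users who want the weaker
criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data import GroupDesign, RegionActivityTable, ValidationError

#: clamp applied to |r| before arctanh so degenerate r = +-1 stays finite
FISHER_EPS = 1e-7

SIDEDNESS = ("two-sided", "one-sided")


def fisher_z(r):
    """Fisher Z transform, z = arctanh(r), with |r| clamped to 1 - 1e-7.

    Accepts scalars or arrays; raises on |r| > 1.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(r[np.isfinite(r)]) > 1 + 1e-12):
            raise ValidationError("correlation coefficient outside [-1, 1]")
    clamped = np.clip(r, -(1 - FISHER_EPS), 1 - FISHER_EPS)
    out = np.arctanh(clamped)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Inverse Fisher transform, r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def pearson_p_value(r, n: int, sided: str = "two-sided"):
    """p-value for Pearson r via the t distribution with n - 2 df."""
    if sided not in SIDEDNESS:
        raise ValidationError(f"sided must be one of {SIDEDNESS}")
    if n < 4:
        raise ValidationError(f"need n >= 4 for a Pearson p-value, got n={n}")
    r = np.asarray(r, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p_two = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p_two = np.where(np.abs(r) >= 1.0, 0.0, p_two)
    if sided == "one-sided":
        # one-sided test for positive correlation
        p = np.where(r >= 0, p_two / 2.0, 1.0 - p_two / 2.0)
    else:
        p = p_two
    p = np.asarray(p, dtype=float)
    return float(p) if p.ndim == 0 else p


@dataclass
class GroupCorrelation:
    """Symmetric Pearson r / p / Fisher-Z matrices for one group."""

    genotype: str
    condition: str
    regions: list[str]
    r: np.ndarray
    p: np.ndarray
    z: np.ndarray
    n: int
    warnings: list[str]

    @property
    def group(self) -> tuple[str, str]:
        return self.genotype, self.condition

    def upper_triangle(self) -> pd.DataFrame:
        """Long table of off-diagonal pairs: region_a, region_b, r, p, z."""
        rows = []
        for i, j in itertools.combinations(range(len(self.regions)), 2):
            rows.append(
                {
                    "region_a": self.regions[i],
                    "region_b": self.regions[j],
                    "r": self.r[i, j],
                    "p": self.p[i, j],
                    "z": self.z[i, j],
                }
            )
        return pd.DataFrame(rows)


def correlation_matrix(
    table: RegionActivityTable,
    design: GroupDesign,
    genotype: str,
    condition: str,
    sided: str = "two-sided",
) -> GroupCorrelation:
    """Pearson correlation matrix over one group's subjects.

    Zero-variance regions stay in the matrix with missing (NaN) r/p
    entries and are listed in the result's warnings.
    """
    subjects = design.subjects_in(genotype, condition)
    if len(subjects) < 4:
        raise ValidationError(
            f"group ({genotype}, {condition}) has {len(subjects)} subjects; "
            "need >= 4 for Pearson p-values"
        )
    sub = table.subset_subjects(subjects)
    counts = sub.counts
    n = counts.shape[1]

    sd = counts.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    warnings = [
        f"region {table.regions[i]!r} has zero variance in group "
        f"({genotype}, {condition}); correlations set to missing"
        for i in degenerate
    ]

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(counts)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0  # exact symmetry
    for i in degenerate:
        r[i, :] = np.nan
        r[:, i] = np.nan
        r[i, i] = 1.0

    p = pearson_p_value(np.nan_to_num(r, nan=0.0), n, sided=sided)
    p = np.where(np.isnan(r), np.nan, p)
    np.fill_diagonal(p, 0.0)
    z = fisher_z(np.nan_to_num(r, nan=0.0))
    z = np.where(np.isnan(r), np.nan, z)

    return GroupCorrelation(
        genotype=genotype,
        condition=condition,
        regions=list(table.regions),
        r=r,
        p=p,
        z=z,
        n=n,
        warnings=warnings,
    )


@dataclass
class DensityComparison:
    """Network-density (mean correlation) comparison across groups."""

    group_mean_r: dict[tuple[str, str], float]
    group_mean_z: dict[tuple[str, str], float]
    anova: pd.DataFrame  # effect, F, p, df
    contrasts: pd.DataFrame  # group_a, group_b, t, p_raw, p_bonferroni
    n_observations: int


def compare_density(
    groups: list[GroupCorrelation],
) -> DensityComparison:
    """Compare mean functional connectivity across groups on the Z scale.

    Fits genotype x condition ANOVA with interaction when both factors
    vary (one-way on whichever factor varies otherwise), then all
    pairwise group contrasts as pooled-variance t tests with Bonferroni
    adjustment. Missing pairs (zero-variance regions) are excluded
    pairwise.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare density")
    ref_regions = groups[0].regions
    for g in groups[1:]:
        if g.regions != ref_regions:
            diff = sorted(set(g.regions) ^ set(ref_regions))
            raise ValidationError(
                f"groups have mismatched region sets; difference: {diff}"
            )

    rows = []
    for g in groups:
        tri = g.upper_triangle().dropna(subset=["z"])
        for z in tri["z"]:
            rows.append(
                {"genotype": g.genotype, "condition": g.condition, "z": z}
            )
    long = pd.DataFrame(rows)

    n_gen = long["genotype"].nunique()
    n_cond = long["condition"].nunique()
    if n_gen > 1 and n_cond > 1:
        formula = "z ~ C(genotype) * C(condition)"
    elif n_gen > 1:
        formula = "z ~ C(genotype)"
    elif n_cond > 1:
        formula = "z ~ C(condition)"
    else:
        raise ValidationError("all groups share one (genotype, condition) cell")
    model = smf.ols(formula, data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2).reset_index(names="effect")

    group_z = {}
    for g in groups:
        mask = (long["genotype"] == g.genotype) & (long["condition"] == g.condition)
        group_z[g.group] = float(long.loc[mask, "z"].mean())
    group_r = {k: float(np.tanh(v)) for k, v in group_z.items()}

    pairs = list(itertools.combinations([g.group for g in groups], 2))
    contrast_rows = []
    for (ga, gb) in pairs:
        za = long[(long["genotype"] == ga[0]) & (long["condition"] == ga[1])]["z"]
        zb = long[(long["genotype"] == gb[0]) & (long["condition"] == gb[1])]["z"]
        t, p = scipy.stats.ttest_ind(za, zb, equal_var=True)
        contrast_rows.append(
            {
                "group_a": "/".join(ga),
                "group_b": "/".join(gb),
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(min(p * len(pairs), 1.0)),
            }
        )
    contrasts = pd.DataFrame(contrast_rows)

    return DensityComparison(
        group_mean_r=group_r,
        group_mean_z=group_z,
        anova=anova,
        contrasts=contrasts,
        n_observations=len(long),
    )
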