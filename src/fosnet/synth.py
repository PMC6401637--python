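"""Synthetic c-Fos count tables with planted correlation structure.

The generator emulates the study design the downstream pipeline targets:
21 named brain regions, 2 genotypes x 3 exposure conditions, 7 subjects
per group. Region counts are built from a Gaussian latent-factor model:

    x_i = a * g + b * f_{c(i)} + [hubs: h * sum_{m != c(i)} f_m] + s_i * e_i

with one shared factor g (between-community correlation), one factor f_m
per planted community (within-community correlation), an extra loading
linking each planted hub to every *other* community's factor, and
independent noise e_i. Loadings are solved from the target correlations
in closed form:

    a = sqrt(rho_between)
    b = sqrt(rho_within - rho_between)
    h = (rho_hub - rho_between) / b

and s_i makes every latent variance 1, so the implied matrix is a valid
correlation matrix (positive semidefinite by construction: it is
L L' + diag(s^2)). Counts are then mapped to mean_count + dispersion * x
and truncated at zero; with the default mean_count >= 5 * dispersion,
truncation is rare and the planted correlations survive essentially
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    CONDITIONS,
    DEFAULT_REGIONS,
    GENOTYPES,
    BehavioralTrial,
    GroupDesign,
    RegionActivityTable,
    ValidationError,
)


def _default_communities() -> list[list[str]]:
    """Three equal blocks of 7 over the 21 default regions."""
    regions = list(DEFAULT_REGIONS)
    return [regions[0:7], regions[7:14], regions[14:21]]


def _default_groups() -> list[tuple[str, str]]:
    return [(g, c) for g in GENOTYPES for c in CONDITIONS]


@dataclass
class SyntheticNetworkSpec:
    """Parameters of the planted-structure count generator.

    rho_within / rho_between / rho_hub are target Pearson correlations:
    within a community, across communities, and between a planted hub and
    the members of *other* communities. The constraint
    0 <= rho_between < rho_hub, rho_within < 1 must hold; hubs
    additionally need enough residual variance (checked at generation,
    with an error naming the violated bound).
    """

    communities: list[list[str]] = field(default_factory=_default_communities)
    n_subjects_per_group: int = 7
    groups: list[tuple[str, str]] = field(default_factory=_default_groups)
    rho_within: float = 0.6
    rho_between: float = 0.1
    hub_regions: tuple[str, ...] = ()
    rho_hub: float = 0.4
    mean_count: float = 50.0
    dispersion: float = 10.0
    group_effects: dict[tuple[str, str], dict[str, float]] | None = None
    seed: int = 0

    @property
    def regions(self) -> list[str]:
        return [r for block in self.communities for r in block]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def community_map(self) -> dict[str, int]:
        return {
            r: m for m, block in enumerate(self.communities) for r in block
        }

    def validate(self) -> None:
        regions = self.regions
        if len(set(regions)) != len(regions):
            raise ValidationError("communities assign a region more than once")
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValidationError(
                "need 0 <= rho_between <= rho_within < 1, got "
                f"rho_between={self.rho_between}, rho_within={self.rho_within}"
            )
        if self.hub_regions:
            unknown = sorted(set(self.hub_regions) - set(regions))
            if unknown:
                raise ValidationError(f"hub regions not in region set: {unknown}")
            if not (self.rho_between < self.rho_hub < 1):
                raise ValidationError(
                    "need rho_between < rho_hub < 1, got "
                    f"rho_hub={self.rho_hub}, rho_between={self.rho_between}"
                )
        if self.n_subjects_per_group < 2:
            raise ValidationError("need at least 2 subjects per group")
        if self.mean_count < 0 or self.dispersion <= 0:
            raise ValidationError("mean_count must be >= 0 and dispersion > 0")


def loading_matrix(spec: SyntheticNetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Solve factor loadings from the correlation targets.

    Returns (L, s): L is regions x (1 + M) loadings (global factor first),
    s the per-region residual SDs, such that the implied correlation
    matrix is L @ L.T + diag(s**2) with unit diagonal.
    """
    spec.validate()
    regions = spec.regions
    cmap = spec.community_map
    M = len(spec.communities)
    a = np.sqrt(spec.rho_between)
    b = np.sqrt(spec.rho_within - spec.rho_between)

    L = np.zeros((len(regions), 1 + M))
    s2 = np.ones(len(regions))
    for i, region in enumerate(regions):
        L[i, 0] = a
        L[i, 1 + cmap[region]] = b
        if region in spec.hub_regions:
            if b == 0:
                raise ValidationError(
                    "infeasible correlation targets: rho_hub > rho_between "
                    "requires rho_within > rho_between (community loading is 0)"
                )
            h = (spec.rho_hub - spec.rho_between) / b
            for m in range(M):
                if m != cmap[region]:
                    L[i, 1 + m] = h
        s2[i] = 1.0 - np.sum(L[i] ** 2)
        if s2[i] < -1e-12:
            raise ValidationError(
                "infeasible correlation targets: loadings for region "
                f"{region!r} imply variance {np.sum(L[i] ** 2):.3f} > 1 "
                "(lower rho_hub or raise rho_within)"
            )
        s2[i] = max(s2[i], 0.0)
    return L, np.sqrt(s2)


def implied_correlation(spec: SyntheticNetworkSpec) -> np.ndarray:
    """Theoretical region x region correlation matrix of the generator."""
    L, s = loading_matrix(spec)
    return L @ L.T + np.diag(s**2)


def generate_activity(
    spec: SyntheticNetworkSpec,
) -> tuple[RegionActivityTable, GroupDesign, dict]:
    """Draw a full multi-group counts table plus design and planted truth.

    Truth is {"community_map": region -> community id, "hubs": tuple of
    hub regions, "seed": seed}; use it for recovery tests downstream.
    """
    L, s = loading_matrix(spec)
    rng = np.random.default_rng(spec.seed)
    regions = spec.regions
    n = spec.n_subjects_per_group

    columns: list[np.ndarray] = []
    subject_ids: list[str] = []
    design_rows: list[dict] = []
    for genotype, condition in spec.groups:
        factors = rng.standard_normal((L.shape[1], n))
        noise = rng.standard_normal((len(regions), n))
        latent = L @ factors + s[:, None] * noise
        counts = spec.mean_count + spec.dispersion * latent
        if spec.group_effects and (genotype, condition) in spec.group_effects:
            shifts = spec.group_effects[(genotype, condition)]
            for region, shift in shifts.items():
                counts[regions.index(region)] += shift
        counts = np.clip(counts, 0.0, None)
        columns.append(counts)
        for k in range(n):
            sid = f"{genotype}_{condition}_{k + 1:02d}"
            subject_ids.append(sid)
            design_rows.append(
                {"subject_id": sid, "genotype": genotype, "condition": condition}
            )

    table = RegionActivityTable(
        regions=list(regions),
        subject_ids=subject_ids,
        counts=np.concatenate(columns, axis=1),
    )
    design = GroupDesign(pd.DataFrame(design_rows))
    truth = {
        "community_map": spec.community_map,
        "hubs": tuple(spec.hub_regions),
        "seed": spec.seed,
    }
    return table, design, truth


@dataclass
class SyntheticBehaviorSpec:
    """Parameters of the three-chamber trial generator.

    preference_strength is the expected chamber preference index in
    [-100, 100]; noise_sd (seconds) perturbs the conspecific-chamber time
    around its target before renormalizing, so at noise_sd = 0 every
    trial hits the target exactly.
    """

    preference_strength: float = 50.0
    session_length: float = 600.0
    noise_sd: float = 30.0
    n_animals: int = 7
    side_fraction: float = 2.0 / 3.0  # fraction of session in side chambers
    proximity_fraction: float = 0.5  # fraction of chamber time near cylinder
    seed: int = 0

    def validate(self) -> None:
        if not -100 <= self.preference_strength <= 100:
            raise ValidationError("preference_strength must be in [-100, 100]")
        if self.session_length <= 0 or self.noise_sd < 0:
            raise ValidationError("session_length > 0 and noise_sd >= 0 required")
        if not 0 < self.side_fraction <= 1 or not 0 < self.proximity_fraction <= 1:
            raise ValidationError("fractions must be in (0, 1]")
        if self.n_animals < 1:
            raise ValidationError("need at least one animal")


def generate_behavior(spec: SyntheticBehaviorSpec) -> list[BehavioralTrial]:
    """Draw trials whose expected chamber preference index equals
    preference_strength; close-proximity times are fractions of chamber
    times, so all trial invariants hold by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    S = spec.side_fraction * spec.session_length
    Tm = spec.session_length - S
    # fraction jitter on the same scale as the time noise
    frac_sd = spec.noise_sd / spec.session_length

    trials = []
    for k in range(spec.n_animals):
        target_tc = S * (1.0 + spec.preference_strength / 100.0) / 2.0
        tc = float(np.clip(target_tc + rng.normal(0.0, spec.noise_sd), 0.0, S)) \
            if spec.noise_sd > 0 else target_tc
        to = S - tc
        uc = float(np.clip(spec.proximity_fraction + rng.normal(0.0, frac_sd), 0.0, 1.0)) \
            if frac_sd > 0 else spec.proximity_fraction
        uo = float(np.clip(spec.proximity_fraction + rng.normal(0.0, frac_sd), 0.0, 1.0)) \
            if frac_sd > 0 else spec.proximity_fraction
        trials.append(
            BehavioralTrial(
                subject_id=f"beh_{k + 1:03d}",
                Tc=tc,
                To=to,
                Tm=Tm,
                Tnc=uc * tc,
                Tno=uo * to,
                distance=float(max(rng.normal(3000.0, 300.0), 0.0)),
                latency=float(min(rng.exponential(15.0), spec.session_length)),
                lit_time=float(rng.uniform(0.2, 0.5) * spec.session_length),
                session_length=spec.session_length,
            )
        )
    return trials
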