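"""Synthetic dual-phase phantoms, cohorts and reader calls.

Phantoms are ellipsoidal "tumors" on a CT-like grid whose in-mask voxels
are drawn from a small number of intensity populations (bivariate over the
arterial/venous phases), laid out concentrically — population 1 occupying
the core-to-middle shells and the last population the rim, mirroring the
enhancement geography of real habitat analyses — or as random blobs for
harder clustering problems.  Intensities are truncated Gaussians clipped
to [-200, 400] HU.

Cohorts plant a feature-outcome association through habitat composition:
per-case population fractions and enhancement levels enter a logistic link
whose intercept is solved so the realized prevalence matches the requested
one.  Reader calls are simulated at the call level with specified
sensitivity/specificity (empirical group) or a conditional Node-RADS score
distribution (RADS group), three repeats per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .habitats import HabitatLabelMap
from .preprocessing import DualPhaseCase, ImageGrid, write_volume

__all__ = [
    "Population",
    "PhantomSpec",
    "CohortEffect",
    "CohortSpec",
    "ReaderSpec",
    "generate_phantom",
    "generate_cohort",
    "simulate_readers",
    "default_phantom_spec",
    "write_case",
    "write_cohort",
]

HU_CLIP = (-200.0, 400.0)


@dataclass(frozen=True)
class Population:
    """One voxel-intensity population inside the tumor."""

    fraction: float
    arterial_mean: float
    venous_mean: float
    sd: float
    layout: str = "concentric"  # or "blob"


# the three enhancement-ordered populations used as study conditions:
# >= 5 SD separation between adjacent arterial means, SD 12 HU
DEFAULT_POPULATIONS = (
    Population(0.40, 150.0, 130.0, 12.0),
    Population(0.35, 90.0, 100.0, 12.0),
    Population(0.25, 30.0, 45.0, 12.0),
)


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (12, 48, 48)
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    center_mm: Optional[tuple[float, float, float]] = None  # default: grid center
    radii_mm: tuple[float, float, float] = (15.0, 14.0, 14.0)
    populations: Sequence[Population] = DEFAULT_POPULATIONS
    background_hu: float = -50.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = sum(p.fraction for p in self.populations)
        if len(self.populations) < 1:
            raise ValueError("need at least one population")
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"population fractions must sum to 1, got {fr}")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii must be positive")


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    return PhantomSpec(seed=seed, **overrides)


def _largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, off by at most 1 from fraction * n."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def generate_phantom(spec: PhantomSpec) -> tuple[DualPhaseCase, HabitatLabelMap]:
    """Build one dual-phase case plus its ground-truth population label map."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing, float)
    grid = ImageGrid(tuple(shape), tuple(spacing))

    center = (
        np.asarray(spec.center_mm, float)
        if spec.center_mm is not None
        else (np.asarray(shape, float) - 1) / 2.0 * spacing
    )
    radii = np.asarray(spec.radii_mm, float)
    extent = (np.asarray(shape, float) - 1) * spacing
    if np.any(center - radii < -spacing / 2) or np.any(center + radii > extent + spacing / 2):
        raise ValueError("tumor ellipsoid exceeds grid bounds")

    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1) * spacing
    r2 = (((coords - center) / radii) ** 2).sum(axis=-1)
    mask = r2 <= 1.0
    n_vox = int(mask.sum())
    if n_vox < len(spec.populations):
        raise ValueError("tumor too small for the requested populations")

    fractions = np.array([p.fraction for p in spec.populations])
    counts = _largest_remainder_counts(fractions, n_vox)

    flat_idx = np.flatnonzero(mask.ravel())
    assign = np.empty(n_vox, dtype=int)
    layouts = {p.layout for p in spec.populations}
    if layouts == {"concentric"}:
        # population order runs from the core/middle shells out to the rim
        order = np.argsort(r2.ravel()[flat_idx], kind="stable")
        bounds = np.cumsum(counts)
        start = 0
        for i, b in enumerate(bounds):
            assign[order[start:b]] = i
            start = b
    else:
        # blob layout: capacity-constrained nearest-seed assignment
        vox_mm = coords.reshape(-1, 3)[flat_idx]
        seeds = vox_mm[rng.choice(n_vox, size=len(spec.populations), replace=False)]
        dist = np.linalg.norm(vox_mm[:, None, :] - seeds[None, :, :], axis=-1)
        remaining = counts.copy()
        assign.fill(-1)
        pref = np.argsort(dist, axis=0)  # voxels sorted by closeness per population
        ptr = np.zeros(len(spec.populations), dtype=int)
        # round-robin greedy fill keeps blobs compact and counts exact
        while (assign == -1).any():
            for p in range(len(spec.populations)):
                if remaining[p] == 0:
                    continue
                while ptr[p] < n_vox and assign[pref[ptr[p], p]] != -1:
                    ptr[p] += 1
                if ptr[p] < n_vox:
                    assign[pref[ptr[p], p]] = p
                    remaining[p] -= 1

    arterial = np.full(shape, spec.background_hu, dtype=float)
    venous = np.full(shape, spec.background_hu, dtype=float)
    label_map = np.zeros(shape, dtype=int)
    flat_a = arterial.ravel()
    flat_v = venous.ravel()
    flat_l = label_map.ravel()
    for i, pop in enumerate(spec.populations):
        sel = flat_idx[assign == i]
        flat_a[sel] = np.clip(rng.normal(pop.arterial_mean, pop.sd, sel.size), *HU_CLIP)
        flat_v[sel] = np.clip(rng.normal(pop.venous_mean, pop.sd, sel.size), *HU_CLIP)
        flat_l[sel] = i + 1

    case = DualPhaseCase(
        arterial=flat_a.reshape(shape),
        venous=flat_v.reshape(shape),
        mask=mask.astype(np.uint8),
        grid=grid,
        case_id=f"phantom{spec.seed:05d}",
    )
    truth = HabitatLabelMap(volume=flat_l.reshape(shape), k=len(spec.populations))
    return case, truth


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortEffect:
    """Log-odds slopes per standardized unit of each planted covariate."""

    frac1_slope: float = 0.0        # share of population 1 (habitat composition)
    enhancement_slope: float = 0.0  # population-1 arterial enhancement level


STRONG_EFFECT = CohortEffect(frac1_slope=4.0, enhancement_slope=4.0)
NULL_EFFECT = CohortEffect()


@dataclass
class CohortSpec:
    n_cases: int = 250
    prevalence: float = 0.59           # training-cohort LNM rate
    effect: CohortEffect = NULL_EFFECT
    noise_sd: float = 12.0             # within-population HU spread
    seed: int = 0
    grid_shape: tuple[int, int, int] = (12, 48, 48)
    radii_mm: tuple[float, float, float] = (15.0, 14.0, 14.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_cases < 2:
            raise ValueError("need at least 2 cases")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[DualPhaseCase], np.ndarray, list[HabitatLabelMap], pd.DataFrame]:
    """Simulate a cohort; returns (cases, labels, truth maps, per-case metadata).

    Composition varies around the default fractions (Dirichlet, concentration
    60) and population-1 arterial enhancement around 150 HU (SD 12); the two
    standardized covariates enter a logistic link whose intercept is solved
    so the expected prevalence equals ``spec.prevalence``.
    """
    rng = np.random.default_rng(spec.seed)
    base_fr = np.array([p.fraction for p in DEFAULT_POPULATIONS])
    conc = 60.0

    fracs = rng.dirichlet(conc * base_fr, size=spec.n_cases)
    art1 = rng.normal(150.0, 12.0, size=spec.n_cases)
    radii_scale = rng.uniform(0.85, 1.15, size=spec.n_cases)

    sd_frac1 = np.sqrt(base_fr[0] * (1 - base_fr[0]) / (conc + 1))
    z = (
        spec.effect.frac1_slope * (fracs[:, 0] - base_fr[0]) / sd_frac1
        + spec.effect.enhancement_slope * (art1 - 150.0) / 12.0
    )

    def mean_prev(b0: float) -> float:
        return float(expit(b0 + z).mean()) - spec.prevalence

    b0 = brentq(mean_prev, -30.0, 30.0)
    labels = (rng.uniform(size=spec.n_cases) < expit(b0 + z)).astype(int)

    cases, truths, meta = [], [], []
    for i in range(spec.n_cases):
        pops = [
            Population(
                fraction=float(fracs[i, j]),
                arterial_mean=(art1[i] if j == 0 else DEFAULT_POPULATIONS[j].arterial_mean),
                venous_mean=(
                    130.0 + 0.8 * (art1[i] - 150.0)
                    if j == 0
                    else DEFAULT_POPULATIONS[j].venous_mean
                ),
                sd=spec.noise_sd,
            )
            for j in range(3)
        ]
        ph = PhantomSpec(
            grid_shape=spec.grid_shape,
            radii_mm=tuple(np.asarray(spec.radii_mm) * radii_scale[i]),
            populations=pops,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        case, truth = generate_phantom(ph)
        case.case_id = f"case{i:04d}"
        case.label = int(labels[i])
        cases.append(case)
        truths.append(truth)
        meta.append(
            {"case_id": case.case_id, "label": int(labels[i]), "frac1": fracs[i, 0],
             "art1": art1[i], "z": z[i]}
        )
    return cases, labels, truths, pd.DataFrame(meta).set_index("case_id")


# ---------------------------------------------------------------------------
# Readers

# default Node-RADS score distributions given the true label
DEFAULT_RADS_MODEL = np.array(
    [
        [0.35, 0.30, 0.20, 0.10, 0.05],  # true negative cases
        [0.05, 0.10, 0.20, 0.30, 0.35],  # true positive cases
    ]
)


@dataclass
class ReaderSpec:
    reader_id: str
    seniority: str = "junior"          # or "senior"
    group: str = "empirical"           # or "RADS"
    sensitivity: float = 0.55
    specificity: float = 0.80
    rads_score_model: Optional[np.ndarray] = None  # 2 x 5, rows sum to 1
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity/specificity must be in [0, 1]")
        if self.group == "RADS":
            m = self.rads_score_model if self.rads_score_model is not None else DEFAULT_RADS_MODEL
            m = np.asarray(m, float)
            if m.shape != (2, 5) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("rads_score_model must be 2x5 with rows summing to 1")
            self.rads_score_model = m


def simulate_readers(
    labels, readers: Sequence[ReaderSpec], round_id: int = 1, case_ids=None
) -> pd.DataFrame:
    """Simulate repeat-level reader assessments for one round.

    Empirical readers call each case correctly with probability
    sensitivity/specificity; RADS readers draw a Node-RADS score from their
    conditional distribution and their call is the binarized score (>= 3).
    """
    labels = np.asarray(labels).astype(int)
    if labels.size == 0:
        raise ValueError("empty labels")
    if case_ids is None:
        case_ids = [f"case{i:04d}" for i in range(len(labels))]
    rows = []
    for reader in readers:
        rng = np.random.default_rng((reader.seed, round_id))
        for rep in range(1, reader.n_repeats + 1):
            if reader.group == "RADS":
                scores = np.array(
                    [
                        rng.choice(5, p=reader.rads_score_model[y]) + 1
                        for y in labels
                    ]
                )
                calls = (scores >= 3).astype(int)
            else:
                p_call = np.where(labels == 1, reader.sensitivity, 1 - reader.specificity)
                calls = (rng.uniform(size=labels.size) < p_call).astype(int)
                scores = np.full(labels.size, np.nan)
            for cid, y, call, score in zip(case_ids, labels, calls, scores):
                rows.append(
                    {
                        "case_id": cid, "reader_id": reader.reader_id,
                        "group": reader.group, "seniority": reader.seniority,
                        "round": round_id, "repeat": rep, "call": int(call),
                        "rads_score": (int(score) if np.isfinite(score) else np.nan),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File export

def write_case(case: DualPhaseCase, out_dir: str | Path) -> dict[str, str]:
    """Write one case as paired NIfTI volumes (arterial/venous/mask)."""
    out = Path(out_dir) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (
        ("arterial", case.arterial), ("venous", case.venous), ("mask", case.mask)
    ):
        path = out / f"{name}.nii.gz"
        write_volume(str(path), np.asarray(arr, float), case.grid)
        paths[name] = str(path)
    return paths


def write_cohort(
    cases: Sequence[DualPhaseCase], labels, out_dir: str | Path,
    readers_table: Optional[pd.DataFrame] = None,
) -> None:
    """Write per-case volumes plus the cohort (and optional reader) CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_case(case, out)
    pd.DataFrame(
        {"case_id": [c.case_id for c in cases], "label": np.asarray(labels).astype(int)}
    ).to_csv(out / "cohort.csv", index=False)
    if readers_table is not None:
        readers_table.to_csv(out / "readers.csv", index=False)
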