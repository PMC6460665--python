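"""Synthetic four-group resting-state cohort with a planted crossover.

The generator emulates the study conditions every downstream stage is
validated against: four diagnosis-by-sex cells (defaults 23 ASD-F, 56
ASD-M, 24 TD-F, 65 TD-M), 137 usable volumes at TR = 3.5 s on a 3 mm
isotropic grid, two "cerebellar" and thirteen "cortical" spherical regions,
group-dependent cerebellar-cortical coupling with a crossover interaction
(+delta for ASD females, -delta for ASD males, on the Fisher-z scale),
polynomial drift, a global shared signal, motion-coupled artifacts,
spatially structured white-matter noise, i.i.d. thermal noise, and 6 mm
FWHM spatial smoothing.

Latent construction: per subject, the K region signals are L @ N(0, I)
with L the Cholesky factor of the planted correlation matrix
C = tanh(Z_cell), so the *model* correlation of every region pair equals
tanh(planted z) exactly; for a single coupled pair this reduces to the
shared-component construction with weight sqrt(r).  Every voxel of a
region carries its region's latent signal; nuisance components are added
on top.

Three tiers are provided, trading realism for speed:

* :func:`simulate_cohort` / :class:`CohortSimulation` — full voxel-level 4D
  series (the flagship; streaming per subject).
* :func:`simulate_region_cohort` — region-mean time series only (for
  matrix-stage calibration and recovery studies).
* :func:`simulate_pattern_cohort` — FC pattern vectors drawn directly
  around configurable cell means (for the similarity stage; its
  gender-incoherence mode places the ASD-female mean at half the
  TD-male/TD-female distance from TD males, a 2:1 ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BinaryMask, VolumeGrid, VolumeSeries
from .masks import sphere_mask
from .network import RegionSet
from .nuisance import legendre_basis

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "TissueMasks",
    "SubjectData",
    "CohortSimulation",
    "simulate_cohort",
    "simulate_region_cohort",
    "simulate_pattern_cohort",
    "planted_interaction_contrast",
]

CELLS = ("ASD_F", "ASD_M", "TD_F", "TD_M")
CELL_DX = {"ASD_F": "ASD", "ASD_M": "ASD", "TD_F": "TD", "TD_M": "TD"}
CELL_SEX = {"ASD_F": "F", "ASD_M": "M", "TD_F": "F", "TD_M": "M"}
# crossover: ASD females up, ASD males down, TD at baseline
CELL_SHIFT = {"ASD_F": +1.0, "ASD_M": -1.0, "TD_F": 0.0, "TD_M": 0.0}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_region_layout(grid: VolumeGrid) -> list[tuple[str, tuple[int, int, int], float]]:
    """Two cerebellar seeds (low z) plus 13 cortical blobs, 6 mm radius.

    Centers are spaced >= 5 voxels so the blobs are pairwise disjoint on a
    3 mm grid.  Scaled positions keep the layout valid on other grid sizes.
    """
    nx, ny, nz = grid.dims
    if min(nx, ny) < 18 or nz < 18:
        raise ValueError("default layout needs a grid of at least 18x18x18")
    layout = [
        ("cereb_R", (6, 7, 2), 6.0),
        ("cereb_L", (13, 16, 2), 6.0),
    ]
    xs, ys, zs = (4, 10, 15), (4, 9, 14, 19), (9, 15)
    k = 0
    for z in zs:
        for y in ys:
            for x in xs:
                if k >= 13:
                    break
                k += 1
                layout.append((f"cortex_{k:02d}", (x, y, z), 6.0))
    return layout


@dataclass
class SimulationDesign:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid((20, 24, 20)))
    n_volumes: int = 137
    tr_s: float = 3.5
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"ASD_F": 23, "ASD_M": 56, "TD_F": 24, "TD_M": 65}
    )
    region_layout: list[tuple[str, tuple[int, int, int], float]] | None = None
    base_coupling: float = 0.35          # z, cerebellar-cortical planted pairs
    interaction_delta: float = 0.15      # z, +ASD-F / -ASD-M crossover shift
    cortical_coupling: float = 0.25      # z, fixed cortico-cortical
    cerebellar_coupling: float = 0.25    # z, fixed between the two seeds
    background_coupling: float = 0.20    # z, unplanted cerebellar-cortical
    interaction_pairs: list[tuple[str, str]] | None = None
    drift_amplitude: float = 1.0         # % signal, per Legendre order
    global_signal_sd: float = 0.3        # % signal, shared across gray
    wm_noise_sd: float = 1.0             # % signal, structured WM artifacts
    motion_spike_rate: float = 0.03      # per volume
    motion_artifact_gain: float = 0.5    # % signal per mm of motion
    noise_sd: float = 0.5                # % signal, i.i.d.
    smoothing_fwhm_mm: float = 6.0
    age_mismatched: bool = False         # negative-testing mode
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group_sizes) != set(CELLS):
            raise ValueError(f"group_sizes must cover cells {CELLS}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every cell needs at least 2 subjects")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.region_layout is None:
            self.region_layout = default_region_layout(self.grid)
        ids = [rid for rid, _, _ in self.region_layout]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if self.interaction_pairs is None:
            cereb = [r for r in ids if r.startswith("cereb")]
            cortex = [r for r in ids if not r.startswith("cereb")]
            pairs = []
            if cereb and cortex:
                half = (len(cortex) + 1) // 2
                pairs = [(cereb[0], c) for c in cortex[:half]]
                if len(cereb) > 1:
                    pairs += [(cereb[1], c) for c in cortex[half:]]
            self.interaction_pairs = pairs

    @property
    def region_ids(self) -> list[str]:
        return [rid for rid, _, _ in self.region_layout]

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class TissueMasks:
    gray: BinaryMask
    white: BinaryMask
    ventricle: BinaryMask
    cerebellum: BinaryMask
    brain: BinaryMask            # per-subject coverage (full box here)
    regions: RegionSet


@dataclass
class GroundTruth:
    """Oracle payload: what was planted, per group and per subject."""

    region_ids: list[str]
    coupling_z: dict[str, np.ndarray]          # cell -> (K, K) planted z
    interaction_pairs: list[tuple[str, str]]
    drift_coeffs: dict[str, np.ndarray]        # subject -> (order,) legendre
    motion_tables: dict[str, np.ndarray]       # subject -> (T, 6)
    n_spikes: dict[str, int]
    tissue: TissueMasks

    def pair_contrast(self, pair: tuple[str, str]) -> float:
        return planted_interaction_contrast(self, pair)


def planted_interaction_contrast(truth: GroundTruth, pair: tuple[str, str]) -> float:
    """(mu_ASD,M - mu_TD,M) - (mu_ASD,F - mu_TD,F) on the planted z scale.

    Equals -2*delta for every planted pair under the default crossover.
    """
    ids = truth.region_ids
    a, b = pair
    if a not in ids or b not in ids or a == b:
        raise KeyError(f"unknown region pair {pair}")
    i, j = ids.index(a), ids.index(b)
    z = {cell: truth.coupling_z[cell][i, j] for cell in CELLS}
    return float((z["ASD_M"] - z["TD_M"]) - (z["ASD_F"] - z["TD_F"]))


def _coupling_matrices(design: SimulationDesign) -> dict[str, np.ndarray]:
    ids = design.region_ids
    k = len(ids)
    cereb = [i for i, r in enumerate(ids) if r.startswith("cereb")]
    cortex = [i for i, r in enumerate(ids) if not r.startswith("cereb")]
    base_z = np.zeros((k, k))
    for i in cortex:
        for j in cortex:
            if i != j:
                base_z[i, j] = design.cortical_coupling
    for i in cereb:
        for j in cereb:
            if i != j:
                base_z[i, j] = design.cerebellar_coupling
    for i in cereb:
        for j in cortex:
            base_z[i, j] = base_z[j, i] = design.background_coupling
    pair_rows = [(ids.index(a), ids.index(b)) for a, b in design.interaction_pairs]
    out = {}
    for cell in CELLS:
        z = base_z.copy()
        planted = design.base_coupling + CELL_SHIFT[cell] * design.interaction_delta
        for i, j in pair_rows:
            z[i, j] = z[j, i] = planted
        c = np.tanh(z)
        np.fill_diagonal(c, 1.0)
        if np.abs(np.tanh(z)).max() >= 1.0:
            raise ValueError("coupling magnitudes imply |r| >= 1")
        if np.linalg.eigvalsh(c).min() <= 1e-6:
            raise ValueError(
                f"planted correlation matrix for {cell} is not positive definite; "
                "reduce couplings"
            )
        out[cell] = z
    return out


def build_tissue_masks(design: SimulationDesign) -> TissueMasks:
    """Regions > ventricle > gray halo > white matter, carved in that order."""
    grid = design.grid
    nx, ny, nz = grid.dims
    brain = np.zeros(grid.dims, bool)
    brain[1:nx - 1, 1:ny - 1, 1:nz - 1] = True

    region_masks, ids = [], []
    occupied = np.zeros(grid.dims, bool)
    for rid, center, radius in design.region_layout:
        m = sphere_mask(grid, center, radius, label="region")
        m.membership &= brain  # regions live inside the brain box
        if m.n_voxels == 0:
            raise ValueError(f"region {rid!r} lies outside the brain box")
        if (occupied & m.membership).any():
            raise ValueError(f"region {rid!r} overlaps an earlier region")
        occupied |= m.membership
        region_masks.append(m)
        ids.append(rid)
    regions = RegionSet(ids, region_masks)

    vent = np.zeros(grid.dims, bool)
    vx, vy, vz = nx - 2, ny // 2, nz // 2
    vent[vx - 1:vx + 1, vy - 1:vy + 2, vz:vz + 3] = True
    vent &= brain & ~occupied

    gray = np.zeros(grid.dims, bool)
    for rid, center, radius in design.region_layout:
        gray |= sphere_mask(grid, center, radius + 3.0).membership
    gray &= brain & ~vent

    # cerebellar compartment: low-z slab of the gray mask
    cereb_z = max(c[2] for r, c, _ in design.region_layout
                  if r.startswith("cereb"))
    cereb = gray.copy()
    cereb[:, :, cereb_z + 3:] = False

    white = brain & ~gray & ~vent
    return TissueMasks(
        gray=BinaryMask(grid, gray, "gray"),
        white=BinaryMask(grid, white, "white"),
        ventricle=BinaryMask(grid, vent, "ventricle"),
        cerebellum=BinaryMask(grid, cereb, "cerebellum"),
        brain=BinaryMask(grid, brain, "coverage"),
        regions=regions,
    )


@dataclass
class SubjectData:
    subject: str
    cell: str
    series: VolumeSeries            # unsmoothed raw BOLD
    series_smoothed: VolumeSeries   # 6 mm FWHM smoothed variant
    motion: np.ndarray              # (T, 6): 3 rotations deg, 3 translations mm


def _ar1(rng: np.random.Generator, n: int, phi: float = 0.3) -> np.ndarray:
    x = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + np.sqrt(1 - phi ** 2) * x[t]
    return x


def _motion_table(rng: np.random.Generator, n: int, spike_rate: float):
    """Slow random-walk motion plus step-like spikes; returns table and count."""
    steps = rng.normal(0.0, 0.005, size=(n, 6))
    spikes = rng.random(n - 1) < spike_rate
    jump = rng.normal(0.0, 0.3, size=(int(spikes.sum()), 6))
    steps[1:][spikes] += jump
    return np.cumsum(steps, axis=0), int(spikes.sum())


class CohortSimulation:
    """Deterministic streaming cohort generator.

    Subject volumes are synthesised on demand (``subject(i)`` or iteration)
    from per-subject seeds spawned off ``design.rng_seed``, so any access
    order reproduces identical data bitwise.
    """

    def __init__(self, design: SimulationDesign):
        self.design = design
        self.masks = build_tissue_masks(design)
        self.coupling_z = _coupling_matrices(design)
        self._chol = {
            cell: np.linalg.cholesky(self._corr(cell)) for cell in CELLS
        }
        root = np.random.SeedSequence(design.rng_seed)
        n = design.n_subjects
        self._seeds = root.spawn(n + 1)
        meta_rng = np.random.default_rng(self._seeds[-1])

        cells, ids = [], []
        i = 0
        for cell in CELLS:
            for _ in range(design.group_sizes[cell]):
                ids.append(f"sub-{i + 1:03d}")
                cells.append(cell)
                i += 1
        age_shift = {c: 0.0 for c in CELLS}
        if design.age_mismatched:
            age_shift["ASD_F"] = 8.0
        ages = np.clip(
            meta_rng.normal(21.5, 8.0, n)
            + np.array([age_shift[c] for c in cells]),
            8.0, 62.0,
        )
        iqs = np.clip(meta_rng.normal(112.0, 14.0, n), 80.0, 160.0)
        self.cohort = pd.DataFrame(
            {
                "subject": ids,
                "diagnosis": [CELL_DX[c] for c in cells],
                "sex": [CELL_SEX[c] for c in cells],
                "age": np.round(ages, 2),
                "iq": np.round(iqs, 1),
            }
        )
        self._cells = cells

        drift, motion, n_spikes = {}, {}, {}
        basis = legendre_basis(design.n_volumes, 4)[:, 1:]
        for sid, seed in zip(ids, self._seeds[:n]):
            srng = np.random.default_rng(np.random.SeedSequence(
                entropy=seed.entropy, spawn_key=seed.spawn_key + (0,)))
            drift[sid] = srng.normal(0.0, design.drift_amplitude, basis.shape[1])
            motion[sid], n_spikes[sid] = _motion_table(
                srng, design.n_volumes, design.motion_spike_rate
            )
        self._drift_basis = basis
        self.truth = GroundTruth(
            region_ids=design.region_ids,
            coupling_z=self.coupling_z,
            interaction_pairs=list(design.interaction_pairs),
            drift_coeffs=drift,
            motion_tables=motion,
            n_spikes=n_spikes,
            tissue=self.masks,
        )

    def _corr(self, cell: str) -> np.ndarray:
        c = np.tanh(self.coupling_z[cell])
        np.fill_diagonal(c, 1.0)
        return c

    def __len__(self) -> int:
        return self.design.n_subjects

    def __iter__(self):
        for i in range(len(self)):
            yield self.subject(i)

    def _geometry(self):
        """Row bookkeeping for brain voxels (built once, cached)."""
        if not hasattr(self, "_geom"):
            masks = self.masks
            brain = masks.brain.membership
            row_of = np.full(self.design.grid.dims, -1, np.int64)
            row_of[brain] = np.arange(int(brain.sum()))
            self._geom = {
                "row_of": row_of,
                "n_brain": int(brain.sum()),
                "coords_mm": masks.brain.indices().astype(np.float64)
                * np.asarray(self.design.grid.voxel_size_mm),
                "gray_rows": row_of[masks.gray.membership],
                "region_rows": [row_of[m.membership]
                                for m in masks.regions.masks],
                "wm_idx": masks.white.indices(),
            }
        return self._geom

    def subject(self, i: int) -> SubjectData:
        design = self.design
        masks = self.masks
        sid = self.cohort["subject"].iloc[i]
        cell = self._cells[i]
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=self._seeds[i].entropy,
            spawn_key=self._seeds[i].spawn_key + (1,)))
        t_len = design.n_volumes
        k = len(design.region_ids)
        geom = self._geometry()
        n_brain = geom["n_brain"]

        # all signal components accumulate on brain-voxel rows (float32:
        # 7 significant digits comfortably exceed BOLD dynamic range)
        sig = np.zeros((n_brain, t_len), np.float32)
        latent = self._chol[cell] @ rng.standard_normal((k, t_len))
        for rows, lat in zip(geom["region_rows"], latent):
            sig[rows] += lat.astype(np.float32)

        if design.global_signal_sd > 0:
            g = design.global_signal_sd * rng.standard_normal(t_len)
            sig[geom["gray_rows"]] += g.astype(np.float32)

        if design.wm_noise_sd > 0:
            centers = geom["wm_idx"][rng.integers(0, len(geom["wm_idx"]), 4)]
            vox = np.asarray(design.grid.voxel_size_mm)
            for c in centers:
                d2 = ((geom["coords_mm"] - c * vox) ** 2).sum(1)
                profile = np.exp(-d2 / (2 * 6.0 ** 2)).astype(np.float32)
                sel = profile > 1e-3
                ts = (design.wm_noise_sd * _ar1(rng, t_len)).astype(np.float32)
                sig[sel] += profile[sel, None] * ts

        drift = self._drift_basis @ self.truth.drift_coeffs[sid]
        sig += drift.astype(np.float32)

        motion = self.truth.motion_tables[sid]
        if design.motion_artifact_gain > 0:
            weights = rng.normal(0.0, 1.0, 6)
            pattern = ndimage.gaussian_filter(
                rng.standard_normal(design.grid.dims), 2.0
            )
            pattern /= max(np.abs(pattern).max(), 1e-12)
            art = (design.motion_artifact_gain * (motion @ weights)).astype(
                np.float32)
            sig += pattern[masks.brain.membership].astype(
                np.float32)[:, None] * art

        if design.noise_sd > 0:
            sig += np.float32(design.noise_sd) * rng.standard_normal(
                (n_brain, t_len), dtype=np.float32)

        raw = np.zeros(design.grid.dims + (t_len,), np.float32)
        raw[masks.brain.membership] = 1000.0 * (1.0 + sig / 100.0)
        series = VolumeSeries(design.grid, raw)
        if design.smoothing_fwhm_mm > 0:
            sigma_vox = [
                design.smoothing_fwhm_mm * FWHM_TO_SIGMA / v
                for v in design.grid.voxel_size_mm
            ]
            smoothed = ndimage.gaussian_filter(raw, sigma=sigma_vox + [0.0])
        else:
            smoothed = raw.copy()
        return SubjectData(sid, cell, series,
                           VolumeSeries(design.grid, smoothed), motion)


def simulate_cohort(design: SimulationDesign):
    """Materialise the full cohort at once (small designs only).

    Returns (subjects, motion_tables, tissue_masks, cohort_table, truth);
    use :class:`CohortSimulation` directly to stream large cohorts.
    """
    sim = CohortSimulation(design)
    subjects = list(sim)
    motion = {s.subject: s.motion for s in subjects}
    return subjects, motion, sim.masks, sim.cohort, sim.truth


def simulate_region_cohort(design: SimulationDesign, region_noise_sd: float = 0.1):
    """Region-mean series per subject, skipping voxel synthesis.

    Emulates the region-mean signals the voxel pipeline would extract:
    latent coupled signals plus the global signal plus averaged-down
    thermal noise.  Returns (series_by_subject (n, K, T), cohort_table
    with motion and gcor covariate columns, truth-like coupling dict).
    """
    from .connectivity import motion_summary

    sim = CohortSimulation(design)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=design.rng_seed, spawn_key=(7,)))
    k = len(design.region_ids)
    t_len = design.n_volumes
    out = np.empty((design.n_subjects, k, t_len))
    gcors, motions = [], []
    # voxel counts for the closed-form GCOR emulation below
    n_region = np.array([m.n_voxels for m in sim.masks.regions.masks])
    n_gray = sim.masks.gray.n_voxels
    n_bg = n_gray - int(n_region.sum())
    sigma2 = design.noise_sd ** 2
    for i, cell in enumerate(sim._cells):
        latent = sim._chol[cell] @ rng.standard_normal((k, t_len))
        amp = abs(rng.normal(design.global_signal_sd,
                             design.global_signal_sd / 2)) \
            if design.global_signal_sd > 0 else 0.0
        g = amp * rng.standard_normal(t_len)
        out[i] = latent + g + region_noise_sd * rng.standard_normal((k, t_len))
        motions.append(motion_summary(sim.truth.motion_tables[
            sim.cohort["subject"].iloc[i]]))
        # emulate the voxel-level GCOR the full pipeline would compute:
        # mean pairwise voxel correlation over the gray mask, where region
        # pairs follow the realized region-series correlations and
        # within-region / background pairs follow the per-voxel model
        # (shared signal variance amp^2, thermal variance sigma^2)
        denom = 1.0 + amp ** 2 + sigma2
        r_between = np.corrcoef(out[i]) * (1.0 + amp ** 2) / denom
        r_within = (1.0 + amp ** 2) / denom
        r_bg = amp ** 2 / denom
        total = float(n_gray)  # self pairs, correlation 1
        total += float(np.sum(n_region * (n_region - 1)) * r_within)
        cross = np.outer(n_region, n_region) * r_between
        total += float(cross.sum() - np.sum(n_region ** 2 * np.diag(r_between)))
        total += float((2 * n_region.sum() * n_bg + n_bg * (n_bg - 1)) * r_bg)
        gcors.append(total / n_gray ** 2)
    cohort = sim.cohort.copy()
    cohort["motion"] = motions
    cohort["gcor"] = gcors
    return out, cohort, sim.truth


def simulate_pattern_cohort(
    n_pairs: int = 13,
    group_sizes: dict[str, int] | None = None,
    base_level: float = 0.35,
    base_spread: float = 0.2,
    sex_effect: float = 0.15,
    asd_female_pull: float = 1.0 / 3.0,
    subject_sd: float = 0.25,
    mode: str = "incoherence",
    rng: np.random.Generator | int | None = None,
) -> dict[str, np.ndarray]:
    """FC pattern vectors per cell for the similarity analysis.

    mode='incoherence': TD males and females differ by a per-pair sex
    signature of magnitude ``sex_effect``; the ASD-female mean sits at
    fraction ``asd_female_pull`` of the way from the midline toward the TD
    male mean, i.e. at distance (1-pull)*|s| from TD males and
    (1+pull)*|s| from TD females (2:1 with the default pull of 1/3); the
    ASD-male mean coincides with the TD-male mean.  mode='null': all four
    cells share one mean (exchangeable null).
    """
    if group_sizes is None:
        group_sizes = {"ASD_F": 23, "ASD_M": 56, "TD_F": 24, "TD_M": 65}
    if mode not in ("incoherence", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    mu0 = rng.normal(base_level, base_spread, n_pairs)
    sig = sex_effect * rng.choice([-1.0, 1.0], n_pairs)
    if mode == "null":
        means = {cell: mu0 for cell in CELLS}
    else:
        means = {
            "TD_M": mu0 + sig,
            "TD_F": mu0 - sig,
            "ASD_F": mu0 + asd_female_pull * sig,
            "ASD_M": mu0 + sig,
        }
    return {
        cell: means[cell] + subject_sd * rng.standard_normal(
            (group_sizes[cell], n_pairs))
        for cell in CELLS
    }
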