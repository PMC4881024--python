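"""In-silico kinome-array experiments with known ground truth.

Each virtual patient gets a control and a treatment slide.  A spot's net
log2 intensity is the sum of independent components:

* basic intensity            N(10, 1.5)   — per substrate, shared by both slides
* inter-patient variation    N(0, 0.5)    — per substrate and patient, shared
* treatment effect E         induced substrates, treatment slide only
* intraslide gradient        one of 15 smooth 96 x 32 fields, drawn per slide
* array effect               U[-2, 0]     — per slide, additive
* spot error                 N(0, 0.4)    — per replicate spot

In pathway mode the realized effect per induced substrate additionally
carries biological (per-patient, N(0, 0.4)) and technical (per-substrate,
uniform) effect-size variation.  Off-spots, when requested, are replaced by
detection-floor noise and arrive pre-flagged (KS flag), mimicking substrates
that are reliably unphosphorylated.

All randomness derives from one master seed through named substreams, so
changing one component's draw leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import ArrayLayout
from .spots import SpotTable

__all__ = [
    "SimulationConfig",
    "VirtualExperiment",
    "generate_gradient_field",
    "simulate_experiment",
    "annotation_fixture",
]

_STREAMS = ("basic", "patient", "effect", "gradient", "array", "spot_error",
            "induced", "offspots", "fields")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the virtual experiment (all intensities log2)."""

    n_patients: int = 8
    layout: ArrayLayout = field(default_factory=ArrayLayout)
    basic_mean: float = 10.0
    basic_sd: float = 1.5
    patient_sd: float = 0.5
    effect_size: float = 0.8          # = 2 x spot error SD
    n_induced: int = 197              # 2 pathways, 18 kinases downstream
    gradient_strength: float = 1.0    # max - min of each field, log2 units
    n_gradient_fields: int = 15
    array_effect_range: tuple[float, float] = (-2.0, 0.0)
    spot_error_sd: float = 0.4
    off_fraction: float = 0.0
    detection_floor: float = 3.0      # log2 level off-spots scatter around
    pathway_mode: bool = False
    bio_effect_sd: float = 0.4
    tech_effect_halfwidth: float | None = None  # default 0.2, or 0.33*E in sweeps
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.off_fraction < 1:
            raise ValueError("off_fraction must be in [0, 1)")
        if self.n_induced >= self.layout.n_substrates:
            raise ValueError("induced substrate count must be below the substrate count")
        for sd in (self.basic_sd, self.patient_sd, self.spot_error_sd, self.bio_effect_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class VirtualExperiment:
    """Simulated slides plus the ground truth that generated them."""

    config: SimulationConfig
    control: list[SpotTable]          # one per patient
    treatment: list[SpotTable]
    induced: np.ndarray               # (R, C) bool
    realized_effect: np.ndarray       # (n_patients, R, C): effect on treatment slide
    gradient_fields: np.ndarray       # (n_fields, total_rows, set_cols)
    field_choice: np.ndarray          # (n_patients, 2) field index per slide
    array_effects: np.ndarray         # (n_patients, 2)
    off_spots: np.ndarray             # (R, C) bool

    @property
    def pairs(self) -> list[tuple[SpotTable, SpotTable]]:
        return list(zip(self.control, self.treatment))


def generate_gradient_field(
    strength: float,
    shape: tuple[int, int] = (96, 32),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One smooth zero-mean gradient field with range max - min = strength.

    Built from 1-3 random low-frequency cosine bumps, mimicking the broad
    loading/deposition gradients seen on real slides.  Deterministic per
    seed; strength 0 yields the zero field.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij")
    f = np.zeros(shape)
    for _ in range(int(rng.integers(1, 4))):
        fy, fx = rng.uniform(0.3, 1.5, size=2)  # < 1.5 cycles across the slide
        phy, phx = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.5, 1.0)
        f += amp * np.cos(2 * np.pi * fy * yy + phy) * np.cos(2 * np.pi * fx * xx + phx)
    if strength == 0:
        return np.zeros(shape)
    span = f.max() - f.min()
    if span == 0:  # degenerate draw: fall back to a plain vertical ramp
        f = yy.copy()
        span = f.max() - f.min()
    f = f * (strength / span)
    return f - f.mean()


def _grid_positions(layout: ArrayLayout):
    """Full-slide (row, col) index arrays per (set, row, col) spot."""
    s, r, c = np.meshgrid(
        np.arange(layout.n_sets), np.arange(layout.set_rows), np.arange(layout.set_cols),
        indexing="ij",
    )
    return s * layout.set_rows + r, c


def simulate_experiment(config: SimulationConfig) -> VirtualExperiment:
    """Generate the full virtual experiment for ``config`` (reproducible)."""
    lay = config.layout
    R, C, S = lay.set_rows, lay.set_cols, lay.n_sets
    P = config.n_patients
    rngs = _rngs(config.seed)

    basic = rngs["basic"].normal(config.basic_mean, config.basic_sd, size=(R, C))
    patient_var = rngs["patient"].normal(0.0, config.patient_sd, size=(P, R, C))

    induced = np.zeros((R, C), dtype=bool)
    flat = rngs["induced"].choice(R * C, size=config.n_induced, replace=False)
    induced.ravel()[flat] = True

    # realized effect per patient on the treatment slide
    eff = np.zeros((P, R, C))
    if config.pathway_mode:
        half = config.tech_effect_halfwidth
        if half is None:
            half = 0.2
        tech = rngs["effect"].uniform(-half, half, size=(R, C))
        bio = rngs["effect"].normal(0.0, config.bio_effect_sd, size=P)
        for p in range(P):
            eff[p] = (config.effect_size + bio[p] + tech) * induced
    else:
        eff[:] = config.effect_size * induced

    n_fields = max(config.n_gradient_fields, 1)
    fields = np.stack([
        generate_gradient_field(config.gradient_strength, (lay.total_rows, C),
                                rngs["fields"])
        for _ in range(n_fields)
    ])
    field_choice = rngs["gradient"].integers(0, n_fields, size=(P, 2))
    lo, hi = config.array_effect_range
    array_effects = rngs["array"].uniform(lo, hi, size=(P, 2))

    off = np.zeros((R, C), dtype=bool)
    if config.off_fraction > 0:
        n_off = int(round(config.off_fraction * R * C))
        off_idx = rngs["offspots"].choice(R * C, size=n_off, replace=False)
        off.ravel()[off_idx] = True

    grid_r, grid_c = _grid_positions(lay)
    control, treatment = [], []
    for p in range(P):
        for cond_i, cond in enumerate(("control", "treatment")):
            g = fields[field_choice[p, cond_i]][grid_r, grid_c]
            base = basic + patient_var[p] + (eff[p] if cond_i else 0.0)
            noise = rngs["spot_error"].normal(0.0, config.spot_error_sd, size=(S, R, C))
            values = base[None, :, :] + g + array_effects[p, cond_i] + noise
            if off.any():
                floor = rngs["offspots"].normal(
                    config.detection_floor, config.spot_error_sd, size=(S, R, C))
                values = np.where(off[None, :, :], floor, values)
            flags = {"ks": np.broadcast_to(off[None, :, :], (S, R, C)).copy()}
            t = SpotTable(lay, values, flags,
                          slide_id=f"p{p}_{cond}", condition=cond)
            (control if cond_i == 0 else treatment).append(t)

    return VirtualExperiment(
        config=config,
        control=control,
        treatment=treatment,
        induced=induced,
        realized_effect=eff,
        gradient_fields=fields,
        field_choice=field_choice,
        array_effects=array_effects,
        off_spots=off,
    )


def annotation_fixture(config: SimulationConfig, n_decoy_pathways: int = 8,
                       decoy_kinases_per_pathway: int = 5,
                       substrates_per_decoy_kinase: int = 10) -> pd.DataFrame:
    """Synthetic substrate -> kinase -> pathway annotation table.

    Assigns the experiment's induced substrates to 18 kinases spread over 2
    induced pathways (mirroring the simulated treatment, which activates two
    downstream pathways) and builds decoy pathways from uninduced
    substrates.  Deterministic given the config seed.  Columns:
    substrate_id, kinase, pathway, induced.
    """
    lay = config.layout
    rngs = _rngs(config.seed)
    induced_flat = np.sort(rngs["induced"].choice(
        lay.n_substrates, size=config.n_induced, replace=False))

    n_kinases = 18
    rows = []
    # split the induced substrates over 18 kinases in 2 pathways, near-evenly
    splits = np.array_split(induced_flat, n_kinases)
    for k, sub_ids in enumerate(splits):
        pathway = f"induced_pw{1 if k < n_kinases // 2 else 2}"
        for sid in sub_ids:
            rows.append((int(sid), f"kin{k:02d}", pathway, 1))

    uninduced = np.setdiff1d(np.arange(lay.n_substrates), induced_flat)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA2201)))
    needed = n_decoy_pathways * decoy_kinases_per_pathway * substrates_per_decoy_kinase
    pool = rng.choice(uninduced, size=min(needed, uninduced.size), replace=False)
    i = 0
    for pw in range(n_decoy_pathways):
        for k in range(decoy_kinases_per_pathway):
            for _ in range(substrates_per_decoy_kinase):
                if i >= pool.size:
                    break
                rows.append((int(pool[i]), f"decoy_pw{pw}_kin{k}", f"decoy_pw{pw}", 0))
                i += 1
    return pd.DataFrame(rows, columns=["substrate_id", "kinase", "pathway", "induced"])
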