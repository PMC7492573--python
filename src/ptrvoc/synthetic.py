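"""Synthetic PTR-TOF-MS experiments, phenotype stacks and fresh-weight tables.

The generator stands in for the instrument and the plant measurements so the
whole downstream pipeline is testable without laboratory data.  It emits
already-quantified per-cycle concentration traces in ppb — the level at which
headspace post-processing starts — never raw ion counts or spectra.

A measurement run consists of a VOC-free N2 background block (3 min, 180
cycles by default) followed by a 45-min sample block (2,700 cycles).  Each
compound channel follows one of three kinetic shapes over the sample block:

* ``decay``     c(t) = c0 * exp(-k t)   (headspace depletion under flushing)
* ``constant``  c(t) = c0
* ``rise``      c(t) = c0 * t / T       (linear ramp reaching c0 at the end)

with t the 0-based cycle offset and T the last offset.  Additive Gaussian
noise, independent per cycle and channel, is layered on top; the background
block is pure noise around zero, and negative excursions are kept so the
net-negative filter downstream is exercised.  Compounds carry an association
(fungal / plant / shared / nuisance) and each treatment scales the clean
trace by its per-association multiplier, which is how the treatment structure
(plant control, fungal control, co-cultivation) is planted.  A compound with
a known formula additionally emits a 13C isotopologue companion channel
1.003355 Th higher at the natural-abundance (M+1)/M ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formulas import C13_MINUS_C12, expected_m1_ratio, parse_formula

__all__ = [
    "CompoundSpec",
    "Treatment",
    "ScenarioConfig",
    "SampleRun",
    "generate_run",
    "generate_experiment",
    "generate_phenotype_stack",
    "generate_fw_table",
    "default_scenario",
    "planted_decay_channels",
    "channel_id_for",
]

ASSOCIATIONS = ("fungal", "plant", "shared", "nuisance")
KINETICS = ("decay", "constant", "rise")

#: Default per-cycle decay constant: the trace halves over a 2,700-cycle run.
DEFAULT_DECAY_RATE = float(np.log(2.0) / 2700.0)


def channel_id_for(mz: float) -> str:
    """Channel label from the 3-decimal m/z, e.g. 137.060 -> '137.060'."""
    return f"{mz:.3f}"


@dataclass(frozen=True)
class CompoundSpec:
    """One emitted compound channel and its kinetic/noise parameters."""

    channel_id: str
    mz: float
    association: str
    kinetics: str
    peak_conc: float
    decay_rate: float = DEFAULT_DECAY_RATE
    noise_sd: float | None = None  # None -> scenario background_noise_sd
    formula: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mz <= 500:
            raise ValueError(f"mz must be in (0, 500], got {self.mz}")
        if self.association not in ASSOCIATIONS:
            raise ValueError(f"unknown association {self.association!r}")
        if self.kinetics not in KINETICS:
            raise ValueError(f"unknown kinetics {self.kinetics!r}")
        if self.peak_conc < 0:
            raise ValueError("peak_conc must be >= 0")
        if self.kinetics == "decay" and self.decay_rate <= 0:
            raise ValueError("decay_rate must be > 0 for decay kinetics")
        if self.formula is not None:
            parse_formula(self.formula)  # validates element symbols


@dataclass(frozen=True)
class Treatment:
    """A treatment condition: label, per-association multipliers, replicates.

    ``category`` groups treatments into the coarse classes the selection
    stage distinguishes (plant / fungal / cocultivation).
    """

    label: str
    multipliers: Mapping[str, float]
    category: str
    n_replicates: int = 1

    def multiplier(self, association: str) -> float:
        return float(self.multipliers.get(association, 0.0))


@dataclass
class ScenarioConfig:
    """Full description of a synthetic headspace experiment."""

    compounds: Sequence[CompoundSpec]
    treatments: Sequence[Treatment]
    n_background_cycles: int = 180
    n_sample_cycles: int = 2700
    background_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sample_cycles < 80:
            raise ValueError("n_sample_cycles must be >= 80 (skip + averaging window)")
        if self.n_background_cycles < 1:
            raise ValueError("n_background_cycles must be >= 1")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("treatment labels must be unique")
        ids = [c.channel_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ValueError("compound channel_ids must be unique")

    def treatment(self, label: str) -> Treatment:
        for t in self.treatments:
            if t.label == label:
                return t
        raise KeyError(f"unknown treatment label {label!r}")


@dataclass
class SampleRun:
    """One PTR measurement: background and sample blocks of per-channel traces."""

    sample_id: str
    treatment: str
    category: str
    background: pd.DataFrame  # cycles x channels, ppb
    sample: pd.DataFrame  # cycles x channels, ppb
    channel_mz: pd.Series  # channel_id -> m/z (Th)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.background.columns) != list(self.sample.columns):
            raise ValueError("background and sample blocks must share channels")
        for block in (self.background, self.sample):
            if not np.isfinite(block.to_numpy()).all():
                raise ValueError("concentrations must be finite")

    @property
    def channels(self) -> list[str]:
        return list(self.sample.columns)


def _clean_trace(spec: CompoundSpec, n_cycles: int, multiplier: float) -> np.ndarray:
    t = np.arange(n_cycles, dtype=float)
    c0 = spec.peak_conc * multiplier
    if spec.kinetics == "decay":
        return c0 * np.exp(-spec.decay_rate * t)
    if spec.kinetics == "constant":
        return np.full(n_cycles, c0)
    # linear ramp reaching c0 at the final cycle
    T = max(n_cycles - 1, 1)
    return c0 * t / T


def _channel_plan(
    scenario: ScenarioConfig,
) -> list[tuple[str, float, CompoundSpec, float]]:
    """Ordered (channel_id, mz, parent spec, isotopologue ratio) quadruples.

    The ratio is 1.0 for main channels; isotopologue companions carry the
    expected (M+1)/M fraction and inherit the parent's kinetics and noise.
    """
    plan: list[tuple[str, float, CompoundSpec, float]] = []
    for spec in scenario.compounds:
        plan.append((spec.channel_id, spec.mz, spec, 1.0))
        if spec.formula is not None:
            n_c = parse_formula(spec.formula).get("C", 0)
            if n_c > 0:
                iso_mz = spec.mz + C13_MINUS_C12
                plan.append((channel_id_for(iso_mz), iso_mz, spec, expected_m1_ratio(n_c)))
    plan.sort(key=lambda item: item[1])
    ids = [item[0] for item in plan]
    if len(set(ids)) != len(ids):
        raise ValueError("channel collision between isotopologue and main channels")
    return plan


def generate_run(
    scenario: ScenarioConfig,
    treatment: str,
    seed: int,
    sample_id: str | None = None,
) -> SampleRun:
    """Simulate one measurement of ``treatment`` under ``scenario``.

    Deterministic: identical (scenario, treatment, seed) gives identical data.
    """
    trt = scenario.treatment(treatment)
    plan = _channel_plan(scenario)
    rng = np.random.default_rng(seed)

    n_bg, n_sm = scenario.n_background_cycles, scenario.n_sample_cycles
    ids = [item[0] for item in plan]
    mzs = pd.Series({item[0]: item[1] for item in plan}, name="mz")
    sds = np.array(
        [
            scenario.background_noise_sd if item[2].noise_sd is None else item[2].noise_sd
            for item in plan
        ]
    )

    clean = np.empty((n_sm, len(plan)))
    for j, (_cid, _mz, spec, ratio) in enumerate(plan):
        clean[:, j] = ratio * _clean_trace(spec, n_sm, trt.multiplier(spec.association))

    bg = rng.normal(loc=0.0, scale=np.broadcast_to(sds, (n_bg, len(plan))))
    sm = clean + rng.normal(loc=0.0, scale=np.broadcast_to(sds, (n_sm, len(plan))))

    cycles_bg = pd.RangeIndex(1, n_bg + 1, name="cycle")
    cycles_sm = pd.RangeIndex(1, n_sm + 1, name="cycle")
    return SampleRun(
        sample_id=sample_id or f"{treatment}-s{seed}",
        treatment=treatment,
        category=trt.category,
        background=pd.DataFrame(bg, index=cycles_bg, columns=ids),
        sample=pd.DataFrame(sm, index=cycles_sm, columns=ids),
        channel_mz=mzs,
        metadata={"seed": seed},
    )


def _run_seed(master_seed: int, run_index: int) -> int:
    # fixed arithmetic, never wall-clock; kept below 2**31
    return (master_seed * 1_000_003 + run_index * 7_919 + 17) % (2**31 - 1)


def generate_experiment(scenario: ScenarioConfig) -> list[SampleRun]:
    """One SampleRun per (treatment, replicate), seeded from scenario.seed."""
    runs: list[SampleRun] = []
    run_index = 0
    for trt in scenario.treatments:
        for rep in range(1, trt.n_replicates + 1):
            runs.append(
                generate_run(
                    scenario,
                    trt.label,
                    seed=_run_seed(scenario.seed, run_index),
                    sample_id=f"{trt.label}-r{rep}",
                )
            )
            run_index += 1
    return runs


# ---------------------------------------------------------------------------
# Default scenario: the study conditions the pipeline is validated against.
# ---------------------------------------------------------------------------

# Decaying fungal-associated compounds.  Channels use theoretical protonated
# m/z; four carry formulas and therefore emit a 13C isotopologue companion,
# giving 12 decaying fungal channels in total (8 mains + 4 isotopologues),
# the planted set the selection cascade must recover.  Peak levels span the
# few-to-tens of ppb range typical of abundant culture-headspace volatiles.
_FUNGAL_DECAY: list[tuple[float, str | None, float]] = [
    (62.026, None, 5.0),
    (63.026, "C2H6S", 20.0),  # dimethyl sulfide
    (75.044, None, 6.0),
    (89.060, "C4H8O2", 8.0),
    (93.034, "C6H4O", 6.0),
    (105.034, None, 4.0),
    (110.982, None, 3.0),
    (137.060, "C8H8O2", 8.0),  # methyl benzoate
]

# Fungal-associated but non-decaying channels: pass the ordination filters,
# fail the kinetics filter (the 30 -> 12 step).
_FUNGAL_CONSTANT = [45.033, 47.049, 59.049, 61.028, 69.070, 71.049, 81.070, 87.044, 99.080]
_FUNGAL_RISE = [101.060, 107.049, 115.112, 121.065, 129.055, 143.107, 145.050, 151.075, 163.075]

# Masses that must not be generated for random channels (reserved +/- 0.02 Th):
# structured channels above plus the default exclusion-list species.
_RESERVED = (
    [mz for mz, _f, _p in _FUNGAL_DECAY]
    + [mz + C13_MINUS_C12 for mz, f, _p in _FUNGAL_DECAY if f]
    + _FUNGAL_CONSTANT
    + _FUNGAL_RISE
    + [19.018, 29.997, 31.989, 37.028, 44.998, 46.005, 55.039, 203.943]
)


def _random_masses(rng: np.random.Generator, n: int, reserved: list[float]) -> list[float]:
    taken = list(reserved)
    out: list[float] = []
    while len(out) < n:
        mz = float(np.round(rng.uniform(33.0, 290.0), 3))
        if all(abs(mz - r) > 0.02 for r in taken):
            out.append(mz)
            taken.append(mz)
    return out


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The default 400-channel scenario with 3 plant / 3 fungal / 3 co-cultivation runs.

    Roster: 8 decaying fungal compounds (12 decaying channels including the
    four 13C isotopologues), 18 non-decaying fungal compounds, 60 plant
    compounds, 300 ubiquitous low-level nuisance compounds, and 10 junk
    channels (out-of-range, exclusion-list masses, empty channels) that
    exercise the reduction filters.  Channel m/z values for the unstructured
    compounds are drawn once from a fixed internal generator, so the roster
    is identical for every ``seed``; ``seed`` only drives measurement noise.
    """
    compounds: list[CompoundSpec] = []
    for mz, formula, peak in _FUNGAL_DECAY:
        compounds.append(
            CompoundSpec(
                channel_id=channel_id_for(mz),
                mz=mz,
                association="fungal",
                kinetics="decay",
                peak_conc=peak,
                formula=formula,
            )
        )
    for i, mz in enumerate(_FUNGAL_CONSTANT):
        compounds.append(
            CompoundSpec(channel_id_for(mz), mz, "fungal", "constant", 3.0 + 0.8 * i)
        )
    for i, mz in enumerate(_FUNGAL_RISE):
        compounds.append(
            CompoundSpec(channel_id_for(mz), mz, "fungal", "rise", 20.0 + 1.2 * i)
        )

    roster_rng = np.random.default_rng(1_234_567)  # fixed: roster is part of the design
    plant_masses = _random_masses(roster_rng, 60, _RESERVED)
    for i, mz in enumerate(plant_masses):
        compounds.append(
            CompoundSpec(
                channel_id_for(mz),
                mz,
                "plant",
                "decay" if i % 2 == 0 else "constant",
                peak_conc=float(np.round(roster_rng.uniform(2.0, 12.0), 2)),
            )
        )
    nuis_masses = _random_masses(roster_rng, 300, _RESERVED + plant_masses)
    for mz in nuis_masses:
        compounds.append(
            CompoundSpec(
                channel_id_for(mz),
                mz,
                "nuisance",
                "constant",
                peak_conc=float(np.round(roster_rng.uniform(0.8, 3.0), 2)),
            )
        )
    # junk channels exercising each reduction filter
    for mz in (12.010, 14.503, 305.120, 402.225):  # outside [15.993, 300.066]
        compounds.append(CompoundSpec(channel_id_for(mz), mz, "nuisance", "constant", 5.0))
    for mz in (19.018, 29.997, 37.028):  # exclusion-list species
        compounds.append(CompoundSpec(channel_id_for(mz), mz, "nuisance", "constant", 50.0))
    for mz in (152.505, 201.505, 250.505):  # empty channels: pure noise
        compounds.append(CompoundSpec(channel_id_for(mz), mz, "nuisance", "constant", 0.0))

    treatments = [
        Treatment(
            "plant",
            {"plant": 1.0, "fungal": 0.0, "shared": 1.0, "nuisance": 1.0},
            category="plant",
            n_replicates=3,
        ),
        Treatment(
            "fungal",
            {"plant": 0.0, "fungal": 1.0, "shared": 1.0, "nuisance": 1.0},
            category="fungal",
            n_replicates=3,
        ),
        Treatment(
            "cocultivation",
            {"plant": 1.0, "fungal": 0.7, "shared": 1.0, "nuisance": 1.0},
            category="cocultivation",
            n_replicates=3,
        ),
    ]
    return ScenarioConfig(compounds=compounds, treatments=treatments, seed=seed)


def planted_decay_channels(scenario: ScenarioConfig) -> set[str]:
    """Ground truth: decaying fungal channels, isotopologue companions included."""
    out: set[str] = set()
    for spec in scenario.compounds:
        if spec.association == "fungal" and spec.kinetics == "decay" and spec.peak_conc > 0:
            out.add(spec.channel_id)
            if spec.formula is not None and parse_formula(spec.formula).get("C", 0) > 0:
                out.add(channel_id_for(spec.mz + C13_MINUS_C12))
    return out


# ---------------------------------------------------------------------------
# Phenotype-stack and fresh-weight fixtures
# ---------------------------------------------------------------------------


def generate_phenotype_stack(
    shape: tuple[int, int],
    class_profile: tuple[Sequence[float], Sequence[float]],
    seed: int,
    index: str = "fvfm",
):
    """Build a multispectral stack whose derived index matches a class profile.

    ``class_profile`` is ``(edges, fractions)``: pixel fractions per class
    must sum to 1.  Pixels are assigned class-midpoint index values (largest-
    remainder rounding of the requested counts, positions shuffled by the
    seeded generator), then the bands are solved backwards so that the named
    index reproduces those values exactly:

    * ``fvfm``: Fm = 2000 counts, F0 = Fm (1 - v);
    * ``ari``:  R700 = R_NIR = 0.5, R550 = 1 / (2 v + 2)  (needs v > -1).
    """
    edges, fractions = class_profile
    edges = np.asarray(edges, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(edges) - 1:
        raise ValueError("need len(fractions) == len(edges) - 1")
    if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("class fractions must be non-negative and sum to 1")

    from .phenotype import MultispectralStack  # local import avoids cycles

    n_pixels = int(np.prod(shape))
    quota = fractions * n_pixels
    counts = np.floor(quota).astype(int)
    remainder = n_pixels - counts.sum()
    order = np.argsort(-(quota - counts))  # largest remainder first
    counts[order[:remainder]] += 1

    mids = (edges[:-1] + edges[1:]) / 2.0
    values = np.repeat(mids, counts)
    rng = np.random.default_rng(seed)
    values = values[rng.permutation(n_pixels)].reshape(shape)

    mask = np.ones(shape, dtype=bool)
    if index == "fvfm":
        fm = np.full(shape, 2000.0)
        f0 = fm * (1.0 - values)
        bands = {"F0": f0, "Fm": fm}
    elif index == "ari":
        if (values <= -1.0).any():
            raise ValueError("ari profile values must exceed -1")
        r700 = np.full(shape, 0.5)
        rnir = np.full(shape, 0.5)
        r550 = 1.0 / (2.0 * values + 2.0)
        bands = {"R550": r550, "R700": r700, "RNIR": rnir}
    else:
        raise ValueError(f"unknown index {index!r}")
    return MultispectralStack(bands=bands, mask=mask)


def generate_fw_table(
    group_means: Mapping[str, float],
    group_sds: Mapping[str, float] | float,
    n_per_group: Mapping[str, int] | int,
    seed: int,
) -> pd.DataFrame:
    """Shoot fresh-weight table (columns treatment, replicate, fw_mg).

    Gaussian per-group sampling; sd = 0 reproduces the group mean exactly.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for label in group_means:
        sd = group_sds[label] if isinstance(group_sds, Mapping) else float(group_sds)
        n = n_per_group[label] if isinstance(n_per_group, Mapping) else int(n_per_group)
        if sd < 0:
            raise ValueError(f"sd must be >= 0 for group {label!r}")
        if n < 1:
            raise ValueError(f"n must be >= 1 for group {label!r}")
        values = group_means[label] + rng.normal(0.0, 1.0, size=n) * sd
        for rep, fw in enumerate(values, start=1):
            rows.append({"treatment": label, "replicate": rep, "fw_mg": float(fw)})
    return pd.DataFrame(rows, columns=["treatment", "replicate", "fw_mg"])
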