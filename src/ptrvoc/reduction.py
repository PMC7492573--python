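"""Per-sample reduction of PTR-TOF-MS traces to filtered net concentrations.

Each channel of a run is reduced to a single net concentration: the mean of
the first 60 sample cycles (after a 20-cycle stabilization skip) minus the
mean of the last 60 background (N2-only) cycles.  Channels are then flagged
and removed when

* the net concentration is not positive (``negative``),
* the m/z matches an exclusion-list species — primary ions, calibrant gas
  molecules, species with proton affinity below water's (``excluded``),
* the net concentration falls below the limit of quantification, defined as
  10 x the standard deviation of the background noise (``below_loq``), or
* the m/z lies outside the scanned window [15.993, 300.066] (``out_of_range``).

A channel is retained iff it carries no flag.  Cycle indexing is 1-based
("the first 60 cycles" are cycles 21-80 after the 20-cycle skip); the
background SD uses the population estimator (divisor n) because the LOQ
characterizes the noise of a fixed window rather than inferring a parent
population — both choices are configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import SampleRun

__all__ = [
    "ExclusionEntry",
    "ExclusionList",
    "ReductionConfig",
    "ReducedPeakTable",
    "default_exclusion_list",
    "average_sample_window",
    "average_background",
    "compute_loq",
    "reduce_run",
    "build_feature_matrix",
    "write_peak_table_csv",
    "read_peak_table_csv",
    "write_reduced_tsv",
    "read_reduced_tsv",
]

FLAG_NAMES = ("negative", "excluded", "below_loq", "out_of_range")


@dataclass(frozen=True)
class ExclusionEntry:
    mz: float
    tolerance: float
    reason: str

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("exclusion tolerance must be > 0")


@dataclass
class ExclusionList:
    entries: tuple[ExclusionEntry, ...] = ()

    def matches(self, mz: float) -> bool:
        return any(abs(mz - e.mz) <= e.tolerance for e in self.entries)


def default_exclusion_list(tolerance: float = 0.005) -> ExclusionList:
    """Shipped defaults: primary ions, calibrant-gas and low-proton-affinity
    species.  The instrument-specific list is user-overridable."""
    species = [
        (19.018, "primary ion H3O+"),
        (37.028, "primary-ion water cluster (H2O)H3O+"),
        (55.039, "primary-ion water cluster (H2O)2H3O+"),
        (31.989, "primary ion O2+"),
        (29.997, "primary ion NO+"),
        (44.998, "CO2H+ (proton affinity below water)"),
        (46.005, "NO2H+ (proton affinity below water)"),
        (203.943, "calibrant-gas fragment (1,3-diiodobenzene)"),
    ]
    return ExclusionList(tuple(ExclusionEntry(mz, tolerance, reason) for mz, reason in species))


@dataclass
class ReductionConfig:
    skip_cycles: int = 20
    sample_window: int = 60
    background_window: int = 60
    loq_factor: float = 10.0
    mz_min: float = 15.993
    mz_max: float = 300.066
    exclusion: ExclusionList = field(default_factory=default_exclusion_list)
    sd_ddof: int = 0  # population SD for the background-noise estimate

    def __post_init__(self) -> None:
        if min(self.skip_cycles, 0) < 0 or self.sample_window < 1 or self.background_window < 1:
            raise ValueError("window counts must be >= 1 (skip >= 0)")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.loq_factor <= 0:
            raise ValueError("loq_factor must be > 0")


@dataclass
class ReducedPeakTable:
    """Per-channel reduction result for one sample.

    ``table`` is indexed by channel_id with columns mz, background_mean,
    background_sd, sample_mean, net_conc, loq, flags (frozenset), retained.
    """

    sample_id: str
    table: pd.DataFrame

    @property
    def retained_ids(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def flag_counts(self) -> dict[str, int]:
        return {
            name: int(self.table["flags"].apply(lambda f: name in f).sum())
            for name in FLAG_NAMES
        }


def _sample_block(run: SampleRun, channel: str) -> np.ndarray:
    return run.sample[channel].to_numpy(dtype=float)


def average_sample_window(run: SampleRun, channel: str, config: ReductionConfig) -> float:
    """Mean over sample cycles skip+1 .. skip+window (1-based, inclusive)."""
    values = _sample_block(run, channel)
    needed = config.skip_cycles + config.sample_window
    if len(values) < needed:
        raise ValueError(
            f"sample block of {len(values)} cycles is shorter than "
            f"skip + window = {needed}"
        )
    return float(values[config.skip_cycles : needed].mean())


def average_background(
    run: SampleRun, channel: str, config: ReductionConfig
) -> tuple[float, float]:
    """Mean and SD over the last ``background_window`` background cycles."""
    values = run.background[channel].to_numpy(dtype=float)
    if len(values) < config.background_window:
        raise ValueError(
            f"background block of {len(values)} cycles is shorter than "
            f"window = {config.background_window}"
        )
    window = values[-config.background_window :]
    return float(window.mean()), float(window.std(ddof=config.sd_ddof))


def compute_loq(background_sd: float, config: ReductionConfig | None = None) -> float:
    """Limit of quantification: loq_factor (default 10) x background SD."""
    if background_sd < 0:
        raise ValueError("background SD must be >= 0")
    factor = 10.0 if config is None else config.loq_factor
    return factor * background_sd


def reduce_run(run: SampleRun, config: ReductionConfig | None = None) -> ReducedPeakTable:
    """Reduce every channel of a run and apply the full filter rule set."""
    config = config or ReductionConfig()
    n_sm = len(run.sample)
    n_bg = len(run.background)
    if n_sm < config.skip_cycles + config.sample_window:
        raise ValueError("sample block too short for skip + averaging window")
    if n_bg < config.background_window:
        raise ValueError("background block too short for averaging window")

    sm = run.sample.to_numpy(dtype=float)
    bg = run.background.to_numpy(dtype=float)
    sample_mean = sm[config.skip_cycles : config.skip_cycles + config.sample_window].mean(axis=0)
    bg_window = bg[-config.background_window :]
    bg_mean = bg_window.mean(axis=0)
    bg_sd = bg_window.std(axis=0, ddof=config.sd_ddof)
    net = sample_mean - bg_mean
    loq = config.loq_factor * bg_sd
    mz = run.channel_mz.reindex(run.channels).to_numpy(dtype=float)

    rows = []
    for j, cid in enumerate(run.channels):
        flags = set()
        if net[j] <= 0:
            flags.add("negative")
        if net[j] < loq[j]:
            flags.add("below_loq")
        if not (config.mz_min <= mz[j] <= config.mz_max):
            flags.add("out_of_range")
        if config.exclusion.matches(mz[j]):
            flags.add("excluded")
        rows.append(
            {
                "mz": mz[j],
                "background_mean": bg_mean[j],
                "background_sd": bg_sd[j],
                "sample_mean": sample_mean[j],
                "net_conc": net[j],
                "loq": loq[j],
                "flags": frozenset(flags),
                "retained": not flags,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(run.channels, name="channel_id"))
    return ReducedPeakTable(sample_id=run.sample_id, table=table)


def build_feature_matrix(
    tables: Sequence[ReducedPeakTable],
    sample_labels: Mapping[str, str] | None = None,
):
    """Samples x compounds matrix over channels retained in >= 1 sample.

    A channel filtered out of a given sample keeps its (possibly sub-LOQ or
    negative) net concentration where computable, else 0 — this preserves the
    geometry the ordination sees.  Rows are ordered by sample_id, columns by
    ascending m/z (ties by channel id).

    ``sample_labels`` maps sample_id to a category (plant / fungal /
    cocultivation); it is required to build a matrix usable by the selection
    stage and defaults to empty labels.
    """
    from .selection import FeatureMatrix  # deferred: selection imports reduction lazily

    if len(tables) < 2:
        raise ValueError("need at least 2 samples")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_ids: {sorted(ids)}")

    union: dict[str, float] = {}
    for t in tables:
        for cid in t.retained_ids:
            union.setdefault(cid, float(t.table.at[cid, "mz"]))
    columns = sorted(union, key=lambda cid: (union[cid], cid))

    by_sample = sorted(tables, key=lambda t: t.sample_id)
    values = np.zeros((len(by_sample), len(columns)))
    for i, t in enumerate(by_sample):
        net = t.table["net_conc"]
        for j, cid in enumerate(columns):
            if cid in net.index and np.isfinite(net[cid]):
                values[i, j] = net[cid]
    df = pd.DataFrame(values, index=[t.sample_id for t in by_sample], columns=columns)
    labels = pd.Series(
        {t.sample_id: (sample_labels or {}).get(t.sample_id, "") for t in by_sample}
    ).loc[df.index]
    mz_map = pd.Series(union).loc[columns]
    return FeatureMatrix(values=df, sample_labels=labels, compound_mz=mz_map)


# ---------------------------------------------------------------------------
# Text I/O: the peak-table CSV dialect and reduced-table TSV
# ---------------------------------------------------------------------------

PEAK_TABLE_HEADER = ["sample_id", "segment", "cycle", "mz", "concentration_ppb"]


def write_peak_table_csv(runs: SampleRun | Iterable[SampleRun], path) -> None:
    """Long-format CSV: sample_id,segment,cycle,mz,concentration_ppb.

    segment is 'background' or 'sample'; cycle is 1-based within its block;
    mz is fixed 3-decimal.  UTF-8 with LF line endings.
    """
    if isinstance(runs, SampleRun):
        runs = [runs]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PEAK_TABLE_HEADER)
        for run in runs:
            for segment, block in (("background", run.background), ("sample", run.sample)):
                mzs = [f"{run.channel_mz[c]:.3f}" for c in block.columns]
                for cycle, row in zip(block.index, block.to_numpy()):
                    for mz_str, conc in zip(mzs, row):
                        writer.writerow([run.sample_id, segment, cycle, mz_str, repr(float(conc))])


def read_peak_table_csv(path, labels: Mapping[str, str] | None = None) -> list[SampleRun]:
    """Read the peak-table CSV back into SampleRun objects.

    ``labels`` optionally maps sample_id to a treatment/category label (the
    CSV itself carries no metadata).
    """
    df = pd.read_csv(path, dtype={"mz": str})
    missing = set(PEAK_TABLE_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"peak-table CSV missing columns: {sorted(missing)}")
    runs = []
    for sid, grp in df.groupby("sample_id", sort=True):
        blocks = {}
        for segment in ("background", "sample"):
            seg = grp[grp["segment"] == segment]
            blocks[segment] = seg.pivot(index="cycle", columns="mz", values="concentration_ppb")
        channels = sorted(blocks["sample"].columns, key=float)
        label = (labels or {}).get(str(sid), "")
        runs.append(
            SampleRun(
                sample_id=str(sid),
                treatment=label,
                category=label,
                background=blocks["background"][channels],
                sample=blocks["sample"][channels],
                channel_mz=pd.Series({c: float(c) for c in channels}),
            )
        )
    return runs


def write_reduced_tsv(reduced: ReducedPeakTable, path) -> None:
    out = reduced.table.copy()
    out["flags"] = out["flags"].apply(lambda f: ";".join(sorted(f)))
    out.insert(0, "sample_id", reduced.sample_id)
    out.to_csv(path, sep="\t", index=True, lineterminator="\n")


def read_reduced_tsv(path) -> ReducedPeakTable:
    df = pd.read_csv(path, sep="\t", index_col="channel_id", dtype={"channel_id": str})
    sample_id = str(df["sample_id"].iloc[0])
    df = df.drop(columns=["sample_id"])
    df.index = df.index.astype(str)
    df["flags"] = [
        frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
        for s in df["flags"]
    ]
    df["retained"] = df["retained"].astype(bool)
    return ReducedPeakTable(sample_id=sample_id, table=df)
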