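"""The NF-kB fingerprinting statistic.

A fingerprint is a pooled, isotype-corrected, z-standardised cells x
markers matrix: per-event background subtraction (isotype-control MFI per
channel), pooling of all cell populations to be compared, then one
z-standardisation per marker over the pooled events so that each marker
has mean 0 and SD 1 across the pool. The same statistic applies to flow
cytometry event tables and to simulated per-cell total protein abundances
(which need no isotype step).

Two distinct isotype procedures coexist, as in standard practice: the
sample-level MFI *ratio* (antibody MFI / isotype MFI) for reporting, and
the per-event *subtraction* of isotype MFI used when building
fingerprints. Negative post-subtraction values are preserved —
z-standardisation tolerates them and clipping would bias low expressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MARKERS = ("cRel", "RelA", "RelB")
CHANNEL_ROLES = (
    "FSC-A",
    "FSC-H",
    "SSC-A",
    "CD20",
    "CD38",
    "cRel",
    "RelA",
    "RelB",
    "pRelA",
)


class GatingError(RuntimeError):
    """No events survived gating; carries the per-gate attrition report."""


@dataclass(frozen=True)
class FlowEventTable:
    """Events x channels fluorescence table with stain metadata."""

    data: pd.DataFrame  # columns are channel roles
    sample_id: str
    stain: str = "antibody"  # "antibody" | "isotype"

    def __post_init__(self) -> None:
        if self.stain not in ("antibody", "isotype"):
            raise ValueError(f"stain must be antibody or isotype, got {self.stain!r}")
        unknown = set(self.data.columns) - set(CHANNEL_ROLES)
        if unknown:
            raise ValueError(f"unknown channel roles: {sorted(unknown)}")
        if (self.data < 0).any().any():
            raise ValueError("fluorescence intensities must be >= 0")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def subset(self, mask: np.ndarray) -> "FlowEventTable":
        return FlowEventTable(self.data.loc[mask].reset_index(drop=True), self.sample_id, self.stain)


@dataclass(frozen=True)
class GatingConfig:
    """Quantile-based gates on the synthetic channels; absolute bounds can
    be given instead by setting the *_abs fields."""

    lymphocyte_quantiles: tuple[float, float] = (0.01, 0.995)  # FSC-A and SSC-A band
    singlet_ratio_band: tuple[float, float] = (0.85, 1.15)  # FSC-H / FSC-A
    #: CD20-high threshold: "split" separates the log-CD20 distribution
    #: into two clusters (1-D 2-means) and cuts at the midpoint; a float is
    #: treated as a quantile; cd20_abs overrides with an absolute cut
    cd20_threshold: str | float = "split"
    lymphocyte_abs: tuple[float, float, float, float] | None = None  # fsc lo/hi, ssc lo/hi
    cd20_abs: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.lymphocyte_quantiles
        if not (0 <= lo < hi <= 1):
            raise ValueError("lymphocyte quantiles must be ordered in [0, 1]")
        rlo, rhi = self.singlet_ratio_band
        if not (0 < rlo < rhi):
            raise ValueError("singlet ratio band must be positive and ordered")


def _two_means_threshold(values: np.ndarray, tol: float = 1e-6, max_iter: int = 200) -> float:
    """Midpoint between the two clusters of log-intensity (1-D 2-means,
    deterministic percentile initialisation). Returns a linear-scale cut."""
    x = np.log(np.clip(values, 1e-9, None))
    c_lo, c_hi = np.percentile(x, [25, 75])
    for _ in range(max_iter):
        mid = (c_lo + c_hi) / 2
        lo, hi = x[x <= mid], x[x > mid]
        if lo.size == 0 or hi.size == 0:
            break
        new_lo, new_hi = lo.mean(), hi.mean()
        if abs(new_lo - c_lo) < tol and abs(new_hi - c_hi) < tol:
            c_lo, c_hi = new_lo, new_hi
            break
        c_lo, c_hi = new_lo, new_hi
    return float(np.exp((c_lo + c_hi) / 2))


def gate_b_cells(
    tbl: FlowEventTable, g: GatingConfig | None = None, cd20_gate: bool = False
) -> FlowEventTable:
    """Lymphocyte (FSC-A/SSC-A) then singlet (FSC-H/FSC-A) then optional
    CD20-high gating. Raises :class:`GatingError` with a per-gate attrition
    report if nothing survives."""
    g = g or GatingConfig()
    df = tbl.data
    report: dict[str, int] = {"input": len(df)}
    if g.lymphocyte_abs is not None:
        flo, fhi, slo, shi = g.lymphocyte_abs
    else:
        flo, fhi = df["FSC-A"].quantile(list(g.lymphocyte_quantiles))
        slo, shi = df["SSC-A"].quantile(list(g.lymphocyte_quantiles))
    mask = (
        df["FSC-A"].between(flo, fhi) & df["SSC-A"].between(slo, shi)
    ).to_numpy()
    report["lymphocyte"] = int(mask.sum())
    ratio = df["FSC-H"] / df["FSC-A"].replace(0, np.nan)
    mask &= ratio.between(*g.singlet_ratio_band).fillna(False).to_numpy()
    report["singlet"] = int(mask.sum())
    if cd20_gate:
        if g.cd20_abs is not None:
            thr = g.cd20_abs
        elif g.cd20_threshold == "split":
            thr = _two_means_threshold(df["CD20"].to_numpy())
        else:
            thr = df["CD20"].quantile(float(g.cd20_threshold))
        mask &= (df["CD20"] > thr).to_numpy()
        report["cd20_high"] = int(mask.sum())
    if not mask.any():
        raise GatingError(f"no events pass gating; attrition: {report}")
    return tbl.subset(mask)


def mfi(tbl: FlowEventTable, channel: str) -> float:
    """Median fluorescence intensity of one channel."""
    if tbl.n_events == 0:
        raise ValueError("empty event table")
    return float(tbl.data[channel].median())


def isotype_normalized_mfi(
    antibody_tbl: FlowEventTable, isotype_tbl: FlowEventTable, channel: str
) -> float:
    """Sample-level MFI ratio: MFI(antibody) / MFI(isotype)."""
    iso = mfi(isotype_tbl, channel)
    if iso == 0:
        raise ZeroDivisionError("isotype MFI is zero; ratio undefined")
    return mfi(antibody_tbl, channel) / iso


def isotype_correct_events(
    tbl: FlowEventTable, isotype_tbl: FlowEventTable, channels: Sequence[str] = MARKERS
) -> pd.DataFrame:
    """Per-event isotype subtraction: each channel minus that channel's
    isotype-control MFI. Negative values are preserved."""
    out = tbl.data.copy()
    for ch in channels:
        out[ch] = out[ch] - mfi(isotype_tbl, ch)
    return out


@dataclass(frozen=True)
class Fingerprint:
    """Pooled standardised cells x markers matrix with population labels."""

    values: pd.DataFrame  # columns = markers, z-scores
    labels: pd.Series  # population label per pooled cell

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("labels must match pooled cells")

    def median_by_population(self) -> pd.DataFrame:
        return self.values.groupby(self.labels.to_numpy()).median()

    def to_long(self) -> pd.DataFrame:
        long = self.values.copy()
        long["population"] = self.labels.to_numpy()
        long["cell_id"] = np.arange(len(long))
        return long.melt(
            id_vars=["cell_id", "population"], var_name="marker", value_name="z"
        )


def build_fingerprint(
    samples: Mapping[str, pd.DataFrame], markers: Sequence[str] = MARKERS
) -> Fingerprint:
    """Pool labelled (corrected) per-cell marker tables, then z-standardise.

    Pooling strictly precedes standardisation: one mean and SD per marker
    over *all* pooled cells (population SD, divisor n), so between-sample
    differences survive as shifted label-conditional distributions.
    """
    frames, labels = [], []
    for label, df in samples.items():
        frames.append(df.loc[:, list(markers)])
        labels.extend([label] * len(df))
    pooled = pd.concat(frames, ignore_index=True)
    if len(pooled) < 2:
        raise ValueError("need at least 2 pooled cells to standardise")
    mu = pooled.mean()
    sd = pooled.std(ddof=0)
    dead = sd[sd == 0]
    if not dead.empty:
        raise ValueError(f"zero pooled SD for marker(s) {list(dead.index)}; cannot standardise")
    return Fingerprint((pooled - mu) / sd, pd.Series(labels, name="population"))


def simulated_fingerprint(
    populations: Mapping[str, np.ndarray],
    spec,
    markers: Sequence[str] = MARKERS,
) -> Fingerprint:
    """Fingerprint of simulated populations from per-cell steady states.

    Each cell's marker value is its total subunit abundance (free + dimeric
    + complexed, both compartments). Simulation has no staining background,
    so there is no isotype step.
    """
    from .core_model import subunit_moiety_map

    moieties = subunit_moiety_map(spec)
    samples = {}
    for label, states in populations.items():
        states = np.asarray(states, dtype=float)
        if states.size == 0:
            raise ValueError(f"population {label!r} is empty")
        cols = {}
        for m in markers:
            idx = np.array([spec.species_index(s) for s in moieties[m]], dtype=np.intp)
            w = np.array(list(moieties[m].values()), dtype=float)
            cols[m] = states[:, idx] @ w
        samples[label] = pd.DataFrame(cols)
    return build_fingerprint(samples, markers)


@dataclass(frozen=True)
class SubcloneComparison:
    fold: float
    p_value: float  # two-sided Mann-Whitney on events
    n_high: int
    n_low: int
    channel: str


def gate_subclones(
    tbl: FlowEventTable, channel: str = "CD38", quantile: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Split gated events into channel-high / channel-low halves around the
    given quantile threshold; returns boolean masks (high, low)."""
    thr = tbl.data[channel].quantile(quantile)
    high = (tbl.data[channel] > thr).to_numpy()
    return high, ~high


def subclone_fold_change(
    tbl: FlowEventTable,
    isotype_tbl: FlowEventTable,
    channel: str,
    subclone_channel: str = "CD38",
    quantile: float = 0.5,
) -> SubcloneComparison:
    """Fold change in isotype-corrected MFI between two gated subclones.

    Ratio is (subclone-channel-high) over (low), e.g. CD38-high R1 over
    CD38-low R2. Significance is a two-sided Mann-Whitney U on the event
    distributions — the event-level test is reported alongside the effect
    size, never alone.
    """
    high, low = gate_subclones(tbl, subclone_channel, quantile)
    if not high.any() or not low.any():
        raise ValueError("empty subclone after gating")
    iso = mfi(isotype_tbl, channel)
    hi_vals = tbl.data.loc[high, channel].to_numpy()
    lo_vals = tbl.data.loc[low, channel].to_numpy()
    hi_mfi = float(np.median(hi_vals)) - iso
    lo_mfi = float(np.median(lo_vals)) - iso
    if lo_mfi == 0:
        raise ZeroDivisionError("low-subclone corrected MFI is zero")
    u = stats.mannwhitneyu(hi_vals, lo_vals, alternative="two-sided")
    return SubcloneComparison(
        fold=hi_mfi / lo_mfi,
        p_value=float(u.pvalue),
        n_high=int(high.sum()),
        n_low=int(low.sum()),
        channel=channel,
    )


def fingerprint_to_long(fp: Fingerprint) -> pd.DataFrame:
    """Long-format export: (cell_id, population, marker, z)."""
    return fp.to_long()
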