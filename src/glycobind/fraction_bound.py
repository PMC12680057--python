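"""Unification of heterogeneous binding data as fraction bound.

Microarray spot intensities (RFU) and literature affinity constants
(Ka/Kd) are put on a common footing: the fraction *f* ∈ [0, 1] of a
glycoconjugate occupied by protein at concentration *C*.

For arrays, each glycoconjugate's net RFU (foreground − background,
averaged over replicate spots) is rescaled linearly so that the
non-/weak-binder background peak — located by kernel density estimation on
the log-RFU axis — maps to zero, and the scanner maximum across all arrays
(65,536 by default) maps to one.  For affinities, the single-site occupancy
curve (Henderson-Hasselbalch form) f = C / (C + Kd) converts a constant to
a full dose–response profile.  Both are then resampled onto a shared
concentration grid by linear interpolation in log10(C) with constant
end-extrapolation.

Concentration units (μg/ml for arrays, μM for affinity data) are carried
explicitly and never silently interconverted — molar masses are not known
for all lectin preparations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KernelDensity

logger = logging.getLogger(__name__)

GLOBAL_MAX_RFU = 65_536.0


@dataclass
class CalibrationParams:
    """Per-array background peak and the global scanner maximum (RFU)."""

    background_peak: float
    global_max: float = GLOBAL_MAX_RFU

    def __post_init__(self) -> None:
        if not 0 <= self.background_peak < self.global_max:
            raise ValueError(
                f"background_peak must be in [0, global_max); got "
                f"{self.background_peak} vs {self.global_max}"
            )


@dataclass
class BindingRecord:
    """One (molecule, lectin group, concentration) fraction-bound value."""

    molecule_id: str
    lectin_group_id: str
    concentration: float
    unit: str
    fraction_bound: float
    source: str  # "array" | "affinity" | "simulated"

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_bound <= 1:
            raise ValueError(f"fraction_bound out of [0,1]: {self.fraction_bound}")
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive: {self.concentration}")


@dataclass
class AffinityRecord:
    """A published Ka or Kd.  Ka and Kd interconvert as reciprocals.

    ``unit`` is the concentration unit of the equivalent Kd; a Ka record
    with unit "uM" means Ka is expressed per μM.
    """

    molecule_id: str
    lectin_group_id: str
    value: float
    kind: str  # "Ka" | "Kd"
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"affinity must be positive: {self.value}")
        if self.kind not in ("Ka", "Kd"):
            raise ValueError(f"kind must be Ka or Kd: {self.kind}")

    @property
    def kd(self) -> float:
        return 1.0 / self.value if self.kind == "Ka" else self.value


@dataclass
class ConcentrationGrid:
    """Strictly increasing positive concentrations with a unit."""

    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) == 0:
            raise ValueError("empty concentration grid")
        if np.any(self.values <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LectinGroup:
    """Arrays sharing (cbpID, sample description, investigator)."""

    group_id: str
    cbp_id: str
    sample_description: str
    investigator: str
    array_ids: list[str] = field(default_factory=list)
    concentrations: list[float] = field(default_factory=list)
    unit: str = "ug/ml"


def summarize_spots(table: pd.DataFrame, expected_replicates: int = 6) -> dict[str, float]:
    """Mean net RFU (foreground − background) per glycoconjugate.

    Negative means are preserved at this stage; they are only clamped later
    during the rescale to fraction bound.  Glycoconjugates with fewer than
    ``expected_replicates`` spots are averaged over what is present, with a
    warning; zero replicates excludes the glycoconjugate.
    """
    required = {"glycoconjugate_id", "foreground", "background"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    net = table["foreground"].astype(float) - table["background"].astype(float)
    grouped = net.groupby(table["glycoconjugate_id"])
    sizes = grouped.size()
    short = sizes[sizes < expected_replicates]
    for gid, k in short.items():
        logger.warning("glycoconjugate %s has %d of %d replicates", gid, k, expected_replicates)
    return grouped.mean().to_dict()


def estimate_background_peak(
    rfus,
    cutoff: float = 4000.0,
    bandwidth: float = 0.2,
    global_max: float = GLOBAL_MAX_RFU,
    array_id: str = "",
    grid_points: int = 512,
) -> CalibrationParams:
    """Locate the non-/weak-binder RFU peak by Gaussian KDE.

    The density is estimated over log10 of the positive RFU values with the
    given bandwidth (on the log axis) and evaluated on a uniform log10 grid
    of ``grid_points`` spanning the data; the returned peak is the RFU
    location of the density maximum restricted to values below ``cutoff``,
    with ties broken toward the lower RFU.  Non-positive net RFUs carry no
    information about the background mode and are excluded from the density.
    """
    rfus = np.asarray(list(rfus), dtype=float)
    if len(rfus) < 10:
        raise ValueError(f"need at least 10 RFU values, got {len(rfus)} (array {array_id!r})")
    positive = rfus[rfus > 0]
    if len(positive) == 0:
        raise ValueError(f"no positive RFU values in array {array_id!r}")
    log_vals = np.log10(positive)
    lo, hi = log_vals.min(), log_vals.max()
    if lo == hi:  # degenerate: all values identical
        grid = np.array([lo])
    else:
        grid = np.linspace(lo, hi, grid_points)
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(log_vals[:, None])
    density = np.exp(kde.score_samples(grid[:, None]))
    below = grid < np.log10(cutoff)
    if not below.any():
        raise ValueError(f"no density mass below {cutoff} RFU in array {array_id!r}")
    masked = np.where(below, density, -np.inf)
    peak_rfu = float(10 ** grid[int(np.argmax(masked))])  # argmax takes lowest on ties
    return CalibrationParams(background_peak=peak_rfu, global_max=global_max)


def rfu_to_fraction(rfu: float, cal: CalibrationParams) -> float:
    """Linear rescale: background peak → 0, global maximum → 1, clamped.

    Values below the peak would rescale negative and are changed to zero.
    """
    f = (rfu - cal.background_peak) / (cal.global_max - cal.background_peak)
    return float(np.clip(f, 0.0, 1.0))


def group_arrays(metadata: pd.DataFrame, min_concentrations: int = 3) -> list[LectinGroup]:
    """Partition arrays by exact (cbpID, sample description, investigator).

    Groups with fewer than ``min_concentrations`` distinct concentrations
    are dropped (and reported): a binding curve needs at least that many
    points to constrain the concentration dependence.
    """
    required = {"array_id", "cbpID", "sample_description", "investigator", "concentration", "unit"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = metadata[["cbpID", "sample_description", "investigator"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"arrays with missing grouping fields: {metadata.loc[bad, 'array_id'].tolist()}"
        )
    groups: list[LectinGroup] = []
    dropped = 0
    for key, sub in metadata.groupby(["cbpID", "sample_description", "investigator"], sort=True):
        n_conc = sub["concentration"].nunique()
        if n_conc < min_concentrations:
            dropped += 1
            continue
        units = sub["unit"].unique()
        if len(units) > 1:
            raise ValueError(f"mixed concentration units within group {key}: {units}")
        groups.append(
            LectinGroup(
                group_id="|".join(str(k) for k in key),
                cbp_id=str(key[0]),
                sample_description=str(key[1]),
                investigator=str(key[2]),
                array_ids=sub["array_id"].tolist(),
                concentrations=sorted(sub["concentration"].unique().tolist()),
                unit=str(units[0]),
            )
        )
    if dropped:
        logger.info("group_arrays: dropped %d groups with < %d concentrations", dropped, min_concentrations)
    return groups


def resample_fractions(
    points: list[tuple[float, float]],
    grid: ConcentrationGrid,
    molecule_id: str = "",
    lectin_group_id: str = "",
    source: str = "array",
) -> list[BindingRecord]:
    """Interpolate measured (concentration, f) points onto a grid.

    Linear interpolation of f against log10(concentration); outside the
    measured range the nearest endpoint value is held constant (no sigmoid
    shape is assumed).  A single measured point therefore expands to a
    constant profile.  Outputs are clamped to [0, 1].
    """
    if not points:
        raise ValueError("need at least one measured point")
    pts = sorted(points)
    if any(c <= 0 for c, _ in pts):
        raise ValueError("measured concentrations must be positive")
    log_c = np.log10([c for c, _ in pts])
    f_vals = np.array([f for _, f in pts], dtype=float)
    interp = np.interp(np.log10(grid.values), log_c, f_vals)  # constant ends
    interp = np.clip(interp, 0.0, 1.0)
    return [
        BindingRecord(
            molecule_id=molecule_id,
            lectin_group_id=lectin_group_id,
            concentration=float(c),
            unit=grid.unit,
            fraction_bound=float(f),
            source=source,
        )
        for c, f in zip(grid.values, interp)
    ]


def affinity_to_fraction(aff: AffinityRecord, c: float, unit: str = "uM") -> float:
    """Single-site occupancy: f = C / (C + Kd), with Kd = 1/Ka for Ka records.

    Satisfies f(C=Kd) = 0.5 exactly and f → 0 as C → 0.
    """
    if unit != aff.unit:
        raise ValueError(f"unit mismatch: concentration in {unit!r}, affinity in {aff.unit!r}")
    if c <= 0:
        raise ValueError(f"concentration must be positive: {c}")
    return c / (c + aff.kd)


def build_concentration_grid(mantissas, decades, extra=(), unit: str = "uM") -> ConcentrationGrid:
    """Sorted deduplicated outer product mantissas × 10^decades, plus extras."""
    mantissas = list(mantissas)
    if not mantissas:
        raise ValueError("mantissas must be non-empty")
    if any(m <= 0 for m in mantissas):
        raise ValueError("mantissas must be positive")
    values = {m * 10.0**d for m in mantissas for d in decades}
    values.update(float(e) for e in extra)
    return ConcentrationGrid(values=np.array(sorted(values)), unit=unit)


def dense50_grid() -> ConcentrationGrid:
    """50-point grid: {1, 1.5, 2, 3, 4, 5, 7} × 10^{−5..1} plus 100 μM."""
    return build_concentration_grid([1, 1.5, 2, 3, 4, 5, 7], range(-5, 2), extra=[100.0], unit="uM")


def cfg_coarse_grid(unit: str = "ug/ml") -> ConcentrationGrid:
    """Default coarse grid 0.1, 1.0, 10.0, 100 (array concentrations)."""
    return ConcentrationGrid(values=np.array([0.1, 1.0, 10.0, 100.0]), unit=unit)
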