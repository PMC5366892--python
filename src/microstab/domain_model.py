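"""Core data types for microcosm community time series and treatment designs.

A *microcosm* is one laboratory container holding an assembled protist
community (green algae + heterotrophic protozoa).  Its census data form a
species x sampling-day density matrix (individuals/mL).  Treatments differ
only in how a fixed total amount of concentrated nutrient medium is pulsed
into the container over the 42-day run.

Densities are stored as real numbers, not integers: counting a 0.32 mL
subsample and rescaling to per-mL units produces non-integer densities
(multiples of 1/0.32).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "TrophicGroup",
    "Origin",
    "CommunityTimeSeries",
    "PulseSchedule",
    "StabilityRecord",
    "ValidationError",
    "read_community_csv",
    "write_community_csv",
    "subset_by_trophic",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["microcosm", "treatment", "day", "species", "trophic", "origin", "density"]


class ValidationError(ValueError):
    """Raised when input data violate the community-table contract."""


class Treatment(str, enum.Enum):
    """Resource-pulse treatment arms.

    The three high-magnitude arms (Early / Coincident / Late) receive the
    concentrated medium on two consecutive days; MultiPulses receives the
    same total volume spread over every day of the run; Control receives
    none.
    """

    CONTROL = "Control"
    EARLY = "Early"
    COINCIDENT = "Coincident"
    LATE = "Late"
    MULTI_PULSES = "MultiPulses"


class TrophicGroup(str, enum.Enum):
    ALGA = "alga"
    PROTOZOAN = "protozoan"


class Origin(str, enum.Enum):
    RESIDENT = "resident"
    INVADER = "invader"


@dataclass(frozen=True)
class CommunityTimeSeries:
    """One microcosm's species x sampling-day density matrix.

    Parameters
    ----------
    microcosm_id : str
        Unique identifier of the container.
    treatment : Treatment
        Resource-pulse arm the container was assigned to.
    sampling_days : tuple of int
        Strictly increasing days since community assembly (assembly = day 0).
    species_names : tuple of str
        Row labels of ``density``.
    trophic_group : mapping species -> TrophicGroup
    origin : mapping species -> Origin
    density : ndarray, shape (n_species, n_days)
        Non-negative densities in individuals/mL.
    """

    microcosm_id: str
    treatment: Treatment
    sampling_days: tuple[int, ...]
    species_names: tuple[str, ...]
    trophic_group: Mapping[str, TrophicGroup]
    origin: Mapping[str, Origin]
    density: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", dens)
        object.__setattr__(self, "sampling_days", tuple(int(d) for d in self.sampling_days))
        object.__setattr__(self, "species_names", tuple(self.species_names))
        if dens.shape != (len(self.species_names), len(self.sampling_days)):
            raise ValidationError(
                f"microcosm {self.microcosm_id!r}: density shape {dens.shape} does not match "
                f"{len(self.species_names)} species x {len(self.sampling_days)} days"
            )
        if not np.all(np.isfinite(dens)):
            raise ValidationError(f"microcosm {self.microcosm_id!r}: non-finite density values")
        if np.any(dens < 0):
            raise ValidationError(f"microcosm {self.microcosm_id!r}: negative density values")
        days = np.asarray(self.sampling_days)
        if len(days) and np.any(np.diff(days) <= 0):
            raise ValidationError(
                f"microcosm {self.microcosm_id!r}: sampling days must be strictly increasing"
            )
        for sp in self.species_names:
            if sp not in self.trophic_group:
                raise ValidationError(f"species {sp!r} has no trophic group label")
            if sp not in self.origin:
                raise ValidationError(f"species {sp!r} has no origin label")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_days(self) -> int:
        return len(self.sampling_days)

    def total_density(self) -> np.ndarray:
        """Total community density per sampling day (sum over species)."""
        return self.density.sum(axis=0)

    def species_density(self, species: str) -> np.ndarray:
        try:
            idx = self.species_names.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in microcosm {self.microcosm_id!r}") from None
        return self.density[idx]

    def select_species(self, names: Sequence[str]) -> "CommunityTimeSeries":
        """Return a copy restricted to ``names`` (given order preserved)."""
        if not names:
            raise ValidationError("cannot build a community time series with zero species")
        idx = [self.species_names.index(n) for n in names]
        return replace(
            self,
            species_names=tuple(names),
            trophic_group={n: self.trophic_group[n] for n in names},
            origin={n: self.origin[n] for n in names},
            density=self.density[idx],
        )

    def residents_only(self) -> "CommunityTimeSeries":
        names = [s for s in self.species_names if self.origin[s] is Origin.RESIDENT]
        return self.select_species(names)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with the canonical CSV columns."""
        rows = []
        for i, sp in enumerate(self.species_names):
            for j, day in enumerate(self.sampling_days):
                rows.append(
                    (
                        self.microcosm_id,
                        self.treatment.value,
                        day,
                        sp,
                        self.trophic_group[sp].value,
                        self.origin[sp].value,
                        self.density[i, j],
                    )
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass(frozen=True)
class PulseSchedule:
    """Per-day volumes (mL) of concentrated medium defining one treatment arm.

    ``concentration`` is the nutrient content of the concentrate expressed in
    units of standard-medium nutrient per mL, so that
    ``volume * concentration / microcosm_volume`` is the per-day increment to
    the microcosm nutrient concentration.
    """

    day_volumes: Mapping[int, float]
    concentration: float = 1.0

    def __post_init__(self) -> None:
        vols = dict(self.day_volumes)
        for day, v in vols.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"pulse volume on day {day} must be finite and >= 0, got {v}")
        object.__setattr__(self, "day_volumes", vols)

    @property
    def total_volume(self) -> float:
        return float(sum(self.day_volumes.values()))

    def volume_on(self, day: int) -> float:
        return float(self.day_volumes.get(day, 0.0))

    def equal_total(self, other: "PulseSchedule", tol: float = 1e-9) -> bool:
        """Whether two arms add the same total volume of concentrate."""
        return abs(self.total_volume - other.total_volume) <= tol


@dataclass(frozen=True)
class StabilityRecord:
    """Per-microcosm, per-trophic-subset derived stability metrics.

    ``temporal_stability`` is 1/CV; ``synchrony`` is the community-wide
    synchrony index phi in [0, 1] and ``asynchrony`` its complement.  Fields
    are None when the metric is undefined for that microcosm (e.g. synchrony
    with all-constant species series); the ``flags`` string records why.
    """

    microcosm_id: str
    treatment: Treatment
    trophic_subset: str  # "alga" | "protozoan" | "all"
    temporal_variability: float | None
    temporal_stability: float | None
    synchrony: float | None
    asynchrony: float | None
    dominance: float | None
    dominant_species: str | None
    dominant_species_variability: float | None
    richness: int
    flags: str = ""


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------


def _parse_enum(cls, value, row_label: str):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValidationError(f"{row_label}: unknown {cls.__name__} label {value!r} (allowed: {allowed})")


def read_community_csv(path: str | Path, fill_zeros: bool = False) -> list[CommunityTimeSeries]:
    """Read a long-format community count table into CommunityTimeSeries objects.

    The file must have the header ``microcosm,treatment,day,species,trophic,
    origin,density``.  Every (species, day) cell must be present for each
    microcosm: the counting protocol censuses all species on each occasion,
    so a missing cell is a data error, not a zero.  Pass ``fill_zeros=True``
    to fill missing cells with 0 for external data known to omit zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"microcosm": str, "species": str}, float_precision="round_trip")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")

    out: list[CommunityTimeSeries] = []
    for mid, grp in df.groupby("microcosm", sort=False):
        treatments = grp["treatment"].unique()
        if len(treatments) != 1:
            raise ValidationError(f"microcosm {mid!r}: multiple treatment labels {list(treatments)}")
        treatment = _parse_enum(Treatment, treatments[0], f"microcosm {mid!r}")

        neg = grp[grp["density"] < 0]
        if not neg.empty:
            r = neg.iloc[0]
            raise ValidationError(
                f"microcosm {mid!r}: negative density {r['density']} for species "
                f"{r['species']!r} on day {int(r['day'])}"
            )

        days = sorted(grp["day"].astype(int).unique())
        species = list(dict.fromkeys(grp["species"]))  # first-appearance order

        trophic: dict[str, TrophicGroup] = {}
        origin: dict[str, Origin] = {}
        for sp, sub in grp.groupby("species", sort=False):
            tlabels = sub["trophic"].unique()
            olabels = sub["origin"].unique()
            if len(tlabels) != 1 or len(olabels) != 1:
                raise ValidationError(f"microcosm {mid!r}: inconsistent labels for species {sp!r}")
            trophic[sp] = _parse_enum(TrophicGroup, tlabels[0], f"species {sp!r}")
            origin[sp] = _parse_enum(Origin, olabels[0], f"species {sp!r}")

        wide = grp.pivot_table(index="species", columns="day", values="density", aggfunc="first")
        wide = wide.reindex(index=species, columns=days)
        if wide.isna().any().any():
            if fill_zeros:
                wide = wide.fillna(0.0)
            else:
                cells = [
                    f"({sp}, day {int(day)})"
                    for sp, row in wide.iterrows()
                    for day, v in row.items()
                    if pd.isna(v)
                ]
                raise ValidationError(
                    f"microcosm {mid!r}: missing (species, day) cells: " + ", ".join(cells)
                )

        dup = grp.duplicated(subset=["species", "day"])
        if dup.any():
            r = grp[dup].iloc[0]
            raise ValidationError(
                f"microcosm {mid!r}: duplicate cell for species {r['species']!r} day {int(r['day'])}"
            )

        out.append(
            CommunityTimeSeries(
                microcosm_id=str(mid),
                treatment=treatment,
                sampling_days=tuple(days),
                species_names=tuple(species),
                trophic_group=trophic,
                origin=origin,
                density=wide.to_numpy(dtype=float),
            )
        )
    return out


def write_community_csv(series: Iterable[CommunityTimeSeries], path: str | Path) -> None:
    """Write CommunityTimeSeries objects to the canonical long-format CSV.

    Densities are written with ``repr`` round-trip precision so that
    ``read_community_csv(write_community_csv(x)) == x`` bit-for-bit.
    """
    series = list(series)
    if not series:
        raise ValidationError("cannot write an empty list of community time series")
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def subset_by_trophic(series: CommunityTimeSeries, group: TrophicGroup | str) -> CommunityTimeSeries:
    """Restrict a community to one trophic group; ``"all"`` returns it unchanged."""
    if group == "all":
        return series
    group = TrophicGroup(group)
    names = [s for s in series.species_names if series.trophic_group[s] is group]
    if not names:
        raise ValidationError(
            f"microcosm {series.microcosm_id!r}: no species with trophic group {group.value!r}"
        )
    return series.select_species(names)
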