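"""Stratified rate tables: the interface between estimation and simulation.

A :class:`RateTable` stores, for each sex x education stratum, the MDD
prevalence at age 18 and piecewise-constant incidence and remittance hazards
(events per person-year) on a shared :class:`~mdd_lifecourse.bands.AgeBands`
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import AgeBands
from .exceptions import ConfigurationError

#: A stratum is identified by (sex, education_years), e.g. ("female", 10).
Stratum = tuple[str, int]

SEXES = ("female", "male")
EDUCATION_LOW = 10
EDUCATION_HIGH = 16
EDUCATION_LEVELS = (EDUCATION_LOW, EDUCATION_HIGH)

#: The four strata compared throughout: sex x (low, high) education.
DEFAULT_STRATA: tuple[Stratum, ...] = (
    ("female", EDUCATION_LOW),
    ("female", EDUCATION_HIGH),
    ("male", EDUCATION_LOW),
    ("male", EDUCATION_HIGH),
)


@dataclass
class RateTable:
    """Per-stratum age-18 prevalence plus banded incidence/remittance hazards.

    Parameters
    ----------
    bands:
        The age partition shared by all hazard vectors.
    incidence, remittance:
        Mapping stratum -> hazard per band (events/person-year).
    prevalence_at_18:
        Mapping stratum -> probability of being in the MDD state at age 18.
    provenance:
        Free-text origin tag: ``"empirical"``, ``"ground_truth"`` or
        ``"counterfactual:<factors>"``.
    """

    bands: AgeBands
    incidence: dict[Stratum, np.ndarray]
    remittance: dict[Stratum, np.ndarray]
    prevalence_at_18: dict[Stratum, float]
    provenance: str = "empirical"

    def __post_init__(self) -> None:
        nb = self.bands.n_bands
        strata = list(self.incidence)
        if set(self.remittance) != set(strata) or set(self.prevalence_at_18) != set(strata):
            raise ConfigurationError("incidence/remittance/prevalence_at_18: strata differ")
        for name, table in (("incidence", self.incidence), ("remittance", self.remittance)):
            for s, h in table.items():
                h = np.asarray(h, dtype=float)
                if h.shape != (nb,):
                    raise ConfigurationError(f"{name}[{s}]: expected {nb} band hazards")
                if not np.all(np.isfinite(h)) or np.any(h < 0):
                    raise ConfigurationError(f"{name}[{s}]: hazards must be finite and >= 0")
                table[s] = h
        for s, p in self.prevalence_at_18.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence_at_18[{s}]: must be in [0, 1]")

    @property
    def strata(self) -> list[Stratum]:
        return list(self.incidence)

    def has_stratum(self, stratum: Stratum) -> bool:
        return stratum in self.incidence

    def copy(self) -> "RateTable":
        return RateTable(
            bands=self.bands,
            incidence={s: h.copy() for s, h in self.incidence.items()},
            remittance={s: h.copy() for s, h in self.remittance.items()},
            prevalence_at_18=dict(self.prevalence_at_18),
            provenance=self.provenance,
        )

    def with_provenance(self, provenance: str) -> "RateTable":
        out = self.copy()
        out.provenance = provenance
        return out

    # ------------------------------------------------------------------ IO

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with band rows and one prevalence row per stratum."""
        rows = []
        for (sex, edu), inc in self.incidence.items():
            rem = self.remittance[(sex, edu)]
            for b in range(self.bands.n_bands):
                rows.append(
                    dict(
                        row_type="band",
                        stratum_sex=sex,
                        stratum_education=edu,
                        band_start=self.bands.starts[b],
                        band_end=self.bands.ends[b],
                        incidence_hazard=inc[b],
                        remittance_hazard=rem[b],
                        prevalence_at_18=np.nan,
                        provenance=self.provenance,
                    )
                )
            rows.append(
                dict(
                    row_type="prevalence",
                    stratum_sex=sex,
                    stratum_education=edu,
                    band_start=np.nan,
                    band_end=np.nan,
                    incidence_hazard=np.nan,
                    remittance_hazard=np.nan,
                    prevalence_at_18=self.prevalence_at_18[(sex, edu)],
                    provenance=self.provenance,
                )
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        # %.17g keeps the binary64 round trip exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RateTable":
        band_rows = frame[frame["row_type"] == "band"]
        prev_rows = frame[frame["row_type"] == "prevalence"]
        starts = np.sort(band_rows["band_start"].unique())
        ends = np.sort(band_rows["band_end"].unique())
        bands = AgeBands(tuple(starts) + (float(ends[-1]),))
        incidence: dict[Stratum, np.ndarray] = {}
        remittance: dict[Stratum, np.ndarray] = {}
        prevalence: dict[Stratum, float] = {}
        for (sex, edu), grp in band_rows.groupby(["stratum_sex", "stratum_education"], sort=False):
            grp = grp.sort_values("band_start")
            stratum = (str(sex), int(edu))
            incidence[stratum] = grp["incidence_hazard"].to_numpy(float)
            remittance[stratum] = grp["remittance_hazard"].to_numpy(float)
        for _, row in prev_rows.iterrows():
            prevalence[(str(row["stratum_sex"]), int(row["stratum_education"]))] = float(
                row["prevalence_at_18"]
            )
        provenance = str(frame["provenance"].iloc[0]) if "provenance" in frame else "empirical"
        return cls(bands, incidence, remittance, prevalence, provenance)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


#: Column mapping for externally deposited per-stratum rate files
#: (one CSV per quantity, wide by stratum).  Maps our column names onto the
#: deposited ones; pass a custom mapping if the external file differs.
DEPOSITED_COLUMN_MAP = {
    "age_group_start": "band_start",
    "age_group_end": "band_end",
    "sex": "stratum_sex",
    "education": "stratum_education",
    "incidence_rate": "incidence_hazard",
    "remission_rate": "remittance_hazard",
    "prevalence_18": "prevalence_at_18",
}


def load_deposited_rates(path, column_map=None, provenance: str = "empirical") -> RateTable:
    """Load a rate table from an externally deposited long-format CSV.

    The external schema is expected to carry one row per stratum x band with
    rate columns, plus per-stratum age-18 prevalence rows (``band_start``
    missing).  ``column_map`` renames external columns onto the package
    schema; defaults to :data:`DEPOSITED_COLUMN_MAP`.
    """
    frame = pd.read_csv(path).rename(columns=column_map or DEPOSITED_COLUMN_MAP)
    frame["row_type"] = np.where(frame["band_start"].isna(), "prevalence", "band")
    frame["provenance"] = provenance
    for col in ("incidence_hazard", "remittance_hazard", "prevalence_at_18"):
        if col not in frame:
            frame[col] = np.nan
    return RateTable.from_frame(frame)
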