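"""Facility registry: loading, validation, sender resolution, expected counts.

The registry is the system's master list of health facilities (HFs). Each
facility is identified downstream by the phone number of the handset it uses
to text reports, so phone uniqueness is a hard invariant. Facilities carry a
planned weekly session schedule (fixed-post and outreach) from which the
fleet's expected weekly report counts are derived.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FACILITY_TYPES = ("hospital", "urban_phc", "primary_hf")

#: Marker returned by :func:`resolve_sender` for unregistered phones.
UNKNOWN_SENDER = "__unknown_sender__"

REGISTRY_COLUMNS = [
    "facility_id",
    "name",
    "district",
    "facility_type",
    "phone",
    "planned_fixed_per_week",
    "planned_outreach_per_week",
    "active",
]


class RegistryError(ValueError):
    """Raised when a registry file violates a structural invariant."""


def normalize_phone(phone: str) -> str:
    """Normalize a sender phone to local digit form.

    Strips every non-digit character, then maps a leading Nigerian country
    code ``234`` to the local leading ``0`` so that ``+2348031112222`` and
    ``08031112222`` resolve to the same facility.
    """
    digits = re.sub(r"\D", "", str(phone))
    if digits.startswith("234") and len(digits) > 10:
        digits = "0" + digits[3:]
    return digits


@dataclass(frozen=True)
class HealthFacility:
    facility_id: str
    name: str
    district: str
    facility_type: str
    phone: str
    planned_fixed_per_week: int
    planned_outreach_per_week: int
    active: bool = True

    def __post_init__(self) -> None:
        if self.facility_type not in FACILITY_TYPES:
            raise RegistryError(
                f"{self.facility_id}: unknown facility_type {self.facility_type!r}"
            )
        if self.planned_fixed_per_week < 0 or self.planned_outreach_per_week < 0:
            raise RegistryError(f"{self.facility_id}: negative planned sessions")
        if self.active and self.planned_fixed_per_week < 1:
            # National policy: every active facility holds at least one
            # fixed-post session per week.
            raise RegistryError(
                f"{self.facility_id}: active facility must plan >=1 fixed session/week"
            )


@dataclass
class Registry:
    facilities: list[HealthFacility]
    phone_index: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        for fac in self.facilities:
            key = normalize_phone(fac.phone)
            if key in index:
                raise RegistryError(
                    f"duplicate phone {fac.phone!r} shared by facilities "
                    f"{index[key]!r} and {fac.facility_id!r}"
                )
            index[key] = fac.facility_id
        self.phone_index = index

    def __len__(self) -> int:
        return len(self.facilities)

    def __iter__(self):
        return iter(self.facilities)

    def get(self, facility_id: str) -> HealthFacility:
        for fac in self.facilities:
            if fac.facility_id == facility_id:
                return fac
        raise KeyError(facility_id)

    @property
    def n_selected(self) -> int:
        """All registry rows — the denominator for participation."""
        return len(self.facilities)

    @property
    def n_active(self) -> int:
        """Facilities actually included in the pilot (``active`` flag)."""
        return sum(1 for f in self.facilities if f.active)

    @property
    def active_facilities(self) -> list[HealthFacility]:
        return [f for f in self.facilities if f.active]

    def counts_by_district(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for fac in self.facilities:
            out[fac.district] = out.get(fac.district, 0) + 1
        return out

    def counts_by_type(self, active_only: bool = False) -> dict[str, int]:
        out = {t: 0 for t in FACILITY_TYPES}
        for fac in self.facilities:
            if active_only and not fac.active:
                continue
            out[fac.facility_type] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "facility_id": f.facility_id,
                    "name": f.name,
                    "district": f.district,
                    "facility_type": f.facility_type,
                    "phone": f.phone,
                    "planned_fixed_per_week": f.planned_fixed_per_week,
                    "planned_outreach_per_week": f.planned_outreach_per_week,
                    "active": f.active,
                }
            for f in self.facilities],
            columns=REGISTRY_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected weekly report counts, per facility and fleet-wide."""

    per_facility: dict[str, dict[str, int]]
    fleet_fixed_per_week: int
    fleet_outreach_per_week: int


_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


def _parse_active(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise RegistryError(f"unparseable active flag: {value!r}")


def load_registry(path: str | Path) -> Registry:
    """Load and validate a facility registry CSV.

    Rejects duplicate phones (naming both facilities), unknown facility
    types, and negative planned session counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"registry file missing columns: {missing}")
    facilities = [
        HealthFacility(
            facility_id=str(row.facility_id),
            name=str(row.name_),
            district=str(row.district),
            facility_type=str(row.facility_type),
            phone=str(row.phone),
            planned_fixed_per_week=int(row.planned_fixed_per_week),
            planned_outreach_per_week=int(row.planned_outreach_per_week),
            active=_parse_active(row.active),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    return Registry(facilities)


def resolve_sender(registry: Registry, phone: str) -> str:
    """Map a sender phone to a facility_id, or :data:`UNKNOWN_SENDER`.

    Unknown senders are data (the reject log records them), not faults.
    """
    return registry.phone_index.get(normalize_phone(phone), UNKNOWN_SENDER)


def expected_counts(registry: Registry) -> ExpectedCounts:
    """Weekly expected report counts from each facility's session schedule.

    Fleet totals sum over *active* facilities only; inactive (excluded)
    facilities contribute zero expectation but remain listed per-facility.
    """
    per: dict[str, dict[str, int]] = {}
    fixed_total = 0
    outreach_total = 0
    for fac in registry:
        per[fac.facility_id] = {
            "fixed": fac.planned_fixed_per_week,
            "outreach": fac.planned_outreach_per_week,
        }
        if fac.active:
            fixed_total += fac.planned_fixed_per_week
            outreach_total += fac.planned_outreach_per_week
    return ExpectedCounts(
        per_facility=per,
        fleet_fixed_per_week=fixed_total,
        fleet_outreach_per_week=outreach_total,
    )
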