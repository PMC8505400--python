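"""Parameter registry: standards, weights, reference values, sample validation.

The registry holds one :class:`ParameterSpec` per measured variable (unit,
permissible limit, optional MWQI assigned weight, optional ideal value for
pH/DO, optional Hakanson preindustrial reference value and toxic-response
coefficient) and the membership sets for the four indices.  Everything
downstream — index computation, comparison statistics, I/O validation —
resolves parameters through a :class:`StandardsTable`.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .errors import ConfigurationError, ValidationError

#: The three sampling windows of the study design this package models:
#: December 2019 (pre-lockdown), June 2020 (lockdown), November 2020 (unlock).
PHASES: tuple[str, ...] = ("pre_lockdown", "lockdown", "unlock")

#: Codes rated by deviation from an ideal value rather than a plain ratio.
IDEAL_VALUE_CODES = frozenset({"ph", "do"})


@dataclass(frozen=True)
class ParameterSpec:
    """Metadata for one measured water-quality variable.

    ``permissible_limit`` is the standard value S_i in the parameter's own
    unit; ``assigned_weight`` (AW) is only set for MWQI members;
    ``ideal_value`` (V_i) only for pH and DO; ``reference_value`` (C_n) and
    ``toxic_response`` (T_r) only for the ecological-risk metals.
    """

    code: str
    name: str
    unit: str
    permissible_limit: float | None = None
    assigned_weight: float | None = None
    ideal_value: float | None = None
    reference_value: float | None = None
    toxic_response: float | None = None
    standard_source: str | None = None

    def __post_init__(self) -> None:
        if self.permissible_limit is not None and self.permissible_limit <= 0:
            raise ConfigurationError(
                f"{self.code}: permissible_limit must be > 0, got {self.permissible_limit}"
            )
        if self.assigned_weight is not None and self.assigned_weight <= 0:
            raise ConfigurationError(
                f"{self.code}: assigned_weight must be > 0, got {self.assigned_weight}"
            )
        if (self.ideal_value is not None) != (self.code in IDEAL_VALUE_CODES):
            raise ConfigurationError(
                f"{self.code}: ideal_value is required for pH and DO and "
                "not allowed for any other parameter"
            )


@dataclass(frozen=True)
class StandardsTable:
    """All parameter specs plus the per-index membership sets."""

    parameters: Mapping[str, ParameterSpec]
    mwqi_set: tuple[str, ...]
    hpi_set: tuple[str, ...]
    ri_set: tuple[str, ...]
    tsi_set: tuple[str, ...]

    def __post_init__(self) -> None:
        for set_name in ("mwqi_set", "hpi_set", "ri_set", "tsi_set"):
            for code in getattr(self, set_name):
                if code not in self.parameters:
                    raise ConfigurationError(
                        f"{set_name} member {code!r} has no ParameterSpec"
                    )
        for code in self.mwqi_set:
            spec = self.parameters[code]
            if spec.assigned_weight is None:
                raise ConfigurationError(f"MWQI member {code} lacks assigned_weight")
            if spec.permissible_limit is None:
                raise ConfigurationError(f"MWQI member {code} lacks permissible_limit")
        for code in self.hpi_set:
            if self.parameters[code].permissible_limit is None:
                raise ConfigurationError(f"HPI member {code} lacks permissible_limit")
        for code in self.ri_set:
            spec = self.parameters[code]
            if spec.reference_value is None or spec.reference_value <= 0:
                raise ConfigurationError(f"RI member {code} lacks reference_value > 0")
            if spec.toxic_response is None or spec.toxic_response <= 0:
                raise ConfigurationError(f"RI member {code} lacks toxic_response > 0")

    def __getitem__(self, code: str) -> ParameterSpec:
        try:
            return self.parameters[code]
        except KeyError:
            raise ConfigurationError(f"unknown parameter code {code!r}") from None

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.parameters)

    def index_sets(self) -> dict[str, tuple[str, ...]]:
        return {
            "MWQI": self.mwqi_set,
            "HPI": self.hpi_set,
            "RI": self.ri_set,
            "TSI": self.tsi_set,
        }


@dataclass(frozen=True)
class SampleRecord:
    """One site × phase vector of measured concentrations.

    ``values`` maps parameter code to the measured value in the registry
    unit.  ``incomplete`` (filled in by :func:`validate_sample`) names the
    indices whose parameter set this record cannot serve; absence is
    recorded, never silently zero-filled.
    """

    site_id: str
    phase: str
    values: Mapping[str, float]
    collected: str | None = None
    incomplete: frozenset[str] = field(default_factory=frozenset)


def _spec_from_config(code: str, entry: Mapping[str, Any]) -> ParameterSpec:
    known = {
        "name", "unit", "permissible_limit", "assigned_weight",
        "ideal_value", "reference_value", "toxic_response", "standard_source",
    }
    unknown = set(entry) - known
    if unknown:
        raise ConfigurationError(f"{code}: unknown config fields {sorted(unknown)}")
    return ParameterSpec(code=code, **{k: entry[k] for k in known if k in entry})


def load_standards(source: str | Path | Mapping[str, Any] | None = None) -> StandardsTable:
    """Build a validated :class:`StandardsTable`.

    Parameters
    ----------
    source
        ``None`` for the packaged BIS/WHO defaults, a path to a YAML file,
        or an already-parsed mapping with ``parameters`` and ``sets`` keys.
    """
    if source is None:
        text = (
            importlib.resources.files("riverwq.data")
            .joinpath("default_standards.yaml")
            .read_text(encoding="utf-8")
        )
        config = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        config = source
    else:
        config = yaml.safe_load(Path(source).read_text(encoding="utf-8"))

    try:
        raw_params = config["parameters"]
        raw_sets = config["sets"]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(
            "standards config needs top-level 'parameters' and 'sets'"
        ) from exc

    parameters = {
        code: _spec_from_config(code, entry or {}) for code, entry in raw_params.items()
    }
    return StandardsTable(
        parameters=parameters,
        mwqi_set=tuple(raw_sets.get("mwqi", ())),
        hpi_set=tuple(raw_sets.get("hpi", ())),
        ri_set=tuple(raw_sets.get("ri", ())),
        tsi_set=tuple(raw_sets.get("tsi", ())),
    )


def standards_to_config(standards: StandardsTable) -> dict[str, Any]:
    """Inverse of :func:`load_standards`: a plain mapping that round-trips."""
    params: dict[str, Any] = {}
    for code, spec in standards.parameters.items():
        entry = {
            "name": spec.name,
            "unit": spec.unit,
            "permissible_limit": spec.permissible_limit,
            "assigned_weight": spec.assigned_weight,
            "ideal_value": spec.ideal_value,
            "reference_value": spec.reference_value,
            "toxic_response": spec.toxic_response,
            "standard_source": spec.standard_source,
        }
        params[code] = {k: v for k, v in entry.items() if v is not None}
    return {
        "parameters": params,
        "sets": {
            "mwqi": list(standards.mwqi_set),
            "hpi": list(standards.hpi_set),
            "ri": list(standards.ri_set),
            "tsi": list(standards.tsi_set),
        },
    }


def dump_standards(standards: StandardsTable, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(standards_to_config(standards), sort_keys=False),
        encoding="utf-8",
    )


def validate_sample(record: SampleRecord, standards: StandardsTable) -> SampleRecord:
    """Check physical invariants and record which indices the sample can serve.

    Raises :class:`ValidationError` for negative concentrations, pH outside
    [0, 14], or a non-positive Secchi depth.  Returns the record with its
    ``incomplete`` field listing every index whose parameter set is not
    fully present (e.g. ``"tsi incomplete"`` when chlorophyll-a is absent).
    """
    for code, value in record.values.items():
        if value is None:
            raise ValidationError(
                f"{record.site_id}/{record.phase}: {code} is None; omit absent values"
            )
        if code == "ph":
            if not 0.0 <= value <= 14.0:
                raise ValidationError(
                    f"{record.site_id}/{record.phase}: pH {value} outside [0, 14]"
                )
        elif code == "sd":
            if value <= 0:
                raise ValidationError(
                    f"{record.site_id}/{record.phase}: Secchi depth {value} must be > 0"
                )
        elif value < 0:
            raise ValidationError(
                f"{record.site_id}/{record.phase}: {code} = {value} is negative"
            )
    incomplete = frozenset(
        f"{name.lower()} incomplete"
        for name, members in standards.index_sets().items()
        if any(code not in record.values for code in members)
    )
    return replace(record, incomplete=incomplete)


def validate_samples(
    records: Iterable[SampleRecord], standards: StandardsTable
) -> list[SampleRecord]:
    return [validate_sample(r, standards) for r in records]
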