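"""The four water-quality indices and their qualitative classification schemes.

* **MWQI** — weighted-arithmetic water quality index: per-parameter quality
  ratings Q_i = (C_i/S_i)·100 (deviation-from-ideal form for pH and DO),
  weighted by relative weights RW_i = AW_i / ΣAW over 11 parameters.
* **HPI** — heavy-metal pollution index over 6 metals with unit weights
  W_i = 1/S_i, HPI = Σ W_i Q_i / Σ W_i.
* **RI** — Hakanson potential ecological risk: contamination factors
  C_f = C_s/C_n against preindustrial reference values, risk factors
  E_r = T_r·C_f, RI = Σ E_r over Cd, Pb, Cr, Zn.
* **TSI** — Carlson trophic state index averaging log transforms of Secchi
  depth (m), total phosphorus (µg/l) and chlorophyll-a (µg/l).

All index functions accept either a :class:`~riverwq.registry.SampleRecord`
or a plain code→value mapping (e.g. a vector of phase means — MWQI, HPI and
RI are linear in concentrations, so the index of a mean vector equals the
mean of per-sample indices).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import ClassificationError, ConfigurationError, IncompleteIndexError
from .registry import SampleRecord, StandardsTable

__all__ = [
    "IndexResult",
    "MetalRiskBreakdown",
    "relative_weights",
    "quality_rating",
    "mwqi",
    "hpi",
    "ecological_risk",
    "tsi",
    "classify_mwqi",
    "classify_hmi",
    "classify_ri",
    "classify_tsi",
    "CLASSIFIERS",
]


@dataclass(frozen=True)
class IndexResult:
    """An index value with its qualitative class for one sample.

    ``components`` maps parameter code to its sub-index contribution
    (MWQI: SI_i = RW_i·Q_i; RI: E_r per metal; TSI: the three Carlson
    component scores).  For MWQI and RI the components sum to ``value``.
    """

    index_name: str
    value: float
    class_label: str
    components: Mapping[str, float]
    site_id: str | None = None
    phase: str | None = None


@dataclass(frozen=True)
class MetalRiskBreakdown:
    """Per-metal Hakanson decomposition.

    ``contamination_factors`` holds C_f = C_s/C_n, ``risk_factors`` holds
    E_r = T_r·C_f; ``degree_of_contamination`` is Σ C_f and ``total_risk``
    is RI = Σ E_r.
    """

    concentrations: Mapping[str, float]
    contamination_factors: Mapping[str, float]
    risk_factors: Mapping[str, float]
    degree_of_contamination: float
    total_risk: float


def _as_values(sample: SampleRecord | Mapping[str, float]) -> Mapping[str, float]:
    return sample.values if isinstance(sample, SampleRecord) else sample


def _site_phase(sample) -> tuple[str | None, str | None]:
    if isinstance(sample, SampleRecord):
        return sample.site_id, sample.phase
    return None, None


def _require(values: Mapping[str, float], members, index_name: str) -> None:
    missing = [c for c in members if c not in values]
    if missing:
        raise IncompleteIndexError(
            f"{index_name} needs {', '.join(missing)}; not computed for this sample"
        )


def relative_weights(standards: StandardsTable) -> dict[str, float]:
    """Normalised MWQI weights RW_i = AW_i / Σ AW; they sum to 1."""
    if not standards.mwqi_set:
        raise ConfigurationError("mwqi_set is empty")
    total = sum(standards[c].assigned_weight for c in standards.mwqi_set)
    return {c: standards[c].assigned_weight / total for c in standards.mwqi_set}


def quality_rating(code: str, value: float, standards: StandardsTable) -> float:
    """Quality rating Q_i of one parameter.

    Ordinary parameters: Q_i = (C_i/S_i)·100.  pH and DO are rated by
    deviation from their ideal values (7.0 and 14.6 mg/l, 100% saturation
    at 23 °C): Q_i = ((C_i − V_i)/(S_i − V_i))·100, so the ideal scores 0
    and the permissible limit scores 100.
    """
    spec = standards[code]
    s = spec.permissible_limit
    if s is None:
        raise ConfigurationError(f"{code} has no permissible_limit; cannot rate")
    if spec.ideal_value is not None:
        v = spec.ideal_value
        if s == v:
            raise ZeroDivisionError(
                f"{code}: permissible limit equals ideal value {v}; rating undefined"
            )
        return (value - v) / (s - v) * 100.0
    return value / s * 100.0


def mwqi(
    sample: SampleRecord | Mapping[str, float], standards: StandardsTable
) -> IndexResult:
    """Modified water quality index: MWQI = Σ RW_i·Q_i over the 11 parameters."""
    values = _as_values(sample)
    _require(values, standards.mwqi_set, "MWQI")
    rw = relative_weights(standards)
    components = {
        c: rw[c] * quality_rating(c, values[c], standards) for c in standards.mwqi_set
    }
    value = sum(components.values())
    site, phase = _site_phase(sample)
    return IndexResult("MWQI", value, classify_mwqi(value), components, site, phase)


def hpi(
    sample: SampleRecord | Mapping[str, float], standards: StandardsTable
) -> IndexResult:
    """Heavy-metal pollution index: HPI = Σ W_i Q_i / Σ W_i with W_i = 1/S_i."""
    values = _as_values(sample)
    _require(values, standards.hpi_set, "HPI")
    weights = {c: 1.0 / standards[c].permissible_limit for c in standards.hpi_set}
    sub_indices = {
        c: values[c] / standards[c].permissible_limit * 100.0 for c in standards.hpi_set
    }
    total_w = sum(weights.values())
    value = sum(weights[c] * sub_indices[c] for c in standards.hpi_set) / total_w
    site, phase = _site_phase(sample)
    return IndexResult("HPI", value, classify_hmi(value), sub_indices, site, phase)


def ecological_risk(
    sample: SampleRecord | Mapping[str, float], standards: StandardsTable
) -> MetalRiskBreakdown:
    """Hakanson potential ecological risk over the four RI metals (µg/l)."""
    values = _as_values(sample)
    _require(values, standards.ri_set, "RI")
    conc = {c: float(values[c]) for c in standards.ri_set}
    cf = {c: conc[c] / standards[c].reference_value for c in standards.ri_set}
    er = {c: standards[c].toxic_response * cf[c] for c in standards.ri_set}
    return MetalRiskBreakdown(
        concentrations=conc,
        contamination_factors=cf,
        risk_factors=er,
        degree_of_contamination=sum(cf.values()),
        total_risk=sum(er.values()),
    )


def ri(
    sample: SampleRecord | Mapping[str, float], standards: StandardsTable
) -> IndexResult:
    """Ecological-risk breakdown wrapped as an :class:`IndexResult`."""
    breakdown = ecological_risk(sample, standards)
    site, phase = _site_phase(sample)
    return IndexResult(
        "RI",
        breakdown.total_risk,
        classify_ri(breakdown.total_risk),
        breakdown.risk_factors,
        site,
        phase,
    )


def tsi(sd_m: float, tp_ugl: float, chla_ugl: float) -> IndexResult:
    """Carlson trophic state index.

    TS(Sd) = 60.0 − 14.41·ln(Sd); TS(TP) = 14.42·ln(TP) + 4.15;
    TS(Chla) = 30.6 + 9.81·ln(Chla); TSI is the mean of the three.
    """
    for name, v in (("sd", sd_m), ("tp", tp_ugl), ("chla", chla_ugl)):
        if not v > 0:
            raise ValueError(f"TSI input {name} must be > 0 (log transform), got {v}")
    components = {
        "sd": 60.0 - 14.41 * math.log(sd_m),
        "tp": 14.42 * math.log(tp_ugl) + 4.15,
        "chla": 30.6 + 9.81 * math.log(chla_ugl),
    }
    value = sum(components.values()) / 3.0
    return IndexResult("TSI", value, classify_tsi(value), components)


def tsi_from(
    sample: SampleRecord | Mapping[str, float], standards: StandardsTable
) -> IndexResult:
    """TSI from a record/mapping holding the registry's tsi_set codes."""
    values = _as_values(sample)
    _require(values, standards.tsi_set, "TSI")
    result = tsi(values["sd"], values["tp"], values["chla"])
    site, phase = _site_phase(sample)
    return IndexResult(
        result.index_name, result.value, result.class_label, result.components,
        site, phase,
    )


# --- classification schemes -------------------------------------------------
# MWQI/HMI bands are lower-exclusive/upper-inclusive (the printed anchors are
# "excellent (≤ 50)" and "excellent (0–25)"); RI/TSI bands are lower-
# inclusive/upper-exclusive (printed anchors "< 150" and "< 30").  Each
# scheme partitions its domain with no gaps or overlaps.


def _check_finite(value: float, scheme: str) -> None:
    if not math.isfinite(value):
        raise ClassificationError(f"{scheme}: cannot classify non-finite value {value}")


def classify_mwqi(value: float) -> str:
    _check_finite(value, "MWQI")
    if value <= 50:
        return "excellent"
    if value <= 100:
        return "good"
    if value <= 200:
        return "poor"
    if value <= 300:
        return "very poor"
    return "unfit for drinking"


def classify_hmi(value: float) -> str:
    _check_finite(value, "HMI")
    if value < 0:
        raise ClassificationError(f"HMI: negative value {value}")
    if value <= 25:
        return "excellent"
    if value <= 50:
        return "good"
    if value <= 75:
        return "poor"
    if value <= 100:
        return "very poor"
    return "unfit for drinking"


def classify_ri(value: float) -> str:
    _check_finite(value, "RI")
    if value < 0:
        raise ClassificationError(f"RI: negative value {value}")
    if value < 150:
        return "Practically uncontaminated"
    if value < 300:
        return "Moderately contaminated"
    if value < 600:
        return "Heavily contaminated"
    return "Extremely contaminated"


def classify_tsi(value: float) -> str:
    _check_finite(value, "TSI")
    if value < 30:
        return "low oligotrophic"
    if value < 40:
        return "high oligotrophic"
    if value < 50:
        return "mesotrophic"
    if value < 60:
        return "low eutrophic"
    if value < 70:
        return "medium eutrophic"
    if value < 80:
        return "high eutrophic"
    return "very high eutrophic"


CLASSIFIERS = {
    "MWQI": classify_mwqi,
    "HPI": classify_hmi,
    "RI": classify_ri,
    "TSI": classify_tsi,
}

#: Ordered class labels per index, for class-percentage tables.
CLASS_ORDER = {
    "MWQI": ("excellent", "good", "poor", "very poor", "unfit for drinking"),
    "HPI": ("excellent", "good", "poor", "very poor", "unfit for drinking"),
    "RI": (
        "Practically uncontaminated",
        "Moderately contaminated",
        "Heavily contaminated",
        "Extremely contaminated",
    ),
    "TSI": (
        "low oligotrophic",
        "high oligotrophic",
        "mesotrophic",
        "low eutrophic",
        "medium eutrophic",
        "high eutrophic",
        "very high eutrophic",
    ),
}
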